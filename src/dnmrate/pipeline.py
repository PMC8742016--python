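"""End-to-end orchestration: simulate (or load) a pedigree dataset,
confirm paternity, detect candidates, account callable sites, estimate
the FNR by spike-in, and produce the corrected rate estimate."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .callable_sites import CallableSummary, callable_summary
from .detect import (
    CandidateMutation,
    DetectParams,
    FilterFunnel,
    detect_candidates,
    flag_comapping_context,
)
from .manifest import SampleManifest
from .paternity import PaternityReport, identify_father
from .rate import RateEstimate, estimate_rate
from .records import reindex_records
from .simulate import SimConfig, SimResult, simulate_pedigree
from .spikein import (
    EmpiricalADDistribution,
    FnrEstimate,
    build_ad_distributions,
    estimate_fnr,
    spike_dataset,
)


@dataclass
class PipelineResult:
    sim: SimResult
    manifest: SampleManifest  # father-confirmed
    paternity: PaternityReport | None
    candidates: list[CandidateMutation]
    funnel: FilterFunnel
    callable: CallableSummary
    ad_dist: EmpiricalADDistribution
    fnr: FnrEstimate
    rate: RateEstimate
    m: int


def mutation_count(candidates: list[CandidateMutation]) -> int:
    """m = carrier-events over unflagged candidates (two-carrier sites
    count twice; flagged sites await manual curation and are excluded)."""
    return sum(len(c.carriers) for c in candidates if not c.comapping_flag)


def run_pipeline(
    config: SimConfig,
    n_spike_per_focal: int = 1000,
    detect_params: DetectParams | None = None,
    run_paternity: bool = True,
    alpha: float = 0.05,
) -> PipelineResult:
    """Simulate one pedigree under ``config`` and run every analysis
    stage. The spike-in stream is seeded from the config seed so the
    whole run is reproducible from a single integer."""
    detect_params = detect_params or DetectParams()
    sim = simulate_pedigree(config)

    paternity = None
    if run_paternity and len(sim.manifest.candidate_fathers) > 1:
        paternity = identify_father(sim.records, sim.manifest, sim.ploidy_map)
        manifest = sim.manifest.confirm_father(paternity.father_id)
    else:
        manifest = sim.manifest.confirm_father(sim.truth.father_id)
    # drop distractor-male columns so record arrays track the manifest
    records = reindex_records(sim.records, sim.manifest, manifest)

    candidates, funnel = detect_candidates(
        records, manifest, sim.ploidy_map, detect_params
    )
    flag_comapping_context(candidates, records, manifest)
    csummary = callable_summary(
        sim.masks, manifest, records, candidates, sim.ploidy_map
    )

    dist = build_ad_distributions(records, manifest, sim.ploidy_map)
    spiked_records, spikes = spike_dataset(
        records,
        manifest,
        sim.ploidy_map,
        sim.masks,
        sim.depth_of,
        dist,
        n_per_focal=n_spike_per_focal,
        seed=np.random.SeedSequence((config.seed, 1)).generate_state(1)[0] % 2**31,
        min_focal_dp=detect_params.min_dp,
        error_rate=config.error_rate,
        min_call_depth=config.min_call_depth,
    )
    spike_candidates, _ = detect_candidates(
        spiked_records, manifest, sim.ploidy_map, detect_params
    )
    fnr = estimate_fnr(spikes, spike_candidates)

    m = mutation_count(candidates)
    rate = estimate_rate(
        m, csummary.total, fnr.inserted_callable, fnr.detected, alpha=alpha
    )
    return PipelineResult(
        sim=sim,
        manifest=manifest,
        paternity=paternity,
        candidates=candidates,
        funnel=funnel,
        callable=csummary,
        ad_dist=dist,
        fnr=fnr,
        rate=rate,
        m=m,
    )
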