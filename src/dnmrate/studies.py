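"""Pre-registered simulation studies exercising the pipeline.

These fix the study conditions (genome scale, pedigree design, noise
levels) used by the validation suite and the analysis drivers:

* ``paternity_study`` — the four-candidate-male design: can both the
  kinship rank test and the Mendelian concordance count recover the
  true father?
* ``recovery_study`` — toy-genome replicates scaled so a replicate
  carries ~8 expected detectable mutations: is the FNR-corrected
  estimator unbiased, and does its exact-Poisson CI cover the truth?
* ``fnr_consistency_study`` — does the spike-in FNR agree with the
  miss rate of genuinely planted mutations at matched depths?
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .manifest import AUTOSOME
from .paternity import identify_father
from .pipeline import run_pipeline
from .records import reindex_records
from .simulate import SimConfig, simulate_pedigree


def paternity_config(seed: int) -> SimConfig:
    """Single mating pair with four candidate males, 10 focal + 19
    bait offspring (the denser of the two study designs)."""
    return SimConfig(
        n_polymorphic_sites=1500,
        n_candidate_fathers=4,
        n_focal=10,
        n_bait=19,
        mu_true=0.0,
        artifact_site_rate=0.0,
        seed=seed,
    )


def paternity_study(n_seeds: int = 100, seed0: int = 0) -> pd.DataFrame:
    """Father recovery by both methods across seeded replicates."""
    rows = []
    for s in range(seed0, seed0 + n_seeds):
        sim = simulate_pedigree(paternity_config(s))
        report = identify_father(sim.records, sim.manifest, sim.ploidy_map)
        rows.append(
            {
                "seed": s,
                "true_father": sim.truth.father_id,
                "kinship_top": report.rank_test.top_candidate,
                "kinship_p": report.rank_test.p_values[report.rank_test.top_candidate],
                "mendelian_pick": report.concordance.selected_father,
            }
        )
    return pd.DataFrame(rows)


def recovery_config(seed: int, mu_true: float = 2e-6) -> SimConfig:
    """One 400 kb autosome, 6 focal + 6 bait: expected planted
    mutations 2 x 4e5 x mu x 6 ~ 9.6, of which ~8 land detectably."""
    return SimConfig(
        chromosomes=(("1", 400_000, AUTOSOME),),
        n_polymorphic_sites=200,
        n_candidate_fathers=1,
        n_focal=6,
        n_bait=6,
        artifact_site_rate=0.0,
        mu_true=mu_true,
        seed=seed,
    )


@dataclass
class RecoveryResult:
    replicates: pd.DataFrame
    mu_true: float

    @property
    def mean_mu(self) -> float:
        return float(self.replicates["mu"].mean())

    @property
    def mean_mu_uncorrected(self) -> float:
        return float(self.replicates["mu_uncorrected"].mean())

    @property
    def coverage(self) -> float:
        return float(self.replicates["covered"].mean())


def recovery_study(
    n_reps: int = 500,
    seed0: int = 0,
    mu_true: float = 2e-6,
    n_spike_per_focal: int = 50,
) -> RecoveryResult:
    """FNR-corrected estimator recovery over toy replicates; also
    tracks the uncorrected m/C rate, which should sit ~FNR low."""
    rows = []
    for s in range(seed0, seed0 + n_reps):
        cfg = recovery_config(s, mu_true)
        r = run_pipeline(cfg, n_spike_per_focal=n_spike_per_focal, run_paternity=False)
        rows.append(
            {
                "seed": s,
                "m": r.m,
                "fnr": r.fnr.fnr,
                "mu": r.rate.mu,
                "mu_uncorrected": r.m / r.callable.total,
                "ci_low": r.rate.ci_low,
                "ci_high": r.rate.ci_high,
                "covered": r.rate.ci_low <= mu_true <= r.rate.ci_high,
            }
        )
    return RecoveryResult(replicates=pd.DataFrame(rows), mu_true=mu_true)


def fnr_consistency_config(seed: int) -> SimConfig:
    """High planted-mutation load (for a tight truth miss rate) on one
    1 Mb autosome, study-like depth design."""
    return SimConfig(
        chromosomes=(("1", 1_000_000, AUTOSOME),),
        n_polymorphic_sites=500,
        n_candidate_fathers=1,
        n_focal=6,
        n_bait=10,
        artifact_site_rate=0.0,
        mu_true=2e-5,
        seed=seed,
    )


@dataclass
class FnrConsistencyResult:
    spike_fnr: float
    n_spikes_callable: int
    truth_miss_rate: float
    n_planted_callable: int

    @property
    def pooled_se(self) -> float:
        """Binomial standard error of the difference of the two rates."""
        f1, n1 = self.spike_fnr, self.n_spikes_callable
        f2, n2 = self.truth_miss_rate, self.n_planted_callable
        return float(np.sqrt(f1 * (1 - f1) / n1 + f2 * (1 - f2) / n2))


def fnr_consistency_study(
    n_seeds: int = 4, seed0: int = 0, n_spike_per_focal: int = 250
) -> FnrConsistencyResult:
    """Pooled spike-in FNR vs pooled truth miss rate at matched depths."""
    sp_miss = sp_n = tr_miss = tr_n = 0
    for s in range(seed0, seed0 + n_seeds):
        cfg = fnr_consistency_config(s)
        r = run_pipeline(cfg, n_spike_per_focal=n_spike_per_focal, run_paternity=False)
        sp_n += r.fnr.inserted_callable
        sp_miss += r.fnr.inserted_callable - r.fnr.detected
        # truth: planted mutations in focal carriers at callable sites
        man = r.manifest
        sim = r.sim
        recs = {
            rec.key(): rec
            for rec in reindex_records(sim.records, sim.manifest, man)
        }
        detected = {
            (c.chrom, c.pos, carrier) for c in r.candidates for carrier in c.carriers
        }
        focal_ids = {f.sample_id for f in man.focal}
        for mut in sim.truth.mutations:
            if mut.carrier_id not in focal_ids:
                continue
            rec = recs[(mut.chrom, mut.pos)]
            ci = man.index[mut.carrier_id]
            mi = man.index[man.mother.sample_id]
            fi = man.index[man.father.sample_id]
            callable_site = (
                rec.dp[ci] >= 10 and rec.dp[mi] >= 10 and rec.dp[fi] >= 10
            )
            if not callable_site:
                continue
            tr_n += 1
            tr_miss += (mut.chrom, mut.pos, mut.carrier_id) not in detected
    return FnrConsistencyResult(
        spike_fnr=sp_miss / sp_n,
        n_spikes_callable=sp_n,
        truth_miss_rate=tr_miss / tr_n,
        n_planted_callable=tr_n,
    )
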