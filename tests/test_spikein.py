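"""Empirical AD distributions, count-level spike-in, FNR arithmetic."""

import numpy as np
import pytest

from dnmrate import (
    DetectParams,
    build_ad_distributions,
    detect_candidates,
    estimate_fnr,
    fnr_from_counts,
    simulate_pedigree,
    spike_dataset,
)
from dnmrate.records import reindex_records
from dnmrate.simulate import SimConfig
from dnmrate.spikein import SpikeError


@pytest.fixture(scope="module")
def sim_setup():
    cfg = SimConfig(
        chromosomes=(("2", 200_000, "autosome"), ("X", 50_000, "X")),
        n_polymorphic_sites=3000,
        n_candidate_fathers=1,
        n_focal=4,
        n_bait=4,
        mu_true=0.0,
        artifact_site_rate=0.0,
        seed=5,
    )
    sim = simulate_pedigree(cfg)
    man = sim.manifest.confirm_father(sim.truth.father_id)
    recs = reindex_records(sim.records, sim.manifest, man)
    return cfg, sim, man, recs


class TestAdDistributions:
    def test_toy_table_uniform(self, manifest, ploidy_map, make_record):
        # three het observations at DP 12 with AD {5, 6, 7}
        recs = [
            make_record(
                pos=p,
                calls={
                    "mother": ((0, 0), 30, 0),
                    "dad": ((1, 1), 30, 30),
                    "focal1": ((0, 1), 12, a),
                },
            )
            for p, a in [(10, 5), (20, 6), (30, 7)]
        ]
        dist = build_ad_distributions(recs, manifest, ploidy_map)
        freqs = dist.frequencies(12)
        assert dist.n_observations(12) == 3
        np.testing.assert_allclose(freqs[[5, 6, 7]], 1 / 3)
        assert freqs.sum() == pytest.approx(1.0)

    def test_support_within_depth_and_means_near_half(self, sim_setup):
        _, sim, man, recs = sim_setup
        dist = build_ad_distributions(recs, man, sim.ploidy_map)
        checked = 0
        for d in range(10, 101):
            t = dist.tables[d]
            assert len(t) == d + 1  # support subset of [0, d]
            n = t.sum()
            if n >= 50:
                mean = (np.arange(d + 1) * t).sum() / n
                se = np.sqrt(d * 0.25 / n)
                assert abs(mean - d / 2) < 3 * se + 0.5, d
                checked += 1
        assert checked > 5

    def test_empty_bin_falls_back_to_binomial(self, manifest, ploidy_map):
        dist = build_ad_distributions([], manifest, ploidy_map)
        rng = np.random.default_rng(0)
        draws = [dist.sample(40, rng) for _ in range(300)]
        assert abs(np.mean(draws) - 20) < 1.0


class TestSpike:
    def test_counts_and_determinism(self, sim_setup):
        cfg, sim, man, recs = sim_setup
        dist = build_ad_distributions(recs, man, sim.ploidy_map)
        args = (recs, man, sim.ploidy_map, sim.masks, sim.depth_of, dist)
        spiked1, spikes1 = spike_dataset(*args, n_per_focal=50, seed=3)
        spiked2, spikes2 = spike_dataset(*args, n_per_focal=50, seed=3)
        assert len(spikes1) == 50 * len(man.focal)
        assert spikes1 == spikes2
        # distinct coordinates, autosomal only
        keys = [(s.chrom, s.pos) for s in spikes1]
        assert len(set(keys)) == len(keys)
        assert all(c != "X" for c, _ in keys)

    def test_only_spiked_entries_modified(self, sim_setup):
        cfg, sim, man, recs = sim_setup
        dist = build_ad_distributions(recs, man, sim.ploidy_map)
        spiked, spikes = spike_dataset(
            recs, man, sim.ploidy_map, sim.masks, sim.depth_of, dist,
            n_per_focal=30, seed=9,
        )
        spike_keys = {(s.chrom, s.pos) for s in spikes}
        originals = {r.key(): r for r in recs}
        for rec in spiked:
            if rec.key() in spike_keys:
                assert rec.key() not in originals  # new invariant coordinate
            else:
                orig = originals[rec.key()]
                assert rec.gts == orig.gts
                assert np.array_equal(rec.ad_alt, orig.ad_alt)

    def test_carrier_ad_from_empirical_table(self, sim_setup):
        """Degenerate table at N = 6 forces AD (6, DP-6)."""
        cfg, sim, man, recs = sim_setup
        from dnmrate.spikein import EmpiricalADDistribution

        tables = {d: np.zeros(d + 1, dtype=np.int64) for d in range(10, 101)}
        for d in range(10, 101):
            tables[d][min(6, d)] = 1
        dist = EmpiricalADDistribution(tables=tables)
        _, spikes = spike_dataset(
            recs, man, sim.ploidy_map, sim.masks, sim.depth_of, dist,
            n_per_focal=20, seed=2,
        )
        for s in spikes:
            if 10 <= s.dp <= 100:
                assert s.n_alt == 6

    def test_insufficient_coordinates_fatal(self, manifest, ploidy_map, make_record):
        from dnmrate import DepthMask
        from dnmrate.spikein import EmpiricalADDistribution

        tiny_masks = {
            s.sample_id: DepthMask(s.sample_id, {"2": [(0, 5)], "X": []})
            for s in manifest.samples
        }
        with pytest.raises(SpikeError):
            spike_dataset(
                [],
                manifest,
                ploidy_map,
                tiny_masks,
                lambda s, c, p: 20,
                EmpiricalADDistribution(),
                n_per_focal=10,
                seed=0,
            )


class TestFnr:
    def test_reported_fnr_arithmetic(self):
        assert round(100 * fnr_from_counts(9914, 7658), 1) == 22.8
        assert round(100 * fnr_from_counts(12724, 9563), 1) == 24.8
        assert fnr_from_counts(9914, 7658) == pytest.approx(2256 / 9914)

    def test_perfect_detection_zero_fnr(self):
        assert fnr_from_counts(100, 100) == 0.0

    def test_zero_callable_fatal(self):
        with pytest.raises(SpikeError):
            fnr_from_counts(0, 0)

    def test_monotone_under_band_tightening(self, sim_setup):
        """On a fixed spike set, narrowing the allele-balance band can
        only raise the FNR."""
        cfg, sim, man, recs = sim_setup
        dist = build_ad_distributions(recs, man, sim.ploidy_map)
        spiked, spikes = spike_dataset(
            recs, man, sim.ploidy_map, sim.masks, sim.depth_of, dist,
            n_per_focal=150, seed=4,
        )
        fnrs = []
        for lo, hi in [(0.05, 0.95), (0.27, 0.73), (0.40, 0.60)]:
            cands, _ = detect_candidates(
                spiked, man, sim.ploidy_map, DetectParams(aaf_low=lo, aaf_high=hi)
            )
            fnrs.append(estimate_fnr(spikes, cands).fnr)
        assert fnrs == sorted(fnrs)
        assert all(0 <= f <= 1 for f in fnrs)
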