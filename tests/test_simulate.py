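"""Generator correctness: determinism, Mendelian structure, planting
rates, depth/allele-depth models, and the ML genotype caller."""

import numpy as np
import pytest
from scipy.stats import binom, poisson

from dnmrate import SimConfig, call_genotype, simulate_pedigree
from dnmrate.manifest import AUTOSOME


def small_config(**kw):
    defaults = dict(
        chromosomes=(("2", 50_000, "autosome"), ("X", 20_000, "X")),
        n_polymorphic_sites=500,
        n_candidate_fathers=2,
        n_focal=3,
        n_bait=3,
        seed=11,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        a = simulate_pedigree(small_config(mu_true=1e-5))
        b = simulate_pedigree(small_config(mu_true=1e-5))
        assert a.truth.father_id == b.truth.father_id
        assert a.truth.mutations == b.truth.mutations
        assert len(a.records) == len(b.records)
        for ra, rb in zip(a.records, b.records):
            assert (ra.chrom, ra.pos, ra.ref, ra.alts) == (rb.chrom, rb.pos, rb.ref, rb.alts)
            assert ra.gts == rb.gts
            assert np.array_equal(ra.ad_alt, rb.ad_alt)
        for sid in a.masks:
            assert a.masks[sid] == b.masks[sid]

    def test_different_seed_differs(self):
        a = simulate_pedigree(small_config(seed=1))
        b = simulate_pedigree(small_config(seed=2))
        assert any(
            not np.array_equal(ra.ad_alt, rb.ad_alt)
            for ra, rb in zip(a.records, b.records)
        )


class TestPedigreeStructure:
    def test_null_case_plants_nothing(self):
        sim = simulate_pedigree(
            small_config(mu_true=0.0, error_rate=0.0, artifact_site_rate=0.0)
        )
        assert sim.truth.mutations == []

    def test_mendelian_consistency_of_true_genotypes(self):
        """At non-mutated autosomal sites every offspring carries one
        maternal and one paternal allele (exhaustive on a small genome)."""
        sim = simulate_pedigree(small_config(mu_true=0.0))
        man = sim.manifest
        mi = man.index["mother"]
        fi = man.index[sim.truth.father_id]
        for (chrom, pos), dose in sim.truth.true_dosage.items():
            dm, df = int(dose[mi]), int(dose[fi])
            for s in man.offspring:
                do = int(dose[man.index[s.sample_id]])
                if chrom == "X":
                    if s.sex == "male":  # maternal allele only
                        assert do in {1 if dm >= 1 else 0, 0 if dm <= 1 else 1}
                        continue
                    allowed = {
                        mt + df for mt in ({1} if dm == 2 else {0} if dm == 0 else {0, 1})
                    }
                else:
                    mat = {1} if dm == 2 else {0} if dm == 0 else {0, 1}
                    pat = {1} if df == 2 else {0} if df == 0 else {0, 1}
                    allowed = {a + b for a in mat for b in pat}
                assert do in allowed, (chrom, pos, s.sample_id)

    def test_planted_mutations_absent_from_parents(self):
        sim = simulate_pedigree(small_config(mu_true=2e-5))
        man = sim.manifest
        assert len(sim.truth.mutations) > 0
        for m in sim.truth.mutations:
            dose = sim.truth.true_dosage[(m.chrom, m.pos)]
            assert dose[man.index["mother"]] == 0
            assert dose[man.index[sim.truth.father_id]] == 0
            assert dose[man.index[m.carrier_id]] == 1
            assert dose.sum() == 1  # exactly one carrier

    def test_planted_count_matches_poisson_mean(self):
        """Expected autosomal plantings: 2 x genome x mu x n_offspring."""
        n_seeds, per_seed_mean = 20, 10.0
        total = 0
        for s in range(n_seeds):
            cfg = SimConfig(
                chromosomes=(("1", 500_000, AUTOSOME), ("2", 500_000, AUTOSOME)),
                n_polymorphic_sites=100,
                n_candidate_fathers=1,
                n_focal=10,
                n_bait=0,
                mu_true=5e-7,
                seed=s,
            )
            total += len(simulate_pedigree(cfg).truth.mutations)
        lo, hi = poisson.ppf([0.005, 0.995], n_seeds * per_seed_mean)
        assert lo <= total <= hi

    def test_planted_het_allele_balance_near_half(self):
        sim = simulate_pedigree(small_config(mu_true=5e-5, n_focal=6, n_bait=2))
        man = sim.manifest
        by_key = {r.key(): r for r in sim.records}
        fracs = []
        for m in sim.truth.mutations:
            if m.chrom == "X":
                continue
            rec = by_key[(m.chrom, m.pos)]
            ci = man.index[m.carrier_id]
            if rec.dp[ci] >= 10:
                fracs.append(rec.ad_alt[ci] / rec.dp[ci])
        assert len(fracs) > 30
        assert abs(np.mean(fracs) - 0.5) < 3 * np.std(fracs) / np.sqrt(len(fracs)) + 0.02

    def test_masks_agree_with_emitted_depths(self):
        sim = simulate_pedigree(small_config())
        man = sim.manifest
        for rec in sim.records[::17]:
            for i, s in enumerate(man.samples):
                assert (rec.dp[i] >= 10) == sim.masks[s.sample_id].contains_pos(
                    rec.chrom, rec.pos
                )

    def test_artifact_sites_shared_across_samples(self):
        cfg = small_config(mu_true=0.0, error_rate=0.0, artifact_site_rate=2e-4)
        sim = simulate_pedigree(cfg)
        # artifact sites are the emitted records with zero true dosage
        shared = 0
        n_art = 0
        for rec in sim.records:
            if sim.truth.true_dosage[rec.key()].sum() == 0 and rec.ad_alt.sum() > 0:
                n_art += 1
                shared += (rec.ad_alt > 0).sum() >= 2
        assert n_art > 0
        assert shared / n_art > 0.8  # share_prob 0.6 across 9 samples


class TestGenotypeCaller:
    def test_obvious_calls(self):
        assert call_genotype(30, 15, 0.002) == (0, 1)
        assert call_genotype(30, 0, 0.002) == (0, 0)
        assert call_genotype(30, 30, 0.002) == (1, 1)
        assert call_genotype(3, 1, 0.002) is None  # below min depth
        assert call_genotype(12, 12, 0.002, ploidy=1) == (1,)
        assert call_genotype(12, 0, 0.002, ploidy=1) == (0,)

    @pytest.mark.parametrize("eps", [0.002, 0.01])
    def test_matches_brute_force_likelihood(self, eps):
        """ML call equals argmax of the three binomial likelihoods."""
        gts = [(0, 0), (0, 1), (1, 1)]
        for dp in range(4, 16):
            for ad in range(dp + 1):
                liks = [binom.pmf(ad, dp, q) for q in (eps, 0.5, 1 - eps)]
                expected = gts[int(np.argmax(liks))]
                assert call_genotype(dp, ad, eps) == expected, (dp, ad)

    def test_specific_derived_example(self):
        # DP 12, AD 3, eps 0.01: enumerated likelihoods favour het
        liks = [binom.pmf(3, 12, q) for q in (0.01, 0.5, 0.99)]
        assert int(np.argmax(liks)) == 1
        assert call_genotype(12, 3, 0.01) == (0, 1)


class TestConfigValidation:
    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(error_rate=1.5)

    def test_too_many_polymorphic_sites_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(
                chromosomes=(("1", 100, "autosome"),), n_polymorphic_sites=1000
            )
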