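"""Four-criteria candidate filtering, funnel accounting, and the
co-mapping advisory flag."""

import random

import pytest

from dnmrate import DetectParams, detect_candidates, flag_comapping_context
from dnmrate.manifest import ManifestError


def detect(recs, manifest, ploidy_map, **kw):
    return detect_candidates(recs, manifest, ploidy_map, DetectParams(**kw))


class TestCriteria:
    def test_constructed_passing_site(self, manifest, ploidy_map, make_record):
        rec = make_record(calls={"focal1": ((0, 1), 20, 10)})
        cands, funnel = detect([rec], manifest, ploidy_map)
        assert len(cands) == 1
        assert cands[0].carriers == ("focal1",)
        assert funnel.counts["allele_balance"] == 1

    def test_published_carrier_allele_depths_pass_band(
        self, manifest, ploidy_map, make_record
    ):
        """AD 15/8 -> DP 23, AAF 0.348, bounds 6.21 <= 8 <= 16.79."""
        rec = make_record(calls={"focal2": ((0, 1), 23, 8)})
        cands, _ = detect([rec], manifest, ploidy_map)
        assert len(cands) == 1
        assert cands[0].carrier_ad_ref == (15,)
        assert cands[0].carrier_ad_alt == (8,)

    def test_single_bait_alt_read_vetoes(self, manifest, ploidy_map, make_record):
        rec = make_record(
            calls={"focal1": ((0, 1), 20, 10), "bait1": ((0, 0), 15, 1)}
        )
        cands, funnel = detect([rec], manifest, ploidy_map)
        assert cands == []
        assert funnel.counts["parents_homref_dp"] == 1
        assert funnel.counts["no_alt_in_bait"] == 0

    def test_allele_balance_boundary_exclusive_miss(
        self, manifest, ploidy_map, make_record
    ):
        # 8 < 0.27 x 30 = 8.1 -> rejected
        rec = make_record(calls={"focal1": ((0, 1), 30, 8)})
        cands, funnel = detect([rec], manifest, ploidy_map)
        assert cands == []
        assert funnel.counts["het_1or2_focal"] == 1
        assert funnel.counts["allele_balance"] == 0

    def test_allele_balance_boundary_inclusive_hit(
        self, manifest, ploidy_map, make_record
    ):
        # 27 = 0.27 x 100 exactly: inclusive bound keeps the site
        rec = make_record(calls={"focal1": ((0, 1), 100, 27)})
        cands, _ = detect([rec], manifest, ploidy_map)
        assert len(cands) == 1

    def test_parent_low_depth_rejected(self, manifest, ploidy_map, make_record):
        rec = make_record(
            calls={"mother": ((0, 0), 9, 0), "focal1": ((0, 1), 20, 10)}
        )
        cands, funnel = detect([rec], manifest, ploidy_map)
        assert cands == []
        assert funnel.counts["parents_homref_dp"] == 0

    def test_parent_missing_ad_rejected_conservatively(
        self, manifest, ploidy_map, make_record
    ):
        rec = make_record(
            calls={"mother": ((0, 0), 30, -1), "focal1": ((0, 1), 20, 10)}
        )
        cands, _ = detect([rec], manifest, ploidy_map)
        assert cands == []

    def test_uncalled_focal_rejected(self, manifest, ploidy_map, make_record):
        rec = make_record(
            calls={"focal1": ((0, 1), 20, 10), "focal2": (None, 3, 0)}
        )
        cands, funnel = detect([rec], manifest, ploidy_map)
        assert cands == []
        assert funnel.counts["called_in_every_focal"] == 0

    def test_uncalled_bait_does_not_veto(self, manifest, ploidy_map, make_record):
        rec = make_record(
            calls={"focal1": ((0, 1), 20, 10), "bait2": (None, 2, 0)}
        )
        cands, _ = detect([rec], manifest, ploidy_map)
        assert len(cands) == 1

    def test_three_carriers_rejected(self, ploidy_map, make_record):
        from dnmrate import Sample, SampleManifest

        man = SampleManifest(
            [
                Sample("mother", "mother", "female"),
                Sample("dad", "candidate_father", "male"),
                Sample("focal1", "focal", "female"),
                Sample("focal2", "focal", "female"),
                Sample("focal3", "focal", "female"),
            ]
        )
        from tests_helpers import make_record_for

        make = make_record_for(man)
        het = ((0, 1), 20, 10)
        rec = make(calls={"focal1": het, "focal2": het, "focal3": het})
        cands, funnel = detect_candidates([rec], man, ploidy_map)
        assert cands == []
        assert funnel.counts["het_1or2_focal"] == 0
        # two carriers pass by default, and both are recorded
        rec2 = make(calls={"focal1": het, "focal2": het})
        cands2, _ = detect_candidates([rec2], man, ploidy_map)
        assert cands2[0].carriers == ("focal1", "focal2")
        # ... unless the single-carrier switch is on
        cands3, _ = detect_candidates(
            [rec2], man, ploidy_map, DetectParams(allow_two_carriers=False)
        )
        assert cands3 == []

    def test_unconfirmed_father_is_fatal(self, manifest, ploidy_map, make_record):
        from dnmrate import Sample, SampleManifest

        two_dads = SampleManifest(
            manifest.samples + [Sample("dad2", "candidate_father", "male")]
        )
        with pytest.raises(ManifestError):
            detect_candidates([make_record()], two_dads, ploidy_map)


class TestMaleXHemizygosity:
    @pytest.mark.parametrize("gt", [(1,), (1, 1)])
    def test_hemizygous_alt_codings_accepted(self, manifest, ploidy_map, make_record, gt):
        # male focal2 on X: full-alt call, band not applicable
        rec = make_record(chrom="X", calls={"focal2": (gt, 14, 14)})
        cands, _ = detect([rec], manifest, ploidy_map)
        assert len(cands) == 1
        assert cands[0].carrier_sexes == ("male",)

    def test_male_x_het_call_discards_site(self, manifest, ploidy_map, make_record):
        rec = make_record(chrom="X", calls={"focal2": ((0, 1), 20, 10)})
        cands, _ = detect([rec], manifest, ploidy_map)
        assert cands == []

    def test_female_x_carrier_needs_band(self, manifest, ploidy_map, make_record):
        good = make_record(chrom="X", pos=100, calls={"focal1": ((0, 1), 20, 10)})
        bad = make_record(chrom="X", pos=200, calls={"focal1": ((0, 1), 20, 3)})
        cands, _ = detect([good, bad], manifest, ploidy_map)
        assert [c.pos for c in cands] == [100]


class TestFunnelProperties:
    def test_counts_non_increasing(self, manifest, ploidy_map, make_record):
        recs = [
            make_record(pos=p, calls=c)
            for p, c in [
                (1, {}),
                (2, {"focal1": ((0, 1), 20, 10)}),
                (3, {"mother": ((0, 1), 30, 15)}),
                (4, {"bait1": ((0, 0), 15, 2), "focal1": ((0, 1), 20, 10)}),
                (5, {"focal2": (None, 2, 0)}),
                (6, {"focal1": ((0, 1), 30, 8)}),
            ]
        ]
        _, funnel = detect(recs, manifest, ploidy_map)
        counts = list(funnel.counts.values())
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_order_invariance(self, manifest, ploidy_map, make_record):
        recs = [
            make_record(pos=p, calls={"focal1": ((0, 1), 20, 10)} if p % 3 else {})
            for p in range(1, 40)
        ]
        cands_fwd, _ = detect(list(recs), manifest, ploidy_map)
        shuffled = list(recs)
        random.Random(5).shuffle(shuffled)
        cands_shuf, _ = detect(shuffled, manifest, ploidy_map)
        assert [c.key() for c in cands_fwd] == [c.key() for c in cands_shuf]


class TestComappingFlag:
    def test_isolated_candidate_unflagged(self, manifest, ploidy_map, make_record):
        rec = make_record(pos=500, calls={"focal1": ((0, 1), 20, 10)})
        cands, _ = detect([rec], manifest, ploidy_map)
        flags = flag_comapping_context(cands, [rec], manifest)
        assert flags == [False]

    def test_bait_shared_nearby_variant_flags(self, manifest, ploidy_map, make_record):
        cand_rec = make_record(pos=500, calls={"focal1": ((0, 1), 20, 10)})
        # 40 bp away: carrier and bait share alt reads with no parental source
        artifact = make_record(
            pos=540, calls={"focal1": ((0, 0), 20, 3), "bait1": ((0, 0), 15, 2)}
        )
        cands, _ = detect([cand_rec, artifact], manifest, ploidy_map)
        assert len(cands) == 1  # artifact site itself fails the bait veto
        flags = flag_comapping_context(cands, [cand_rec, artifact], manifest)
        assert flags == [True]

    def test_inherited_polymorphism_nearby_does_not_flag(
        self, manifest, ploidy_map, make_record
    ):
        cand_rec = make_record(pos=500, calls={"focal1": ((0, 1), 20, 10)})
        # ordinary segregating SNP: the alt allele has a parental source
        snp = make_record(
            pos=560,
            calls={
                "dad": ((0, 1), 30, 14),
                "focal1": ((0, 1), 20, 9),
                "bait1": ((0, 1), 15, 8),
            },
        )
        cands, _ = detect([cand_rec, snp], manifest, ploidy_map)
        flags = flag_comapping_context(cands, [cand_rec, snp], manifest)
        assert flags == [False]

    def test_far_variant_outside_window_ignored(self, manifest, ploidy_map, make_record):
        cand_rec = make_record(pos=500, calls={"focal1": ((0, 1), 20, 10)})
        artifact = make_record(
            pos=700, calls={"focal1": ((0, 0), 20, 3), "bait1": ((0, 0), 15, 2)}
        )
        cands, _ = detect([cand_rec, artifact], manifest, ploidy_map)
        flags = flag_comapping_context(cands, [cand_rec, artifact], manifest, window=150)
        assert flags == [False]
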