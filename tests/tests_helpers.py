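"""Record-builder usable with arbitrary manifests (the conftest
``make_record`` fixture is bound to the default six-sample pedigree)."""

import numpy as np

from dnmrate import SampleManifest, SiteRecord


def make_record_for(manifest: SampleManifest):
    def _make(pos=1000, chrom="2", ref="A", alt="T", calls=None):
        calls = calls or {}
        gts, dp, ad_alt = [], [], []
        for s in manifest.samples:
            default_dp = 15 if s.role == "bait" else 30
            default_gt = (0,) if (chrom == "X" and s.sex == "male") else (0, 0)
            gt, d, a = calls.get(s.sample_id, (default_gt, default_dp, 0))
            gts.append(gt)
            dp.append(d)
            ad_alt.append(a)
        dp = np.array(dp)
        ad_alt = np.array(ad_alt)
        return SiteRecord(
            chrom=chrom,
            pos=pos,
            ref=ref,
            alts=(alt,),
            gts=gts,
            dp=dp,
            ad_ref=dp - np.maximum(ad_alt, 0),
            ad_alt=ad_alt,
        )

    return _make


def opposite_hom_pedigree(n_cand=1, n_focal=3, n_bait=3):
    """Mother + candidate male(s) + offspring, for concordance tests."""
    from dnmrate import Sample

    samples = [Sample("mother", "mother", "female")]
    samples += [Sample(f"c{i}", "candidate_father", "male") for i in range(n_cand)]
    samples += [Sample(f"f{i}", "focal", "female") for i in range(n_focal)]
    samples += [Sample(f"b{i}", "bait", "male") for i in range(n_bait)]
    return SampleManifest(samples)


def opposite_hom_records(make, manifest, n_sites, het_sites, mother_gt=(0, 0), cand_gt=(1, 1)):
    """Opposite-homozygote parental sites; offspring het at the first
    ``het_sites`` sites and hom-ref (discordant) at the rest."""
    recs = []
    for i in range(n_sites):
        off_gt = (0, 1) if i < het_sites else (0, 0)
        calls = {"mother": (mother_gt, 30, 0 if mother_gt == (0, 0) else 30)}
        calls.update(
            {
                s.sample_id: (cand_gt, 30, 30 if cand_gt == (1, 1) else 0)
                for s in manifest.candidate_fathers
            }
        )
        calls.update(
            {
                s.sample_id: (off_gt, 30, 15 if off_gt == (0, 1) else 0)
                for s in manifest.offspring
            }
        )
        recs.append(make(pos=i + 1, calls=calls))
    return recs
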