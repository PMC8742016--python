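"""Candidate de novo mutation detection.

A biallelic SNP site is a candidate when all four criteria hold:

(i)   both parents hom-ref with DP >= 10 and AD_ALT exactly 0;
(ii)  no bait offspring shows any alternate read, and bait offspring
      with called genotypes are hom-ref;
(iii) every focal offspring has a called genotype; exactly 1 or 2 are
      heterozygous (or hemizygous-alt for males on X) with DP >= 10,
      the rest hom-ref with AD_ALT = 0;
(iv)  carrier allele balance 0.27*DP <= AD_ALT <= 0.73*DP (inclusive,
      exact rational arithmetic) — autosomal carriers and female
      carriers on X; male-X hemizygous carriers skip the band.

The filtering funnel (input count surviving after each stage) is the
audit artifact of the run.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .manifest import PloidyMap, SampleManifest
from .records import SiteRecord, is_het, is_hom_ref

log = logging.getLogger(__name__)

FUNNEL_STAGES = (
    "total_variants",
    "biallelic_snps",
    "parents_homref_dp",
    "no_alt_in_bait",
    "called_in_every_focal",
    "het_1or2_focal",
    "allele_balance",
)


@dataclass
class DetectParams:
    min_dp: int = 10
    aaf_low: Fraction = Fraction(27, 100)
    aaf_high: Fraction = Fraction(73, 100)
    allow_two_carriers: bool = True

    def __post_init__(self) -> None:
        # floats go through their decimal repr so 0.27 means exactly
        # 27/100 (the binary float is a hair above, breaking the
        # inclusive boundary)
        self.aaf_low = self._as_fraction(self.aaf_low)
        self.aaf_high = self._as_fraction(self.aaf_high)

    @staticmethod
    def _as_fraction(x) -> Fraction:
        return Fraction(str(x)) if isinstance(x, float) else Fraction(x)


@dataclass
class FilterFunnel:
    counts: dict[str, int] = field(
        default_factory=lambda: {s: 0 for s in FUNNEL_STAGES}
    )

    def passed(self, stage: str) -> None:
        self.counts[stage] += 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stage": list(self.counts), "sites": list(self.counts.values())}
        )


@dataclass
class CandidateMutation:
    chrom: str
    pos: int
    ref: str
    alt: str
    carriers: tuple[str, ...]  # 1 or 2 focal sample ids
    carrier_ad_ref: tuple[int, ...]
    carrier_ad_alt: tuple[int, ...]
    carrier_dp: tuple[int, ...]
    mean_parent_dp: float
    mean_focal_dp: float
    chrom_class: str
    carrier_sexes: tuple[str, ...]
    comapping_flag: bool = False

    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


def _passes_allele_balance(dp: int, ad_alt: int, params: DetectParams) -> bool:
    # inclusive band in exact rational arithmetic: no float boundary artifacts
    return params.aaf_low * dp <= ad_alt <= params.aaf_high * dp


def detect_candidates(
    records: Iterable[SiteRecord],
    manifest: SampleManifest,
    ploidy_map: PloidyMap,
    params: DetectParams | None = None,
) -> tuple[list[CandidateMutation], FilterFunnel]:
    """Apply criteria (i)-(iv) to a record stream.

    Requires a manifest with the father already confirmed. Output order
    is (chrom, pos)-sorted and independent of input order.
    """
    params = params or DetectParams()
    father = manifest.father  # raises if paternity unresolved
    mi = manifest.index[manifest.mother.sample_id]
    fi = manifest.index[father.sample_id]
    bait_idx = [manifest.index[s.sample_id] for s in manifest.bait]
    focal = manifest.focal
    focal_idx = [manifest.index[s.sample_id] for s in focal]

    funnel = FilterFunnel()
    out: list[CandidateMutation] = []
    for rec in records:
        funnel.passed("total_variants")
        if not rec.is_biallelic_snp() or rec.chrom not in ploidy_map:
            continue
        funnel.passed("biallelic_snps")

        # (i) parents hom-ref, DP >= min, zero alt reads (missing AD fails)
        ok = True
        for pi in (mi, fi):
            if not (
                is_hom_ref(rec.gts[pi])
                and rec.dp[pi] >= params.min_dp
                and rec.ad_alt[pi] == 0
            ):
                ok = False
                break
        if not ok:
            continue
        funnel.passed("parents_homref_dp")

        # (ii) any bait alternate read vetoes, called or not; called bait
        # genotypes must be hom-ref with positive evidence of AD_ALT = 0
        ok = True
        for bi in bait_idx:
            if rec.ad_alt[bi] > 0:
                ok = False
                break
            if rec.gts[bi] is not None and not (
                is_hom_ref(rec.gts[bi]) and rec.ad_alt[bi] == 0
            ):
                ok = False
                break
        if not ok:
            continue
        funnel.passed("no_alt_in_bait")

        # (iii-a) every focal offspring called
        if any(rec.gts[oi] is None for oi in focal_idx):
            continue
        funnel.passed("called_in_every_focal")

        # (iii-b) 1-2 carriers, rest hom-ref with AD_ALT = 0
        on_x = not ploidy_map.is_autosome(rec.chrom)
        carriers: list[int] = []
        ok = True
        for oi, s in zip(focal_idx, focal):
            gt = rec.gts[oi]
            male_x = on_x and s.sex == "male"
            if male_x and is_het(gt):
                # biologically impossible call: mis-mapping signal
                ok = False
                break
            hemi_alt = male_x and gt in ((1,), (1, 1))
            if is_het(gt) or hemi_alt:
                carriers.append(oi)
            elif not (is_hom_ref(gt) and rec.ad_alt[oi] == 0):
                ok = False
                break
        max_carriers = 2 if params.allow_two_carriers else 1
        if not ok or not 1 <= len(carriers) <= max_carriers:
            continue
        if any(rec.dp[ci] < params.min_dp for ci in carriers):
            continue
        funnel.passed("het_1or2_focal")

        # (iv) allele balance for diploid carriers (autosomes, female X)
        ok = True
        for ci in carriers:
            sex = manifest.samples[ci].sex
            if on_x and sex == "male":
                continue  # hemizygous-alt: band not applicable
            if rec.ad_alt[ci] < 0 or not _passes_allele_balance(
                int(rec.dp[ci]), int(rec.ad_alt[ci]), params
            ):
                ok = False
                break
        if not ok:
            continue
        funnel.passed("allele_balance")

        parent_dp = [int(rec.dp[pi]) for pi in (mi, fi)]
        focal_dp = [int(rec.dp[oi]) for oi in focal_idx if rec.dp[oi] >= 0]
        out.append(
            CandidateMutation(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=rec.alts[0],
                carriers=tuple(manifest.samples[ci].sample_id for ci in carriers),
                carrier_ad_ref=tuple(int(rec.ad_ref[ci]) for ci in carriers),
                carrier_ad_alt=tuple(int(rec.ad_alt[ci]) for ci in carriers),
                carrier_dp=tuple(int(rec.dp[ci]) for ci in carriers),
                mean_parent_dp=float(np.mean(parent_dp)),
                mean_focal_dp=float(np.mean(focal_dp)) if focal_dp else float("nan"),
                chrom_class=ploidy_map.chrom_class(rec.chrom),
                carrier_sexes=tuple(manifest.samples[ci].sex for ci in carriers),
            )
        )
    out.sort(key=lambda c: c.key())
    log.info(
        "detection funnel: %s",
        " -> ".join(f"{s}={funnel.counts[s]}" for s in FUNNEL_STAGES),
    )
    return out, funnel


def flag_comapping_context(
    candidates: Sequence[CandidateMutation],
    records: Iterable[SiteRecord],
    manifest: SampleManifest,
    window: int = 150,
) -> list[bool]:
    """Advisory mis-mapping flag: another variant within ``window`` bp
    (one read length) showing alternate reads in the candidate's
    carrier and in a bait sample *without a parental source* (both
    parents called hom-ref there). Alt reads shared by offspring and
    bait that no parent carries are the co-segregating mis-mapping
    signature; an ordinary inherited polymorphism nearby shows the
    alternate allele in a parent and does not flag. Flagged candidates
    are reported, not removed — the final visual curation is a human
    step."""
    if window <= 0:
        raise ValueError("window must be positive")
    mi = manifest.index[manifest.mother.sample_id]
    fi = manifest.index[manifest.father.sample_id]
    bait_idx = [manifest.index[s.sample_id] for s in manifest.bait]
    by_chrom: dict[str, list[tuple[int, SiteRecord]]] = {}
    for rec in records:
        by_chrom.setdefault(rec.chrom, []).append((rec.pos, rec))
    for lst in by_chrom.values():
        lst.sort(key=lambda t: t[0])
    flags: list[bool] = []
    for cand in candidates:
        lst = by_chrom.get(cand.chrom, [])
        positions = [p for p, _ in lst]
        lo = bisect_left(positions, cand.pos - window)
        hi = bisect_right(positions, cand.pos + window)
        flagged = False
        carrier_idx = [manifest.index[c] for c in cand.carriers]
        for pos, rec in lst[lo:hi]:
            if pos == cand.pos:
                continue
            parents_ref = is_hom_ref(rec.gts[mi]) and is_hom_ref(rec.gts[fi])
            carrier_alt = any(rec.ad_alt[ci] > 0 for ci in carrier_idx)
            bait_alt = any(rec.ad_alt[bi] > 0 for bi in bait_idx)
            if parents_ref and carrier_alt and bait_alt:
                flagged = True
                break
        cand.comapping_flag = flagged
        flags.append(flagged)
    return flags


def candidates_frame(candidates: Sequence[CandidateMutation]) -> pd.DataFrame:
    """Candidate table with the published report's columns."""
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in candidates],
            "pos": [c.pos for c in candidates],
            "ref": [c.ref for c in candidates],
            "alt": [c.alt for c in candidates],
            "carriers": [",".join(c.carriers) for c in candidates],
            "ad_ref": [",".join(map(str, c.carrier_ad_ref)) for c in candidates],
            "ad_alt": [",".join(map(str, c.carrier_ad_alt)) for c in candidates],
            "mean_parent_dp": [c.mean_parent_dp for c in candidates],
            "mean_focal_dp": [c.mean_focal_dp for c in candidates],
            "comapping_flag": [c.comapping_flag for c in candidates],
        }
    )
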