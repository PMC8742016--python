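"""In-memory representation of one joint-called variant site.

A :class:`SiteRecord` carries, for every manifest sample in manifest
order, the genotype call (tuple of allele indices, or ``None`` when
missing), the total read depth DP, and the reference / alternate allele
read counts AD_REF / AD_ALT. Depth fields use ``MISSING_DEPTH`` (-1)
when the caller emitted no usable value; any filter that demands
positive evidence (e.g. AD_ALT == 0) then fails conservatively.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import numpy as np

MISSING_DEPTH = -1

BASES = ("A", "C", "G", "T")

Genotype = Optional[tuple[int, ...]]

HOM_REF = (0, 0)
HET = (0, 1)
HOM_ALT = (1, 1)
HEMI_REF = (0,)
HEMI_ALT = (1,)


@dataclass
class SiteRecord:
    chrom: str
    pos: int  # 1-based, VCF-style
    ref: str
    alts: tuple[str, ...]
    gts: list[Genotype]  # parallel to manifest sample order
    dp: np.ndarray  # int array, MISSING_DEPTH where unavailable
    ad_ref: np.ndarray
    ad_alt: np.ndarray

    def __post_init__(self) -> None:
        self.dp = np.asarray(self.dp, dtype=np.int64)
        self.ad_ref = np.asarray(self.ad_ref, dtype=np.int64)
        self.ad_alt = np.asarray(self.ad_alt, dtype=np.int64)

    @property
    def n_samples(self) -> int:
        return len(self.gts)

    def is_biallelic_snp(self) -> bool:
        return (
            len(self.alts) == 1
            and len(self.ref) == 1
            and len(self.alts[0]) == 1
            and self.ref in BASES
            and self.alts[0] in BASES
        )

    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


def filter_biallelic_snps(records: Iterable[SiteRecord]) -> Iterator[SiteRecord]:
    """Keep only biallelic single-base substitutions, preserving order."""
    for rec in records:
        if rec.is_biallelic_snp():
            yield rec


def reindex_records(
    records: Iterable[SiteRecord], old_manifest, new_manifest
) -> list[SiteRecord]:
    """Project record columns onto a sub-manifest's sample order.

    Needed when samples are dropped after the fact (e.g. distractor
    males removed once paternity is confirmed): per-sample arrays are
    parallel to the manifest the records were built against.
    """
    idx = [old_manifest.index[sid] for sid in new_manifest.sample_ids()]
    out = []
    for rec in records:
        out.append(
            SiteRecord(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alts=rec.alts,
                gts=[rec.gts[i] for i in idx],
                dp=rec.dp[idx],
                ad_ref=rec.ad_ref[idx],
                ad_alt=rec.ad_alt[idx],
            )
        )
    return out


def is_het(gt: Genotype) -> bool:
    return gt is not None and len(gt) == 2 and gt[0] != gt[1]


def is_hom_ref(gt: Genotype) -> bool:
    return gt is not None and all(a == 0 for a in gt)


def is_hom_alt(gt: Genotype) -> bool:
    return gt is not None and len(gt) == 2 and gt[0] == gt[1] and gt[0] > 0


def dosage(gt: Genotype) -> int:
    """Alt-allele count of a call; -1 for missing. Diploid calls only
    map onto the 0/1/2 coding used by the kinship estimator."""
    if gt is None:
        return -1
    return sum(1 for a in gt if a > 0)
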