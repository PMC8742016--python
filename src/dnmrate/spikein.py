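"""Synthetic-mutation spike-in and false-negative-rate estimation.

The detection pipeline consumes only GT/DP/AD, so mutations are
inserted at the allele-count level: new records are appended at
invariant autosomal coordinates where both parents reach 10x, the
focal sample's alternate-read count is drawn from the depth-matched
empirical distribution of alternate allele depths observed at known
heterozygous sites (parents homozygous for different alleles), and the
genotype is re-called. Re-running detection on the spiked dataset and
dividing misses by callable insertions gives the FNR used as the
multiplicative correction on the mutation rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .detect import CandidateMutation
from .manifest import PloidyMap, SampleManifest
from .masks import DepthMask, intersect_two
from .records import BASES, SiteRecord, dosage
from .simulate import call_genotype

log = logging.getLogger(__name__)

DEPTH_MIN, DEPTH_MAX = 10, 100


class SpikeError(ValueError):
    pass


@dataclass
class EmpiricalADDistribution:
    """Per-depth frequency tables of alternate allele read counts at
    known heterozygous sites, for overall depths in [10, 100]."""

    tables: dict[int, np.ndarray] = field(default_factory=dict)  # d -> counts[0..d]

    def n_observations(self, d: int) -> int:
        return int(self.tables[d].sum()) if d in self.tables else 0

    def frequencies(self, d: int) -> np.ndarray | None:
        t = self.tables.get(d)
        if t is None or t.sum() == 0:
            return None
        return t / t.sum()

    def sample(self, d: int, rng: np.random.Generator) -> int:
        """Draw an alternate-read count for total depth d; empty or
        out-of-range depth bins fall back to Binomial(d, 0.5) (the
        empirical tables track that shape)."""
        freqs = self.frequencies(d) if DEPTH_MIN <= d <= DEPTH_MAX else None
        if freqs is None:
            return int(rng.binomial(d, 0.5))
        return int(rng.choice(len(freqs), p=freqs))


def build_ad_distributions(
    records: Iterable[SiteRecord],
    manifest: SampleManifest,
    ploidy_map: PloidyMap,
) -> EmpiricalADDistribution:
    """Harvest (DP, AD_ALT) pairs from every offspring at autosomal
    sites where the confirmed parents are homozygous for different
    alleles (all true offspring are heterozygous there)."""
    mi = manifest.index[manifest.mother.sample_id]
    fi = manifest.index[manifest.father.sample_id]
    off_idx = [manifest.index[s.sample_id] for s in manifest.offspring]
    tables = {d: np.zeros(d + 1, dtype=np.int64) for d in range(DEPTH_MIN, DEPTH_MAX + 1)}
    for rec in records:
        if not rec.is_biallelic_snp() or not ploidy_map.is_autosome(rec.chrom):
            continue
        dm, df = dosage(rec.gts[mi]), dosage(rec.gts[fi])
        if {dm, df} != {0, 2}:
            continue
        for oi in off_idx:
            d, a = int(rec.dp[oi]), int(rec.ad_alt[oi])
            if DEPTH_MIN <= d <= DEPTH_MAX and 0 <= a <= d:
                tables[d][a] += 1
    return EmpiricalADDistribution(tables=tables)


@dataclass
class SpikeRecord:
    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    n_alt: int
    dp: int
    callable: bool  # focal DP >= 10 (parents >= 10 by construction)
    detected: bool | None = None


def _interval_space(
    intervals: Mapping[str, np.ndarray], chroms: Sequence[str]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Flatten per-chromosome intervals into a sampleable coordinate
    space: parallel arrays of cumulative lengths and interval starts."""
    chrom_of: list[str] = []
    starts: list[int] = []
    lens: list[int] = []
    for c in chroms:
        arr = intervals.get(c)
        if arr is None:
            continue
        for s, e in arr:
            chrom_of.append(c)
            starts.append(int(s))
            lens.append(int(e - s))
    return chrom_of, np.asarray(starts, dtype=np.int64), np.asarray(lens, dtype=np.int64)


def spike_mutations(
    records: Sequence[SiteRecord],
    manifest: SampleManifest,
    ploidy_map: PloidyMap,
    masks: Mapping[str, DepthMask],
    depth_of: Callable[[str, str, int], int],
    focal_id: str,
    n: int,
    dist: EmpiricalADDistribution,
    rng: np.random.Generator,
    exclude: set[tuple[str, int]] | None = None,
    min_focal_dp: int = 10,
    error_rate: float = 0.001,
    min_call_depth: int = 4,
) -> tuple[list[SiteRecord], list[SpikeRecord]]:
    """Insert ``n`` synthetic mutations into one focal sample.

    Sites are drawn uniformly among autosomal coordinates inside both
    parents' depth masks, avoiding existing variant records and the
    ``exclude`` set (coordinates already spiked this run; updated in
    place). Returns the new records and their spike annotations.
    """
    if n < 1:
        raise SpikeError("n must be >= 1")
    exclude = exclude if exclude is not None else set()
    mother_ivs = masks[manifest.mother.sample_id].intervals
    father_ivs = masks[manifest.father.sample_id].intervals
    autosomes = [c for c in ploidy_map.chromosomes() if ploidy_map.is_autosome(c)]
    both = {
        c: intersect_two(
            mother_ivs.get(c, np.empty((0, 2), dtype=np.int64)),
            father_ivs.get(c, np.empty((0, 2), dtype=np.int64)),
        )
        for c in autosomes
    }
    taken = {(r.chrom, r.pos) for r in records} | exclude
    chrom_of, starts, lens = _interval_space(both, autosomes)
    total = int(lens.sum())
    if total - len(taken) < n:
        raise SpikeError(
            f"only {max(total - len(taken), 0)} qualifying coordinates for {n} spikes"
        )
    cum = np.concatenate([[0], np.cumsum(lens)])

    new_records: list[SiteRecord] = []
    spikes: list[SpikeRecord] = []
    n_samples = len(manifest)
    fo = manifest.index[focal_id]
    while len(spikes) < n:
        r = int(rng.integers(total))
        ii = int(np.searchsorted(cum, r, side="right")) - 1
        chrom = chrom_of[ii]
        pos = int(starts[ii] + (r - int(cum[ii]))) + 1  # 0-based coord -> 1-based pos
        if (chrom, pos) in taken:
            continue
        taken.add((chrom, pos))
        exclude.add((chrom, pos))
        ref = BASES[int(rng.integers(4))]
        alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
        dp = np.array(
            [depth_of(s.sample_id, chrom, pos) for s in manifest.samples],
            dtype=np.int64,
        )
        # non-carrier samples carry sequencing-error alt reads under the
        # same model the rest of the data obeys, so a spiked site is
        # exposed to the identical parent/bait veto risk as a genuinely
        # planted mutation (BAM-level insertion would keep real reads)
        ad_alt = rng.binomial(dp, error_rate)
        gts: list = [None] * n_samples
        for i, s in enumerate(manifest.samples):
            ploidy = ploidy_map.copy_number(chrom, s.sex)
            gts[i] = call_genotype(
                int(dp[i]), int(ad_alt[i]), error_rate, ploidy, min_call_depth
            )
        d_f = int(dp[fo])
        n_alt = min(dist.sample(d_f, rng), d_f)
        ad_alt[fo] = n_alt
        gts[fo] = call_genotype(d_f, n_alt, error_rate, 2, min_call_depth)
        new_records.append(
            SiteRecord(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alts=(alt,),
                gts=gts,
                dp=dp,
                ad_ref=dp - ad_alt,
                ad_alt=ad_alt,
            )
        )
        spikes.append(
            SpikeRecord(
                sample_id=focal_id,
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                n_alt=n_alt,
                dp=d_f,
                callable=d_f >= min_focal_dp,
            )
        )
    return new_records, spikes


def spike_dataset(
    records: Sequence[SiteRecord],
    manifest: SampleManifest,
    ploidy_map: PloidyMap,
    masks: Mapping[str, DepthMask],
    depth_of: Callable[[str, str, int], int],
    dist: EmpiricalADDistribution,
    n_per_focal: int,
    seed: int,
    **kwargs,
) -> tuple[list[SiteRecord], list[SpikeRecord]]:
    """Spike every focal sample (one shared coordinate pool, no reuse)
    and return the merged, position-sorted record list plus spikes."""
    rng = np.random.default_rng(seed)
    exclude: set[tuple[str, int]] = set()
    new_records: list[SiteRecord] = []
    spikes: list[SpikeRecord] = []
    for focal in manifest.focal:
        recs, sps = spike_mutations(
            records,
            manifest,
            ploidy_map,
            masks,
            depth_of,
            focal.sample_id,
            n_per_focal,
            dist,
            rng,
            exclude=exclude,
            **kwargs,
        )
        new_records.extend(recs)
        spikes.extend(sps)
    combined = sorted(list(records) + new_records, key=lambda r: (r.chrom, r.pos))
    return combined, spikes


@dataclass
class FnrEstimate:
    inserted: int
    inserted_callable: int
    detected: int
    fnr: float  # (callable - detected) / callable

    @property
    def correction(self) -> float:
        return self.inserted_callable / self.detected


def fnr_from_counts(inserted_callable: int, detected: int) -> float:
    if inserted_callable == 0:
        raise SpikeError("FNR undefined: no callable insertions")
    return (inserted_callable - detected) / inserted_callable


def estimate_fnr(
    spikes: Sequence[SpikeRecord], candidates: Sequence[CandidateMutation]
) -> FnrEstimate:
    """Match redetected candidates back to spikes (same coordinate and
    carrier) and compute FNR over callable insertions only."""
    detected_keys = {
        (c.chrom, c.pos, carrier) for c in candidates for carrier in c.carriers
    }
    n_detected = 0
    n_callable = 0
    for sp in spikes:
        sp.detected = (sp.chrom, sp.pos, sp.sample_id) in detected_keys
        if sp.callable:
            n_callable += 1
            n_detected += sp.detected
    fnr = fnr_from_counts(n_callable, n_detected)
    log.info(
        "FNR: %d inserted, %d callable, %d detected -> %.1f%%",
        len(spikes),
        n_callable,
        n_detected,
        100 * fnr,
    )
    return FnrEstimate(
        inserted=len(spikes),
        inserted_callable=n_callable,
        detected=n_detected,
        fnr=fnr,
    )
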