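"""Father identification among candidate males.

Two complementary strategies, both restricted to autosomal biallelic
SNPs with called genotypes:

1. KING-robust kinship between each candidate and every offspring,
   with a one-sided rank-sum test of the top candidate's kinship
   values against all other candidates pooled. Parent-offspring pairs
   sit near phi = 0.25, unrelated pairs near 0.
2. Mendelian concordance: at sites where mother and candidate are
   homozygous for different alleles every true offspring must be
   heterozygous; the candidate maximizing the count of such
   all-offspring-het sites is the father.

The Mendelian count is decisive; kinship corroborates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .manifest import PloidyMap, SampleManifest
from .records import SiteRecord, dosage


class PaternityError(ValueError):
    pass


class PaternityTieError(PaternityError):
    """Two candidates are exactly tied; requires manual resolution."""


def genotype_dosage_matrix(
    records: Iterable[SiteRecord],
    manifest: SampleManifest,
    ploidy_map: PloidyMap,
    min_dp: int | None = None,
) -> np.ndarray:
    """(n_sites, n_samples) alt-dosage matrix over autosomal biallelic
    SNPs; -1 marks missing calls (and haploid male-X calls never enter
    because only autosomes are used). Optional per-sample DP filter."""
    rows = []
    for rec in records:
        if not rec.is_biallelic_snp() or not ploidy_map.is_autosome(rec.chrom):
            continue
        row = np.array([dosage(gt) for gt in rec.gts], dtype=np.int8)
        if min_dp is not None:
            row = np.where(rec.dp >= min_dp, row, -1)
        rows.append(row)
    if not rows:
        return np.empty((0, len(manifest)), dtype=np.int8)
    return np.vstack(rows)


@dataclass
class KinshipResult:
    phi: float | None  # None when the denominator is zero
    n_both_het: int
    n_opposite_hom: int
    n_het_i: int
    n_het_j: int
    n_sites: int


def king_kinship(genotypes_i: np.ndarray, genotypes_j: np.ndarray) -> KinshipResult:
    """KING-robust between-sample kinship from dosage vectors.

    phi = (N_Aa,Aa - 2 N_AA,aa) / (N_Aa,i + N_Aa,j) over sites where
    both samples are called; missing entries (-1) are excluded
    pairwise. A zero denominator yields phi = None (flagged, not a
    crash).
    """
    gi = np.asarray(genotypes_i)
    gj = np.asarray(genotypes_j)
    ok = (gi >= 0) & (gj >= 0)
    gi, gj = gi[ok], gj[ok]
    n_both_het = int(((gi == 1) & (gj == 1)).sum())
    n_opp = int((((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0))).sum())
    n_het_i = int((gi == 1).sum())
    n_het_j = int((gj == 1).sum())
    denom = n_het_i + n_het_j
    phi = (n_both_het - 2.0 * n_opp) / denom if denom > 0 else None
    return KinshipResult(phi, n_both_het, n_opp, n_het_i, n_het_j, int(ok.sum()))


def kinship_table(
    records: Iterable[SiteRecord],
    manifest: SampleManifest,
    ploidy_map: PloidyMap,
    min_dp: int | None = None,
) -> pd.DataFrame:
    """Candidate-father x offspring kinship values as a tidy frame."""
    mat = genotype_dosage_matrix(records, manifest, ploidy_map, min_dp)
    rows = []
    for cand in manifest.candidate_fathers:
        ci = manifest.index[cand.sample_id]
        for off in manifest.offspring:
            oi = manifest.index[off.sample_id]
            res = king_kinship(mat[:, ci], mat[:, oi])
            rows.append(
                {
                    "candidate": cand.sample_id,
                    "offspring": off.sample_id,
                    "phi": res.phi,
                    "n_sites": res.n_sites,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class RankTestResult:
    top_candidate: str
    p_values: dict[str, float]  # candidate -> one-sided rank-sum p


def rank_relatedness_test(kinships: dict[str, Sequence[float]]) -> RankTestResult:
    """One-sided rank-sum test of each candidate's offspring kinships
    against all other candidates pooled (alternative: greater).

    Exact enumeration when the combined sample is small (<= 20) and
    tie-free; normal approximation with tie correction otherwise.
    All-tied input reports p = 1 (selection then falls back to the
    Mendelian method).
    """
    if len(kinships) < 2:
        raise PaternityError("need at least two candidates")
    for cand, vals in kinships.items():
        if len(vals) < 3:
            raise PaternityError(f"candidate {cand}: need >= 3 offspring kinships")
    p_values: dict[str, float] = {}
    for cand, vals in kinships.items():
        others = [v for c, vs in kinships.items() if c != cand for v in vs]
        vals = list(vals)
        if len(set(vals + others)) == 1:
            p_values[cand] = 1.0
            continue
        n_total = len(vals) + len(others)
        has_ties = len(set(vals + others)) < n_total
        method = "exact" if (n_total <= 20 and not has_ties) else "asymptotic"
        p_values[cand] = float(
            stats.mannwhitneyu(vals, others, alternative="greater", method=method).pvalue
        )
    top = max(kinships, key=lambda c: float(np.mean(kinships[c])))
    return RankTestResult(top_candidate=top, p_values=p_values)


@dataclass
class ConcordanceTable:
    table: pd.DataFrame  # candidate, orientation, n_sites, n_all_het, percentage
    selected_father: str


def mendelian_paternity(
    records: Iterable[SiteRecord],
    manifest: SampleManifest,
    ploidy_map: PloidyMap,
) -> ConcordanceTable:
    """Opposite-homozygote concordance per candidate and orientation.

    Orientation "ref_x_alt" = mother hom-ref, candidate hom-alt (and
    vice versa). A site counts toward n_all_het when every *called*
    offspring is heterozygous; offspring with missing calls are
    ignored at that site. The father is the candidate with the largest
    total n_all_het across orientations; an exact tie raises
    PaternityTieError.
    """
    mat = genotype_dosage_matrix(records, manifest, ploidy_map)
    if mat.shape[0] == 0:
        raise PaternityError("no autosomal biallelic sites with genotypes")
    mi = manifest.index[manifest.mother.sample_id]
    off_idx = [manifest.index[s.sample_id] for s in manifest.offspring]
    off = mat[:, off_idx]
    called = off >= 0
    all_het = np.logical_and(called, off == 1).sum(axis=1) == called.sum(axis=1)
    any_called = called.any(axis=1)
    all_het &= any_called

    rows = []
    totals: dict[str, int] = {}
    for cand in manifest.candidate_fathers:
        ci = manifest.index[cand.sample_id]
        total = 0
        for name, m_dose, c_dose in (("ref_x_alt", 0, 2), ("alt_x_ref", 2, 0)):
            sel = (mat[:, mi] == m_dose) & (mat[:, ci] == c_dose)
            n_sites = int(sel.sum())
            n_all_het = int((sel & all_het).sum())
            pct = 100.0 * n_all_het / n_sites if n_sites else float("nan")
            rows.append(
                {
                    "candidate": cand.sample_id,
                    "orientation": name,
                    "n_sites": n_sites,
                    "n_all_het": n_all_het,
                    "percentage": pct,
                }
            )
            total += n_all_het
        totals[cand.sample_id] = total
    if all(v == 0 for v in totals.values()):
        if all(r["n_sites"] == 0 for r in rows):
            raise PaternityError("no opposite-homozygote sites for any candidate")
    best = max(totals.values())
    winners = [c for c, v in totals.items() if v == best]
    if len(winners) > 1:
        raise PaternityTieError(f"candidates tied on all-het count: {winners}")
    return ConcordanceTable(table=pd.DataFrame(rows), selected_father=winners[0])


@dataclass
class PaternityReport:
    kinship: pd.DataFrame
    rank_test: RankTestResult
    concordance: ConcordanceTable
    father_id: str


def identify_father(
    records: Sequence[SiteRecord],
    manifest: SampleManifest,
    ploidy_map: PloidyMap,
    min_dp: int | None = None,
) -> PaternityReport:
    """Run both strategies; Mendelian concordance decides."""
    kin = kinship_table(records, manifest, ploidy_map, min_dp)
    kinships = {
        cand: grp["phi"].dropna().tolist() for cand, grp in kin.groupby("candidate")
    }
    rank = rank_relatedness_test(kinships)
    conc = mendelian_paternity(records, manifest, ploidy_map)
    return PaternityReport(
        kinship=kin,
        rank_test=rank,
        concordance=conc,
        father_id=conc.selected_father,
    )
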