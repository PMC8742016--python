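"""Synthetic pedigree generator.

Emulates the study design the analysis assumes: one mating pair plus
unrelated distractor males, high-coverage focal offspring and
low-coverage bait offspring, segregating biallelic SNPs under
Hardy-Weinberg founders and Mendelian transmission (X-aware), de novo
mutations planted per offspring at a configurable true rate, read
depths from an overdispersed (negative binomial) coverage model held
constant over short windows, binomial allele-depth sampling with a
per-read error rate, and shared mis-mapping artifact sites that leak
low-level alternate reads into random subsets of samples.

Only polymorphic, planted and artifact sites are emitted as records —
invariant sites are carried implicitly by the depth masks, as in real
joint-caller output. Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from .manifest import (
    AUTOSOME,
    BAIT,
    CANDIDATE_FATHER,
    FOCAL,
    MOTHER,
    PloidyMap,
    Sample,
    SampleManifest,
    X,
)
from .masks import DepthMask
from .records import BASES, SiteRecord

_EPS_FLOOR = 1e-9  # keeps log-likelihoods finite when error_rate = 0


@dataclass
class SimConfig:
    """Study conditions for one synthetic pedigree.

    Coverage means follow the sequencing design (parents and focal
    ~20-46x, bait ~9-20x); the default genome is a toy layout (two
    500 kb autosomes + 200 kb X) small enough to simulate in seconds.
    ``mu_true`` is the per-site per-generation rate on one haploid
    genome copy; the default is scaled up from the real ~1e-9 so a toy
    genome still plants a handful of mutations.
    """

    chromosomes: tuple[tuple[str, int, str], ...] = (
        ("2", 500_000, AUTOSOME),
        ("3", 500_000, AUTOSOME),
        ("X", 200_000, X),
    )
    n_polymorphic_sites: int = 10_000
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    n_candidate_fathers: int = 4
    n_focal: int = 10
    n_bait: int = 19
    mean_coverage: dict = field(
        default_factory=lambda: {
            MOTHER: 20.4,
            CANDIDATE_FATHER: 32.4,
            FOCAL: 25.7,
            BAIT: 13.1,
        }
    )
    depth_dispersion: float = 10.0  # negative binomial size parameter
    depth_window: int = 500  # bp over which depth is held constant
    error_rate: float = 5e-4  # per-read alt-miscall probability in AD fields
    artifact_site_rate: float = 2e-5  # artifact sites per bp
    artifact_alt_fraction: float = 0.2
    artifact_share_prob: float = 0.6
    mu_true: float = 5e-7
    mask_threshold: int = 10
    min_call_depth: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.error_rate,
            self.artifact_alt_fraction,
            self.artifact_share_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if not 0.0 <= self.mu_true < 1.0:
            raise ValueError("mu_true must be in [0, 1)")
        if any(m <= 0 for m in self.mean_coverage.values()):
            raise ValueError("coverages must be positive")
        total = sum(length for _, length, _ in self.chromosomes)
        if self.n_polymorphic_sites > total:
            raise ValueError("more polymorphic sites than genome coordinates")

    def ploidy_map(self) -> PloidyMap:
        return PloidyMap({c: (cls, length) for c, length, cls in self.chromosomes})


@dataclass(frozen=True)
class PlantedMutation:
    chrom: str
    pos: int  # 1-based
    carrier_id: str
    ref: str
    alt: str


@dataclass
class TruthSet:
    """Ground truth for parameter-recovery and FNR tests."""

    father_id: str
    mutations: list[PlantedMutation]
    # per emitted site: true alt-allele dosage per sample (manifest order)
    true_dosage: dict[tuple[str, int], np.ndarray]
    # per sample: copy number on each chromosome
    ploidy: dict[str, dict[str, int]]


@dataclass
class SimResult:
    config: SimConfig
    manifest: SampleManifest
    ploidy_map: PloidyMap
    records: list[SiteRecord]
    masks: dict[str, DepthMask]
    truth: TruthSet
    depth_of: Callable[[str, str, int], int]

    def write_outputs(self, outdir: str | Path) -> None:
        """Emit the exact inputs the analysis stages consume: VCF,
        per-sample BED masks, manifest TSV, ploidy YAML, truth TSV."""
        from .vcfio import write_joint_vcf

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_joint_vcf(outdir / "joint.vcf", self.records, self.manifest, self.ploidy_map)
        self.manifest.to_tsv(outdir / "manifest.tsv")
        self.ploidy_map.to_yaml(outdir / "ploidy.yaml")
        maskdir = outdir / "masks"
        maskdir.mkdir(exist_ok=True)
        for sid, mask in self.masks.items():
            mask.to_bed(maskdir / f"{sid}.bed")
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write(f"#true_father={self.truth.father_id}\n")
            fh.write("chrom\tpos\tcarrier\tref\talt\n")
            for m in self.truth.mutations:
                fh.write(f"{m.chrom}\t{m.pos}\t{m.carrier_id}\t{m.ref}\t{m.alt}\n")


# ---------------------------------------------------------------------------
# genotype calling


def _call_matrix(
    dp: np.ndarray,
    ad_alt: np.ndarray,
    ploidy: np.ndarray,
    error_rate: float,
    min_call_depth: int,
) -> np.ndarray:
    """Maximum-likelihood genotype codes under Binomial(DP, q).

    Codes: -1 missing, 0 hom-ref, 1 het, 2 hom-alt (diploid);
    3 hemi-ref, 4 hemi-alt (haploid). Diploid q in {eps, 0.5, 1-eps},
    haploid q in {eps, 1-eps}. Likelihood ties resolve toward the
    reference call (conservative for mutation detection).
    """
    eps = max(error_rate, _EPS_FLOOR)
    dp = np.asarray(dp, dtype=np.int64)
    ad = np.asarray(ad_alt, dtype=np.int64)

    def ll(q: float) -> np.ndarray:
        return ad * np.log(q) + (dp - ad) * np.log1p(-q)

    l_ref, l_het, l_alt = ll(eps), ll(0.5), ll(1.0 - eps)
    dip = np.select(
        [(l_het > l_ref) & (l_het >= l_alt), l_alt > l_ref], [1, 2], default=0
    )
    hap = np.where(ll(1.0 - eps) > ll(eps), 4, 3)
    out = np.where(np.asarray(ploidy) == 1, hap, dip)
    return np.where(dp < min_call_depth, -1, out)


_CODE_TO_GT = {-1: None, 0: (0, 0), 1: (0, 1), 2: (1, 1), 3: (0,), 4: (1,)}


def call_genotype(
    dp: int,
    ad_alt: int,
    error_rate: float,
    ploidy: int = 2,
    min_call_depth: int = 4,
) -> Optional[tuple[int, ...]]:
    """ML call for a single sample at a biallelic site (None = missing)."""
    if not 0 <= ad_alt <= dp:
        raise ValueError("require 0 <= AD_ALT <= DP")
    code = _call_matrix(
        np.array([dp]), np.array([ad_alt]), np.array([ploidy]), error_rate, min_call_depth
    )[0]
    return _CODE_TO_GT[int(code)]


# ---------------------------------------------------------------------------
# simulation


def _nb_depths(rng: np.random.Generator, mean: float, k: float, size: int) -> np.ndarray:
    p = k / (k + mean)
    return rng.negative_binomial(k, p, size=size).astype(np.int64)


def _transmit(rng: np.random.Generator, dose: np.ndarray) -> np.ndarray:
    """One allele drawn from a diploid parent: P(alt) = dose/2."""
    return ((dose == 2) | ((dose == 1) & (rng.random(dose.shape) < 0.5))).astype(np.int8)


def simulate_pedigree(config: SimConfig) -> SimResult:
    rng = np.random.default_rng(config.seed)
    ploidy_map = config.ploidy_map()

    # ---- samples -----------------------------------------------------
    samples = [Sample("mother", MOTHER, "female")]
    samples += [
        Sample(f"male{i+1}", CANDIDATE_FATHER, "male")
        for i in range(config.n_candidate_fathers)
    ]
    offspring_sexes = rng.random(config.n_focal + config.n_bait) < 0.5
    samples += [
        Sample(f"focal{i+1:02d}", FOCAL, "female" if offspring_sexes[i] else "male")
        for i in range(config.n_focal)
    ]
    samples += [
        Sample(
            f"bait{i+1:02d}",
            BAIT,
            "female" if offspring_sexes[config.n_focal + i] else "male",
        )
        for i in range(config.n_bait)
    ]
    manifest = SampleManifest(samples)
    n_samples = len(manifest)
    father_idx = 1 + int(rng.integers(config.n_candidate_fathers))
    father_id = samples[father_idx].sample_id
    offspring_idx = [manifest.index[s.sample_id] for s in manifest.offspring]

    ploidy_by_sample = {
        s.sample_id: {c: ploidy_map.copy_number(c, s.sex) for c, _, _ in config.chromosomes}
        for s in samples
    }

    # ---- window-constant depths and masks ----------------------------
    win = config.depth_window
    depths: dict[str, dict[str, np.ndarray]] = {}
    masks: dict[str, DepthMask] = {}
    for s in samples:
        per_chrom_depth: dict[str, np.ndarray] = {}
        per_chrom_ivs: dict[str, list[tuple[int, int]]] = {}
        for chrom, length, cls in config.chromosomes:
            mean = config.mean_coverage[s.role]
            if cls == X and s.sex == "male":
                mean /= 2.0
            n_win = -(-length // win)
            d = _nb_depths(rng, mean, config.depth_dispersion, n_win)
            per_chrom_depth[chrom] = d
            ok = d >= config.mask_threshold
            ivs = [
                (int(i * win), int(min((i + 1) * win, length)))
                for i in np.flatnonzero(ok)
            ]
            per_chrom_ivs[chrom] = ivs
        depths[s.sample_id] = per_chrom_depth
        masks[s.sample_id] = DepthMask(s.sample_id, per_chrom_ivs, config.mask_threshold)

    def depth_of(sample_id: str, chrom: str, pos: int) -> int:
        return int(depths[sample_id][chrom][(pos - 1) // win])

    # ---- coordinate bookkeeping --------------------------------------
    chrom_names = [c for c, _, _ in config.chromosomes]
    chrom_len = {c: length for c, length, _ in config.chromosomes}
    offsets = np.concatenate([[0], np.cumsum([chrom_len[c] for c in chrom_names])])
    total_len = int(offsets[-1])

    def to_chrom_pos(g: int) -> tuple[str, int]:
        ci = int(np.searchsorted(offsets, g, side="right")) - 1
        return chrom_names[ci], int(g - offsets[ci]) + 1  # 1-based

    used: set[int] = set()

    def draw_positions(n: int, space: list[int]) -> list[int]:
        # `space` = chromosome indices eligible (autosome vs X spaces)
        lens = np.array([chrom_len[chrom_names[i]] for i in space])
        cum = np.concatenate([[0], np.cumsum(lens)])
        out = []
        while len(out) < n:
            r = int(rng.integers(cum[-1]))
            ci = int(np.searchsorted(cum, r, side="right")) - 1
            g = int(offsets[space[ci]]) + (r - int(cum[ci]))
            if g not in used:
                used.add(g)
                out.append(g)
        return out

    auto_space = [i for i, (_, _, cls) in enumerate(config.chromosomes) if cls == AUTOSOME]
    x_space = [i for i, (_, _, cls) in enumerate(config.chromosomes) if cls == X]
    auto_len = int(sum(chrom_len[chrom_names[i]] for i in auto_space))
    x_len = int(sum(chrom_len[chrom_names[i]] for i in x_space))

    # ---- founder polymorphism and Mendelian transmission -------------
    poly_g = sorted(draw_positions(config.n_polymorphic_sites, list(range(len(chrom_names)))))
    poly_freq = rng.uniform(*config.allele_freq_range, size=len(poly_g))
    poly_chrom_idx = np.searchsorted(offsets, poly_g, side="right") - 1
    poly_is_x = np.array(
        [config.chromosomes[ci][2] == X for ci in poly_chrom_idx]
    )

    n_poly = len(poly_g)
    dose = np.zeros((n_poly, n_samples), dtype=np.int8)

    # founders: mother + candidate males (distractors are unrelated founders)
    p = poly_freq
    mother_dose = (rng.random(n_poly) < p).astype(np.int8) + (
        rng.random(n_poly) < p
    ).astype(np.int8)
    dose[:, 0] = mother_dose
    for j in range(1, 1 + config.n_candidate_fathers):
        d = (rng.random(n_poly) < p).astype(np.int8) + (rng.random(n_poly) < p).astype(
            np.int8
        )
        d[poly_is_x] = (rng.random(int(poly_is_x.sum())) < p[poly_is_x]).astype(np.int8)
        dose[:, j] = d
    father_dose = dose[:, father_idx]

    for oi in offspring_idx:
        sex = samples[oi].sex
        maternal = _transmit(rng, mother_dose)
        paternal = _transmit(rng, father_dose)
        # X: father is hemizygous; daughters get his single X allele,
        # sons get no paternal X
        paternal[poly_is_x] = father_dose[poly_is_x] if sex == "female" else 0
        d = maternal + paternal
        if sex == "male":
            d[poly_is_x] = maternal[poly_is_x]
        dose[:, oi] = d

    # ---- planted de novo mutations -----------------------------------
    mu = config.mu_true
    planted: list[tuple[int, int]] = []  # (global coord, carrier sample index)
    for oi in offspring_idx:
        if mu == 0.0:
            break
        sex = samples[oi].sex
        n_auto = rng.poisson(2.0 * auto_len * mu)
        x_copies = 2 if sex == "female" else 1
        n_x = rng.poisson(x_copies * x_len * mu) if x_len else 0
        if n_auto + n_x > total_len - len(used):
            raise ValueError("mu_true too large: planted sites exceed coordinates")
        for g in draw_positions(int(n_auto), auto_space):
            planted.append((g, oi))
        for g in draw_positions(int(n_x), x_space):
            planted.append((g, oi))

    # ---- artifact (mis-mapping) sites --------------------------------
    n_art = rng.poisson(config.artifact_site_rate * total_len)
    artifact_g = draw_positions(int(n_art), list(range(len(chrom_names))))
    artifact_affect: dict[int, np.ndarray] = {
        g: rng.random(n_samples) < config.artifact_share_prob for g in artifact_g
    }

    # ---- assemble all emitted sites ----------------------------------
    site_g = poly_g + [g for g, _ in planted] + list(artifact_g)
    kind = ["poly"] * n_poly + ["planted"] * len(planted) + ["artifact"] * len(artifact_g)
    carrier = [-1] * n_poly + [oi for _, oi in planted] + [-1] * len(artifact_g)
    dose_rows = list(dose)
    for g, oi in planted:
        row = np.zeros(n_samples, dtype=np.int8)
        row[oi] = 1
        dose_rows.append(row)
    for g in artifact_g:
        dose_rows.append(np.zeros(n_samples, dtype=np.int8))

    order = np.argsort(site_g, kind="stable")
    records: list[SiteRecord] = []
    truth_dosage: dict[tuple[str, int], np.ndarray] = {}
    mutations: list[PlantedMutation] = []
    eps = config.error_rate

    ploidy_mat_by_chrom = {
        chrom: np.array(
            [ploidy_by_sample[s.sample_id][chrom] for s in samples], dtype=np.int8
        )
        for chrom in chrom_names
    }

    base_idx = rng.integers(0, 4, size=len(site_g))
    alt_shift = rng.integers(1, 4, size=len(site_g))

    for rank, si in enumerate(order):
        g = site_g[si]
        chrom, pos = to_chrom_pos(g)
        ploidy_row = ploidy_mat_by_chrom[chrom]
        d_row = dose_rows[si].astype(np.int64)
        dp = np.array(
            [depths[s.sample_id][chrom][(pos - 1) // win] for s in samples],
            dtype=np.int64,
        )
        # alt-read probability by true genotype
        q = np.where(
            ploidy_row == 1,
            np.where(d_row >= 1, 1.0 - eps, eps),
            np.select([d_row == 1, d_row == 2], [0.5, 1.0 - eps], default=eps),
        )
        if kind[si] == "artifact":
            q = np.where(artifact_affect[g], config.artifact_alt_fraction, q)
        ad_alt = rng.binomial(dp, q)
        ad_ref = dp - ad_alt
        codes = _call_matrix(dp, ad_alt, ploidy_row, eps, config.min_call_depth)
        gts = [_CODE_TO_GT[int(c)] for c in codes]
        ref = BASES[base_idx[si]]
        alt = BASES[(base_idx[si] + alt_shift[si]) % 4]
        rec = SiteRecord(
            chrom=chrom,
            pos=pos,
            ref=ref,
            alts=(alt,),
            gts=gts,
            dp=dp,
            ad_ref=ad_ref,
            ad_alt=ad_alt,
        )
        records.append(rec)
        truth_dosage[(chrom, pos)] = dose_rows[si].copy()
        if kind[si] == "planted":
            mutations.append(
                PlantedMutation(chrom, pos, samples[carrier[si]].sample_id, ref, alt)
            )

    truth = TruthSet(
        father_id=father_id,
        mutations=mutations,
        true_dosage=truth_dosage,
        ploidy=ploidy_by_sample,
    )
    return SimResult(
        config=config,
        manifest=manifest,
        ploidy_map=ploidy_map,
        records=records,
        masks=masks,
        truth=truth,
        depth_of=depth_of,
    )
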