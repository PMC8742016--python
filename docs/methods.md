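# Methods

## The estimator

The quantity estimated is µ, the expected number of single-base
germline mutations per site per generation on one haploid genome
copy. With m confirmed de novo mutation events among the focal
offspring, C callable coordinates (summed over parent–focal trios and
doubled for diploidy), and a spike-in experiment in which
`inserted` synthetic mutations landed in callable sites and
`detected` of them survived re-detection,

    mu = (m / C) * (inserted / detected).

m is treated as a Poisson count; its 95% interval is the exact
(Garwood) construction from chi-square quantiles,
lower = χ²(α/2, 2m)/2 (zero when m = 0) and
upper = χ²(1−α/2, 2m+2)/2, scaled by (inserted/detected)/C. The FNR
correction and 1/C are treated as constants: their sampling error
(binomial over ~10⁴ spikes; deterministic interval arithmetic for C)
is negligible next to the Poisson noise of a single-digit m. Display
rounding is 3 significant figures; machine outputs keep full
precision.

Assumptions worth stating: mutations arise independently and
uniformly across callable coordinates (no hotspot model); the spike-in
is representative of real mutations at matched depths (see below); and
the uniform ×2 diploid doubling slightly over-counts X coordinates in
male focal samples, for whom X is hemizygous — a `sex_aware_x` option
counts those singly instead, and is off by default to keep the
headline definition simple and conservative-in-no-direction (X is a
small fraction of the genome).

## Filtering criteria and their reading

Detection operates on joint-called biallelic SNPs and applies, in
funnel order: (i) both parents hom-ref with DP ≥ 10 and AD_ALT
exactly 0; (ii) bait veto; (iii) focal completeness and 1–2 carriers
with DP ≥ 10; (iv) carrier allele balance. Interpretive choices:

* **Inclusive allele-balance bounds.** 0.27·DP ≤ AD_ALT ≤ 0.73·DP,
  evaluated in exact rational arithmetic (27·DP ≤ 100·AD_ALT is an
  integer comparison), so a count sitting exactly on the bound passes
  and no float rounding can flip a boundary case.
* **Positive evidence of absence.** Wherever a criterion demands
  AD_ALT = 0 (parents, bait with called genotypes, non-carrier
  focal), a missing AD field fails the criterion: the site is
  discarded rather than assumed clean.
* **Bait missing genotypes do not veto**, but any bait alternate read
  does, called or not — the bait panel exists precisely to catch
  recurrent low-level artifact reads.
* **Male X.** Hemizygous-alt carriers are accepted in either haploid
  (`1`) or diploid-coded (`1/1`) form and skip the allele-balance band
  (all reads should be alternate); a heterozygous call for a male on X
  is biologically impossible and discards the site as a mis-mapping
  signal. Carrier DP ≥ 10 applies to carriers only; non-carrier focal
  samples need a called genotype and zero alternate reads.
* **Two-carrier sites** are allowed (a mutation in one parental
  pre-meiotic cell lineage can appear in two offspring) and counted as
  one event per carrier; a config switch restricts to single carriers.
* **Depth threshold semantics.** "Callable" means DP ≥ 10
  (inclusive) everywhere — masks, criterion (i), carrier depth, and
  the spike-in denominator use the same comparison, so the callable
  set and the detectable set coincide by construction.

The co-mapping flag is advisory, not a filter: a candidate is flagged
when another variant within 150 bp (one read length) shows alternate
reads in the same carrier **and** in a bait sample **without a
parental source** (both parents called hom-ref there). Shared
offspring/bait alternate reads that no parent carries are the
signature of reads mis-mapped from a paralogous locus; requiring the
absent parental source keeps ordinary nearby polymorphisms — which
also show carrier and bait alternate reads, at any realistic SNP
density — from flagging every true candidate. Flagged candidates are
excluded from the default m (they await visual curation) but are
reported in full.

## Callable-site accounting

Per trio, the three ≥10x depth masks (mother, father, focal) are
intersected exactly by interval sweep; every joint-caller-reported
coordinate inside the intersection is then removed unless it survived
filtering in that trio, since a reported-but-filtered site has proven
un-callable. Counts are summed over trios and doubled once. Masks are
BED-convention (0-based, half-open); site records are VCF-convention
(1-based); the single conversion point (`pos − 1`) is covered by a
dedicated test.

## Spike-in FNR

Synthetic mutations are inserted at the allele-count level: the
detector consumes only GT/DP/AD, so modifying counts is equivalent to
read-level insertion *for this pipeline* (it cannot probe
alignment-level artifacts, which is a stated limitation, not a bug).
New records are appended at invariant autosomal coordinates drawn
uniformly where both parents' masks reach 10x, one spike per
coordinate, never reused across focal samples. The carrier's
alternate-read count N is drawn from the per-depth empirical
distribution of AD_ALT at known heterozygous sites — sites where the
parents are homozygous for different alleles, so every offspring is
heterozygous — built for total depths 10–100; empty depth bins fall
back to Binomial(d, 0.5), which the empirical tables track. All
*other* samples at a spiked record draw AD_ALT from the same
sequencing-error model as the rest of the data,
Binomial(DP, error_rate), and are re-called. This matters: the
zero-alternate-read criteria mean a real mutation is vetoed whenever
any parent or bait sample catches a stray error read at its site, and
spikes must be exposed to the identical risk or the FNR is biased
low. (Read-level insertion achieves this automatically by keeping the
real reads of the other samples.) FNR excludes from its denominator
spikes whose focal depth fell below 10x — those sites are not
callable and are equally excluded from C.

## The synthetic pedigree generator

The generator emulates the statistical structure the analysis relies
on, not reads: founder genotypes from Hardy–Weinberg at allele
frequencies uniform on [0.05, 0.95]; one designated candidate male is
the true mate, the others unrelated founders; offspring inherit one
allele per parent per autosomal site, X transmitted by sex (sons:
maternal only, hemizygous). De novo mutations are planted per
offspring as Poisson with mean 2·L_autosome·µ_true (plus 1 or 2 ×
L_X·µ_true by sex), uniformly over coordinates, converting one
inherited reference allele.

Depth is negative binomial per role (defaults from the sequencing
design: mother 20.4x, candidate males 32.4x, focal 25.7x, bait 13.1x;
dispersion k = 10, halved mean for male X), held constant over 500 bp
windows. The windows give coverage its short-range autocorrelation and
make the ≥10x masks, the emitted record depths, and the spike-in depth
lookups exactly consistent with one another. Allele depths are
Binomial(DP, q) with q = 0.5 for heterozygotes, ε for hom-ref, 1−ε
for hom/hemizygous-alt. Genotypes are maximum-likelihood calls among
the binomial models (ties resolve toward the reference call; missing
below 4x). Mis-mapping artifact sites are injected at 2×10⁻⁵ per bp;
each sample is independently affected with probability 0.6 and
affected samples draw AD_ALT at a 20% alternate fraction — these
exist so the bait veto and the co-mapping flag have real work to do.

The per-read error rate ε defaults to 5×10⁻⁴. This is an error rate
*for observations that reach the AD fields of a joint caller*, not a
raw base-calling error; with ~530x of summed parent/bait/non-carrier
depth per site under this design, the zero-alternate-read criteria
then veto ~20–25% of true mutations, which is the scale of FNR this
study design produces. Default µ_true is 5×10⁻⁷ so a 1.2 Mb toy
genome plants a handful of mutations; real insect rates (~10⁻⁹)
would plant essentially none at toy scale, and nothing in the
machinery depends on the value.

What the generator does **not** model: read-level alignment (so no
true mapping-quality or clipping signal), indels, recombination
hotspots, selection, GC-biased coverage, batch effects, or
contamination. Passing tests therefore demonstrate the pipeline's
statistical correctness under the stated generative model — unbiased
recovery, honest FNR, correct accounting — not robustness to every
artifact class of real sequencing data.

## Validation studies and problem sizes

The suite validates, at sizes chosen to run in minutes on one CPU:

* **Null soundness** — no mutations, no error, no artifacts → zero
  candidates, exhaustively.
* **Detection completeness** — on genomes with many planted
  mutations, the candidate set at planted coordinates equals an
  independent re-derivation of the four criteria from raw counts.
* **Callable oracle** — interval-sweep counts equal per-coordinate
  brute force on 10 kb genomes with random masks.
* **Paternity recovery** — the four-candidate design (10 focal + 19
  bait, 1500 SNPs): both methods recover the true father in 100/100
  seeded replicates.
* **Parameter recovery** — 500 replicates on a 400 kb autosome with
  6 focal + 6 bait and µ_true = 2×10⁻⁶ (≈ 8 expected detectable
  events each): mean corrected µ̂ within 15% of truth, exact-Poisson
  CI coverage ≥ 90%, and the uncorrected m/C biased low by ≈ FNR —
  the correction's necessity made visible.
* **FNR self-consistency** — pooled spike-in FNR agrees with the
  ground-truth miss rate of planted mutations within binomial error.

## Known limitations

Count-level spiking cannot detect artifacts introduced by the act of
read editing itself; the FNR is conditional on the generative model's
error structure. The estimator ignores uncertainty in C and in the
FNR correction (negligible here, not necessarily at other designs).
Mendelian concordance assumes the candidate males are unrelated to
the true father; close relatives would compress the gap. The X
doubling convention is a deliberate simplification (see above). False
positives are controlled by design (bait veto + curation flag) but
not formally estimated — the pipeline validates positives downstream,
which is outside this package's scope.
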