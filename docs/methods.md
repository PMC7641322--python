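# Methods

`epiwindow` reimplements, as a tested pipeline, the quantitative procedures
used to compare the chromatin and signalling state of mouse embryonic stem
cells (mESCs) cultured in serum versus 2i medium, across three "epitypes":
wild-type J1, the constitutively hypomethylated Dnmt triple-knockout (TKO),
and a constitutively methylated rescue line (3B3l). The real study rests on
deposited MeDIP-seq, ChIP-seq, RNA-seq, microarray, bisulfite, HPLC and
DigiWest datasets; this package reproduces the *methods* and validates them
on synthetic data with planted ground truth, not the dataset-dependent
headline numbers.

## Window quantification model

Aligned fragments (BED intervals; strandless, since immunoprecipitated DNA
is double-stranded) are binned into a fixed 200 bp genome grid. Each
fragment contributes exactly one count to the window containing its midpoint
`floor((start+end)/2)`; midpoint assignment (rather than
overlap-proportional spreading) conserves totals exactly, which the tests
exploit (`sum(counts) == total_mapped`). The final partial window of a
chromosome is kept at native width without rescaling — this touches at most
one window per chromosome.

Tracks are scaled to reads-per-million (`score * 1e6 / library_total`; any
common scale yields identical downstream calls, a tested invariant), and
background is removed by subtracting the depth-normalized matched input
(sheared non-immunoprecipitated DNA) window-by-window, floored at zero. The
floor loses no information downstream: both the enriched-window definition
(score > 0) and the percentile threshold only use positive excess.

## Peak calling

The threshold is the 95th percentile (nearest-rank: the value at rank
`ceil(p/100 * n)`) of the *positive* window scores of a designated reference
sample (the serum-cultured wild type in the study). Zero windows are
excluded because genome-wide grids are zero-inflated and would drag any
percentile to 0 on sparse data. The threshold is computed once on the
reference and reused verbatim for every other sample, so peak-count
differences between samples are meaningful ("reference asymmetry", tested).

A window qualifies when its score is strictly above the threshold. Every run
of 3 consecutive windows (600 bp) holding at least 2 qualifying windows
marks its full span; overlapping or book-ended spans merge into maximal
peaks. The scanner is verified against exhaustive triplet enumeration plus
interval union on 1000 random grids.

Each peak gets exactly one of six compartment labels by strict precedence:
promoter core (TSS ±100 bp) > promoter proximal (within 1 kb of the TSS) >
promoter distal (1–2 kb) > exonic > intronic > intergenic. Promoter windows
are strand-aware around each gene's TSS and, by default, symmetric: the
source convention "TSS + 1 kb" reads directional, but promoters
conventionally extend upstream, so the symmetric reading is the default and
a `promoter_side="downstream"` flag implements the literal directional
variant. A peak overlapping features of several genes resolves purely by
precedence, never by gene distance — this keeps the six labels an exact
partition (tested against a brute-force oracle).

## Metaprofiles and stratified sets

"Sliding window" feature profiles are realized as fixed binning with
per-base-pair averaging: a feature's span is cut into equal bins and each
bin takes the overlap-length-weighted mean of the window scores it touches
(equivalently, the mean of the window step function over the bin's base
pairs). Defaults: promoters TSS ±2 kb in 40 bins; gene bodies scaled to 100
bins with flanks of 25% gene length in 25 bins each; elements (e.g.
Oct4/Sox2/Nanog binding sites) scaled with flanks of 100% element length.
Bin counts are configurable — the source states the feature spans but not
the step size. Minus-strand features are reversed so bin 0 is always the
5'/upstream end; profiles are exactly invariant to reversing the genome
together with all strands, and constant tracks profile exactly flat (both
tested). Bins falling off a chromosome end are NaN and excluded from the
feature average.

Companion operations: per-gene promoter means (TSS ±1 kb, per-bp weighted,
checked against an independent per-base expansion oracle to 1e-9);
expression quartiles Q1 (high) … Q4 (low) with sizes differing by at most
one and ties broken by gene id; promoter-state stratification (a gene is
"enriched" iff ≥1 peak overlaps TSS ±1 kb); nearest-gene assignment for
distal TF sites (distance to the gene *body*, 0 when overlapping, reported
only within 10 kb, ties to the smaller gene id); and consensus
differential-expression sets (per table: |log2FC| ≥ log2(2) and adjusted
p ≤ 0.05; consensus = intersection across tables, so opposite-direction
genes land in neither set).

## Retrotransposon counting

Each counting unit (a read pair collapsed to its outer span, or a singleton)
is assigned to at most one repeat location: the overlapping annotation with
maximal overlap length, ties broken by the repeat's genomic coordinate so
results are independent of fragment and annotation order. Counts are summed
per subfamily (paired LTR/internal labels use the `name::internal-name`
form), rolled up to class (LTR/LINE/SINE/other) on demand, and normalized
per million mapped fragments. Differential testing of the resulting count
matrix is deliberately out of scope — the matrix is written as TSV for
count-model tools. Note that per-million normalization slightly compresses
planted fold changes when the elevated family is a non-trivial fraction of
the library; the simulation keeps repeats a minor library component, as in
real RNA-seq, and recovers a 3-fold elevation within 25%.

## Bisulfite and HPLC methylation

A bisulfite amplicon is a clone × CpG ternary matrix (methylated /
unmethylated / missing). Percent methylation is
`100 * methylated / (methylated + unmethylated)` over non-missing calls.
Two conditions are compared by a two-tailed Mann–Whitney U test on
*per-clone* methylation levels — clones are the independent sequencing
units; per-CpG column levels are exposed as an alternative observation
unit. The test is exact (full enumeration) when the combined sample size is
at most 20 and tie-free, matching the small clone counts this design
targets, and otherwise uses the normal approximation with tie and
continuity corrections (delegated to `scipy.stats.mannwhitneyu`; the test
suite checks it against an independent full-enumeration oracle).

Global 5mC is quantified from HPLC peak areas at the detection maxima of
dCMP (276 nm) and 5mdCMP (282 nm): areas are converted to molar amounts
with the extinction coefficients 8.86e3 (dCMP) and 9.0e3 (5mdCMP), and
percent 5mC = `100 * n_5mC / (n_C + n_5mC)`. The formula is exactly
invariant to common rescaling of both areas.

## DigiWest statistics

Each sample is resolved into 96 molecular-weight fractions read on a
Luminex instrument. Per antibody, background-subtracted data are scaled to
[0, 1] by the antibody-wide maximum; blot-like images paint each
(fraction, sample) cell as a block and apply a Gaussian diffusion of radius
half the element height (implemented as `gaussian_filter` with
sigma = radius/2, reflective padding — mass-conserving to well under 1%).

Analyte values are band-window sums over fractions (the aggregation used by
the original analysis tool is unstated, so the window is an explicit
input), normalized to β-actin, and log2-transformed; zeros are lifted to a
pseudo-floor (half the smallest positive value of the analyte) before the
log. The two-factor ANOVA (factor 1: 2i treatment; factor 2: cell type
J1/TKO/3B3l) uses Type-II sums of squares — identical to Type I/III on the
balanced design, and well-defined on unbalanced synthetic inputs. The null
distribution permutes sample labels jointly (unrestricted; the same seeded
permutation set shared across analytes, MEV-style), and
`p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)` with n_perm = 1000 and
significance at p ≤ 0.005. All-constant analytes take F = 0, p = 1.
Implementation note: residual-maker matrices for the four nested models are
precomputed once, so each permutation costs four quadratic forms across all
analytes simultaneously.

A statistical subtlety worth documenting: with 12 samples in a 6/6
treatment split, a random unrestricted permutation recreates the treatment
partition with probability 2·(6!·6!)/12! = 1/462, so ~2 of 1000
permutations do; conditional on recreating the partition, the permuted
treatment F exceeds the observed one with probability ≈ 1/2 (the balanced
treatment sum of squares depends only on the partition while the residual
varies with the scrambled cell-type labels). Even an arbitrarily strong
treatment effect therefore attains the floor p = 1/1001 only for a fraction
of seeds; the expected saturated p is (1 + K)/1001 with K approximately
Poisson(1.1), and the tests assert the derived bound p ≤ 6/1001 rather than
the knife-edge floor.

Significant analytes (min of the three permutation p-values ≤ alpha) are
clustered on their sample vectors with Euclidean distance and average
linkage (the MEV default; configurable), analytes pre-sorted by name so the
leaf order is deterministic.

## Synthetic data: what it emulates and what it does not

Every generator is deterministic per seed and exports its planted truth.

* **Fragments.** Lengths follow the sonication protocol (150–700 bp, mean
  300 bp). A triangular distribution cannot realize that mean on that
  support (its minimum mean is ≈333 bp), so lengths are drawn from a
  truncated exponential on [min, max] whose scale is solved numerically
  (Brent) to match the mean; the mirrored variant covers means above the
  interval midpoint and the exact midpoint falls back to uniform. Input
  fragments have uniform midpoints; IP fragments are drawn by rejection
  against a piecewise-constant midpoint density multiplied by the
  enrichment fold inside each planted region (exact, testable). Fragments
  straddling a chromosome end are clipped. Not emulated: GC/mappability
  bias, duplicates, chromatin accessibility structure — so passing recovery
  tests demonstrate correctness of the quantification chain, not robustness
  to those real-data artefacts.
* **Genome.** Non-overlapping stranded multi-exon genes placed on a slot
  grid; repeats drawn from a small catalog of mouse retrotransposon
  subfamily labels; OSN-style sites of 200–500 bp. No sequence is
  generated — the pipeline consumes aligned intervals.
* **Expression.** Log2 expression Normal per gene (log-normal expression)
  with a planted ±3 log2 2i shift for consensus genes in every epitype;
  per-epitype tables carry Welch-t / Benjamini–Hochberg adjusted p-values
  from 3 replicates per condition.
* **Clone matrices.** Bernoulli(p_meth) calls with cells missing at a 5%
  default rate; defaults 24 clones × 20 CpGs per condition.
* **DigiWest.** Gaussian bands at analyte-specific fractions; a sample's
  amplitude carries multiplicative log-normal noise (sigma 0.1, shared
  across the 96 fractions) so band sums are exactly log-normal and planted
  effects — specified in pooled-SD units of the final log2 actin-normalized
  response — convert exactly to log2 fold changes (one SD unit =
  sigma·sqrt(2)/ln 2; the sqrt(2) accounts for the actin denominator's own
  noise). A no-effect `beta_actin` analyte is always included. Real
  bead-count noise, cross-reactivity and fraction bleed-over are not
  modelled.

## Problem sizes and numerical choices

The packaged study runs on a 1 Mb single-chromosome genome (5000 windows),
40 genes, 1e5 IP + 1e5 input fragments, 10 planted 2 kb regions at fold 10
for peak recovery, and 50 regions at fold 100 for the enriched-window
halving comparison — the high fold keeps background windows at zero after
input subtraction so the enriched-window count is dominated by planted
territory, mirroring the strongly enriched MeDIP regime the window counting
is meant for. DigiWest calibration uses 200 analytes, 1000 permutations, a
2×3 design with n = 2 per cell. These sizes keep the full suite and the
acceptance script to a few minutes on one CPU while leaving every
statistical check well-powered.

Tie-breaks are deterministic everywhere (gene id for quartiles and nearest
genes, genomic coordinate for repeat assignment, analyte name for cluster
leaves). Degenerate inputs fail loudly: all-zero reference tracks, empty
element lists, zero library totals, empty design cells, all-missing clone
matrices, and non-positive actin values raise errors naming the problem.

## Known limitations

* BAM input is not parsed; fragments enter as BED intervals (the
  `FragmentSet` contract leaves room for a pysam-backed reader).
* The peak caller has no FDR control or per-peak p-values by design — it
  reproduces the percentile/2-of-3 procedure, whose statistical guarantees
  are entirely determined by the reference percentile.
* Repeat differential testing, GO enrichment and microarray model fitting
  are consumed from, or delegated to, external tools.
* The enriched-window halving result is a property of the planted geometry;
  at low enrichment folds, background windows surviving subtraction would
  dilute the ratio toward 1.
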