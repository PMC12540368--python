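# Methods

This note records the model behind each stage, the tunable parameters
and their defaults, what the synthetic cohorts do and do not emulate,
and the numerical choices made where the design was genuinely open.

## CNV inference from expression

The residual profile is built from log-normalized expression
(`ln(1 + 10^4·c/C)`), not raw counts, in four steps along
position-ordered genes (stable sort by natural chromosome order, then
start coordinate; genes without coordinates are dropped with a logged
count; mitochondrial genes are excluded by default because their
abundance tracks cell quality, not copy number):

1. subtract the per-gene mean over the reference cells (all pooled
   NT epithelial cells);
2. clip residuals into [−3, +3] (`clip`, default 3.0) to bound the
   influence of single highly expressed genes;
3. moving average of length `window` (default 101 genes, odd) applied
   independently within each chromosome; chromosome ends use truncated
   (shrinking) windows rather than padding, so no values are
   fabricated and chromosomes never mix;
4. subtract each cell's median (robust to large aberrant segments),
   then the mean smoothed reference profile, so reference residuals
   center on zero by construction.

The per-cell CNV score is the mean squared residual (`mean_square`;
`sum_square` selectable). No formula is canonical for this score in
the literature; mean-square is the common convention in
inferCNV-style analyses and makes the 0.001 malignancy threshold
scale-interpretable. Window, clip and score method are config-exposed.

On the synthetic cohorts the score separates cleanly: the noise floor
of normal cells is ≈0.007 (driven by window length and NB dispersion)
and a clone with 20% of genes at copy ratio 2.0/0.5 scores ≈0.038.
Note the 0.001 threshold is therefore nearly always exceeded even by
normal cells; the correlation criterion does the discriminating, which
matches how the dual rule behaves on real data.

## Malignancy calling

Within each pathological group the top `ceil(0.05·n)` cells by CNV
score (ties broken by score desc, then cell id asc — deterministic)
are averaged into a high-CNV reference profile. Correlation is Pearson
on CNV residual profiles, not raw expression: residuals are already
library- and program-corrected, so correlation measures shared
aberration structure. (`correlate-on: expression` remains possible by
passing a different matrix; the residual default is the package's
choice where the procedure is ambiguous.) Each cell is compared
against its own group's profile, per the per-group selection. A cell
is malignant iff score > 0.001 AND r > 0.5, both strict; reference-
group (NT) cells are never called malignant; cells with missing
evidence are flagged unclassified rather than silently dropped.

## Module scores

Genes are ranked by mean expression across cells and split into
`n_bins` (default 24) equal-frequency bins; ranking instead of
quantile cutting guarantees non-empty bins. For each set gene,
`n_ctrl` (default 100) control genes are drawn from its bin — without
replacement when the bin is large enough, with replacement otherwise —
from a deterministic RNG stream keyed by (set name, seed) (CRC-32 of
the name mixed into the seed sequence). The score is the mean
expression of the set genes minus the mean of the pooled control draws
(duplicates kept), per cell. Control-sampling noise moves scores by
<0.1 between seeds at genome size 2,000; a fixed seed reproduces them
bit-for-bit.

Curated MSigDB hallmark sets are not vendored (license and version
drift); users supply a GMT file. The pipeline otherwise scores
deterministic synthetic stand-in sets so that downstream stages always
run.

## States and subtypes

Cluster functional states are a formalization of a visual heatmap
classification, made deterministic and auditable: per-cluster program
means (EMT, proliferation, CNV, antigen presentation) are z-scored
across clusters with the population SD; the cascade assigns gamma when
`proliferation_z + cnv_z > 0` and `antigen_z < 0`, else beta when
`emt_z > 0` and `antigen_z < 0`, else alpha. All three thresholds
(0 on the z scale) are config-exposed; z-scoring makes the assignment
invariant to affine rescaling of any program and to cluster order. A
rule trace is recorded per cluster. Fewer than three clusters is an
error — three states are not derivable.

Subtype calls use malignant cells only (tumor-sample marker expression
is what the classification is defined on). Marker means per unit are
z-scaled across units; with a single unit, or a marker flat across
units, the raw mean / a centered zero is used instead. Ties resolve by
fixed priority NEUROG3 → POU2F3 → ASCL1 with a warning; the margin
(winner minus runner-up, z-units) is reported as call confidence. The
marker triple follows the NEUROG3/POU2F3/ASCL1 definition of
SCCE_N/P/A; one published figure variant lists SCGN in place of ASCL1,
and the marker tuple is an argument for that reason.

## Marker detection

pct_in/pct_out count cells with normalized value > 0. The prefilter
keeps genes with max(pct_in, pct_out) ≥ min.pct (0.25), matching the
usual one-vs-rest semantics; the fold change is
`log2((mean(expm1(in)) + 1) / (mean(expm1(out)) + 1))` (natural-log
variant selectable), thresholded at 0.25 (positive-only by default).
P-values come from the Wilcoxon rank-sum test; adjustment is
Benjamini–Hochberg jointly across all tested (gene, cluster) pairs
(a Bonferroni flag is provided, since tools differ here), and rows
with adjusted p < 0.05 are kept. Clusters with fewer than 3 cells are
skipped with a warning.

## Statistical machinery

- **Rank-sum test**: when the smaller group has ≤8 observations (and
  the labeling count is tractable) the two-sided p is exact — full
  enumeration over labelings of the mid-rank sum, so ties are handled
  exactly; otherwise the tie-corrected normal approximation with
  continuity correction. Exact and approximate p agree within 0.02 at
  8-vs-8 in the test suite.
- **Dip test**: the dip statistic (sup-distance from the empirical CDF
  to the nearest unimodal CDF) is computed by alternating greatest
  convex minorant / least concave majorant envelopes on a shrinking
  modal interval. It is validated in the test suite against an exact
  oracle that solves the fixed-mode unimodal-fit problem as a linear
  program, and against closed forms (an equal two-point mixture gives
  0.25; an evenly spaced sample gives the 1/(2n) floor). Samples tied
  at the mode are treated without an atom there, which can only raise
  the statistic; continuous scores are unaffected. The p-value is
  Monte-Carlo calibrated against uniform null samples of the same size
  (default 200 replicates, seeded), the classical null for this test.
- Spearman (mid-ranks, t-approximation) and Kruskal–Wallis come from
  scipy; BH from statsmodels, verified against a step-up oracle.

## Synthetic cohorts

The generator emulates exactly the features the analysis consumes:
NB(μ, r) counts (variance μ + μ²/r, dispersion r = 2) around
log-normal gene means (σ = 1) scaled to a 5,000-count target library;
log-normal library-size variation (σ = 0.3); clone segments
multiplying μ by their copy ratio; mutually exclusive subtype programs
(15 genes each, fold 6) and a 7-gene NE program (fold 4; ASCL1 is left
to the subtype-A program so exclusivity holds) in malignant cells;
per-cell Beta(2, 38) mitochondrial fractions (mean 5%, ≈10% of cells
beyond the QC threshold) inflating flagged genes; and a 2% fraction of
low-depth cells for the detected-genes filter to remove. Marker and
program genes are placed at the front of autosomes 1..n−1 and CNV
segments in back halves / the last autosome, so expression programs
and copy-number implants never overlap.

The default study conditions: a 2,000-gene, 10-autosome genome plus 10
genes on chrM; 250 NT reference cells; 250 tumor-resident normal
epithelial cells; one 500-cell malignant clone carrying a 2.0 gain of
the whole last autosome (10% of genes, emulating a broad
chromosome-level amplification) plus scattered 0.5 losses over another
10%; three tumor samples carrying subtypes N/P/A. The two-clone
variant (300+300 cells, 10% vs 40% of genes aberrant) produces the
bimodal CNV-score distribution used to test the dip statistic. Desk
scale was chosen so the full suite runs in seconds; effect sizes are
moderate (copy ratios 0.5–3), not tuned to the classifier.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: doublets, ambient RNA, batch effects,
UMI saturation, correlated gene programs beyond the implanted ones,
smooth CNV boundary decay, or subclonal phylogenies. Real-data use
additionally requires genuine gene annotations and curated gene sets.

## Degenerate inputs and tie-breaks

Constant vectors: Pearson/Spearman return 0 / NaN with a warning
rather than raising. QC retains boundary cells exactly (199 detected
genes is excluded, 200 is retained; mitochondrial fraction exactly 10%
is retained). Equal CNV scores at the top-5% boundary resolve by cell
id. Subtype ties resolve by marker priority. All RNG flows from
`numpy.random.default_rng` seeded per component, so every artifact is
byte-reproducible under a fixed seed.
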