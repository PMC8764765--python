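# Methods

## Gene flattening and windowing

All interval arithmetic is 0-based half-open; GTF input (1-based closed) is
converted on parse.  A gene's annotated exons are merged into disjoint
blocks; overlapping *and book-ended* blocks are joined (the behaviour of the
standard interval-merging tools this step mirrors).  Introns are the gaps
between consecutive merged exons; flanks extend `flank_length` bp (default
1500) beyond the terminal exons, clipped at position 0 and at the
chromosome length when one is supplied, so a flank may be shorter than
configured or absent entirely.

Each of the `2E + 1` regions is tiled into `n_w` contiguous windows
(default 3).  When the region length is not divisible by `n_w`, the
remainder goes to the earliest windows in genomic order — a deterministic
rule that keeps window sizes within 1 bp of each other.  Regions shorter
than `n_w` bp produce zero-length windows, which are dropped with a
warning; undefined (0-length) features are never emitted.  Region ordinals
and window indices are assigned 5′→3′ with respect to the strand, while
coordinates stay genomic, so reversing the strand reverses the labelling
but not the intervals.  Unstranded genes are ordered as if on the + strand
(warned).  Defaults `n_w = 3`, `flank_length = 1500` are the operating
point at which the window count balances resolution against overfitting
and per-window read depth.

## Counting and the proportion feature

A read contributes +1 to every window that any of its aligned blocks
overlaps by ≥ 1 bp, and at most +1 per window per read (a spliced read
whose two blocks touch the same window counts once).  The splice gap of a
split read creates no intron-window counts.  The per-gene denominator
("gene reads") is the number of *distinct* reads overlapping any window of
the gene — not the column sum, which would double-count boundary-spanning
reads — so the <10-read sample filter is a genuine read-depth filter.
Samples are filtered per gene: a sample excluded at one gene participates
normally at others.  The feature is

```
value[s, w] = (count[s, w] / gene_total[s]) / length[w]
```

Counting is implemented with a vectorized binary-search algorithm over the
sorted, non-overlapping window boundaries, with (read, window) pairs
deduplicated; a brute-force all-pairs loop covers arbitrary (overlapping)
window sets and serves as the independent oracle in the tests.  Counting is
invariant to read input order.  Paired-end mates count as two reads;
secondary/supplementary/duplicate BAM records are skipped; strandedness is
off by default and opt-in, since public cohorts differ in library design.

## Per-gene classification

Split: stratified 80/20, per-class training count = round-half-up of
0.8 × class size, seeded per gene so reruns and permutation runs share the
identical partition.  Preprocessing is fit on training rows only:
near-zero-variance filter (drop a window when it is constant, or when the
most-common/second-most-common frequency ratio exceeds 19 = 95/5 *and*
unique values are < 10% of samples — the conventional defaults), then
z-scaling by training mean and SD (ddof = 1).  Tuning: mean accuracy over
10-fold stratified CV with 5 repeats across the hyperparameter grid; ties
go to the earlier grid point; the winner is refit on the full training
set.  With a single-point grid the CV stage is skipped (tuning over one
candidate selects nothing) and `cv_accuracy` is reported as NaN.

Grids.  Full defaults: elastic net — mixing ratio 0.1…1.0 (10 values) × 10
log-spaced penalty strengths; gradient boosting — depth {1,2,3} × learning
rate {0.3, 0.1} × {50,100,150} trees; random forest — features-per-split
{√p, p/3, p} at 500 trees; logistic — none.  Reduced (`small`) presets
(elastic net 3 × 2, boosting depth {1,2} at 60 trees, forest single point)
keep cohort-scale simulation studies to desk runtimes; results should be,
and in the simulation suite are, robust to this choice.

Scoring.  The *P* value is the one-sided exact binomial tail
P(X ≥ k), X ~ Binomial(n_test, NIR), with k the number of correct held-out
predictions and NIR the majority-class share of the test set.  This is the
standard "accuracy vs no-information rate" test of the caret-style
workflow; it is conservative (super-uniform) under the null, and with
small or imbalanced test sets its discreteness caps attainable
significance — e.g. 12 test samples at NIR 0.83 cannot reach p < 0.05 even
at perfect accuracy.  Exact probability ties at 0.5 predict the training
majority class.  Class imbalance is handled by stratification only; no
reweighting.

Importance.  logistic: Wald |z| from the observed information matrix
(fallback to |coefficient| when the information matrix is degenerate, e.g.
perfect separation); elastic net: |coefficient| on the standardized scale;
random forest: mean impurity decrease; gradient boosting: total split
gain, 0 for unused features.  Scores are rescaled to [0, 100] within the
gene (max = 100; all-zero stays all-zero).

## Permutations and FDR

Ten permutation runs by default: training labels are shuffled uniformly
(class counts preserved; not stratified or blocked), the test partition
and labels untouched, and the full tune/fit/score pipeline repeated.  At
threshold t, FDR = min(1, mean permuted count ≤ t / observed count ≤ t);
enrichment is the reciprocal ratio; an undefined ratio (0 observed) is
reported NA.  Default reporting bins: 0.001, 0.01, 0.05, 0.1, 1.  FDR is
reported per model type.

## The simulator

What it emulates: a two-group cohort on a synthetic chromosome of
multi-exon genes; each AS gene has a canonical isoform (the public
annotation) and a withheld variant isoform realizing one of the nine event
types, assigned round-robin so types are equally frequent.  Affected
samples (group 1) draw each read from canonical vs variant at 50:50
(`variant_ratio` configurable); unaffected samples express canonical only.
Null datasets carry no variants and random labels with the same group
split.  The grid generator reproduces the full design — cohorts
{250, 500, 1000} × depths {100k, 400k, 1M} × affected fractions
{0.8, 0.7, 0.6} = 27 AS datasets plus 9 matched nulls — with the same gene
carrying the same event in every dataset.

Numbers chosen here (stated, not fitted): exon count 4–12, exon length
50–300 bp, intron length 200–3000 bp, 4 kb gene spacing (no overlapping
genes, by construction); single-end 75 bp reads placed uniformly on the
mature transcript and spliced back to genomic blocks; per-gene expression
weights log-normal(0, 0.5) fixed within a dataset, per-sample per-gene
read counts Poisson so the per-sample chromosomal total is
Poisson(`chrom_read_count`); alternative 3′/5′ splice-site shifts of
20–100 bp; alternative first/last exons placed 100–800 bp into the flank
(inside the windowed span).  The default 60-gene chromosome uses
`chrom_read_count` = round(400000 · 60/513) = 46784, preserving the
per-gene depth of a 400k-read, 513-gene chromosome.  All randomness
derives from one seed via independent streams keyed by (gene, sample), so
output is byte-identical across reruns and identical whether reads are
materialized per sample (BED12) or consumed in memory per gene.

What it does **not** model: sequencing error, GC/positional bias, mappability
and alignment artefacts, overlapping genes, partial isoform usage in
"unaffected" samples, and — deliberately simple — realistic heavy-tailed
expression: log-normal(0, 0.5) spreads per-gene depth by only ~3× across
the 95% range, so virtually no simulated gene is low-coverage.  Passing
power numbers on these simulations therefore speak to the method's
behaviour under clean, adequately covered genes, not to sensitivity on
real cohorts where low expression is the dominant failure mode.

## Numerical and degenerate-input choices

Binomial tails via the exact survival function; information-matrix
inversion by pseudo-inverse with finite-value guards; saga solver at
tol 1e-3 / 5000 iterations for the elastic net on standardized features;
xgboost `hist` with 64 bins, single thread, seeded.  Genes become
"untestable" (reported, never fatal) when every sample fails the read
filter, a class cannot appear in both partitions, or the variance filter
removes every window.  Decile transform: ceil(10 · rank / W) with average
ranks for ties (all-tied genes land mid-scale rather than at 10).  In the
region profile each exon contributes once — to its from-5′ slot when within
the first 8, else to its from-3′ slot — avoiding double counting in genes
with 9–16 exons.  "Splice-site window": a window whose closed interval
touches an internal exon/intron junction; gene start/end are excluded as
transcription, not splice, boundaries.  The splice-site t-test is Welch,
one-sided (splice > other), pooled across the profiled genes.

## Known limitations

Single-chromosome, non-overlapping synthetic genes; binary groups only;
the model P value is a test of *discriminability*, not effect size, so very
large cohorts can flag subtle distributional differences of no biological
consequence; and the binomial test's discreteness limits per-gene
significance when test sets are small or severely imbalanced.  Windows are
built per gene independently, so overlapping genes in real annotations can
shadow each other's signal.

## Problem sizes in the shipped checks

The test suite and acceptance script run the power study at 60 genes
(cohort 500, depth 46784), null calibration at 40 genes (cohort 200), and
importance recovery at 12 exon-skipping genes (cohort 200, balanced) —
sizes chosen to keep the whole suite within ordinary desk runtimes while
leaving every statistical check adequately powered.
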