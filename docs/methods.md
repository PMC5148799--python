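# Methods

This note documents the statistical model behind `rexpress`, the choices
made where the procedure is genuinely open, and what the synthetic-data
tests do and do not establish about real data.

## The rEx enrichment call

For one day, each gene's focal-tissue **maximum** FPKM is compared to its
**median** FPKM over all non-focal samples. Max-vs-median is deliberately
asymmetric: the maximum is sensitive to expression in any focal replicate
(a gene need only be "on" in the focal tissue), while the median is robust
to a single aberrant comparison tissue. The ratio is taken on log2 scale
with a pseudocount:

    rEx = log2((focal_max + ε) / (other_median + ε)),  ε = 0.1 FPKM default.

ε exists for the tissue-absent case (median 0, a common and meaningful
outcome), bounds the ratio, and keeps every gene scoreable. It is
configurable; 0.1 FPKM is a conventional "detection floor" scale for
FPKM data. The cost is compression of ratios for genes expressed well below
1 FPKM — the dominant source of missed calls in recovery experiments.

Two filters are applied jointly:

1. **z-score** — rEx standardized against the all-gene rEx distribution of
   the same day, using the sample (n−1) standard deviation, with no
   expression floor by default (an optional `min_focal_fpkm` floor exists).
   The call is one-sided (`z > 2`): enrichment names the upper tail;
   depletion is not of interest.
2. **t-test** — a per-gene two-sided Welch (unequal-variance) test of
   log2(FPKM + ε) between focal and pooled non-focal replicates of that
   day. The replicate-level two-sample test is the reading that uses the
   study's replicate structure; an alternative `t_test="ratio_normal"` mode
   (normal p-value of the gene's standardized ratio, i.e. a one-sample test
   against the global distribution) is provided for comparison. p-values are
   uncorrected by default, matching the procedure being reproduced;
   Benjamini–Hochberg adjustment is available behind a flag for principled
   reuse. Genes with fewer than two replicates on either side, or with zero
   variance on both sides, get an undefined (NaN) p-value and are never
   called enriched.

"Median over all other tissues" is read as the median over all non-focal
samples **pooled** (default); a `median_mode="per_tissue"` switch takes the
median of per-tissue medians instead, which weighs tissues equally
regardless of replicate count.

Each day is scored strictly independently: scores for day *d* are a function
of day-*d* samples only. Useful invariants, all property-tested: multiplying
every FPKM by c > 0 (with ε scaled by c) changes nothing; raising only one
gene's focal values never lowers its z-score; permuting gene rows permutes
outputs.

## Set decomposition and fold changes

Three per-day enriched lists are decomposed into the unique 7-region
disjoint Venn partition (A = day 21, B = day 22, C = day 42 in reports).
Conservation (regions partition the union) and permutation equivariance are
property-tested.

Between-day fold change for a named gene is the ratio of per-day **mean**
focal-tissue FPKM, optionally ε-stabilized. The function's own default is
ε = 0 — the worked values bundled with the package are plain ratios of
published day means — while the CLI and pipeline pass the scoring ε. Mean
(not max) matches the convention of per-day mean-FPKM reporting. No
statistical test is attached to fold changes; the validation route for them
is qPCR.

## Term over-representation

Enrichment of an annotation term among called genes is tested with the
one-sided Fisher exact test: P(X ≥ k) for X ~ Hypergeom(N, K, n), where N is
the universe size, K the universe genes carrying the term, n the called
genes in the universe, and k the overlap. The universe defaults to all genes
scored that day — the defensible background when none is stated — and is
overridable. The annotation is a user-supplied, versioned flat table
(gene_id, term_id, term_name, term_class ∈ {GO, pathway, TF}); no ontology
DAG propagation and no live database queries, so term statistics are exactly
reproducible against a pinned annotation. The TF term class doubles as the
transcription-factor filter. The implementation delegates to
`scipy.stats.hypergeom.sf`; tests verify it against exhaustive exact-integer
enumeration for every consistent table up to N = 60.

## qPCR delta-Ct summaries

Ct tables carry an explicit reference-gene Ct per well, since the choice of
housekeeping gene belongs to the experimenter. Technical replicates are
averaged within each biological replicate first; delta Ct = mean target Ct −
mean reference Ct per biological replicate; the *inverse* delta Ct (its
negation, so higher = more expressed) is averaged over biological
replicates with SEM = sample SD / √n. With a single biological replicate the
mean is defined but the SEM is flagged undefined rather than reported as 0.
Shift invariance (adding a constant to both Ct columns) and the
two-level averaging order are property-tested. Relative quantification
against a calibrator day (ddCt) and efficiency correction are out of scope.

## Synthetic compendium generator

The generator emulates the study design: one matrix per day for a focal
tissue (pituitary; 15/10/10 replicates at days 21/22/42) plus 13 comparison
tissues at 3 replicates each, 5000 genes. Expression is log-normal:

    log2 FPKM = baseline_g + tissue_offset_{g,t,day} + noise_{sample}

with baseline ~ N(3, 2²) between genes, tissue offsets ~ N(0, 0.5²) redrawn
per day (each day is an independent experiment), and replicate noise
~ N(0, 0.25²). Log-normality is the minimal generative model consistent with
analyzing FPKM on log2 scale; the defaults give a realistic right-skewed
FPKM distribution spanning ~0.01–10⁴. Planted enriched genes (default
50-fold, laid out as 25/295/74/92/407/0/0 across the Venn regions of days
21∩22∩42, 21∩22, 21, 22, 42, 21∩42, 22∩42) have all focal values of their
planted days multiplied by the fold. Dropout zeroes a whole (gene, non-focal
tissue, day) block with probability 0.05 — modelling tissue-absent
expression, the degenerate zero-median case the scorer must handle — rather
than per-sample zeros, which FPKM data rarely show in isolation. All
randomness flows from one integer seed through a single generator stream;
identical configs are bitwise-reproducible.

What the generator does *not* emulate: count-level sampling noise (no
negative-binomial layer, no gene-length or library-size artifacts),
correlated gene modules, partially enriched genes (planted folds are all-or
-nothing at one magnitude), or tissue-lineage similarity structure
(offsets are independent across tissues). Passing recovery tests therefore
show the pipeline correctly extracts the signal class it assumes — strong
multiplicative focal enrichment over log-normal noise — not that the
thresholds are optimal for any real compendium.

## Numerical and operational choices

* Problem sizes: recovery and null-calibration checks run at the full study
  design (5000 genes × ~150 samples across three days); the Fisher
  enumeration sweep covers all ~6.4×10⁵ consistent tables with N ≤ 60.
* The zero-variance degenerate input (all genes share one ratio) raises a
  "degenerate ratio distribution" error rather than emitting z = NaN.
* FPKM tables are TSV with a mandatory header and full-precision (`%.17g`)
  rendering, so write→read round-trips are exact; NA tokens are rejected —
  undetected expression is 0 by convention.
* Under the null (no planted genes) the joint z-and-p filter calls ~2.3% of
  genes, consistent with the ~2.28% upper-tail mass above +2 SD of a
  near-Gaussian empirical ratio distribution; the t-test filter removes
  little because genes in the far upper ratio tail usually also separate in
  replicate means.
* Venn plotting is not included; the partition is emitted as a TSV of
  region, size and members.

## Known limitations

* The rEx z-threshold is distribution-relative: with many strongly planted
  genes the all-gene SD inflates, so recovery of *weak* enrichment degrades
  as the enriched fraction grows.
* The pooled non-focal median weighs tissues by replicate count; use
  `median_mode="per_tissue"` when replicate numbers differ widely.
* With a single focal replicate the Welch test is undefined and no gene can
  be called enriched under the default joint filter; the `ratio_normal`
  mode is the fallback for replicate-poor designs.
* Fold changes on genes near zero FPKM are unstable at ε = 0; pass a
  pseudocount for silent genes.
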