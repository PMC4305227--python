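# Methods

## The analysis in one paragraph

`copdmarkers` re-implements, as a tested library plus CLI, a biomarker
discovery procedure for peripheral blood mononuclear cell (PBMC)
expression data in chronic obstructive pulmonary disease (COPD): five
sample groups — healthy controls (CON), stable COPD (STABLE) and acute
exacerbation patients followed longitudinally at hospital days 1, 3 and
10 (AE1/AE3/AE10) — are compared across ten fixed group pairs by pure
fold-change filtering; genes that change consistently across a
designated comparison set form the COPD-specific panel (four
disease-vs-control comparisons) or the AECOPD-specific panel (six
exacerbation-vs-baseline comparisons); each gene's two-step dynamic
pattern over the exacerbation course is classified and compared with the
trajectory of a composite clinical severity score (DESS); selected
lists are tested for gene-set over-representation with the one-sided
Fisher's exact test.

## Preprocessing (RMA-style)

Probe-level linear intensities are quantile normalized (columns forced
onto the row-wise mean of the sorted columns; ties within a column get
the mean of the reference quantiles they span), log2 transformed, and
summarized per gene by two-way median polish (rows first, at most 10
sweeps or until the largest sweep adjustment is below 1e-6). The
reported gene value is the sample effect re-centred to preserve the
block's grand mean; single-probe genes pass through unchanged. No
optical background correction is applied — inputs are assumed
background-free — so the chain is "RMA-style", not full RMA.

Tie handling makes quantile normalization exactly idempotent on
tie-free data; on pathological all-tied columns the midrank convention
re-averages and exact idempotence is lost. Real intensity data are
effectively tie-free.

**A caveat worth knowing:** quantile normalization assumes most genes
are unchanged between samples. When a large one-sided signal is present
(e.g. 2.5 % of genes shifted 12-fold in one arm, as in the default
recovery simulation), the normalization compresses true fold changes by
roughly 0.3 log2 units. The pipeline keeps quantile normalization as a
default stage — real arrays have technical column effects that need it —
but recovery benchmarks against planted truth measure fold changes on
the generated matrix directly (log2 + median polish, no quantile step),
since the simulator plants no technical column effects.

## Fold changes, census and panels

For a pair (A, B), the ratio is `2 ** |mean_A - mean_B|` of group-mean
log2 expression, with direction up/down by the sign of the difference
and "flat" at exactly zero. Group means pool all samples in a group (no
subject pairing). All thresholds are **inclusive** (`>= t`): a gene at
exactly 2.0-fold counts under a 2-fold filter, which is the only reading
consistent with the worked examples' printed membership (3.0-fold rows
surviving a "more than threefold" panel, 2.0-fold pairs in a
"more than twofold" pattern table).

The census counts genes per (pair, threshold) for each direction, with
default threshold ladders 2, 5, 8, 10, 15, 20, 30, 50, 100 (up) and
2, 5, 6, 8, 10, 15, 20, 30, 50, 100 (down). Counts are non-increasing
along the ladder — a property test, not an assumption.

Panel selection ("co-differential") requires the same non-flat direction
in every comparison of the panel's set and a minimum fold across the set
at or above the panel threshold (COPD panel defaults 10/10;
AECOPD panel defaults 10 up / 3 down). Selection runs on whatever row
identity the records carry — on the original array platform several
rows can share one gene symbol — so a symbol-deduplicated count is
reported alongside the row-level lists.

## Trajectories and DESS concordance

The two steps are the AE3-vs-AE1 and AE10-vs-AE3 fold changes; the
pattern is the Cartesian product of the two step directions, with any
flat step yielding "unclassified" (the four patterns cover strict
movements only). The qualifying fold is the weaker step ratio, and the
pattern census is thresholded on it, inclusively.

DESS (Digital Evaluation Score System) grades 64 clinical components at
0/1/2/4 (0 = within normal physiological range, 4 = far outside) and
sums them, so totals lie in [0, 256]. The component rubric is external;
records arrive graded, and incomplete records are rejected (the
component inventory is configurable but the count of 64 is enforced —
it is what makes the 256 ceiling exact). Group summaries report mean and
SE (n−1 standard deviation over √n), displayed half-up to one decimal;
internal values keep full precision.

Concordance compares a gene's signed stable-relative trajectory
(fold vs the STABLE group at the three exacerbation days, negative when
below stable) with the DESS group means on the same days: the primary
output is whether the two-step sign patterns agree; the Pearson r of
the two 3-vectors is reported but explicitly descriptive (one degree of
freedom). An optional log scale (sign × log2|fold|) tempers very large
folds; it cannot change the sign pattern.

## Over-representation

One-sided hypergeometric upper tail
`p = Σ_{i=k}^{min(n,K)} C(K,i) C(N−K,n−i) / C(N,n)` with k the overlap,
n the query size, K the set size within the universe, N the universe
size. The universe is the set of genes actually measured (the gene
matrix), not the genome. Benjamini–Hochberg adjustment is applied
within each annotation domain (the three GO domains, pathways, other);
the enrichment score is −log10(p). Gene sets are flat GMT membership
lists — no GO-graph ancestor propagation.

## Synthetic studies

The generator emulates the study design: six subjects per arm by
default, exacerbation subjects longitudinal across the three days
(shared subject ids), controls and stable arms independent. Per probe
and sample, log2 intensity = gene baseline N(8, 1.5²) + fixed per-probe
offset N(0, 0.25²) centred within each gene + group effect + residual
N(0, noise_sd²), exponentiated to the linear scale (hence strictly
positive). Planted labels add ±log2(fold) to the groups their panel
membership dictates; trajectory plantings set the three exacerbation-day
effects to (2,1,0)·log2(s) for down-down, (0,1,2)·log2(s) for up-up,
(1,0,1) and (0,1,0) for the mixed patterns. The default residual
noise_sd of 0.25 log2 units is a conventional within-group residual for
PBMC arrays, not an estimate; no batch effects, technical column
effects, missing values or scanner background are simulated, so passing
recovery tests demonstrates correctness of the selection logic under the
stated noise, not robustness to real-array artefacts.

DESS records are generated by drawing a per-sample target total
N(group target, dispersion²) clipped to [0, 256] and then raising
randomly chosen components one grade at a time (0→1→2→4) until the
running total reaches the target; simple, and sufficient to make group
means track the targets to within the dispersion.

Problem sizes in the shipped tests and benchmarks — 2 000 genes × 3
probes × 30 samples for recovery, smaller for unit tests — were chosen
to exercise every stage while keeping the full suite around a few
seconds; recovery at these conditions achieves sensitivity ≥ 0.94 and
precision 1.0 at the 10-fold panel threshold against genes planted at
12-fold.

## Numerical and edge-case choices

- Fold changes on log2 means (not ratios of linear means): the
  convention of RMA-scale data.
- Genes with ratio exactly 1 are "flat": excluded from both directions,
  unclassified in trajectories.
- Panel ordering: min fold descending, gene id as tie-break; enrichment
  ordering: p ascending, set id as tie-break — output files are stable.
- Median polish on a 1×n block degenerates to the row itself; the
  decomposition `block = overall + row + col + residual` is exact at
  every exit.
- r is NaN (flagged, never silently 0) when either 3-vector has zero
  variance.
- Readers reject duplicate ids, missing and non-numeric cells with file
  and line coordinates; an exacerbation subject missing a sampling day
  is a warning, not an error (the trajectory stage simply lacks that
  subject's step).

## Known limitations

- Genome-wide counts from the original platform (tens of thousands of
  probes) are not reproducible from the bundled worked examples; the
  examples validate selection logic on the rows whose folds are fully
  known.
- Pearson r over three time points is descriptive; no significance is
  attached to concordance beyond the sign-pattern match.
- The enrichment universe and any term filtering of proprietary
  array-analysis suites differ from this implementation; results are
  methodologically comparable, not numerically.
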