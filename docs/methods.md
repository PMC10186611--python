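# Methods

## Positional model

Telomeres are modelled as the two extremities of each assembled
chromosome: coordinate 0 and coordinate L. The centromere interval
splits a chromosome into a p arm (telomere at 0) and a q arm (telomere
at L); when no centromere is known a zero-width midpoint centromere is
assumed (with a warning) so arm assignment remains defined. All
internal coordinates are 0-based half-open; GTF/GFF3 input is converted
on read, BED is native, and a BED round trip preserves coordinates
exactly.

Each gene's distance to the closest telomere is computed from an
**anchor**. The default, `nearest_edge`, takes the p-side distance as
the gene start and the q-side distance as L − end, then the minimum of
the two; `start`, `midpoint` and `tss` use a single coordinate for both
sides. The anchor is configurable because published analyses of this
kind rarely state it; `nearest_edge` is the default as it is symmetric
and strand-insensitive. A gene equidistant from both telomeres is
assigned to the p arm — an arbitrary but deterministic tie-break with
measure zero on real coordinates.

A **subtelomere window** is the terminal `width` bp of an arm
(default 2,000,000): `[0, width)` on p, `[L − width, L)` on q,
truncated at the chromosome, optionally clipped at the centromere. On
human-scale arms 2 Mb is far from any centromere, so clipping is off by
default and only matters for toy genomes.

Gene records are filtered to protein-coding genes plus all pseudogene
biotypes by default, the universe in which the enrichment statistics
are defined; the filter is a parameter.

## Enrichment statistic

For a gene set of interest of size `s` among `N` genes, and an interval
holding `M` genes of which `k` are in the set:

- p-value: upper tail `P(X ≥ k)` of `Hypergeometric(N, M, s)`. Because
  the survival function convention excludes the observed value, the
  tail is evaluated at `k − 1`, so the observed count is included.
- fold enrichment: `FE = (k/s) / (M/N)` — the set's observed proportion
  in the interval over the interval's share of all genes. `FE = 1` is
  the null expectation; `FE` is undefined (NaN) for gene-free intervals
  and 0 exactly when `k = 0`.

Numerics: for population sizes N ≤ 600 the tail is summed in exact
rational arithmetic (`math.comb` / `Fraction`), which makes small-N
values agree bit-for-bit with brute-force enumeration; larger
populations use scipy's log-gamma-based survival function, which
matches direct pmf summation to well below 1e-12 at the sizes used
here. The two paths agree on their boundary.

Bin profiles group genes by distance into non-overlapping bins of a
configurable width (1 Mb for fine profiles, 2 Mb for the interval
analysis) up to a maximum distance (default 15 Mb); arm windows use the
subtelomere windows above with `s` counted genome-wide by default
(restricting `s` to a subset is done upstream by passing a smaller gene
set). Arms are flagged "enriched" when raw p < 0.05 **and** FE > 1 —
positive enrichment only. p-values are reported raw by default, as is
conventional for these per-figure test families; Benjamini–Hochberg
adjustment (via statsmodels) is an explicit opt-in and adds a
`p_adjusted` column without changing the raw values.

One note on the FE definition: the printed rendering of this formula in
the source material is typographically garbled (it reads as a *product*
of the two proportions, which cannot exceed 1 and so could not produce
any of the reported enrichments above 1). The ratio form used here is
the standard fold-enrichment definition and is the only reading
consistent with the reported behaviour.

## DEG sets, partitions and the derepression test

DESeq2-style tables are thresholded as: up if `padj < α` (default 0.05)
and `log2FC ≥ t`; down if `padj < α` and `log2FC ≤ −t`; `t` defaults
to 1 with 0.58 as the documented alternative for weaker knockdown
contrasts. Rows with missing `padj` (DESeq2 independent filtering) are
never DEGs but remain in the universe, matching DESeq2 semantics.
Classification is monotone in both thresholds.

Two DEG sets partition into A-only / shared / B-only groups. By default
a gene is shared when it is a DEG in both sets regardless of direction
(which reproduces the published 1051/1366/856 → 195/510 arithmetic);
`direction_strict` requires concordant direction.

The derepression comparison takes genes within the window width of a
telomere, splits them into {no-DEG, up-DEG, down-DEG} × {young,
senescent} groups of per-gene *mean* normalized counts (the replicate
summary is configurable in principle; the mean is the default since the
source analyses plot normalized counts without stating a summary), and
reports per-group median/IQR, a Kruskal–Wallis omnibus test over all
non-empty groups, and four pairwise rank-sum contrasts: up young vs up
senescent, down young vs down senescent, and each DEG class vs no-DEGs
in young. Pairwise p-values are unadjusted by default (BH opt-in).
If every value is identical the omnibus statistic is 0 with p = 1
rather than an error.

## Chromatin coverage and grouping

Peak tracks are normalized to sorted, merged interval sets (bookended
intervals united; merging is idempotent and length-preserving on
disjoint input). Two coverage notions are computed, because the source
material describes both and they answer different questions:
`window_coverage` (percent of a subtelomere window under peaks) and
`deg_gene_coverage` (percent of the union of DEG gene bodies under
peaks, shared bases counted once). Both equal a per-base boolean-mask
oracle to 1e-9 on randomized instances. Peak strand, score and summit
columns are ignored.

Per-factor association with the enriched/other arm grouping is the
Spearman rank correlation between the coverage vector and the binary
group indicator (enriched = 1), i.e. a rank point-biserial coefficient
with midranks for ties and a two-sided t-approximation p-value;
rho > 0 means higher coverage on enriched arms. A constant coverage
vector has no defined rank correlation and yields NaN.

The proportion matrix divides each dataset's per-arm upregulated-DEG
count by its total across arms (rows sum to 100; empty datasets drop
with a warning). Standardization is column-wise z-scoring with the
n−1 denominator (the `scale` convention); zero-variance columns become
all-zero and are flagged. Clustering is agglomerative with Euclidean
distance and complete linkage by default (deterministic ties by input
order), returning the dendrogram leaf order and merge heights; merge
heights match a direct O(n³) agglomeration oracle.

## Synthetic data: what it emulates, and what it does not

The generators produce, deterministically per seed (independent named
substreams of one global seed):

- **Genome**: 8 chromosomes of 20–30 Mb (205 Mb total), centromeres at
  45% of each length, 20,000 genes with uniform starts and lognormal
  lengths (median 20 kb). This is deliberately *gene-dense* rather than
  human-scale: at human density a 2 Mb window holds ~20 genes and
  per-arm tests are uninformative at desk scale, whereas ~200 genes per
  window gives per-arm detection power above 99% at the fold
  enrichments studied (a pre-hoc binomial/Poisson power calculation,
  not a fitted value). The distance and windowing logic is
  scale-free, so nothing else depends on this choice.
- **DEG sets**: each gene becomes an up-DEG with probability `p_in`
  inside the planted-arm windows and `p_out` outside, solved so the
  expected total equals `n_degs × up_fraction` (default 1250 × 0.8)
  and the *expected FE statistic* over the planted windows equals
  `planted_fold` (default 3.6, the reported first-bin value).
  Planting on the statistic's own scale makes recovery tests
  self-consistent. Feasibility requires fold × window-gene-share ≤ 1;
  infeasible configurations raise an error naming the bound. Down-DEGs
  are drawn uniformly. The raw generator defaults to planting on all
  arms (so the genome-wide first-bin FE equals the planted fold); the
  on-disk simulation bundle plants every third arm to emulate the
  study's situation of a minority of enriched chromosome ends.
- **Peak tracks**: per window, a target coverage fraction drawn from
  the arm group's mean ± sd (defaults 0.4 enriched vs 0.2 other,
  sd 0.05), realised as equal-length non-overlapping peaks (~5 kb) at
  random offsets. Discreteness limits coverage accuracy to roughly one
  peak length per window.
- **Counts**: negative binomial with variance μ + αμ² (α = 0.05,
  μ0 = 500, 3 replicates per condition, matching triplicate designs).
  Planted up-DEGs have young mean μ0/r and senescent mean (μ0/r)·d
  with repression r = 3 and derepression d = 4; down-DEGs mirror this
  (elevated young, reduced at senescence). No-DEGs are exchangeable
  across conditions.

Not emulated: realistic karyotypes and gene-density gradients,
sequence content, correlated gene expression, library-size variation
(counts are already "normalized"), overdispersion heterogeneity across
genes, and peak-width distributions. Passing recovery tests therefore
demonstrates the statistical machinery is correct and calibrated on
data with known truth — not that any particular biological dataset
will show the effect.

## Validation battery

The acceptance script and test suite recompute, from scratch each run:
exact enumeration agreement of the hypergeometric tail (all valid
parameter tuples with N ≤ 12; pmf tail sums to N ≤ 500); null
calibration of the arm flag rate (uniform DEGs, 1000 replicates —
discreteness makes the test conservative, so the rate sits at or below
the nominal 0.05); planted-FE recovery (median over 200 seeds) and
planted-arm detection power at p < 0.001; overlap-FE recovery on
planted set pairs; the published Venn partition arithmetic as exact
integers; per-base coverage oracle agreement over 1000 randomized
instances; the derepression pattern rate over 100 seeds; and
coverage-group correlation sign recovery with its label-permutation
null. Replication counts were chosen so the battery completes in about
a minute on one core while keeping Monte-Carlo error well inside the
stated tolerances.

## Known limitations

- The per-arm test treats genes as exchangeable units: no correction
  for gene length, expression level or local gene-density bias, and no
  permutation null (the hypergeometric null *is* the model).
- Arm-level grouping for the chromatin correlation is binary
  (enriched/other); degrees of enrichment are ignored.
- The pipeline consumes DESeq2-style output; it does not model count
  normalization or dispersion estimation itself.
- The exact/scipy boundary in the hypergeometric tail (N = 600) is a
  numerical convenience; both paths are validated, but values a few
  ulps apart across the boundary are possible.
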