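# Methods

`stagehet` quantifies how transcriptionally *alike* the cells of one
histological stage are, across a multi-stage single-cell RNA-seq design
(normal tissue → atypical adenomatous hyperplasia (AAH) → adenoma →
adenocarcinoma in situ (AIS)), and provides the two companion
procedures such a study needs: expression-bin-matched gene-set module
scores, and Pearson correlations between gene-set scores or cell-group
pseudobulk profiles. Because raw progression cohorts are large and
external, the package ships a ground-truthed simulator so every claim
the statistics make can be tested end to end.

## Quality control and normalization

Cells are excluded when any of the following holds: total UMIs above
`umi_max` (default 10,000) or below `umi_min` (500); detected genes
(count > 0) above `genes_max` (5,000) or below `genes_min` (300);
mitochondrial UMI fraction above `mito_frac_max` (0.10). Genes detected
in fewer than `gene_min_cells` (10) cells are then removed. All bounds
are exclusive — a cell at exactly 10,000 UMIs or exactly 10.0%
mitochondrial content is retained — reflecting a strict reading of
"more than / fewer than / over". Cells are filtered before genes by
default (so gene support counts reflect retained cells); the order is
configurable because either convention is defensible. Normalization is
`ln(1 + c · sf / total)` with `sf = 10,000`, computed in double
precision on the sparse matrix so every value recomputes exactly from
counts; zeros stay zero.

## The within-stage heterogeneity statistic

**Feature panel.** Discretization is restricted to an informative gene
panel: the union of the top `top_m` (default 100) one-vs-rest marker
genes per cluster (Wilcoxon rank-sum p-value, ties broken by |log
fold-change| then gene ID) and the top `top_k` (default 100) genes by
absolute loading of each of the first `n_components` (default 20)
principal components of the normalized matrix. Cluster labels are an
input — the package deliberately does no clustering or batch
integration — and the embedding source is pluggable; plain PCA is the
built-in.

**Discretization.** Each panel gene is cut into `n_bins = 10` bins.
Default is equal width over the gene's observed range across all cells,
with the top bin right-closed; equal-frequency (quantile) binning is
available since the choice is a genuine free parameter. Constant genes
map to bin 0.

**NMI between two cells.** A cell's discretized panel profile defines
an empirical distribution over bin values (frequency of each bin among
its panel genes); two cells define a joint distribution over
gene-aligned bin pairs. Then

    I(x,y)   = Σ_a Σ_b p(a,b) ln [ p(a,b) / (p(a) p(b)) ]
    NMI(x,y) = I(x,y) / √(H(x) H(y))

in nats; NMI is invariant to the log base since it is a ratio.
Zero-probability joint cells contribute nothing. A constant (zero
entropy) profile would make NMI 0/0; it is defined as 0 with a warning,
and the count of such cells is reported, so stage medians stay
computable. NMI(x,x) = 1 for any non-constant x, and symmetry holds
bit-exactly (the implementation canonicalizes argument order before
summing the joint table).

**Subsampling design.** For each stage, `n_cells = 100` cells are
drawn without replacement `n_draws = 500` times; each draw is
summarized by the median of its C(100,2) pairwise NMIs, giving 500
draw medians per stage. Stages with fewer than `n_cells` cells use all
cells (every draw is then identical, computed once and replicated,
with a warning); stages with fewer than 2 cells are excluded. The
implementation computes the full within-stage pairwise NMI matrix once
via per-bin indicator cross-products (BLAS) and lets draws index into
it — algebraically identical to recomputing per draw, and what makes
500 draws over hundreds of cells take seconds.

**Stage comparisons.** Draw-median distributions are compared pairwise
with a two-tailed unpaired Student's t-test by default; Mann–Whitney
(asymptotic or exact) is offered because draw medians are bounded and
non-normal. Every output row carries an explicit caveat: draws are
resampled from the same cells, so they are not independent replicates
and p-values are optimistic. The test answers "is the difference
stable under resampling", not "would it replicate in new tissue".

**Randomness.** Per-stage subsample streams are derived from
`(seed, crc32(stage name))`, so adding or removing a stage never
perturbs another stage's draws.

## Gene-set module score

All genes are partitioned into `n_expr_bins = 24` equal-frequency bins
of their mean normalized expression across cells. For each bin holding
at least one target gene, `n_ctrl_per_bin = 100` non-target genes are
sampled uniformly without replacement (all of them, with a warning, if
the bin is smaller). A cell's score is mean(target genes) − mean(all
selected control genes). Matching controls on mean expression removes
the abundance component a naive target mean would carry; under a null
where the target set is random, the expected score is 0. The "100
controls per occupied expression bin" reading is the convention of the
score this reimplements; a per-target-gene alternative exists in the
wild, and the bin count is exposed because nothing pins it down.

## Correlations

Gene-set score vectors are correlated with Pearson's r; the 95% CI is
Fisher-z (`tanh(atanh r ± 1.96/√(n−3))`) and the two-sided p comes from
the t distribution with n − 2 df. Cell-group correlation forms each
group's pseudobulk mean-expression vector, keeps the `top_n = 1000`
genes with the greatest standard deviation of group means (sample SD,
ddof 1 — the ranking is SD-convention invariant for fixed group count;
ties broken by gene ID), and correlates group vectors; the matrix is
symmetric with unit diagonal.

## The synthetic-data generator

The generator emulates a multi-sample progression experiment, not any
particular dataset. For cell c of stage s and gene g:

    μ[c,g] = base[g] · 2^{marker_lfc[type(c),g]} · e^{ε[c,g]} · 2^{program_lfc[c,g]}
    count  ~ NB( mean = μ[c,g] · lib[c] / Σ_g μ[c,g],  var = mean + α·mean² )

with gene base means log-normal (location 0, scale 1), disjoint
25-gene marker blocks per cell type at +2 log2FC, dispersion α = 0.1,
library sizes Gamma (mean 5,000, shape 10), and a contiguous
mitochondrial block rescaled to a 5% expected count share so QC
fixtures can sit on either side of the 10% rule. Counts are drawn per
stage from a substream of `(seed, crc32(stage))`, so output is
bit-reproducible and stage-local.

The heterogeneity knob is ε[c,g] ~ iid Normal(−sd²/2, sd) per cell and
gene — mean-corrected so jitter changes dispersion, never expected
expression. One scalar `stage_noise_sd` per stage thus controls how
unlike a stage's cells are; defaults (0.10, 0.30, 0.55, 0.85) increase
along the progression and were chosen to span the dynamic range of the
NMI statistic at desk scale. Injected programs multiply a chosen gene
set by 2^effect in one cell type at chosen stages, with per-cell truth
recorded.

**What the simulation does not model:** batch effects, ambient RNA,
doublets, compositional shifts between stages (cell-type proportions
are uniform by default, though configurable), gene–gene correlation
beyond cell-type and program structure, and stage-specific library
chemistry. Passing tests therefore show the statistics behave as
designed under a clean negative-binomial world; they do not certify
effect sizes on real tissue.

## Numerical choices and limitations

- MI/NMI are computed in double precision; the fast pairwise path
  matches the scalar definition to ~1e-12 and both match a brute-force
  joint-count oracle and sklearn's contingency MI in tests.
- Equal-width binning over a globally pooled range couples stages: one
  stage's outliers compress another stage's occupied bins. With the
  mean-corrected jitter this did not affect orderings in testing, but
  comparisons should always use a common panel and binning, as the
  pipeline does.
- Pairwise MI over a finite panel of L genes carries an upward
  estimation bias of order (Bx−1)(By−1)/2L that grows with bin
  occupancy. Panels of only ~100 genes can let this bias term distort
  stage orderings; the default panel (~1,000 genes on the simulated
  data) keeps it an order of magnitude below the signal. Compare NMI
  only across groups scored with the same panel.
- Draw medians are means of order statistics of dependent pairs; their
  nominal p-values are anti-conservative (see caveat above).
- Problem sizes used by the shipped experiments — 4 stages × 600
  cells × 2,000 genes, 100-cell/100-draw subsampling, 1,000 null gene
  sets — were chosen so the full validation runs in minutes on one
  core while keeping every comparison far from its decision boundary.
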