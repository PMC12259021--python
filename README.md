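# stagehet

Quantify how transcriptionally *alike* the cells of one histological
stage are, across a premalignant progression scRNA-seq design
(normal → AAH → adenoma → AIS), using a pairwise normalized mutual
information (NMI) statistic under a fixed subsampling scheme — plus the
companion procedures such a study needs: the four standard cell/gene QC
exclusion criteria with library-size log normalization, gene-set module
scores against expression-bin-matched control genes, and Pearson
correlations between gene-set scores or cell-group pseudobulk profiles.
A ground-truthed synthetic progression simulator makes every statistic
testable end to end without external data.

It is a library first (`import stagehet`), with narrative scripts in
`examples/` and a thin `stagehet` CLI (`simulate`, `qc`, `run`) for
shell use.

## The statistic

Each cell's expression profile over a feature-gene panel (union of
per-cluster Wilcoxon marker genes and top PCA-loading genes) is
discretized per gene into 10 bins. For two cells x and y, with p(x),
p(y) the empirical distributions of their bin values over the panel
genes and p(x,y) the joint over gene-aligned bin pairs,

    I(x,y)   = Σₐ Σᵦ p(a,b) ln [ p(a,b) / (p(a) p(b)) ]
    NMI(x,y) = I(x,y) / √(H(x) H(y))   ∈ [0, 1]

Within each stage, 100 cells are subsampled 500 times; each draw is
summarized by the median of its pairwise NMIs, and stages are compared
on these draw-median distributions (Student's t by default). Falling
median NMI along the continuum reads as rising transcriptional
heterogeneity. The module score of a gene set G in cell c is
mean(G) − mean(controls), with controls drawn per expression bin of
gene mean so the background is abundance-matched.

## Worked example

`examples/01_simulate_progression.py` writes a four-stage fixture
(2,000 genes, 4 × 600 cells, per-cell jitter SD rising 0.10 → 0.85);
`examples/03_stage_heterogeneity.py` then measures the trend:

```
panel: 1016 genes
  normal   median draw-median NMI = 0.0306
  AAH      median draw-median NMI = 0.0285
  adenoma  median draw-median NMI = 0.0269
  AIS      median draw-median NMI = 0.0261
stage_a stage_b  statistic        pvalue direction
 normal     AAH  43.917705 5.008212e-104       a>b
 ...
adenoma     AIS  25.368842  3.945882e-64       a>b
```

Median within-stage NMI falls strictly from normal to AIS — cells grow
less alike as simulated progression advances — and every pairwise
comparison is significant (p-values carry an explicit caveat: draws
resample the same cells, so they are not independent replicates).
`examples/04_module_score.py` scores an injected 40-gene program
(log2FC 2 in one cell type at AAH) at +1.02 in targeted cells vs −0.14
in background; `examples/05_correlations.py` prints Pearson r with
Fisher-z 95% CI for two score vectors and the stage × stage pseudobulk
correlation matrix. See `docs/methods.md` for the model, parameters and
limitations.

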