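"""Gene-set module scores and correlation procedures.

The module score measures per-cell activity of a gene set against an
expression-matched background: genes are binned by their mean
log-normalized expression across cells (equal-frequency bins), control
genes are drawn from the bins that contain target genes, and each
cell's score is mean(target genes) − mean(control genes). Matching
controls on mean expression removes the depth/abundance component that
a naive target mean would carry.

Correlations (between gene-set scores, or between cell-group pseudobulk
profiles) are Pearson, with Fisher-z 95% confidence intervals and
t-distribution p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.stats


@dataclass
class GeneSet:
    name: str
    gene_ids: list[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"gene set {self.name!r} contains duplicate IDs")


@dataclass
class ModuleScoreResult:
    """Per-cell scores plus the control-gene assignment behind them."""

    scores: pd.Series  # index = cell barcodes
    gene_set: str
    n_expr_bins: int
    n_ctrl_per_bin: int
    seed: int
    controls: dict[int, list[str]]  # bin -> control genes sampled
    target_bins: pd.Series  # target gene -> bin index


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X, float)


def expression_bins(norm: ad.AnnData, n_expr_bins: int = 24) -> pd.Series:
    """Equal-frequency bin index of each gene's mean expression across cells."""
    means = pd.Series(np.ravel(_dense(norm.X).mean(axis=0)), index=norm.var_names)
    ranks = means.rank(method="first") - 1
    bins = np.floor(ranks / len(means) * n_expr_bins).astype(int).clip(0, n_expr_bins - 1)
    return pd.Series(bins, index=means.index, name="expr_bin")


def module_score(
    norm: ad.AnnData,
    gene_set: GeneSet,
    n_expr_bins: int = 24,
    n_ctrl_per_bin: int = 100,
    seed: int = 0,
    bins: pd.Series | None = None,
) -> ModuleScoreResult:
    """Score a gene set per cell against bin-matched control genes.

    Controls (``n_ctrl_per_bin`` per occupied bin, default 100) are
    sampled uniformly without replacement from the non-target genes of
    each expression bin containing at least one target gene; if a bin
    holds fewer, all its non-target genes are used with a warning.
    Deterministic for a fixed seed. ``bins`` lets callers reuse a
    precomputed :func:`expression_bins` result when scoring many sets.
    """
    present = [g for g in gene_set.gene_ids if g in norm.var_names]
    if not present:
        missing = gene_set.gene_ids[:10]
        raise ValueError(
            f"gene set {gene_set.name!r} has no genes in the matrix; missing IDs: {missing}"
        )
    if bins is None:
        bins = expression_bins(norm, n_expr_bins)
    target_bins = bins.loc[present]
    targets = set(present)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(seed),)))
    controls: dict[int, list[str]] = {}
    for b in sorted(target_bins.unique()):
        pool = bins.index[(bins == b) & ~bins.index.isin(targets)]
        if len(pool) == 0:
            warnings.warn(f"expression bin {b} has no non-target genes", stacklevel=2)
            continue
        if len(pool) < n_ctrl_per_bin:
            warnings.warn(
                f"expression bin {b}: only {len(pool)} control candidates "
                f"(< {n_ctrl_per_bin}); using all",
                stacklevel=2,
            )
            chosen = list(pool)
        else:
            chosen = list(rng.choice(np.asarray(pool), size=n_ctrl_per_bin, replace=False))
        controls[int(b)] = chosen
    ctrl_genes = [g for gl in controls.values() for g in gl]
    if not ctrl_genes:
        raise ValueError("no control genes available in any occupied expression bin")
    X_t = _dense(norm[:, present].X)
    X_c = _dense(norm[:, ctrl_genes].X)
    scores = X_t.mean(axis=1) - X_c.mean(axis=1)
    return ModuleScoreResult(
        scores=pd.Series(np.ravel(scores), index=norm.obs.index, name=gene_set.name),
        gene_set=gene_set.name,
        n_expr_bins=n_expr_bins,
        n_ctrl_per_bin=n_ctrl_per_bin,
        seed=seed,
        controls=controls,
        target_bins=target_bins,
    )


@dataclass
class CorrelationResult:
    r: float
    ci95: tuple[float, float]
    p: float
    n: int


def geneset_correlation(scores_a, scores_b) -> CorrelationResult:
    """Pearson correlation of two per-cell score vectors with 95% CI
    (Fisher z) and two-sided p (t distribution, n−2 df)."""
    a = np.asarray(scores_a, float).ravel()
    b = np.asarray(scores_b, float).ravel()
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 3:
        raise ValueError("need n >= 3 for a correlation with a finite CI")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant input vector")
    res = scipy.stats.pearsonr(a, b)
    ci = res.confidence_interval(0.95)
    return CorrelationResult(
        r=float(res.statistic),
        ci95=(float(ci.low), float(ci.high)),
        p=float(res.pvalue),
        n=a.size,
    )


def group_correlation(
    norm: ad.AnnData, group_key: str, top_n: int = 1000
) -> pd.DataFrame:
    """Pearson correlation between cell groups on pseudobulk profiles.

    Each group is represented by its per-gene mean expression; genes
    are ranked by the standard deviation (sample, ddof=1) of these
    group means and the ``top_n`` most variable are kept (ties broken
    by gene ID) before correlating group vectors.
    """
    labels = norm.obs[group_key].astype(str)
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("group_correlation needs at least 2 groups")
    X = _dense(norm.X)
    means = pd.DataFrame(
        {g: X[(labels == g).to_numpy()].mean(axis=0) for g in groups},
        index=norm.var_names,
    )
    sd = means.std(axis=1, ddof=1)
    if top_n > len(sd):
        warnings.warn(
            f"top_n={top_n} exceeds {len(sd)} available genes; using all", stacklevel=2
        )
        top_n = len(sd)
    order = pd.DataFrame({"sd": sd, "gene": sd.index}).sort_values(
        ["sd", "gene"], ascending=[False, True], kind="mergesort"
    )
    kept = order["gene"].head(top_n)
    sub = means.loc[kept]
    corr = np.corrcoef(sub.to_numpy().T)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=groups, columns=groups)
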