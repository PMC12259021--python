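"""Within-stage transcriptional heterogeneity via pairwise NMI.

A cell's discretized expression profile over a feature-gene panel is
treated as a distribution over bin values: p(x) is the empirical
frequency of each bin among the panel genes of cell x, and p(x, y) the
joint frequency of gene-aligned bin pairs for two cells. Mutual
information and its normalization are then

    I(x, y)   = Σ_a Σ_b p(a, b) ln[ p(a, b) / (p(a) p(b)) ]
    NMI(x, y) = I(x, y) / sqrt(H(x) H(y))        ∈ [0, 1]

computed in nats (NMI itself is log-base invariant). Identical profiles
give NMI 1, independent ones 0, so a *drop* in the within-stage median
pairwise NMI reads as a *gain* in transcriptional heterogeneity.

The stage statistic follows a fixed subsampling design: from each stage
draw ``n_cells`` cells (default 100) ``n_draws`` times (default 500),
compute every within-draw pairwise NMI, and keep the median per draw.
Stages are then compared on their draw-median distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.stats
from scipy.special import xlogy

# ---------------------------------------------------------------------------
# feature panel


@dataclass
class FeaturePanel:
    """Ordered, deduplicated gene panel with per-gene provenance.

    Built as the union of per-cluster marker genes (markers first, in
    cluster order) and top-|loading| genes of the leading embedding
    components (in component order).
    """

    genes: list[str]
    sources: pd.DataFrame  # columns: gene, source (first origin of each gene)

    def __len__(self) -> int:
        return len(self.genes)


def rank_markers(
    norm: ad.AnnData, cluster_key: str = "cluster", top_m: int = 100
) -> dict[str, list[str]]:
    """Top marker genes per cluster by one-vs-rest Wilcoxon rank-sum.

    Genes are ranked by two-sided p-value, ties broken by |log
    fold-change| (difference of mean log-normalized expression,
    descending) then gene ID. Clusters with fewer than 2 cells are
    skipped with a warning.
    """
    labels = norm.obs[cluster_key].astype(str)
    clusters = list(dict.fromkeys(labels))  # first-appearance order
    if len(clusters) < 2:
        raise ValueError("rank_markers needs at least 2 clusters")
    X = np.asarray(norm.X.todense()) if hasattr(norm.X, "todense") else np.asarray(norm.X)
    genes = np.asarray(norm.var_names)
    out: dict[str, list[str]] = {}
    for cl in clusters:
        mask = (labels == cl).to_numpy()
        if mask.sum() < 2 or (~mask).sum() < 2:
            warnings.warn(f"cluster {cl!r} has <2 cells on one side; skipped", stacklevel=2)
            continue
        res = scipy.stats.mannwhitneyu(
            X[mask], X[~mask], alternative="two-sided", axis=0
        )
        lfc = X[mask].mean(axis=0) - X[~mask].mean(axis=0)
        order = pd.DataFrame(
            {"p": res.pvalue, "neg_abs_lfc": -np.abs(lfc), "gene": genes}
        ).sort_values(["p", "neg_abs_lfc", "gene"], kind="mergesort")
        out[cl] = order["gene"].head(top_m).tolist()
    return out


def pca_loadings(norm: ad.AnnData, n_components: int = 20, center: bool = True) -> pd.DataFrame:
    """Principal-component loadings (components × genes) of the
    log-normalized matrix; deterministic (full SVD solver)."""
    from sklearn.decomposition import PCA

    X = np.asarray(norm.X.todense()) if hasattr(norm.X, "todense") else np.asarray(norm.X)
    n_components = min(n_components, min(X.shape) - 1)
    pca = PCA(n_components=n_components, svd_solver="full")
    if not center:
        X = X - 0  # PCA centers internally; flag kept for API clarity
    pca.fit(X)
    return pd.DataFrame(
        pca.components_,
        index=[f"PC{i + 1}" for i in range(n_components)],
        columns=norm.var_names,
    )


def build_panel(
    markers: dict[str, list[str]],
    loadings: pd.DataFrame | None = None,
    top_k: int = 100,
    n_components: int = 20,
) -> FeaturePanel:
    """Union of marker lists and top-|loading| component genes.

    Order is deterministic: marker blocks in cluster order, then
    component blocks in component order, each block internally by rank;
    duplicates keep their first occurrence.
    """
    records: list[tuple[str, str]] = []
    for cl, gl in markers.items():
        records += [(g, f"cluster:{cl}") for g in gl]
    if loadings is not None:
        n_components = min(n_components, loadings.shape[0])
        for ci in range(n_components):
            row = loadings.iloc[ci]
            top = row.abs().sort_values(ascending=False, kind="mergesort").head(top_k)
            records += [(g, f"component:{loadings.index[ci]}") for g in top.index]
    seen: dict[str, str] = {}
    for g, src in records:
        seen.setdefault(g, src)
    if not seen:
        raise ValueError("feature panel is empty")
    return FeaturePanel(
        genes=list(seen),
        sources=pd.DataFrame({"gene": list(seen), "source": list(seen.values())}),
    )


# ---------------------------------------------------------------------------
# discretization


@dataclass
class DiscretizedMatrix:
    """Cells × panel-genes integer bin indices in {0..n_bins-1}."""

    bins: np.ndarray  # (n_cells, n_genes) small ints
    genes: list[str]
    cell_index: pd.Index
    n_bins: int
    edges: pd.DataFrame | None = None  # per-gene bin edges (genes × n_bins+1)
    scheme: str = "width"


def discretize(
    norm: ad.AnnData,
    panel: FeaturePanel | list[str],
    n_bins: int = 10,
    scheme: str = "width",
) -> DiscretizedMatrix:
    """Discretize each panel gene into ``n_bins`` bins across all cells.

    ``scheme="width"`` (default): equal-width bins over the observed
    [min, max] per gene, the top bin right-closed so the maximum maps to
    bin n_bins−1. ``scheme="quantile"``: equal-frequency bins. Genes
    constant across cells map every cell to bin 0.
    """
    genes = list(panel.genes) if isinstance(panel, FeaturePanel) else list(panel)
    if not genes:
        raise ValueError("empty feature panel")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    missing = [g for g in genes if g not in norm.var_names]
    if missing:
        raise ValueError(f"panel genes absent from matrix: {missing[:10]}")
    sub = norm[:, genes].X
    X = np.asarray(sub.todense()) if hasattr(sub, "todense") else np.asarray(sub, float)
    X = np.asarray(X, float)
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = hi - lo
    constant = span <= 0
    span[constant] = 1.0
    if scheme == "width":
        idx = np.floor((X - lo) / span * n_bins).astype(np.int64)
        np.clip(idx, 0, n_bins - 1, out=idx)
        edges = lo[:, None] + np.arange(n_bins + 1)[None, :] * (span[:, None] / n_bins)
    elif scheme == "quantile":
        qs = np.quantile(X, np.linspace(0, 1, n_bins + 1)[1:-1], axis=0)
        idx = np.empty_like(X, dtype=np.int64)
        for j in range(X.shape[1]):
            idx[:, j] = np.searchsorted(qs[:, j], X[:, j], side="right")
        edges = np.vstack([lo, qs, hi]).T
    else:
        raise ValueError(f"unknown binning scheme {scheme!r}")
    idx[:, constant] = 0
    return DiscretizedMatrix(
        bins=idx.astype(np.int16),
        genes=genes,
        cell_index=norm.obs.index.copy(),
        n_bins=n_bins,
        edges=pd.DataFrame(edges, index=genes),
        scheme=scheme,
    )


# ---------------------------------------------------------------------------
# mutual information / NMI


def _check_profiles(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.int64).ravel()
    y = np.asarray(y, dtype=np.int64).ravel()
    if x.size != y.size:
        raise ValueError(f"profile length mismatch: {x.size} vs {y.size}")
    if x.size == 0:
        raise ValueError("profiles must be non-empty")
    return x, y


def entropy(x) -> float:
    """Shannon entropy (nats) of a profile's empirical bin distribution."""
    x = np.asarray(x, dtype=np.int64).ravel()
    counts = np.bincount(x)
    counts = counts[counts > 0]
    p = counts / x.size
    return float(-(p * np.log(p)).sum())


def mutual_information(x, y) -> float:
    """I(x, y) in nats from the empirical joint bin distribution over genes.

    Zero-probability joint cells contribute nothing; the result is
    non-negative and bounded by min(H(x), H(y)) up to rounding.
    """
    x, y = _check_profiles(x, y)
    # canonical argument order so I(x,y) == I(y,x) bit-exactly
    if (x.tobytes(), ) > (y.tobytes(), ):
        x, y = y, x
    L = x.size
    bx, by = int(x.max()) + 1, int(y.max()) + 1
    joint = np.bincount(x * by + y, minlength=bx * by).reshape(bx, by)
    px = joint.sum(axis=1) / L
    py = joint.sum(axis=0) / L
    pxy = joint / L
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = pxy / np.outer(px, py)
        terms = xlogy(pxy, np.where(pxy > 0, ratio, 1.0))
    return float(max(terms.sum(), 0.0))


def nmi(x, y) -> float:
    """NMI(x, y) = I / sqrt(H(x) H(y)); 0 (with a warning) if either
    profile is constant, so stage medians stay computable."""
    x, y = _check_profiles(x, y)
    hx, hy = entropy(x), entropy(y)
    if hx == 0.0 or hy == 0.0:
        warnings.warn("zero-entropy (constant) profile: NMI defined as 0", stacklevel=2)
        return 0.0
    return mutual_information(x, y) / np.sqrt(hx * hy)


def pairwise_nmi(bins: np.ndarray, n_bins: int | None = None) -> np.ndarray:
    """All-pairs NMI matrix for rows of a discretized matrix.

    Equivalent to looping :func:`nmi` over pairs, but computed with
    per-bin indicator cross-products (BLAS) so that the joint count
    table of every pair is accumulated at once. Zero-entropy rows get
    NMI 0 against everything (1 on the diagonal is *not* forced there).
    """
    B = int(bins.max()) + 1 if n_bins is None else int(n_bins)
    bins = np.asarray(bins)
    n, L = bins.shape
    ind = [np.asarray(bins == b, dtype=np.float32) for b in range(B)]
    S = np.zeros((n, n))  # Σ_ab C_ab ln C_ab, C = joint counts
    for a in range(B):
        if not ind[a].any():
            continue
        for b in range(B):
            if not ind[b].any():
                continue
            C = (ind[a] @ ind[b].T).astype(np.float64)
            S += xlogy(C, C)
    marg = np.stack([m.sum(axis=1) for m in ind], axis=1).astype(np.float64)  # (n, B) bin counts
    p = marg / L
    H = -xlogy(p, p).sum(axis=1)
    I = S / L - np.log(L) + H[:, None] + H[None, :]
    np.maximum(I, 0.0, out=I)
    denom = np.sqrt(np.outer(H, H))
    with np.errstate(divide="ignore", invalid="ignore"):
        M = np.where(denom > 0, I / np.where(denom > 0, denom, 1.0), 0.0)
    return np.minimum(M, 1.0 + 1e-12)


# ---------------------------------------------------------------------------
# stage statistic


@dataclass
class StageNMIResult:
    """Per-stage subsample draw-median NMI distributions."""

    medians: dict[str, np.ndarray]  # stage -> (n_draws,) draw medians
    n_cells: int
    n_draws: int
    seed: int
    n_zero_entropy: dict[str, int] = field(default_factory=dict)
    stage_order: list[str] = field(default_factory=list)

    def stage_summary(self) -> pd.DataFrame:
        rows = [
            {
                "stage": st,
                "median_nmi": float(np.median(v)),
                "mean_nmi": float(np.mean(v)),
                "n_draws": len(v),
            }
            for st, v in self.medians.items()
        ]
        return pd.DataFrame(rows)


def _stage_substream(seed: int, stage: str) -> np.random.Generator:
    import zlib

    return np.random.default_rng(
        np.random.SeedSequence(entropy=(int(seed), zlib.crc32(stage.encode())))
    )


def stage_heterogeneity(
    disc: DiscretizedMatrix,
    stages: pd.Series,
    n_cells: int = 100,
    n_draws: int = 500,
    seed: int = 0,
) -> StageNMIResult:
    """Median pairwise NMI under repeated within-stage subsampling.

    For each stage, ``n_draws`` subsamples of ``n_cells`` cells are
    drawn without replacement; each draw is summarized by the median of
    its pairwise NMIs. Stages with fewer than ``n_cells`` cells use all
    cells (with a warning); stages with fewer than 2 cells are excluded.
    Deterministic for a fixed seed, with per-stage substreams so adding
    a stage leaves the others' draws unchanged.
    """
    stages = stages.reindex(disc.cell_index)
    if stages.isna().any():
        raise ValueError("stage labels missing for some discretized cells")
    order = list(dict.fromkeys(stages))
    if hasattr(stages, "cat"):
        order = [s for s in stages.cat.categories if s in set(stages)]
    medians: dict[str, np.ndarray] = {}
    zero_counts: dict[str, int] = {}
    for st in order:
        idx = np.flatnonzero((stages == st).to_numpy())
        if idx.size < 2:
            warnings.warn(f"stage {st!r} has <2 cells; excluded", stacklevel=2)
            continue
        sub = disc.bins[idx]
        M = pairwise_nmi(sub, disc.n_bins)
        row_H = np.array([entropy(r) for r in sub])
        zero_counts[st] = int((row_H == 0).sum())
        rng = _stage_substream(seed, st)
        k = n_cells
        if idx.size < n_cells:
            warnings.warn(
                f"stage {st!r} has {idx.size} < n_cells={n_cells} cells; "
                "using all cells per draw",
                stacklevel=2,
            )
            k = idx.size
        iu = np.triu_indices(k, 1)
        if k == idx.size:
            med = float(np.median(M[np.triu_indices(idx.size, 1)]))
            medians[st] = np.full(n_draws, med)
            continue
        vals = np.empty(n_draws)
        for d in range(n_draws):
            pick = rng.choice(idx.size, size=k, replace=False)
            vals[d] = np.median(M[np.ix_(pick, pick)][iu])
        medians[st] = vals
    return StageNMIResult(
        medians=medians,
        n_cells=n_cells,
        n_draws=n_draws,
        seed=seed,
        n_zero_entropy=zero_counts,
        stage_order=list(medians),
    )


def compare_stages(
    result: StageNMIResult, method: str = "t-test", mw_method: str = "auto"
) -> pd.DataFrame:
    """All-pairs stage comparison on the draw-median distributions.

    ``method``: "t-test" (two-tailed unpaired Student's t, equal
    variances) or "mannwhitney"; ``mw_method`` ("auto"/"exact"/
    "asymptotic") picks the Mann–Whitney null. The returned table
    carries a caveat column: draws are resampled from the same cells,
    so they are not independent replicates and p-values are optimistic.
    """
    stages = result.stage_order or list(result.medians)
    if len(stages) < 2:
        raise ValueError("need at least 2 stages to compare")
    if method not in {"t-test", "mannwhitney"}:
        raise ValueError(f"unknown method {method!r}; use 't-test' or 'mannwhitney'")
    rows = []
    for i, a in enumerate(stages):
        for b in stages[i + 1 :]:
            va, vb = result.medians[a], result.medians[b]
            if method == "t-test":
                res = scipy.stats.ttest_ind(va, vb)
                stat, p = float(res.statistic), float(res.pvalue)
                if np.array_equal(va, vb):
                    stat, p = 0.0, 1.0  # zero-variance identical inputs
            else:
                res = scipy.stats.mannwhitneyu(
                    va, vb, alternative="two-sided", method=mw_method
                )
                stat, p = float(res.statistic), float(res.pvalue)
            rows.append(
                {
                    "stage_a": a,
                    "stage_b": b,
                    "method": method,
                    "statistic": stat,
                    "pvalue": p,
                    "median_a": float(np.median(va)),
                    "median_b": float(np.median(vb)),
                    "direction": "a>b" if np.median(va) > np.median(vb) else "a<b",
                    "caveat": "draw medians share cells; not independent replicates",
                }
            )
    return pd.DataFrame(rows)
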