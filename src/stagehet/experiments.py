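"""Canned simulation experiments exercising the full method end-to-end.

These reproduce, at desk scale on synthetic data, the qualitative
behaviors the statistic is built to detect: loss of within-stage
transcriptional homogeneity along premalignant progression, and
detection of an injected gene program by the bin-matched module score.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats

from .heterogeneity import (
    build_panel,
    compare_stages,
    discretize,
    pca_loadings,
    rank_markers,
    stage_heterogeneity,
)
from .qc import run_qc
from .scoring import GeneSet, expression_bins, module_score
from .simulate import ProgramSpec, SimConfig, simulate_counts


def four_stage_trend(
    seed: int = 0,
    cells_per_stage: int = 600,
    n_cells: int = 100,
    n_draws: int = 100,
    top_m: int = 100,
    top_k: int = 100,
    n_components: int = 20,
    config: SimConfig | None = None,
) -> dict:
    """Simulate the four-stage design and measure the within-stage NMI trend.

    Simulates normal → AAH → adenoma → AIS with strictly increasing
    per-cell jitter, runs QC/normalization, builds the marker + PCA
    feature panel, discretizes into 10 bins and applies the subsampling
    NMI statistic. Returns per-stage median draw-median NMI, the full
    comparison table, and the maximum adjacent-pair p-value.
    """
    cfg = config or SimConfig(cells_per_stage=cells_per_stage, seed=seed)
    adata, _ = simulate_counts(cfg)
    norm, report = run_qc(adata)
    markers = rank_markers(norm, "cell_type", top_m=top_m)
    loadings = pca_loadings(norm, n_components=n_components)
    panel = build_panel(markers, loadings, top_k=top_k, n_components=n_components)
    disc = discretize(norm, panel)
    het = stage_heterogeneity(
        disc, norm.obs["stage"], n_cells=n_cells, n_draws=n_draws, seed=seed
    )
    comp = compare_stages(het, method="t-test")
    stage_order = het.stage_order
    medians = {st: float(np.median(v)) for st, v in het.medians.items()}
    pos = {st: i for i, st in enumerate(stage_order)}
    adjacent = comp[
        (comp["stage_a"].map(pos) - comp["stage_b"].map(pos)).abs() == 1
    ]
    return {
        "config": cfg,
        "qc": report.summary(),
        "panel_size": len(panel),
        "stage_order": stage_order,
        "medians": medians,
        "monotone_decreasing": bool(np.all(np.diff([medians[s] for s in stage_order]) < 0)),
        "comparisons": comp,
        "max_adjacent_p": float(adjacent["pvalue"].max()),
        "result": het,
    }


def null_score_calibration(
    seed: int = 0,
    n_sets: int = 1000,
    set_size: int = 50,
    n_genes: int = 3000,
    cells_per_stage: int = 500,
) -> dict:
    """Score many random gene sets on program-free data.

    With no injected signal the per-set mean module scores should be
    centred at zero; returns their mean, SE, and |mean|/SE.
    """
    cfg = SimConfig(
        n_genes=n_genes,
        stages=("a", "b"),
        stage_noise_sd=(0.1, 0.1),
        cells_per_stage=cells_per_stage,
        seed=seed,
    )
    adata, _ = simulate_counts(cfg)
    norm, _ = run_qc(adata)
    bins = expression_bins(norm, 24)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), 101)))
    genes = np.asarray(norm.var_names)
    set_means = np.empty(n_sets)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small bins fall back to all candidates
        for i in range(n_sets):
            gs = GeneSet(f"null-{i}", list(rng.choice(genes, set_size, replace=False)))
            res = module_score(norm, gs, seed=int(rng.integers(2**31)), bins=bins)
            set_means[i] = float(res.scores.mean())
    se = set_means.std(ddof=1) / np.sqrt(n_sets)
    return {
        "mean_of_means": float(set_means.mean()),
        "se": float(se),
        "abs_mean_over_se": float(abs(set_means.mean()) / se),
        "set_means": set_means,
    }


def program_detection(
    seed: int = 0,
    effect_log2fc: float = 2.0,
    n_program_genes: int = 50,
    target_cell_type: str = "type0",
    target_stage: str = "AAH",
) -> dict:
    """Inject a gene program and test that targeted cells outscore the rest.

    Returns the mean module score of targeted vs background cells and
    the two-sample t-test p-value, using the simulation's ground-truth
    labels as the reference.
    """
    cfg = SimConfig(seed=seed)
    program_genes = [f"ENSG{i:05d}" for i in range(300, 300 + n_program_genes)]
    prog = ProgramSpec(
        gene_ids=program_genes,
        target_cell_type=target_cell_type,
        target_stages=(target_stage,),
        effect_log2fc=effect_log2fc,
    )
    adata, truth = simulate_counts(cfg, [prog])
    norm, _ = run_qc(adata)
    present = [g for g in program_genes if g in norm.var_names]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = module_score(norm, GeneSet("program", present), seed=seed)
    targeted = (truth.cells.loc[norm.obs.index, "program_effect"] > 0).to_numpy()
    t, p = scipy.stats.ttest_ind(res.scores[targeted], res.scores[~targeted])
    return {
        "mean_targeted": float(res.scores[targeted].mean()),
        "mean_background": float(res.scores[~targeted].mean()),
        "t": float(t),
        "p": float(p),
        "n_targeted": int(targeted.sum()),
        "scores": res.scores,
        "targeted": pd.Series(targeted, index=norm.obs.index),
    }
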