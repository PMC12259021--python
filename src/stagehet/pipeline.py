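"""End-to-end orchestration: QC → normalize → panel → NMI → scores → correlations.

Configured by a YAML/JSON file mirroring :class:`PipelineConfig`; every
run emits TSV tables plus a JSON manifest (config hash, input
checksums, per-stage wall time, seeds) so a run is reproducible from
its output directory alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as shio
from .heterogeneity import (
    build_panel,
    compare_stages,
    discretize,
    pca_loadings,
    rank_markers,
    stage_heterogeneity,
)
from .qc import QCThresholds, run_qc
from .scoring import GeneSet, expression_bins, geneset_correlation, group_correlation, module_score

log = logging.getLogger("stagehet")

FLOAT_FMT = "%.10g"


@dataclass
class HetParams:
    n_bins: int = 10
    n_cells: int = 100
    n_draws: int = 500
    top_m: int = 100
    top_k: int = 100
    n_components: int = 20
    scheme: str = "width"
    test: str = "t-test"


@dataclass
class ScoreParams:
    n_expr_bins: int = 24
    n_ctrl_per_bin: int = 100


@dataclass
class PipelineConfig:
    counts_dir: str
    outdir: str
    gene_sets: str | None = None
    cluster_key: str = "cell_type"
    stage_key: str = "stage"
    qc: QCThresholds = field(default_factory=QCThresholds)
    scale_factor: float = 10_000.0
    het: HetParams = field(default_factory=HetParams)
    score: ScoreParams = field(default_factory=ScoreParams)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        for key, sub in (("qc", QCThresholds), ("het", HetParams), ("score", ScoreParams)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        cfg = cls(**raw)
        if not Path(cfg.counts_dir).exists():
            raise FileNotFoundError(f"counts directory not found: {cfg.counts_dir}")
        if cfg.gene_sets is not None and not Path(cfg.gene_sets).exists():
            raise FileNotFoundError(f"gene-set file not found: {cfg.gene_sets}")
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis; returns the output directory.

    Writes: qc_report.json, cells_qc.tsv, panel.tsv, stage_nmi_medians.tsv,
    stage_comparisons.tsv, module_scores.tsv + geneset_correlation.tsv
    (when gene sets are given), group_correlation.tsv, summary.json,
    manifest.json. Partial outputs from a failed run are moved under
    ``partial/``.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "stagehet 0.1.0",
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "inputs": {},
        "wall_time_s": {},
        "seeds": {"pipeline": config.seed},
    }
    indir = Path(config.counts_dir)
    for f in sorted(indir.iterdir()):
        if f.is_file():
            manifest["inputs"][f.name] = _sha256(f)

    stage_names: list[str] = []
    try:
        t0 = time.perf_counter()
        adata = shio.read_matrix(indir)
        log.info("read %d cells × %d genes from %s", adata.n_obs, adata.n_vars, indir)
        manifest["wall_time_s"]["read"] = round(time.perf_counter() - t0, 3)

        t0 = time.perf_counter()
        norm, report = run_qc(adata, config.qc, config.scale_factor)
        _write_tsv(report.flags.reset_index(), outdir / "cells_qc.tsv")
        (outdir / "qc_report.json").write_text(json.dumps(report.summary(), indent=2))
        log.info(
            "QC: %d/%d cells retained, %d genes", report.n_retained_cells,
            report.n_input_cells, report.n_retained_genes,
        )
        manifest["wall_time_s"]["qc"] = round(time.perf_counter() - t0, 3)

        t0 = time.perf_counter()
        markers = rank_markers(norm, config.cluster_key, top_m=config.het.top_m)
        loadings = pca_loadings(norm, n_components=config.het.n_components)
        panel = build_panel(
            markers, loadings, top_k=config.het.top_k, n_components=config.het.n_components
        )
        _write_tsv(panel.sources, outdir / "panel.tsv")
        log.info("feature panel: %d genes", len(panel))
        manifest["wall_time_s"]["panel"] = round(time.perf_counter() - t0, 3)

        t0 = time.perf_counter()
        disc = discretize(norm, panel, n_bins=config.het.n_bins, scheme=config.het.scheme)
        het = stage_heterogeneity(
            disc,
            norm.obs[config.stage_key],
            n_cells=config.het.n_cells,
            n_draws=config.het.n_draws,
            seed=config.seed,
        )
        stage_names = het.stage_order
        med = pd.DataFrame(het.medians)
        med.insert(0, "draw", np.arange(len(med)))
        _write_tsv(med, outdir / "stage_nmi_medians.tsv")
        comp = compare_stages(het, method=config.het.test)
        _write_tsv(comp, outdir / "stage_comparisons.tsv")
        log.info("stage NMI: %s", het.stage_summary().to_dict("records"))
        manifest["wall_time_s"]["heterogeneity"] = round(time.perf_counter() - t0, 3)

        summary: dict = {
            "qc": report.summary(),
            "panel_size": len(panel),
            "stage_nmi": het.stage_summary().to_dict("records"),
            "zero_entropy_cells": het.n_zero_entropy,
        }

        t0 = time.perf_counter()
        score_tables = []
        if config.gene_sets:
            sets = shio.read_gene_sets(config.gene_sets)
            bins = expression_bins(norm, config.score.n_expr_bins)
            results = {}
            for name, genes in sets.items():
                genes = [g for g in genes if g in norm.var_names]
                if not genes:
                    warnings.warn(f"gene set {name!r}: no genes in matrix; skipped")
                    continue
                res = module_score(
                    norm,
                    GeneSet(name, genes),
                    n_expr_bins=config.score.n_expr_bins,
                    n_ctrl_per_bin=config.score.n_ctrl_per_bin,
                    seed=config.seed,
                    bins=bins,
                )
                results[name] = res.scores
            if results:
                scores = pd.DataFrame(results)
                scores.insert(0, "barcode", scores.index)
                _write_tsv(scores, outdir / "module_scores.tsv")
                names = list(results)
                rows = []
                for i, a in enumerate(names):
                    for b in names[i + 1 :]:
                        c = geneset_correlation(results[a], results[b])
                        rows.append(
                            {"set_a": a, "set_b": b, "r": c.r, "ci_lo": c.ci95[0],
                             "ci_hi": c.ci95[1], "p": c.p, "n": c.n}
                        )
                if rows:
                    _write_tsv(pd.DataFrame(rows), outdir / "geneset_correlation.tsv")
                score_tables = names
        manifest["wall_time_s"]["scoring"] = round(time.perf_counter() - t0, 3)

        t0 = time.perf_counter()
        gcorr = group_correlation(norm, config.stage_key, top_n=1000)
        _write_tsv(gcorr.reset_index().rename(columns={"index": "group"}),
                   outdir / "group_correlation.tsv")
        manifest["wall_time_s"]["group_correlation"] = round(time.perf_counter() - t0, 3)

        summary["gene_sets_scored"] = score_tables
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    except Exception:
        partial = outdir / "partial"
        partial.mkdir(exist_ok=True)
        for f in outdir.iterdir():
            if f.is_file():
                f.rename(partial / f.name)
        log.exception("pipeline failed after stages %s; outputs moved to %s",
                      list(manifest["wall_time_s"]), partial)
        raise
    manifest["stages_analyzed"] = stage_names
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir
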