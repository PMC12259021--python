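"""Cell and gene quality control and library-size log normalization.

Four exclusion criteria, applied to raw counts:

1. library size (total UMIs) above ``umi_max`` or below ``umi_min``;
2. detected genes (count > 0) above ``genes_max`` or below ``genes_min``;
3. mitochondrial UMI fraction above ``mito_frac_max``;
4. genes detected in fewer than ``gene_min_cells`` cells.

All bounds are exclusive: a cell sitting exactly on a limit (e.g. 10,000
UMIs or a 10.0% mitochondrial fraction) is retained. Normalization is
ln(1 + count × scale_factor / cell_total) per cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc


@dataclass
class QCThresholds:
    umi_max: int = 10_000
    umi_min: int = 500
    genes_max: int = 5_000
    genes_min: int = 300
    mito_frac_max: float = 0.10
    gene_min_cells: int = 10

    def __post_init__(self) -> None:
        if not self.umi_min < self.umi_max:
            raise ValueError(f"umi_min ({self.umi_min}) must be < umi_max ({self.umi_max})")
        if not self.genes_min < self.genes_max:
            raise ValueError(
                f"genes_min ({self.genes_min}) must be < genes_max ({self.genes_max})"
            )
        if not 0 <= self.mito_frac_max <= 1:
            raise ValueError("mito_frac_max must lie in [0, 1]")


@dataclass
class QCReport:
    """Per-criterion exclusion counts and per-cell flags.

    Flags are not mutually exclusive: one cell may fail several criteria.
    """

    n_input_cells: int
    n_retained_cells: int
    exclusions: dict[str, int]
    flags: pd.DataFrame  # index barcode; boolean fail columns + retained
    n_retained_genes: int | None = None

    def summary(self) -> dict:
        return {
            "n_input_cells": self.n_input_cells,
            "n_retained_cells": self.n_retained_cells,
            "n_retained_genes": self.n_retained_genes,
            "exclusions": dict(self.exclusions),
        }


def cell_qc_metrics(adata: ad.AnnData) -> pd.DataFrame:
    """Per-cell total UMIs, detected genes and mitochondrial fraction."""
    if "mito" not in adata.var:
        raise ValueError("gene table has no 'mito' flag column; mito fraction undefined")
    X = adata.X.tocsr()
    total = np.asarray(X.sum(axis=1)).ravel()
    detected = X.getnnz(axis=1)
    mito_mask = adata.var["mito"].to_numpy(bool)
    mito_total = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_total / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {"total_umis": total, "detected_genes": detected, "mito_frac": mito_frac},
        index=adata.obs.index,
    )


def filter_cells(
    adata: ad.AnnData, thresholds: QCThresholds | None = None
) -> tuple[ad.AnnData, QCReport]:
    """Drop cells failing the UMI, detected-gene or mitochondrial criteria."""
    t = thresholds or QCThresholds()
    m = cell_qc_metrics(adata)
    fail_umi = (m["total_umis"] > t.umi_max) | (m["total_umis"] < t.umi_min)
    fail_genes = (m["detected_genes"] > t.genes_max) | (m["detected_genes"] < t.genes_min)
    fail_mito = m["mito_frac"] > t.mito_frac_max
    flags = pd.DataFrame(
        {
            "fail_umi": fail_umi,
            "fail_genes": fail_genes,
            "fail_mito": fail_mito,
        }
    )
    flags["retained"] = ~flags.any(axis=1)
    kept = flags["retained"].to_numpy()
    if not kept.any():
        warnings.warn("all cells removed by QC thresholds", stacklevel=2)
    report = QCReport(
        n_input_cells=adata.n_obs,
        n_retained_cells=int(kept.sum()),
        exclusions={
            "umi": int(fail_umi.sum()),
            "genes": int(fail_genes.sum()),
            "mito": int(fail_mito.sum()),
        },
        flags=pd.concat([m, flags], axis=1),
    )
    return adata[kept].copy(), report


def filter_genes(adata: ad.AnnData, thresholds: QCThresholds | None = None) -> ad.AnnData:
    """Drop genes detected in fewer than ``gene_min_cells`` cells (order kept)."""
    t = thresholds or QCThresholds()
    out = adata.copy()
    sc.pp.filter_genes(out, min_cells=t.gene_min_cells)
    return out


def normalize(adata: ad.AnnData, scale_factor: float = 10_000.0) -> ad.AnnData:
    """Library-size normalize and log-transform: ln(1 + c × sf / total).

    Raw counts are kept in ``layers["counts"]``; zeros stay exactly zero.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be > 0")
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    if (totals <= 0).any():
        n = int((totals <= 0).sum())
        raise ValueError(
            f"{n} cells have zero total counts; run filter_cells before normalize"
        )
    out = adata.copy()
    out.layers["counts"] = out.X.copy()
    # double precision throughout so values recompute exactly from counts
    X = out.X.tocsr().astype(np.float64)
    X = X.multiply(scale_factor / totals[:, None]).tocsr()
    X.data = np.log1p(X.data)
    out.X = X
    out.uns["normalization"] = {"scale_factor": float(scale_factor), "log": "natural"}
    return out


def run_qc(
    adata: ad.AnnData,
    thresholds: QCThresholds | None = None,
    scale_factor: float = 10_000.0,
    genes_first: bool = False,
) -> tuple[ad.AnnData, QCReport]:
    """Full QC: filter cells, filter genes, normalize (order configurable)."""
    t = thresholds or QCThresholds()
    if genes_first:
        adata = filter_genes(adata, t)
        filtered, report = filter_cells(adata, t)
    else:
        filtered, report = filter_cells(adata, t)
        filtered = filter_genes(filtered, t)
    report.n_retained_genes = filtered.n_vars
    if filtered.n_obs == 0:
        return filtered, report
    return normalize(filtered, scale_factor), report
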