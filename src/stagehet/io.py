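"""Readers and writers for the plain-text formats the pipeline touches.

On disk the count matrix follows the 10x triplet convention: Matrix
Market coordinate file with genes as rows and cells as columns, plus
genes.tsv / barcodes.tsv and a cells.tsv metadata table keyed by
barcode. In memory everything is an AnnData (cells × genes).
"""

from __future__ import annotations

import gzip
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

GENES_TSV = "genes.tsv"
BARCODES_TSV = "barcodes.tsv"
MATRIX_MTX = "matrix.mtx"
CELLS_TSV = "cells.tsv"


def write_matrix(adata: ad.AnnData, outdir) -> dict:
    """Write counts + metadata as an MTX/TSV triplet; returns the paths."""
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError(
            f"refusing to write an empty matrix ({adata.n_obs} cells × {adata.n_vars} genes)"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / name for name in (MATRIX_MTX, GENES_TSV, BARCODES_TSV, CELLS_TSV)}
    X = sp.csc_matrix(adata.X.T)  # genes × cells, 10x orientation
    scipy.io.mmwrite(str(paths[MATRIX_MTX]), X, field="integer")
    genes = adata.var.reset_index()
    genes.columns = ["gene_id"] + list(genes.columns[1:])
    cols = ["gene_id", "symbol", "mito"]
    genes["mito"] = genes["mito"].astype(int)
    genes[cols].to_csv(paths[GENES_TSV], sep="\t", index=False)
    pd.Series(adata.obs.index, name="barcode").to_csv(paths[BARCODES_TSV], sep="\t", index=False)
    cells = adata.obs.reset_index()
    cells.columns = ["barcode"] + list(cells.columns[1:])
    keep = [c for c in ("barcode", "stage", "sample", "cell_type", "cluster") if c in cells]
    cells[keep].to_csv(paths[CELLS_TSV], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}


def _maybe_gz(path: Path) -> Path:
    gz = path.with_name(path.name + ".gz")
    if path.exists():
        return path
    if gz.exists():
        return gz
    raise FileNotFoundError(f"missing input file: {path} (or {gz.name})")


def _read_tsv(path: Path) -> pd.DataFrame:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return pd.read_csv(fh, sep="\t")


def read_matrix(indir) -> ad.AnnData:
    """Read an MTX/TSV triplet (optionally gzipped) into AnnData.

    Mitochondrial flags come from the genes.tsv ``mito`` column when
    present, else from a ``mt-``/``MT-`` symbol prefix. Raises on any
    dimension mismatch between the MTX header and the TSV files, and on
    barcodes absent from the metadata table.
    """
    indir = Path(indir)
    mtx = _maybe_gz(indir / MATRIX_MTX)
    opener = gzip.open if mtx.suffix == ".gz" else open
    with opener(mtx, "rb") as fh:
        X = scipy.io.mmread(fh)
    X = sp.csr_matrix(X.T).astype(np.int64)  # cells × genes
    genes = _read_tsv(_maybe_gz(indir / GENES_TSV))
    barcodes = _read_tsv(_maybe_gz(indir / BARCODES_TSV))
    if X.shape[1] != len(genes):
        raise ValueError(
            f"matrix declares {X.shape[1]} genes but {GENES_TSV} lists {len(genes)}"
        )
    if X.shape[0] != len(barcodes):
        raise ValueError(
            f"matrix declares {X.shape[0]} cells but {BARCODES_TSV} lists {len(barcodes)}"
        )
    var = genes.set_index("gene_id")
    if "mito" in var:
        var["mito"] = var["mito"].astype(bool)
    else:
        var["mito"] = var["symbol"].str.lower().str.startswith("mt-")
    obs = pd.DataFrame(index=pd.Index(barcodes["barcode"], name="barcode"))
    cells_path = indir / CELLS_TSV
    try:
        cells = _read_tsv(_maybe_gz(cells_path))
    except FileNotFoundError:
        cells = None
    if cells is not None:
        cells = cells.set_index("barcode")
        missing = obs.index.difference(cells.index)
        if len(missing):
            raise ValueError(
                f"{len(missing)} barcodes missing from {CELLS_TSV}: "
                f"{list(missing[:10])}"
            )
        obs = obs.join(cells, how="left")
    return ad.AnnData(X=X, obs=obs, var=var)


def read_gene_sets(path) -> dict[str, list[str]]:
    """Read gene sets from GMT (name, description, genes...) or a plain
    one-gene-per-line list (set name = file stem)."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    lines = path.read_text().splitlines()
    if path.suffix.lower() == ".gmt":
        for ln in lines:
            if not ln.strip():
                continue
            parts = ln.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line (need name, description, genes): {ln!r}")
            name, genes = parts[0], [g for g in parts[2:] if g]
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            sets[name] = genes
    else:
        genes = [ln.strip() for ln in lines if ln.strip()]
        if not genes:
            raise ValueError(f"gene list {path} is empty")
        sets[path.stem] = genes
    return sets
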