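import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import stagehet as sh


def make_adata(X, mito_flags=None, obs=None, gene_ids=None):
    """AnnData from a dense cells × genes array with a mito flag column."""
    X = np.asarray(X)
    n_cells, n_genes = X.shape
    if gene_ids is None:
        gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    var = pd.DataFrame(
        {
            "symbol": [f"sym-{g}" for g in gene_ids],
            "mito": np.zeros(n_genes, bool) if mito_flags is None else np.asarray(mito_flags),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    if obs is None:
        obs = pd.DataFrame(index=pd.Index([f"cell{i:04d}" for i in range(n_cells)], name="barcode"))
    return ad.AnnData(X=sp.csr_matrix(X), obs=obs, var=var)


def build_cell_counts(specs, n_mito=100, n_genes=5300):
    """Cells × genes integer matrix realizing (total, detected, mito_counts) specs.

    Each cell detects 10 mitochondrial genes plus (detected − 10)
    non-mitochondrial genes; remainders are dumped on the first
    non-mito gene so totals come out exact.
    """
    X = np.zeros((len(specs), n_genes), dtype=np.int64)
    for c, (total, detected, mito_counts) in enumerate(specs):
        base, rem = divmod(mito_counts, 10)
        X[c, :10] = base
        X[c, :rem] += 1
        n_non = detected - 10
        assert 0 < n_non <= n_genes - n_mito
        X[c, n_mito : n_mito + n_non] = 1
        X[c, n_mito] += total - mito_counts - n_non
        assert X[c].sum() == total and (X[c] > 0).sum() == detected
    mito = np.zeros(n_genes, bool)
    mito[:n_mito] = True
    return make_adata(X, mito_flags=mito)


@pytest.fixture(scope="session")
def six_cell_fixture():
    """The hand-built QC fixture: exactly one cell passes all criteria.

    Cells fail, in order: UMIs below 500; detected genes below 300;
    UMIs above 10,000; mito fraction above 10%; detected genes above
    5,000; the last cell passes everything.
    """
    specs = [
        (400, 350, 20),  # 400 UMIs -> fewer than 500
        (600, 299, 30),  # 299 genes -> fewer than 300
        (10_001, 400, 500),  # more than 10,000 UMIs
        (2_000, 400, 220),  # 11% mito -> over 10%
        (6_000, 5_001, 300),  # more than 5,000 genes
        (2_000, 400, 100),  # passes all criteria
    ]
    return build_cell_counts(specs)


@pytest.fixture(scope="session")
def two_stage_sim():
    """Small two-stage simulation (low vs high jitter) with ground truth."""
    cfg = sh.SimConfig(
        n_genes=500,
        stages=("low", "high"),
        stage_noise_sd=(0.1, 0.8),
        cells_per_stage=150,
        seed=1,
    )
    return sh.simulate_counts(cfg), cfg


@pytest.fixture(scope="session")
def two_stage_norm(two_stage_sim):
    (adata, _), _ = two_stage_sim
    norm, _ = sh.run_qc(adata)
    return norm


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
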