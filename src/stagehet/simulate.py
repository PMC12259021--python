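"""Synthetic multi-stage scRNA-seq count generator with known ground truth.

Emulates a premalignant progression experiment (normal → AAH → adenoma →
AIS): several cell types with private marker genes, negative-binomial
counts, a flagged mitochondrial gene block, Gamma-distributed library
sizes, and — the heterogeneity knob — stage-specific per-cell log-mean
jitter. Gene programs (coordinated up-regulation of a gene set in one
cell type at chosen stages) can be injected on top.

The count model for cell c, gene g:

    mu[c, g]  = base[g] * 2**marker_lfc[type(c), g]
                        * exp(eps[c, g]) * 2**program_lfc[c, g]
    count     ~ NB(mean = mu[c, g] * lib[c] / sum_g mu[c, g],
                   var  = mean + dispersion * mean**2)

with eps[c, g] ~ iid Normal(-sd²/2, sd), sd = stage_noise_sd[stage(c)]
(mean-corrected so jitter changes dispersion, not means), and
lib[c] ~ Gamma(shape, scale = library_size_mean / shape). With jitter and
programs off, the per-gene mean count across cells converges to
base[g] * library_size_mean / sum(base).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

DEFAULT_STAGES = ("normal", "AAH", "adenoma", "AIS")


def _stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    """Per-stage seed stream; adding/removing other stages does not perturb it."""
    return np.random.SeedSequence(entropy=(int(seed), zlib.crc32(stage.encode())))


@dataclass
class SimConfig:
    """Parameters of the multi-stage simulation.

    stage_noise_sd is the heterogeneity knob: the SD of iid per-cell,
    per-gene Gaussian jitter on the log mean. Larger values make cells of
    a stage less alike, which lowers the within-stage pairwise NMI
    downstream. Defaults increase along the premalignant continuum.
    """

    n_genes: int = 2000
    n_mito_genes: int = 50
    stages: tuple[str, ...] = DEFAULT_STAGES
    cells_per_stage: int = 600
    n_cell_types: int = 4
    base_log_mean: float = 0.0
    base_log_sd: float = 1.0
    nb_dispersion: float = 0.1
    stage_noise_sd: tuple[float, ...] = (0.10, 0.30, 0.55, 0.85)
    library_size_mean: float = 5000.0
    library_size_shape: float = 10.0
    mito_frac_mean: float = 0.05
    marker_genes_per_type: int = 25
    marker_log2fc: float = 2.0
    cell_type_props: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        if not self.stages:
            raise ValueError("stages must be non-empty")
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("stage names must be unique")
        if isinstance(self.stage_noise_sd, (int, float)):
            self.stage_noise_sd = (float(self.stage_noise_sd),) * len(self.stages)
        self.stage_noise_sd = tuple(float(s) for s in self.stage_noise_sd)
        if len(self.stage_noise_sd) != len(self.stages):
            raise ValueError("stage_noise_sd must give one value per stage")
        if any(s < 0 for s in self.stage_noise_sd):
            raise ValueError("stage_noise_sd must be >= 0")
        if self.cells_per_stage < 2:
            raise ValueError("cells_per_stage must be >= 2 (pairs must exist)")
        if self.n_genes <= 0 or self.n_mito_genes < 0 or self.n_mito_genes >= self.n_genes:
            raise ValueError("need 0 <= n_mito_genes < n_genes, n_genes > 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.library_size_mean <= 0 or self.library_size_shape <= 0:
            raise ValueError("library size parameters must be > 0")
        if self.n_cell_types < 1:
            raise ValueError("n_cell_types must be >= 1")
        if self.cell_type_props is not None:
            p = np.asarray(self.cell_type_props, float)
            if p.shape != (self.n_cell_types,) or (p < 0).any() or p.sum() <= 0:
                raise ValueError("cell_type_props must be n_cell_types non-negative weights")
            self.cell_type_props = tuple(p / p.sum())

    @property
    def cell_types(self) -> list[str]:
        return [f"type{i}" for i in range(self.n_cell_types)]


@dataclass
class ProgramSpec:
    """A gene program injected into one cell type at selected stages."""

    gene_ids: list[str]
    target_cell_type: str
    target_stages: tuple[str, ...]
    effect_log2fc: float = 2.0

    def validate(self, config: SimConfig, gene_universe: set[str]) -> None:
        missing = [g for g in self.gene_ids if g not in gene_universe]
        if missing:
            raise ValueError(f"program genes not in simulated universe: {missing[:10]}")
        if self.target_cell_type not in config.cell_types:
            raise ValueError(f"unknown target cell type {self.target_cell_type!r}")
        bad = set(self.target_stages) - set(config.stages)
        if bad:
            raise ValueError(f"unknown target stages {sorted(bad)}")


@dataclass
class GroundTruth:
    """Per-cell and per-gene truth records for the simulation."""

    cells: pd.DataFrame  # index barcode; columns cell_type, stage, program_effect
    gene_programs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene_id", "program"])
    )


def _gene_table(config: SimConfig) -> pd.DataFrame:
    ids, symbols, mito = [], [], []
    for i in range(config.n_mito_genes):
        ids.append(f"ENSG-MT-{i:05d}")
        symbols.append(f"mt-Gene{i}")
        mito.append(True)
    for i in range(config.n_genes - config.n_mito_genes):
        ids.append(f"ENSG{i:05d}")
        symbols.append(f"Gene{i}")
        mito.append(False)
    return pd.DataFrame({"gene_id": ids, "symbol": symbols, "mito": mito}).set_index(
        "gene_id"
    )


def _base_means(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    base = rng.lognormal(config.base_log_mean, config.base_log_sd, config.n_genes)
    if config.n_mito_genes:
        # rescale the mito block so its expected share of counts is mito_frac_mean
        m = config.n_mito_genes
        non_mito = base[m:].sum()
        target = config.mito_frac_mean / (1 - config.mito_frac_mean) * non_mito
        base[:m] *= target / base[:m].sum()
    return base


def _marker_lfc(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """(n_cell_types, n_genes) log2 fold-changes: disjoint marker blocks per type."""
    lfc = np.zeros((config.n_cell_types, config.n_genes))
    start = config.n_mito_genes
    for t in range(config.n_cell_types):
        block = slice(start, start + config.marker_genes_per_type)
        if block.stop > config.n_genes:
            raise ValueError("not enough genes for the requested marker blocks")
        lfc[t, block] = config.marker_log2fc
        start = block.stop
    return lfc


def simulate_counts(
    config: SimConfig, programs: list[ProgramSpec] | None = None
) -> tuple[ad.AnnData, GroundTruth]:
    """Simulate counts; returns (AnnData of raw counts, GroundTruth).

    The AnnData is cells × genes: ``X`` holds sparse integer counts,
    ``obs`` the per-cell metadata (stage, sample, cell_type), ``var`` the
    gene table with the ``mito`` flag. Identical (config, programs, seed)
    give bit-identical output.
    """
    programs = list(programs or [])
    master = np.random.default_rng(np.random.SeedSequence(entropy=(int(config.seed), 0)))
    genes = _gene_table(config)
    universe = set(genes.index)
    for p in programs:
        p.validate(config, universe)
    base = _base_means(config, master)
    marker_lfc = _marker_lfc(config, master)

    gene_pos = {g: i for i, g in enumerate(genes.index)}
    prog_records = [
        {"gene_id": g, "program": k} for k, p in enumerate(programs) for g in p.gene_ids
    ]

    X_blocks, obs_frames = [], []
    disp = config.nb_dispersion
    props = config.cell_type_props
    for si, stage in enumerate(config.stages):
        rng = np.random.default_rng(_stage_seed(config.seed, stage))
        n = config.cells_per_stage
        if props is None:
            ctype_idx = np.arange(n) % config.n_cell_types
        else:
            ctype_idx = rng.choice(config.n_cell_types, size=n, p=np.asarray(props))
        lib = rng.gamma(
            config.library_size_shape,
            config.library_size_mean / config.library_size_shape,
            size=n,
        )
        log_mu = np.log(base)[None, :] + np.log(2.0) * marker_lfc[ctype_idx]
        sd = config.stage_noise_sd[si]
        if sd > 0:
            # mean-corrected lognormal jitter: E[exp(eps)] = 1, so noise does
            # not shift per-gene expected expression between stages
            log_mu = log_mu + rng.normal(-0.5 * sd * sd, sd, size=log_mu.shape)
        applied = np.zeros(n)
        for p in programs:
            if stage not in p.target_stages:
                continue
            mask = ctype_idx == config.cell_types.index(p.target_cell_type)
            idx = np.array([gene_pos[g] for g in p.gene_ids])
            log_mu[np.ix_(mask, idx)] += np.log(2.0) * p.effect_log2fc
            applied[mask] += p.effect_log2fc
        mu = np.exp(log_mu)
        mu *= (lib / mu.sum(axis=1))[:, None]
        if disp > 0:
            lam = rng.gamma(1.0 / disp, disp * mu)
        else:
            lam = mu
        counts = rng.poisson(lam)
        X_blocks.append(sp.csr_matrix(counts))
        barcodes = [f"{stage}-{i:05d}" for i in range(n)]
        obs_frames.append(
            pd.DataFrame(
                {
                    "stage": stage,
                    "sample": f"sample-{stage}",
                    "cell_type": [config.cell_types[t] for t in ctype_idx],
                    "program_effect": applied,
                },
                index=barcodes,
            )
        )

    obs = pd.concat(obs_frames)
    obs.index.name = "barcode"
    obs["stage"] = pd.Categorical(obs["stage"], categories=list(config.stages), ordered=True)
    adata = ad.AnnData(
        X=sp.vstack(X_blocks).tocsr().astype(np.int64), obs=obs, var=genes.copy()
    )
    truth = GroundTruth(
        cells=obs[["cell_type", "stage", "program_effect"]].copy(),
        gene_programs=pd.DataFrame(prog_records, columns=["gene_id", "program"]),
    )
    return adata, truth


def write_fixture(adata: ad.AnnData, outdir) -> dict:
    """Write a 10x-style plain-text triplet plus a cell-metadata TSV.

    Files: matrix.mtx (genes × cells, integer coordinate format),
    genes.tsv (gene_id, symbol, mito), barcodes.tsv, cells.tsv
    (barcode, stage, sample, cell_type). Round-trips bit-exactly through
    :func:`stagehet.io.read_matrix`.
    """
    from . import io as _io  # local import: io depends on nothing here

    return _io.write_matrix(adata, outdir)


def two_noise_stage_pair(
    noise_low: float = 0.1, noise_high: float = 0.8, cells_per_stage: int = 300, seed: int = 0
) -> tuple[ad.AnnData, GroundTruth]:
    """Convenience: a two-stage simulation differing only in jitter SD."""
    cfg = SimConfig(
        stages=("low", "high"),
        stage_noise_sd=(noise_low, noise_high),
        cells_per_stage=cells_per_stage,
        seed=seed,
    )
    return simulate_counts(cfg)
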