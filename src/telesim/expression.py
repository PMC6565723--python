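"""From EVFs and gene effects to kinetic parameters and true counts.

For each kinetic parameter, the raw per-gene, per-cell value is the dot
product of the cell's EVF vector with the gene's (sparse) effect vector.
Because dot products live on an arbitrary scale, they are quantile-mapped
onto reference samples of plausible kinetic-parameter values: all
genes x cells raw values are ranked jointly, an equally large sample is
drawn from the reference distribution, and the i-th ranked raw value is
replaced by the i-th ranked reference draw.  The mapped parameters (after
the cell-size multiplier ``scale_s``, the ``bimod`` adjustment and outlier
inflation) drive the Beta-Poisson sampler to produce true transcript counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import kinetics, manifold
from .kinetics import KineticParams, OutlierConfig
from .manifold import PARAM_NAMES, CellStateTree, EVFMatrices

__all__ = [
    "GeneEffectMatrices",
    "ReferenceParamDistributions",
    "TrueCountsResult",
    "sample_gene_effects",
    "raw_params",
    "quantile_map",
    "simulate_true_counts",
]


@dataclass
class GeneEffectMatrices:
    """Genes x n_evf effect coefficients, one matrix per kinetic parameter.

    Entries are N(0, gene_effects_sd) zeroed independently with probability
    ``eta``, so each gene responds to only a small subset of EVFs.
    """

    effects: dict[str, np.ndarray]
    eta: float
    gene_effects_sd: float

    @property
    def n_genes(self) -> int:
        return next(iter(self.effects.values())).shape[0]


@dataclass
class ReferenceParamDistributions:
    """Sample vectors of plausible k_on, k_off and s values (d=1 units)."""

    k_on: np.ndarray
    k_off: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size == 0:
                raise ValueError(f"reference {name} sample is empty")
            if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                raise ValueError(f"reference {name} must be positive and finite")
            setattr(self, name, arr)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReferenceParamDistributions":
        missing = set(PARAM_NAMES) - set(df.columns)
        if missing:
            raise ValueError(f"reference table lacks columns: {sorted(missing)}")
        return cls(df["k_on"].to_numpy(), df["k_off"].to_numpy(), df["s"].to_numpy())

    def to_frame(self) -> pd.DataFrame:
        n = min(self.k_on.size, self.k_off.size, self.s.size)
        return pd.DataFrame({
            "k_on": self.k_on[:n], "k_off": self.k_off[:n], "s": self.s[:n],
        })


@dataclass
class TrueCountsResult:
    """True transcript counts with full generative provenance."""

    counts: np.ndarray  # genes x cells, integer
    kinetics: KineticParams
    evfs: EVFMatrices
    effects: GeneEffectMatrices
    meta: pd.DataFrame
    outlier_mask: np.ndarray
    scale_s: float

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]


def sample_gene_effects(
    n_genes: int,
    n_evf: int,
    eta: float = 0.7,
    gene_effects_sd: float = 1.0,
    rng: np.random.Generator | None = None,
) -> GeneEffectMatrices:
    """Draw sparse gene-effect matrices for the three kinetic parameters."""
    if not (0 <= eta <= 1):
        raise ValueError("eta must be in [0, 1]")
    if gene_effects_sd <= 0:
        raise ValueError("gene_effects_sd must be > 0")
    rng = np.random.default_rng() if rng is None else rng
    effects = {}
    for param in PARAM_NAMES:
        mat = rng.normal(0.0, gene_effects_sd, size=(n_genes, n_evf))
        mat[rng.random((n_genes, n_evf)) < eta] = 0.0
        effects[param] = mat
    return GeneEffectMatrices(effects, eta, gene_effects_sd)


def raw_params(evf_matrix: np.ndarray, gene_effect_matrix: np.ndarray) -> np.ndarray:
    """Raw kinetic values: raw[g, c] = sum_j effect[g, j] * evf[c, j]."""
    evf_matrix = np.asarray(evf_matrix, float)
    gene_effect_matrix = np.asarray(gene_effect_matrix, float)
    if evf_matrix.shape[1] != gene_effect_matrix.shape[1]:
        raise ValueError("EVF and gene-effect matrices disagree on n_evf")
    return gene_effect_matrix @ evf_matrix.T


def quantile_map(
    raw_matrix: np.ndarray,
    reference_samples: np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Replace raw values by equally ranked draws from a reference sample.

    All m*n raw values are ranked jointly (stable sort, so ties keep
    (gene, cell) order); m*n values are drawn from the reference with
    replacement, sorted, and matched rank for rank.  The output is a
    strictly positive matrix whose value ranking equals the input's.
    """
    reference_samples = np.asarray(reference_samples, float)
    if reference_samples.size == 0:
        raise ValueError("reference sample is empty")
    rng = np.random.default_rng() if rng is None else rng
    raw = np.asarray(raw_matrix, float)
    flat = raw.ravel()
    order = np.argsort(flat, kind="stable")
    draws = np.sort(rng.choice(reference_samples, size=flat.size, replace=True))
    mapped = np.empty_like(flat)
    mapped[order] = draws
    return mapped.reshape(raw.shape)


def simulate_true_counts(
    config,
    tree: CellStateTree | None = None,
    reference: ReferenceParamDistributions | None = None,
    rng: np.random.Generator | None = None,
) -> TrueCountsResult:
    """Run the full true-count pipeline for a SimulationConfig.

    EVF sampling (mode-dependent) -> gene effects -> per-parameter dot
    products -> joint quantile mapping onto the reference distributions ->
    cell-size scaling of s -> bimod adjustment -> high-expression outliers
    -> Beta-Poisson draws (outlier genes drawn Poisson, always on).
    """
    from .io import load_example_tree, load_reference_params  # lazy, avoids cycle

    rng = np.random.default_rng() if rng is None else rng
    tree = load_example_tree() if tree is None else tree
    reference = load_reference_params() if reference is None else reference

    if config.mode == "discrete":
        evfs, meta = manifold.sample_evfs_discrete(
            tree, config.cells_per_population(tree), config.sigma,
            config.n_evf, config.n_diff_evf, rng)
    elif config.mode == "continuous":
        evfs, meta = manifold.sample_evfs_continuous(
            tree, config.n_cells, config.sigma,
            config.n_evf, config.n_diff_evf, rng)
    elif config.mode == "impulse":
        evfs, meta = manifold.sample_evfs_impulse(
            tree, config.n_cells, config.sigma, config.impulse,
            config.n_evf, config.n_diff_evf, rng)
    else:
        raise ValueError(f"unknown mode: {config.mode!r}")

    effects = sample_gene_effects(
        config.n_genes, config.n_evf, config.eta, config.gene_effects_sd, rng)

    mapped = {}
    for param in PARAM_NAMES:
        raw = raw_params(evfs.evfs[param], effects.effects[param])
        mapped[param] = quantile_map(raw, getattr(reference, param), rng)
    mapped["s"] = mapped["s"] * config.scale_s

    params = KineticParams(mapped["k_on"], mapped["k_off"], mapped["s"])
    params = kinetics.apply_bimod(params, config.bimod)
    outlier_cfg = OutlierConfig(config.prop_hge, config.mean_hge)
    params, outlier_mask = kinetics.apply_high_expression_outliers(
        params, outlier_cfg, rng)

    p = rng.beta(params.k_on, params.k_off)
    # outlier genes are constitutively on: Poisson(s), no Beta mixing
    p[outlier_mask, :] = 1.0
    counts = rng.poisson(params.s * p)

    return TrueCountsResult(
        counts=counts, kinetics=params, evfs=evfs, effects=effects,
        meta=meta, outlier_mask=outlier_mask, scale_s=config.scale_s)
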