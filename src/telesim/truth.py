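"""Ground-truth differential expression and experimental-design calculators.

A gene is differentially expressed between two populations by construction
when (a) it has at least one Diff-EVF with a non-zero gene-effect entry —
the mechanism by which between-population signal reaches its kinetics — and
(b) the log2 fold change of its mean expression passes a threshold.  The
mean expression of a gene in a cell is the stationary Beta-Poisson mean
``s * k_on / (k_on + k_off)``, so the LFC can be computed directly from the
kinetic parameters, without sampling noise.

The design calculators answer "how many cells must I sequence to see a rare
population": the probability that at least ``x`` of ``N`` sequenced cells
come from a population of proportion ``r`` is a binomial tail, and the
empirical detection rule declares success when some cluster contains at
least ``x`` rare cells making up at least a target precision of it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import GeneEffectMatrices
from .kinetics import KineticParams, theoretical_mean
from .manifold import PARAM_NAMES

__all__ = [
    "DetectionSpec",
    "theoretical_lfc",
    "n_diff_evf_per_gene",
    "de_ground_truth",
    "detection_probability",
    "min_cells_for_success",
    "rare_pop_detected",
    "bimod_expression_change",
]


@dataclass(frozen=True)
class DetectionSpec:
    """Rare-population detection criterion."""

    N: int
    r: float
    x: int = 50
    min_precision: float = 0.7

    def __post_init__(self) -> None:
        if not (0 < self.r < 1):
            raise ValueError("r must be in (0, 1)")
        if self.x < 1:
            raise ValueError("x must be >= 1")
        if not (0 < self.min_precision <= 1):
            raise ValueError("min_precision must be in (0, 1]")


def theoretical_lfc(kinetics_a: KineticParams,
                    kinetics_b: KineticParams) -> np.ndarray:
    """Per-gene log2 fold change of cell-averaged theoretical means, A vs B.

    Zero means produce signed infinities (never NaN) so downstream
    thresholding still behaves.
    """
    if kinetics_a.shape[0] != kinetics_b.shape[0]:
        raise ValueError("populations must share one gene panel")
    mean_a = theoretical_mean(kinetics_a.k_on, kinetics_a.k_off,
                              kinetics_a.s).mean(axis=-1)
    mean_b = theoretical_mean(kinetics_b.k_on, kinetics_b.k_off,
                              kinetics_b.s).mean(axis=-1)
    with np.errstate(divide="ignore"):
        return np.log2(mean_a) - np.log2(mean_b)


def n_diff_evf_per_gene(effects: GeneEffectMatrices,
                        diff_mask: np.ndarray) -> np.ndarray:
    """Count of Diff-EVF columns with non-zero effect, summed over the
    three kinetic parameters' effect matrices."""
    diff_mask = np.asarray(diff_mask, bool)
    total = np.zeros(effects.n_genes, dtype=int)
    for param in PARAM_NAMES:
        mat = effects.effects[param]
        if mat.shape[1] != diff_mask.size:
            raise ValueError("diff_mask length must equal n_evf")
        total += np.count_nonzero(mat[:, diff_mask], axis=1)
    return total


def de_ground_truth(
    effects: GeneEffectMatrices,
    diff_mask: np.ndarray,
    kinetics_a: KineticParams,
    kinetics_b: KineticParams,
    lfc_threshold: float = 0.8,
) -> pd.DataFrame:
    """Ground-truth DE table: nDiff_EVF, theoretical LFC and the DE flag.

    ``is_de`` requires both a mechanistic route (nDiff_EVF > 0) and a large
    enough effect (|LFC| > lfc_threshold; thresholds of 0.6-1 are typical).
    """
    n_diff = n_diff_evf_per_gene(effects, diff_mask)
    lfc = theoretical_lfc(kinetics_a, kinetics_b)
    if n_diff.size != lfc.size:
        raise ValueError("effects and kinetics disagree on n_genes")
    return pd.DataFrame({
        "gene": np.arange(n_diff.size),
        "n_diff_evf": n_diff,
        "lfc": lfc,
        "is_de": (n_diff > 0) & (np.abs(lfc) > lfc_threshold),
        "lfc_threshold": lfc_threshold,
    })


def detection_probability(N: int, r: float, x: int) -> float:
    """P(at least x of N cells come from a population of proportion r).

    The binomial upper tail ``1 - sum_{k<x} C(N,k) r^k (1-r)^(N-k)``,
    evaluated through the survival function for numerical stability.
    """
    if not (0 < r < 1):
        raise ValueError("r must be in (0, 1)")
    if x <= 0:
        return 1.0
    if x > N:
        return 0.0
    return float(stats.binom.sf(x - 1, N, r))


def min_cells_for_success(r: float, x: int, target_prob: float) -> int:
    """Smallest N with detection_probability(N, r, x) >= target_prob.

    Monotone bisection; the detection probability is non-decreasing in N.
    """
    if not (0 < target_prob < 1):
        raise ValueError("target_prob must be in (0, 1)")
    lo = x
    hi = max(x, int(np.ceil(x / r)))
    while detection_probability(hi, r, x) < target_prob:
        lo, hi = hi, hi * 2
    while lo < hi:
        mid = (lo + hi) // 2
        if detection_probability(mid, r, x) >= target_prob:
            hi = mid
        else:
            lo = mid + 1
    return lo


def rare_pop_detected(
    cluster_labels: np.ndarray,
    true_labels: np.ndarray,
    rare_population,
    x: int = 50,
    min_precision: float = 0.7,
) -> bool:
    """Empirical success criterion for detecting a rare population.

    True iff some cluster contains at least ``x`` cells of the rare
    population and those cells make up at least ``min_precision`` of the
    cluster.
    """
    cluster_labels = np.asarray(cluster_labels)
    true_labels = np.asarray(true_labels)
    if cluster_labels.shape != true_labels.shape:
        raise ValueError("label vectors must be aligned")
    if rare_population not in true_labels:
        raise ValueError(f"unknown population: {rare_population!r}")
    is_rare = true_labels == rare_population
    for cluster in np.unique(cluster_labels):
        members = cluster_labels == cluster
        n_rare = int(np.count_nonzero(members & is_rare))
        if n_rare >= x and n_rare / members.sum() >= min_precision:
            return True
    return False


def bimod_expression_change(counts_low: np.ndarray,
                            counts_high: np.ndarray) -> np.ndarray:
    """Per-gene fractional change of total transcripts between two runs.

    ``(sum_j x_j - sum_j x'_j) / sum_j x_j`` per gene; genes with a zero
    baseline total are flagged NaN (undefined, not infinite).
    """
    counts_low = np.asarray(counts_low, float)
    counts_high = np.asarray(counts_high, float)
    if counts_low.shape[0] != counts_high.shape[0]:
        raise ValueError("gene panels must match")
    base = counts_low.sum(axis=1)
    other = counts_high.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (base - other) / base
    out[base == 0] = np.nan
    return out
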