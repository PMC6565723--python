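"""Two-state (telegraph) promoter kinetics.

A gene's promoter switches on with rate ``k_on`` and off with rate ``k_off``;
while on, transcripts are synthesised at rate ``s`` and degrade at rate
``d``.  With ``d`` fixed to 1 (all rates expressed relative to degradation),
the stationary transcript-count distribution is a Beta-Poisson mixture:

    p ~ Beta(k_on, k_off),   count ~ Poisson(s * p)

This module samples that stationary law and implements the knobs layered on
top of it: the ``bimod`` bimodality control (divide ``k_on`` and ``k_off`` by
``10**bimod``, preserving burst frequency ``k_on/(k_on+k_off)`` and mean),
constitutively-on high-expression outlier genes, and a modality diagnostic
that labels a parameter triple as zero-unimodal, nonzero-unimodal or bimodal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "KineticParams",
    "OutlierConfig",
    "beta_poisson_sample",
    "theoretical_mean",
    "theoretical_variance",
    "apply_bimod",
    "apply_high_expression_outliers",
    "classify_modality",
]


@dataclass
class KineticParams:
    """Per-gene (optionally per-cell) kinetic rates relative to d=1.

    Arrays ``k_on``, ``k_off`` and ``s`` share a common shape; for a full
    simulation that shape is ``(n_genes, n_cells)``.  The degradation rate is
    the unit of time and is never a free parameter.
    """

    k_on: np.ndarray
    k_off: np.ndarray
    s: np.ndarray
    d: float = field(default=1.0, init=False)

    def __post_init__(self) -> None:
        self.k_on = np.asarray(self.k_on, dtype=float)
        self.k_off = np.asarray(self.k_off, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if not (self.k_on.shape == self.k_off.shape == self.s.shape):
            raise ValueError("k_on, k_off and s must share one shape")
        for name in ("k_on", "k_off", "s"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                raise ValueError(f"{name} must be strictly positive and finite")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.k_on.shape

    def copy(self) -> "KineticParams":
        return KineticParams(self.k_on.copy(), self.k_off.copy(), self.s.copy())


@dataclass(frozen=True)
class OutlierConfig:
    """High-expression outlier genes: proportion and inflation scale."""

    prop_hge: float = 0.0
    mean_hge: float = 3.0

    def __post_init__(self) -> None:
        if not (0 <= self.prop_hge < 1):
            raise ValueError("prop_hge must be in [0, 1)")
        if self.prop_hge > 0 and self.mean_hge <= 1:
            raise ValueError("mean_hge must be > 1")


def _check_positive(**kwargs) -> None:
    for name, value in kwargs.items():
        arr = np.asarray(value, dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError(f"{name} must be strictly positive and finite")


def beta_poisson_sample(k_on, k_off, s, n_draws: int | None = None,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw stationary transcript counts from the Beta-Poisson mixture.

    Parameters broadcast against each other; if ``n_draws`` is given, that
    many iid draws are made for scalar parameters.
    """
    _check_positive(k_on=k_on, k_off=k_off, s=s)
    if rng is None:
        rng = np.random.default_rng()
    k_on, k_off, s = np.broadcast_arrays(
        np.asarray(k_on, float), np.asarray(k_off, float), np.asarray(s, float)
    )
    size = k_on.shape if n_draws is None else (n_draws,) + k_on.shape
    if n_draws is not None and n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    p = rng.beta(k_on, k_off, size=size)
    return rng.poisson(s * p)


def theoretical_mean(k_on, k_off, s) -> np.ndarray:
    """Expected stationary expression ``s * k_on / (k_on + k_off)``."""
    _check_positive(k_on=k_on, k_off=k_off, s=s)
    k_on = np.asarray(k_on, float)
    k_off = np.asarray(k_off, float)
    return np.asarray(s, float) * k_on / (k_on + k_off)


def theoretical_variance(k_on, k_off, s) -> np.ndarray:
    """Stationary variance of the Beta-Poisson mixture.

    Var = E + s^2 * k_on * k_off / ((k_on+k_off)^2 (k_on+k_off+1)).
    """
    k_on = np.asarray(k_on, float)
    k_off = np.asarray(k_off, float)
    s = np.asarray(s, float)
    mean = theoretical_mean(k_on, k_off, s)
    tot = k_on + k_off
    return mean + s**2 * k_on * k_off / (tot**2 * (tot + 1))


def apply_bimod(params: KineticParams, bimod: float) -> KineticParams:
    """Divide ``k_on`` and ``k_off`` by ``10**bimod`` (``s`` untouched).

    Slower switching at unchanged burst frequency increases the bimodality
    of the stationary distribution while leaving the mean invariant.
    """
    if not (0 <= bimod <= 1):
        raise ValueError("bimod must be in [0, 1]")
    factor = 10.0 ** bimod
    return KineticParams(params.k_on / factor, params.k_off / factor, params.s.copy())


def apply_high_expression_outliers(
    params: KineticParams, config: OutlierConfig, rng: np.random.Generator
) -> tuple[KineticParams, np.ndarray]:
    """Flag a random fraction of genes as constitutively-on outliers.

    Flagged genes get their synthesis rate multiplied by
    ``2 ** (mean_hge - 1 + rank / n)`` where ``rank`` (1..n) orders the
    flagged genes by mean ``s`` (ties broken by gene index), and are meant to
    be sampled as Poisson(s), bypassing the Beta mixing — the caller uses the
    returned mask for that.

    Returns the adjusted parameters and the boolean outlier mask (length
    n_genes).  Parameters of unflagged genes are returned bit-identical.
    """
    if params.k_on.ndim not in (1, 2):
        raise ValueError("expected (n_genes,) or (n_genes, n_cells) parameters")
    n_genes = params.shape[0]
    mask = np.zeros(n_genes, dtype=bool)
    n_out = int(round(config.prop_hge * n_genes))
    out = params.copy()
    if n_out == 0:
        return out, mask
    chosen = rng.choice(n_genes, size=n_out, replace=False)
    mask[chosen] = True
    mean_s = params.s[chosen] if params.s.ndim == 1 else params.s[chosen].mean(axis=1)
    # stable sort: ties among mean s broken by gene index
    order = np.lexsort((chosen, mean_s))
    ranks = np.empty(n_out, dtype=float)
    ranks[order] = np.arange(1, n_out + 1)
    factors = 2.0 ** (config.mean_hge - 1 + ranks / n_out)
    if out.s.ndim == 1:
        out.s[chosen] *= factors
    else:
        out.s[chosen] *= factors[:, None]
    return out, mask


def classify_modality(k_on: float, k_off: float, s: float,
                      n_draws: int = 10_000, seed: int = 0) -> str:
    """Label the stationary count distribution of one parameter triple.

    A large sample is drawn with a fixed sub-seed, histogrammed on the
    integer grid and smoothed with a Gaussian kernel (deterministic
    bandwidth rule: sigma = max(1, range/30) bins).  Modes of the smoothed
    density determine the label:

    * a mode at zero only            -> ``"zero-unimodal"``
    * an interior mode only          -> ``"nonzero-unimodal"``
    * a zero mode and interior mode  -> ``"bimodal"``
    """
    _check_positive(k_on=k_on, k_off=k_off, s=s)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6D6F6465]))
    draws = beta_poisson_sample(k_on, k_off, s, n_draws=n_draws, rng=rng)
    hi = int(draws.max())
    hist = np.bincount(draws, minlength=hi + 2).astype(float)
    sigma = max(1.0, (hi + 1) / 30.0)
    dens = gaussian_filter1d(hist, sigma=sigma, mode="constant")
    # local maxima, treating the left boundary as a candidate zero mode
    interior = np.flatnonzero(
        (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    ) + 1
    zero_mode = dens[0] > dens[1]
    has_interior = interior.size > 0
    if zero_mode and has_interior:
        return "bimodal"
    if has_interior:
        return "nonzero-unimodal"
    return "zero-unimodal"
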