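"""Matching simulation parameters to a target count matrix.

The simulator is run over a grid of parameter configurations; for each run
three per-gene summary statistics are kept (mean, percent non-zero and
standard deviation over cells).  A target matrix is then matched to the
grid point whose statistics have the most similar per-gene distributions.
The distance between two datasets is the sum, over the three statistics, of
the mean absolute difference between 100 evenly spaced quantiles of their
per-gene distributions — scale-robust and indifferent to gene count.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import substream
from .config import SimulationConfig
from .expression import simulate_true_counts
from .libprep import true2observed

logger = logging.getLogger(__name__)

__all__ = [
    "SummaryStats",
    "SimGridDatabase",
    "summary_stats",
    "quantile_distance",
    "build_database",
    "best_match",
]

N_QUANTILES = 100


@dataclass
class SummaryStats:
    """Per-gene mean, percent non-zero (0-100) and sample SD over cells."""

    mean: np.ndarray
    pct_nonzero: np.ndarray
    sd: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mean": self.mean, "pct_nonzero": self.pct_nonzero, "sd": self.sd})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SummaryStats":
        return cls(df["mean"].to_numpy(), df["pct_nonzero"].to_numpy(),
                   df["sd"].to_numpy())


@dataclass
class SimGridDatabase:
    """Parameter configurations paired with their simulated statistics."""

    entries: list[tuple[dict, SummaryStats]]

    def __len__(self) -> int:
        return len(self.entries)


def summary_stats(counts: np.ndarray) -> SummaryStats:
    """Compute the three per-gene summary vectors of a count matrix."""
    counts = np.asarray(counts, float)
    if counts.size == 0:
        raise ValueError("empty count matrix")
    n_cells = counts.shape[1]
    mean = counts.mean(axis=1)
    pct = 100.0 * np.count_nonzero(counts, axis=1) / n_cells
    sd = counts.std(axis=1, ddof=1) if n_cells > 1 else np.zeros_like(mean)
    return SummaryStats(mean, pct, sd)


def _qvec(values: np.ndarray) -> np.ndarray:
    return np.quantile(values, np.linspace(0, 1, N_QUANTILES))


def quantile_distance(a: SummaryStats, b: SummaryStats) -> float:
    """Sum over statistics of mean |quantile difference| (a metric on
    summary distributions: zero iff the quantile profiles coincide)."""
    total = 0.0
    for attr in ("mean", "pct_nonzero", "sd"):
        total += float(np.mean(np.abs(
            _qvec(getattr(a, attr)) - _qvec(getattr(b, attr)))))
    return total


def simulate_stats(config: SimulationConfig, seed: int,
                   gene_lengths: np.ndarray, tree=None,
                   reference=None) -> SummaryStats:
    """One simulation (true counts + technical pipeline) -> summary stats."""
    true = simulate_true_counts(config, tree=tree, reference=reference,
                                rng=substream(seed, "true_counts"))
    observed = true2observed(true.counts, config.tech_params(), gene_lengths,
                             substream(seed, "libprep"))
    return summary_stats(observed.counts)


def _grid_points(grid: dict[str, list]) -> list[dict]:
    keys = list(grid)
    points = [{}]
    for key in keys:
        points = [dict(p, **{key: v}) for p in points for v in grid[key]]
    return points


def build_database(
    grid: dict[str, list],
    base_config: SimulationConfig,
    gene_lengths: np.ndarray,
    seed: int = 0,
    outdir: str | Path | None = None,
    tree=None,
    reference=None,
) -> SimGridDatabase:
    """Simulate every configuration in a parameter grid.

    ``grid`` maps parameter names (fields of SimulationConfig) to value
    lists; the Cartesian product is simulated at fixed ``seed`` so the
    database is reproducible.  With ``outdir`` the entries are persisted
    (JSON configuration + TSV statistics) and existing entries are reused,
    making interrupted builds resumable.  Invalid configurations are
    skipped with a warning.
    """
    if not grid:
        raise ValueError("empty parameter grid")
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    entries: list[tuple[dict, SummaryStats]] = []
    for i, point in enumerate(_grid_points(grid)):
        if outdir is not None:
            cfg_path = outdir / f"entry{i:04d}.json"
            stats_path = outdir / f"entry{i:04d}.tsv"
            if cfg_path.exists() and stats_path.exists():
                entries.append((
                    json.loads(cfg_path.read_text()),
                    SummaryStats.from_frame(pd.read_csv(stats_path, sep="\t")),
                ))
                continue
        try:
            config = SimulationConfig.from_dict({**base_config.to_dict(),
                                                 **point})
        except ValueError as exc:
            logger.warning("skipping invalid grid point %r: %s", point, exc)
            continue
        stats = simulate_stats(config, seed + i, gene_lengths,
                               tree=tree, reference=reference)
        entries.append((point, stats))
        if outdir is not None:
            cfg_path.write_text(json.dumps(point))
            stats.to_frame().to_csv(stats_path, sep="\t", index=False)
    return SimGridDatabase(entries)


def best_match(target: SummaryStats,
               database: SimGridDatabase) -> tuple[dict, float]:
    """Configuration whose statistics are closest to the target's.

    Deterministic: ties resolve to the earliest grid entry.
    """
    if len(database) == 0:
        raise ValueError("empty database")
    best = None
    best_dist = np.inf
    for point, stats in database.entries:
        dist = quantile_distance(target, stats)
        if dist < best_dist:
            best, best_dist = point, dist
    return best, best_dist
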