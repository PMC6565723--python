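"""Library preparation and sequencing: true molecules to observed counts.

The observed count matrix is produced by explicitly simulating the main
experimental steps, per molecule:

1. capture       — each molecule survives with per-cell efficiency
                   alpha_hat ~ N(alpha_mean, alpha_sd) truncated to (0, 1];
2. preamplify    — nPCR1 cycles of PCR in which every existing copy is
                   duplicated with its gene's amplification rate (or, for
                   IVT-based protocols, one round of linear amplification);
3. fragment      — each copy is broken into fragments (count calibrated so
                   the mean fragment length is ``frag_len_mean``); full-length
                   (non-UMI) protocols keep every fragment inside the size-
                   selection window, 3'-tag (UMI) protocols keep at most the
                   3'-end fragment of each copy;
4. amplify_fragments — nPCR2 further PCR cycles on the fragments;
5. sequence      — per-cell read totals ~ N(depth_mean, depth_sd); reads are
                   drawn from the cell's fragment pool without replacement;
6. count         — reads per gene (non-UMI) or distinct original molecules
                   with at least one read (UMI), then optional gene-by-batch
                   multiplicative batch factors.

Per-gene amplification rates carry a transcript-length bias: genes are
binned by length into ``nbins`` rank bins and the bias of bin i is
``lenslope * (median_rank - i)``, bounded by ``MaxAmpBias`` together with a
per-gene random component.  Sequencing errors and read mis-assignment are
not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "TechParams",
    "MoleculePool",
    "FragmentPool",
    "ObservedCountsResult",
    "capture",
    "amplification_rates",
    "preamplify",
    "fragment",
    "fragment_counts_per_copy",
    "amplify_fragments",
    "sequence_and_count",
    "add_batch_effects",
    "true2observed",
]


@dataclass(frozen=True)
class TechParams:
    """Knobs of the library-preparation and sequencing model."""

    protocol: str = "UMI"  # "UMI" or "nonUMI"
    alpha_mean: float = 0.1
    alpha_sd: float = 0.02
    rate_2PCR: float = 0.7
    nPCR1: int = 10
    nPCR2: int = 10
    linear_amp: bool = False
    linear_amp_rounds: int = 12
    lenslope: float = 0.02
    MaxAmpBias: float = 0.2
    nbins: int = 20
    depth_mean: float = 1e5
    depth_sd: float = 3e3
    frag_len_mean: float = 400.0
    frag_size_window: tuple[float, float] = (100.0, 1000.0)
    n_batches: int = 1
    batch_factor_sd: float = 0.3
    sequencing_approx: bool = False  # multinomial approximation of sequencing

    def __post_init__(self) -> None:
        if self.protocol not in ("UMI", "nonUMI"):
            raise ValueError("protocol must be 'UMI' or 'nonUMI'")
        if not (0 < self.alpha_mean <= 1):
            raise ValueError("alpha_mean must be in (0, 1]")
        if not (0 < self.rate_2PCR <= 1):
            raise ValueError("rate_2PCR must be in (0, 1]")
        if (self.lenslope > 0 and self.nbins > 1
                and self.lenslope >= 2 * self.MaxAmpBias / (self.nbins - 1)):
            raise ValueError(
                "length bias too steep: lenslope must be smaller than "
                "2 * MaxAmpBias / (nbins - 1)")
        lo, hi = self.frag_size_window
        if not lo < hi:
            raise ValueError("frag_size_window must satisfy low < high")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")


@dataclass
class MoleculePool:
    """Flat arrays over captured molecules; UMI identity = array position."""

    gene: np.ndarray    # gene index per molecule
    cell: np.ndarray    # cell index per molecule
    copies: np.ndarray  # current copy count per molecule
    gene_lengths: np.ndarray  # length (bp) per gene
    n_genes: int
    n_cells: int

    @property
    def n_molecules(self) -> int:
        return self.gene.size

    def counts_matrix(self) -> np.ndarray:
        """Captured-molecule counts as a genes x cells matrix."""
        out = np.zeros((self.n_genes, self.n_cells), dtype=np.int64)
        np.add.at(out, (self.gene, self.cell), 1)
        return out


@dataclass
class FragmentPool:
    """Retained sequencable fragments, aligned with a MoleculePool."""

    molecules: MoleculePool
    fragments: np.ndarray  # fragment count per molecule


@dataclass
class ObservedCountsResult:
    """Observed (read or UMI) counts plus realised technical covariates."""

    counts: np.ndarray          # genes x cells
    protocol: str
    capture_eff: np.ndarray     # realised alpha_hat per cell
    depths: np.ndarray          # realised reads per cell
    amp_rates: np.ndarray       # per-gene amplification rate
    batch: Optional[np.ndarray] = None  # batch label per cell


def capture(
    true_counts: np.ndarray,
    gene_lengths: np.ndarray,
    alpha_mean: float,
    alpha_sd: float,
    rng: np.random.Generator,
) -> tuple[MoleculePool, np.ndarray]:
    """Binomial thinning of true counts with per-cell capture efficiency."""
    if alpha_mean <= 0:
        raise ValueError("alpha_mean must be > 0")
    true_counts = np.asarray(true_counts)
    n_genes, n_cells = true_counts.shape
    gene_lengths = np.asarray(gene_lengths)
    if gene_lengths.size != n_genes:
        raise ValueError("gene_lengths length must equal n_genes")
    alpha = rng.normal(alpha_mean, alpha_sd, size=n_cells)
    alpha = np.clip(alpha, 1e-6, 1.0)
    captured = rng.binomial(true_counts, alpha[None, :])
    gene_idx, cell_idx = np.nonzero(captured)
    reps = captured[gene_idx, cell_idx]
    pool = MoleculePool(
        gene=np.repeat(gene_idx, reps),
        cell=np.repeat(cell_idx, reps),
        copies=np.ones(int(reps.sum()), dtype=np.int64),
        gene_lengths=gene_lengths,
        n_genes=n_genes,
        n_cells=n_cells,
    )
    return pool, alpha


def amplification_rates(
    gene_lengths: np.ndarray,
    rate_2PCR: float = 0.7,
    lenslope: float = 0.02,
    MaxAmpBias: float = 0.2,
    nbins: int = 20,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-gene PCR amplification probability with length bias.

    Genes are split into ``nbins`` equal-occupancy bins by length rank; the
    systematic bias of bin i (1-based) is ``lenslope * (median_rank - i)``
    (longer transcripts amplify worse for lenslope > 0).  A per-gene random
    bias N(0, MaxRandBias) with ``MaxRandBias = MaxAmpBias - max|B_length|``
    is added and the total rate clamped to [0, 1].
    """
    if lenslope > 0 and nbins > 1 and lenslope >= 2 * MaxAmpBias / (nbins - 1):
        raise ValueError(
            "lenslope must be smaller than 2 * MaxAmpBias / (nbins - 1)")
    rng = np.random.default_rng() if rng is None else rng
    gene_lengths = np.asarray(gene_lengths, float)
    n = gene_lengths.size
    order = np.argsort(gene_lengths, kind="stable")
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    bin_idx = (rank * nbins) // n + 1  # 1..nbins
    median_rank = (nbins + 1) / 2.0
    b_length = lenslope * (median_rank - bin_idx)
    max_rand = MaxAmpBias - np.abs(b_length).max() if n else MaxAmpBias
    b_rand = rng.normal(0.0, max(max_rand, 0.0), size=n)
    return np.clip(rate_2PCR + b_length + b_rand, 0.0, 1.0)


def _pcr_cycles(copies: np.ndarray, rates: np.ndarray, n_cycles: int,
                rng: np.random.Generator) -> np.ndarray:
    out = copies.copy()
    for _ in range(n_cycles):
        out = out + rng.binomial(out, rates)
    return out


def preamplify(
    pool: MoleculePool,
    rates: np.ndarray,
    nPCR1: int,
    rng: np.random.Generator,
    linear_amp: bool = False,
    linear_amp_rounds: int = 12,
) -> MoleculePool:
    """Amplify molecule copies: exponential PCR or one linear IVT round.

    PCR: per cycle, every existing copy is duplicated with probability equal
    to its gene's amplification rate, so after N cycles the expected copy
    number is ``(1 + rate)**N`` per initial copy.  Linear (IVT) mode scales
    each copy to ``round(rate * rounds)`` transcripts without compounding —
    a deterministic-mean approximation.
    """
    rates = np.asarray(rates, float)
    if np.any((rates < 0) | (rates > 1)):
        raise ValueError("amplification rates must lie in [0, 1]")
    per_mol = rates[pool.gene]
    if linear_amp:
        copies = pool.copies * np.maximum(
            1, np.round(per_mol * linear_amp_rounds).astype(np.int64))
    else:
        copies = _pcr_cycles(pool.copies, per_mol, nPCR1, rng)
    return replace(pool, copies=copies)


def fragment_counts_per_copy(
    lengths: np.ndarray,
    frag_len_mean: float = 400.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Fragments per transcript copy, before size selection.

    ``max(1, Poisson(length / frag_len_mean))`` — calibrated so that, over a
    pool of copies with realistic transcript lengths, total length divided
    by total fragment count is the target mean fragment length.
    """
    rng = np.random.default_rng() if rng is None else rng
    lengths = np.asarray(lengths, float)
    return np.maximum(1, rng.poisson(lengths / frag_len_mean))


def _per_copy_retained_pmf(
    length: float,
    protocol: str,
    frag_len_mean: float,
    window: tuple[float, float],
    rng: np.random.Generator,
    n_mc: int = 256,
) -> np.ndarray:
    """Empirical pmf of retained fragments per copy for one gene length.

    Fragments arise from uniform random breakpoints.  Non-UMI keeps every
    fragment inside the size window; UMI keeps the 3'-end fragment only,
    and only if it is inside the window.
    """
    lo, hi = window
    n_frag = fragment_counts_per_copy(np.full(n_mc, length), frag_len_mean, rng)
    retained = np.zeros(n_mc, dtype=int)
    for i, k in enumerate(n_frag):
        if k == 1:
            sizes = np.array([length])
        else:
            cuts = np.sort(rng.uniform(0.0, length, size=k - 1))
            sizes = np.diff(np.concatenate([[0.0], cuts, [length]]))
        if protocol == "UMI":
            retained[i] = int(lo <= sizes[-1] <= hi)
        else:
            retained[i] = int(np.count_nonzero((sizes >= lo) & (sizes <= hi)))
    return np.bincount(retained) / n_mc


def _sum_iid_discrete(copies: np.ndarray, pmf: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Sum of ``copies[i]`` iid draws from ``pmf`` for each molecule i.

    Sampled exactly via the multinomial decomposition: the number of copies
    landing on each support value is conditionally binomial.
    """
    total = np.zeros_like(copies)
    remaining = copies.copy()
    prob_left = 1.0
    for k, p in enumerate(pmf):
        if prob_left <= 0:
            break
        frac = min(p / prob_left, 1.0)
        n_k = rng.binomial(remaining, frac)
        total += k * n_k
        remaining -= n_k
        prob_left -= p
    return total


def fragment(
    pool: MoleculePool,
    protocol: str,
    frag_len_mean: float = 400.0,
    frag_size_window: tuple[float, float] = (100.0, 1000.0),
    rng: np.random.Generator | None = None,
) -> FragmentPool:
    """Fragment every copy of every molecule; apply size selection."""
    rng = np.random.default_rng() if rng is None else rng
    fragments = np.zeros(pool.n_molecules, dtype=np.int64)
    for g in np.unique(pool.gene):
        idx = np.flatnonzero(pool.gene == g)
        pmf = _per_copy_retained_pmf(
            float(pool.gene_lengths[g]), protocol, frag_len_mean,
            frag_size_window, rng)
        if protocol == "UMI":
            q = pmf[1] if pmf.size > 1 else 0.0
            fragments[idx] = rng.binomial(pool.copies[idx], q)
        else:
            fragments[idx] = _sum_iid_discrete(pool.copies[idx], pmf, rng)
    return FragmentPool(molecules=pool, fragments=fragments)


def amplify_fragments(
    frag_pool: FragmentPool,
    rates: np.ndarray,
    nPCR2: int,
    rng: np.random.Generator,
) -> FragmentPool:
    """nPCR2 further PCR cycles applied to the fragment pool."""
    rates = np.asarray(rates, float)
    if np.any((rates < 0) | (rates > 1)):
        raise ValueError("amplification rates must lie in [0, 1]")
    per_mol = rates[frag_pool.molecules.gene]
    fragments = _pcr_cycles(frag_pool.fragments, per_mol, nPCR2, rng)
    return FragmentPool(molecules=frag_pool.molecules, fragments=fragments)


def sequence_and_count(
    frag_pool: FragmentPool,
    depth_mean: float,
    depth_sd: float,
    protocol: str,
    rng: np.random.Generator,
    capture_eff: np.ndarray | None = None,
    amp_rates: np.ndarray | None = None,
    approx: bool = False,
) -> ObservedCountsResult:
    """Sample reads per cell and collapse to read or UMI counts.

    Per-cell read totals are N(depth_mean, depth_sd) truncated at zero and
    rounded.  Reads are physical fragments, drawn without replacement
    (multivariate hypergeometric over the cell's per-molecule fragment
    pool); with ``approx=True`` a multinomial draw is used instead.  Non-UMI
    counts are reads per gene; UMI counts are the number of distinct
    original molecules with at least one read.
    """
    if depth_mean <= 0:
        raise ValueError("depth_mean must be > 0")
    pool = frag_pool.molecules
    counts = np.zeros((pool.n_genes, pool.n_cells), dtype=np.int64)
    depths = np.maximum(0, np.round(
        rng.normal(depth_mean, depth_sd, size=pool.n_cells))).astype(np.int64)
    order = np.argsort(pool.cell, kind="stable")
    cell_sorted = pool.cell[order]
    bounds = np.searchsorted(cell_sorted, np.arange(pool.n_cells + 1))
    realised = np.zeros(pool.n_cells, dtype=np.int64)
    for c in range(pool.n_cells):
        sel = order[bounds[c]:bounds[c + 1]]
        if sel.size == 0:
            continue
        frags = frag_pool.fragments[sel]
        total = int(frags.sum())
        n_reads = int(min(depths[c], total))
        realised[c] = n_reads
        if n_reads == 0 or total == 0:
            continue
        if n_reads == total:
            reads = frags
        elif approx or total >= 1_000_000_000:
            # multinomial approximation; exact hypergeometric sampling is
            # infeasible for pools this large, where the sampling fraction
            # is tiny and the two laws coincide anyway
            reads = rng.multinomial(n_reads, frags / total)
        else:
            reads = rng.multivariate_hypergeometric(
                frags, n_reads, method="marginals")
        genes = pool.gene[sel]
        if protocol == "UMI":
            np.add.at(counts, (genes[reads > 0], c), 1)
        else:
            np.add.at(counts, (genes, c), reads)
    return ObservedCountsResult(
        counts=counts, protocol=protocol,
        capture_eff=(np.full(pool.n_cells, np.nan)
                     if capture_eff is None else capture_eff),
        depths=realised,
        amp_rates=(np.full(pool.n_genes, np.nan)
                   if amp_rates is None else amp_rates))


def add_batch_effects(
    observed: ObservedCountsResult,
    n_batches: int,
    batch_factor_sd: float,
    rng: np.random.Generator,
) -> ObservedCountsResult:
    """Multiply counts by gene- and batch-specific factors 2**N(0, sd)."""
    if n_batches < 1:
        raise ValueError("n_batches must be >= 1")
    n_genes, n_cells = observed.counts.shape
    batch = rng.permuted(np.arange(n_cells) % n_batches)
    if n_batches == 1 or batch_factor_sd == 0:
        return replace(observed, batch=batch)
    factors = 2.0 ** rng.normal(0.0, batch_factor_sd, size=(n_genes, n_batches))
    counts = np.round(observed.counts * factors[:, batch]).astype(np.int64)
    return replace(observed, counts=counts, batch=batch)


def true2observed(
    true_counts: np.ndarray,
    tech: TechParams,
    gene_lengths: np.ndarray,
    rng: np.random.Generator,
) -> ObservedCountsResult:
    """Full technical pipeline from true counts to observed counts."""
    pool, alpha = capture(true_counts, gene_lengths,
                          tech.alpha_mean, tech.alpha_sd, rng)
    rates = amplification_rates(gene_lengths, tech.rate_2PCR, tech.lenslope,
                                tech.MaxAmpBias, tech.nbins, rng)
    pool = preamplify(pool, rates, tech.nPCR1, rng,
                      linear_amp=tech.linear_amp,
                      linear_amp_rounds=tech.linear_amp_rounds)
    frags = fragment(pool, tech.protocol, tech.frag_len_mean,
                     tech.frag_size_window, rng)
    frags = amplify_fragments(frags, rates, tech.nPCR2, rng)
    observed = sequence_and_count(
        frags, tech.depth_mean, tech.depth_sd, tech.protocol, rng,
        capture_eff=alpha, amp_rates=rates, approx=tech.sequencing_approx)
    return add_batch_effects(observed, tech.n_batches,
                             tech.batch_factor_sd, rng)
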