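"""Cell-state manifolds: tree-structured extrinsic variability factors.

Each cell carries three low-dimensional EVF vectors (one per kinetic
parameter).  Most EVF coordinates are drawn iid N(1, sigma) for every cell;
a designated subset (the Diff-EVFs) instead has an expected value that
varies over a user-supplied tree of cell states, obtained by Brownian motion
from the root (value 1) with per-branch step variance equal to the branch
length.  The expected absolute difference between the Diff-EVF values of two
positions is then proportional to the square root of their tree distance.

Three sampling modes:

* discrete   — cells sit at the leaves; each leaf is one population.
* continuous — cells are spread along the branches (count per branch
  proportional to branch length); sorted positions define pseudotime.
* impulse    — like continuous, but Diff-EVF means along one root-to-tip
  path follow a two-sigmoid impulse curve instead of a Brownian path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

PARAM_NAMES = ("k_on", "k_off", "s")

__all__ = [
    "PARAM_NAMES",
    "CellStateTree",
    "EVFMatrices",
    "ImpulseConfig",
    "parse_tree",
    "brownian_tip_means",
    "sample_evfs_discrete",
    "sample_evfs_continuous",
    "sample_evfs_impulse",
]


@dataclass
class CellStateTree:
    """A rooted tree with non-negative branch lengths and labelled leaves."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        root = self.tree.seed_node
        labels: list[str] = []
        for node in self.tree.preorder_node_iter():
            if node is not root:
                length = node.edge.length
                if length is None:
                    raise ValueError("every branch must carry a length")
                if length < 0:
                    raise ValueError(f"negative branch length: {length}")
            if node.is_leaf():
                if node.taxon is None or not node.taxon.label:
                    raise ValueError("every leaf must be labelled")
                labels.append(str(node.taxon.label))
        if len(set(labels)) != len(labels):
            raise ValueError("leaf labels must be unique")
        self._label_nodes()

    def _label_nodes(self) -> None:
        for i, node in enumerate(self.tree.preorder_node_iter()):
            if node.is_leaf():
                node.sim_id = str(node.taxon.label)
            else:
                node.sim_id = f"node{i}"
            parent = node.parent_node
            node.depth = 0.0 if parent is None else parent.depth + node.edge.length

    @property
    def leaves(self) -> list[str]:
        return [str(l.taxon.label) for l in self.tree.leaf_node_iter()]

    def node(self, sim_id: str) -> dendropy.Node:
        for node in self.tree.preorder_node_iter():
            if node.sim_id == sim_id:
                return node
        raise KeyError(sim_id)

    def distance(self, leaf_a: str, leaf_b: str) -> float:
        """Patristic distance between two leaves."""
        pdm = self.tree.phylogenetic_distance_matrix()
        ta = self.tree.taxon_namespace.get_taxon(leaf_a)
        tb = self.tree.taxon_namespace.get_taxon(leaf_b)
        return pdm.patristic_distance(ta, tb)


@dataclass
class EVFMatrices:
    """Cells x n_evf factor matrices, one per kinetic parameter."""

    evfs: dict[str, np.ndarray]
    diff_mask: np.ndarray
    sigma: float

    @property
    def n_cells(self) -> int:
        return next(iter(self.evfs.values())).shape[0]

    @property
    def n_evf(self) -> int:
        return int(self.diff_mask.size)


@dataclass(frozen=True)
class ImpulseConfig:
    """Two-sigmoid-product impulse: onset/peak/offset levels and timing.

    Times are fractions of the root-to-tip path length; ``slope`` is in
    inverse pseudotime units.  With all three levels equal the curve is
    constant at that level.
    """

    onset_level: float = 1.0
    peak_level: float = 3.0
    offset_level: float = 1.0
    t_on: float = 0.3
    t_off: float = 0.7
    slope: float = 8.0


def parse_tree(newick_text: str) -> CellStateTree:
    """Parse a Newick string (branch lengths required) into a CellStateTree."""
    try:
        tree = dendropy.Tree.get(
            data=newick_text, schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    return CellStateTree(tree)


def _brownian_node_values(tree: CellStateTree, rng: np.random.Generator) -> dict:
    """One Brownian realisation: value at every node, root fixed at 1."""
    values: dict[int, float] = {}
    for node in tree.tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            values[id(node)] = 1.0
        else:
            step = rng.normal(0.0, np.sqrt(node.edge.length))
            values[id(node)] = values[id(parent)] + step
    return values


def brownian_tip_means(tree: CellStateTree, n_diff_evf: int,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Expected Diff-EVF values at the leaves (one Brownian path per EVF).

    Internal-node values are shared by all descendant branches, so sibling
    leaves share their path up to the common ancestor.
    """
    leaves = list(tree.tree.leaf_node_iter())
    out = np.empty((len(leaves), n_diff_evf))
    for j in range(n_diff_evf):
        values = _brownian_node_values(tree, rng)
        out[:, j] = [values[id(l)] for l in leaves]
    return pd.DataFrame(out, index=[str(l.taxon.label) for l in leaves],
                        columns=[f"diff_evf{j}" for j in range(n_diff_evf)])


def _make_diff_mask(n_evf: int, n_diff_evf: int) -> np.ndarray:
    if not (0 <= n_diff_evf <= n_evf):
        raise ValueError("need 0 <= n_diff_evf <= n_evf")
    mask = np.zeros(n_evf, dtype=bool)
    mask[:n_diff_evf] = True
    return mask


def sample_evfs_discrete(
    tree: CellStateTree,
    cells_per_population: int | dict[str, int],
    sigma: float,
    n_evf: int = 20,
    n_diff_evf: int = 4,
    rng: np.random.Generator | None = None,
) -> tuple[EVFMatrices, pd.DataFrame]:
    """Sample EVFs for cells sitting at the leaves of the tree.

    Each kinetic parameter gets an independent EVF matrix and independent
    Brownian tip means for its Diff-EVF columns.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng() if rng is None else rng
    leaves = tree.leaves
    if isinstance(cells_per_population, int):
        counts = {l: cells_per_population for l in leaves}
    else:
        counts = dict(cells_per_population)
        if set(counts) - set(leaves):
            raise ValueError("unknown population label in cells_per_population")
    if any(c < 1 for c in counts.values()):
        raise ValueError("need at least one cell per population")
    pops = np.concatenate([[l] * counts.get(l, 0) for l in leaves])
    n_cells = len(pops)
    mask = _make_diff_mask(n_evf, n_diff_evf)

    evfs: dict[str, np.ndarray] = {}
    for param in PARAM_NAMES:
        tips = brownian_tip_means(tree, n_diff_evf, rng)
        mat = rng.normal(1.0, sigma, size=(n_cells, n_evf))
        mat[:, :n_diff_evf] = (
            tips.loc[pops].to_numpy()
            + rng.normal(0.0, sigma, size=(n_cells, n_diff_evf))
        )
        evfs[param] = mat

    meta = pd.DataFrame({
        "cell_id": [f"cell{i + 1}" for i in range(n_cells)],
        "population": pops,
        "branch": pops,
        "pseudotime": [tree.node(p).depth for p in pops],
        "mode": "discrete",
    })
    return EVFMatrices(evfs, mask, sigma), meta


def _place_cells(tree: CellStateTree, n_cells: int, rng: np.random.Generator):
    """Multinomial allocation of cells to branches (prob ~ branch length),
    uniform positions within each branch, sorted to define pseudotime."""
    edges = [n for n in tree.tree.preorder_node_iter() if n.parent_node is not None]
    lengths = np.array([e.edge.length for e in edges], dtype=float)
    if lengths.sum() <= 0:
        raise ValueError("tree has no positive-length branches")
    alloc = rng.multinomial(n_cells, lengths / lengths.sum())
    placements = []  # (edge_node, position_along_edge)
    for node, k in zip(edges, alloc):
        if k == 0:
            continue
        pos = np.sort(rng.uniform(0.0, node.edge.length, size=k))
        for p in pos:
            placements.append((node, p))
    return placements


def sample_evfs_continuous(
    tree: CellStateTree,
    n_cells: int,
    sigma: float,
    n_evf: int = 20,
    n_diff_evf: int = 4,
    rng: np.random.Generator | None = None,
) -> tuple[EVFMatrices, pd.DataFrame]:
    """Sample EVFs for cells spread along the branches of the tree.

    Diff-EVF means follow a Brownian path evaluated at each cell's position:
    within a branch, consecutive cells take Gaussian steps with variance
    equal to the gap between their positions.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    mask = _make_diff_mask(n_evf, n_diff_evf)
    placements = _place_cells(tree, n_cells, rng)

    # cell indices grouped by the edge (child node) they sit on
    by_edge: dict[int, list[int]] = {}
    for i, (node, _) in enumerate(placements):
        by_edge.setdefault(id(node), []).append(i)

    evfs: dict[str, np.ndarray] = {}
    for param in PARAM_NAMES:
        mat = rng.normal(1.0, sigma, size=(n_cells, n_evf))
        for j in range(n_diff_evf):
            # one Brownian realisation per Diff-EVF: walk the tree in
            # preorder, sampling the path at the cell positions on each edge
            # and letting the child-node value continue from the path's end,
            # so descendant branches share their ancestor's history
            node_vals: dict[int, float] = {}
            means = np.empty(n_cells)
            for node in tree.tree.preorder_node_iter():
                if node.parent_node is None:
                    node_vals[id(node)] = 1.0
                    continue
                value = node_vals[id(node.parent_node)]
                t = 0.0
                for i in by_edge.get(id(node), ()):
                    pos = placements[i][1]
                    value += rng.normal(0.0, np.sqrt(max(pos - t, 0.0)))
                    means[i] = value
                    t = pos
                value += rng.normal(0.0, np.sqrt(max(node.edge.length - t, 0.0)))
                node_vals[id(node)] = value
            mat[:, j] = means + rng.normal(0.0, sigma, size=n_cells)
        evfs[param] = mat

    meta = pd.DataFrame({
        "cell_id": [f"cell{i + 1}" for i in range(n_cells)],
        "population": [node.sim_id for node, _ in placements],
        "branch": [node.sim_id for node, _ in placements],
        "pseudotime": [node.parent_node.depth + p for node, p in placements],
        "mode": "continuous",
    })
    return EVFMatrices(evfs, mask, sigma), meta


def _impulse(t: np.ndarray, cfg: ImpulseConfig, depth: float) -> np.ndarray:
    """Two-sigmoid-product impulse evaluated at pseudotime ``t``."""
    t_on = cfg.t_on * depth
    t_off = cfg.t_off * depth
    h0, h1, h2, b = cfg.onset_level, cfg.peak_level, cfg.offset_level, cfg.slope
    sig_on = 1.0 / (1.0 + np.exp(-b * (t - t_on)))
    sig_off = 1.0 / (1.0 + np.exp(b * (t - t_off)))
    return (h0 + (h1 - h0) * sig_on) * (h2 + (h1 - h2) * sig_off) / h1


def sample_evfs_impulse(
    tree: CellStateTree,
    n_cells: int,
    sigma: float,
    impulse: ImpulseConfig | None = None,
    n_evf: int = 20,
    n_diff_evf: int = 4,
    rng: np.random.Generator | None = None,
) -> tuple[EVFMatrices, pd.DataFrame]:
    """Continuous-mode sampling with impulse-shaped Diff-EVF means.

    Each Diff-EVF is assigned one root-to-tip path (tips cycled in order);
    cells on that path take the impulse value at their pseudotime, cells off
    the path take the impulse value at the deepest node their lineage shares
    with the path (their most recent common ancestor with it).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng() if rng is None else rng
    impulse = ImpulseConfig() if impulse is None else impulse
    mask = _make_diff_mask(n_evf, n_diff_evf)
    placements = _place_cells(tree, n_cells, rng)
    leaves = list(tree.tree.leaf_node_iter())
    pseudotime = np.array([n.parent_node.depth + p for n, p in placements])

    def path_nodes(tip):
        nodes = []
        node = tip
        while node is not None:
            nodes.append(node)
            node = node.parent_node
        return set(id(n) for n in nodes)

    evfs: dict[str, np.ndarray] = {}
    for param in PARAM_NAMES:
        mat = rng.normal(1.0, sigma, size=(n_cells, n_evf))
        for j in range(n_diff_evf):
            tip = leaves[j % len(leaves)]
            on_path = path_nodes(tip)
            depth = tip.depth
            means = np.empty(n_cells)
            for i, (node, pos) in enumerate(placements):
                if id(node) in on_path:
                    means[i] = _impulse(np.array([pseudotime[i]]), impulse, depth)[0]
                else:
                    anc = node.parent_node
                    while id(anc) not in on_path:
                        anc = anc.parent_node
                    means[i] = _impulse(np.array([anc.depth]), impulse, depth)[0]
            mat[:, j] = means + rng.normal(0.0, sigma, size=n_cells)
        evfs[param] = mat

    meta = pd.DataFrame({
        "cell_id": [f"cell{i + 1}" for i in range(n_cells)],
        "population": [node.sim_id for node, _ in placements],
        "branch": [node.sim_id for node, _ in placements],
        "pseudotime": pseudotime,
        "mode": "impulse",
    })
    return EVFMatrices(evfs, mask, sigma), meta
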