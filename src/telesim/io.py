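"""File formats and packaged fixtures.

Counts travel as Matrix Market (sparse, 1-based indices) or dense TSV, with
TSV sidecars for cell and gene metadata.  The packaged fixtures — a 5-leaf
example tree, a gene-length table and reference kinetic-parameter samples —
are synthetic stand-ins that load offline.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .expression import ReferenceParamDistributions
from .manifold import CellStateTree, parse_tree

__all__ = [
    "load_example_tree",
    "load_tree",
    "load_gene_lengths",
    "load_reference_params",
    "write_counts",
    "read_counts",
]


def _data_path(name: str):
    return resources.files("telesim.data").joinpath(name)


def load_example_tree() -> CellStateTree:
    """The packaged 5-population example tree (populations 2 and 4 are
    siblings, population 1 is an outgroup).  Branch lengths are
    illustrative, in squared-EVF-value units."""
    return parse_tree(_data_path("example_tree.nwk").read_text())


def load_tree(path: str | Path) -> CellStateTree:
    return parse_tree(Path(path).read_text())


def load_gene_lengths(path: str | Path | None = None) -> pd.DataFrame:
    """Gene-length table (gene_id, length_bp); packaged synthetic default."""
    if path is None:
        with resources.as_file(_data_path("gene_lengths.tsv")) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "length_bp"} <= set(df.columns):
        raise ValueError("gene-length table needs columns gene_id, length_bp")
    if (df["length_bp"] <= 0).any():
        raise ValueError("gene lengths must be positive")
    return df


def load_reference_params(path: str | Path | None = None) -> ReferenceParamDistributions:
    """Reference kinetic-parameter samples; packaged synthetic default."""
    if path is None:
        with resources.as_file(_data_path("reference_params.tsv")) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return ReferenceParamDistributions.from_frame(df)


def sample_gene_lengths(n_genes: int, rng: np.random.Generator,
                        path: str | Path | None = None) -> np.ndarray:
    """Draw ``n_genes`` transcript lengths from a gene-length table."""
    table = load_gene_lengths(path)["length_bp"].to_numpy()
    if n_genes <= table.size:
        return rng.choice(table, size=n_genes, replace=False)
    return rng.choice(table, size=n_genes, replace=True)


def write_counts(
    matrix: np.ndarray,
    cell_meta: pd.DataFrame,
    gene_meta: pd.DataFrame,
    outdir: str | Path,
    prefix: str = "counts",
    fmt: str = "mtx",
) -> dict[str, Path]:
    """Write a counts matrix plus sidecar metadata tables.

    ``fmt='mtx'`` writes sparse Matrix Market; ``fmt='tsv'`` writes a dense
    table with gene ids as the index and cell ids as columns.  Integer
    counts round-trip losslessly either way.
    """
    matrix = np.asarray(matrix)
    n_genes, n_cells = matrix.shape
    if len(cell_meta) != n_cells:
        raise ValueError("cell_meta rows must equal n_cells")
    if len(gene_meta) != n_genes:
        raise ValueError("gene_meta rows must equal n_genes")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if fmt == "mtx":
        paths["counts"] = outdir / f"{prefix}.mtx"
        spio.mmwrite(paths["counts"], sparse.coo_matrix(matrix), field="integer")
    elif fmt == "tsv":
        paths["counts"] = outdir / f"{prefix}.tsv"
        pd.DataFrame(
            matrix,
            index=gene_meta.iloc[:, 0].astype(str),
            columns=cell_meta.iloc[:, 0].astype(str),
        ).to_csv(paths["counts"], sep="\t")
    else:
        raise ValueError("fmt must be 'mtx' or 'tsv'")
    paths["cells"] = outdir / f"{prefix}_cells.tsv"
    cell_meta.to_csv(paths["cells"], sep="\t", index=False)
    paths["genes"] = outdir / f"{prefix}_genes.tsv"
    gene_meta.to_csv(paths["genes"], sep="\t", index=False)
    return paths


def read_counts(path: str | Path) -> np.ndarray:
    """Read a counts matrix from Matrix Market or dense TSV."""
    path = Path(path)
    if path.suffix == ".mtx":
        return np.asarray(spio.mmread(path).todense())
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy()
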