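"""Regenerate the synthetic data fixtures packaged under ``telesim/data``.

All three fixtures are synthetic stand-ins:

* ``example_tree.nwk`` — an illustrative 5-population cell-state tree in which
  populations 2 and 4 are siblings and population 1 is an outgroup.
* ``gene_lengths.tsv`` — log-normal transcript lengths with a realistic median
  (~1.6 kb) and range, NOT taken from any reference genome.
* ``reference_params.tsv`` — log-normal samples of (k_on, k_off, s) spanning
  the ranges reported for mammalian transcriptional kinetics in the
  literature; NOT inferred from any real dataset.

Run from the repository root: ``python scripts/generate_fixtures.py``
"""

from pathlib import Path

import numpy as np

OUT = Path(__file__).resolve().parents[1] / "src" / "telesim" / "data"

TREE = "(((2:1.0,4:1.0):1.0,(3:1.5,5:1.5):0.5):0.5,1:3.0);\n"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "example_tree.nwk").write_text(TREE)

    rng = np.random.default_rng(20240517)

    # Transcript lengths: log-normal, clipped to a plausible mRNA range.
    n_genes = 2500
    lengths = np.exp(rng.normal(7.4, 0.7, n_genes))
    lengths = np.clip(lengths, 200, 20000).round().astype(int)
    with open(OUT / "gene_lengths.tsv", "w") as fh:
        fh.write("gene_id\tlength_bp\n")
        for i, l in enumerate(lengths):
            fh.write(f"gene{i + 1}\t{l}\n")

    # Reference kinetic-parameter samples (relative to degradation rate d=1).
    n = 1200
    k_on = 10 ** rng.normal(-0.3, 0.5, n)
    k_off = 10 ** rng.normal(0.2, 0.5, n)
    s = 10 ** rng.normal(1.6, 0.5, n)
    with open(OUT / "reference_params.tsv", "w") as fh:
        fh.write("k_on\tk_off\ts\n")
        for a, b, c in zip(k_on, k_off, s):
            fh.write(f"{a:.6g}\t{b:.6g}\t{c:.6g}\n")


if __name__ == "__main__":
    main()
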