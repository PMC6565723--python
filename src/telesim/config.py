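"""Structured simulation configuration with validation and YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

from .libprep import TechParams
from .manifold import ImpulseConfig

__all__ = ["SimulationConfig", "load_config", "save_config"]


@dataclass
class SimulationConfig:
    """Every knob of the simulator, named as a practitioner would set them.

    ``n_cells`` is the total cell count; in discrete mode it is split as
    evenly as possible over the tree's leaves unless ``pop_sizes`` gives an
    explicit per-population allocation.
    """

    # true-count knobs
    n_genes: int = 500
    n_cells: int = 300
    mode: str = "discrete"  # discrete | continuous | impulse
    sigma: float = 0.5
    n_evf: int = 20
    n_diff_evf: int = 4
    eta: float = 0.7
    gene_effects_sd: float = 1.0
    bimod: float = 0.0
    scale_s: float = 1.0
    prop_hge: float = 0.015
    mean_hge: float = 5.0
    pop_sizes: Optional[dict] = None
    # technical knobs
    protocol: str = "UMI"
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
    n_batches: int = 1
    batch_factor_sd: float = 0.3
    sequencing_approx: bool = False
    # impulse-mode shape
    impulse: ImpulseConfig = field(default_factory=ImpulseConfig)
    # plumbing
    seed: int = 0
    tree_path: Optional[str] = None
    gene_lengths_path: Optional[str] = None
    reference_path: Optional[str] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        checks = [
            ("n_genes", self.n_genes >= 1, ">= 1"),
            ("n_cells", self.n_cells >= 1, ">= 1"),
            ("mode", self.mode in ("discrete", "continuous", "impulse"),
             "one of discrete/continuous/impulse"),
            ("sigma", self.sigma >= 0, ">= 0"),
            ("n_evf", self.n_evf >= 1, ">= 1"),
            ("n_diff_evf", 0 <= self.n_diff_evf <= self.n_evf,
             "in [0, n_evf]"),
            ("eta", 0 <= self.eta <= 1, "in [0, 1]"),
            ("gene_effects_sd", self.gene_effects_sd > 0, "> 0"),
            ("bimod", 0 <= self.bimod <= 1, "in [0, 1]"),
            ("scale_s", self.scale_s > 0, "> 0"),
            ("prop_hge", 0 <= self.prop_hge < 1, "in [0, 1)"),
            ("mean_hge", self.prop_hge == 0 or self.mean_hge > 1,
             "> 1 when prop_hge > 0"),
            ("nPCR1", self.nPCR1 >= 0, ">= 0"),
            ("nPCR2", self.nPCR2 >= 0, ">= 0"),
            ("depth_sd", self.depth_sd >= 0, ">= 0"),
        ]
        for name, ok, valid in checks:
            if not ok:
                raise ValueError(f"invalid {name}: must be {valid}")
        # delegate the technical-parameter constraints
        self.tech_params()

    def tech_params(self) -> TechParams:
        return TechParams(
            protocol=self.protocol, alpha_mean=self.alpha_mean,
            alpha_sd=self.alpha_sd, rate_2PCR=self.rate_2PCR,
            nPCR1=self.nPCR1, nPCR2=self.nPCR2, linear_amp=self.linear_amp,
            linear_amp_rounds=self.linear_amp_rounds, lenslope=self.lenslope,
            MaxAmpBias=self.MaxAmpBias, nbins=self.nbins,
            depth_mean=self.depth_mean, depth_sd=self.depth_sd,
            n_batches=self.n_batches, batch_factor_sd=self.batch_factor_sd,
            sequencing_approx=self.sequencing_approx)

    def cells_per_population(self, tree) -> dict[str, int]:
        leaves = tree.leaves
        if self.pop_sizes is not None:
            sizes = {str(k): int(v) for k, v in self.pop_sizes.items()}
            if set(sizes) - set(leaves):
                raise ValueError("pop_sizes names unknown populations")
            return sizes
        base, extra = divmod(self.n_cells, len(leaves))
        return {l: base + (1 if i < extra else 0)
                for i, l in enumerate(leaves)}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["impulse"] = asdict(self.impulse)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data or {})
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "impulse" in data and isinstance(data["impulse"], dict):
            data["impulse"] = ImpulseConfig(**data["impulse"])
        return cls(**data)


def load_config(path: str | Path) -> SimulationConfig:
    """Load a YAML config file; missing keys take their defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return SimulationConfig.from_dict(data or {})


def save_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
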