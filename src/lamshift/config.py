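"""Pipeline configuration: every threshold and generator parameter with its
default, serializable to/from YAML with unknown keys rejected."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # analysis thresholds
    window_bp: int = 100_000
    step_bp: int = 10_000
    fold_threshold: float = 2.0
    n_iter: int = 1000
    alpha: float = 0.01
    lfc_cut: float = 0.5
    fdr_cut: float = 0.05
    fold_class: float = 1.4
    n_shells: int = 5
    min_lad_bp: int = 100_000
    merge_gap_bp: int = 30_000
    lad_bin_bp: int = 10_000
    min_fragments: int = 10
    pseudocount: float = 1.0
    # synthetic-data generator
    seed: int = 0
    n_chrom: int = 5
    chrom_length: int = 20_000_000
    n_lads: int = 60
    shared_fraction: float = 0.94
    n_ip: int = 20
    n_pi: int = 20
    shift_size_min: int = 300_000
    shift_size_max: int = 600_000
    n_genes: int = 2_000
    depth: float = 5.0
    dispersion: float = 0.1
    lad_mu: float = 0.8
    interlad_mu: float = -0.8
    ratio_sd: float = 0.3
    shift_delta: float = 1.2
    concordance: float = 0.70
    noise_sd: float = 0.25
    n_replicates: int = 3
    n_cells: int = 30

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def to_dict(self) -> dict:
        return asdict(self)

    def sim_params(self, seed: int | None = None):
        from .synthetic import SimParams

        return SimParams(
            seed=self.seed if seed is None else seed,
            depth=self.depth,
            dispersion=self.dispersion,
            lad_mu=self.lad_mu,
            interlad_mu=self.interlad_mu,
            ratio_sd=self.ratio_sd,
            shift_delta=self.shift_delta,
            concordance=self.concordance,
            noise_sd=self.noise_sd,
            n_replicates=self.n_replicates,
        )
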