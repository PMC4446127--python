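"""Pipeline configuration: every analysis constant in one place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .synthetic import SimulationConfig


@dataclass
class PipelineConfig:
    """All tunable constants of the analysis, with their standard defaults."""

    activity_distance: int = 10          # bp, same-strand cluster -> active
    bidirectional_distance: int = 1000   # bp, opposite-strand evidence
    cluster_cap: int = 29857             # max CAGE clusters retained
    read_extension: int = 147            # bp, nucleosome-length extension
    flank: int = 1000                    # bp, footprint half-window
    n_bootstrap: int = 100
    n_segments: int = 13
    fold_thresholds: tuple = (5, 10, 20, 50, 100, 200)
    alpha: float = 0.05
    q_threshold: float = 0.05
    smooth_halfwidth: int = 20           # bp, motif-coverage smoothing
    motif_site_distance: int = 100       # bp, motif-to-site tolerance
    min_ctcf_reads: int = 100
    cluster_bin_bp: int = 25
    k: int = 2
    n_restarts: int = 10
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    @property
    def bonferroni_m(self) -> int:
        return self.n_segments * len(self.fold_thresholds)

    def stage_seed(self, stage: str) -> int:
        """A stable per-stage seed derived from the base seed (< 2^31)."""
        offsets = {"simulate": 0, "footprint": 1, "bins": 2, "peaks": 3,
                   "motif": 4, "cluster": 5}
        return (self.seed * 1000 + offsets[stage]) % (2 ** 31)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["fold_thresholds"] = list(self.fold_thresholds)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim = d.pop("simulation", None)
        cfg = cls(**{k: v for k, v in d.items()})
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        if isinstance(cfg.fold_thresholds, list):
            cfg.fold_thresholds = tuple(cfg.fold_thresholds)
        if "seed" in d:
            cfg.simulation.seed = cfg.simulation.seed or cfg.seed
        return cfg
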