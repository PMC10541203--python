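"""Run configuration: every pipeline threshold in one validated object.

Configs are JSON (YAML also accepted when PyYAML is available).  Unknown
keys are rejected rather than ignored, so a typo in a threshold name fails
loudly instead of silently running with defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .containers import ConfigurationError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All pipeline stage toggles, thresholds and paths."""

    # paths
    counts_dir: str = ""
    reference_dir: str = ""
    reference_labels: str = ""
    out_dir: str = "results/run"
    # stage toggles
    do_qc: bool = True
    do_doublets: bool = True
    do_cluster: bool = True
    do_annotate: bool = False
    # QC thresholds
    min_genes: int = 600
    min_cells: int = 5
    doublet_cut: float = 0.3
    # embedding
    normalization: str = "pooled"
    n_hvg: int = 2000
    scale_clip: float = 10.0
    pc_min: int = 15
    pc_max: int = 30
    # clustering
    knn_k: int = 20
    resolution_start: float = 0.2
    resolution_step: float = 0.2
    max_resolution: float = 3.0
    # annotation / conservation / DE
    vote_k: int = 15
    conserve_threshold: float = 0.8
    de_alpha: float = 0.05
    neuronal_whitelist: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_genes <= 0 or self.min_cells <= 0:
            raise ConfigurationError("retention thresholds must be positive")
        if not 0 < self.doublet_cut < 1:
            raise ConfigurationError("doublet_cut must be in (0, 1)")
        if not 0 < self.resolution_step:
            raise ConfigurationError("resolution_step must be > 0")
        if self.vote_k < 1:
            raise ConfigurationError("vote_k must be >= 1")
        if not 0.5 < self.conserve_threshold <= 1:
            raise ConfigurationError("conserve_threshold must be in (0.5, 1]")
        if not 0 < self.de_alpha < 1:
            raise ConfigurationError("de_alpha must be in (0, 1)")
        if not 0 < self.pc_min <= self.pc_max:
            raise ConfigurationError("need 0 < pc_min <= pc_max")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(
                f"unknown config keys: {sorted(unknown)} (known: {sorted(known)})"
            )
        cfg = cls(**data)
        if cfg.counts_dir and not Path(cfg.counts_dir).exists():
            raise ConfigurationError(f"counts_dir does not exist: {cfg.counts_dir}")
        if cfg.reference_dir and not Path(cfg.reference_dir).exists():
            raise ConfigurationError(
                f"reference_dir does not exist: {cfg.reference_dir}"
            )
        return cfg

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
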