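"""Pipeline configuration: validated thresholds, paths and seeds."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ConfigurationError"]


class ConfigurationError(ValueError):
    """Invalid pipeline configuration; the message names the key."""


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, checked before any stage starts."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    lfc_threshold: float = 0.5
    fdr_threshold: float = 0.05
    min_cells: int = 10
    mu_floor: float = 0.5
    patient_fdr_threshold: float = 0.05
    set_logic_mode: str = "both_contrasts"   # or "one_vs_rest"
    contingency_include_losses: bool = False
    age_bin_edges: tuple = (0.0, 1.0, 20.0)
    module_n_bins: int = 25
    module_n_ctrl: int = 50
    log_level: str = "INFO"
    # synthetic-input knobs forwarded to SimConfig
    sim: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.fdr_threshold <= 1:
            raise ConfigurationError("fdr_threshold must lie in (0, 1]")
        if not 0 < self.patient_fdr_threshold <= 1:
            raise ConfigurationError("patient_fdr_threshold must lie in (0, 1]")
        if self.lfc_threshold < 0:
            raise ConfigurationError("lfc_threshold must be >= 0")
        if self.min_cells < 1:
            raise ConfigurationError("min_cells must be >= 1")
        if self.mu_floor <= 0:
            raise ConfigurationError("mu_floor must be > 0")
        if self.set_logic_mode not in ("both_contrasts", "one_vs_rest"):
            raise ConfigurationError(
                "set_logic_mode must be 'both_contrasts' or 'one_vs_rest'"
            )
        if self.module_n_bins < 1 or self.module_n_ctrl < 1:
            raise ConfigurationError("module_n_bins and module_n_ctrl must be >= 1")
        if list(self.age_bin_edges) != sorted(self.age_bin_edges):
            raise ConfigurationError("age_bin_edges must be sorted")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        if "age_bin_edges" in raw:
            raw["age_bin_edges"] = tuple(raw["age_bin_edges"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_bin_edges"] = list(self.age_bin_edges)
        return d

    @property
    def out(self) -> Path:
        return Path(self.out_dir)
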