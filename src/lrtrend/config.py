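"""Pipeline configuration: thresholds, model settings, paths, seed.

Serializes losslessly to/from YAML so every run can be stamped with the
exact configuration (plus its hash) that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .cohort import CohortConfig
from .errors import ConfigurationError

DEFAULT_BANDS = ((2, 14), (15, 20), (21, 28))


@dataclass
class PipelineConfig:
    """End-to-end settings for the trend-analysis pipeline."""

    # inputs / outputs (unused fields may stay None when driven from Python)
    features_csv: str | None = None
    labels_csv: str | None = None
    transforms_csv: str | None = None
    out_dir: str = "lrt_output"
    region: str = "PTV"

    # stage settings
    norm_bound: float = 3.0
    err_kind: str = "absolute"
    alpha: float = 0.05
    bh_correct: bool = False
    logistic_screen: bool = True
    min_accuracy: float = 0.7
    logistic_C: float = 1.0
    sw_orient: bool = True
    rf_n_trees: int = 500
    rf_max_depth: int | None = None
    regqc_threshold: float = 0.05

    # evaluation design
    bands: tuple[tuple[int, int], ...] = DEFAULT_BANDS
    consistency_cut: float = 0.8
    consistency_window_start: int = 15

    seed: int = 0
    # simulation settings (used when no features_csv is given)
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def validate(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ConfigurationError("alpha must be in (0, 1]")
        if self.norm_bound <= 0:
            raise ConfigurationError("norm_bound must be positive")
        if not 0.0 <= self.min_accuracy <= 1.0:
            raise ConfigurationError("min_accuracy must be in [0, 1]")
        if not 0.0 <= self.consistency_cut <= 1.0:
            raise ConfigurationError("consistency_cut must be in [0, 1]")
        if self.rf_n_trees < 1:
            raise ConfigurationError("rf_n_trees must be >= 1")
        if self.region not in ("GTV", "PTV"):
            raise ConfigurationError("region must be GTV or PTV")
        for lo, hi in self.bands:
            if lo > hi or lo < 2:
                raise ConfigurationError(f"invalid fraction band ({lo}, {hi})")
        self.cohort.validate()

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["bands"] = [list(b) for b in self.bands]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "bands" in d:
            d["bands"] = tuple(tuple(b) for b in d["bands"])
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortConfig(**d["cohort"])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def hash(self) -> str:
        """Stable short hash of the analytic settings (paths excluded)."""
        d = self.to_dict()
        for key in ("features_csv", "labels_csv", "transforms_csv", "out_dir"):
            d.pop(key, None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
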