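"""Run configuration: one serializable object governing every stage.

A :class:`RunConfig` round-trips through a single human-readable YAML or JSON
file; unknown keys are rejected so that typos fail loudly.  A short hash of
the configuration is stamped into every output table for provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, ValidationError

from . import io as _io
from .exceptions import ConfigError

__all__ = ["RunConfig"]


class RunConfig(BaseModel):
    """All tunable stage parameters with their defaults."""

    model_config = ConfigDict(extra="forbid")

    # profile extraction / smoothing
    smoothing_window: int = 5
    row_strategy: Literal["systolic", "variance"] = "systolic"
    # event detection
    polarity: Literal["minima", "maxima"] = "minima"
    prominence_k: float = 4.0
    refractory_s: float = 0.15
    # diameters
    n_diameter_lines: int = 10
    # metric conventions
    hr_strategy: Literal["mean", "count"] = "mean"
    ai_strategy: Literal["sd_over_median", "sd_over_mean", "sd"] = "sd_over_median"
    # Poincare
    ellipse_level: float = 0.99
    area_units: Literal["ms2", "s2"] = "ms2"
    # statistics
    exact_cutoff: int = 16
    zero_method: Literal["wilcox", "pratt"] = "wilcox"
    alpha: float = 0.05
    holm: bool = False
    # run plumbing
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        try:
            return cls(**_io.load_mapping(path))
        except ValidationError as e:
            raise ConfigError(f"invalid configuration {path}: {e}") from e

    def to_file(self, path: str | Path) -> Path:
        return _io.dump_mapping(path, self.model_dump())

    def hash(self) -> str:
        """Short stable digest of the full configuration."""
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def metrics_kwargs(self) -> dict:
        """Keyword arguments for :func:`flyheart.metrics.compute_metrics`."""
        return dict(
            window=self.smoothing_window,
            row_strategy=self.row_strategy,
            polarity=self.polarity,
            prominence_k=self.prominence_k,
            refractory_s=self.refractory_s,
            n_diameter_lines=self.n_diameter_lines,
            hr_strategy=self.hr_strategy,
            ai_strategy=self.ai_strategy,
        )
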