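"""Run configuration: geometry margins, pipeline tolerances, thresholds.

All tunables of the monitoring chain live in one YAML-serialisable object so
that a deployment (or an experiment) is reproducible from a single file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .classifier import ThresholdSet
from .pipeline import (
    DEFAULT_FOREGROUND_THRESHOLD_CM,
    DEFAULT_MOTION_TOLERANCE_CM,
)


@dataclass(frozen=True)
class Config:
    """Complete tunable configuration of the monitoring chain."""

    thresholds: ThresholdSet = field(default_factory=ThresholdSet)
    foreground_threshold_cm: float = DEFAULT_FOREGROUND_THRESHOLD_CM
    motion_tolerance_cm: float = DEFAULT_MOTION_TOLERANCE_CM
    match_window_s: float = 10.0
    noise_sd_cm: float = 1.0
    lying_thickness_cm: float = 25.0
    leave_margin_exit_cm: float = 50.0
    leave_margin_other_cm: float = 50.0
    boundary_margin_cm: float = 50.0
    cbd_pattern_window_s: float = 30.0
    cbd_visitor_presses_mat: bool = True

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["thresholds"] = asdict(self.thresholds)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @staticmethod
    def from_yaml(path: str | Path) -> "Config":
        d = yaml.safe_load(Path(path).read_text()) or {}
        th = d.pop("thresholds", {})
        return Config(thresholds=ThresholdSet(**th), **d)
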