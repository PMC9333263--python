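"""Analysis configuration.

All tunable constants of the pipeline live in :class:`AnalysisConfig` so that
every stage draws its numbers from one place.  Defaults reproduce the
published protocol: 1 kHz acquisition, 70–150 Hz high-gamma filter bank,
−600..−100 ms baseline, 0–500 ms onset and 500–2,000 ms sustained windows,
100 ms / 50 ms sliding decoding windows, and the permutation counts used for
decoding (1,000) and single-channel / encoding inference (10,000).

All windows are half-open ``[start, end)`` in milliseconds relative to
stimulus onset; all sample indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Tuple

import yaml

#: epoch padding after stimulus offset, per task (ms)
POST_OFFSET_MS = {"VL": 1450.0, "NatS": 1000.0}

#: stimulus duration per task (ms)
TASK_DURATION_MS = {"VL": 550.0, "NatS": 2000.0}


@dataclass
class AnalysisConfig:
    # epoching / normalization
    epoch_pre_ms: float = 1000.0
    baseline_window_ms: Tuple[float, float] = (-600.0, -100.0)
    baseline_edge_discard_ms: float = 100.0

    # high-gamma filter bank
    hga_low_hz: float = 70.0
    hga_high_hz: float = 150.0
    n_bands: int = 8
    filter_order: int = 6
    bandwidth_low_hz: float = 16.0
    bandwidth_high_hz: float = 64.0
    hga_output_rate_hz: float = 100.0
    hga_clip_pre_ms: float = 900.0
    hga_clip_post_offset_ms: float = 900.0

    # single-channel windows
    onset_window_ms: Tuple[float, float] = (0.0, 500.0)
    sustained_window_ms: Tuple[float, float] = (500.0, 2000.0)

    # channel selection
    responsiveness_alpha: float = 0.05

    # cluster permutation inference
    n_perm_decoding: int = 1000
    n_perm_single_channel: int = 10000
    cluster_window_alpha: float = 0.05
    cluster_alpha: float = 0.001

    # decoding
    decode_window_width_ms: float = 100.0
    decode_window_step_ms: float = 50.0
    cross_task_max_center_ms: float = 550.0
    n_outer_folds: int = 5
    n_inner_folds: int = 10
    n_lambda: int = 20
    lambda_min_ratio: float = 1e-3

    # encoding
    pca_variance_target: float = 0.9999
    n_perm_encoding: int = 10000

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("responsiveness_alpha", "cluster_window_alpha", "cluster_alpha"):
            a = getattr(self, name)
            if not 0.0 < a < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {a}")
        if self.n_bands < 2:
            raise ValueError("n_bands must be >= 2")
        for lo, hi in (self.baseline_window_ms, self.onset_window_ms, self.sustained_window_ms):
            if lo >= hi:
                raise ValueError(f"window bounds must satisfy start < end, got ({lo}, {hi})")

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["baseline_window_ms"] = list(self.baseline_window_ms)
        data["onset_window_ms"] = list(self.onset_window_ms)
        data["sustained_window_ms"] = list(self.sustained_window_ms)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("baseline_window_ms", "onset_window_ms", "sustained_window_ms"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def epoch_post_ms(self, task: str, duration_ms: float) -> float:
        """Epoch end relative to onset: stimulus offset plus task-specific pad."""
        if task not in POST_OFFSET_MS:
            raise ValueError(f"unknown task {task!r}")
        return duration_ms + POST_OFFSET_MS[task]
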