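"""Shared data containers.

Conventions used package-wide: trial time in milliseconds relative to
color-patch onset (t = 0); bins half-open [a, b); positions in degrees of
visual angle; angles in degrees, mathematical convention, cue-relative
angles wrapped to (-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

#: canonical column order of a detected-microsaccade table
MICROSACCADE_COLUMNS = [
    "session_id", "trial_id", "onset_ms", "offset_ms", "dx_deg", "dy_deg",
    "amplitude_deg", "peak_speed_dps", "direction_deg", "rel_direction_deg",
    "label",
]

TRIAL_COLUMNS = [
    "session_id", "trial_id", "monkey", "block", "trial_type", "cue_dir_deg",
    "cue_in_rf", "patch_in_rf", "change_type", "change_time_ms", "outcome",
    "rt_ms", "t_start_ms", "t_end_ms",
]


def wrap_angle_deg(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to the half-open interval (-180, 180]."""
    wrapped = -((-np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0)
    return wrapped if np.ndim(a) else float(wrapped)


@dataclass
class EyeTrace:
    """Uniformly sampled monocular gaze position for one trial."""

    t_start_ms: float
    fs_hz: float
    x: np.ndarray  # degrees
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.fs_hz

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def times_ms(self) -> np.ndarray:
        return self.t_start_ms + np.arange(self.n) * self.dt_ms

    @property
    def t_end_ms(self) -> float:
        return self.t_start_ms + (self.n - 1) * self.dt_ms


@dataclass
class VelocityTrace:
    """Windowed-derivative eye velocity aligned to its source trace."""

    t_start_ms: float
    fs_hz: float
    vx: np.ndarray  # deg/s
    vy: np.ndarray
    valid: np.ndarray  # False at boundary samples the window cannot cover

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.vx, self.vy)

    @property
    def times_ms(self) -> np.ndarray:
        return self.t_start_ms + np.arange(self.vx.size) * (1000.0 / self.fs_hz)


@dataclass
class GroundTruth:
    """Generative parameters and injected events of one simulated session."""

    events: pd.DataFrame  # trial_id, onset_ms, offset_ms, dx_deg, dy_deg, ...
    unit_params: pd.DataFrame  # unit_id + NeuronModel fields


@dataclass
class SessionData:
    """One session: trials, units, spike times, and eye traces.

    ``spikes[unit_id][trial_id]`` is an array of spike times (ms, patch-
    onset-relative).  ``ground_truth`` is populated by the simulator and
    absent for externally loaded data.
    """

    session_id: str
    monkey: int
    rf_dir_deg: float
    trials: pd.DataFrame
    units: pd.DataFrame  # unit_id (+ model parameters when simulated)
    spikes: dict[str, dict[int, np.ndarray]]
    eye: dict[int, EyeTrace]
    ground_truth: GroundTruth | None = None

    @property
    def unit_ids(self) -> list[str]:
        return list(self.units["unit_id"])

    def trial_span(self, trial_id: int) -> tuple[float, float]:
        row = self.trials.loc[self.trials["trial_id"] == trial_id].iloc[0]
        return float(row["t_start_ms"]), float(row["t_end_ms"])


@dataclass
class BinnedCounts:
    """Per-(unit, trial) spike counts in half-open bins."""

    counts: np.ndarray  # units x trials x bins, nonnegative ints
    unit_ids: list[str]
    trial_ids: list[int]
    bin_edges: np.ndarray  # ms
    alignment: str  # 'patch_onset' | 'microsaccade_onset'

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


@dataclass
class NormalizedRateMatrix:
    """Unit x trial x bin z-scored counts with normalization provenance."""

    z: np.ndarray
    unit_ids: list[str]
    trial_ids: list[int]
    bin_edges: np.ndarray
    alignment: str
    unit_mean: np.ndarray  # per-unit mean count used for z-scoring
    unit_sd: np.ndarray  # per-unit population SD used for z-scoring
    provenance: dict[str, Any] = field(default_factory=dict)

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


@dataclass
class AlignedRates:
    """Event-aligned z-scored rates: one row block per (unit, event).

    ``index`` has one row per aligned event with at least ``unit_id``,
    ``trial_id`` and ``align_ms``; ``z[i]`` is the time course for
    ``index.iloc[i]``.  ``eye_speed`` is the average eye-speed trace over
    the same events (deg/s, one value per bin).
    """

    z: np.ndarray  # n_rows x n_bins
    index: pd.DataFrame
    bin_edges: np.ndarray
    eye_speed: np.ndarray | None = None
    n_dropped: int = 0
    provenance: dict[str, Any] = field(default_factory=dict)

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


@dataclass
class MatchedEventSet:
    """Result of a per-bin minimum-count subsampling control.

    ``selections[condition]`` holds the retained rows (trial_id, align_ms,
    bin); per-bin pre- and post-match counts make the defining invariant --
    equal post counts across conditions in every bin -- checkable at any
    time.  The seed that produced the subsample is recorded.
    """

    kind: str  # 'timing' | 'position'
    spec: dict[str, Any]
    seed: int
    selections: dict[str, pd.DataFrame]
    pre_counts: pd.DataFrame  # index: bin, columns: condition
    post_counts: pd.DataFrame

    def assert_matched(self) -> None:
        post = self.post_counts.to_numpy()
        if post.size and not (post == post[:, [0]]).all():
            raise AssertionError("post-match counts differ across conditions")
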