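"""Configuration dataclasses for the task simulator and analysis pipeline.

All times are milliseconds relative to color-patch onset (t = 0) unless a
field name says otherwise; positions and amplitudes are degrees of visual
angle; angles follow the mathematical convention (0 deg = +x, counter-
clockwise) and cue-relative angles are wrapped to (-180, 180].
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when a configuration field fails validation.

    The message always names the offending field.
    """


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{name}: {msg}")


@dataclass
class TaskConfig:
    """Structure of one covert-attention session.

    A session is a sequence of cued blocks with alternating cue side; each
    block is preceded by single-patch transition trials whose lone patch
    marks the upcoming cued location.  Within cued blocks the saturation
    change occurs at the cued or the foil patch in a fixed ratio, 1-4 s
    after patch onset, and a correct joystick release must fall inside the
    response window.
    """

    n_sessions_per_monkey: int = 5
    blocks_per_session: int = 2
    trials_per_block: int = 70
    single_patch_trials_per_transition: int = 18
    cue_flash_ms: float = 133.0
    cue_to_patch_ms: float = 500.0
    change_window_ms: tuple[float, float] = (1000.0, 4000.0)
    response_window_ms: tuple[float, float] = (150.0, 750.0)
    cue_foil_ratio: tuple[int, int] = (3, 1)
    sample_rate_hz: float = 1000.0
    cue_ecc_deg: float = 8.0
    patch_radius_deg: float = 1.5
    pre_cue_ms: float = 200.0  # recorded fixation time before cue onset

    def validate(self) -> None:
        _require(self.n_sessions_per_monkey >= 1, "n_sessions_per_monkey", "must be >= 1")
        _require(self.blocks_per_session >= 1, "blocks_per_session", "must be >= 1")
        _require(self.trials_per_block >= 1, "trials_per_block", "must be >= 1")
        _require(self.single_patch_trials_per_transition >= 0,
                 "single_patch_trials_per_transition", "must be >= 0")
        for name in ("cue_flash_ms", "cue_to_patch_ms", "pre_cue_ms"):
            _require(getattr(self, name) > 0, name, "must be positive")
        lo, hi = self.change_window_ms
        _require(0 < lo <= hi, "change_window_ms", "must satisfy 0 < lo <= hi")
        rlo, rhi = self.response_window_ms
        _require(0 < rlo < rhi, "response_window_ms", "must satisfy 0 < lo < hi")
        c, f = self.cue_foil_ratio
        _require(int(c) == c and int(f) == f and c > 0 and f > 0,
                 "cue_foil_ratio", "must be a pair of positive integers")
        _require(self.sample_rate_hz >= 500.0, "sample_rate_hz", "must be >= 500 Hz")
        _require(self.cue_ecc_deg > 0, "cue_ecc_deg", "must be positive")

    @property
    def trial_start_ms(self) -> float:
        """Start of the recorded trace relative to patch onset."""
        return -(self.cue_to_patch_ms + self.pre_cue_ms)


@dataclass
class EyeModel:
    """Generative model of fixational eye position.

    The trace is an Ornstein-Uhlenbeck drift (diffusion ``drift_diffusion``
    deg^2/s, reversion toward fixation with time constant
    ``drift_reversion_s``) plus white tremor, with microsaccades injected
    from a piecewise-constant hazard.  The hazard dips to ``dip_rate_hz``
    for ``dip_duration_ms`` after patch onset and then rebounds to
    ``rebound_rate_hz`` before relaxing to the base rate -- the classic
    post-stimulus microsaccadic inhibition and rebound.

    Each microsaccade follows a minimum-jerk displacement profile whose
    peak speed is ``main_sequence_slope * amplitude`` (so duration is
    1.875 / slope seconds); amplitudes are gamma distributed and clipped to
    [``amplitude_min_deg``, ``amplitude_max_deg``]; cue-relative directions
    are a mixture of von Mises lobes at 0 deg (toward) and 180 deg (away)
    plus a uniform component.
    """

    drift_diffusion: float = 0.001  # deg^2/s
    drift_reversion_s: float = 0.5
    tremor_sd: float = 0.005  # deg per sample
    microsaccade_rate_hz: float = 1.5
    dip_start_ms: float = 0.0  # relative to patch onset
    dip_duration_ms: float = 150.0
    dip_rate_hz: float = 0.05
    rebound_rate_hz: float = 2.0
    rebound_duration_ms: float = 500.0
    amplitude_shape: float = 4.0
    amplitude_mean_deg: float = 0.4
    amplitude_min_deg: float = 0.1
    amplitude_max_deg: float = 1.0
    direction_mixture: tuple[float, float, float] = (0.25, 0.25, 0.5)  # toward, away, uniform
    direction_kappa: float = 4.0
    main_sequence_slope: float = 100.0  # peak speed per amplitude, 1/s
    refractory_ms: float = 150.0

    def validate(self) -> None:
        _require(self.drift_diffusion >= 0, "drift_diffusion", "must be >= 0")
        _require(self.drift_reversion_s > 0, "drift_reversion_s", "must be positive")
        _require(self.tremor_sd >= 0, "tremor_sd", "must be >= 0")
        for name in ("microsaccade_rate_hz", "dip_rate_hz", "rebound_rate_hz"):
            _require(getattr(self, name) >= 0, name, "rates must be >= 0")
        _require(0 < self.amplitude_min_deg <= self.amplitude_max_deg,
                 "amplitude_min_deg", "need 0 < min <= max amplitude")
        _require(self.amplitude_mean_deg > 0, "amplitude_mean_deg", "must be positive")
        _require(abs(sum(self.direction_mixture) - 1.0) < 1e-9,
                 "direction_mixture", "weights must sum to 1")
        _require(all(w >= 0 for w in self.direction_mixture),
                 "direction_mixture", "weights must be nonnegative")
        _require(self.main_sequence_slope > 0, "main_sequence_slope", "must be positive")
        _require(self.refractory_ms >= 0, "refractory_ms", "must be >= 0")

    @property
    def saccade_duration_ms(self) -> float:
        """Minimum-jerk duration implied by the main-sequence slope."""
        return 1000.0 * 1.875 / self.main_sequence_slope


@dataclass
class NeuronModel:
    """Generative firing-rate model for one unit.

    rate(t) = baseline
              + visual transient (exponential decay after a fixed latency,
                present only when a patch is inside the RF)
              + attention_delta during the delay period when the cue is in
                the RF
              + optional pre-microsaccadic bias / post-microsaccadic motor
                burst for microsaccades directed toward the RF,
    then suppressed after every microsaccade onset: multiplicatively by
    (1 - suppression_depth), or additively by suppression_depth * baseline
    when ``suppression_mode == "additive"``.
    """

    baseline_rate: float = 20.0  # spikes/s
    visual_amp: float = 60.0
    visual_latency_ms: float = 50.0
    visual_decay_ms: float = 80.0
    attention_delta: float = 5.0
    attention_onset_ms: float = 200.0
    suppression_depth: float = 0.5  # fraction in [0, 1]
    suppression_latency_ms: float = 20.0
    suppression_duration_ms: float = 60.0
    suppression_mode: str = "multiplicative"
    premicrosaccade_bias: float = 0.0  # spikes/s, [-40, 0) ms before toward-RF events
    motor_burst: float = 0.0  # spikes/s, [0, 100) ms after toward-RF events

    def validate(self) -> None:
        for name in ("baseline_rate", "visual_amp", "visual_decay_ms"):
            _require(getattr(self, name) >= 0, name, "must be >= 0")
        _require(self.visual_latency_ms >= 0, "visual_latency_ms", "must be >= 0")
        _require(0.0 <= self.suppression_depth <= 1.0,
                 "suppression_depth", "must be in [0, 1]")
        _require(self.suppression_latency_ms >= 0, "suppression_latency_ms", "must be >= 0")
        _require(self.suppression_duration_ms >= 0, "suppression_duration_ms", "must be >= 0")
        _require(self.suppression_mode in ("multiplicative", "additive"),
                 "suppression_mode", "must be 'multiplicative' or 'additive'")


@dataclass
class BehaviorModel:
    """Outcome and reaction-time generator.

    Hit probability and RT can be conditioned on microsaccades occurring
    within ``coupling_window_ms`` of the change onset, so analyses of
    microsaccade-conditioned behavior have a known generative counterpart.
    """

    hit_rate: float = 0.83
    false_alarm_rate: float = 0.05
    rt_mean_ms: float = 350.0
    rt_sd_ms: float = 80.0
    rt_penalty_away_ms: float = 30.0
    rt_penalty_toward_ms: float = 0.0
    hit_delta_away: float = 0.0
    hit_delta_toward: float = 0.0
    coupling_window_ms: float = 50.0  # half-window around change onset

    def validate(self) -> None:
        _require(0.0 <= self.hit_rate <= 1.0, "hit_rate", "must be in [0, 1]")
        _require(0.0 <= self.false_alarm_rate <= 1.0, "false_alarm_rate", "must be in [0, 1]")
        _require(self.rt_sd_ms >= 0, "rt_sd_ms", "must be >= 0")


@dataclass
class DetectionParams:
    """Velocity-threshold microsaccade detection parameters.

    ``lambda_rel`` scales the per-axis robust velocity SD into an
    elliptical threshold; candidate events shorter than ``min_duration_ms``
    are rejected, events closer than ``merge_gap_ms`` are merged, and
    events larger than ``max_amplitude_deg`` are discarded (automated
    surrogate for manual screening).
    """

    lambda_rel: float = 4.0
    min_duration_ms: float = 6.0
    merge_gap_ms: float = 20.0
    velocity_window_samples: int = 5
    max_amplitude_deg: float = 2.0

    def validate(self) -> None:
        _require(self.lambda_rel > 0, "lambda_rel", "must be positive")
        _require(self.min_duration_ms > 0, "min_duration_ms", "must be positive")
        _require(self.merge_gap_ms >= 0, "merge_gap_ms", "must be >= 0")
        _require(self.velocity_window_samples in (3, 5),
                 "velocity_window_samples", "supported window sizes are 3 and 5")
        _require(self.max_amplitude_deg > 0, "max_amplitude_deg", "must be positive")


@dataclass
class TimingMatchSpec:
    """Temporal matching of microsaccade-aligned data.

    The delay period is tiled by ``n_bins`` equal bins; the no-microsaccade
    condition requires zero detected onsets within
    ``event_free_halfwindow_ms`` of a bin center, which then stands in as
    the alignment time.
    """

    window_ms: tuple[float, float] = (200.0, 1000.0)
    n_bins: int = 8
    event_free_halfwindow_ms: float = 200.0

    def validate(self) -> None:
        lo, hi = self.window_ms
        _require(hi > lo, "window_ms", "must be increasing")
        _require(self.n_bins >= 1, "n_bins", "must be >= 1")
        half_bin = (hi - lo) / self.n_bins / 2.0
        _require(self.event_free_halfwindow_ms >= half_bin,
                 "event_free_halfwindow_ms", "must be >= half the bin width")

    @property
    def bin_edges(self) -> list[float]:
        lo, hi = self.window_ms
        w = (hi - lo) / self.n_bins
        return [lo + i * w for i in range(self.n_bins + 1)]

    @property
    def bin_centers(self) -> list[float]:
        e = self.bin_edges
        return [(a + b) / 2.0 for a, b in zip(e[:-1], e[1:])]


@dataclass
class PositionMatchSpec:
    """2D eye-position matching on a square grid."""

    bin_deg: float = 0.25
    before_window_ms: tuple[float, float] = (-60.0, 0.0)

    def validate(self) -> None:
        _require(self.bin_deg > 0, "bin_deg", "must be positive")
        lo, hi = self.before_window_ms
        _require(hi > lo, "before_window_ms", "must be increasing")


@dataclass
class EpochSpec:
    """Delay-period epochs and the measurement window that follows each."""

    epochs_ms: tuple[tuple[float, float], ...] = (
        (200.0, 300.0), (350.0, 450.0), (500.0, 600.0),
        (650.0, 750.0), (800.0, 900.0),
    )
    measure_ms: float = 100.0

    def validate(self) -> None:
        prev_end = -float("inf")
        for lo, hi in self.epochs_ms:
            _require(hi > lo, "epochs_ms", "each epoch must be increasing")
            _require(lo >= prev_end, "epochs_ms", "epochs must be ordered, non-overlapping")
            prev_end = hi
        _require(self.measure_ms > 0, "measure_ms", "must be positive")

    def measurement_window(self, i: int) -> tuple[float, float]:
        """The window abutting the end of epoch ``i``."""
        _, hi = self.epochs_ms[i]
        return (hi, hi + self.measure_ms)


@dataclass
class RateSpec:
    """Binning and normalization of spike counts."""

    bin_ms: float = 20.0
    norm_window_ms: tuple[float, float] = (-100.0, 1000.0)  # z-scoring sample, patch-aligned
    delay_window_ms: tuple[float, float] = (200.0, 1000.0)
    align_halfspan_ms: float = 200.0  # half-span of microsaccade-aligned matrices

    def validate(self) -> None:
        _require(self.bin_ms > 0, "bin_ms", "must be positive")
        lo, hi = self.norm_window_ms
        _require(hi > lo, "norm_window_ms", "must be increasing")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; YAML round-trippable."""

    seed: int = 0
    task: TaskConfig = field(default_factory=TaskConfig)
    eye: EyeModel = field(default_factory=EyeModel)
    neuron: NeuronModel = field(default_factory=NeuronModel)
    behavior: BehaviorModel = field(default_factory=BehaviorModel)
    detection: DetectionParams = field(default_factory=DetectionParams)
    rates: RateSpec = field(default_factory=RateSpec)
    timing_match: TimingMatchSpec = field(default_factory=TimingMatchSpec)
    position_match: PositionMatchSpec = field(default_factory=PositionMatchSpec)
    epochs: EpochSpec = field(default_factory=EpochSpec)
    units_per_monkey: int = 34
    write_hdf5: bool = False
    write_figures: bool = False

    def validate(self) -> None:
        _require(self.seed >= 0, "seed", "must be >= 0")
        _require(self.units_per_monkey >= 1, "units_per_monkey", "must be >= 1")
        for block in (self.task, self.eye, self.neuron, self.behavior,
                      self.detection, self.rates, self.timing_match,
                      self.position_match, self.epochs):
            block.validate()

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        def _tuplify(x: Any) -> Any:
            if isinstance(x, list):
                return tuple(_tuplify(v) for v in x)
            return x

        kwargs: dict[str, Any] = {}
        blocks = {
            "task": TaskConfig, "eye": EyeModel, "neuron": NeuronModel,
            "behavior": BehaviorModel, "detection": DetectionParams,
            "rates": RateSpec, "timing_match": TimingMatchSpec,
            "position_match": PositionMatchSpec, "epochs": EpochSpec,
        }
        for key, val in d.items():
            if key in blocks:
                sub = {k: _tuplify(v) for k, v in val.items()}
                kwargs[key] = blocks[key](**sub)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        """Stable hash stamped into every artifact this run writes."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
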