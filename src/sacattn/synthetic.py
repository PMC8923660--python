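"""Synthetic covert-attention sessions with known ground truth.

Generates complete sessions -- block-structured trials, fixational eye
traces containing injected microsaccades, and inhomogeneous-Poisson spike
trains -- from explicit generative models, so every downstream stage of the
pipeline has a parameter-recovery test against the truth.

Eye traces are an Ornstein-Uhlenbeck drift plus white tremor; microsaccades
are drawn from a piecewise-constant hazard (with the post-stimulus
inhibition dip and rebound) and injected as minimum-jerk displacement
profiles obeying a main-sequence relation.  Spike trains are drawn by
thinning from each unit's rate function: baseline + visual transient +
delay-period attention delta (cue-in-RF only) + peri-microsaccadic
suppression and optional motor terms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import BehaviorModel, EyeModel, NeuronModel, TaskConfig
from .core import EyeTrace, GroundTruth, SessionData, wrap_angle_deg

EVENT_COLUMNS = ["trial_id", "onset_ms", "offset_ms", "dx_deg", "dy_deg",
                 "amplitude_deg", "peak_speed_dps", "direction_deg",
                 "rel_direction_deg"]


def _as_rng(seed: int | np.random.Generator | np.random.SeedSequence) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def minimum_jerk(n: int) -> np.ndarray:
    """Fractional minimum-jerk displacement at n+1 equally spaced samples."""
    tau = np.linspace(0.0, 1.0, n + 1)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def microsaccade_hazard(t_ms: np.ndarray, eye: EyeModel,
                        patch_onset_ms: float | None) -> np.ndarray:
    """Piecewise-constant microsaccade rate (events/s) at the given times."""
    rate = np.full(t_ms.shape, eye.microsaccade_rate_hz)
    if patch_onset_ms is not None:
        dip0 = patch_onset_ms + eye.dip_start_ms
        dip1 = dip0 + eye.dip_duration_ms
        reb1 = dip1 + eye.rebound_duration_ms
        rate[(t_ms >= dip0) & (t_ms < dip1)] = eye.dip_rate_hz
        rate[(t_ms >= dip1) & (t_ms < reb1)] = eye.rebound_rate_hz
    return rate


def _sample_direction(rng: np.random.Generator, eye: EyeModel) -> float:
    """Cue-relative direction (deg) from the toward/away/uniform mixture."""
    p_toward, p_away, _ = eye.direction_mixture
    u = rng.uniform()
    if u < p_toward:
        ang = np.degrees(rng.vonmises(0.0, eye.direction_kappa))
    elif u < p_toward + p_away:
        ang = np.degrees(rng.vonmises(np.pi, eye.direction_kappa))
    else:
        ang = rng.uniform(-180.0, 180.0)
    return float(wrap_angle_deg(ang))


def simulate_eye_trace(
    trial_span_ms: float,
    eye: EyeModel,
    seed: int | np.random.Generator,
    sample_rate_hz: float = 1000.0,
    t_start_ms: float = 0.0,
    patch_onset_ms: float | None = None,
    cue_dir_deg: float = 0.0,
    trial_id: int = 0,
) -> tuple[EyeTrace, pd.DataFrame]:
    """Simulate one fixational eye trace and return it with its true events.

    The trace spans ``[t_start_ms, t_start_ms + trial_span_ms]`` at the
    given sample rate.  Returned events are the injected microsaccades
    (ground truth), one row per event, in onset order.
    """
    eye.validate()
    if trial_span_ms <= 0:
        raise ValueError("trial_span_ms must be positive")
    rng = _as_rng(seed)
    dt_ms = 1000.0 / sample_rate_hz
    dt_s = dt_ms / 1000.0
    n = int(round(trial_span_ms / dt_ms)) + 1
    t = t_start_ms + np.arange(n) * dt_ms

    # Ornstein-Uhlenbeck drift toward fixation + white tremor.
    noise = rng.standard_normal(n) * np.sqrt(eye.drift_diffusion * dt_s)
    noise2 = rng.standard_normal(n) * np.sqrt(eye.drift_diffusion * dt_s)
    a = 1.0 - dt_s / eye.drift_reversion_s
    x = lfilter([1.0], [1.0, -a], noise)
    y = lfilter([1.0], [1.0, -a], noise2)
    x = x + rng.standard_normal(n) * eye.tremor_sd
    y = y + rng.standard_normal(n) * eye.tremor_sd

    # Microsaccade onsets from the hazard, with a refractory period and a
    # margin keeping the full displacement profile inside the trace.
    dur_ms = eye.saccade_duration_ms
    n_dur = max(int(round(dur_ms / dt_ms)), 1)
    hazard = microsaccade_hazard(t, eye, patch_onset_ms)
    candidates = np.flatnonzero(rng.uniform(size=n) < hazard * dt_s)
    min_sep = n_dur + int(round(eye.refractory_ms / dt_ms))
    onsets: list[int] = []
    last = -min_sep
    lo_idx = 5  # keep clear of the velocity filter's invalid boundary
    hi_idx = n - n_dur - 5
    for idx in candidates:
        if idx < lo_idx or idx > hi_idx:
            continue
        if idx - last >= min_sep:
            onsets.append(int(idx))
            last = idx

    records = []
    profile = minimum_jerk(n_dur)
    for i0 in onsets:
        amp = float(np.clip(
            rng.gamma(eye.amplitude_shape,
                      eye.amplitude_mean_deg / eye.amplitude_shape),
            eye.amplitude_min_deg, eye.amplitude_max_deg))
        rel = _sample_direction(rng, eye)
        ang = wrap_angle_deg(cue_dir_deg + rel)
        dx = amp * np.cos(np.radians(ang))
        dy = amp * np.sin(np.radians(ang))
        x[i0:i0 + n_dur + 1] += dx * profile
        x[i0 + n_dur + 1:] += dx
        y[i0:i0 + n_dur + 1] += dy * profile
        y[i0 + n_dur + 1:] += dy
        records.append({
            "trial_id": trial_id,
            "onset_ms": float(t[i0]),
            "offset_ms": float(t[i0 + n_dur]),
            "dx_deg": float(dx),
            "dy_deg": float(dy),
            "amplitude_deg": amp,
            "peak_speed_dps": 1.875 * amp / (n_dur * dt_s),
            "direction_deg": float(ang),
            "rel_direction_deg": float(rel),
        })

    events = pd.DataFrame(records, columns=EVENT_COLUMNS)
    trace = EyeTrace(t_start_ms=t_start_ms, fs_hz=sample_rate_hz, x=x, y=y)
    return trace, events


def unit_rate(
    t_ms: np.ndarray,
    unit: NeuronModel,
    *,
    patch_in_rf: bool,
    cue_in_rf: bool,
    events: pd.DataFrame | None = None,
    rf_dir_deg: float = 0.0,
) -> np.ndarray:
    """Evaluate a unit's generative firing rate (spikes/s) at times ``t_ms``.

    This is the exact rate function the thinning sampler draws from, exposed
    so analyses can be checked against the generative truth.
    """
    t = np.asarray(t_ms, dtype=float)
    r = np.full(t.shape, unit.baseline_rate)
    if patch_in_rf and unit.visual_amp > 0:
        tt = t - unit.visual_latency_ms
        with np.errstate(over="ignore"):
            r += np.where(tt >= 0,
                          unit.visual_amp * np.exp(-np.maximum(tt, 0.0) / unit.visual_decay_ms),
                          0.0)
    if cue_in_rf and unit.attention_delta:
        r += unit.attention_delta * (t >= unit.attention_onset_ms)

    supp = np.ones(t.shape)
    supp_any = np.zeros(t.shape, dtype=bool)
    if events is not None and len(events):
        for ev in events.itertuples():
            s = ev.onset_ms
            toward_rf = abs(wrap_angle_deg(ev.direction_deg - rf_dir_deg)) < 90.0
            if toward_rf and unit.premicrosaccade_bias:
                r += unit.premicrosaccade_bias * ((t >= s - 40.0) & (t < s))
            if toward_rf and unit.motor_burst:
                r += unit.motor_burst * ((t >= s) & (t < s + 100.0))
            if unit.suppression_depth > 0:
                m = (t >= s + unit.suppression_latency_ms) & \
                    (t < s + unit.suppression_latency_ms + unit.suppression_duration_ms)
                supp[m] *= (1.0 - unit.suppression_depth)
                supp_any |= m
    if unit.suppression_mode == "multiplicative":
        r = r * supp
    else:  # additive: fixed decrement while any suppression window is active
        r = r - unit.suppression_depth * unit.baseline_rate * supp_any
    return np.maximum(r, 0.0)


def _rate_ceiling(unit: NeuronModel) -> float:
    return (unit.baseline_rate + unit.visual_amp
            + max(unit.attention_delta, 0.0)
            + max(unit.premicrosaccade_bias, 0.0)
            + max(unit.motor_burst, 0.0))


def simulate_spike_train(
    rng: np.random.Generator,
    unit: NeuronModel,
    t_start_ms: float,
    t_end_ms: float,
    *,
    patch_in_rf: bool,
    cue_in_rf: bool,
    events: pd.DataFrame | None,
    rf_dir_deg: float,
) -> np.ndarray:
    """Inhomogeneous-Poisson spike times (ms) via thinning."""
    span_s = (t_end_ms - t_start_ms) / 1000.0
    rmax = _rate_ceiling(unit)
    if rmax <= 0 or span_s <= 0:
        return np.empty(0)
    n = rng.poisson(rmax * span_s)
    times = np.sort(rng.uniform(t_start_ms, t_end_ms, n))
    accept = rng.uniform(size=n) * rmax
    rate = unit_rate(times, unit, patch_in_rf=patch_in_rf, cue_in_rf=cue_in_rf,
                     events=events, rf_dir_deg=rf_dir_deg)
    return times[accept < rate]


def _block_change_types(rng: np.random.Generator, n: int,
                        ratio: tuple[int, int]) -> np.ndarray:
    """Pseudorandom cue/foil sequence at the configured ratio."""
    c, f = ratio
    n_foil = int(round(n * f / (c + f)))
    arr = np.array(["cue"] * (n - n_foil) + ["foil"] * n_foil)
    return rng.permutation(arr)


def simulate_session(
    task: TaskConfig,
    eye: EyeModel,
    neurons: list[NeuronModel],
    seed: int | np.random.Generator,
    behavior: BehaviorModel | None = None,
    monkey: int = 1,
    session_id: str = "m1s0",
    rf_dir_deg: float = 0.0,
) -> SessionData:
    """Simulate one full session; deterministic given the seed.

    Trials are generated block by block (single-patch transition trials at
    the upcoming cued location, then the cued block, cue side alternating),
    each with its own eye trace, outcome, and per-unit spike train.
    """
    task.validate()
    eye.validate()
    for i, nm in enumerate(neurons):
        try:
            nm.validate()
        except Exception as exc:
            raise type(exc)(f"neuron {i}: {exc}") from exc
    behavior = behavior or BehaviorModel()
    behavior.validate()
    rng = _as_rng(seed)

    unit_ids = [f"{session_id}_u{i:02d}" for i in range(len(neurons))]
    trial_rows: list[dict] = []
    all_events: list[pd.DataFrame] = []
    eye_traces: dict[int, EyeTrace] = {}
    spikes: dict[str, dict[int, np.ndarray]] = {u: {} for u in unit_ids}

    trial_id = 0
    for block in range(task.blocks_per_session):
        cue_dir = float(wrap_angle_deg(rf_dir_deg + (0.0 if block % 2 == 0 else 180.0)))
        cue_in_rf = abs(wrap_angle_deg(cue_dir - rf_dir_deg)) < 90.0
        plan = ([("single_patch", "cue")] * task.single_patch_trials_per_transition
                + [("two_patch", ct) for ct in
                   _block_change_types(rng, task.trials_per_block, task.cue_foil_ratio)])
        for trial_type, change_type in plan:
            change_ms = float(rng.uniform(*task.change_window_ms))
            t_start = task.trial_start_ms
            t_end = change_ms + task.response_window_ms[1]
            trace, events = simulate_eye_trace(
                t_end - t_start, eye, rng,
                sample_rate_hz=task.sample_rate_hz, t_start_ms=t_start,
                patch_onset_ms=0.0, cue_dir_deg=cue_dir, trial_id=trial_id)

            # microsaccade labels near the change, for behavioral coupling
            near = events[(events["onset_ms"] >= change_ms - behavior.coupling_window_ms)
                          & (events["onset_ms"] <= change_ms + behavior.coupling_window_ms)]
            has_toward = bool((np.abs(near["rel_direction_deg"]) < 90.0).any())
            has_away = bool((np.abs(near["rel_direction_deg"]) >= 90.0).any())

            rt = np.nan
            if change_type == "cue":
                p_hit = behavior.hit_rate
                if has_away:
                    p_hit += behavior.hit_delta_away
                if has_toward:
                    p_hit += behavior.hit_delta_toward
                if rng.uniform() < np.clip(p_hit, 0.0, 1.0):
                    outcome = "hit"
                    mu = behavior.rt_mean_ms
                    if has_away:
                        mu += behavior.rt_penalty_away_ms
                    if has_toward:
                        mu += behavior.rt_penalty_toward_ms
                    rt = float(np.clip(rng.normal(mu, behavior.rt_sd_ms),
                                       *task.response_window_ms))
                else:
                    outcome = "miss"
            else:  # foil change: responding is a false alarm
                if rng.uniform() < behavior.false_alarm_rate:
                    outcome = "fa"
                    rt = float(np.clip(rng.normal(behavior.rt_mean_ms, behavior.rt_sd_ms),
                                       *task.response_window_ms))
                else:
                    outcome = "cr"

            patch_in_rf = cue_in_rf if trial_type == "single_patch" else True
            for u, nm in zip(unit_ids, neurons):
                spikes[u][trial_id] = simulate_spike_train(
                    rng, nm, t_start, t_end,
                    patch_in_rf=patch_in_rf,
                    cue_in_rf=(cue_in_rf and trial_type == "two_patch"),
                    events=events, rf_dir_deg=rf_dir_deg)

            eye_traces[trial_id] = trace
            all_events.append(events)
            trial_rows.append({
                "session_id": session_id, "trial_id": trial_id, "monkey": monkey,
                "block": block, "trial_type": trial_type, "cue_dir_deg": cue_dir,
                "cue_in_rf": bool(cue_in_rf), "patch_in_rf": bool(patch_in_rf),
                "change_type": change_type, "change_time_ms": change_ms,
                "outcome": outcome, "rt_ms": rt,
                "t_start_ms": t_start, "t_end_ms": t_end,
            })
            trial_id += 1

    trials = pd.DataFrame(trial_rows)
    nonempty = [e for e in all_events if len(e)]
    events_df = (pd.concat(nonempty, ignore_index=True)
                 if nonempty else pd.DataFrame(columns=EVENT_COLUMNS))
    units = pd.DataFrame([{"unit_id": u, **vars(nm)}
                          for u, nm in zip(unit_ids, neurons)])
    truth = GroundTruth(events=events_df, unit_params=units.copy())
    return SessionData(session_id=session_id, monkey=monkey, rf_dir_deg=rf_dir_deg,
                       trials=trials, units=units, spikes=spikes, eye=eye_traces,
                       ground_truth=truth)


def make_neurons(
    template: NeuronModel,
    n: int,
    rng: np.random.Generator | None = None,
    baseline_jitter: tuple[float, float] = (0.7, 1.4),
    visual_jitter: tuple[float, float] = (0.8, 1.2),
) -> list[NeuronModel]:
    """A population of units: the template with jittered baseline/transient.

    The attention delta and suppression parameters are left at the template
    values so recovery tests have a single known truth.
    """
    out = []
    for _ in range(n):
        nm = NeuronModel(**vars(template))
        if rng is not None:
            nm.baseline_rate = template.baseline_rate * rng.uniform(*baseline_jitter)
            nm.visual_amp = template.visual_amp * rng.uniform(*visual_jitter)
        out.append(nm)
    return out


def simulate_experiment(
    task: TaskConfig,
    eye: EyeModel,
    neuron_template: NeuronModel,
    seed: int,
    behavior: BehaviorModel | None = None,
    units_per_monkey: int = 34,
    jitter_units: bool = True,
) -> list[SessionData]:
    """Simulate the two-monkey experiment: sessions with units split evenly.

    Units are distributed as evenly as possible across each monkey's
    sessions; all sessions share the same RF direction (0 deg) and the cue
    alternates between 0 and 180 deg across blocks.
    """
    root = np.random.SeedSequence(seed)
    sessions: list[SessionData] = []
    n_sess = task.n_sessions_per_monkey
    for monkey in (1, 2):
        base = units_per_monkey // n_sess
        extra = units_per_monkey % n_sess
        for s in range(n_sess):
            child = root.spawn(1)[0]
            rng = np.random.default_rng(child)
            n_units = base + (1 if s < extra else 0)
            neurons = make_neurons(neuron_template, n_units,
                                   rng if jitter_units else None)
            sessions.append(simulate_session(
                task, eye, neurons, rng, behavior=behavior, monkey=monkey,
                session_id=f"m{monkey}s{s}", rf_dir_deg=0.0))
    return sessions
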