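"""Velocity-threshold microsaccade detection and cue-relative summaries.

Detection follows the classic 2D velocity method: eye velocity from a
moving-window derivative, per-axis robust (median-based) noise estimates
scaled by a relative threshold lambda into an elliptical criterion, and
candidate events kept when the criterion holds for at least the minimum
duration.  Detected events are classified toward/away relative to the cued
location with a +/-90 deg (180 deg wide) window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import DetectionParams
from .core import (MICROSACCADE_COLUMNS, EyeTrace, SessionData, VelocityTrace,
                   wrap_angle_deg)


class DegenerateTraceError(ValueError):
    """Raised when a trace's velocity noise estimate is zero on an axis."""


def compute_velocity(trace: EyeTrace, params: DetectionParams | None = None,
                     times_ms: np.ndarray | None = None) -> VelocityTrace:
    """Moving-window derivative of eye position.

    With the default 5-sample window,
    ``v_n = (x_{n+2} + x_{n+1} - x_{n-1} - x_{n-2}) / (6 dt)``;
    the 3-sample window is the central difference.  Boundary samples the
    window cannot cover are flagged invalid.  If explicit ``times_ms`` are
    supplied they must be uniform.
    """
    params = params or DetectionParams()
    params.validate()
    if times_ms is not None:
        d = np.diff(np.asarray(times_ms, dtype=float))
        if d.size and not np.allclose(d, d[0], rtol=0, atol=1e-9):
            raise ValueError("non-uniform timestamps")
    w = params.velocity_window_samples
    n = trace.n
    if n < w:
        raise ValueError(f"trace has {n} samples; need >= {w}")
    dt_s = trace.dt_ms / 1000.0
    vx = np.zeros(n)
    vy = np.zeros(n)
    valid = np.zeros(n, dtype=bool)
    half = w // 2
    if w == 5:
        sl = slice(2, n - 2)
        vx[sl] = (trace.x[4:] + trace.x[3:-1] - trace.x[1:-3] - trace.x[:-4]) / (6 * dt_s)
        vy[sl] = (trace.y[4:] + trace.y[3:-1] - trace.y[1:-3] - trace.y[:-4]) / (6 * dt_s)
    else:  # w == 3
        sl = slice(1, n - 1)
        vx[sl] = (trace.x[2:] - trace.x[:-2]) / (2 * dt_s)
        vy[sl] = (trace.y[2:] - trace.y[:-2]) / (2 * dt_s)
    valid[half:n - half] = True
    return VelocityTrace(t_start_ms=trace.t_start_ms, fs_hz=trace.fs_hz,
                         vx=vx, vy=vy, valid=valid)


def estimate_thresholds(vel: VelocityTrace, params: DetectionParams | None = None,
                        trial_id: int | str | None = None) -> tuple[float, float]:
    """Per-axis elliptical thresholds eta = lambda * sigma.

    sigma is the median-based robust SD
    ``sqrt(median(v^2) - median(v)^2)`` over valid samples.
    """
    params = params or DetectionParams()
    etas = []
    for v in (vel.vx[vel.valid], vel.vy[vel.valid]):
        if v.size < 10:
            raise ValueError("need >= 10 valid velocity samples")
        var = np.median(v**2) - np.median(v) ** 2
        sigma = np.sqrt(var) if var > 0 else 0.0
        if sigma <= 0:
            raise DegenerateTraceError(
                f"degenerate velocity trace (sigma = 0) in trial {trial_id!r}")
        etas.append(params.lambda_rel * sigma)
    return float(etas[0]), float(etas[1])


def classify_direction(rel_direction_deg: float) -> str:
    """Toward/away grouping of a cue-relative direction.

    The toward half-circle is the half-open interval [-90, 90): directions
    within +/-90 deg of the cue, with the -90 boundary assigned toward and
    +90 away so each label covers exactly half the circle.
    """
    a = wrap_angle_deg(rel_direction_deg)
    return "toward" if -90.0 <= a < 90.0 else "away"


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end] index runs of True samples."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def detect_microsaccades(
    trace: EyeTrace,
    params: DetectionParams | None = None,
    cue_direction_deg: float = 0.0,
    trial_id: int = 0,
    session_id: str = "",
) -> pd.DataFrame:
    """Detect microsaccades in one trace.

    A sample is suprathreshold when ``(vx/eta_x)^2 + (vy/eta_y)^2 > 1``.
    Maximal suprathreshold runs separated by less than ``merge_gap_ms`` are
    merged, runs shorter than ``min_duration_ms`` (counting samples) are
    rejected, and events whose displacement exceeds ``max_amplitude_deg``
    are discarded.  Returns the canonical microsaccade table sorted by
    onset.
    """
    params = params or DetectionParams()
    params.validate()
    vel = compute_velocity(trace, params)
    eta_x, eta_y = estimate_thresholds(vel, params, trial_id=trial_id)
    crit = ((vel.vx / eta_x) ** 2 + (vel.vy / eta_y) ** 2 > 1.0) & vel.valid

    # maximal suprathreshold runs meeting the minimum duration ...
    min_samples = params.min_duration_ms / trace.dt_ms
    runs = [(s, e) for s, e in _runs_above(crit) if (e - s + 1) >= min_samples]
    # ... then events closer than merge_gap_ms fused (overshoot suppression)
    gap_samples = params.merge_gap_ms / trace.dt_ms
    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged and (s - merged[-1][1] - 1) < gap_samples:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))

    t = trace.times_ms
    speed = np.hypot(vel.vx, vel.vy)
    rows = []
    for s, e in merged:
        dx = trace.x[e] - trace.x[s]
        dy = trace.y[e] - trace.y[s]
        amp = float(np.hypot(dx, dy))
        if amp > params.max_amplitude_deg:
            continue
        direction = float(np.degrees(np.arctan2(dy, dx)))
        rel = float(wrap_angle_deg(direction - cue_direction_deg))
        rows.append({
            "session_id": session_id, "trial_id": trial_id,
            "onset_ms": float(t[s]), "offset_ms": float(t[e]),
            "dx_deg": float(dx), "dy_deg": float(dy), "amplitude_deg": amp,
            "peak_speed_dps": float(speed[s:e + 1].max()),
            "direction_deg": float(wrap_angle_deg(direction)),
            "rel_direction_deg": rel, "label": classify_direction(rel),
        })
    df = pd.DataFrame(rows, columns=MICROSACCADE_COLUMNS)
    return df.sort_values("onset_ms", ignore_index=True) if len(df) else df


def detect_session(session: SessionData,
                   params: DetectionParams | None = None) -> pd.DataFrame:
    """Run detection on every trial of a session; concatenated table."""
    parts = []
    for row in session.trials.itertuples():
        parts.append(detect_microsaccades(
            session.eye[row.trial_id], params,
            cue_direction_deg=row.cue_dir_deg,
            trial_id=row.trial_id, session_id=session.session_id))
    parts = [p for p in parts if len(p)]
    if not parts:
        return pd.DataFrame(columns=MICROSACCADE_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def relabel_relative_to(events: pd.DataFrame, reference_deg: float | pd.Series,
                        trials: pd.DataFrame | None = None) -> pd.DataFrame:
    """Relabel events toward/away relative to a new reference direction.

    ``reference_deg`` may be a scalar (e.g. the RF direction for the motor
    control) applied to all events.
    """
    out = events.copy()
    out["rel_direction_deg"] = wrap_angle_deg(
        out["direction_deg"].to_numpy() - reference_deg)
    out["label"] = [classify_direction(a) for a in out["rel_direction_deg"]]
    return out


def microsaccade_probability(
    events: pd.DataFrame,
    trials: pd.DataFrame,
    bin_ms: float = 20.0,
    window_ms: tuple[float, float] = (-500.0, 1000.0),
) -> pd.DataFrame:
    """Per-bin probability that a trial contains a labeled onset.

    For each time bin and label, the fraction of trials with at least one
    onset of that label in the bin is computed per session, then averaged
    across sessions; the SEM is across sessions.  Returns a long table with
    columns bin_start_ms, bin_center_ms, label, prob, sem.
    """
    if "session_id" not in trials.columns or trials["session_id"].nunique() == 0:
        raise ValueError("no sessions in trial table")
    edges = np.arange(window_ms[0], window_ms[1] + bin_ms / 2, bin_ms)
    labels = ("toward", "away")
    sessions = sorted(trials["session_id"].unique())
    curves = {lab: [] for lab in labels}
    for sid in sessions:
        tr = trials[trials["session_id"] == sid]
        n_trials = len(tr)
        ev = events[events["session_id"] == sid] if "session_id" in events.columns else events
        for lab in labels:
            sub = ev[ev["label"] == lab]
            frac = np.zeros(edges.size - 1)
            if len(sub) and n_trials:
                b = np.searchsorted(edges, sub["onset_ms"].to_numpy(), side="right") - 1
                ok = (b >= 0) & (b < edges.size - 1) & \
                     (sub["onset_ms"].to_numpy() < edges[-1])
                pairs = set(zip(sub["trial_id"].to_numpy()[ok], b[ok]))
                for _, bi in pairs:
                    frac[bi] += 1
                frac /= n_trials
            curves[lab].append(frac)
    rows = []
    for lab in labels:
        arr = np.vstack(curves[lab])
        mean = arr.mean(axis=0)
        sem = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0]) if arr.shape[0] > 1 \
            else np.zeros(arr.shape[1])
        for i in range(edges.size - 1):
            rows.append({"bin_start_ms": edges[i],
                         "bin_center_ms": (edges[i] + edges[i + 1]) / 2,
                         "label": lab, "prob": mean[i], "sem": sem[i]})
    return pd.DataFrame(rows)


def direction_histogram(
    events: pd.DataFrame,
    delay_window_ms: tuple[float, float] = (200.0, 1000.0),
    n_bins: int = 36,
) -> dict:
    """Polar histogram of cue-relative directions in the delay period.

    Returns bin edges/counts plus toward/away proportions (NaN and flagged
    undefined when no event falls in the window).
    """
    sel = events[(events["onset_ms"] >= delay_window_ms[0])
                 & (events["onset_ms"] < delay_window_ms[1])]
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    ang = sel["rel_direction_deg"].to_numpy()
    # wrap convention (-180, 180]: np.histogram's closed last bin catches +180
    counts, _ = np.histogram(ang, bins=edges)
    n = len(sel)
    if n == 0:
        return {"bin_edges_deg": edges, "counts": counts, "n": 0,
                "prop_toward": float("nan"), "prop_away": float("nan"),
                "defined": False}
    n_toward = int((sel["label"] == "toward").sum())
    return {"bin_edges_deg": edges, "counts": counts, "n": n,
            "prop_toward": n_toward / n, "prop_away": (n - n_toward) / n,
            "defined": True}
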