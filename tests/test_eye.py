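"""Detection tests: velocity filter, robust thresholds, elliptical criterion,
direction grouping, and the brute-force scan oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sacattn.config import DetectionParams, EyeModel
from sacattn.core import EyeTrace, VelocityTrace, wrap_angle_deg
from sacattn.eye import (DegenerateTraceError, classify_direction,
                         compute_velocity, detect_microsaccades,
                         direction_histogram, estimate_thresholds,
                         microsaccade_probability)
from sacattn.synthetic import simulate_eye_trace


def _trace(x, y, fs=1000.0, t0=0.0):
    return EyeTrace(t_start_ms=t0, fs_hz=fs, x=np.asarray(x, float),
                    y=np.asarray(y, float))


# ---------------------------------------------------------------------------
# velocity
# ---------------------------------------------------------------------------

def test_velocity_constant_zero():
    v = compute_velocity(_trace(np.ones(100), np.zeros(100)))
    assert np.all(v.vx[v.valid] == 0) and np.all(v.vy[v.valid] == 0)
    assert not v.valid[:2].any() and not v.valid[-2:].any()


def test_velocity_linear_ramp():
    t = np.arange(200) / 1000.0
    v = compute_velocity(_trace(2.0 * t, np.zeros(200)))
    np.testing.assert_allclose(v.vx[v.valid], 2.0, atol=1e-9)


def test_velocity_matches_convolution_oracle():
    """5 Hz sinusoid: the windowed derivative equals direct convolution."""
    fs = 1000.0
    t = np.arange(1000) / fs
    x = 0.3 * np.sin(2 * np.pi * 5 * t)
    v = compute_velocity(_trace(x, np.zeros_like(x), fs=fs))
    kernel = np.array([1.0, 1.0, 0.0, -1.0, -1.0]) / (6.0 / fs)
    oracle = np.convolve(x, kernel, mode="same")
    np.testing.assert_allclose(v.vx[v.valid], oracle[2:-2], atol=1e-9)
    # amplitude agrees with the analytic derivative times the filter gain
    w = 2 * np.pi * 5
    gain = (np.sin(w * 2 / fs) + np.sin(w / fs)) / (3 * w / fs)
    assert v.vx[v.valid].max() == pytest.approx(0.3 * w * gain, rel=1e-3)


def test_velocity_rejects_nonuniform_times():
    with pytest.raises(ValueError, match="non-uniform"):
        compute_velocity(_trace(np.zeros(10), np.zeros(10)),
                         times_ms=np.array([0, 1, 2, 3, 4, 5, 6, 7, 8, 10.5]))


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------

def test_thresholds_known_sigma():
    """sigma_x=10, sigma_y=5 with lambda=4 gives eta=(40, 20) exactly."""
    vx = np.tile([10.0, -10.0], 50)
    vy = np.tile([5.0, -5.0], 50)
    vel = VelocityTrace(0.0, 1000.0, vx, vy, np.ones(100, bool))
    assert estimate_thresholds(vel, DetectionParams(lambda_rel=4.0)) == (40.0, 20.0)


def test_thresholds_degenerate_error():
    vel = VelocityTrace(0.0, 1000.0, np.ones(50), np.ones(50),
                        np.ones(50, bool))
    with pytest.raises(DegenerateTraceError, match="trial 17"):
        estimate_thresholds(vel, trial_id=17)


def test_threshold_sigma_matches_direct_formula(rng):
    """Median-based scale equals the direct formula on the same sample.

    For a Gaussian the median-of-squares scale is 0.6745 sigma (the median
    of |N(0,1)|), so sd = 10 gives ~6.745, not 10.
    """
    v = rng.normal(0, 10.0, 100_000)
    vel = VelocityTrace(0.0, 1000.0, v, v.copy(), np.ones(v.size, bool))
    eta_x, _ = estimate_thresholds(vel, DetectionParams(lambda_rel=1.0))
    direct = np.sqrt(np.median(v**2) - np.median(v) ** 2)
    assert eta_x == pytest.approx(direct, rel=1e-12)
    assert eta_x == pytest.approx(6.7449, rel=0.02)


# ---------------------------------------------------------------------------
# direction grouping
# ---------------------------------------------------------------------------

def test_direction_enumeration_partitions_circle():
    labels = [classify_direction(a) for a in range(-179, 181)]
    oracle = ["toward" if -90 <= wrap_angle_deg(a) < 90 else "away"
              for a in range(-179, 181)]
    assert labels == oracle
    assert labels.count("toward") == labels.count("away") == 180


def test_direction_boundaries_and_flip():
    assert classify_direction(45.0) == "toward"
    assert classify_direction(180.0) == "away"
    assert classify_direction(-90.0) == "toward"
    assert classify_direction(90.0) == "away"
    for a in np.arange(-175.0, 181.0, 5.0):
        flipped = classify_direction(wrap_angle_deg(a - 180.0))
        assert flipped != classify_direction(a)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def detection_oracle(trace: EyeTrace, params: DetectionParams,
                     cue_dir: float) -> list[tuple[int, int]]:
    """Independent exhaustive scan of the elliptical criterion.

    Recomputes velocity by explicit per-sample sums, thresholds from the
    median formula, scans every sample, collects runs meeting the minimum
    duration, then fuses runs with short gaps.  Returns (onset, offset)
    sample indices.
    """
    n = trace.n
    dt = trace.dt_ms / 1000.0
    vx = np.zeros(n)
    vy = np.zeros(n)
    for i in range(2, n - 2):
        vx[i] = (trace.x[i + 2] + trace.x[i + 1] - trace.x[i - 1]
                 - trace.x[i - 2]) / (6 * dt)
        vy[i] = (trace.y[i + 2] + trace.y[i + 1] - trace.y[i - 1]
                 - trace.y[i - 2]) / (6 * dt)
    valid = np.zeros(n, bool)
    valid[2:n - 2] = True
    sx = np.sqrt(np.median(vx[valid] ** 2) - np.median(vx[valid]) ** 2)
    sy = np.sqrt(np.median(vy[valid] ** 2) - np.median(vy[valid]) ** 2)
    ex, ey = params.lambda_rel * sx, params.lambda_rel * sy
    above = [(valid[i] and (vx[i] / ex) ** 2 + (vy[i] / ey) ** 2 > 1)
             for i in range(n)]
    runs, start = [], None
    for i, flag in enumerate(above + [False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    runs = [(s, e) for s, e in runs
            if (e - s + 1) * trace.dt_ms >= params.min_duration_ms]
    fused = []
    for s, e in runs:
        if fused and (s - fused[-1][1] - 1) * trace.dt_ms < params.merge_gap_ms:
            fused[-1] = (fused[-1][0], e)
        else:
            fused.append((s, e))
    keep = []
    for s, e in fused:
        amp = np.hypot(trace.x[e] - trace.x[s], trace.y[e] - trace.y[s])
        if amp <= params.max_amplitude_deg:
            keep.append((s, e))
    return keep


def test_subthreshold_noise_yields_empty(rng):
    x = rng.normal(0, 1e-4, 1500)
    y = rng.normal(0, 1e-4, 1500)
    det = detect_microsaccades(_trace(x, y), DetectionParams(), 0.0)
    assert len(det) == len(detection_oracle(_trace(x, y), DetectionParams(), 0.0))


def test_single_injected_event_onset_accuracy():
    eye = EyeModel(tremor_sd=0.005, microsaccade_rate_hz=0.0)
    rng = np.random.default_rng(0)
    trace, _ = simulate_eye_trace(1500, eye, seed=11)
    # inject one known 0.5 deg rightward event at 500 ms
    from sacattn.synthetic import minimum_jerk
    n_dur = int(round(eye.saccade_duration_ms))
    prof = minimum_jerk(n_dur) * 0.5
    i0 = 500
    trace.x[i0:i0 + n_dur + 1] += prof
    trace.x[i0 + n_dur + 1:] += 0.5
    det = detect_microsaccades(trace, DetectionParams(), 0.0)
    assert len(det) == 1
    assert abs(det["onset_ms"].iloc[0] - 500.0) <= 5.0
    assert det["label"].iloc[0] == "toward"
    assert det["amplitude_deg"].iloc[0] == pytest.approx(0.5, abs=0.05)


def test_five_sample_excursion_rejected(rng):
    """5 suprathreshold samples at 1 kHz (5 ms) fail the 6-ms minimum."""
    x = rng.normal(0, 0.002, 2000)
    y = rng.normal(0, 0.002, 2000)
    for start, n_fast in ((600, 7), (1200, 9)):
        x[start:start + n_fast] += np.linspace(0, 0.25, n_fast)
        x[start + n_fast:] += 0.25
    tr = _trace(x, y)
    base = detect_microsaccades(tr, DetectionParams(merge_gap_ms=0.0), 0.0)
    assert len(base) == 2
    # rebuild with a burst spanning only 5 samples above threshold
    x2 = rng.normal(0, 0.002, 2000)
    step = np.linspace(0, 0.08, 4)
    x2[900:904] += step
    x2[904:] += 0.08
    det = detect_microsaccades(_trace(x2, y), DetectionParams(merge_gap_ms=0.0),
                               0.0)
    oracle = detection_oracle(_trace(x2, y), DetectionParams(merge_gap_ms=0.0),
                              0.0)
    assert len(det) == len(oracle)
    sub = detect_microsaccades(_trace(x2, y),
                               DetectionParams(min_duration_ms=3.0,
                                               merge_gap_ms=0.0), 0.0)
    assert len(sub) >= len(det)


def test_detection_equals_oracle_on_random_traces():
    params = DetectionParams()
    eye = EyeModel()
    for seed in range(40):
        trace, _ = simulate_eye_trace(2000, eye, seed=seed)
        det = detect_microsaccades(trace, params, 0.0)
        oracle = detection_oracle(trace, params, 0.0)
        assert len(det) == len(oracle)
        t = trace.times_ms
        for row, (s, e) in zip(det.itertuples(), oracle):
            assert row.onset_ms == t[s] and row.offset_ms == t[e]


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_labels_partition_and_flip_under_cue_change(seed):
    """Toward/away partition all events; flipping the cue side swaps labels."""
    trace, _ = simulate_eye_trace(1500, EyeModel(), seed=seed)
    det0 = detect_microsaccades(trace, DetectionParams(), cue_direction_deg=0.0)
    det180 = detect_microsaccades(trace, DetectionParams(),
                                  cue_direction_deg=180.0)
    assert det0["label"].isin(["toward", "away"]).all()
    assert len(det0) == len(det180)
    for a, b in zip(det0["label"], det180["label"]):
        assert a != b


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _fake_events(rows):
    return pd.DataFrame(rows, columns=["session_id", "trial_id", "onset_ms",
                                       "label", "rel_direction_deg"])


def test_probability_no_events_zero():
    trials = pd.DataFrame({"session_id": ["a"] * 10, "trial_id": range(10)})
    prob = microsaccade_probability(_fake_events([]), trials, 20.0, (0.0, 200.0))
    assert (prob["prob"] == 0).all()


def test_probability_counts_trial_fractions():
    trials = pd.DataFrame({"session_id": ["a"] * 4, "trial_id": range(4)})
    events = _fake_events([
        ("a", 0, 10.0, "toward", 0.0),
        ("a", 0, 15.0, "toward", 0.0),  # same trial+bin counts once
        ("a", 1, 10.0, "away", 180.0),
        ("a", 2, 30.0, "toward", 0.0),
    ])
    prob = microsaccade_probability(events, trials, 20.0, (0.0, 40.0))
    tw = prob[prob["label"] == "toward"].set_index("bin_start_ms")["prob"]
    aw = prob[prob["label"] == "away"].set_index("bin_start_ms")["prob"]
    assert tw[0.0] == 0.25 and tw[20.0] == 0.25
    assert aw[0.0] == 0.25 and aw[20.0] == 0.0


def test_probability_matches_hazard_oracle():
    """Constant hazard, unbiased directions: each label ~ rate/2 per bin."""
    eye = EyeModel(microsaccade_rate_hz=1.5,
                   direction_mixture=(0.0, 0.0, 1.0))
    rows, trials_rows = [], []
    rng = np.random.default_rng(5)
    n_trials = 400
    for t in range(n_trials):
        _, ev = simulate_eye_trace(1000, eye, seed=int(rng.integers(2**31)))
        trials_rows.append({"session_id": "s", "trial_id": t})
        for e in ev.itertuples():
            rows.append(("s", t, e.onset_ms,
                         "toward" if abs(e.rel_direction_deg) < 90 else "away",
                         e.rel_direction_deg))
    prob = microsaccade_probability(_fake_events(rows),
                                    pd.DataFrame(trials_rows), 20.0,
                                    (100.0, 900.0))
    # effective rate after refractory thinning, split evenly between labels
    dead_s = (eye.saccade_duration_ms + eye.refractory_ms) / 1000.0
    rate_eff = 1.5 / (1.0 + 1.5 * dead_s)
    p_bin = rate_eff * 0.020 / 2.0
    for lab in ("toward", "away"):
        got = prob.loc[prob["label"] == lab, "prob"].mean()
        se = np.sqrt(p_bin * (1 - p_bin) / (n_trials * 40))
        assert abs(got - p_bin) < 4 * se


def test_direction_histogram_properties(rng):
    ev = pd.DataFrame({
        "onset_ms": np.full(10_000, 500.0),
        "rel_direction_deg": wrap_angle_deg(rng.uniform(-180, 180, 10_000)),
    })
    ev["label"] = ["toward" if -90 <= a < 90 else "away"
                   for a in ev["rel_direction_deg"]]
    h = direction_histogram(ev)
    assert h["prop_toward"] + h["prop_away"] == pytest.approx(1.0)
    assert abs(h["prop_toward"] - 0.5) < 3 * np.sqrt(0.25 / 10_000)
    # all events at 0 deg: one occupied bin, toward proportion 1
    single = ev.copy()
    single["rel_direction_deg"] = 0.0
    single["label"] = "toward"
    h1 = direction_histogram(single)
    assert (h1["counts"] > 0).sum() == 1 and h1["prop_toward"] == 1.0
    # rotation equivariance: rotating all relative angles by 90 deg shifts bins
    rot = ev.copy()
    rot["rel_direction_deg"] = wrap_angle_deg(ev["rel_direction_deg"] + 90.0)
    h2 = direction_histogram(rot)
    assert h2["counts"].sum() == h["counts"].sum()
    np.testing.assert_array_equal(np.roll(h["counts"], 9), h2["counts"])
    # empty window flagged undefined
    h3 = direction_histogram(ev[ev["onset_ms"] < 0])
    assert not h3["defined"] and np.isnan(h3["prop_toward"])
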