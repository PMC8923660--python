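"""Resampling controls: timing-matched and eye-position-matched subsampling.

Both controls share one scheme: tabulate candidate counts per bin
(temporal 100-ms bins of the delay period, or 0.25 deg square spatial bins
of pre-event eye position) for every condition, then subsample each
condition without replacement down to the per-bin minimum, so the binned
distributions are exactly equal across conditions afterwards.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PositionMatchSpec, TimingMatchSpec
from .core import MatchedEventSet, SessionData

#: documented RNG consumption order for reproducibility
_MSACC_ORDER = ("none", "toward", "away")


def timing_match(
    events: pd.DataFrame,
    trials: pd.DataFrame,
    spec: TimingMatchSpec | None = None,
    seed: int = 0,
    attention_col: str | None = "cue_in_rf",
    level: str = "event",
) -> MatchedEventSet:
    """Timing-matched subsampling of microsaccade-aligned conditions.

    The analysis window is tiled into ``n_bins`` temporal bins.  For each
    bin and condition the candidates are: events of that label with onset
    in the bin (``level='event'``: every event is a candidate;
    ``level='trial'``: one candidate per trial, aligned at its first event
    in the bin), and -- for the no-microsaccade condition -- trials with no
    detected onset within the event-free half-window of the bin center,
    aligned at the bin center.  Every condition is then subsampled without
    replacement to the per-bin minimum across all conditions, with a single
    seeded generator consumed in condition-then-bin order.

    ``events`` must be the full detected-event table for the trials in
    ``trials`` (the event-free rule inspects onsets outside the analysis
    window too).
    """
    spec = spec or TimingMatchSpec()
    spec.validate()
    if level not in ("event", "trial"):
        raise ValueError("level must be 'event' or 'trial'")
    lo, hi = spec.window_ms
    edges = np.asarray(spec.bin_edges)
    centers = np.asarray(spec.bin_centers)
    n_bins = spec.n_bins

    if attention_col is not None:
        groups = {"in": trials[trials[attention_col]],
                  "out": trials[~trials[attention_col].astype(bool)]}
    else:
        groups = {"": trials}

    ev = events[events["trial_id"].isin(set(trials["trial_id"]))]
    onsets_by_trial = {t: g["onset_ms"].to_numpy() for t, g in ev.groupby("trial_id")}

    candidates: dict[str, dict[int, pd.DataFrame]] = {}
    for gname, gtrials in groups.items():
        tset = set(gtrials["trial_id"])
        gev = ev[ev["trial_id"].isin(tset)]
        in_win = gev[(gev["onset_ms"] >= lo) & (gev["onset_ms"] < hi)].copy()
        in_win["bin"] = np.minimum(
            ((in_win["onset_ms"] - lo) // ((hi - lo) / n_bins)).astype(int),
            n_bins - 1)
        for m in _MSACC_ORDER:
            cname = f"{m}_{gname}" if gname else m
            candidates[cname] = {}
            for b in range(n_bins):
                if m == "none":
                    c = centers[b]
                    rows = []
                    for t in sorted(tset):
                        on = onsets_by_trial.get(t, np.empty(0))
                        if not np.any(np.abs(on - c) <= spec.event_free_halfwindow_ms):
                            rows.append({"trial_id": t, "align_ms": c, "bin": b})
                    cand = pd.DataFrame(rows, columns=["trial_id", "align_ms", "bin"])
                else:
                    sub = in_win[(in_win["label"] == m) & (in_win["bin"] == b)]
                    if level == "trial" and len(sub):
                        sub = sub.sort_values("onset_ms").groupby("trial_id",
                                                                  as_index=False).first()
                    cand = pd.DataFrame({
                        "trial_id": sub["trial_id"].to_numpy(),
                        "align_ms": sub["onset_ms"].to_numpy(),
                        "bin": b,
                    })
                candidates[cname][b] = cand

    return _subsample(candidates, list(range(n_bins)), seed, kind="timing",
                      spec_dict={"window_ms": list(spec.window_ms),
                                 "n_bins": spec.n_bins,
                                 "event_free_halfwindow_ms": spec.event_free_halfwindow_ms,
                                 "level": level,
                                 "attention_col": attention_col})


def eye_position_match(
    samples: pd.DataFrame,
    spec: PositionMatchSpec | None = None,
    seed: int = 0,
) -> MatchedEventSet:
    """Match 2D pre-event eye-position distributions across conditions.

    ``samples`` has one row per aligned event with columns ``condition``,
    ``trial_id``, ``align_ms``, ``x_deg``, ``y_deg`` (the average eye
    position in the 'before' window).  Positions are histogrammed on a
    square grid and every condition is subsampled without replacement to
    the per-cell minimum across conditions.
    """
    spec = spec or PositionMatchSpec()
    spec.validate()
    s = samples.copy()
    s["bin"] = list(zip((np.floor(s["x_deg"] / spec.bin_deg)).astype(int),
                        (np.floor(s["y_deg"] / spec.bin_deg)).astype(int)))
    conditions = sorted(s["condition"].unique())
    bins = sorted(s["bin"].unique())
    candidates: dict[str, dict] = {}
    for cname in conditions:
        sub = s[s["condition"] == cname]
        candidates[cname] = {
            b: sub[sub["bin"] == b][["trial_id", "align_ms", "bin"]]
            for b in bins}
    return _subsample(candidates, bins, seed, kind="position",
                      spec_dict={"bin_deg": spec.bin_deg,
                                 "before_window_ms": list(spec.before_window_ms)})


def _subsample(candidates: dict[str, dict], bins: list, seed: int,
               kind: str, spec_dict: dict) -> MatchedEventSet:
    """Per-bin minimum-count subsampling without replacement (shared core)."""
    rng = np.random.default_rng(seed)
    conditions = list(candidates)
    pre = pd.DataFrame(
        {c: [len(candidates[c].get(b, ())) for b in bins] for c in conditions},
        index=pd.Index(bins, name="bin", tupleize_cols=False))
    minima = dict(zip(bins, pre.min(axis=1).to_numpy()))

    selections: dict[str, pd.DataFrame] = {}
    for c in conditions:  # documented order: condition, then bin
        parts = []
        for b in bins:
            cand = candidates[c].get(b)
            m = int(minima.get(b, 0))
            if cand is None or len(cand) == 0 or m == 0:
                continue
            take = rng.choice(len(cand), size=m, replace=False)
            parts.append(cand.iloc[np.sort(take)])
        selections[c] = (pd.concat(parts, ignore_index=True) if parts
                         else pd.DataFrame(columns=["trial_id", "align_ms", "bin"]))

    post = pd.DataFrame(
        {c: [int(selections[c]["bin"].map(lambda v: v == b).sum())
             for b in bins] for c in conditions},
        index=pd.Index(bins, name="bin", tupleize_cols=False))
    out = MatchedEventSet(kind=kind, spec=spec_dict, seed=seed,
                          selections=selections, pre_counts=pre,
                          post_counts=post)
    out.assert_matched()
    return out


def event_positions(
    session: SessionData,
    events: pd.DataFrame,
    before_window_ms: tuple[float, float] = (-60.0, 0.0),
) -> pd.DataFrame:
    """Average eye position in the pre-event window for each aligned event.

    ``events`` needs ``trial_id`` and ``align_ms``; adds ``x_deg``/``y_deg``
    columns (NaN when the window has no samples inside the trace).
    """
    out = events.copy()
    xs, ys = [], []
    for ev in events.itertuples():
        trace = session.eye[int(ev.trial_id)]
        t = trace.times_ms - float(ev.align_ms)
        m = (t >= before_window_ms[0]) & (t < before_window_ms[1])
        xs.append(float(trace.x[m].mean()) if m.any() else np.nan)
        ys.append(float(trace.y[m].mean()) if m.any() else np.nan)
    out["x_deg"] = xs
    out["y_deg"] = ys
    return out
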