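"""Binned, z-normalized, event-aligned firing rates and unit screening.

Spike counts are taken in non-overlapping 20-ms half-open bins.  Each
unit's counts are z-scored with the mean and population SD of its binned
counts across all trials and conditions of the normalization span (by
default -100 to 1000 ms around patch onset); the constants are stored so
event-aligned data can be expressed on the same scale.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import RateSpec
from .core import (AlignedRates, BinnedCounts, NormalizedRateMatrix,
                   SessionData)
from .eye import compute_velocity

log = logging.getLogger(__name__)


def bin_edges(window_ms: tuple[float, float], bin_ms: float) -> np.ndarray:
    """Uniform half-open bin edges covering the window."""
    lo, hi = window_ms
    n = int(round((hi - lo) / bin_ms))
    return lo + np.arange(n + 1) * bin_ms


def count_in_bins(spike_times: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Spike counts in half-open bins [a, b); spikes at the last edge fall out."""
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    t = np.asarray(spike_times, dtype=float)
    if t.size and not np.all(np.isfinite(t)):
        raise ValueError("spike times must be finite")
    idx = np.searchsorted(edges, t, side="right") - 1
    ok = (idx >= 0) & (idx < edges.size - 1) & (t < edges[-1])
    return np.bincount(idx[ok], minlength=edges.size - 1)


def bin_spikes(session: SessionData, edges: np.ndarray,
               trial_ids: list[int] | None = None,
               alignment: str = "patch_onset") -> BinnedCounts:
    """Bin every unit x trial of a session on a common edge grid."""
    edges = np.asarray(edges, dtype=float)
    trial_ids = list(trial_ids if trial_ids is not None
                     else session.trials["trial_id"])
    units = session.unit_ids
    counts = np.zeros((len(units), len(trial_ids), edges.size - 1), dtype=int)
    for i, u in enumerate(units):
        per_trial = session.spikes[u]
        for j, tr in enumerate(trial_ids):
            counts[i, j] = count_in_bins(per_trial.get(tr, np.empty(0)), edges)
    return BinnedCounts(counts=counts, unit_ids=units, trial_ids=trial_ids,
                        bin_edges=edges, alignment=alignment)


def zscore_normalize(binned: BinnedCounts,
                     norm_window_ms: tuple[float, float] | None = None
                     ) -> NormalizedRateMatrix:
    """Z-score each unit's counts with mean/SD over the normalization span.

    The normalization sample is every bin fully inside ``norm_window_ms``
    (all trials and conditions); units with zero SD are excluded with a
    logged reason and do not appear in the output.
    """
    edges = binned.bin_edges
    if norm_window_ms is None:
        sel = np.ones(edges.size - 1, dtype=bool)
    else:
        sel = (edges[:-1] >= norm_window_ms[0]) & (edges[1:] <= norm_window_ms[1])
    if sel.sum() < 2 and binned.counts.shape[1] < 2:
        raise ValueError("need >= 2 bins in the normalization sample")

    keep, means, sds, excluded = [], [], [], []
    for i, u in enumerate(binned.unit_ids):
        sample = binned.counts[i][:, sel].astype(float)
        mu = sample.mean()
        sd = sample.std()  # population SD
        if sd <= 0:
            excluded.append({"unit_id": u, "reason": "zero-variance counts"})
            log.warning("unit %s excluded from normalization: zero SD", u)
            continue
        keep.append(i)
        means.append(mu)
        sds.append(sd)
    z = (binned.counts[keep].astype(float)
         - np.asarray(means)[:, None, None]) / np.asarray(sds)[:, None, None]
    return NormalizedRateMatrix(
        z=z, unit_ids=[binned.unit_ids[i] for i in keep],
        trial_ids=binned.trial_ids, bin_edges=edges, alignment=binned.alignment,
        unit_mean=np.asarray(means), unit_sd=np.asarray(sds),
        provenance={"norm_window_ms": norm_window_ms, "excluded": excluded})


def normalize_session(session: SessionData,
                      spec: RateSpec | None = None) -> NormalizedRateMatrix:
    """Patch-onset-aligned z-scored matrix for one session."""
    spec = spec or RateSpec()
    spec.validate()
    edges = bin_edges(spec.norm_window_ms, spec.bin_ms)
    binned = bin_spikes(session, edges)
    return zscore_normalize(binned, spec.norm_window_ms)


def window_mean(z: np.ndarray, edges: np.ndarray,
                window_ms: tuple[float, float]) -> np.ndarray:
    """Mean over the bins fully inside the half-open window.

    Works on the last axis of any z array (matrix or aligned rows); partial
    bins are excluded; an empty selection is an error.
    """
    edges = np.asarray(edges, dtype=float)
    sel = (edges[:-1] >= window_ms[0]) & (edges[1:] <= window_ms[1])
    if not sel.any():
        raise ValueError(f"no bin fully inside window {window_ms}")
    return np.asarray(z)[..., sel].mean(axis=-1)


def align_to_events(
    session: SessionData,
    norm: NormalizedRateMatrix,
    events: pd.DataFrame,
    window_ms: tuple[float, float] = (-200.0, 200.0),
    bin_ms: float = 20.0,
    with_eye_speed: bool = True,
) -> AlignedRates:
    """Event-aligned z-scored counts, one row per (unit, event).

    ``events`` needs columns ``trial_id`` and ``align_ms`` (plus any
    bookkeeping columns, which are carried through).  Counts are re-binned
    relative to each event and converted to z with the unit's stored
    normalization constants.  Events whose window exceeds the trial's
    recorded span are dropped and counted.  The companion ``eye_speed`` is
    the average speed trace over the retained events (binned the same way).
    """
    rel_edges = bin_edges(window_ms, bin_ms)
    spans = {int(r.trial_id): (r.t_start_ms, r.t_end_ms)
             for r in session.trials.itertuples()}
    kept_rows, dropped = [], 0
    for ev in events.itertuples():
        t0 = float(ev.align_ms)
        lo, hi = spans[int(ev.trial_id)]
        if t0 + window_ms[0] < lo or t0 + window_ms[1] > hi:
            dropped += 1
            continue
        kept_rows.append(ev)
    if dropped:
        log.info("align_to_events: dropped %d events crossing trial bounds", dropped)

    n_bins = rel_edges.size - 1
    blocks, index_rows = [], []
    speed_acc = np.zeros(n_bins)
    n_speed = 0
    extra_cols = [c for c in events.columns if c not in ("trial_id", "align_ms")]
    for ev in kept_rows:
        t0 = float(ev.align_ms)
        tr = int(ev.trial_id)
        for ui, u in enumerate(norm.unit_ids):
            counts = count_in_bins(session.spikes[u].get(tr, np.empty(0)) - t0,
                                   rel_edges)
            z = (counts - norm.unit_mean[ui]) / norm.unit_sd[ui]
            blocks.append(z)
            row = {"unit_id": u, "trial_id": tr, "align_ms": t0}
            for c in extra_cols:
                row[c] = getattr(ev, c)
            index_rows.append(row)
        if with_eye_speed:
            trace = session.eye[tr]
            vel = compute_velocity(trace)
            sp = np.hypot(vel.vx, vel.vy)
            t_rel = trace.times_ms - t0
            bi = np.searchsorted(rel_edges, t_rel, side="right") - 1
            ok = (bi >= 0) & (bi < n_bins) & (t_rel < rel_edges[-1]) & vel.valid
            sums = np.bincount(bi[ok], weights=sp[ok], minlength=n_bins)
            ns = np.bincount(bi[ok], minlength=n_bins)
            speed_acc += np.where(ns > 0, sums / np.maximum(ns, 1), 0.0)
            n_speed += 1

    z_arr = np.vstack(blocks) if blocks else np.empty((0, n_bins))
    index = pd.DataFrame(index_rows)
    eye_speed = speed_acc / n_speed if (with_eye_speed and n_speed) else None
    return AlignedRates(z=z_arr, index=index, bin_edges=rel_edges,
                        eye_speed=eye_speed, n_dropped=dropped,
                        provenance={"window_ms": window_ms, "bin_ms": bin_ms})


def screen_units(
    session: SessionData,
    alpha: float = 0.01,
    visual_window_ms: tuple[float, float] = (50.0, 150.0),
    baseline_window_ms: tuple[float, float] = (-100.0, 0.0),
    delay_window_ms: tuple[float, float] = (200.0, 1000.0),
) -> pd.DataFrame:
    """Apply the responsiveness and attention-modulation inclusion screens.

    A unit is visually responsive if its spike counts 50-150 ms after patch
    onset differ from baseline (-100 to 0 ms) at p < alpha (two-sided
    rank-sum) on both two-patch trials and in-RF single-patch trials.  It
    is attention modulated if its mean delay-period rate is higher with
    cue-in-RF than cue-out-of-RF on two-patch trials (two-sided rank-sum
    p < alpha plus the sign requirement).  ``included`` is the conjunction.
    """
    trials = session.trials
    two_patch = trials[trials["trial_type"] == "two_patch"]
    single_in = trials[(trials["trial_type"] == "single_patch")
                       & trials["patch_in_rf"]]
    rows = []
    for u in session.unit_ids:
        per_trial = session.spikes[u]

        def counts(tr_ids, window):
            return np.array([
                np.sum((per_trial.get(t, np.empty(0)) >= window[0])
                       & (per_trial.get(t, np.empty(0)) < window[1]))
                for t in tr_ids], dtype=float)

        rec = {"unit_id": u, "p_visual_two_patch": np.nan,
               "p_visual_single_patch": np.nan, "p_attention": np.nan,
               "visually_responsive": False, "attention_modulated": False,
               "screenable": True, "included": False}
        if len(two_patch) == 0 or len(single_in) == 0:
            rec["screenable"] = False
            rows.append(rec)
            continue

        resp_flags = {}
        for key, tr_set in (("two_patch", two_patch), ("single_patch", single_in)):
            evoked = counts(tr_set["trial_id"], visual_window_ms)
            base = counts(tr_set["trial_id"], baseline_window_ms)
            if evoked.std() == 0 and base.std() == 0 and evoked.mean() == base.mean():
                p = 1.0
            else:
                p = sps.mannwhitneyu(evoked, base, alternative="two-sided",
                                     method="asymptotic").pvalue
            rec[f"p_visual_{key}"] = float(p)
            resp_flags[key] = p < alpha
        rec["visually_responsive"] = all(resp_flags.values())

        cue_in = two_patch[two_patch["cue_in_rf"]]
        cue_out = two_patch[~two_patch["cue_in_rf"]]
        if len(cue_in) and len(cue_out):
            dur_s = (delay_window_ms[1] - delay_window_ms[0]) / 1000.0
            r_in = counts(cue_in["trial_id"], delay_window_ms) / dur_s
            r_out = counts(cue_out["trial_id"], delay_window_ms) / dur_s
            if r_in.std() == 0 and r_out.std() == 0 and r_in.mean() == r_out.mean():
                p = 1.0
            else:
                p = sps.mannwhitneyu(r_in, r_out, alternative="two-sided",
                                     method="asymptotic").pvalue
            rec["p_attention"] = float(p)
            rec["attention_modulated"] = bool(p < alpha and r_in.mean() > r_out.mean())
        else:
            rec["screenable"] = False
        rec["included"] = bool(rec["screenable"] and rec["visually_responsive"]
                               and rec["attention_modulated"])
        rows.append(rec)
    return pd.DataFrame(rows)
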