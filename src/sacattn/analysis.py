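"""Attention-modulation analysis surfaces.

Covers: delay-period modulation split by behavioral outcome,
microsaccade-conditioned behavior, the epoch time-course analysis
(classifying trials by microsaccade content of each 100-ms epoch and
measuring normalized rates in the window that follows), the
peri-microsaccadic before/after analysis on timing-matched data, the
single-patch motor control, and the eye-position-matched variant.

All measurements are means of z-scored 20-ms counts; Delta_attention is
cue-in-RF minus cue-out-of-RF, Delta_suppression is after minus before.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import EpochSpec, PositionMatchSpec, RateSpec, TimingMatchSpec
from .core import MatchedEventSet, NormalizedRateMatrix, SessionData
from .eye import relabel_relative_to
from .matching import event_positions, eye_position_match, timing_match
from .spikes import align_to_events, window_mean
from .stats import (binomial_ci, fit_factorial_anova, proportion_test,
                    rank_tests, tukey_kramer)

log = logging.getLogger(__name__)

BEFORE_WINDOW_MS = (-60.0, 0.0)
AFTER_WINDOW_MS = (40.0, 100.0)


# ---------------------------------------------------------------------------
# outcome-split delay modulation
# ---------------------------------------------------------------------------

def modulation_by_outcome(
    norm: NormalizedRateMatrix,
    trials: pd.DataFrame,
    delay_window_ms: tuple[float, float] = (200.0, 1000.0),
) -> dict:
    """Per-unit attention modulation on hit vs miss trials, with paired test.

    Delta = mean delay-period z (cue-in-RF) minus (cue-out-of-RF), computed
    separately on hit and miss cue-change trials; units lacking any of the
    four cells are excluded and counted.
    """
    wm = window_mean(norm.z, norm.bin_edges, delay_window_ms)  # units x trials
    tmap = {t: j for j, t in enumerate(norm.trial_ids)}
    tr = trials[(trials["trial_type"] == "two_patch")
                & (trials["change_type"] == "cue")
                & trials["outcome"].isin(["hit", "miss"])]
    cols = {}
    for outcome in ("hit", "miss"):
        for cue_in in (True, False):
            sel = tr[(tr["outcome"] == outcome) & (tr["cue_in_rf"] == cue_in)]
            cols[(outcome, cue_in)] = [tmap[t] for t in sel["trial_id"] if t in tmap]

    rows, excluded = [], 0
    for i, u in enumerate(norm.unit_ids):
        if any(len(cols[k]) == 0 for k in cols):
            excluded += 1
            continue
        d_hit = wm[i, cols[("hit", True)]].mean() - wm[i, cols[("hit", False)]].mean()
        d_miss = wm[i, cols[("miss", True)]].mean() - wm[i, cols[("miss", False)]].mean()
        rows.append({"unit_id": u, "delta_hit": d_hit, "delta_miss": d_miss})
    per_unit = pd.DataFrame(rows)
    if excluded:
        log.info("modulation_by_outcome: %d units lacked an outcome cell", excluded)
    if len(per_unit) >= 2:
        stat, p = rank_tests(per_unit["delta_hit"], per_unit["delta_miss"],
                             paired=True)
    else:
        stat, p = np.nan, np.nan
    return {"per_unit": per_unit, "statistic": stat, "p_value": p,
            "n_excluded": excluded}


# ---------------------------------------------------------------------------
# microsaccade-conditioned behavior
# ---------------------------------------------------------------------------

def behavior_by_microsaccade(
    trials: pd.DataFrame,
    events: pd.DataFrame,
    halfwindow_ms: float = 50.0,
) -> dict:
    """Hit rates and RTs split by microsaccades around the change onset.

    Change-present cue trials are classed by detected onsets within
    +/-``halfwindow_ms`` of the change: none / toward / away (trials with
    both directions are excluded and counted).  Hit rates carry 95%
    Clopper-Pearson intervals; classes are compared pairwise with the
    chi-square proportion test, and RTs of hits with two-sided rank-sum
    tests.
    """
    tr = trials[(trials["trial_type"] == "two_patch")
                & (trials["change_type"] == "cue")
                & trials["outcome"].isin(["hit", "miss"])]
    ev_by_trial = {t: g for t, g in events.groupby("trial_id")}
    classes: dict[int, str] = {}
    n_mixed = 0
    for row in tr.itertuples():
        g = ev_by_trial.get(row.trial_id)
        if g is None:
            classes[row.trial_id] = "none"
            continue
        near = g[(g["onset_ms"] >= row.change_time_ms - halfwindow_ms)
                 & (g["onset_ms"] <= row.change_time_ms + halfwindow_ms)]
        has_t = bool((near["label"] == "toward").any())
        has_a = bool((near["label"] == "away").any())
        if has_t and has_a:
            n_mixed += 1
            classes[row.trial_id] = "mixed"
        elif has_t:
            classes[row.trial_id] = "toward"
        elif has_a:
            classes[row.trial_id] = "away"
        else:
            classes[row.trial_id] = "none"

    tr = tr.assign(msacc=tr["trial_id"].map(classes))
    summary_rows = []
    data = {}
    for cls in ("none", "toward", "away"):
        sub = tr[tr["msacc"] == cls]
        n = len(sub)
        k = int((sub["outcome"] == "hit").sum())
        rts = sub.loc[sub["outcome"] == "hit", "rt_ms"].dropna().to_numpy()
        if n:
            lo, hi = binomial_ci(k, n)
            summary_rows.append({"msacc": cls, "n": n, "hits": k,
                                 "hit_rate": k / n, "ci_lo": lo, "ci_hi": hi,
                                 "rt_mean_ms": rts.mean() if rts.size else np.nan,
                                 "rt_sem_ms": (rts.std(ddof=1) / np.sqrt(rts.size)
                                               if rts.size > 1 else np.nan)})
        else:
            summary_rows.append({"msacc": cls, "n": 0, "hits": 0,
                                 "hit_rate": np.nan, "ci_lo": np.nan,
                                 "ci_hi": np.nan, "rt_mean_ms": np.nan,
                                 "rt_sem_ms": np.nan})
        data[cls] = (k, n, rts)

    pair_rows = []
    for a, b in (("none", "toward"), ("none", "away"), ("toward", "away")):
        ka, na, rta = data[a]
        kb, nb, rtb = data[b]
        if na == 0 or nb == 0:
            pair_rows.append({"a": a, "b": b, "p_hit": np.nan, "p_rt": np.nan,
                              "skipped": True})
            continue
        _, p_hit = proportion_test(ka, na, kb, nb)
        p_rt = (rank_tests(rta, rtb, paired=False)[1]
                if rta.size and rtb.size else np.nan)
        pair_rows.append({"a": a, "b": b, "p_hit": p_hit, "p_rt": p_rt,
                          "skipped": False})
    return {"summary": pd.DataFrame(summary_rows),
            "pairwise": pd.DataFrame(pair_rows), "n_mixed_excluded": n_mixed}


# ---------------------------------------------------------------------------
# epoch time-course analysis
# ---------------------------------------------------------------------------

def classify_epoch_trial(onsets: np.ndarray, labels: np.ndarray,
                         epoch: tuple[float, float]) -> str:
    """Partition rule for one (trial, epoch): none/toward/away/mixed."""
    m = (onsets >= epoch[0]) & (onsets < epoch[1])
    if not m.any():
        return "none"
    has_t = bool(np.any(labels[m] == "toward"))
    has_a = bool(np.any(labels[m] == "away"))
    if has_t and has_a:
        return "mixed"
    return "toward" if has_t else "away"


def epoch_cells(
    norm: NormalizedRateMatrix,
    events: pd.DataFrame,
    trials: pd.DataFrame,
    spec: EpochSpec | None = None,
    measure_offset_ms: float = 0.0,
) -> tuple[pd.DataFrame, dict]:
    """Per-(unit, epoch, attention, microsaccade-class) mean normalized rate.

    For each epoch, trials are classed by their detected onsets inside the
    epoch; the measurement is the mean z in the 100-ms window immediately
    after the epoch (shiftable via ``measure_offset_ms`` for robustness
    sweeps).  Trials containing both directions are excluded and counted.
    """
    spec = spec or EpochSpec()
    spec.validate()
    tr = trials[trials["trial_type"] == "two_patch"]
    tmap = {t: j for j, t in enumerate(norm.trial_ids)}
    ev_by_trial = {t: (g["onset_ms"].to_numpy(), g["label"].to_numpy())
                   for t, g in events.groupby("trial_id")}
    rows = []
    n_mixed = 0
    for ei, epoch in enumerate(spec.epochs_ms):
        win = spec.measurement_window(ei)
        win = (win[0] + measure_offset_ms, win[1] + measure_offset_ms)
        meas = window_mean(norm.z, norm.bin_edges, win)  # units x trials
        cls: dict[str, dict[bool, list[int]]] = {
            m: {True: [], False: []} for m in ("none", "toward", "away")}
        for row in tr.itertuples():
            if row.trial_id not in tmap:
                continue
            on, lab = ev_by_trial.get(row.trial_id, (np.empty(0), np.empty(0)))
            c = classify_epoch_trial(on, lab, epoch)
            if c == "mixed":
                n_mixed += 1
                continue
            cls[c][bool(row.cue_in_rf)].append(tmap[row.trial_id])
        for m in ("none", "toward", "away"):
            for cue_in in (True, False):
                idx = cls[m][cue_in]
                for ui, u in enumerate(norm.unit_ids):
                    rows.append({
                        "unit_id": u, "epoch": ei,
                        "attention": "in" if cue_in else "out", "msacc": m,
                        "mean_z": meas[ui, idx].mean() if idx else np.nan,
                        "n_trials": len(idx)})
    cells = pd.DataFrame(rows)
    return cells, {"n_mixed_excluded": n_mixed}


def complete_units(cells: pd.DataFrame, factors: list[str]) -> pd.DataFrame:
    """Keep only units with a value in every factor cell (logged)."""
    ok_units = []
    n_cells = int(np.prod([cells[f].nunique() for f in factors]))
    for u, g in cells.groupby("unit_id"):
        if g["mean_z"].notna().sum() == n_cells:
            ok_units.append(u)
    dropped = cells["unit_id"].nunique() - len(ok_units)
    if dropped:
        log.info("dropping %d units with incomplete cells before ANOVA", dropped)
    return cells[cells["unit_id"].isin(ok_units)]


def epoch_anova(cells: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Three-factor ANOVA (epoch x attention x microsaccade) + post hoc.

    Observations are unit-level cell means.  The Tukey-Kramer family is the
    full set of cell pairs; the attention contrasts (in vs out within each
    epoch x microsaccade cell) are extracted and flagged significant when
    the adjusted p < alpha and the cue-in mean is higher.
    """
    factors = ["epoch", "attention", "msacc"]
    usable = complete_units(cells, factors)
    anova = fit_factorial_anova(usable.rename(columns={"mean_z": "value"}),
                                factors)
    pairs = []
    for e in anova.levels["epoch"]:
        for m in anova.levels["msacc"]:
            pairs.append(((e, "in", m), (e, "out", m)))
    post = tukey_kramer(anova, comparisons=pairs)
    post["epoch"] = [a[0] for a in post["cell_a"]]
    post["msacc"] = [a[2] for a in post["cell_a"]]
    post["significant"] = (post["p_adj"] < alpha) & (post["diff"] > 0)
    return {"anova": anova, "posthoc": post,
            "n_units": usable["unit_id"].nunique()}


# ---------------------------------------------------------------------------
# peri-microsaccadic analysis (timing-matched)
# ---------------------------------------------------------------------------

def _parse_condition(name: str) -> tuple[str, str | None]:
    if "_" in name:
        m, a = name.rsplit("_", 1)
        return m, a
    return name, None


def perisaccadic_cell_means(
    session: SessionData,
    norm: NormalizedRateMatrix,
    matched: MatchedEventSet,
    rate_spec: RateSpec | None = None,
    before_ms: tuple[float, float] = BEFORE_WINDOW_MS,
    after_ms: tuple[float, float] = AFTER_WINDOW_MS,
) -> dict:
    """Before/after window means per (unit, condition) on matched data.

    Refuses to run without a ``MatchedEventSet`` -- the timing (or
    position) matching control is mandatory for this analysis.  Returns
    per-unit cell means plus the companion average eye-speed trace per
    condition.
    """
    if not isinstance(matched, MatchedEventSet):
        raise ValueError("perisaccadic analysis requires a MatchedEventSet "
                         "(timing/position matching provenance)")
    rate_spec = rate_spec or RateSpec()
    half = rate_spec.align_halfspan_ms
    rows = []
    eye_speed = {}
    for cond, sel in matched.selections.items():
        msacc, attn = _parse_condition(cond)
        if len(sel) == 0:
            eye_speed[cond] = None
            continue
        aligned = align_to_events(session, norm, sel,
                                  window_ms=(-half, half),
                                  bin_ms=rate_spec.bin_ms)
        eye_speed[cond] = aligned.eye_speed
        if not len(aligned.index):
            continue
        before = window_mean(aligned.z, aligned.bin_edges, before_ms)
        after = window_mean(aligned.z, aligned.bin_edges, after_ms)
        idx = aligned.index
        for u, grp in idx.groupby("unit_id"):
            for wname, vals in (("before", before), ("after", after)):
                rows.append({"unit_id": u, "msacc": msacc, "attention": attn,
                             "window": wname,
                             "mean_z": float(vals[grp.index.to_numpy()].mean()),
                             "n_events": len(grp)})
    cells = pd.DataFrame(rows)
    return {"cells": cells, "eye_speed": eye_speed,
            "matched_seed": matched.seed, "matched_kind": matched.kind}


def attention_deltas(cells: pd.DataFrame) -> pd.DataFrame:
    """Delta_attention (in minus out) per unit, microsaccade class, window."""
    piv = cells.pivot_table(index=["unit_id", "msacc", "window"],
                            columns="attention", values="mean_z")
    out = piv.reset_index()
    out["delta_attention"] = out["in"] - out["out"]
    return out.dropna(subset=["delta_attention"])


def suppression_deltas(cells: pd.DataFrame) -> pd.DataFrame:
    """Delta_suppression (after minus before) per unit, class, attention."""
    piv = cells.pivot_table(index=["unit_id", "msacc", "attention"],
                            columns="window", values="mean_z")
    out = piv.reset_index()
    out["delta_suppression"] = out["after"] - out["before"]
    return out.dropna(subset=["delta_suppression"])


def perisaccadic_anovas(cells: pd.DataFrame, alpha: float = 0.05) -> dict:
    """The three peri-microsaccadic ANOVAs on one cell-mean table.

    (1) window x attention x microsaccade on cell means; post hoc attention
    contrasts per (window, msacc) and suppression contrasts per
    (attention, msacc).  (2) window x microsaccade on Delta_attention.
    (3) attention x microsaccade on Delta_suppression.
    """
    out: dict = {}
    base = complete_units(cells, ["msacc", "attention", "window"])
    a1 = fit_factorial_anova(
        base.rename(columns={"mean_z": "value"}),
        ["window", "attention", "msacc"])
    pairs_attn = [((w, "in", m), (w, "out", m))
                  for w in a1.levels["window"] for m in a1.levels["msacc"]]
    pairs_supp = [(("after", a, m), ("before", a, m))
                  for a in a1.levels["attention"] for m in a1.levels["msacc"]]
    post1 = tukey_kramer(a1, comparisons=pairs_attn + pairs_supp)
    post1["contrast"] = (["attention"] * len(pairs_attn)
                         + ["suppression"] * len(pairs_supp))
    sig = np.zeros(len(post1), dtype=bool)
    attn_rows = post1["contrast"] == "attention"
    sig[attn_rows.to_numpy()] = ((post1.loc[attn_rows, "p_adj"] < alpha)
                                 & (post1.loc[attn_rows, "diff"] > 0))
    supp_rows = (post1["contrast"] == "suppression").to_numpy()
    sig[supp_rows] = ((post1.loc[supp_rows, "p_adj"] < alpha)
                      & (post1.loc[supp_rows, "diff"] < 0)).to_numpy()
    post1["significant"] = sig
    out["rates"] = {"anova": a1, "posthoc": post1}

    da = attention_deltas(cells)
    da_c = complete_units(da.rename(columns={"delta_attention": "mean_z"}),
                          ["msacc", "window"]).rename(
        columns={"mean_z": "delta_attention"})
    a2 = fit_factorial_anova(da_c.rename(columns={"delta_attention": "value"}),
                             ["window", "msacc"])
    pairs2 = [(("after", m), ("before", m)) for m in a2.levels["msacc"]]
    post2 = tukey_kramer(a2, comparisons=pairs2)
    post2["significant"] = post2["p_adj"] < alpha
    out["delta_attention"] = {"anova": a2, "posthoc": post2}

    ds = suppression_deltas(cells)
    ds_c = complete_units(ds.rename(columns={"delta_suppression": "mean_z"}),
                          ["msacc", "attention"]).rename(
        columns={"mean_z": "delta_suppression"})
    a3 = fit_factorial_anova(ds_c.rename(columns={"delta_suppression": "value"}),
                             ["attention", "msacc"])
    pairs3 = [(("in", m), ("out", m)) for m in a3.levels["msacc"]]
    post3 = tukey_kramer(a3, comparisons=pairs3)
    post3["significant"] = post3["p_adj"] < alpha
    out["delta_suppression"] = {"anova": a3, "posthoc": post3}
    return out


# ---------------------------------------------------------------------------
# single-patch motor control and eye-position-matched variant
# ---------------------------------------------------------------------------

def motor_control_cell_means(
    session: SessionData,
    norm: NormalizedRateMatrix,
    events: pd.DataFrame,
    timing_spec: TimingMatchSpec | None = None,
    rate_spec: RateSpec | None = None,
    seed: int = 0,
) -> dict:
    """Before/after means on ipsilateral single-patch trials, RF-relative.

    Uses trials whose lone patch is opposite the RF (no stimulus in the
    RF), relabels microsaccades toward/away relative to the RF direction,
    timing-matches the three microsaccade conditions, and computes the same
    before/after window means.
    """
    tr = session.trials
    single = tr[(tr["trial_type"] == "single_patch") & (~tr["patch_in_rf"])]
    if len(single) == 0:
        raise ValueError("no ipsilateral single-patch trials in session")
    ev = events[events["trial_id"].isin(set(single["trial_id"]))]
    ev_rf = relabel_relative_to(ev, session.rf_dir_deg)
    matched = timing_match(ev_rf, single, timing_spec, seed=seed,
                           attention_col=None)
    res = perisaccadic_cell_means(session, norm, matched, rate_spec)
    res["matched"] = matched
    return res


def motor_control_anova(cells: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Window x microsaccade ANOVA for the single-patch motor control."""
    usable = complete_units(cells, ["msacc", "window"])
    anova = fit_factorial_anova(usable.rename(columns={"mean_z": "value"}),
                                ["window", "msacc"])
    pairs = [(("after", m), ("before", m)) for m in anova.levels["msacc"]]
    post = tukey_kramer(anova, comparisons=pairs)
    post["significant"] = post["p_adj"] < alpha
    return {"anova": anova, "posthoc": post}


def position_matched_analysis(
    session: SessionData,
    norm: NormalizedRateMatrix,
    events: pd.DataFrame,
    trials: pd.DataFrame,
    spec: PositionMatchSpec | None = None,
    rate_spec: RateSpec | None = None,
    delay_window_ms: tuple[float, float] = (200.0, 1000.0),
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Eye-position-matched peri-microsaccadic analysis.

    Candidate events are delay-period microsaccades toward/away from the
    cue under each cue condition (four conditions).  Their average eye
    positions in the 'before' window are matched on the spatial grid, and
    the before/after analysis is re-run on the matched sets; the ANOVA has
    factors window x attention x microsaccade-direction (two levels).
    """
    spec = spec or PositionMatchSpec()
    tr = trials[trials["trial_type"] == "two_patch"]
    cue_map = dict(zip(tr["trial_id"], tr["cue_in_rf"]))
    ev = events[events["trial_id"].isin(cue_map)
                & (events["onset_ms"] >= delay_window_ms[0])
                & (events["onset_ms"] < delay_window_ms[1])].copy()
    ev["condition"] = [f"{lab}_{'in' if cue_map[t] else 'out'}"
                       for lab, t in zip(ev["label"], ev["trial_id"])]
    ev = ev.rename(columns={"onset_ms": "align_ms"})
    pos = event_positions(session, ev[["condition", "trial_id", "align_ms"]],
                          spec.before_window_ms).dropna(subset=["x_deg", "y_deg"])
    matched = eye_position_match(pos, spec, seed=seed)
    res = perisaccadic_cell_means(session, norm, matched, rate_spec)
    res["matched"] = matched
    return res


def position_matched_anova(cells: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Window x attention x microsaccade(2) ANOVA on position-matched data."""
    usable = complete_units(cells, ["msacc", "attention", "window"])
    anova = fit_factorial_anova(usable.rename(columns={"mean_z": "value"}),
                                ["window", "attention", "msacc"])
    pairs = [((w, "in", m), (w, "out", m))
             for w in anova.levels["window"] for m in anova.levels["msacc"]]
    post = tukey_kramer(anova, comparisons=pairs)
    post["significant"] = (post["p_adj"] < alpha) & (post["diff"] > 0)
    return {"anova": anova, "posthoc": post}
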