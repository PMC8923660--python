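"""End-to-end orchestration: simulate -> detect -> screen -> match -> analyze.

Each stage is re-runnable from the library functions it wraps; the pipeline
adds seeding, logging of per-stage counts, canonical outputs, and a summary
report.  Every artifact embeds the config hash; a fixed seed reproduces the
whole output tree.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Any

import numpy as np
import pandas as pd

from . import analysis as an
from . import io as sio
from .config import RunConfig
from .core import SessionData
from .eye import detect_session, direction_histogram, microsaccade_probability
from .matching import timing_match
from .spikes import normalize_session, screen_units
from .stats import UnbalancedDesignError
from .synthetic import simulate_experiment

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending ids."""

    def __init__(self, stage: str, msg: str):
        super().__init__(f"[stage {stage}] {msg}")
        self.stage = stage


def _global_ids(df: pd.DataFrame) -> pd.DataFrame:
    """Disambiguate trial ids across sessions for pooled behavioral tables."""
    out = df.copy()
    out["trial_id"] = out["session_id"].astype(str) + ":" + out["trial_id"].astype(str)
    return out


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrapper
    return deco


@_stage("simulate")
def stage_simulate(cfg: RunConfig) -> list[SessionData]:
    sessions = simulate_experiment(cfg.task, cfg.eye, cfg.neuron, cfg.seed,
                                   behavior=cfg.behavior,
                                   units_per_monkey=cfg.units_per_monkey)
    log.info("simulated %d sessions, %d trials, %d units",
             len(sessions), sum(len(s.trials) for s in sessions),
             sum(len(s.unit_ids) for s in sessions))
    return sessions


@_stage("detect")
def stage_detect(cfg: RunConfig, sessions: list[SessionData]) -> dict[str, pd.DataFrame]:
    events = {s.session_id: detect_session(s, cfg.detection) for s in sessions}
    log.info("detected %d microsaccades",
             sum(len(e) for e in events.values()))
    return events


@_stage("screen")
def stage_screen(sessions: list[SessionData]) -> pd.DataFrame:
    parts = []
    for s in sessions:
        df = screen_units(s)
        df.insert(0, "session_id", s.session_id)
        parts.append(df)
    screen = pd.concat(parts, ignore_index=True)
    log.info("screen: %d/%d units included",
             int(screen["included"].sum()), len(screen))
    return screen


def _skip(reason: str) -> dict[str, Any]:
    return {"skipped": True, "reason": reason}


def _factor_ok(df: pd.DataFrame, factors: list[str]) -> str | None:
    for f in factors:
        if df[f].nunique() < 2:
            return f"factor {f!r} has < 2 populated levels"
    return None


def run_pipeline(cfg: RunConfig, outdir: str) -> dict[str, Any]:
    """Run the full pipeline and write all canonical outputs to ``outdir``."""
    cfg.validate()
    os.makedirs(outdir, exist_ok=True)
    chash = cfg.config_hash()
    cfg.to_yaml(os.path.join(outdir, "config.yaml"))
    report: dict[str, Any] = {"config_hash": chash, "seed": cfg.seed,
                              "counts": {}}

    sessions = stage_simulate(cfg)
    events = stage_detect(cfg, sessions)
    all_trials = pd.concat([s.trials for s in sessions], ignore_index=True)
    all_events = pd.concat(
        [e for e in events.values() if len(e)], ignore_index=True) \
        if any(len(e) for e in events.values()) else next(iter(events.values()))
    sio.validate_trials(all_trials)
    if len(all_events):
        sio.validate_microsaccades(all_events)
    all_trials.to_csv(os.path.join(outdir, "trials.csv"), index=False)
    all_events.to_csv(os.path.join(outdir, "microsaccades.csv"), index=False)
    report["counts"]["sessions"] = len(sessions)
    report["counts"]["trials"] = int(len(all_trials))
    report["counts"]["microsaccades"] = int(len(all_events))

    screen = stage_screen(sessions)
    screen.to_csv(os.path.join(outdir, "unit_screen.csv"), index=False)
    report["counts"]["units_total"] = int(len(screen))
    report["counts"]["units_included"] = int(screen["included"].sum())

    # normalized matrices restricted to included units
    norms = {}
    for s in sessions:
        norm = normalize_session(s, cfg.rates)
        inc = set(screen.loc[(screen["session_id"] == s.session_id)
                             & screen["included"], "unit_id"])
        keep = [i for i, u in enumerate(norm.unit_ids) if u in inc]
        norm.z = norm.z[keep]
        norm.unit_mean = norm.unit_mean[keep]
        norm.unit_sd = norm.unit_sd[keep]
        norm.unit_ids = [norm.unit_ids[i] for i in keep]
        norms[s.session_id] = norm

    # microsaccade timing/direction summaries
    g_ev, g_tr = _global_ids(all_events), _global_ids(all_trials)
    try:
        prob = microsaccade_probability(g_ev, g_tr)
        prob.to_csv(os.path.join(outdir, "microsaccade_probability.csv"),
                    index=False)
        report["microsaccade_probability"] = "microsaccade_probability.csv"
    except ValueError as exc:
        report["microsaccade_probability"] = _skip(str(exc))
    hist = direction_histogram(all_events)
    report["direction_histogram"] = {
        "n": hist["n"], "prop_toward": hist["prop_toward"],
        "prop_away": hist["prop_away"], "defined": hist["defined"]}

    # behavior conditioned on microsaccades
    behav = an.behavior_by_microsaccade(g_tr, g_ev,
                                        cfg.behavior.coupling_window_ms)
    behav["summary"].to_csv(os.path.join(outdir, "behavior_by_microsaccade.csv"),
                            index=False)
    report["behavior"] = {
        "summary": behav["summary"].to_dict(orient="records"),
        "pairwise": behav["pairwise"].to_dict(orient="records"),
        "n_mixed_excluded": behav["n_mixed_excluded"]}

    # outcome-split modulation (pooled across sessions)
    mod_parts, mod_p = [], np.nan
    for s in sessions:
        res = an.modulation_by_outcome(norms[s.session_id], s.trials,
                                       cfg.rates.delay_window_ms)
        mod_parts.append(res["per_unit"])
    per_unit = pd.concat([p for p in mod_parts if len(p)], ignore_index=True) \
        if any(len(p) for p in mod_parts) else pd.DataFrame()
    if len(per_unit) >= 2:
        from .stats import rank_tests
        _, mod_p = rank_tests(per_unit["delta_hit"], per_unit["delta_miss"],
                              paired=True)
    per_unit.to_csv(os.path.join(outdir, "modulation_by_outcome.csv"),
                    index=False)
    report["modulation_by_outcome"] = {
        "n_units": int(len(per_unit)), "p_value": float(mod_p)
        if np.isfinite(mod_p) else None,
        "mean_delta_hit": float(per_unit["delta_hit"].mean()) if len(per_unit) else None,
        "mean_delta_miss": float(per_unit["delta_miss"].mean()) if len(per_unit) else None}

    # epoch time-course analysis
    cell_parts = []
    mixed = 0
    for s in sessions:
        cells, info = an.epoch_cells(norms[s.session_id], events[s.session_id],
                                     s.trials, cfg.epochs)
        cell_parts.append(cells)
        mixed += info["n_mixed_excluded"]
    epoch_cells = pd.concat(cell_parts, ignore_index=True)
    epoch_cells.to_csv(os.path.join(outdir, "analysis_cells.csv"), index=False)
    report["counts"]["epoch_mixed_excluded"] = mixed
    populated = epoch_cells.dropna(subset=["mean_z"])
    reason = _factor_ok(populated, ["epoch", "attention", "msacc"])
    if reason is None:
        try:
            res = an.epoch_anova(epoch_cells)
            report["epoch_anova"] = sio.anova_to_dict(res)
            report["epoch_anova"]["n_units"] = res["n_units"]
        except (UnbalancedDesignError, ValueError) as exc:
            report["epoch_anova"] = _skip(str(exc))
    else:
        report["epoch_anova"] = _skip(reason)

    # timing-matched peri-microsaccadic analysis
    seed_root = np.random.SeedSequence(cfg.seed)
    match_seeds = [int(s.generate_state(1)[0] % (2**31))
                   for s in seed_root.spawn(3 * len(sessions))]
    peri_parts, matched_dicts = [], []
    for i, s in enumerate(sessions):
        cued = s.trials[s.trials["trial_type"] == "two_patch"]
        m = timing_match(events[s.session_id], cued, cfg.timing_match,
                         seed=match_seeds[i])
        matched_dicts.append(sio.matched_set_to_dict(m))
        res = an.perisaccadic_cell_means(s, norms[s.session_id], m, cfg.rates)
        peri_parts.append(res["cells"])
    peri_cells = pd.concat([p for p in peri_parts if len(p)],
                           ignore_index=True) if any(len(p) for p in peri_parts) \
        else pd.DataFrame(columns=["unit_id", "msacc", "attention", "window",
                                   "mean_z", "n_events"])
    peri_cells.to_csv(os.path.join(outdir, "perisaccadic_cells.csv"),
                      index=False)
    with open(os.path.join(outdir, "matched_sets.json"), "w") as fh:
        json.dump({"config_hash": chash, "timing": matched_dicts}, fh, indent=1)
    if len(peri_cells) and _factor_ok(peri_cells, ["msacc", "attention",
                                                   "window"]) is None:
        try:
            peri = an.perisaccadic_anovas(peri_cells)
            report["perisaccadic"] = {k: sio.anova_to_dict(v)
                                      for k, v in peri.items()}
        except (UnbalancedDesignError, ValueError) as exc:
            report["perisaccadic"] = _skip(str(exc))
        deltas_a = an.attention_deltas(peri_cells)
        deltas_s = an.suppression_deltas(peri_cells)
        deltas_a.to_csv(os.path.join(outdir, "deltas_attention.csv"), index=False)
        deltas_s.to_csv(os.path.join(outdir, "deltas_suppression.csv"), index=False)
    else:
        report["perisaccadic"] = _skip("no populated microsaccade conditions")

    # single-patch motor control
    mc_parts = []
    for i, s in enumerate(sessions):
        try:
            res = an.motor_control_cell_means(
                s, norms[s.session_id], events[s.session_id],
                cfg.timing_match, cfg.rates,
                seed=match_seeds[len(sessions) + i])
            mc_parts.append(res["cells"])
        except ValueError as exc:
            log.info("motor control skipped for %s: %s", s.session_id, exc)
    mc_cells = pd.concat([p for p in mc_parts if len(p)], ignore_index=True) \
        if any(len(p) for p in mc_parts) else pd.DataFrame()
    if len(mc_cells) and _factor_ok(mc_cells, ["msacc", "window"]) is None:
        try:
            report["motor_control"] = sio.anova_to_dict(
                an.motor_control_anova(mc_cells))
        except (UnbalancedDesignError, ValueError) as exc:
            report["motor_control"] = _skip(str(exc))
    else:
        report["motor_control"] = _skip("no populated motor-control conditions")

    # eye-position-matched variant
    pm_parts = []
    for i, s in enumerate(sessions):
        try:
            res = an.position_matched_analysis(
                s, norms[s.session_id], events[s.session_id], s.trials,
                cfg.position_match, cfg.rates,
                delay_window_ms=cfg.rates.delay_window_ms,
                seed=match_seeds[2 * len(sessions) + i])
            pm_parts.append(res["cells"])
        except (ValueError, KeyError) as exc:
            log.info("position match skipped for %s: %s", s.session_id, exc)
    pm_cells = pd.concat([p for p in pm_parts if len(p)], ignore_index=True) \
        if any(len(p) for p in pm_parts) else pd.DataFrame()
    if len(pm_cells) and _factor_ok(pm_cells, ["msacc", "attention",
                                               "window"]) is None:
        try:
            report["position_matched"] = sio.anova_to_dict(
                an.position_matched_anova(pm_cells))
        except (UnbalancedDesignError, ValueError) as exc:
            report["position_matched"] = _skip(str(exc))
    else:
        report["position_matched"] = _skip("no populated position-matched conditions")

    if cfg.write_hdf5:
        for s in sessions:
            sio.write_session_h5(s, os.path.join(outdir, f"{s.session_id}.h5"))

    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, default=_json_default)
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        v = float(o)
        return v if np.isfinite(v) else None
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, float) and not np.isfinite(o):
        return None
    return str(o)
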