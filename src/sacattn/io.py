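"""Canonical table formats and validation.

Plain CSV tables (trials, units, spikes, microsaccades, rates, screens,
analysis cells) with strict schema checks, JSON for matched-set provenance
and ANOVA tables, and an optional single-file HDF5 mirror for bulky eye
traces.  Conventions: times in ms relative to patch onset, half-open bins,
degrees for positions, angles wrapped to (-180, 180].
"""

from __future__ import annotations

import dataclasses
import json
import os
from typing import Any

import numpy as np
import pandas as pd

from .config import NeuronModel
from .core import (MICROSACCADE_COLUMNS, TRIAL_COLUMNS, EyeTrace, GroundTruth,
                   MatchedEventSet, SessionData)


class SchemaError(ValueError):
    """A table failed validation; the message names columns/rows."""


def _check_columns(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing columns {missing}")


def validate_microsaccades(df: pd.DataFrame) -> None:
    _check_columns(df, MICROSACCADE_COLUMNS, "microsaccades")
    if len(df) == 0:
        return
    rel = df["rel_direction_deg"].to_numpy(dtype=float)
    bad = np.flatnonzero((rel <= -180.0) | (rel > 180.0))
    if bad.size:
        raise SchemaError(
            f"microsaccades: rel_direction_deg outside (-180, 180] at rows "
            f"{bad[:10].tolist()}")
    if (df["offset_ms"] <= df["onset_ms"]).any():
        rows = df.index[df["offset_ms"] <= df["onset_ms"]].tolist()[:10]
        raise SchemaError(f"microsaccades: offset <= onset at rows {rows}")
    bad_lab = ~df["label"].isin(["toward", "away"])
    if bad_lab.any():
        raise SchemaError(
            f"microsaccades: bad labels at rows {df.index[bad_lab].tolist()[:10]}")


def validate_trials(df: pd.DataFrame) -> None:
    _check_columns(df, TRIAL_COLUMNS, "trials")
    if df.duplicated(subset=["session_id", "trial_id"]).any():
        raise SchemaError("trials: duplicate (session_id, trial_id)")


def validate_rates(df: pd.DataFrame) -> None:
    """Long-format rate table: non-overlapping bins per (unit, trial)."""
    _check_columns(df, ["unit_id", "trial_id", "alignment", "bin_start_ms",
                        "bin_end_ms", "z"], "rates")
    for (u, t), g in df.groupby(["unit_id", "trial_id"]):
        g = g.sort_values("bin_start_ms")
        if (g["bin_end_ms"] <= g["bin_start_ms"]).any():
            raise SchemaError(f"rates: empty/inverted bin for unit {u} trial {t}")
        if (g["bin_start_ms"].to_numpy()[1:] < g["bin_end_ms"].to_numpy()[:-1]).any():
            raise SchemaError(f"rates: overlapping bins for unit {u} trial {t}")


# ---------------------------------------------------------------------------
# session round trip
# ---------------------------------------------------------------------------

def write_session(session: SessionData, outdir: str,
                  include_eye: bool = True) -> None:
    """Write one session as canonical CSV tables under ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    session.trials.to_csv(os.path.join(outdir, "trials.csv"), index=False)
    session.units.to_csv(os.path.join(outdir, "units.csv"), index=False)
    spike_rows = []
    for u, per_trial in session.spikes.items():
        for t, times in per_trial.items():
            for ts in times:
                spike_rows.append((session.session_id, u, t, ts))
    pd.DataFrame(spike_rows, columns=["session_id", "unit_id", "trial_id",
                                      "t_ms"]).to_csv(
        os.path.join(outdir, "spikes.csv"), index=False)
    if include_eye:
        parts = []
        for t, trace in session.eye.items():
            parts.append(pd.DataFrame({
                "session_id": session.session_id, "trial_id": t,
                "t_ms": trace.times_ms, "x_deg": trace.x, "y_deg": trace.y}))
        pd.concat(parts, ignore_index=True).to_csv(
            os.path.join(outdir, "eye.csv"), index=False)
    meta = {"session_id": session.session_id, "monkey": session.monkey,
            "rf_dir_deg": session.rf_dir_deg,
            "fs_hz": (next(iter(session.eye.values())).fs_hz
                      if session.eye else None)}
    with open(os.path.join(outdir, "session.json"), "w") as fh:
        json.dump(meta, fh, indent=1)
    if session.ground_truth is not None:
        session.ground_truth.events.to_csv(
            os.path.join(outdir, "true_events.csv"), index=False)


def read_session(indir: str) -> SessionData:
    """Read a session written by :func:`write_session` (eye table required)."""
    with open(os.path.join(indir, "session.json")) as fh:
        meta = json.load(fh)
    trials = pd.read_csv(os.path.join(indir, "trials.csv"))
    validate_trials(trials)
    units = pd.read_csv(os.path.join(indir, "units.csv"))
    spikes_df = pd.read_csv(os.path.join(indir, "spikes.csv"))
    spikes: dict[str, dict[int, np.ndarray]] = {
        u: {} for u in units["unit_id"]}
    for (u, t), g in spikes_df.groupby(["unit_id", "trial_id"]):
        spikes[u][int(t)] = np.sort(g["t_ms"].to_numpy(dtype=float))
    for u in spikes:
        for t in trials["trial_id"]:
            spikes[u].setdefault(int(t), np.empty(0))
    eye: dict[int, EyeTrace] = {}
    eye_path = os.path.join(indir, "eye.csv")
    if os.path.exists(eye_path):
        eye_df = pd.read_csv(eye_path)
        for t, g in eye_df.groupby("trial_id"):
            g = g.sort_values("t_ms")
            eye[int(t)] = EyeTrace(t_start_ms=float(g["t_ms"].iloc[0]),
                                   fs_hz=float(meta["fs_hz"]),
                                   x=g["x_deg"].to_numpy(),
                                   y=g["y_deg"].to_numpy())
    truth = None
    truth_path = os.path.join(indir, "true_events.csv")
    if os.path.exists(truth_path):
        truth = GroundTruth(events=pd.read_csv(truth_path),
                            unit_params=units.copy())
    return SessionData(session_id=meta["session_id"], monkey=meta["monkey"],
                       rf_dir_deg=meta["rf_dir_deg"], trials=trials,
                       units=units, spikes=spikes, eye=eye, ground_truth=truth)


def write_session_h5(session: SessionData, path: str) -> None:
    """Single-file HDF5 mirror of the canonical tables (eye traces included)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["session_id"] = session.session_id
        f.attrs["monkey"] = session.monkey
        f.attrs["rf_dir_deg"] = session.rf_dir_deg
        tg = f.create_group("trials")
        for col in session.trials.columns:
            data = session.trials[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            tg.create_dataset(col, data=data)
        sg = f.create_group("spikes")
        for u, per_trial in session.spikes.items():
            ug = sg.create_group(u)
            for t, times in per_trial.items():
                ug.create_dataset(str(t), data=times)
        eg = f.create_group("eye")
        for t, trace in session.eye.items():
            g = eg.create_group(str(t))
            g.attrs["t_start_ms"] = trace.t_start_ms
            g.attrs["fs_hz"] = trace.fs_hz
            g.create_dataset("x", data=trace.x)
            g.create_dataset("y", data=trace.y)


def rates_to_long(z: np.ndarray, unit_ids: list, trial_ids: list,
                  bin_edges: np.ndarray, alignment: str) -> pd.DataFrame:
    """Flatten a unit x trial x bin matrix to the long rates schema."""
    n_u, n_t, n_b = z.shape
    ui, ti, bi = np.meshgrid(np.arange(n_u), np.arange(n_t), np.arange(n_b),
                             indexing="ij")
    return pd.DataFrame({
        "unit_id": np.asarray(unit_ids)[ui.ravel()],
        "trial_id": np.asarray(trial_ids)[ti.ravel()],
        "alignment": alignment,
        "bin_start_ms": bin_edges[:-1][bi.ravel()],
        "bin_end_ms": bin_edges[1:][bi.ravel()],
        "z": z.ravel(),
    })


def matched_set_to_dict(m: MatchedEventSet) -> dict[str, Any]:
    return {
        "kind": m.kind, "spec": m.spec, "seed": m.seed,
        "pre_counts": {str(k): v for k, v in
                       m.pre_counts.to_dict(orient="index").items()},
        "post_counts": {str(k): v for k, v in
                        m.post_counts.to_dict(orient="index").items()},
        "selections": {c: df.assign(bin=df["bin"].astype(str))
                       .to_dict(orient="list")
                       for c, df in m.selections.items()},
    }


def anova_to_dict(result: dict) -> dict[str, Any]:
    """JSON-ready form of an {'anova': AnovaTable, 'posthoc': df} result."""
    a = result["anova"]
    out = {
        "factors": a.factors,
        "levels": {k: [str(v) for v in lv] for k, lv in a.levels.items()},
        "df_error": a.df_error, "df_total": a.df_total, "mse": a.mse,
        "table": a.table.reset_index().to_dict(orient="records"),
    }
    if "posthoc" in result:
        ph = result["posthoc"].copy()
        for col in ("cell_a", "cell_b"):
            ph[col] = ph[col].map(lambda t: list(map(str, t)))
        out["posthoc"] = ph.to_dict(orient="records")
    return out


def neuron_from_row(row: pd.Series) -> NeuronModel:
    fields = {f.name for f in dataclasses.fields(NeuronModel)}
    return NeuronModel(**{k: row[k] for k in fields if k in row})
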