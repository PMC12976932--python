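"""Session directory readers/writers.

A session on disk is one directory holding:

* ``trajectories.csv`` — frame, t_s, variable, x_px, y_px, valid
* ``spikes.csv``       — frame, neuron_id, count (sparse; zeros omitted)
* ``trials.csv``       — trial_id, start_frame, end_frame, outcome,
                         chosen_prey_id, reward
* ``config.json``      — field size, frame_dt, generator settings
* ``ground_truth.json``— optional planted-population bookkeeping

All CSVs are comma-separated UTF-8 with a header row; floats are written
with 9 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import TRIAL_COLUMNS, Session, SpikeMatrix, Trajectory

FLOAT_FMT = "%.9g"


class SchemaError(ValueError):
    """A session file is missing columns or internally inconsistent."""


def write_session(session: Session, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for v, tr in session.trajectories.items():
        rows.append(
            pd.DataFrame(
                {
                    "frame": tr.frames,
                    "t_s": tr.t,
                    "variable": v,
                    "x_px": tr.x,
                    "y_px": tr.y,
                    "valid": tr.valid.astype(int),
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(
        out / "trajectories.csv", index=False, float_format=FLOAT_FMT
    )

    if session.spikes is not None:
        fr, nid = np.nonzero(session.spikes.counts)
        pd.DataFrame(
            {
                "frame": fr,
                "neuron_id": nid,
                "count": session.spikes.counts[fr, nid],
            }
        ).to_csv(out / "spikes.csv", index=False)

    session.trials.to_csv(out / "trials.csv", index=False)
    cfg = {
        "frame_dt": session.frame_dt,
        "field_width": session.field_size[0],
        "field_height": session.field_size[1],
        "n_neurons": None if session.spikes is None else session.spikes.n_neurons,
        "meta": _jsonable(session.meta),
    }
    (out / "config.json").write_text(json.dumps(cfg, indent=1))
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _require(df: pd.DataFrame, cols: tuple[str, ...], fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{fname}: missing column(s) {missing}")


def read_session(session_dir: str | Path) -> Session:
    """Load a session directory, validating frame alignment across files."""
    d = Path(session_dir)
    traj_df = pd.read_csv(d / "trajectories.csv")
    _require(traj_df, ("frame", "t_s", "variable", "x_px", "y_px", "valid"),
             "trajectories.csv")
    cfg = json.loads((d / "config.json").read_text())

    trajectories: dict[str, Trajectory] = {}
    n_frames = None
    for v, g in traj_df.groupby("variable", sort=False):
        g = g.sort_values("frame")
        frames = g["frame"].to_numpy()
        t = g["t_s"].to_numpy()
        if np.any(np.diff(t) <= 0):
            row = int(np.argmax(np.diff(t) <= 0)) + 1
            raise SchemaError(f"trajectories.csv: non-monotone t_s for "
                              f"{v!r} near row {row}")
        if n_frames is None:
            n_frames = len(frames)
        elif len(frames) != n_frames:
            raise SchemaError(
                f"trajectories.csv: variable {v!r} has {len(frames)} frames, "
                f"expected {n_frames}"
            )
        trajectories[str(v)] = Trajectory(
            variable_id=str(v),
            frames=frames,
            t=t,
            x=g["x_px"].to_numpy(float),
            y=g["y_px"].to_numpy(float),
            valid=g["valid"].to_numpy().astype(bool),
        )
    if n_frames is None:
        raise SchemaError("trajectories.csv: no trajectories found")

    trials = pd.read_csv(d / "trials.csv")
    _require(trials, TRIAL_COLUMNS, "trials.csv")

    spikes = None
    spikes_path = d / "spikes.csv"
    if spikes_path.exists():
        sp = pd.read_csv(spikes_path)
        _require(sp, ("frame", "neuron_id", "count"), "spikes.csv")
        n_neurons = cfg.get("n_neurons")
        if n_neurons is None:
            n_neurons = int(sp["neuron_id"].max()) + 1 if len(sp) else 0
        counts = np.zeros((n_frames, int(n_neurons)), dtype=np.int64)
        if len(sp):
            bad = (sp["frame"] < 0) | (sp["frame"] >= n_frames)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise SchemaError(
                    f"spikes.csv row {row}: frame "
                    f"{int(sp['frame'].iloc[row])} outside session"
                )
            counts[sp["frame"].to_numpy(), sp["neuron_id"].to_numpy()] = (
                sp["count"].to_numpy()
            )
        spikes = SpikeMatrix(counts, float(cfg["frame_dt"]))

    return Session(
        trajectories=trajectories,
        trials=trials,
        spikes=spikes,
        frame_dt=float(cfg["frame_dt"]),
        field_size=(float(cfg["field_width"]), float(cfg["field_height"])),
        meta=cfg.get("meta", {}),
    )
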