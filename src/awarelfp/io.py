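"""On-disk formats and the topographic surface projection.

Layouts: trial tables as CSV, electrode tables as BIDS-iEEG-style TSV,
epochs and gaze as HDF5 (``data[channel, time, trial]`` in uV with the time
axis and an ``fs`` attribute), results as JSON/TSV.  Every file carries a
schema-version tag; readers fail with the offending field and file named.
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import (EpochArray, TRIAL_COLUMNS, ELECTRODE_COLUMNS,
                         validate_trial_table, validate_electrode_table)

SCHEMA_VERSION = "awarelfp-1"

__all__ = [
    "write_trial_table", "read_trial_table", "write_electrode_table",
    "read_electrode_table", "write_epochs", "read_epochs", "write_gaze",
    "read_gaze", "write_json", "read_json", "project_to_surface",
    "make_icosphere",
]


def write_trial_table(trials: pd.DataFrame, path) -> None:
    validate_trial_table(trials)
    cols = TRIAL_COLUMNS + [c for c in trials.columns if c not in TRIAL_COLUMNS]
    trials[cols].to_csv(path, index=False)


def read_trial_table(path) -> pd.DataFrame:
    # 'NA' is a real condition label, not a missing value
    df = pd.read_csv(path, keep_default_na=False,
                     na_values=["", "nan", "NaN"])
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: trial table missing columns {missing}")
    return df


def write_electrode_table(montage: pd.DataFrame, path) -> None:
    validate_electrode_table(montage)
    montage[ELECTRODE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_electrode_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ELECTRODE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: electrode table missing columns {missing}")
    return df


def write_epochs(epochs: EpochArray, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = SCHEMA_VERSION
        f.attrs["fs"] = epochs.fs
        f.attrs["reference"] = epochs.reference
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("time_ms", data=epochs.times)
        f.create_dataset("channels",
                         data=np.array(epochs.channels, dtype="S"))


def read_epochs(path) -> EpochArray:
    with h5py.File(path, "r") as f:
        if "fs" not in f.attrs:
            raise ValueError(f"{path}: missing required attribute 'fs'")
        for key in ("data", "time_ms", "channels"):
            if key not in f:
                raise ValueError(f"{path}: missing required dataset '{key}'")
        return EpochArray(
            f["data"][()], f["time_ms"][()],
            [c.decode() for c in f["channels"][()]],
            float(f.attrs["fs"]),
            str(f.attrs.get("reference", "monopolar")))


def write_gaze(gaze: np.ndarray, gaze_times: np.ndarray, path) -> None:
    """``gaze[trial, time, 2]`` in degrees, time axis stored alongside."""
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = SCHEMA_VERSION
        d = f.create_dataset("gaze", data=gaze)
        d.attrs["units"] = "degrees"
        f.create_dataset("time_ms", data=gaze_times)


def read_gaze(path):
    with h5py.File(path, "r") as f:
        for key in ("gaze", "time_ms"):
            if key not in f:
                raise ValueError(f"{path}: missing required dataset '{key}'")
        return f["gaze"][()], f["time_ms"][()]


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return super().default(o)


def write_json(obj, path) -> None:
    payload = {"schema": SCHEMA_VERSION, "payload": obj}
    Path(path).write_text(json.dumps(payload, cls=_NumpyEncoder, indent=1))


def read_json(path):
    data = json.loads(Path(path).read_text())
    if "payload" not in data:
        raise ValueError(f"{path}: missing 'payload' field")
    return data["payload"]


# ---------------------------------------------------------------------------
# Topographic display
# ---------------------------------------------------------------------------

def project_to_surface(values: np.ndarray, contact_xyz: np.ndarray,
                       vertex_xyz: np.ndarray, radius: float = 15.0) -> np.ndarray:
    """Shepard inverse-square-distance interpolation of contact values onto
    surface vertices.

    Each vertex gets ``sum(w_k v_k) / sum(w_k)`` with ``w_k = 1/d_k^2`` over
    the contacts within ``radius`` mm; contacts farther away contribute
    nothing, a vertex with no contact in range is NaN, and a vertex
    coincident with a contact takes that contact's value exactly.
    """
    values = np.asarray(values, dtype=float)
    contact_xyz = np.atleast_2d(contact_xyz)
    vertex_xyz = np.atleast_2d(vertex_xyz)
    if values.shape[0] != contact_xyz.shape[0]:
        raise ValueError("one value per contact required")
    d = np.linalg.norm(vertex_xyz[:, None, :] - contact_xyz[None, :, :], axis=2)
    out = np.full(vertex_xyz.shape[0], np.nan)
    for v in range(vertex_xyz.shape[0]):
        dv = d[v]
        hit = dv == 0.0
        if hit.any():
            out[v] = values[np.argmax(hit)]
            continue
        near = dv <= radius
        if not near.any():
            continue
        w = 1.0 / dv[near] ** 2
        out[v] = float((w * values[near]).sum() / w.sum())
    return out


def make_icosphere(radius: float = 70.0) -> np.ndarray:
    """Vertices of an icosahedron scaled to ``radius`` mm — a minimal
    synthetic stand-in surface for testing the projection without
    anatomical data."""
    phi = (1 + np.sqrt(5)) / 2
    verts = []
    for a in (-1.0, 1.0):
        for b in (-phi, phi):
            verts += [(0, a, b), (a, b, 0), (b, 0, a)]
    v = np.array(verts)
    return v / np.linalg.norm(v, axis=1, keepdims=True) * radius
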