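"""File formats: HDF5 containers for LFP and grid patterns, CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import GridPattern, LaminarRecording, UnitTable, SPIKE_COLUMNS
from .synthetic import CohortManifest, manifest_from_frame, manifest_to_frame


# --- LFP container: /lfp (channels x samples, µV), /depths (µm), /fs (Hz),
# --- /trial_onsets (s)

def save_recording(path: str | Path, rec: LaminarRecording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("lfp", data=rec.lfp, compression="gzip", compression_opts=4)
        f.create_dataset("depths", data=rec.depths)
        f.create_dataset("fs", data=float(rec.fs))
        f.create_dataset("trial_onsets", data=rec.trial_onsets)
        f.attrs["area"] = rec.area


def load_recording(path: str | Path) -> LaminarRecording:
    with h5py.File(path, "r") as f:
        return LaminarRecording(
            lfp=f["lfp"][()],
            depths=f["depths"][()],
            fs=float(f["fs"][()]),
            trial_onsets=f["trial_onsets"][()],
            area=str(f.attrs.get("area", "V1")),
        )


# --- grid patterns: /values, /depth_axis, /time_axis with a units attribute

def save_pattern(path: str | Path, pattern: GridPattern) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=pattern.values)
        f.create_dataset("depth_axis", data=pattern.depth_axis)
        f.create_dataset("time_axis", data=pattern.time_axis)
        f.attrs["units"] = pattern.units


def load_pattern(path: str | Path) -> GridPattern:
    with h5py.File(path, "r") as f:
        return GridPattern(
            values=f["values"][()],
            depth_axis=f["depth_axis"][()],
            time_axis=f["time_axis"][()],
            units=str(f.attrs.get("units", "")),
        )


# --- manifests and spike tables (CSV)

def save_manifest(path: str | Path, manifest: list[CohortManifest]) -> None:
    manifest_to_frame(manifest).to_csv(path, index=False)


def load_manifest(path: str | Path) -> list[CohortManifest]:
    return manifest_from_frame(pd.read_csv(path))


def save_spikes(path: str | Path, table: UnitTable) -> None:
    table.to_long().to_csv(path, index=False)


def load_spikes(path: str | Path, n_trials: int | None = None) -> UnitTable:
    df = pd.read_csv(path)
    missing = set(SPIKE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"spike CSV missing columns: {sorted(missing)}")
    return UnitTable.from_long(df, n_trials=n_trials)


# --- JSON helpers

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
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def save_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n")


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
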