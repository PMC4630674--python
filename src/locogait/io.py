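"""Track and stride table readers/writers.

Tracks travel as tidy CSV: one row per frame x feature with columns
``trial_id, frame, time_s, feature, x_mm, y_mm, z_mm, quality_flag``, plus a
versioned comment header recording fps, scale and the config hash.  An HDF5
container (same content, one array per feature) is available for speed.
"""

from __future__ import annotations

import io as _io
import logging

import numpy as np
import pandas as pd

from .core import FEATURES, MouseMeta, TrackSet
from .gait import STRIDE_COLUMNS, StrideTable

logger = logging.getLogger(__name__)

TRACK_SCHEMA = ["trial_id", "frame", "time_s", "feature",
                "x_mm", "y_mm", "z_mm", "quality_flag"]
FORMAT_VERSION = 1


def write_tracks(tracks: TrackSet, path: str) -> None:
    """Write a TrackSet as tidy CSV with a versioned header line."""
    rows = []
    times = tracks.times
    for name, arr in tracks.features.items():
        quality = np.where(np.isfinite(arr).all(axis=1), "ok", "gap")
        rows.append(pd.DataFrame({
            "trial_id": tracks.trial_id,
            "frame": np.arange(tracks.n_frames),
            "time_s": times,
            "feature": name,
            "x_mm": arr[:, 0], "y_mm": arr[:, 1], "z_mm": arr[:, 2],
            "quality_flag": quality,
        }))
    df = pd.concat(rows, ignore_index=True)
    header = (f"# locogait-tracks v{FORMAT_VERSION} fps={tracks.fps} "
              f"px_per_mm={tracks.px_per_mm} "
              f"config_hash={tracks.meta.get('config_hash', 'none')}\n")
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.9g")


def read_tracks(path: str) -> list[TrackSet]:
    """Read tidy track CSV; one TrackSet per trial_id found in the file.

    Raises a schema error naming the missing columns; unknown feature names
    are rejected.
    """
    with open(path) as fh:
        first = fh.readline()
        fps, px_per_mm = 400.0, 1.0
        if first.startswith("#"):
            for tok in first.split():
                if tok.startswith("fps="):
                    fps = float(tok[4:])
                elif tok.startswith("px_per_mm="):
                    px_per_mm = float(tok[10:])
            body = fh.read()
        else:
            body = first + fh.read()
    df = pd.read_csv(_io.StringIO(body))
    missing = [c for c in TRACK_SCHEMA if c not in df.columns]
    if missing:
        raise ValueError(f"track file schema error: missing columns {missing}; "
                         f"expected {TRACK_SCHEMA}")
    unknown = set(df["feature"].unique()) - set(FEATURES)
    if unknown:
        raise ValueError(f"unknown feature names: {sorted(unknown)}")

    out = []
    for trial_id, grp in df.groupby("trial_id", sort=False):
        features = {}
        n = int(grp["frame"].max()) + 1
        for name, fgrp in grp.groupby("feature", sort=False):
            arr = np.full((n, 3), np.nan)
            idx = fgrp["frame"].to_numpy(dtype=int)
            arr[idx, 0] = fgrp["x_mm"].to_numpy(dtype=float)
            arr[idx, 1] = fgrp["y_mm"].to_numpy(dtype=float)
            arr[idx, 2] = fgrp["z_mm"].to_numpy(dtype=float)
            features[name] = arr
        out.append(TrackSet(features, fps=fps, px_per_mm=px_per_mm,
                            trial_id=str(trial_id)))
    return out


def write_tracks_hdf5(tracks: TrackSet, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["fps"] = tracks.fps
        fh.attrs["px_per_mm"] = tracks.px_per_mm
        fh.attrs["trial_id"] = tracks.trial_id
        for name, arr in tracks.features.items():
            fh.create_dataset(name, data=arr)


def read_tracks_hdf5(path: str) -> TrackSet:
    import h5py

    with h5py.File(path, "r") as fh:
        features = {name: np.asarray(fh[name]) for name in fh}
        return TrackSet(features, fps=float(fh.attrs["fps"]),
                        px_per_mm=float(fh.attrs["px_per_mm"]),
                        trial_id=str(fh.attrs["trial_id"]))


def write_strides(table: StrideTable, path: str) -> None:
    df = table.data.copy()
    df["subject"] = table.meta.subject_id
    df["weight_g"] = table.meta.weight_g
    df["body_length_mm"] = table.meta.body_length_mm
    with open(path, "w") as fh:
        fh.write(f"# locogait-strides v{FORMAT_VERSION} fps={table.fps}\n")
        df.to_csv(fh, index=False, float_format="%.9g")


def read_strides(path: str) -> StrideTable:
    with open(path) as fh:
        first = fh.readline()
        fps = 400.0
        if first.startswith("#"):
            for tok in first.split():
                if tok.startswith("fps="):
                    fps = float(tok[4:])
            body = fh.read()
        else:
            body = first + fh.read()
    df = pd.read_csv(_io.StringIO(body))
    missing = [c for c in STRIDE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"stride file schema error: missing columns {missing}")
    meta = MouseMeta(
        subject_id=str(df["subject"].iloc[0]) if "subject" in df else "subject",
        weight_g=float(df["weight_g"].iloc[0]) if "weight_g" in df else 20.0,
        body_length_mm=float(df["body_length_mm"].iloc[0])
        if "body_length_mm" in df else 80.0)
    return StrideTable(df[STRIDE_COLUMNS].copy(), meta=meta, fps=fps)
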