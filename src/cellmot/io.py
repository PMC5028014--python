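"""Readers and writers for the pipeline's on-disk formats.

Frames: multi-page TIFF or a directory of numbered PNG/TIFF frames, 8-bit
grayscale.  Tables are plain CSV: tracks as ``track_id,frame,x,y`` (frame
0-based, coordinates in pixels with up to two decimals), contacts as
``frame,id_a,id_b``, clump episodes as ``track_id,enter_frame,exit_frame``,
features as one row per video with the ten canonical columns plus an
optional label (empty cell = undefined feature).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureVector
from .simulate import FEATURE_NAMES
from .tracking import Track

__all__ = [
    "write_frames", "read_frames",
    "write_tracks", "read_tracks",
    "write_contacts", "write_episodes",
    "write_features", "read_features",
]


def write_frames(frames: np.ndarray, path: str | os.PathLike, fmt: str = "tiff") -> None:
    """Write a (T, H, W) uint8 stack as multi-page TIFF (``*.tif`` path) or
    as numbered PNGs in a directory (``fmt="png"``)."""
    path = Path(path)
    if fmt == "tiff":
        import tifffile

        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, np.asarray(frames, dtype=np.uint8))
    elif fmt == "png":
        import imageio.v3 as iio

        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(frames):
            iio.imwrite(path / f"frame_{i:04d}.png", np.asarray(frame, dtype=np.uint8))
    else:
        raise ValueError(f"unknown frame format {fmt!r}")


def read_frames(path: str | os.PathLike) -> np.ndarray:
    """Read frames from a multi-page TIFF or a directory of numbered images."""
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".png", ".tif", ".tiff"))
        if not files:
            raise FileNotFoundError(f"no frames in {path}")
        return np.stack([np.asarray(iio.imread(p)) for p in files])
    import tifffile

    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def write_tracks(tracks, path: str | os.PathLike) -> None:
    """Tracks CSV ``track_id,frame,x,y``; accepts Track objects or a
    ``{id: [(frame, x, y), ...]}`` mapping (e.g. synthetic ground truth)."""
    rows = []
    if isinstance(tracks, dict):
        items = tracks.items()
    else:
        items = ((t.id, t.points) for t in tracks)
    for tid, points in items:
        for f, x, y in points:
            rows.append((tid, f, round(x, 2), round(y, 2)))
    df = pd.DataFrame(rows, columns=["track_id", "frame", "x", "y"])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.2f")


def read_tracks(path: str | os.PathLike) -> list[Track]:
    df = pd.read_csv(path)
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        pts = [(int(f), float(x), float(y))
               for f, x, y in zip(grp["frame"], grp["x"], grp["y"])]
        tracks.append(Track(id=int(tid), points=pts, status="lost"))
    return tracks


def write_contacts(contacts: dict[int, set[tuple[int, int]]], path) -> None:
    rows = [(f, a, b) for f in sorted(contacts) for a, b in sorted(contacts[f])]
    pd.DataFrame(rows, columns=["frame", "id_a", "id_b"]).to_csv(path, index=False)


def write_episodes(episodes, path) -> None:
    rows = [(e.track_id, e.enter_frame, e.exit_frame) for e in episodes]
    pd.DataFrame(rows, columns=["track_id", "enter_frame", "exit_frame"]).to_csv(
        path, index=False)


def write_features(rows: list[tuple[str, FeatureVector, str | None]], path) -> None:
    """Features CSV, one row per video; undefined features become empty cells."""
    records = []
    for video_id, fv, label in rows:
        rec = {"video_id": video_id, **fv.to_dict()}
        rec["label"] = label if label is not None else ""
        records.append(rec)
    df = pd.DataFrame(records, columns=["video_id", *FEATURE_NAMES, "label"])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6f")


def read_features(path) -> pd.DataFrame:
    """Read a features CSV; NaN marks undefined features."""
    return pd.read_csv(path)
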