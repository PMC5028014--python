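"""Distance-transform cell detection and frame-to-frame tracking.

The pipeline per frame: Gaussian blur to suppress noise, fixed-value
thresholding to a binary foreground mask, then a Euclidean distance
transform so that the centres of cells (or groups of cells) score high,
cell edges low, and background exactly 0.  Detection picks suppressed local
maxima of the distance image; tracking follows each cell by maximising the
distance image weighted by a Gaussian centred on the previous location.
Duplicate tracks are pruned and detection re-runs at regular intervals to
pick up cells that appear or were lost.

Coordinates are 0-based pixel centres with x = column, y = row, origin at
the top-left corner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "DetectionParams",
    "TrackingParams",
    "Track",
    "LOST",
    "preprocess_frame",
    "detect_cells",
    "track_step",
    "prune_duplicates",
    "run_tracking",
]

#: Sentinel returned by :func:`track_step` when a cell cannot be followed.
LOST = None


@dataclass(frozen=True)
class DetectionParams:
    """Preprocessing and detection knobs.

    ``threshold`` is the fixed gray level separating cells from background
    after blurring (pixels strictly above it are foreground).  The default
    of 120 is the midpoint of the synthetic generator's foreground (200) and
    background (40) intensities.  ``suppression_radius`` should be about one
    cell radius; ``min_peak_value`` rejects shallow maxima caused by noise.
    """

    blur_sigma: float = 2.0
    threshold: float = 120.0
    suppression_radius: float = 8.0
    min_peak_value: float = 3.0

    def validate(self, pixel_max: float = 255.0) -> None:
        if min(self.blur_sigma, self.suppression_radius, self.min_peak_value) < 0:
            raise ValueError("detection parameters must be >= 0")
        if not (0 <= self.threshold <= pixel_max):
            raise ValueError("threshold outside pixel-depth range")


@dataclass(frozen=True)
class TrackingParams:
    """Frame-to-frame tracking knobs.

    ``search_halfwidth`` bounds how far a cell may move between frames;
    ``gaussian_sigma`` controls how strongly nearby matches are preferred.
    Sensible defaults are twice / once the expected cell radius.
    """

    search_halfwidth: int = 16
    gaussian_sigma: float = 8.0
    lost_threshold: float = 1.0
    duplicate_radius: float = 8.0
    redetect_interval: int = 10

    def validate(self) -> None:
        if self.search_halfwidth < 1:
            raise ValueError("search_halfwidth must be >= 1")
        if self.redetect_interval < 1:
            raise ValueError("redetect_interval must be >= 1")
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be > 0")


@dataclass
class Track:
    """One cell's trajectory: ordered (frame, x, y) with consecutive frames."""

    id: int
    points: list[tuple[int, float, float]] = field(default_factory=list)
    status: str = "active"  # active | lost | pruned

    @property
    def start_frame(self) -> int:
        return self.points[0][0]

    @property
    def last_frame(self) -> int:
        return self.points[-1][0]

    @property
    def last_position(self) -> tuple[float, float]:
        return self.points[-1][1], self.points[-1][2]

    def age_at(self, frame: int) -> int:
        return frame - self.start_frame

    def position_at(self, frame: int) -> tuple[float, float] | None:
        i = frame - self.start_frame
        if 0 <= i < len(self.points):
            return self.points[i][1], self.points[i][2]
        return None


def preprocess_frame(frame: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Blur, threshold and distance-transform one grayscale frame.

    Returns an array of the same shape where each foreground pixel holds its
    exact Euclidean distance to the nearest background pixel and background
    pixels hold 0.  For a clean hard-edged disk the maximum is at the disk
    centre with value close to the radius.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.size == 0:
        raise ValueError("frame must be a non-empty 2-D grayscale image")
    params.validate()
    blurred = ndimage.gaussian_filter(frame, params.blur_sigma) if params.blur_sigma > 0 else frame
    mask = blurred > params.threshold
    if not mask.any():
        return np.zeros_like(frame)
    if mask.all():
        raise ValueError("no background pixels after thresholding; lower the threshold")
    return ndimage.distance_transform_edt(mask)


def _local_maxima(dist: np.ndarray, min_value: float) -> list[tuple[float, int, int]]:
    """(value, y, x) of pixels >= all 8 neighbours, value >= min_value, > 0."""
    footprint = np.ones((3, 3), dtype=bool)
    maxed = ndimage.maximum_filter(dist, footprint=footprint, mode="constant", cval=0.0)
    mask = (dist == maxed) & (dist >= max(min_value, np.finfo(float).tiny))
    ys, xs = np.nonzero(mask)
    return [(float(dist[y, x]), int(y), int(x)) for y, x in zip(ys, xs)]


def detect_cells(dist: np.ndarray, params: DetectionParams) -> list[tuple[float, float]]:
    """Greedy suppressed-maxima detection on a distance image.

    Local maxima with value >= ``min_peak_value`` are accepted from highest
    to lowest score; a candidate within ``suppression_radius`` of an already
    accepted maximum is discarded.  Ties are broken row-major (smaller y,
    then smaller x), so the result is deterministic and independent of
    traversal order.  Returns (x, y) pairs.
    """
    params.validate()
    cands = _local_maxima(np.asarray(dist, dtype=float), params.min_peak_value)
    cands.sort(key=lambda c: (-c[0], c[1], c[2]))
    accepted: list[tuple[float, float]] = []
    r2 = params.suppression_radius ** 2
    for _v, y, x in cands:
        if all((x - ax) ** 2 + (y - ay) ** 2 > r2 for ax, ay in accepted):
            accepted.append((float(x), float(y)))
    return accepted


def track_step(
    dist: np.ndarray,
    prev: tuple[float, float],
    params: TrackingParams,
) -> tuple[float, float] | None:
    """Follow one cell from ``prev`` into the frame whose distance image is given.

    Over the square window of half-width ``search_halfwidth`` centred on
    ``prev`` (clipped at the field boundary), returns the pixel maximising
    dist(p) * exp(-||p - prev||^2 / (2 sigma^2)); ties break row-major.
    Returns :data:`LOST` when that weighted maximum falls below
    ``lost_threshold`` (e.g. the cell left the field or faded out).
    """
    params.validate()
    dist = np.asarray(dist, dtype=float)
    h, w = dist.shape
    px, py = prev
    cx, cy = int(round(px)), int(round(py))
    hw = params.search_halfwidth
    x0, x1 = max(0, cx - hw), min(w - 1, cx + hw)
    y0, y1 = max(0, cy - hw), min(h - 1, cy + hw)
    if x1 < x0 or y1 < y0:
        return LOST
    window = dist[y0:y1 + 1, x0:x1 + 1]
    yy, xx = np.mgrid[y0:y1 + 1, x0:x1 + 1]
    weight = np.exp(-((xx - px) ** 2 + (yy - py) ** 2) / (2.0 * params.gaussian_sigma ** 2))
    scored = window * weight
    best = scored.max()
    if best < params.lost_threshold:
        return LOST
    iy, ix = np.unravel_index(int(np.argmax(scored)), scored.shape)  # row-major tie-break
    return float(x0 + ix), float(y0 + iy)


def prune_duplicates(tracks: list[Track], frame: int, duplicate_radius: float) -> list[Track]:
    """Resolve tracks that converged onto the same cell.

    Among tracks active at ``frame``, no two retained tracks may lie within
    ``duplicate_radius`` of each other; conflicts keep the longer-lived
    track (lower id on tie).  Discarded tracks get status ``"pruned"``.
    Returns the retained tracks.
    """
    order = sorted(tracks, key=lambda t: (-t.age_at(frame), t.id))
    kept: list[Track] = []
    r2 = duplicate_radius ** 2
    for t in order:
        x, y = t.last_position
        if any((x - k.last_position[0]) ** 2 + (y - k.last_position[1]) ** 2 <= r2
               for k in kept):
            t.status = "pruned"
        else:
            kept.append(t)
    kept.sort(key=lambda t: t.id)
    return kept


def run_tracking(
    frames,
    det: DetectionParams | None = None,
    trk: TrackingParams | None = None,
) -> list[Track]:
    """Track every cell through an ordered frame stack.

    Detection on frame 0 seeds the initial tracks.  Each subsequent frame
    advances every active track with :func:`track_step`, closes lost tracks
    (never revived), prunes duplicates, and every ``redetect_interval``
    frames re-runs detection, seeding a new track for any detection farther
    than ``duplicate_radius`` from all active tracks.

    Returns all tracks (active, lost and pruned) sorted by id.
    """
    det = det or DetectionParams()
    trk = trk or TrackingParams()
    det.validate()
    trk.validate()
    frames = list(frames)
    if len(frames) < 2:
        raise ValueError("need at least two frames to track")
    shape = np.asarray(frames[0]).shape
    for i, f in enumerate(frames):
        if np.asarray(f).shape != shape:
            raise ValueError(f"frame {i} shape {np.asarray(f).shape} != {shape}")

    all_tracks: list[Track] = []
    next_id = 0
    dist0 = preprocess_frame(frames[0], det)
    active: list[Track] = []
    for x, y in detect_cells(dist0, det):
        t = Track(id=next_id, points=[(0, x, y)])
        next_id += 1
        active.append(t)
        all_tracks.append(t)
    active = prune_duplicates(active, 0, trk.duplicate_radius)

    for f in range(1, len(frames)):
        dist = preprocess_frame(frames[f], det)
        survivors: list[Track] = []
        for t in active:
            new = track_step(dist, t.last_position, trk)
            if new is LOST:
                t.status = "lost"
            else:
                t.points.append((f, new[0], new[1]))
                survivors.append(t)
        active = prune_duplicates(survivors, f, trk.duplicate_radius)
        if f % trk.redetect_interval == 0:
            r2 = trk.duplicate_radius ** 2
            for x, y in detect_cells(dist, det):
                if all((x - t.last_position[0]) ** 2 + (y - t.last_position[1]) ** 2 > r2
                       for t in active):
                    t = Track(id=next_id, points=[(f, x, y)])
                    next_id += 1
                    active.append(t)
                    all_tracks.append(t)
    return sorted(all_tracks, key=lambda t: t.id)
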