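"""Synthetic monolayer time-lapse videos with known ground truth.

Emulates the statistical structure of videomicroscopy of adherent cells in
monolayer culture: bright roughly-circular cells on a darker background,
persistent-random-walk motion, transient cell-cell contacts and clumps,
cells leaving the field of view, and optional divisions.  Every generated
scene carries its true trajectories and contact pairs, so trackers and
feature extractors can be validated against an exact answer.

Motion model
------------
Each cell performs a persistent random walk.  Per frame, the heading changes
by a wrapped-normal deviate whose spread is controlled by a single
concentration parameter ``turn_concentration`` (kappa): the deviate is drawn
from N(0, 1/kappa) and wrapped to (-pi, pi].  kappa = 0 degenerates to a
uniform heading change (isotropic walk); kappa = inf gives straight-line
motion.  Step length is drawn per frame from N(speed_mean, speed_sd),
truncated at zero.

An optional pairwise attraction pulls each cell toward the centroid of its
neighbours within three contact radii, producing clumps; an optional
slow-down factor reduces the step length of cells currently in contact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SceneConfig",
    "SceneTruth",
    "FeatureTableConfig",
    "generate_scene",
    "generate_feature_table",
    "FEATURE_NAMES",
]

# Canonical feature order used by every module downstream (one row per video).
FEATURE_NAMES = [
    "avg_migration_speed",
    "post_contact_speed",
    "in_contact_speed",
    "avg_angular_velocity",
    "post_contact_angular_velocity",
    "in_contact_angular_velocity",
    "cohesivity",
    "avg_clump_size",
    "avg_contact_duration",
    "cell_count",
]


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic monolayer scene.

    Defaults emulate a 24 h acquisition at one frame per 5 minutes of an
    untreated, sparsely seeded culture: moderately fast cells (~3.5 px/frame)
    with intermediate directional persistence.
    """

    field_width: int = 512
    field_height: int = 512
    n_frames: int = 288          # 24 h at 5 min/frame
    n_cells: int = 30
    cell_radius_mean: float = 8.0
    cell_radius_sd: float = 1.0
    speed_mean: float = 3.5      # px/frame
    speed_sd: float = 0.5
    turn_concentration: float = 0.6   # 1/sd of wrapped-normal heading change
    clump_attraction: float = 0.0     # px/frame drift toward nearby neighbours
    contact_slowdown: float = 1.0     # speed multiplier while in contact
    foreground_intensity: int = 200
    background_intensity: int = 40
    noise_sd: float = 5.0        # additive Gaussian, gray levels
    division_rate: float = 0.0   # per cell per frame
    contact_radius: float | None = None  # default: 2 * cell_radius_mean
    initial_heading: float | None = None  # fixed start heading for all cells
    seed: int = 0

    def resolved_contact_radius(self) -> float:
        if self.contact_radius is not None:
            return float(self.contact_radius)
        return 2.0 * self.cell_radius_mean

    def validate(self) -> None:
        if self.field_width <= 4 * self.cell_radius_mean or self.field_height <= 4 * self.cell_radius_mean:
            raise ValueError("field dimensions must exceed 4x the mean cell radius")
        if self.foreground_intensity <= self.background_intensity:
            raise ValueError("foreground_intensity must exceed background_intensity")
        for name in ("cell_radius_sd", "speed_sd", "noise_sd", "division_rate",
                     "clump_attraction", "turn_concentration", "speed_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_frames < 1 or self.n_cells < 0:
            raise ValueError("n_frames >= 1 and n_cells >= 0 required")
        expected_area = self.n_cells * math.pi * self.cell_radius_mean ** 2
        if expected_area > 0.5 * self.field_width * self.field_height:
            raise ValueError(
                "overcrowded scene: expected cell area exceeds half the field"
            )


@dataclass
class SceneTruth:
    """A rendered scene plus its exact ground truth.

    ``frames`` is a (n_frames, H, W) uint8 stack.  ``true_tracks`` maps cell
    id to an ordered list of (frame, x, y) with x = column, y = row, 0-based.
    ``true_contacts`` maps frame index to the set of id pairs (a < b) whose
    centre distance is at most the contact radius.  ``exited`` lists ids of
    cells removed after crossing the field boundary.
    """

    frames: np.ndarray
    true_tracks: dict[int, list[tuple[int, float, float]]]
    true_contacts: dict[int, set[tuple[int, int]]]
    exited: set[int] = field(default_factory=set)
    config: SceneConfig | None = None

    def positions_at(self, frame: int) -> list[tuple[int, float, float]]:
        """(id, x, y) of every cell present at ``frame``."""
        out = []
        for cid, pts in self.true_tracks.items():
            for f, x, y in pts:
                if f == frame:
                    out.append((cid, x, y))
                    break
        return out


def _draw_turn(rng: np.random.Generator, kappa: float, size: int) -> np.ndarray:
    """Wrapped-normal heading change; kappa=0 -> uniform, kappa=inf -> 0."""
    if kappa == 0:
        return rng.uniform(-math.pi, math.pi, size)
    if math.isinf(kappa):
        return np.zeros(size)
    dtheta = rng.normal(0.0, 1.0 / kappa, size)
    return np.mod(dtheta + math.pi, 2 * math.pi) - math.pi


def _render_frame(
    positions: np.ndarray,
    radii: np.ndarray,
    cfg: SceneConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Hard-edged filled disks, additive Gaussian noise, 8-bit grayscale."""
    h, w = cfg.field_height, cfg.field_width
    img = np.full((h, w), float(cfg.background_intensity))
    for (x, y), r in zip(positions, radii):
        x0 = max(0, int(math.floor(x - r)))
        x1 = min(w - 1, int(math.ceil(x + r)))
        y0 = max(0, int(math.floor(y - r)))
        y1 = min(h - 1, int(math.ceil(y + r)))
        if x1 < x0 or y1 < y0:
            continue
        yy, xx = np.mgrid[y0:y1 + 1, x0:x1 + 1]
        mask = (xx - x) ** 2 + (yy - y) ** 2 <= r ** 2
        img[y0:y1 + 1, x0:x1 + 1][mask] = cfg.foreground_intensity
    if cfg.noise_sd > 0:
        img += rng.normal(0.0, cfg.noise_sd, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_scene(config: SceneConfig) -> SceneTruth:
    """Simulate a scene and render it; deterministic given ``config.seed``."""
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    w, h = cfg.field_width, cfg.field_height
    r_contact = cfg.resolved_contact_radius()

    # Initial placement: rejection-sample non-overlapping positions.
    pos: list[np.ndarray] = []
    radii: list[float] = []
    margin = 2 * cfg.cell_radius_mean
    for _ in range(cfg.n_cells):
        for _attempt in range(1000):
            p = np.array([rng.uniform(margin, w - 1 - margin),
                          rng.uniform(margin, h - 1 - margin)])
            if all(np.hypot(*(p - q)) > 2 * cfg.cell_radius_mean for q in pos):
                break
        pos.append(p)
        radii.append(max(1.0, rng.normal(cfg.cell_radius_mean, cfg.cell_radius_sd)))
    positions = np.array(pos).reshape(-1, 2)
    radii_arr = np.array(radii)
    if cfg.initial_heading is not None:
        headings = np.full(cfg.n_cells, float(cfg.initial_heading))
    else:
        headings = rng.uniform(-math.pi, math.pi, cfg.n_cells)
    ids = list(range(cfg.n_cells))
    next_id = cfg.n_cells

    tracks: dict[int, list[tuple[int, float, float]]] = {i: [] for i in ids}
    contacts: dict[int, set[tuple[int, int]]] = {}
    exited: set[int] = set()
    frames = np.empty((cfg.n_frames, h, w), dtype=np.uint8)

    for f in range(cfg.n_frames):
        n = len(ids)
        # record truth
        for k, cid in enumerate(ids):
            tracks[cid].append((f, float(positions[k, 0]), float(positions[k, 1])))
        pair_set: set[tuple[int, int]] = set()
        in_contact = np.zeros(n, dtype=bool)
        if n > 1:
            diff = positions[:, None, :] - positions[None, :, :]
            d = np.hypot(diff[..., 0], diff[..., 1])
            close = (d <= r_contact) & ~np.eye(n, dtype=bool)
            in_contact = close.any(axis=1)
            for a in range(n):
                for b in range(a + 1, n):
                    if close[a, b]:
                        pair_set.add((min(ids[a], ids[b]), max(ids[a], ids[b])))
        contacts[f] = pair_set

        frames[f] = _render_frame(positions, radii_arr, cfg, rng)

        if f == cfg.n_frames - 1:
            break

        # advance the walk
        headings = np.mod(headings + _draw_turn(rng, cfg.turn_concentration, n)
                          + math.pi, 2 * math.pi) - math.pi
        speeds = np.maximum(0.0, rng.normal(cfg.speed_mean, cfg.speed_sd, n))
        if cfg.contact_slowdown != 1.0:
            speeds = np.where(in_contact, speeds * cfg.contact_slowdown, speeds)
        step = np.stack([speeds * np.cos(headings), speeds * np.sin(headings)], axis=1)
        if cfg.clump_attraction > 0 and n > 1:
            attract_r = 6.0 * r_contact
            diff = positions[None, :, :] - positions[:, None, :]
            d = np.hypot(diff[..., 0], diff[..., 1])
            near = (d <= attract_r) & (d > 1e-9)
            for k in range(n):
                if near[k].any():
                    centroid = positions[near[k]].mean(axis=0)
                    v = centroid - positions[k]
                    nv = np.hypot(*v)
                    if nv > 1e-9:
                        step[k] += cfg.clump_attraction * v / nv
        positions = positions + step

        # divisions: daughter one radius away at a uniform random angle
        if cfg.division_rate > 0:
            born = rng.random(n) < cfg.division_rate
            for k in np.nonzero(born)[0]:
                ang = rng.uniform(-math.pi, math.pi)
                dpos = positions[k] + radii_arr[k] * np.array([math.cos(ang), math.sin(ang)])
                positions = np.vstack([positions, dpos])
                radii_arr = np.append(radii_arr, radii_arr[k])
                headings = np.append(headings, rng.uniform(-math.pi, math.pi))
                ids.append(next_id)
                tracks[next_id] = []
                next_id += 1

        # remove cells whose centre crossed the boundary
        inside = ((positions[:, 0] >= 0) & (positions[:, 0] <= w - 1)
                  & (positions[:, 1] >= 0) & (positions[:, 1] <= h - 1))
        if not inside.all():
            for k in np.nonzero(~inside)[0]:
                exited.add(ids[k])
            keep = np.nonzero(inside)[0]
            positions = positions[keep]
            radii_arr = radii_arr[keep]
            headings = headings[keep]
            ids = [ids[k] for k in keep]

    tracks = {cid: pts for cid, pts in tracks.items() if pts}
    return SceneTruth(frames=frames, true_tracks=tracks, true_contacts=contacts,
                      exited=exited, config=cfg)


@dataclass(frozen=True)
class FeatureTableConfig:
    """Labelled two-class Gaussian feature tables for classifier experiments.

    Default class means follow the observed treatment trend: the first class
    is control-like (mean speed 3.57 px/frame, mean angular velocity
    1.35 rad/frame), the second emulates a 50 uM ATP culture (2.03 px/frame,
    1.79 rad/frame); the remaining contact features are given plausible,
    mildly separated values.
    """

    n_per_class: int = 12
    class_means: tuple[tuple[float, ...], tuple[float, ...]] = (
        (3.57, 3.2, 2.4, 1.35, 1.40, 1.55, 0.60, 5.4, 6.0, 4.0),
        (2.03, 1.9, 1.4, 1.79, 1.82, 1.90, 0.85, 5.9, 9.0, 6.0),
    )
    class_sds: tuple[tuple[float, ...], tuple[float, ...]] = (
        (0.1,) * 10,
        (0.1,) * 10,
    )
    class_labels: tuple[str, str] = ("control", "treated")
    seed: int = 0

    def validate(self) -> None:
        for vec in (*self.class_means, *self.class_sds):
            if len(vec) != len(FEATURE_NAMES):
                raise ValueError("class mean/sd vectors must have length 10")
        for sds in self.class_sds:
            if any(s < 0 for s in sds):
                raise ValueError("class sds must be >= 0")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")


def generate_feature_table(config: FeatureTableConfig):
    """Draw a labelled feature table; deterministic given ``config.seed``.

    Returns a pandas DataFrame with the ten feature columns in canonical
    order plus a ``label`` column.
    """
    import pandas as pd

    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    labels = []
    for means, sds, lab in zip(config.class_means, config.class_sds, config.class_labels):
        block = rng.normal(np.asarray(means), np.asarray(sds),
                           size=(config.n_per_class, len(FEATURE_NAMES)))
        rows.append(block)
        labels.extend([lab] * config.n_per_class)
    df = pd.DataFrame(np.vstack(rows), columns=FEATURE_NAMES)
    df["label"] = labels
    return df


def with_seed(config: SceneConfig, seed: int) -> SceneConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
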