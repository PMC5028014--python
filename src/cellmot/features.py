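"""The ten per-video motility and contact features.

Kinematics follow the standard trajectory definitions: step speed is the
Euclidean distance between a cell's positions in consecutive frames
(px/frame); the direction of travel is the angle of the displacement
vector; angular velocity — a proxy for (the inverse of) migratory
persistence — is the absolute change of direction between consecutive
steps, wrapped to [0, pi] (rad/frame).

Per-video features pool steps across all tracks (not mean-of-track-means),
so long tracks weigh more; a ``per_track_mean`` switch gives the other
convention.  Features whose defining set is empty (e.g. in-contact speed in
a video with no clumps) are *undefined* and reported as NaN; a documented
imputation to 0 is applied only when feeding the classifier.

Feature order (canonical, used everywhere downstream):

1. avg_migration_speed          6. in_contact_angular_velocity
2. post_contact_speed           7. cohesivity (mean contacts per cell)
3. in_contact_speed             8. avg_clump_size
4. avg_angular_velocity         9. avg_contact_duration
5. post_contact_angular_velocity 10. cell_count (max tracked minus initial)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from .contacts import ContactAnalysis, ContactGraph
from .simulate import FEATURE_NAMES
from .tracking import Track

__all__ = [
    "FeatureVector",
    "step_speeds",
    "step_directions",
    "angular_velocities",
    "kinematic_features",
    "cohesivity",
    "clump_and_count_features",
    "extract_features",
]

#: Marker for features whose defining set is empty.
UNDEFINED = float("nan")


@dataclass
class FeatureVector:
    """The ten features of one video, in canonical order."""

    avg_migration_speed: float
    post_contact_speed: float
    in_contact_speed: float
    avg_angular_velocity: float
    post_contact_angular_velocity: float
    in_contact_angular_velocity: float
    cohesivity: float
    avg_clump_size: float
    avg_contact_duration: float
    cell_count: float

    def to_array(self, impute: float | None = None) -> np.ndarray:
        vals = np.array([getattr(self, f.name) for f in fields(self)], dtype=float)
        if impute is not None:
            vals = np.where(np.isnan(vals), impute, vals)
        return vals

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


assert [f.name for f in fields(FeatureVector)] == FEATURE_NAMES


def step_speeds(track: Track) -> list[float]:
    """Euclidean displacement per consecutive frame pair (px/frame)."""
    pts = track.points
    return [math.hypot(pts[i + 1][1] - pts[i][1], pts[i + 1][2] - pts[i][2])
            for i in range(len(pts) - 1)]


def step_directions(track: Track) -> list[float]:
    """Heading atan2(dy, dx) per step, in (-pi, pi]; NaN for zero steps."""
    pts = track.points
    out = []
    for i in range(len(pts) - 1):
        dx = pts[i + 1][1] - pts[i][1]
        dy = pts[i + 1][2] - pts[i][2]
        out.append(UNDEFINED if dx == 0 and dy == 0 else math.atan2(dy, dx))
    return out


def _wrap_abs(delta: float) -> float:
    """|angle difference| wrapped to [0, pi]."""
    d = abs(delta) % (2 * math.pi)
    return 2 * math.pi - d if d > math.pi else d


def angular_velocities(track: Track) -> list[float]:
    """Absolute change of heading per consecutive step pair, in [0, pi].

    Pairs involving an undefined heading (zero-displacement step) are
    reported as NaN and excluded from all statistics.
    """
    dirs = step_directions(track)
    return [UNDEFINED if (math.isnan(dirs[i]) or math.isnan(dirs[i + 1]))
            else _wrap_abs(dirs[i + 1] - dirs[i])
            for i in range(len(dirs) - 1)]


def _mean_or_undef(values: list[float]) -> float:
    vals = [v for v in values if not math.isnan(v)]
    return float(np.mean(vals)) if vals else UNDEFINED


def kinematic_features(
    tracks: list[Track],
    in_contact: dict[int, set[int]] | None = None,
    post_contact: dict[int, set[int]] | None = None,
    per_track_mean: bool = False,
) -> dict[str, float]:
    """Features 1-6: overall / post-contact / in-contact speed and turning.

    ``in_contact`` and ``post_contact`` map track id to the set of frames
    that are clump-member / post-contact for that track.  A speed step
    (t -> t+1) belongs to the in-contact (post-contact) statistic iff its
    start frame t is in the respective set; a turning value, computed at
    the vertex frame t+1 between two steps, belongs iff that vertex frame
    is in the set.
    """
    in_contact = in_contact or {}
    post_contact = post_contact or {}
    speed_all: list[list[float]] = []
    speed_in: list[list[float]] = []
    speed_post: list[list[float]] = []
    turn_all: list[list[float]] = []
    turn_in: list[list[float]] = []
    turn_post: list[list[float]] = []
    for t in tracks:
        if len(t.points) < 2:
            continue
        sp = step_speeds(t)
        av = angular_velocities(t)
        ic = in_contact.get(t.id, set())
        pc = post_contact.get(t.id, set())
        f0 = t.start_frame
        speed_all.append(sp)
        speed_in.append([s for i, s in enumerate(sp) if f0 + i in ic])
        speed_post.append([s for i, s in enumerate(sp) if f0 + i in pc])
        turn_all.append(av)
        turn_in.append([a for i, a in enumerate(av) if f0 + i + 1 in ic])
        turn_post.append([a for i, a in enumerate(av) if f0 + i + 1 in pc])

    def pool(groups: list[list[float]]) -> float:
        if per_track_mean:
            per = [_mean_or_undef(g) for g in groups if g]
            return _mean_or_undef(per)
        return _mean_or_undef([v for g in groups for v in g])

    return {
        "avg_migration_speed": pool(speed_all),
        "post_contact_speed": pool(speed_post),
        "in_contact_speed": pool(speed_in),
        "avg_angular_velocity": pool(turn_all),
        "post_contact_angular_velocity": pool(turn_post),
        "in_contact_angular_velocity": pool(turn_in),
    }


def cohesivity(graphs: dict[int, ContactGraph] | list[ContactGraph]) -> float:
    """Feature 7: mean over frames of contacts per cell (mean degree).

    Frames with no cells are skipped; undefined if no frame has cells.
    """
    if isinstance(graphs, dict):
        graphs = [graphs[f] for f in sorted(graphs)]
    per_frame = [g.n_contacts_per_cell for g in graphs if g.nodes]
    return _mean_or_undef(per_frame)


def clump_and_count_features(
    analysis: ContactAnalysis,
    tracks: list[Track],
) -> dict[str, float]:
    """Features 8-10: mean clump size, mean clump-contact duration, cell count.

    Mean clump size averages over every clump-frame instance; contact
    duration averages episode lengths in frames; cell count is the maximum
    number of simultaneously tracked cells minus the number tracked in the
    first analysed frame.
    """
    sizes = [len(c) for cl in analysis.clumps.values() for c in cl]
    durations = [ep.duration for ep in analysis.episodes]
    counts: dict[int, int] = {}
    for t in tracks:
        for f, _x, _y in t.points:
            counts[f] = counts.get(f, 0) + 1
    if counts:
        first = counts[min(counts)]
        cell_count = float(max(counts.values()) - first)
    else:
        cell_count = UNDEFINED
    return {
        "avg_clump_size": _mean_or_undef([float(s) for s in sizes]),
        "avg_contact_duration": _mean_or_undef([float(d) for d in durations]),
        "cell_count": cell_count,
    }


def extract_features(
    tracks: list[Track],
    analysis: ContactAnalysis,
    per_track_mean: bool = False,
) -> FeatureVector:
    """Assemble the full ten-feature vector for one video."""
    kin = kinematic_features(
        tracks,
        in_contact={t.id: {f for f, m in analysis.membership.items() if t.id in m}
                    for t in tracks},
        post_contact=analysis.post_contact,
        per_track_mean=per_track_mean,
    )
    rest = clump_and_count_features(analysis, tracks)
    return FeatureVector(
        **kin,
        cohesivity=cohesivity(analysis.graphs),
        **rest,
    )
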