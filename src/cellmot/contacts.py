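"""Contact graphs, clumps and contact episodes derived from point tracks.

Since tracks carry positions only (no cell outlines), two cells are "in
contact" when their centre distance is at most ``contact_radius`` —
by default twice the expected cell radius, i.e. touching disks.  A *clump*
is a connected component of the per-frame contact graph containing at least
``min_clump_size`` cells (default 5, counting the cell itself; a strict
"five others" reading is available via ``count_self=False``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .tracking import Track

__all__ = [
    "ContactParams",
    "ContactGraph",
    "ClumpEpisode",
    "ContactAnalysis",
    "contact_graph",
    "find_clumps",
    "clump_episodes",
    "post_contact_frames",
    "analyse_contacts",
]


@dataclass(frozen=True)
class ContactParams:
    contact_radius: float = 16.0      # px; 2x the expected cell radius
    min_clump_size: int = 5           # cells, including self
    post_contact_window: int = 3      # frames after leaving a clump
    count_self: bool = True           # False: clump needs min_clump_size+1 cells

    def validate(self) -> None:
        if self.contact_radius <= 0:
            raise ValueError("contact_radius must be > 0")
        if self.min_clump_size < 2:
            raise ValueError("min_clump_size must be >= 2")
        if self.post_contact_window < 1:
            raise ValueError("post_contact_window must be >= 1")

    @property
    def effective_clump_size(self) -> int:
        return self.min_clump_size if self.count_self else self.min_clump_size + 1


@dataclass
class ContactGraph:
    """Per-frame contact relation: nodes are track ids, edges are contacts."""

    frame: int
    nodes: list[int]
    edges: list[tuple[int, int]]  # unordered pairs stored (a < b)

    @property
    def n_contacts_per_cell(self) -> float:
        """Mean degree, 2|E| / |V|; raises on an empty frame."""
        if not self.nodes:
            raise ValueError("no cells in frame")
        return 2.0 * len(self.edges) / len(self.nodes)


@dataclass
class ClumpEpisode:
    """A maximal run of consecutive frames a track spends inside clumps."""

    track_id: int
    enter_frame: int
    exit_frame: int  # inclusive

    @property
    def duration(self) -> int:
        return self.exit_frame - self.enter_frame + 1


def contact_graph(positions, params: ContactParams, frame: int = 0) -> ContactGraph:
    """Build the contact graph for one frame from (id, x, y) triples."""
    params.validate()
    positions = list(positions)
    ids = [p[0] for p in positions]
    if len(set(ids)) != len(ids):
        raise ValueError("track ids must be unique within a frame")
    r2 = params.contact_radius ** 2
    edges = []
    for i in range(len(positions)):
        a, xa, ya = positions[i]
        for j in range(i + 1, len(positions)):
            b, xb, yb = positions[j]
            if (xa - xb) ** 2 + (ya - yb) ** 2 <= r2:
                edges.append((min(a, b), max(a, b)))
    return ContactGraph(frame=frame, nodes=sorted(ids), edges=sorted(edges))


def find_clumps(graph: ContactGraph, params: ContactParams) -> list[set[int]]:
    """Connected components of the contact graph with enough members.

    Components smaller than the clump threshold are not clumps.  Returned
    in ascending order of their smallest member id.
    """
    params.validate()
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    g.add_edges_from(graph.edges)
    comps = [set(c) for c in nx.connected_components(g)
             if len(c) >= params.effective_clump_size]
    return sorted(comps, key=min)


def clump_episodes(
    tracks: list[Track],
    membership: dict[int, set[int]],
) -> list[ClumpEpisode]:
    """Maximal consecutive clump-membership runs per track.

    ``membership`` maps frame index to the set of track ids that are clump
    members in that frame.
    """
    episodes: list[ClumpEpisode] = []
    for t in tracks:
        run_start: int | None = None
        prev = None
        for f, _x, _y in t.points:
            member = t.id in membership.get(f, set())
            if member and run_start is None:
                run_start = f
            elif not member and run_start is not None:
                episodes.append(ClumpEpisode(t.id, run_start, prev))
                run_start = None
            prev = f
        if run_start is not None:
            episodes.append(ClumpEpisode(t.id, run_start, t.points[-1][0]))
    episodes.sort(key=lambda e: (e.track_id, e.enter_frame))
    return episodes


def post_contact_frames(
    episode: ClumpEpisode,
    track: Track,
    params: ContactParams,
    membership: dict[int, set[int]] | None = None,
) -> list[int]:
    """Frames of the post-contact window following a clump exit.

    At most ``post_contact_window`` frames immediately after
    ``episode.exit_frame``, truncated where the track ends or the cell
    re-enters a clump; empty if the track ends at the exit frame.
    """
    params.validate()
    frames = []
    for f in range(episode.exit_frame + 1,
                   episode.exit_frame + 1 + params.post_contact_window):
        if f > track.last_frame:
            break
        if membership is not None and track.id in membership.get(f, set()):
            break
        frames.append(f)
    return frames


@dataclass
class ContactAnalysis:
    """All per-frame contact structure for one video, ready for features."""

    graphs: dict[int, ContactGraph]
    clumps: dict[int, list[set[int]]]
    membership: dict[int, set[int]]        # frame -> clump-member track ids
    episodes: list[ClumpEpisode]
    post_contact: dict[int, set[int]] = field(default_factory=dict)  # track -> frames


def analyse_contacts(tracks: list[Track], params: ContactParams) -> ContactAnalysis:
    """Run the full contact analysis over every frame any track covers."""
    params.validate()
    by_frame: dict[int, list[tuple[int, float, float]]] = {}
    for t in tracks:
        for f, x, y in t.points:
            by_frame.setdefault(f, []).append((t.id, x, y))
    graphs: dict[int, ContactGraph] = {}
    clumps: dict[int, list[set[int]]] = {}
    membership: dict[int, set[int]] = {}
    for f in sorted(by_frame):
        g = contact_graph(by_frame[f], params, frame=f)
        graphs[f] = g
        cl = find_clumps(g, params)
        clumps[f] = cl
        membership[f] = set().union(*cl) if cl else set()
    episodes = clump_episodes(tracks, membership)
    track_by_id = {t.id: t for t in tracks}
    post: dict[int, set[int]] = {}
    for ep in episodes:
        fs = post_contact_frames(ep, track_by_id[ep.track_id], params, membership)
        if fs:
            post.setdefault(ep.track_id, set()).update(fs)
    return ContactAnalysis(graphs=graphs, clumps=clumps, membership=membership,
                           episodes=episodes, post_contact=post)
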