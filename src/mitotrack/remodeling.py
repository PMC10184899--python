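"""Sliding-window fission/fusion detection on tracked skeleton frames.

A remodeling event changes which fragment (connected component) a node
belongs to.  Raw per-frame component labels are not comparable across
frames, so labels are first made temporally consistent by propagating them
through the tracking correspondences (a component inherits the label of the
previous-frame component it shares the most tracked nodes with; competing
components keep fresh labels).

For every network edge (u, v) at a window's center, fission is declared
when u and v share a fragment at every frame of the pre-window but their
fragment sets over the post-window are disjoint; fusion uses the
time-reversed criterion (disjoint before, identical after, with the edge
present in the frame after the center).  Requiring persistence over the
half-windows rejects transient segmentation noise.  Nearby same-type events
at one center frame (graph distance < 5 edges) are grouped into a single
event site, and each event carries the size asymmetry of the two fragments
involved: |n1 - n2| / max(n1, n2), 0 for symmetric events and close to 1
for events between a large and a small fragment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .skeleton import SkeletonFrame
from .tracks import NodeTrack

log = logging.getLogger(__name__)

GROUP_MAX_EDGE_DISTANCE = 5  # sites merge when closer than this many edges
DEFAULT_HALF_WINDOW = 2


@dataclass
class RemodelingEvent:
    """A detected fission or fusion event."""

    kind: str                      # 'fission' | 'fusion'
    center_frame: int
    site_frame: int                # frame whose graph holds the event edge
    site_nodes: tuple[int, ...]    # node ids in the site frame
    fragment_sizes: tuple[int, int]  # node counts of the two fragments
    asymmetry: float
    n_edges: int = 1               # constituent edges after grouping


def event_asymmetry(n1: int, n2: int) -> float:
    """Normalized fragment size difference |n1 - n2| / max(n1, n2)."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("fragment sizes must be positive")
    return abs(n1 - n2) / max(n1, n2)


def consecutive_correspondences(tracks: list[NodeTrack], n_frames: int
                                ) -> list[dict[int, int]]:
    """Per consecutive frame pair, the node-id map implied by the tracks."""
    corr: list[dict[int, int]] = [dict() for _ in range(max(n_frames - 1, 0))]
    for t in tracks:
        for a, b in zip(t.entries[:-1], t.entries[1:]):
            if b.frame_index == a.frame_index + 1:
                corr[a.frame_index][a.node_id] = b.node_id
    return corr


def fragment_label_series(frames: list[SkeletonFrame],
                          tracks: list[NodeTrack]
                          ) -> list[dict[int, int]]:
    """Temporally consistent fragment label per node, per frame.

    Within a frame the labels partition the nodes into connected
    components; across frames a component keeps the label of its
    best-overlapping tracked predecessor.
    """
    corr = consecutive_correspondences(tracks, len(frames))
    labels: list[dict[int, int]] = []
    next_label = 0
    for t, frame in enumerate(frames):
        comps = sorted((sorted(c) for c in
                        nx.connected_components(frame.graph)),
                       key=lambda c: c[0])
        assign: dict[int, int] = {}
        if t == 0:
            for comp in comps:
                for v in comp:
                    assign[v] = next_label
                next_label += 1
        else:
            inv = {b: a for a, b in corr[t - 1].items()}
            prev = labels[-1]
            votes: list[tuple[int, dict[int, int]]] = []
            for ci, comp in enumerate(comps):
                count: dict[int, int] = {}
                for v in comp:
                    u = inv.get(v)
                    if u is not None and u in prev:
                        count[prev[u]] = count.get(prev[u], 0) + 1
                votes.append((ci, count))
            # each previous label goes to the component with most votes
            claimed: dict[int, tuple[int, int]] = {}  # label -> (votes, ci)
            for ci, count in votes:
                for lab, n in count.items():
                    if lab not in claimed or (n, -ci) > (claimed[lab][0],
                                                         -claimed[lab][1]):
                        claimed[lab] = (n, ci)
            # a component claiming several labels keeps its best one
            best: dict[int, int] = {}
            for ci, count in votes:
                mine = [lab for lab, (_, c) in claimed.items() if c == ci]
                if mine:
                    best[ci] = max(mine, key=lambda lab: (count[lab], -lab))
            for ci, comp in enumerate(comps):
                lab = best.get(ci)
                if lab is None:
                    lab = next_label
                    next_label += 1
                for v in comp:
                    assign[v] = lab
        labels.append(assign)
    return labels


def _node_frame_series(tracks: list[NodeTrack], n_frames: int
                       ) -> list[dict[int, int]]:
    """Per frame: node id -> track id."""
    out: list[dict[int, int]] = [dict() for _ in range(n_frames)]
    for t in tracks:
        for e in t.entries:
            if 0 <= e.frame_index < n_frames:
                out[e.frame_index][e.node_id] = t.track_id
    return out


def detect_events(frames: list[SkeletonFrame], tracks: list[NodeTrack],
                  half_win_size: int = DEFAULT_HALF_WINDOW,
                  group_sites: bool = True) -> list[RemodelingEvent]:
    """Detect persistent fission and fusion events over a sliding window.

    For each candidate edge both endpoints must be tracked at every frame
    of the +/- half_win_size window around the center; otherwise the edge
    is skipped.  Returns grouped events sorted by (center frame, kind).
    """
    if half_win_size < 1:
        raise ValueError("half_win_size must be >= 1")
    T = len(frames)
    labels = fragment_label_series(frames, tracks)
    node_track = _node_frame_series(tracks, T)
    track_entries: dict[int, dict[int, int]] = {}
    for t in tracks:
        track_entries[t.track_id] = {e.frame_index: e.node_id
                                     for e in t.entries}

    def node_of(track_id: int, f: int) -> int | None:
        return track_entries[track_id].get(f)

    def label_of(track_id: int, f: int) -> int | None:
        v = node_of(track_id, f)
        return labels[f].get(v) if v is not None else None

    h = half_win_size
    events: list[RemodelingEvent] = []
    for c in range(T):
        for kind in ("fission", "fusion"):
            # the window shapes are exact time-reversal duals: h + 1 frames
            # of shared fragment on the joined side of the boundary, h
            # frames of disjoint fragments on the separated side
            if kind == "fission":
                site_f = c
                same_frames = range(c - h, c + 1)
                other_frames = range(c + 1, c + h + 1)
            else:
                site_f = c + 1
                same_frames = range(c + 1, c + h + 2)
                other_frames = range(c + 1 - h, c + 1)
            win = range(min(same_frames.start, other_frames.start),
                        max(same_frames.stop, other_frames.stop))
            if win.start < 0 or win.stop > T:
                continue
            for u, v in frames[site_f].edges:
                tu = node_track[site_f].get(int(u))
                tv = node_track[site_f].get(int(v))
                if tu is None or tv is None or tu == tv:
                    continue
                lu = [label_of(tu, f) for f in win]
                lv = [label_of(tv, f) for f in win]
                if any(x is None for x in lu) or any(x is None for x in lv):
                    log.debug("edge (%d,%d) untracked in window at %d",
                              u, v, c)
                    continue
                lu_map = dict(zip(win, lu))
                lv_map = dict(zip(win, lv))
                if not all(lu_map[f] == lv_map[f] for f in same_frames):
                    continue
                if {lu_map[f] for f in other_frames} & \
                        {lv_map[f] for f in other_frames}:
                    continue
                # fragment sizes on the separated side of the boundary
                sep = c + 1 if kind == "fission" else c
                nu, nv = node_of(tu, sep), node_of(tv, sep)
                sizes = (sum(1 for x in labels[sep].values()
                             if x == labels[sep][nu]),
                         sum(1 for x in labels[sep].values()
                             if x == labels[sep][nv]))
                events.append(RemodelingEvent(
                    kind=kind, center_frame=c, site_frame=site_f,
                    site_nodes=(int(u), int(v)), fragment_sizes=sizes,
                    asymmetry=event_asymmetry(*sizes)))
    if group_sites:
        events = group_event_sites(events, frames)
    return sorted(events, key=lambda e: (e.center_frame, e.kind,
                                         e.site_nodes))


def group_event_sites(events: list[RemodelingEvent],
                      frames: list[SkeletonFrame]) -> list[RemodelingEvent]:
    """Merge same-type, same-center events whose nodes are < 5 edges apart.

    Grouping equals the connected components of the proximity graph over
    events; idempotent.
    """
    out: list[RemodelingEvent] = []
    by_key: dict[tuple[str, int], list[RemodelingEvent]] = {}
    for e in events:
        by_key.setdefault((e.kind, e.center_frame), []).append(e)
    for (kind, c), group in sorted(by_key.items()):
        if len(group) == 1:
            out.extend(group)
            continue
        g = frames[group[0].site_frame].graph
        # distances between event node sets
        prox = nx.Graph()
        prox.add_nodes_from(range(len(group)))
        lengths = {}
        for i, ei in enumerate(group):
            for j in range(i + 1, len(group)):
                ej = group[j]
                dmin = np.inf
                for a in ei.site_nodes:
                    for b in ej.site_nodes:
                        key = (min(a, b), max(a, b))
                        if key not in lengths:
                            try:
                                lengths[key] = nx.shortest_path_length(
                                    g, key[0], key[1])
                            except (nx.NetworkXNoPath, nx.NodeNotFound):
                                lengths[key] = np.inf
                        dmin = min(dmin, lengths[key])
                if dmin < GROUP_MAX_EDGE_DISTANCE:
                    prox.add_edge(i, j)
        for cc in nx.connected_components(prox):
            members = [group[i] for i in sorted(cc)]
            nodes = tuple(sorted({n for e in members for n in e.site_nodes}))
            rep = max(members, key=lambda e: max(e.fragment_sizes))
            out.append(RemodelingEvent(
                kind=kind, center_frame=c, site_frame=members[0].site_frame,
                site_nodes=nodes, fragment_sizes=rep.fragment_sizes,
                asymmetry=rep.asymmetry,
                n_edges=sum(e.n_edges for e in members)))
    return out


def event_site_motility(events: list[RemodelingEvent],
                        node_diffusivity: dict[tuple[int, int], float],
                        rng: np.random.Generator
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Matched diffusivity samples: event-site nodes vs random nodes.

    ``node_diffusivity`` maps (frame index, node id) to a fitted D.  For
    every event node with a known D, one node is drawn uniformly from the
    same frame's mapped nodes, so the two samples are equally sized and
    frame-matched.
    """
    event_sample = []
    random_sample = []
    by_frame: dict[int, list[float]] = {}
    for (f, _), d in node_diffusivity.items():
        by_frame.setdefault(f, []).append(d)
    for e in events:
        pool = by_frame.get(e.site_frame)
        if not pool:
            continue
        for v in e.site_nodes:
            d = node_diffusivity.get((e.site_frame, v))
            if d is None:
                continue
            event_sample.append(d)
            random_sample.append(pool[rng.integers(len(pool))])
    return np.asarray(event_sample), np.asarray(random_sample)
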