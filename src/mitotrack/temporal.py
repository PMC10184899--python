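"""Temporal-network metrics and transport simulation on tracked networks.

A tracked movie is a *temporal network*: the stack of per-frame skeleton
graphs plus the node correspondences produced by tracking.  Two scalar
metrics summarize remodeling per timestep: the temporal intersection
TI_t (fraction of frame-t nodes with a tracked correspondent at t-1; high
TI = consistent network, low TI = heavy remodeling) and the mean degree
difference MDD_t (mean absolute degree change of the linked nodes; high
MDD = nodes connect and disconnect frequently).

Transport is modeled by token diffusion: every node starts with a token
labeled by itself; at each timestep every node duplicates its tokens into
all same-frame neighbors, and tokens ride the tracking correspondences to
the next frame.  A node's global reachability is its final unique-token
count normalized by the number of sources, in (0, 1].  Temporal betweenness
counts, over all sources, targets, and start frames, the fraction of
earliest-arrival time-respecting paths passing through each node, and
node-removal experiments compare reachability before and after deleting the
most central (or random) node identities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .skeleton import SkeletonFrame
from .tracks import NodeTrack

__all__ = [
    "TemporalNetwork",
    "temporal_intersection",
    "mean_degree_difference",
    "simulate_reachability",
    "temporal_betweenness",
    "resilience_experiment",
]


@dataclass
class TemporalNetwork:
    """Frame stack plus per-frame-pair node correspondences.

    ``correspondence[t]`` maps node ids of frame t to node ids of frame
    t+1 and must be a partial bijection; ``identities`` optionally carries
    persistent (gap-closed) node identities per frame, otherwise identities
    are derived by chaining the correspondences.
    """

    frames: list[SkeletonFrame]
    correspondence: list[dict[int, int]]
    identities: list[dict[int, int]] | None = field(default=None)

    def __post_init__(self) -> None:
        if len(self.correspondence) != max(len(self.frames) - 1, 0):
            raise ValueError("need one correspondence per frame pair")
        for t, corr in enumerate(self.correspondence):
            ids_t = set(int(v) for v in self.frames[t].node_ids)
            ids_t1 = set(int(v) for v in self.frames[t + 1].node_ids)
            if not set(corr) <= ids_t or not set(corr.values()) <= ids_t1:
                raise ValueError(f"correspondence {t} references "
                                 "unknown nodes")
            if len(set(corr.values())) != len(corr):
                raise ValueError(f"correspondence {t} is not injective")

    @classmethod
    def from_tracks(cls, frames: list[SkeletonFrame],
                    tracks: list[NodeTrack]) -> "TemporalNetwork":
        """Build correspondences and persistent identities from tracks."""
        T = len(frames)
        corr: list[dict[int, int]] = [dict() for _ in range(T - 1)]
        idents: list[dict[int, int]] = [dict() for _ in range(T)]
        for tr in tracks:
            for e in tr.entries:
                if 0 <= e.frame_index < T:
                    idents[e.frame_index][e.node_id] = tr.track_id
            for a, b in zip(tr.entries[:-1], tr.entries[1:]):
                if b.frame_index == a.frame_index + 1:
                    corr[a.frame_index][a.node_id] = b.node_id
        return cls(frames=frames, correspondence=corr, identities=idents)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def node_identities(self) -> list[dict[int, int]]:
        """Persistent identity per node per frame.

        Uses the stored (gap-closed) identities when available; otherwise
        chains the consecutive correspondences, starting a new identity at
        every uncorresponded node.
        """
        if self.identities is not None:
            return self.identities
        idents: list[dict[int, int]] = []
        next_id = 0
        for t, frame in enumerate(self.frames):
            cur: dict[int, int] = {}
            if t > 0:
                prev = idents[-1]
                for u, v in self.correspondence[t - 1].items():
                    cur[v] = prev[u]
            for v in frame.node_ids:
                if int(v) not in cur:
                    cur[int(v)] = next_id
                    next_id += 1
            idents.append(cur)
        return idents


def temporal_intersection(tn: TemporalNetwork, t: int) -> float:
    """Fraction of frame-t nodes with a correspondent at frame t-1.

    Undefined (nan) for an empty frame.
    """
    if not 1 <= t < tn.n_frames:
        raise IndexError("t must be in [1, n_frames)")
    n_t = len(tn.frames[t])
    if n_t == 0:
        return float("nan")
    linked = len(tn.correspondence[t - 1])
    return linked / n_t


def mean_degree_difference(tn: TemporalNetwork, t: int) -> float:
    """Mean |degree change| of nodes linked between frames t-1 and t.

    Undefined (nan) when no nodes are linked.
    """
    if not 1 <= t < tn.n_frames:
        raise IndexError("t must be in [1, n_frames)")
    corr = tn.correspondence[t - 1]
    if not corr:
        return float("nan")
    f0, f1 = tn.frames[t - 1], tn.frames[t]
    deg0 = dict(zip((int(v) for v in f0.node_ids), f0.degrees))
    deg1 = dict(zip((int(v) for v in f1.node_ids), f1.degrees))
    diffs = [abs(int(deg1[v]) - int(deg0[u])) for u, v in corr.items()]
    return float(np.mean(diffs))


def simulate_reachability(tn: TemporalNetwork) -> dict[int, float]:
    """Token-diffusion global reachability per final-frame node.

    Every node is seeded with its own token at its first appearance; each
    timestep tokens are duplicated into all same-frame neighbors and then
    carried along the tracking correspondence.  Reachability of a node is
    its unique-token count divided by the number of sources.
    """
    if tn.n_frames == 0:
        return {}
    tokens: dict[int, set[int]] = {}
    n_sources = 0
    for t, frame in enumerate(tn.frames):
        for v in frame.node_ids:
            v = int(v)
            if v not in tokens:
                tokens[v] = {n_sources}
                n_sources += 1
        # one synchronous diffusion round within the frame
        new_tokens = {v: set(s) for v, s in tokens.items()}
        for u, v in frame.edges:
            new_tokens[int(v)] |= tokens[int(u)]
            new_tokens[int(u)] |= tokens[int(v)]
        tokens = new_tokens
        if t < tn.n_frames - 1:
            tokens = {v1: tokens[u] for u, v1
                      in tn.correspondence[t].items()}
    return {v: len(s) / n_sources for v, s in tokens.items()}


def _temporal_successors(tn: TemporalNetwork, t: int
                         ) -> dict[int, list[int]]:
    """Successors of frame-t nodes in frame t+1 under diffuse-then-carry."""
    frame = tn.frames[t]
    corr = tn.correspondence[t]
    adj: dict[int, list[int]] = {int(v): [int(v)] for v in frame.node_ids}
    for u, v in frame.edges:
        adj[int(u)].append(int(v))
        adj[int(v)].append(int(u))
    succ: dict[int, list[int]] = {}
    for u, closed_nb in adj.items():
        succ[u] = sorted({corr[w] for w in closed_nb if w in corr})
    return succ


def temporal_betweenness(tn: TemporalNetwork,
                         start_frames: list[int] | None = None,
                         auto_sample_threshold: int = 200
                         ) -> dict[int, float]:
    """Earliest-arrival temporal betweenness per node identity.

    For every start frame, source node, and reachable target identity, the
    fraction of earliest-arrival time-respecting paths passing through
    each intermediate node-time is accumulated (Brandes-style) and summed
    over time per identity.  By default every frame is a start frame;
    above ``auto_sample_threshold`` node-frames only every 5th frame is,
    an explicit approximation knob for large movies.
    """
    idents = tn.node_identities()
    T = tn.n_frames
    if start_frames is None:
        total = sum(len(f) for f in tn.frames)
        step = 5 if total > auto_sample_threshold else 1
        start_frames = list(range(0, max(T - 1, 1), step))
    succs = [_temporal_successors(tn, t) for t in range(T - 1)]
    centrality: dict[int, float] = {i: 0.0
                                    for fr in idents for i in fr.values()}
    for t0 in start_frames:
        for s in tn.frames[t0].node_ids:
            _accumulate_source(tn, idents, succs, int(s), t0, centrality)
    return centrality


def _accumulate_source(tn, idents, succs, s: int, t0: int,
                       centrality: dict[int, float]) -> None:
    T = tn.n_frames
    # sigma[t][v]: number of time-respecting paths from (t0, s) to (t, v)
    sigma: list[dict[int, float]] = [dict() for _ in range(T)]
    sigma[t0][s] = 1.0
    first_arrival: dict[int, int] = {idents[t0][s]: t0}
    targets: list[tuple[int, int, int]] = []  # (t, node, identity)
    for t in range(t0, T - 1):
        if not sigma[t]:
            break
        for v, sv in sigma[t].items():
            for w in succs[t].get(v, ()):
                sigma[t + 1][w] = sigma[t + 1].get(w, 0.0) + sv
        for w in sigma[t + 1]:
            ident = idents[t + 1][w]
            if ident not in first_arrival:
                first_arrival[ident] = t + 1
                targets.append((t + 1, w, ident))
    if not targets:
        return
    is_target: list[set[int]] = [set() for _ in range(T)]
    for t, w, _ in targets:
        is_target[t].add(w)
    # backward dependency accumulation over the layered DAG
    delta: list[dict[int, float]] = [dict() for _ in range(T)]
    last_t = max(t for t, _, _ in targets)
    for t in range(last_t - 1, t0 - 1, -1):
        for v, sv in sigma[t].items():
            acc = 0.0
            for w in succs[t].get(v, ()):
                sw = sigma[t + 1].get(w)
                if not sw:
                    continue
                term = delta[t + 1].get(w, 0.0)
                if w in is_target[t + 1]:
                    term += 1.0
                acc += sv / sw * term
            if acc:
                delta[t][v] = acc
                if not (t == t0 and v == s):
                    centrality[idents[t][v]] += acc


def resilience_experiment(tn: TemporalNetwork,
                          removal_fraction: float = 0.05,
                          mode: str = "central",
                          seed: int | None = None
                          ) -> dict[str, object]:
    """Reachability before and after removing a fraction of node identities.

    ``mode='central'`` removes the identities with the highest temporal
    betweenness; ``mode='random'`` removes uniformly chosen identities.
    Returns the paired reachability distributions and their means.
    """
    if not 0 <= removal_fraction < 1:
        raise ValueError("removal_fraction must be in [0, 1)")
    before = simulate_reachability(tn)
    idents = tn.node_identities()
    all_ids = sorted({i for fr in idents for i in fr.values()})
    n_remove = int(round(removal_fraction * len(all_ids)))
    if n_remove == 0:
        return {"before": before, "after": dict(before), "removed": [],
                "mean_before": float(np.mean(list(before.values()))),
                "mean_after": float(np.mean(list(before.values())))}
    if mode == "central":
        cent = temporal_betweenness(tn)
        ranked = sorted(all_ids, key=lambda i: (-cent.get(i, 0.0), i))
        removed = ranked[:n_remove]
    elif mode == "random":
        rng = np.random.default_rng(seed)
        removed = list(rng.choice(all_ids, size=n_remove, replace=False))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    removed_set = set(int(i) for i in removed)
    reduced = _remove_identities(tn, idents, removed_set)
    after = simulate_reachability(reduced)
    return {"before": before, "after": after, "removed": sorted(removed_set),
            "mean_before": float(np.mean(list(before.values()))),
            "mean_after": (float(np.mean(list(after.values())))
                           if after else float("nan"))}


def _remove_identities(tn: TemporalNetwork, idents, removed: set[int]
                       ) -> TemporalNetwork:
    frames = []
    for t, f in enumerate(tn.frames):
        keep = np.array([idents[t][int(v)] not in removed
                         for v in f.node_ids])
        ids = f.node_ids[keep]
        keep_set = set(int(v) for v in ids)
        edges = np.array([[u, v] for u, v in f.edges
                          if int(u) in keep_set and int(v) in keep_set],
                         dtype=np.int64).reshape(-1, 2)
        frames.append(SkeletonFrame(
            frame_index=f.frame_index, node_ids=ids,
            positions=f.positions[keep], edges=edges,
            frame_interval=f.frame_interval,
            intensity=f.intensity[keep], width=f.width[keep]))
    corr = []
    for t, c in enumerate(tn.correspondence):
        keep_t = {int(v) for v in frames[t].node_ids}
        keep_t1 = {int(v) for v in frames[t + 1].node_ids}
        corr.append({u: v for u, v in c.items()
                     if u in keep_t and v in keep_t1})
    new_idents = [{int(v): idents[t][int(v)] for v in frames[t].node_ids}
                  for t in range(len(frames))]
    return TemporalNetwork(frames=frames, correspondence=corr,
                           identities=new_idents)
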