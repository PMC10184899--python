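"""Skeleton-graph containers for segmented mitochondrial networks.

A *skeleton frame* is one timepoint's full-resolution mitochondrial network:
points discretized along the segmented tubule centerlines ("skeleton nodes"),
each carrying a 3D position in micrometers plus optional fluorescence
intensity and tubular width, connected by the skeleton edge list.  Nodes are
classified by degree: terminal (degree 1), bulk (degree 2), branching
(degree > 2).

The *classic network* is the reduced graph used for topology comparison:
bulk nodes are eliminated and each maximal chain of bulk nodes between two
non-bulk endpoints is collapsed into a single weighted edge whose weight is
the summed Euclidean path length along the chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx

__all__ = [
    "SkeletonFrame",
    "ClassicNetwork",
    "Chain",
    "to_classic_network",
    "node_classes",
]


class SkeletonFormatError(ValueError):
    """Raised for malformed skeleton node/edge tables."""


@dataclass
class SkeletonFrame:
    """One timepoint of a full-resolution mitochondrial skeleton graph.

    Parameters
    ----------
    frame_index : int
        0-based timepoint index.
    node_ids : (n,) int array
        Unique node identifiers.
    positions : (n, 3) float array
        Node coordinates in micrometers.
    edges : (m, 2) int array
        Unordered node-id pairs; stored with first id < second id.
    frame_interval : float
        Acquisition interval between consecutive frames, in seconds.
    intensity, width : (n,) float arrays, optional
        Fluorescence intensity (a.u.) and tubular width (um); default 0.
    """

    frame_index: int
    node_ids: np.ndarray
    positions: np.ndarray
    edges: np.ndarray
    frame_interval: float
    intensity: np.ndarray | None = None
    width: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        n = len(self.node_ids)
        if self.intensity is None:
            self.intensity = np.zeros(n)
        if self.width is None:
            self.width = np.zeros(n)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.width = np.asarray(self.width, dtype=float)
        if self.frame_index < 0:
            raise SkeletonFormatError("frame_index must be >= 0")
        if self.frame_interval <= 0:
            raise SkeletonFormatError("frame_interval must be > 0")
        if len(np.unique(self.node_ids)) != n:
            dup = self.node_ids[np.argmax(np.bincount(
                self.node_ids - self.node_ids.min()))] if n else -1
            raise SkeletonFormatError(f"duplicate node id {dup}")
        if self.positions.shape != (n, 3):
            raise SkeletonFormatError("positions must be (n, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise SkeletonFormatError("non-finite coordinate")
        self._index = {int(v): i for i, v in enumerate(self.node_ids)}
        if self.edges.size:
            for u, v in self.edges:
                if int(u) not in self._index:
                    raise SkeletonFormatError(f"edge endpoint {int(u)} not a node")
                if int(v) not in self._index:
                    raise SkeletonFormatError(f"edge endpoint {int(v)} not a node")
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise SkeletonFormatError("self-loop edge")
            self.edges = np.sort(self.edges, axis=1)
            order = np.lexsort((self.edges[:, 1], self.edges[:, 0]))
            self.edges = self.edges[order]
            if len({(int(u), int(v)) for u, v in self.edges}) != len(self.edges):
                raise SkeletonFormatError("duplicate edge")
        self._graph: nx.Graph | None = None

    # -- basic accessors ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.node_ids)

    def index_of(self, node_id: int) -> int:
        return self._index[int(node_id)]

    def position_of(self, node_id: int) -> np.ndarray:
        return self.positions[self.index_of(node_id)]

    @property
    def graph(self) -> nx.Graph:
        """The frame as a networkx graph (nodes keyed by node id)."""
        if self._graph is None:
            g = nx.Graph()
            g.add_nodes_from(int(v) for v in self.node_ids)
            g.add_edges_from((int(u), int(v)) for u, v in self.edges)
            self._graph = g
        return self._graph

    @property
    def degrees(self) -> np.ndarray:
        """Degree per node, aligned with ``node_ids``."""
        deg = np.zeros(len(self.node_ids), dtype=np.int64)
        for u, v in self.edges:
            deg[self._index[int(u)]] += 1
            deg[self._index[int(v)]] += 1
        return deg

    def edge_lengths(self) -> np.ndarray:
        """Euclidean length of every skeleton edge, um."""
        if not len(self.edges):
            return np.zeros(0)
        a = self.positions[[self._index[int(u)] for u in self.edges[:, 0]]]
        b = self.positions[[self._index[int(v)] for v in self.edges[:, 1]]]
        return np.linalg.norm(a - b, axis=1)


def node_classes(frame: SkeletonFrame) -> np.ndarray:
    """Classify nodes as 'terminal', 'bulk', or 'branching' by degree.

    Degree-0 singletons are reported as 'terminal' (an isolated node is its
    own fragment end).
    """
    deg = frame.degrees
    out = np.where(deg == 2, "bulk", np.where(deg > 2, "branching", "terminal"))
    return out.astype(object)


@dataclass
class Chain:
    """A maximal run of bulk nodes between two non-bulk endpoints.

    ``interior`` lists the eliminated bulk node ids in order from ``u`` to
    ``v``; ``cum_lengths[i]`` is the path length in um from ``u`` to the
    i-th node of the sequence (u, *interior, v).
    """

    u: int
    v: int
    interior: list[int]
    path_length: float
    cum_lengths: np.ndarray

    @property
    def bulk_count(self) -> int:
        return len(self.interior)


@dataclass
class ClassicNetwork:
    """Reduced terminal/branching-node network with weighted chain edges."""

    node_ids: list[int]
    chains: list[Chain]
    # bulk node id -> (chain index, position in the chain's node sequence)
    bulk_location: dict[int, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._adj: dict[int, list[tuple[int, float]]] = {
            int(v): [] for v in self.node_ids}
        for c in self.chains:
            self._adj[c.u].append((c.v, c.path_length))
            self._adj[c.v].append((c.u, c.path_length))
        for v in self._adj:
            self._adj[v].sort()

    @property
    def edges(self) -> list[tuple[int, int, float, int]]:
        """(u, v, path_length, bulk_count) per collapsed chain."""
        return [(c.u, c.v, c.path_length, c.bulk_count) for c in self.chains]

    def neighbors(self, node_id: int) -> list[tuple[int, float]]:
        """Sorted (neighbor, edge weight) pairs; parallel chain edges kept."""
        return self._adj[int(node_id)]

    def __contains__(self, node_id: int) -> bool:
        return int(node_id) in self._adj

    def __len__(self) -> int:
        return len(self.node_ids)


def _chain_from(frame: SkeletonFrame, adj: dict[int, list[int]],
                start: int, first: int, is_bulk: dict[int, bool]) -> Chain:
    """Walk from non-bulk ``start`` through bulk nodes beginning at ``first``."""
    seq = [start]
    prev, cur = start, first
    while is_bulk[cur]:
        seq.append(cur)
        nxt = [w for w in adj[cur] if w != prev]
        if not nxt:  # chain dead-ends on a bulk node: cannot happen (deg 2)
            break
        prev, cur = cur, nxt[0]
    seq.append(cur)
    pos = np.array([frame.position_of(v) for v in seq])
    seg = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    return Chain(u=seq[0], v=seq[-1], interior=seq[1:-1],
                 path_length=float(cum[-1]), cum_lengths=cum)


def to_classic_network(frame: SkeletonFrame) -> ClassicNetwork:
    """Collapse bulk chains of a skeleton frame into weighted classic edges.

    Every maximal chain of degree-2 nodes between two non-bulk endpoints
    becomes one weighted edge carrying the summed Euclidean path length.
    A connected component made entirely of bulk nodes (a pure ring, e.g. a
    mitochondrial toroid) has no non-bulk anchor; the lowest-id ring node and
    the node halfway around are promoted to classic nodes joined by the two
    half-ring edges, so rings are retained rather than dropped.
    """
    deg = frame.degrees
    adj: dict[int, list[int]] = {int(v): [] for v in frame.node_ids}
    for u, v in frame.edges:
        adj[int(u)].append(int(v))
        adj[int(v)].append(int(u))
    for v in adj:
        adj[v].sort()
    is_bulk = {int(v): int(d) == 2 for v, d in zip(frame.node_ids, deg)}

    classic_ids = sorted(v for v in adj if not is_bulk[v])
    chains: list[Chain] = []
    seen: set[tuple] = set()  # chain keys, canonical orientation
    for s in classic_ids:
        for first in adj[s]:
            chain = _chain_from(frame, adj, s, first, is_bulk)
            key_fwd = (chain.u, chain.v, tuple(chain.interior))
            key_rev = (chain.v, chain.u, tuple(reversed(chain.interior)))
            key = min(key_fwd, key_rev)  # each chain found once from each end
            if key in seen:
                continue
            seen.add(key)
            chains.append(chain)

    # pure-bulk rings: components never touched above
    covered = set(classic_ids)
    for c in chains:
        covered.update(c.interior)
    remaining = [v for v in adj if v not in covered]
    rem_set = set(remaining)
    while rem_set:
        anchor = min(rem_set)
        ring = [anchor]
        prev, cur = anchor, adj[anchor][0]
        while cur != anchor:
            ring.append(cur)
            nxt = [w for w in adj[cur] if w != prev][0]
            prev, cur = cur, nxt
        rem_set.difference_update(ring)
        mid = ring[len(ring) // 2]
        mid_idx = ring.index(mid)
        # two half rings anchor..mid and mid..anchor
        for seq in (ring[: mid_idx + 1], ring[mid_idx:] + [anchor]):
            pos = np.array([frame.position_of(v) for v in seq])
            seg = np.linalg.norm(np.diff(pos, axis=0), axis=1)
            cum = np.concatenate([[0.0], np.cumsum(seg)])
            chains.append(Chain(u=seq[0], v=seq[-1], interior=seq[1:-1],
                                path_length=float(cum[-1]), cum_lengths=cum))
        classic_ids.extend([anchor, mid])

    classic_ids = sorted(set(classic_ids))
    bulk_location: dict[int, tuple[int, int]] = {}
    for ci, c in enumerate(chains):
        for pos_in_chain, node in enumerate(c.interior, start=1):
            bulk_location[node] = (ci, pos_in_chain)
    return ClassicNetwork(node_ids=classic_ids, chains=chains,
                          bulk_location=bulk_location)
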