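"""Alignment-based topological dissimilarity between network neighborhoods.

To compare the local topology around two candidate nodes in two classic
networks, each neighborhood is expanded into a *level tree*: a breadth-first
tree rooted at the target node, truncated at a maximum level ``k_level``
(level k holds the nodes whose shortest path to the target has k hops).
Loops are opened by keeping only the first BFS discovery of each node, and
the shallower tree is padded with pseudo-nodes and weight-zero pseudo-edges
so both trees have the same number of nodes at each level.

The two trees are then aligned level by level, from the root upward, by
solving a small linear assignment problem per level.  The node dissimilarity
used as the per-level assignment cost for a real pair (u, v) is

    |deg(u) - deg(v)| + |d(u) - d(v)| + (w_u + w_v) * [parents not aligned]

where deg is the classic-network degree, d the weighted path length from the
target along the tree, and w the weight of the edge to the parent.  A
pseudo-node pairs with a real node at cost d + deg of the real partner, and
with another pseudo-node at cost 0.  The parent-consistency term vanishes
for identical neighborhoods and guarantees that a zero-cost alignment exists
exactly when the two weighted neighborhoods are isomorphic, so the score is
zero only there (ties between indistinguishable siblings would otherwise
scramle parent assignments).

Finally the two distance-weighted adjacency matrices, with rows and columns
ordered by the alignment and pseudo entries set to zero, are subtracted and
the Euclidean (Frobenius) norm of the difference is the topological
dissimilarity score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .skeleton import ClassicNetwork, to_classic_network, SkeletonFrame

__all__ = [
    "LevelTree",
    "extract_level_tree",
    "level_tree_for_node",
    "align_level_trees",
    "tree_dissimilarity",
    "topological_dissimilarity",
    "TopologyScorer",
]


@dataclass
class Level:
    """One BFS level of a level tree (parallel arrays over level nodes)."""

    ids: np.ndarray      # node ids; -1 for pseudo-nodes
    deg: np.ndarray      # classic-network degree (0 for pseudo)
    d: np.ndarray        # weighted path length from the target, um
    w: np.ndarray        # weight of the edge to the parent, um (0 at root)
    parent: np.ndarray   # index into the previous level (-1 at root)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_real(self) -> int:
        return int(np.sum(self.ids >= 0))


@dataclass
class LevelTree:
    """BFS tree of the classic-network neighborhood of one target node."""

    target: int
    levels: list[Level]

    @property
    def k_level(self) -> int:
        return len(self.levels) - 1


def _bfs_tree(start_neighbors, neighbors_of, target: int, target_deg: int,
              k_level: int) -> LevelTree:
    """Generic BFS level-tree builder.

    ``start_neighbors``: (node, weight) list of the target's neighbors.
    ``neighbors_of(v)``: (node, weight) list for any other node; both are
    scanned in ascending node-id order so loop opening and equal-level
    parent choice are deterministic (smallest id / smallest parent wins).
    """
    levels = [Level(ids=np.array([target]), deg=np.array([float(target_deg)]),
                    d=np.zeros(1), w=np.zeros(1),
                    parent=np.array([-1]))]
    visited = {target}
    frontier = [(target, 0.0, 0)]  # (node, d, index in its level)
    cur_neighbors = {target: sorted(start_neighbors)}
    for _ in range(k_level):
        found: dict[int, tuple[float, int, float]] = {}  # id -> (d, parent_idx, w)
        for node, dist, idx in frontier:
            nbrs = cur_neighbors.pop(node, None)
            if nbrs is None:
                nbrs = sorted(neighbors_of(node))
            for nb, w in nbrs:
                if nb in visited:
                    continue
                cand = (dist + w, idx, w)
                # first discovery in ascending (node, parent) order wins;
                # a shorter weighted path through a later parent does not
                # replace it (pure BFS, hop-count levels)
                if nb not in found:
                    found[nb] = cand
        if not found:
            break
        ids = np.array(sorted(found))
        d = np.array([found[i][0] for i in ids])
        parent = np.array([found[i][1] for i in ids])
        w = np.array([found[i][2] for i in ids])
        deg = np.array([float(len(neighbors_of(int(i)))) for i in ids])
        levels.append(Level(ids=ids, deg=deg, d=d, w=w, parent=parent))
        visited.update(int(i) for i in ids)
        frontier = [(int(i), float(dd), k)
                    for k, (i, dd) in enumerate(zip(ids, d))]
    return LevelTree(target=target, levels=levels)


def extract_level_tree(net: ClassicNetwork, target: int,
                       k_level: int) -> LevelTree:
    """Level tree around a classic-network node.

    Raises ``KeyError`` if the target is not a classic node.
    """
    if target not in net:
        raise KeyError(f"node {target} not in classic network")
    if k_level < 1:
        raise ValueError("k_level must be >= 1")
    return _bfs_tree(net.neighbors(target), net.neighbors, int(target),
                     len(net.neighbors(target)), k_level)


def level_tree_for_node(net: ClassicNetwork, node_id: int,
                        k_level: int) -> LevelTree:
    """Level tree for any full-resolution node.

    Terminal/branching nodes are classic nodes and use the classic network
    directly.  A bulk node sits in the interior of a collapsed chain; it is
    inserted as a virtual degree-2 target connected to the chain's two
    endpoint nodes with the partial path lengths as edge weights.
    """
    node_id = int(node_id)
    if node_id in net:
        return extract_level_tree(net, node_id, k_level)
    try:
        ci, pos = net.bulk_location[node_id]
    except KeyError:
        raise KeyError(f"node {node_id} not in classic network") from None
    chain = net.chains[ci]
    d_u = float(chain.cum_lengths[pos])
    d_v = float(chain.path_length - d_u)
    start = [(chain.u, d_u), (chain.v, d_v)]
    return _bfs_tree(start, net.neighbors, node_id, 2, k_level)


def _pad(level: Level, size: int) -> Level:
    """Pad a level with pseudo-nodes (id -1, zero weights, parent 0)."""
    extra = size - len(level)
    if extra <= 0:
        return level
    z = np.zeros(extra)
    return Level(
        ids=np.concatenate([level.ids, -np.ones(extra, dtype=np.int64)]),
        deg=np.concatenate([level.deg, z]),
        d=np.concatenate([level.d, z]),
        w=np.concatenate([level.w, z]),
        parent=np.concatenate([level.parent, np.zeros(extra, dtype=np.int64)]),
    )


def pair_cost_matrix(la: Level, lb: Level, prev_map: np.ndarray) -> np.ndarray:
    """Node-dissimilarity cost between all (padded) slot pairs of one level.

    Real slots come first in each level, so the matrix decomposes into a
    real-real block, two pseudo-real strips, and a zero pseudo-pseudo
    corner.
    """
    na, nb = la.n_real, lb.n_real
    s = len(la)
    cost = np.zeros((s, s))
    if na and nb:
        # real-real: |ddeg| + |dd| + parent-consistency penalty
        dd = np.abs(la.deg[:na, None] - lb.deg[None, :nb])
        dd += np.abs(la.d[:na, None] - lb.d[None, :nb])
        mapped_parent = prev_map[la.parent[:na]]  # A's parents in B slots
        mismatch = mapped_parent[:, None] != lb.parent[None, :nb]
        dd += (la.w[:na, None] + lb.w[None, :nb]) * mismatch
        cost[:na, :nb] = dd
    if s > na and nb:
        cost[na:, :nb] = lb.d[None, :nb] + lb.deg[None, :nb]
    if s > nb and na:
        cost[:na, nb:] = (la.d[:na] + la.deg[:na])[:, None]
    return cost


_EMPTY_LEVEL = Level(ids=np.zeros(0, dtype=np.int64), deg=np.zeros(0),
                     d=np.zeros(0), w=np.zeros(0),
                     parent=np.zeros(0, dtype=np.int64))
_MAP0 = np.zeros(1, dtype=np.int64)


def _align(a: LevelTree, b: LevelTree
           ) -> tuple[list[Level], list[Level], list[np.ndarray], float]:
    """Bottom-up per-level LAP alignment on the unpadded levels.

    Returns the (unpadded) levels, per-level assignment over padded slots
    (``maps[k][i]`` = B slot matched to A slot i), and the total cost.
    """
    depth = max(a.k_level, b.k_level)
    la_levels: list[Level] = []
    lb_levels: list[Level] = []
    maps: list[np.ndarray] = [_MAP0]
    total = 0.0
    prev_map = _MAP0
    for k in range(depth + 1):
        la = a.levels[k] if k <= a.k_level else _EMPTY_LEVEL
        lb = b.levels[k] if k <= b.k_level else _EMPTY_LEVEL
        la_levels.append(la)
        lb_levels.append(lb)
        if k == 0:
            continue
        size = max(len(la), len(lb), 1)
        pla = la if len(la) == size else _pad(la, size)
        plb = lb if len(lb) == size else _pad(lb, size)
        cost = pair_cost_matrix(pla, plb, prev_map)
        rows, cols = linear_sum_assignment(cost)
        m = np.empty(size, dtype=np.int64)
        m[rows] = cols
        total += float(cost[rows, cols].sum())
        maps.append(m)
        prev_map = m
    return la_levels, lb_levels, maps, total


def align_level_trees(a: LevelTree, b: LevelTree
                      ) -> tuple[list[Level], list[Level], list[np.ndarray],
                                 float]:
    """Align two level trees bottom-up, one LAP per level.

    Returns the padded levels of both trees, the per-level assignment
    (``maps[k][i]`` = B slot matched to A slot i), and the total
    alignment cost.
    """
    la_levels, lb_levels, maps, total = _align(a, b)
    pa = [_pad(l, len(m)) for l, m in zip(la_levels, maps)]
    pb = [_pad(l, len(m)) for l, m in zip(lb_levels, maps)]
    return pa, pb, maps, total


def tree_dissimilarity(a: LevelTree, b: LevelTree) -> float:
    """Topological dissimilarity score between two level trees.

    Frobenius norm of the difference of the two distance-weighted adjacency
    matrices after reordering tree B's nodes by the alignment.  Only
    parent-child entries are nonzero, so the norm is accumulated over the
    union of occupied (child, parent) slots.
    """
    la_levels, lb_levels, maps, _ = _align(a, b)
    wa: dict[tuple[int, int], float] = {}
    wb: dict[tuple[int, int], float] = {}
    offset = 0
    prev_offset = 0
    prev_inv = _MAP0
    for k in range(1, len(maps)):
        la, lb, m = la_levels[k], lb_levels[k], maps[k]
        offset = prev_offset + len(maps[k - 1])
        inv = np.empty_like(m)
        inv[m] = np.arange(len(m))
        for i in range(la.n_real):
            wa[(offset + i, prev_offset + la.parent[i])] = la.w[i]
        for j in range(lb.n_real):
            wb[(offset + inv[j],
                prev_offset + prev_inv[lb.parent[j]])] = lb.w[j]
        prev_inv = inv
        prev_offset = offset
    sq = 0.0
    for key in wa.keys() | wb.keys():
        diff = wa.get(key, 0.0) - wb.get(key, 0.0)
        sq += diff * diff
    return float(np.sqrt(2.0 * sq))  # symmetric matrix: each edge twice


def topological_dissimilarity(netA: ClassicNetwork, nodeA: int,
                              netB: ClassicNetwork, nodeB: int,
                              k_level: int = 2) -> float:
    """Score how different the k-level neighborhoods of two nodes are.

    Zero for isomorphic distance-weighted neighborhoods, positive otherwise;
    symmetric up to assignment ties.
    """
    ta = level_tree_for_node(netA, nodeA, k_level)
    tb = level_tree_for_node(netB, nodeB, k_level)
    return tree_dissimilarity(ta, tb)


class TopologyScorer:
    """Per-frame cache of classic network and level trees for fast scoring."""

    def __init__(self, frame: SkeletonFrame, k_level: int = 2,
                 classic: ClassicNetwork | None = None):
        self.frame = frame
        self.k_level = int(k_level)
        self.classic = classic if classic is not None \
            else to_classic_network(frame)
        self._trees: dict[int, LevelTree] = {}

    def tree(self, node_id: int) -> LevelTree:
        node_id = int(node_id)
        t = self._trees.get(node_id)
        if t is None:
            t = level_tree_for_node(self.classic, node_id, self.k_level)
            self._trees[node_id] = t
        return t

    def score(self, node_id: int, other: "TopologyScorer",
              other_node_id: int) -> float:
        return tree_dissimilarity(self.tree(node_id),
                                  other.tree(other_node_id))
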