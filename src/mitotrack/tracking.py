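"""Frame-to-frame LAP linking of mitochondrial skeleton nodes.

Each pair of consecutive frames is linked by solving a linear assignment
problem over three options per node: link to a candidate node in the next
frame, terminate, or initiate.  Candidates are restricted by two radii (the
distance to the node's nn_threshold-th nearest neighbor within its own
frame, and the hard cap max_node_speed * frame_interval).  The link cost is
the product of spatial distance and topological dissimilarity, each raised
to a configurable exponent; the termination/initiation alternative cost is
the 98th percentile of previously accepted link costs (twice the minimum
candidate cost for the very first frame pair).  The assembled cost matrix
follows the u-track construction: an upper-left link block, diagonal
termination/initiation blocks, and a transposed auxiliary lower-right block
filled at the minimum cost so the assignment stays feasible.

After the global solve, three physical-constraint corrections prune or
reassign implausible arrows using the concerted motion of skeleton segments,
and quality warnings flag frames with excessive speeds, low linked
fractions, or strong node-count fluctuation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .config import TrackingConfig
from .graph_compare import TopologyScorer
from .skeleton import SkeletonFrame, to_classic_network, ClassicNetwork
from .tracks import NodeTrack

log = logging.getLogger(__name__)

BLOCK = 1e12  # blocking value for forbidden assignments
COST_HISTORY_CAP = 50_000  # most recent accepted link costs kept


# --------------------------------------------------------------------------
# candidate generation
# --------------------------------------------------------------------------

@dataclass
class CandidateSet:
    """Linking candidates from frame T to frame T+1.

    ``candidates[i]`` holds (indices into frame T+1, distances in um) for
    the i-th node of frame T; ``thresholds[i]`` is that node's candidate
    search radius.
    """

    frame_t: SkeletonFrame
    frame_t1: SkeletonFrame
    candidates: list[tuple[np.ndarray, np.ndarray]]
    thresholds: np.ndarray

    @property
    def n_pairs(self) -> int:
        return int(sum(len(ix) for ix, _ in self.candidates))


def neighbor_thresholds(frame: SkeletonFrame, nn_threshold: int) -> np.ndarray:
    """Distance from each node to its nn_threshold-th nearest neighbor.

    Measured within the node's own frame so the radius tracks local network
    density.  Frames with fewer nodes than requested fall back to the
    farthest available neighbor; a single-node frame gets +inf (the speed
    cap alone applies).
    """
    n = len(frame)
    if n <= 1:
        return np.full(n, np.inf)
    k = min(nn_threshold, n - 1)
    tree = cKDTree(frame.positions)
    dist, _ = tree.query(frame.positions, k=k + 1)  # self included
    return dist[:, -1]


def build_candidates(frame_t: SkeletonFrame, frame_t1: SkeletonFrame,
                     cfg: TrackingConfig) -> CandidateSet:
    """Candidate frame-T+1 nodes within both radii for every frame-T node."""
    if len(frame_t) == 0 or len(frame_t1) == 0:
        log.warning("empty frame in pair (%d, %d)",
                    frame_t.frame_index, frame_t1.frame_index)
        return CandidateSet(frame_t, frame_t1,
                            [(np.zeros(0, dtype=np.int64), np.zeros(0))
                             for _ in range(len(frame_t))],
                            np.zeros(len(frame_t)))
    thr = neighbor_thresholds(frame_t, cfg.nn_threshold)
    cap = cfg.max_node_speed * frame_t.frame_interval
    radius = np.minimum(thr, cap)
    tree1 = cKDTree(frame_t1.positions)
    cands = []
    for i in range(len(frame_t)):
        idx = np.array(sorted(tree1.query_ball_point(
            frame_t.positions[i], radius[i])), dtype=np.int64)
        d = (np.linalg.norm(frame_t1.positions[idx] - frame_t.positions[i],
                            axis=1) if len(idx) else np.zeros(0))
        cands.append((idx, d))
    return CandidateSet(frame_t, frame_t1, cands, radius)


def candidate_topology_scores(cands: CandidateSet,
                              scorer_t: TopologyScorer,
                              scorer_t1: TopologyScorer
                              ) -> list[np.ndarray]:
    """Topological dissimilarity for every candidate pair."""
    out = []
    ids_t = cands.frame_t.node_ids
    ids_t1 = cands.frame_t1.node_ids
    for i, (idx, _) in enumerate(cands.candidates):
        out.append(np.array([scorer_t.score(ids_t[i], scorer_t1,
                                            ids_t1[j]) for j in idx]))
    return out


# --------------------------------------------------------------------------
# cost assembly and LAP solve
# --------------------------------------------------------------------------

@dataclass
class CostStructure:
    """Assembled (N+M)x(N+M) LAP matrix plus bookkeeping."""

    matrix: np.ndarray
    n_t: int
    n_t1: int
    alternative_cost: float


def percentile_cost(cost_history, percentile: float) -> float:
    return float(np.percentile(np.asarray(cost_history, dtype=float),
                               percentile))


def assemble_cost(cands: CandidateSet, cfg: TrackingConfig,
                  cost_history=None,
                  topology_scores: list[np.ndarray] | None = None
                  ) -> CostStructure:
    """Build the u-track style cost matrix for one frame pair.

    Combined link cost is ``distance**de * topology**te``.  With no cost
    history yet, the alternative cost is twice the minimum candidate cost.
    """
    n, m = len(cands.frame_t), len(cands.frame_t1)
    de, te = cfg.distance_exponent, cfg.topology_exponent
    link = np.full((n, m), BLOCK)
    for i, (idx, dist) in enumerate(cands.candidates):
        if not len(idx):
            continue
        c = dist ** de
        if te != 0:
            topo = (topology_scores[i] if topology_scores is not None
                    else np.zeros(len(idx)))
            c = c * topo ** te
        link[i, idx] = c
    finite = link[link < BLOCK]
    if cost_history is not None and len(cost_history):
        b = percentile_cost(cost_history, cfg.alt_cost_percentile)
    elif len(finite):
        b = 2.0 * float(finite.min())
    else:
        b = 1.0  # no candidates anywhere: everything terminates/initiates
    if b <= 0:
        b = max(float(finite.min()) if len(finite) else 1.0, 1e-12)
    full = np.full((n + m, n + m), BLOCK)
    full[:n, :m] = link
    full[np.arange(n), m + np.arange(n)] = b          # termination
    full[n + np.arange(m), np.arange(m)] = b          # initiation
    # auxiliary block: transposed link topology at the minimum cost
    aux_fill = float(finite.min()) if len(finite) else 0.0
    allowed = link < BLOCK
    full[n:, m:][allowed.T] = aux_fill
    return CostStructure(matrix=full, n_t=n, n_t1=m, alternative_cost=b)


@dataclass
class AssignmentResult:
    """Outcome of one frame pair's LAP: links plus unmatched nodes."""

    links: list[tuple[int, int, float]]  # (node id at T, node id at T+1, cost)
    terminated: list[int]
    initiated: list[int]
    total_cost: float
    corrections: list[tuple[str, int]] = field(default_factory=list)

    def link_map(self) -> dict[int, int]:
        return {m: n for m, n, _ in self.links}


def solve_assignment(cost: CostStructure, cands: CandidateSet
                     ) -> AssignmentResult:
    """Solve the assembled LAP (Jonker-Volgenant) for the optimal links."""
    rows, cols = linear_sum_assignment(cost.matrix)
    n, m = cost.n_t, cost.n_t1
    ids_t, ids_t1 = cands.frame_t.node_ids, cands.frame_t1.node_ids
    links, terminated, initiated = [], [], []
    total = float(cost.matrix[rows, cols].sum())
    for r, c in zip(rows, cols):
        if r < n and c < m and cost.matrix[r, c] < BLOCK:
            links.append((int(ids_t[r]), int(ids_t1[c]),
                          float(cost.matrix[r, c])))
        elif r < n and c >= m:
            terminated.append(int(ids_t[r]))
        elif r >= n and c < m:
            initiated.append(int(ids_t1[c]))
    return AssignmentResult(links=links, terminated=sorted(terminated),
                            initiated=sorted(initiated), total_cost=total)


# --------------------------------------------------------------------------
# physical-constraint corrections
# --------------------------------------------------------------------------

def segment_membership(frame: SkeletonFrame,
                       classic: ClassicNetwork | None = None
                       ) -> tuple[dict[int, int], dict[int, set[int]]]:
    """Segment labels for every node of a frame.

    A segment is a maximal branch between non-bulk nodes, i.e. one collapsed
    chain of the classic network.  Returns (primary label per node, set of
    segment labels per node); bulk nodes belong to exactly one segment,
    junction nodes to every chain they terminate, isolated nodes to a
    singleton segment of their own.
    """
    if classic is None:
        classic = to_classic_network(frame)
    membership: dict[int, set[int]] = {int(v): set() for v in frame.node_ids}
    for si, chain in enumerate(classic.chains):
        membership[chain.u].add(si)
        membership[chain.v].add(si)
        for v in chain.interior:
            membership[v].add(si)
    next_label = len(classic.chains)
    for v, segs in membership.items():
        if not segs:
            segs.add(next_label)
            next_label += 1
    primary = {v: min(segs) for v, segs in membership.items()}
    return primary, membership


MIN_REFERENCE_VECTORS = 3  # rule 3 needs this many conforming arrows
RULE3_ANGLE_DEG = 30.0


def apply_corrections(result: AssignmentResult, frame_t: SkeletonFrame,
                      frame_t1: SkeletonFrame) -> AssignmentResult:
    """Prune/reassign implausible arrows using segment-coherence rules.

    1. Unlink arrows longer than 3x the mean displacement of the largest
       coherently tracked arrow set of the same source segment.
    2. Unlink a node tracked alone into a segment reached by none of its
       graph neighbors.
    3. Reassign arrows deviating > 30 degrees from the segment's average
       direction to the node nearest the position predicted by the
       conforming (reference) arrows, provided enough references exist.

    Unlinked nodes become terminations/initiations; the LAP is not re-run.
    """
    if not result.links:
        return result
    prim_t, memb_t = segment_membership(frame_t)
    prim_t1, memb_t1 = segment_membership(frame_t1)
    links = {m: (n, c) for m, n, c in result.links}
    corrections: list[tuple[str, int]] = list(result.corrections)

    by_segment: dict[int, list[int]] = {}
    for m in links:
        by_segment.setdefault(prim_t[m], []).append(m)

    def vec(m: int) -> np.ndarray:
        n = links[m][0]
        return frame_t1.position_of(n) - frame_t.position_of(m)

    # rule 1: overly long arrows relative to the segment's coherent set
    for seg, ms in by_segment.items():
        groups: dict[int, list[int]] = {}
        for m in ms:
            groups.setdefault(prim_t1[links[m][0]], []).append(m)
        largest = max(groups.values(), key=len)
        ref_mean = float(np.mean([np.linalg.norm(vec(m)) for m in largest]))
        for m in list(ms):
            if np.linalg.norm(vec(m)) > 3.0 * ref_mean:
                del links[m]
                corrections.append(("rule1", m))

    # rule 2: a node tracked alone into a segment is a likely
    # mis-assignment; an arrow is supported when some other node of its
    # neighborhood (graph neighbor or same segment) is tracked into a
    # segment shared with the arrow's target
    g_t = frame_t.graph
    for m in list(links):
        if g_t.degree(m) == 0:
            continue
        target_segs = memb_t1[links[m][0]]
        own_segs = memb_t[m]
        supported = False
        for m2, (n2, _) in links.items():
            if m2 == m:
                continue
            if not (memb_t[m2] & own_segs or g_t.has_edge(m, m2)):
                continue
            if memb_t1[n2] & target_segs:
                supported = True
                break
        if not supported:
            del links[m]
            corrections.append(("rule2", m))

    # rule 3: crossing arrows reassigned toward the segment consensus motion
    owner = {n: m for m, (n, _) in links.items()}
    tree1 = cKDTree(frame_t1.positions) if len(frame_t1) else None
    cos_thr = np.cos(np.deg2rad(RULE3_ANGLE_DEG))
    reassign_queue: list[tuple[int, np.ndarray]] = []
    for seg, ms in by_segment.items():
        ms = [m for m in ms if m in links]
        if len(ms) < MIN_REFERENCE_VECTORS:
            continue
        vecs = {m: vec(m) for m in ms}
        mean_v = np.mean(list(vecs.values()), axis=0)
        norm_mean = np.linalg.norm(mean_v)
        if norm_mean == 0:
            continue
        refs = []
        others = []
        for m, v in vecs.items():
            nv = np.linalg.norm(v)
            cos = 1.0 if nv == 0 else float(v @ mean_v / (nv * norm_mean))
            (refs if cos > cos_thr else others).append(m)
        if len(refs) < MIN_REFERENCE_VECTORS or not others:
            continue
        ref_mean = np.mean([vecs[m] for m in refs], axis=0)
        for m in others:
            reassign_queue.append((m, frame_t.position_of(m) + ref_mean))
    for m, predicted in reassign_queue:
        _, nearest = tree1.query(predicted, k=min(2, len(frame_t1)))
        cand_ids = [int(frame_t1.node_ids[j])
                    for j in np.atleast_1d(nearest)]
        cur = links[m][0]
        if cur in cand_ids:
            continue  # already points where the references predict
        for new in cand_ids:
            # an already-claimed node is never taken away: unlinking a
            # plausible arrow to fix another does more harm than good
            if new in owner:
                continue
            del owner[cur]
            owner[new] = m
            dist = float(np.linalg.norm(
                frame_t1.position_of(new) - frame_t.position_of(m)))
            links[m] = (new, dist)
            corrections.append(("rule3", m))
            break

    linked_t = set(links)
    linked_t1 = {n for n, _ in links.values()}
    return AssignmentResult(
        links=[(m, n, c) for m, (n, c) in sorted(links.items())],
        terminated=sorted(int(v) for v in frame_t.node_ids
                          if int(v) not in linked_t),
        initiated=sorted(int(v) for v in frame_t1.node_ids
                         if int(v) not in linked_t1),
        total_cost=result.total_cost,
        corrections=corrections)


# --------------------------------------------------------------------------
# warnings
# --------------------------------------------------------------------------

def check_warnings(frame_t: SkeletonFrame, frame_t1: SkeletonFrame,
                   result: AssignmentResult, cfg: TrackingConfig
                   ) -> list[str]:
    """Quality warnings for one linked frame pair (never abort)."""
    warnings = []
    tau = frame_t.frame_interval
    for m, n, _ in result.links:
        d = np.linalg.norm(frame_t1.position_of(n) - frame_t.position_of(m))
        if d / tau > cfg.max_node_speed:
            warnings.append(
                f"speed: link {m}->{n} at {d / tau:.6g} um/s exceeds "
                f"{cfg.max_node_speed:.6g} um/s")
            break
    if len(frame_t):
        frac = 100.0 * len(result.links) / len(frame_t)
        if frac < cfg.min_frac_linked:
            warnings.append(
                f"linked-fraction: {frac:.6g}% of frame "
                f"{frame_t.frame_index} nodes linked "
                f"(< {cfg.min_frac_linked:.6g}%)")
    mean_n = 0.5 * (len(frame_t) + len(frame_t1))
    if mean_n > 0:
        fluct = 100.0 * abs(len(frame_t1) - len(frame_t)) / mean_n
        if fluct > cfg.max_node_fluctuation:
            warnings.append(
                f"fluctuation: node count changed {fluct:.6g}% between "
                f"frames {frame_t.frame_index},{frame_t1.frame_index} "
                f"(> {cfg.max_node_fluctuation:.6g}%)")
    return warnings


# --------------------------------------------------------------------------
# whole-movie tracking
# --------------------------------------------------------------------------

@dataclass
class TrackingResult:
    """Tracks plus the temporal correspondence structure for a movie."""

    tracks: list[NodeTrack]
    link_maps: list[dict[int, int]]  # per frame pair: node id T -> node id T+1
    warnings: list[str]
    cost_history: list[float]

    def temporal_network(self, frames):
        from .temporal import TemporalNetwork
        return TemporalNetwork(frames=list(frames),
                               correspondence=list(self.link_maps))


def link_frame_pair(frame_t: SkeletonFrame, frame_t1: SkeletonFrame,
                    cfg: TrackingConfig, cost_history,
                    scorer_t: TopologyScorer | None = None,
                    scorer_t1: TopologyScorer | None = None,
                    corrections: bool = True) -> AssignmentResult:
    """Candidate search, cost assembly, LAP solve and corrections for a pair."""
    cands = build_candidates(frame_t, frame_t1, cfg)
    topo = None
    if cfg.topology_exponent != 0 and cands.n_pairs:
        scorer_t = scorer_t or TopologyScorer(frame_t, cfg.k_level)
        scorer_t1 = scorer_t1 or TopologyScorer(frame_t1, cfg.k_level)
        topo = candidate_topology_scores(cands, scorer_t, scorer_t1)
    cost = assemble_cost(cands, cfg, cost_history, topo)
    result = solve_assignment(cost, cands)
    if corrections:
        result = apply_corrections(result, frame_t, frame_t1)
    return result


def track_all(frames: list[SkeletonFrame], cfg: TrackingConfig | None = None,
              corrections: bool = True) -> TrackingResult:
    """Track every skeleton node through a movie of >= 2 frames."""
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to track")
    cfg = cfg or TrackingConfig()
    cost_history: list[float] = []
    link_maps: list[dict[int, int]] = []
    all_warnings: list[str] = []
    tracks: list[NodeTrack] = []
    active: dict[int, NodeTrack] = {}
    for v in frames[0].node_ids:
        t = NodeTrack(len(tracks))
        t.append(frames[0].frame_index, int(v), frames[0].position_of(v))
        tracks.append(t)
        active[int(v)] = t

    use_topo = cfg.topology_exponent != 0
    scorer_t = TopologyScorer(frames[0], cfg.k_level) if use_topo else None
    for ft, ft1 in zip(frames[:-1], frames[1:]):
        scorer_t1 = TopologyScorer(ft1, cfg.k_level) if use_topo else None
        cands = build_candidates(ft, ft1, cfg)
        topo = (candidate_topology_scores(cands, scorer_t, scorer_t1)
                if use_topo and cands.n_pairs else None)
        cost = assemble_cost(cands, cfg, cost_history, topo)
        result = solve_assignment(cost, cands)
        # every candidate cost of this assignment problem enters the
        # history: the alternative cost is a percentile of the full cost
        # distribution, not only of the accepted links (accepted-only
        # feedback collapses the linked fraction)
        link_block = cost.matrix[:cost.n_t, :cost.n_t1]
        cost_history.extend(link_block[link_block < BLOCK].tolist())
        if len(cost_history) > COST_HISTORY_CAP:
            del cost_history[:len(cost_history) - COST_HISTORY_CAP]
        if corrections:
            result = apply_corrections(result, ft, ft1)
        all_warnings.extend(check_warnings(ft, ft1, result, cfg))
        link_maps.append(result.link_map())

        next_active: dict[int, NodeTrack] = {}
        for m, n, _ in result.links:
            tr = active[m]
            tr.append(ft1.frame_index, n, ft1.position_of(n))
            next_active[n] = tr
        for n in result.initiated:
            tr = NodeTrack(len(tracks))
            tr.append(ft1.frame_index, int(n), ft1.position_of(n))
            tracks.append(tr)
            next_active[int(n)] = tr
        active = next_active
        scorer_t = scorer_t1
    return TrackingResult(tracks=tracks, link_maps=link_maps,
                          warnings=all_warnings, cost_history=cost_history)
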