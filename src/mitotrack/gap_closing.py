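"""Close temporal gaps between prematurely terminated node tracks.

A track that ends at frame e may be the same physical node as a track that
starts at frame s > e + 1 (a transient segmentation dropout).  Candidate
pairs must satisfy ``1 < gap < max_gap_size`` with ``gap = s - e`` and a
distance bound scaled by the gap and the pooled variance of the two tracks'
per-frame displacements.  The pair cost reuses the linking cost form
(distance x topology between A's end node and B's start node, with the
classic networks of those two frames).

Because the number of tracks can be large, the start-frame-sorted cost
matrix is solved in overlapping NxN diagonal blocks (N = max_gap_size x
average tracks per frame, advanced by 0.8 N), a sub-optimal but memory-
bounded scheme that closes almost the same set of gaps as the full matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .config import TrackingConfig
from .graph_compare import TopologyScorer
from .skeleton import SkeletonFrame
from .tracking import BLOCK, percentile_cost
from .tracks import NodeTrack

log = logging.getLogger(__name__)

VARIANCE_FACTOR = 9.0  # distance < gap * 9 * var(pooled displacements)
BLOCK_STEP_FRACTION = 0.8


@dataclass
class GapCandidate:
    """A candidate merge of track_a's end onto track_b's start."""

    track_a: int
    track_b: int
    gap_size: int
    distance: float
    cost: float


def qualify_tracks(tracks: list[NodeTrack], min_track_size: int
                   ) -> list[NodeTrack]:
    """Tracks longer than min_track_size frames, sorted by start frame."""
    eligible = [t for t in tracks if len(t) > min_track_size]
    return sorted(eligible, key=lambda t: (t.start_frame, t.track_id))


def gap_cost(a: NodeTrack, b: NodeTrack, cfg: TrackingConfig,
             scorers: dict[int, TopologyScorer] | None = None
             ) -> GapCandidate | None:
    """Candidate for closing the gap a -> b, or None if rejected."""
    gap = b.start_frame - a.end_frame
    if not (1 < gap < cfg.max_gap_size):
        return None
    end_pos = a.entries[-1].position
    start_pos = b.entries[0].position
    distance = float(np.linalg.norm(start_pos - end_pos))
    pooled = np.concatenate([a.displacements(), b.displacements()])
    variance = float(np.var(pooled)) if len(pooled) else 0.0
    if not distance < gap * VARIANCE_FACTOR * variance:
        return None
    topo = 0.0
    if cfg.topology_exponent != 0 and scorers is not None:
        sa = scorers.get(a.end_frame)
        sb = scorers.get(b.start_frame)
        if sa is not None and sb is not None:
            topo = sa.score(a.entries[-1].node_id, sb, b.entries[0].node_id)
    cost = (distance ** cfg.distance_exponent
            * (topo ** cfg.topology_exponent
               if cfg.topology_exponent != 0 else 1.0))
    return GapCandidate(track_a=a.track_id, track_b=b.track_id,
                        gap_size=gap, distance=distance, cost=cost)


def _merge(a: NodeTrack, b: NodeTrack) -> NodeTrack:
    merged = NodeTrack(a.track_id)
    merged.entries = list(a.entries)
    for i, e in enumerate(b.entries):
        merged.append(e.frame_index, e.node_id, e.position,
                      gap_closed=e.gap_closed or i == 0)
    return merged


def close_gaps(tracks: list[NodeTrack], cfg: TrackingConfig | None = None,
               frames: list[SkeletonFrame] | None = None,
               cost_history=None,
               block_size: int | None = None) -> list[NodeTrack]:
    """Merge gap candidates with a block-wise LAP over sorted tracks.

    ``frames`` enables the topology cost term at the gap junctions; without
    them only the distance term is used.  ``cost_history`` (accepted link
    costs from tracking) sets the no-merge alternative cost; otherwise
    twice the minimum candidate cost in each block is used.
    """
    cfg = cfg or TrackingConfig()
    eligible = qualify_tracks(tracks, cfg.min_track_size)
    eligible_ids = {t.track_id for t in eligible}
    rest = [t for t in tracks if t.track_id not in eligible_ids]
    if len(eligible) < 2:
        return sorted(tracks, key=lambda t: t.track_id)

    scorers = None
    if frames is not None and cfg.topology_exponent != 0:
        by_index = {f.frame_index: f for f in frames}
        junction_frames = ({t.end_frame for t in eligible}
                           | {t.start_frame for t in eligible})
        scorers = {fi: TopologyScorer(by_index[fi], cfg.k_level)
                   for fi in junction_frames if fi in by_index}

    n_frames = (max(t.end_frame for t in eligible)
                - min(t.start_frame for t in eligible) + 1)
    avg_per_frame = sum(len(t) for t in eligible) / max(n_frames, 1)
    if block_size is None:
        block_size = max(int(round(cfg.max_gap_size * avg_per_frame)), 2)
    step = max(int(round(BLOCK_STEP_FRACTION * block_size)), 1)

    alt = None
    if cost_history is not None and len(cost_history):
        alt = percentile_cost(cost_history, cfg.alt_cost_percentile)

    current = {t.track_id: t for t in eligible}
    order = [t.track_id for t in eligible]
    consumed: set[int] = set()   # merged-away track ids (b side)

    start = 0
    while start < len(order):
        ids = [i for i in order[start:start + block_size]
               if i not in consumed]
        nb = len(ids)
        if nb >= 2:
            cands: dict[tuple[int, int], GapCandidate] = {}
            sub = np.full((nb, nb), BLOCK)
            for i, ia in enumerate(ids):
                for j, ib in enumerate(ids):
                    if ia == ib or ib in consumed:
                        continue
                    gc = gap_cost(current[ia], current[ib], cfg, scorers)
                    if gc is not None:
                        sub[i, j] = gc.cost
                        cands[(i, j)] = gc
            if cands:
                finite = sub[sub < BLOCK]
                b_alt = alt if alt is not None else 2.0 * float(finite.min())
                if b_alt <= 0:
                    b_alt = 1e-12
                size = 2 * nb
                full = np.full((size, size), BLOCK)
                full[:nb, :nb] = sub
                full[np.arange(nb), nb + np.arange(nb)] = b_alt
                full[nb + np.arange(nb), np.arange(nb)] = b_alt
                full[nb:, nb:][(sub < BLOCK).T] = float(finite.min())
                rows, cols = linear_sum_assignment(full)
                pairs = {ids[r]: ids[c] for r, c in zip(rows, cols)
                         if r < nb and c < nb and full[r, c] < BLOCK}
                # chains (A->B, B->C) merge front to back
                tails = set(pairs.values())
                for head in [a for a in pairs if a not in tails]:
                    cur = head
                    while cur in pairs:
                        nxt = pairs.pop(cur)
                        current[head] = _merge(current[head], current[nxt])
                        consumed.add(nxt)
                        log.info("gap closed: track %d -> %d", head, nxt)
                        cur = nxt
        if start + block_size >= len(order):
            break
        start += step

    out = [current[i] for i in order if i not in consumed] + rest
    return sorted(out, key=lambda t: t.track_id)
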