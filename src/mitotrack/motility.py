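"""Motility measurements on node tracks: MSD curves, diffusivities, and
tracking-vector correlations.

Node motion is summarized by time-averaged mean squared displacement
curves, MSD(tau), fitted with the three-dimensional Brownian law
MSD = 6 D tau (a least-squares line through the origin, since MSD(0) = 0).
Diffusivity maps aggregate the fits at node, segment, or fragment level; at
the coarser levels the entity's motion is the motion of the centroid of its
member nodes.  Tracking-vector correlations quantify concerted motion: the
correlation of two displacement vectors is their dot product divided by the
squared norm of the longer one, in [-1, 1], so anti-parallel motion scores
-1 and equal vectors score 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .skeleton import SkeletonFrame
from .tracking import segment_membership
from .tracks import NodeTrack

DEFAULT_HALF_WINDOW = 10  # frames around the center for diffusivity maps


@dataclass
class MsdCurve:
    """Time-averaged MSD versus delay for one tracked entity."""

    delays_frames: np.ndarray   # strictly increasing, frames
    delays_seconds: np.ndarray
    msd: np.ndarray             # um^2
    level: str = "node"         # node | segment | fragment
    diffusivity: float | None = None  # um^2/s after fitting
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.delays_frames) <= 0):
            raise ValueError("delays must be strictly increasing")


def track_msd(track: NodeTrack, max_delay: int | None = None,
              frame_interval: float = 1.0, level: str = "node") -> MsdCurve:
    """Time-averaged MSD of one track over all ordered entry pairs.

    Delays with no pair in the track (gaps) are dropped.
    """
    if len(track) < 2:
        raise ValueError("track too short for MSD")
    frames = track.frames
    pos = track.positions
    return _msd_from_series(frames, pos, max_delay, frame_interval, level)


def _msd_from_series(frames: np.ndarray, pos: np.ndarray,
                     max_delay: int | None, frame_interval: float,
                     level: str) -> MsdCurve:
    span = int(frames[-1] - frames[0])
    max_delay = span if max_delay is None else min(max_delay, span)
    index = {int(f): i for i, f in enumerate(frames)}
    delays, msds = [], []
    for d in range(1, max_delay + 1):
        sq = [np.sum((pos[index[f + d]] - pos[index[f]]) ** 2)
              for f in index if f + d in index]
        if sq:
            delays.append(d)
            msds.append(float(np.mean(sq)))
    return MsdCurve(delays_frames=np.array(delays),
                    delays_seconds=np.array(delays, dtype=float)
                    * frame_interval,
                    msd=np.array(msds), level=level)


def fit_diffusivity(curve: MsdCurve) -> tuple[float, float]:
    """Fit MSD = 6 D tau through the origin; returns (D, R^2).

    R^2 is reported against the mean of the MSD values; for a degenerate
    all-zero curve D = 0 and R^2 = nan (flagged undefined).  The fitted
    values are also stored on the curve.
    """
    tau = curve.delays_seconds
    y = curve.msd
    if len(tau) < 1 or np.all(y == 0):
        curve.diffusivity, curve.r_squared = 0.0, float("nan")
        return 0.0, float("nan")
    slope = float(np.sum(tau * y) / np.sum(tau * tau))
    resid = y - slope * tau
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    curve.diffusivity, curve.r_squared = slope / 6.0, r2
    return slope / 6.0, r2


def diffusivity_map(tracks: list[NodeTrack], center_frame: int,
                    half_window: int = DEFAULT_HALF_WINDOW,
                    level: str = "node",
                    frames: list[SkeletonFrame] | None = None,
                    frame_interval: float | None = None
                    ) -> dict[int, float]:
    """Fitted D per entity over a +/- half_window frame window.

    node level: keys are node ids at the center frame; segment/fragment
    level (requires ``frames``): keys are segment/fragment labels of the
    center frame and the entity track is the centroid of its member nodes.
    Entities with fewer than 3 window points are skipped.
    """
    lo, hi = center_frame - half_window, center_frame + half_window
    if frame_interval is None:
        frame_interval = (frames[0].frame_interval if frames else 1.0)

    def window_track(t: NodeTrack):
        sel = [(e.frame_index, e.position) for e in t.entries
               if lo <= e.frame_index <= hi]
        return sel

    if level == "node":
        out: dict[int, float] = {}
        for t in tracks:
            node = t.node_at(center_frame)
            if node is None:
                continue
            sel = window_track(t)
            if len(sel) < 3:
                continue
            f = np.array([s[0] for s in sel])
            p = np.array([s[1] for s in sel])
            curve = _msd_from_series(f, p, None, frame_interval, level)
            d, _ = fit_diffusivity(curve)
            out[node] = d
        return out

    if frames is None:
        raise ValueError(f"{level}-level map requires frames")
    center = next(f for f in frames if f.frame_index == center_frame)
    if level == "segment":
        primary, _ = segment_membership(center)
        entity_of = primary
    elif level == "fragment":
        import networkx as nx
        entity_of = {v: i for i, cc in enumerate(
            sorted((sorted(c) for c in
                    nx.connected_components(center.graph)),
                   key=lambda c: c[0]))
            for v in cc}
    else:
        raise ValueError(f"unknown level {level!r}")

    members: dict[int, list[NodeTrack]] = {}
    for t in tracks:
        node = t.node_at(center_frame)
        if node is not None and node in entity_of:
            members.setdefault(entity_of[node], []).append(t)
    out = {}
    for ent, ts in members.items():
        by_frame: dict[int, list[np.ndarray]] = {}
        for t in ts:
            for f, p in window_track(t):
                by_frame.setdefault(f, []).append(p)
        if len(by_frame) < 3:
            continue
        fs = np.array(sorted(by_frame))
        ps = np.array([np.mean(by_frame[f], axis=0) for f in fs])
        curve = _msd_from_series(fs, ps, None, frame_interval, level)
        d, _ = fit_diffusivity(curve)
        out[ent] = d
    return out


def node_diffusivity_table(tracks: list[NodeTrack],
                           frames: list[SkeletonFrame],
                           half_window: int = DEFAULT_HALF_WINDOW
                           ) -> dict[tuple[int, int], float]:
    """(frame index, node id) -> fitted D for every usable center frame."""
    out: dict[tuple[int, int], float] = {}
    for f in frames:
        dm = diffusivity_map(tracks, f.frame_index, half_window,
                             frame_interval=f.frame_interval)
        for node, d in dm.items():
            out[(f.frame_index, node)] = d
    return out


def normalized_diffusivity(dmap: dict[int, float]) -> dict[int, float]:
    """Diffusivities divided by their cell-wide median.

    "Mean normalized diffusivity" comparisons between node groups are
    scale-free this way; entries are left untouched (all zero) when the
    median vanishes.
    """
    if not dmap:
        return {}
    med = float(np.median(list(dmap.values())))
    if med == 0:
        return dict(dmap)
    return {k: v / med for k, v in dmap.items()}


def vector_correlation(v1, v2) -> float:
    """Dot product over the squared norm of the longer vector; in [-1, 1].

    Undefined (nan) when both vectors are zero.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    longer = max(float(v1 @ v1), float(v2 @ v2))
    if longer == 0:
        return float("nan")
    return float(v1 @ v2) / longer


def correlation_maps(tracks: list[NodeTrack],
                     frames: list[SkeletonFrame]
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spatial and temporal tracking-vector correlation matrices.

    Rows are track ids, columns frame indices (of the frame the
    displacement starts at).  The spatial value for a node at frame t is
    the mean correlation between its displacement vector t -> t+1 and the
    vectors of its directly connected neighbors that are linked over the
    same frame pair; the temporal value is the mean correlation with the
    same track's previous- and next-pair vectors (one-sided at the
    boundaries).  Cells with no defined partner are NaN.
    """
    T = len(frames)
    by_index = {f.frame_index: f for f in frames}
    # displacement vector per (track, start frame)
    vec: dict[int, dict[int, np.ndarray]] = {}
    node_at: dict[int, dict[int, int]] = {}
    for t in tracks:
        vec[t.track_id] = {}
        node_at[t.track_id] = {e.frame_index: e.node_id for e in t.entries}
        for a, b in zip(t.entries[:-1], t.entries[1:]):
            if b.frame_index == a.frame_index + 1:
                vec[t.track_id][a.frame_index] = b.position - a.position
    # node -> track per frame
    track_of: dict[int, dict[int, int]] = {fi: {} for fi in by_index}
    for tid, na in node_at.items():
        for f, node in na.items():
            if f in track_of:
                track_of[f][node] = tid

    tids = sorted(vec)
    frame_idx = sorted(by_index)[:-1]
    spatial = pd.DataFrame(np.nan, index=tids, columns=frame_idx)
    temporal = pd.DataFrame(np.nan, index=tids, columns=frame_idx)
    for tid in tids:
        for f, v in vec[tid].items():
            # spatial: directly connected neighbors with a vector this pair
            frame = by_index[f]
            node = node_at[tid][f]
            vals = []
            for nb in frame.graph.neighbors(node):
                nb_tid = track_of[f].get(nb)
                if nb_tid is None:
                    continue
                w = vec[nb_tid].get(f)
                if w is not None:
                    c = vector_correlation(v, w)
                    if np.isfinite(c):
                        vals.append(c)
            if vals:
                spatial.loc[tid, f] = float(np.mean(vals))
            tvals = []
            for g in (f - 1, f + 1):
                w = vec[tid].get(g)
                if w is not None:
                    c = vector_correlation(v, w)
                    if np.isfinite(c):
                        tvals.append(c)
            if tvals:
                temporal.loc[tid, f] = float(np.mean(tvals))
    return spatial, temporal
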