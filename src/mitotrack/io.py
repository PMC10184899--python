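"""Readers and writers for skeleton frames and node tracks.

File dialect: per-frame node and edge tables are comma-separated with a
header row.  The node table needs columns ``node_id, x, y, z`` and may carry
``intensity`` and ``width``; the edge table needs ``source, target``.
Coordinates are micrometers, node ids 0-based integers, edges unordered and
written with source < target.  A GraphML reader is provided as a convenience
for graphs exported by other tools.
"""

from __future__ import annotations

import logging
import os
import re
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx

from .skeleton import SkeletonFrame, SkeletonFormatError
from .tracks import NodeTrack

log = logging.getLogger(__name__)

_NODE_COLS = ("node_id", "x", "y", "z")
_TRACK_COLS = ("track_id", "frame", "node_id", "x", "y", "z", "gap_closed")


def read_skeleton_frame(node_table_path, edge_table_path,
                        frame_index: int, frame_interval: float = 1.0
                        ) -> SkeletonFrame:
    """Read one frame's node and edge CSV tables into a SkeletonFrame.

    Missing ``intensity``/``width`` columns default to 0 with a logged
    notice.  Malformed tables (duplicate node ids, edges naming absent
    nodes) raise :class:`SkeletonFormatError`.
    """
    nodes = pd.read_csv(node_table_path)
    for col in _NODE_COLS:
        if col not in nodes.columns:
            raise SkeletonFormatError(
                f"{node_table_path}: missing column {col!r}")
    edges = pd.read_csv(edge_table_path)
    if len(edges) and not {"source", "target"} <= set(edges.columns):
        raise SkeletonFormatError(
            f"{edge_table_path}: needs columns source,target")
    for col in ("intensity", "width"):
        if col not in nodes.columns:
            log.info("%s: no %r column, defaulting to 0",
                     node_table_path, col)
            nodes[col] = 0.0
    edge_arr = (edges[["source", "target"]].to_numpy(dtype=np.int64)
                if len(edges) else np.zeros((0, 2), dtype=np.int64))
    return SkeletonFrame(
        frame_index=frame_index,
        node_ids=nodes["node_id"].to_numpy(dtype=np.int64),
        positions=nodes[["x", "y", "z"]].to_numpy(dtype=float),
        edges=edge_arr,
        frame_interval=frame_interval,
        intensity=nodes["intensity"].to_numpy(dtype=float),
        width=nodes["width"].to_numpy(dtype=float),
    )


def write_skeleton_frame(frame: SkeletonFrame, node_table_path,
                         edge_table_path) -> None:
    """Write a frame back to the node/edge CSV dialect (lossless round-trip)."""
    nodes = pd.DataFrame({
        "node_id": frame.node_ids,
        "x": frame.positions[:, 0],
        "y": frame.positions[:, 1],
        "z": frame.positions[:, 2],
        "intensity": frame.intensity,
        "width": frame.width,
    })
    nodes.to_csv(node_table_path, index=False)
    edges = pd.DataFrame(frame.edges, columns=["source", "target"])
    edges.to_csv(edge_table_path, index=False)


def read_skeleton_graphml(path, frame_index: int,
                          frame_interval: float = 1.0) -> SkeletonFrame:
    """Read a frame from GraphML with node attributes x, y, z (um)."""
    g = nx.read_graphml(path)
    keys = sorted(g.nodes, key=lambda v: int(v))
    ids = np.array([int(v) for v in keys], dtype=np.int64)
    pos = np.array([[float(g.nodes[v].get(c, 0.0)) for c in "xyz"]
                    for v in keys])
    inten = np.array([float(g.nodes[v].get("intensity", 0.0)) for v in keys])
    width = np.array([float(g.nodes[v].get("width", 0.0)) for v in keys])
    edges = np.array([[int(u), int(v)] for u, v in g.edges],
                     dtype=np.int64).reshape(-1, 2)
    return SkeletonFrame(frame_index, ids, pos, edges,
                         frame_interval, inten, width)


def frame_paths(directory) -> list[tuple[Path, Path]]:
    """Discover (node, edge) CSV pairs frame_XXX_nodes.csv / _edges.csv."""
    directory = Path(directory)
    pairs = []
    for p in sorted(directory.glob("frame_*_nodes.csv")):
        m = re.match(r"frame_(\d+)_nodes\.csv", p.name)
        if not m:
            continue
        e = directory / f"frame_{m.group(1)}_edges.csv"
        if e.exists():
            pairs.append((p, e))
    return pairs


def read_frames(directory, frame_interval: float) -> list[SkeletonFrame]:
    """Read every frame pair in a directory, ordered by frame number."""
    frames = []
    for i, (np_, ep) in enumerate(frame_paths(directory)):
        frames.append(read_skeleton_frame(np_, ep, i, frame_interval))
    return frames


def write_frames(frames, directory) -> None:
    directory = Path(directory)
    os.makedirs(directory, exist_ok=True)
    for f in frames:
        write_skeleton_frame(
            f, directory / f"frame_{f.frame_index:04d}_nodes.csv",
            directory / f"frame_{f.frame_index:04d}_edges.csv")


def write_tracks(tracks: list[NodeTrack], path) -> None:
    """Write tracks as CSV (track_id, frame, node_id, x, y, z, gap_closed)."""
    rows = []
    for t in tracks:
        for e in t.entries:
            rows.append((t.track_id, e.frame_index, e.node_id,
                         e.position[0], e.position[1], e.position[2],
                         int(e.gap_closed)))
    df = pd.DataFrame(rows, columns=_TRACK_COLS)
    df.to_csv(path, index=False)


def read_tracks(path) -> list[NodeTrack]:
    """Read tracks written by :func:`write_tracks`."""
    df = pd.read_csv(path)
    tracks: dict[int, NodeTrack] = {}
    for row in df.itertuples(index=False):
        t = tracks.setdefault(int(row.track_id), NodeTrack(int(row.track_id)))
        t.append(int(row.frame), int(row.node_id),
                 (row.x, row.y, row.z), bool(row.gap_closed))
    return [tracks[k] for k in sorted(tracks)]
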