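"""Node track container: one tracked skeleton node through time."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(eq=False)
class TrackEntry:
    frame_index: int
    node_id: int
    position: np.ndarray  # (3,) um
    gap_closed: bool = False  # True if this entry follows a closed gap


@dataclass(eq=False)
class NodeTrack:
    """A time-ordered sequence of linked node identities for one node.

    Entries are strictly increasing in frame index, with at most one entry
    per frame. ``gap_closed`` on an entry marks that the junction into this
    entry was produced by gap closing rather than frame-to-frame linking.
    """

    track_id: int
    entries: list[TrackEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def start_frame(self) -> int:
        return self.entries[0].frame_index

    @property
    def end_frame(self) -> int:
        return self.entries[-1].frame_index

    @property
    def frames(self) -> np.ndarray:
        return np.array([e.frame_index for e in self.entries], dtype=np.int64)

    @property
    def positions(self) -> np.ndarray:
        return np.array([e.position for e in self.entries], dtype=float)

    def append(self, frame_index: int, node_id: int, position,
               gap_closed: bool = False) -> None:
        if self.entries and frame_index <= self.entries[-1].frame_index:
            raise ValueError(
                f"track {self.track_id}: frame {frame_index} not after "
                f"{self.entries[-1].frame_index}")
        pos = np.asarray(position, dtype=float)
        if not np.all(np.isfinite(pos)):
            raise ValueError("non-finite track position")
        self.entries.append(TrackEntry(frame_index, int(node_id), pos,
                                       gap_closed))

    def node_at(self, frame_index: int) -> int | None:
        """Node id at a frame, or None if the track has no entry there."""
        for e in self.entries:
            if e.frame_index == frame_index:
                return e.node_id
        return None

    def displacements(self) -> np.ndarray:
        """Per-junction displacement magnitudes between consecutive entries, um."""
        if len(self.entries) < 2:
            return np.zeros(0)
        p = self.positions
        return np.linalg.norm(np.diff(p, axis=0), axis=1)
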