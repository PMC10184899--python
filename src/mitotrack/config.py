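"""Tracking configuration with the default thresholds used throughout."""

from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass
class TrackingConfig:
    """Parameters of LAP node tracking and gap closing.

    Attributes
    ----------
    nn_threshold : int
        Per-node candidate search radius is the distance to this node's
        nn_threshold-th nearest neighbor within its own frame, so the radius
        adapts to local network density.
    max_node_speed : float
        Hard speed cap, um/s; candidates farther than
        ``max_node_speed * frame_interval`` are never considered.
    distance_exponent, topology_exponent : float
        Weights of the two cost terms: combined cost is
        ``distance**de * topology**te``. Equal weighting (1, 1) by default.
    alt_cost_percentile : float
        Percentile of previously accepted link costs used as the
        termination/initiation (self-assignment) cost.
    k_level : int
        Neighborhood depth of the topological dissimilarity comparison.
    min_frac_linked : float
        Warning threshold, percent of frame-T nodes that must be linked.
    max_node_fluctuation : float
        Warning threshold, percent change in node count between frames.
    min_track_size : int
        Tracks must have more than this many frames to enter gap closing.
    max_gap_size : int
        Gaps must satisfy ``1 < gap < max_gap_size`` (frames) to be closed.
    """

    nn_threshold: int = 10
    max_node_speed: float = 1.0  # um/s
    distance_exponent: float = 1.0
    topology_exponent: float = 1.0
    alt_cost_percentile: float = 98.0
    k_level: int = 2
    min_frac_linked: float = 75.0  # percent
    max_node_fluctuation: float = 20.0  # percent
    min_track_size: int = 4  # frames
    max_gap_size: int = 5  # frames

    def __post_init__(self) -> None:
        if self.nn_threshold <= 0:
            raise ValueError("nn_threshold must be > 0")
        for name in ("max_node_speed", "min_track_size", "max_gap_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("alt_cost_percentile", "min_frac_linked",
                     "max_node_fluctuation"):
            v = getattr(self, name)
            if not 0 < v <= 100:
                raise ValueError(f"{name} must be in (0, 100]")
        if self.k_level < 1:
            raise ValueError("k_level must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrackingConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)
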