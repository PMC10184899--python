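# Methods

This note records the models, parameter choices and numerical decisions
behind `mitotrack`, and what the simulation-based validation does and does
not establish.

## Skeleton graphs and the classic network

A frame is a simple graph of skeleton nodes with 3D positions in µm.
Nodes are terminal (degree 1), bulk (degree 2) or branching (degree > 2).
The *classic network* eliminates bulk nodes: every maximal chain of bulk
nodes between two non-bulk endpoints becomes one edge weighted by the
summed Euclidean path length along the chain. A *segment* is one such
chain; a *fragment* is a connected component. A ring made entirely of
bulk nodes (a toroid) has no non-bulk anchor; the lowest-id ring node and
the node halfway around are promoted and joined by the two half-ring
edges, so rings survive the reduction and component counts are preserved.

## Topological dissimilarity

The topology cost between two candidate nodes compares their k-level
classic-network neighborhoods (default k = 2; mitochondrial connectivity
is sparse enough that a small neighborhood carries most of the signal,
and per-pair cost grows quickly with k). Each neighborhood is a
breadth-first level tree: level ℓ holds nodes ℓ classic hops from the
target, loops are opened by keeping the first discovery (ties broken
toward ascending node id, equal-level parents toward the smallest id, for
determinism), and the shallower tree is padded per level with pseudo-nodes
on weight-zero pseudo-edges. A bulk target is inserted as a virtual
degree-2 node splitting its chain, with the partial path lengths as its
two edge weights — this is what lets every full-resolution node, not just
junctions and tips, carry a topology cost, and what makes the cost
sensitive to position along a chain.

Trees are aligned bottom-up with one small assignment problem per level.
The node dissimilarity for a real pair (u, v) is

    |deg(u) − deg(v)| + |d(u) − d(v)| + (w_u + w_v)·[parents not aligned]

with d the weighted path length to the target and w the edge weight to
the parent; a pseudo-node pairs with a real node at the partner's
d + deg. The parent-consistency term is needed for the score to vanish
exactly on isomorphic weighted neighborhoods: without it, siblings with
equal (deg, d) but different parents can be swapped by assignment ties,
and the reordered adjacency matrices then differ for identical trees.
The final score is the Frobenius norm of the difference of the two
aligned distance-weighted adjacency matrices (pseudo rows/columns zero).
It is non-negative, zero on isomorphic weighted neighborhoods, invariant
to node relabeling, and symmetric up to assignment ties (exact ties have
measure zero for continuous edge weights).

## Linking

Candidates per node: frame-T+1 nodes within
min(distance to the node's 10th nearest neighbor *within frame T*,
max_node_speed × frame interval). The in-frame radius adapts to local
network density; defaults are nn_threshold = 10 and 1 µm/s.

Combined cost = distance^α · topology^β with α = β = 1. The
termination/initiation alternative cost is the 98th percentile of the
*cost history*; the history accumulates every candidate cost of the
previous assignment problems (capped at the most recent 50 000). Feeding
it only the accepted link costs is unstable: the first-pair bootstrap
(2 × the minimum candidate cost) is nearly zero for product costs, only
near-zero links then get accepted, and the percentile of accepted costs
can never climb back — the linked fraction collapses to a few percent.
With the full cost distribution the linked fraction settles at 97–99 %
after the first frame pair. The first pair itself still uses the printed
2 × minimum bootstrap and therefore links almost nothing; movies should
be long enough that this warm-up pair is a negligible fraction of links.

The padded matrix follows the u-track construction: link block,
diagonal termination/initiation blocks at the alternative cost, and a
transposed auxiliary block filled with the minimum cost; it is solved
with scipy's Jonker–Volgenant-family solver. Corrections, in order:

1. unlink arrows longer than 3× the mean displacement of the largest
   coherently tracked arrow set of the same source segment;
2. unlink an arrow whose target segment is reached by no other arrow from
   the node's neighborhood (graph neighbors or same segment) — "a single
   node tracked alone to an isolated segment";
3. for arrows deviating more than 30° from their segment's mean direction
   (only when at least 3 conforming reference arrows exist), reassign to
   the nearest unclaimed node around the reference-predicted position.
   Reassignments never steal a node already claimed by another arrow; a
   stealing variant was tried against simulation ground truth and lowered
   precision.

Unlinked nodes become terminations/initiations; the LAP is not re-run.
Warnings (never fatal) flag links faster than 1 µm/s, linked fractions
below 75 %, and node-count fluctuations above 20 %.

## Gap closing

Tracks longer than min_track_size (default 4 frames) are sorted by start
frame. A pair (A ends, B starts) qualifies when 1 < gap < max_gap_size
(default 5) and the end-to-start distance is below
gap × 9 × var(pooled per-frame displacement magnitudes of A and B).
The pair cost reuses the linking form with the classic networks of A's
end frame and B's start frame. The start-frame-sorted cost matrix is
solved in overlapping N×N blocks (N = max_gap_size × average tracks per
frame, advanced by 0.8 N); chains A→B→C merge greedily in block order.
min_track_size and max_gap_size have no published defaults; 4 and 5
frames suit movies of order 100 frames with occasional 1–3 frame
segmentation dropouts.

## Simulator

Study conditions (defaults): box 20×20×5 µm with harmonic walls
(k_box = 100), node diameter 0.35 µm, harmonic bond k = 1 and spherical
repulsion k = 1 (per (10 nm)², i.e. reduced thermal units with kT = 1),
harmonic angle k = 10 kT/rad² at 180°, diffusivity D = 0.005 µm²/s,
timestep 2 ms (4 ms in the validation protocol; bond lengths stay within
a few percent of rest length either way, and a drift clamp at one tenth
of the node diameter guards the stiff-force limit). Mobility equals D
(kT = 1), so an unbonded particle obeys MSD = 6Dτ exactly — the
calibration anchor tested to sub-percent precision.

The initial topology is an Erdős–Rényi mixture: partitions of 60 nodes at
mean degree 1.0, isolated nodes removed, accumulated to exactly 300 nodes
(the last partition is trimmed leaf by leaf; a partition that cannot land
exactly is regenerated). Classic edges are subdivided by 2–5 bulk
particles at the node diameter and the network is laid out by
breadth-first traversal in box-respecting random directions; equilibration
relaxes the embedding.

Fission deletes one uniformly chosen bond per component with probability
fission_rate × (component edges / total edges), skipping components below
4 nodes and rejecting deletions that would leave a fragment below 4 nodes
(the model explicitly avoids unrealistically small fragments, and real
skeletons do not shed single-node shards). Fusion bonds unbonded pairs
within 0.7 µm (2× node diameter) at fusion_rate, capped at 3 bonds per
particle, excluding pairs that share a bonded neighbor (otherwise
next-nearest chain neighbors, which sit near the capture radius,
triangulate constantly) and pairs within a refractory period (default
1000 steps) of their own fission — without the refractory period most
fission events re-fuse within a fraction of a frame and the event log
stops describing persistent remodeling. Rate balancing alternates
remodeling epochs with damped rate updates (ratio of mean fragment size
to its pre-remodeling value, clipped to [0.5, 2] per epoch) until the
per-epoch drift falls below 5 %.

Exports shuffle node ids per frame and keep the node→particle map and the
event log, so link precision and detector recall are measured exactly.

## Validation protocol and what it shows

The precision experiment simulates three seeds per condition, samples one
trajectory at intervals of 10–50 s of simulated time, and scores each
movie's links against ground truth. The per-frame node MSD *measured*
from ground truth spans ≈ 0.07–0.30 µm² across these intervals — the
experimentally relevant range for ~seconds-scale volumetric imaging. The
measured MSD sits well below the free-particle 6Dτ at the same interval
because bonded nodes are confined by their neighbors; network motion in
this regime is dominated by fragment-level diffusion, which is exactly
where spatial proximity alone becomes ambiguous (fragments displace
beyond the 0.35 µm node spacing) while network topology remains
informative. Distance-only tracking degrades steeply there; the combined
cost keeps most links correct, reproducing the characteristic ordering of
the two cost schemes. At desk scale the combined-cost precision is ≈ 99 % at the low end of
the MSD grid, declining to ≈ 90 % at 0.29 µm²; with remodeling enabled
it runs a few points lower still (≈ 98 % down to ≈ 84 % at the top of
the grid). The residual errors are adjacent-node swaps along chains and
candidate-radius misses, both growing with per-frame motion, plus
event-site ambiguity when remodeling is on.

Initial fission/fusion rate guesses of 2×10⁻⁴ per step put the balanced
system in the sparse-remodeling regime (a persistent event every few tens
of seconds of simulated time network-wide), matching the phenomenology of
live-cell data where individual events are separable; the detector is
scored only against *persistent* logged bridge fissions (those whose
fragments stay separated for the detection half-window, evaluated on
ground-truth graphs), since the sliding-window criterion is by design
blind to sub-window kiss-and-run events.

What passing these tests does not show: the simulator has no active
transport, no membrane volume, no intensity/width signal, idealized
isotropic diffusion, and exact (noise-free) node positions — real
segmentation adds localization noise, spurious and missing nodes, and
frame-rate-dependent artifacts, so precision on microscopy data depends
on segmentation quality in ways no simulation test can certify.

## Fission/fusion detection

Per-frame fragment labels are made temporally consistent by propagating
them through tracking links (a component inherits the label of the
previous-frame component it shares most tracked nodes with; competitors
get fresh labels). For an edge (u, v) present at the center frame,
fission requires a shared label at every frame of [c−h, c] and disjoint
label sets over [c+1, c+h]; fusion is the exact time-reversal (edge at
c+1, disjoint over [c+1−h, c], shared over [c+1, c+h+1]), so fusion
detection on a reversed movie equals fission detection forward. The
default half-window h = 2 rejects single-frame transients at minimal
latency. Same-type events at one center frame whose nodes lie < 5 edges
apart merge into one site. Event asymmetry uses the two fragments' node
counts on the separated side of the boundary.

## Motility and temporal metrics

MSD fits go through the origin (MSD(0) = 0; the model has no intercept),
with R² reported against the mean. Segment/fragment motion is the motion
of the centroid of member nodes. Vector correlation is v₁·v₂ divided by
the squared norm of the longer vector — bounded in [−1, 1] and deliberately
penalizing magnitude mismatch; it is undefined (and excluded) when both
vectors vanish. Diffusivity maps use a ±10 frame window and skip entities
with fewer than 3 points.

Temporal intersection at t is the fraction of frame-t nodes with a
correspondent at t−1; mean degree difference averages |Δdegree| over the
linked nodes (a signed average would cancel). Token diffusion seeds every
node with its own label at first appearance, performs one synchronous
neighbor-union round per frame, and carries tokens along correspondences;
reachability is the final unique-token count over the number of sources.
Temporal betweenness counts earliest-arrival time-respecting paths
(Brandes-style accumulation over the layered node-time DAG) per persistent
node identity; start frames are exhaustive for small movies and every 5th
frame above 200 node-frames — an explicit approximation knob. Resilience
experiments remove the top-betweenness (or random) identities from every
frame and rerun the token diffusion; reachability after removal is
normalized by the reduced network's own source count.

## Known limitations

* The first frame pair of every movie under-links by construction
  (alternative-cost bootstrap); statistics should discard or out-weigh it.
* Correction rule 2 intentionally sacrifices true links to newly isolated
  single-node fragments; the simulator avoids generating such fragments,
  but segmentation noise in real data will trigger it.
* The block-wise gap closer is sub-optimal near block boundaries (bounded
  by the overlap fraction); exact equivalence to the full matrix is only
  checked statistically.
* Exhaustive temporal betweenness is O(V²T) and is meant for movies of at
  most a few hundred node-frames without sampling.
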