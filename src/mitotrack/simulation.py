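"""Reaction-diffusion polymer simulation of mitochondrial networks.

Ground-truth generator for validating the tracker: mitochondrial skeleton
nodes are modeled as diffusive particles connected into a network by
harmonic potentials, inside a cell-like rectangular box.

Model
-----
* Box 20 x 20 x 5 um with a harmonic confinement potential (k_box = 100)
  outside the walls.
* Particles repel below the tubule diameter of 0.35 um (harmonic spherical
  repulsion), bonded pairs sit at a harmonic bond (k_bond = 1) with rest
  length equal to the node diameter, and every bonded triple feels a
  harmonic angle potential (k_angle = 10, equilibrium 180 degrees) that
  keeps tubules locally straight.  Force constants are in reduced (thermal)
  units per simulation length unit (10 nm), i.e. k_bond = 1 kT per (10 nm)^2.
* Motion is overdamped Langevin: displacement per step is D*dt*F plus an
  isotropic Gaussian kick of variance 2*D*dt per axis (kT = 1, so the
  mobility equals the diffusivity D, default 0.005 um^2/s).
* Fission removes one uniformly chosen bond per connected component with
  probability fission_rate * (component edges / total edges), skipping
  components below four nodes; fusion bonds any unbonded particle pair
  closer than twice the node diameter with probability fusion_rate, capped
  at three bonds per particle and excluding pairs that already share a
  bonded neighbor.  A refractory period keeps a just-fissioned pair from
  instantly re-fusing before it can diffuse apart, so logged events are
  persistent network changes.

The initial network is a mixture of Erdos-Renyi partitions (n = 60 nodes at
mean degree 1.0, isolated nodes removed) accumulated to exactly N = 300
classic nodes; every classic edge is subdivided by 2-5 bulk particles when
the network is embedded in space.

Exported movies carry the per-frame skeleton graphs with shuffled node ids,
the ground-truth particle identity of every exported node, and the
fission/fusion event log, which is what tracking validation scores against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .skeleton import SkeletonFrame

log = logging.getLogger(__name__)


@dataclass
class SimulationParams:
    """Physical and network parameters of the simulator (um, s, kT)."""

    box: tuple[float, float, float] = (20.0, 20.0, 5.0)
    unit_length: float = 0.01        # 10 nm, the reduced length unit
    k_box: float = 100.0             # per unit_length^2
    node_diameter: float = 0.35      # um
    k_bond: float = 1.0              # per unit_length^2
    k_repulsion: float = 1.0         # per unit_length^2
    k_angle: float = 10.0            # per rad^2
    diffusivity: float = 0.005       # um^2/s
    dt: float = 0.002                # s; keeps per-step moves << node size
    partition_size: int = 60         # ER partition node count
    partition_mean_degree: float = 1.0
    total_nodes: int = 300           # classic nodes before bulk subdivision
    bulk_range: tuple[int, int] = (2, 5)  # bulk nodes per classic edge
    fission_rate: float = 0.0        # per-step probability scale
    fusion_rate: float = 0.0
    fusion_capture_factor: float = 2.0  # capture radius = factor * diameter
    min_fission_size: int = 4        # nodes; smaller fragments never fission
    max_bonds: int = 3               # degree cap at fusion
    refractory_steps: int = 1000     # no re-fusion of a fissioned pair
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k_box", "k_bond", "k_repulsion", "k_angle"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("fission_rate", "fusion_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.total_nodes < self.partition_size:
            raise ValueError("total_nodes must be >= partition_size")

    @property
    def fusion_capture_radius(self) -> float:
        return self.fusion_capture_factor * self.node_diameter

    @property
    def box_lo(self) -> np.ndarray:
        return -0.5 * np.asarray(self.box)

    @property
    def box_hi(self) -> np.ndarray:
        return 0.5 * np.asarray(self.box)


@dataclass
class RemodelingEventLogEntry:
    step: int
    kind: str  # 'fission' | 'fusion'
    u: int     # particle ids
    v: int


@dataclass
class SimulationState:
    """Particle positions, bond topology and event log of a running sim."""

    positions: np.ndarray                 # (P, 3) um
    bonds: set[tuple[int, int]]           # sorted particle-id pairs
    step: int = 0
    event_log: list[RemodelingEventLogEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._bond_arr: np.ndarray | None = None
        self._triples: np.ndarray | None = None
        self._labels: np.ndarray | None = None
        self._adj: tuple[np.ndarray, list[set[int]]] | None = None
        self.bond_version = 0

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    def bond_array(self) -> np.ndarray:
        if self._bond_arr is None:
            self._bond_arr = (np.array(sorted(self.bonds), dtype=np.int64)
                              .reshape(-1, 2))
        return self._bond_arr

    def angle_triples(self) -> np.ndarray:
        """All bonded triples (i, j, k) centered at j, each pair once."""
        if self._triples is None:
            adj: dict[int, list[int]] = {}
            for u, v in self.bonds:
                adj.setdefault(u, []).append(v)
                adj.setdefault(v, []).append(u)
            triples = []
            for j, nbrs in adj.items():
                nbrs = sorted(nbrs)
                for a in range(len(nbrs)):
                    for b in range(a + 1, len(nbrs)):
                        triples.append((nbrs[a], j, nbrs[b]))
            self._triples = (np.array(sorted(triples), dtype=np.int64)
                             .reshape(-1, 3))
        return self._triples

    def add_bond(self, u: int, v: int) -> None:
        self.bonds.add((min(u, v), max(u, v)))
        self._invalidate()

    def remove_bond(self, u: int, v: int) -> None:
        self.bonds.remove((min(u, v), max(u, v)))
        self._invalidate()

    def _invalidate(self) -> None:
        self._bond_arr = self._triples = self._labels = self._adj = None
        self.bond_version += 1

    def components(self) -> np.ndarray:
        """Connected-component label per particle (cached per topology)."""
        if self._labels is None:
            P = self.n_particles
            ba = self.bond_array()
            if not len(ba):
                self._labels = np.arange(P)
            else:
                g = csr_matrix((np.ones(len(ba)), (ba[:, 0], ba[:, 1])),
                               shape=(P, P))
                _, self._labels = connected_components(g, directed=False)
        return self._labels

    def adjacency(self) -> tuple[np.ndarray, list[set[int]]]:
        """(degree array, neighbor sets) cached per topology."""
        if self._adj is None:
            deg = np.zeros(self.n_particles, dtype=np.int64)
            nbrs: list[set[int]] = [set() for _ in range(self.n_particles)]
            for u, v in self.bonds:
                deg[u] += 1
                deg[v] += 1
                nbrs[u].add(v)
                nbrs[v].add(u)
            self._adj = (deg, nbrs)
        return self._adj


# --------------------------------------------------------------------------
# network generation
# --------------------------------------------------------------------------

def _er_partition(n: int, mean_degree: float, rng: np.random.Generator
                  ) -> list[tuple[int, int]]:
    """One Erdos-Renyi partition on local ids 0..n-1, isolated nodes removed."""
    p = mean_degree / (n - 1)
    mask = np.triu(rng.random((n, n)) < p, k=1)
    ii, jj = np.nonzero(mask)
    keep = sorted(set(ii) | set(jj))
    relabel = {old: new for new, old in enumerate(keep)}
    return [(relabel[i], relabel[j]) for i, j in zip(ii, jj)], len(keep)


def generate_initial_network(params: SimulationParams,
                             rng: np.random.Generator
                             ) -> list[tuple[int, int]]:
    """Classic-network bond topology: an ER mixture with exactly N nodes.

    Partitions are accumulated until the node total reaches N; the last
    partition is trimmed leaf-by-leaf to land exactly on N (regenerated if
    trimming cannot, which only happens when every remaining fragment is a
    bonded pair).  Every node has degree >= 1.
    """
    N = params.total_nodes
    for _ in range(100):
        edges: list[tuple[int, int]] = []
        total = 0
        slot_retries = 0
        while total < N:
            part, n_part = _er_partition(params.partition_size,
                                         params.partition_mean_degree, rng)
            if total + n_part > N:
                trimmed = _trim_partition(part, n_part, N - total)
                if trimmed is None:
                    # the remaining slot may be structurally unfillable
                    # (e.g. a single node, which cannot have degree >= 1):
                    # after a few fresh draws, restart the whole assembly
                    slot_retries += 1
                    if slot_retries > 20:
                        break
                    continue
                part, n_part = trimmed
            edges.extend((u + total, v + total) for u, v in part)
            total += n_part
        if total == N:
            return edges
    raise RuntimeError("could not assemble initial network")


def _trim_partition(edges, n: int, target: int):
    """Remove leaves until the partition has exactly ``target`` nodes."""
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    alive = set(range(n))
    while len(alive) > target:
        leaf = next((v for v in sorted(alive)
                     if len(adj[v]) == 1
                     and len(adj[next(iter(adj[v]))]) >= 2), None)
        if leaf is None:
            # only bonded pairs (or cycles) left; drop a whole pair
            pair = next((v for v in sorted(alive) if len(adj[v]) == 1), None)
            if pair is None or len(alive) - 2 < target:
                return None
            other = next(iter(adj[pair]))
            for v in (pair, other):
                for w in adj[v]:
                    adj[w].discard(v)
                adj[v] = set()
                alive.discard(v)
            continue
        nb = next(iter(adj[leaf]))
        adj[nb].discard(leaf)
        adj[leaf] = set()
        alive.discard(leaf)
    relabel = {old: new for new, old in enumerate(sorted(alive))}
    out = [(relabel[u], relabel[v]) for u in sorted(alive) for v in adj[u]
           if u < v]
    return out, len(alive)


def embed_full_resolution(topology: list[tuple[int, int]],
                          params: SimulationParams,
                          rng: np.random.Generator) -> SimulationState:
    """Place the classic network in the box and subdivide edges with bulk
    particles.

    Each component is traversed breadth-first from a randomly placed root;
    every classic edge is replaced by a straight chain of 2-5 bulk particles
    spaced at the node diameter, in a random direction that keeps the chain
    inside the box (retried, then clamped).  Relaxation during equilibration
    removes residual overlaps.
    """
    n_classic = 1 + max(max(e) for e in topology) if topology else 0
    adj: dict[int, list[int]] = {i: [] for i in range(n_classic)}
    for u, v in topology:
        adj[u].append(v)
        adj[v].append(u)
    d0 = params.node_diameter
    margin = 2.0 * d0
    lo, hi = params.box_lo + margin, params.box_hi - margin

    positions: list[np.ndarray] = [None] * n_classic
    bonds: set[tuple[int, int]] = set()
    placed = [False] * n_classic
    next_id = n_classic  # bulk particles appended after classic ones

    def chain_between(pa: np.ndarray, pb: np.ndarray | None, start: int,
                      end: int, n_bulk: int):
        """Lay bulk particles from start (at pa) towards end (at pb)."""
        nonlocal next_id
        if pb is None:
            for _ in range(30):
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                pb_try = pa + direction * (n_bulk + 1) * d0
                if np.all(pb_try > lo) and np.all(pb_try < hi):
                    break
            pb = np.clip(pa + direction * (n_bulk + 1) * d0, lo, hi)
            positions[end] = pb
            placed[end] = True
        pts = np.linspace(pa, pb, n_bulk + 2)[1:-1]
        prev = start
        for p in pts:
            positions.append(np.clip(p, lo, hi))
            bonds.add((min(prev, next_id), max(prev, next_id)))
            prev = next_id
            next_id += 1
        bonds.add((min(prev, end), max(prev, end)))

    b_lo, b_hi = params.bulk_range
    for root in range(n_classic):
        if placed[root]:
            continue
        positions[root] = rng.uniform(lo, hi)
        placed[root] = True
        queue = [root]
        seen_edges: set[tuple[int, int]] = set()
        while queue:
            u = queue.pop(0)
            for v in sorted(adj[u]):
                key = (min(u, v), max(u, v))
                if key in seen_edges:
                    continue
                seen_edges.add(key)
                n_bulk = int(rng.integers(b_lo, b_hi + 1))
                if placed[v]:
                    chain_between(positions[u], positions[v], u, v, n_bulk)
                else:
                    chain_between(positions[u], None, u, v, n_bulk)
                    queue.append(v)
    pos = np.array(positions).reshape(-1, 3)
    return SimulationState(positions=pos, bonds=bonds)


# --------------------------------------------------------------------------
# dynamics
# --------------------------------------------------------------------------

class PairCache:
    """Skin-radius neighbor list, rebuilt only after sufficient motion.

    Candidate pairs within ``radius + skin`` are cached from a KD-tree
    build; callers filter by exact distance.  Rebuilt when any particle has
    moved more than skin/2 since the build, so no true pair within
    ``radius`` is ever missed.
    """

    def __init__(self, radius: float, skin: float = 0.2):
        self.radius = radius
        self.skin = skin
        self._pairs: np.ndarray | None = None
        self._built_at: np.ndarray | None = None
        self._build_id = 0
        self._unbonded_key: tuple[int, int] | None = None
        self._unbonded: np.ndarray | None = None

    def pairs(self, positions: np.ndarray) -> np.ndarray:
        if (self._pairs is None
                or len(self._built_at) != len(positions)
                or np.max(np.abs(positions - self._built_at))
                > self.skin / 2):
            tree = cKDTree(positions)
            self._pairs = tree.query_pairs(self.radius + self.skin,
                                           output_type="ndarray")
            self._built_at = positions.copy()
            self._build_id += 1
        return self._pairs

    def unbonded_mask(self, state: "SimulationState") -> np.ndarray:
        """Which cached pairs are not bonds (cached per build/topology)."""
        key = (self._build_id, state.bond_version)
        if self._unbonded_key != key:
            P = state.n_particles
            ba = state.bond_array()
            if len(ba):
                self._unbonded = ~np.isin(
                    self._pairs[:, 0] * P + self._pairs[:, 1],
                    ba[:, 0] * P + ba[:, 1])
            else:
                self._unbonded = np.ones(len(self._pairs), dtype=bool)
            self._unbonded_key = key
        return self._unbonded


def compute_forces(state: SimulationState, params: SimulationParams,
                   pair_cache: PairCache | None = None) -> np.ndarray:
    """Total deterministic force (kT/um) on every particle."""
    pos = state.positions
    F = np.zeros_like(pos)
    inv_ul2 = 1.0 / params.unit_length ** 2
    d0 = params.node_diameter

    ba = state.bond_array()
    if len(ba):
        dvec = pos[ba[:, 1]] - pos[ba[:, 0]]
        r = np.linalg.norm(dvec, axis=1)
        r = np.maximum(r, 1e-12)
        fmag = params.k_bond * inv_ul2 * (r - d0)
        fvec = (fmag / r)[:, None] * dvec
        np.add.at(F, ba[:, 0], fvec)
        np.add.at(F, ba[:, 1], -fvec)

    # spherical repulsion for all pairs below the node diameter
    if params.k_repulsion > 0 and len(pos) > 1:
        if pair_cache is not None:
            pairs = pair_cache.pairs(pos)
        else:
            pairs = cKDTree(pos).query_pairs(d0, output_type="ndarray")
        if len(pairs):
            dvec = pos[pairs[:, 1]] - pos[pairs[:, 0]]
            r = np.maximum(np.linalg.norm(dvec, axis=1), 1e-12)
            close = r < d0
            if len(ba):
                if pair_cache is not None:
                    close &= pair_cache.unbonded_mask(state)
                else:
                    P = len(pos)
                    close &= ~np.isin(pairs[:, 0] * P + pairs[:, 1],
                                      ba[:, 0] * P + ba[:, 1])
            pairs, dvec, r = pairs[close], dvec[close], r[close]
        if len(pairs):
            fmag = params.k_repulsion * inv_ul2 * (r - d0)  # negative: push
            fvec = (fmag / r)[:, None] * dvec
            np.add.at(F, pairs[:, 0], fvec)
            np.add.at(F, pairs[:, 1], -fvec)

    tri = state.angle_triples()
    if len(tri) and params.k_angle > 0:
        a = pos[tri[:, 0]] - pos[tri[:, 1]]
        b = pos[tri[:, 2]] - pos[tri[:, 1]]
        na = np.maximum(np.linalg.norm(a, axis=1), 1e-12)
        nb = np.maximum(np.linalg.norm(b, axis=1), 1e-12)
        cos = np.clip(np.einsum("ij,ij->i", a, b) / (na * nb), -1.0, 1.0)
        theta = np.arccos(cos)
        sin = np.sqrt(np.maximum(1.0 - cos ** 2, 1e-12))
        # dU/dtheta = k (theta - pi); near theta = pi the prefactor
        # (theta-pi)/sin -> -1, so the clamped sin stays well behaved
        pref = params.k_angle * (theta - np.pi) / sin
        dcos_di = (b - cos[:, None] * a * (nb / na)[:, None]) / (na * nb)[:, None]
        dcos_dk = (a - cos[:, None] * b * (na / nb)[:, None]) / (na * nb)[:, None]
        Fi = pref[:, None] * dcos_di
        Fk = pref[:, None] * dcos_dk
        np.add.at(F, tri[:, 0], Fi)
        np.add.at(F, tri[:, 2], Fk)
        np.add.at(F, tri[:, 1], -(Fi + Fk))

    # harmonic box confinement
    clamped = np.clip(pos, params.box_lo, params.box_hi)
    F -= params.k_box * inv_ul2 * (pos - clamped)
    if not np.all(np.isfinite(F)):
        raise FloatingPointError("non-finite force")
    return F


def step_dynamics(state: SimulationState, params: SimulationParams,
                  rng: np.random.Generator,
                  pair_cache: PairCache | None = None) -> SimulationState:
    """One overdamped Langevin step (in place); returns the state."""
    D, dt = params.diffusivity, params.dt
    F = compute_forces(state, params, pair_cache)
    drift = D * dt * F  # mobility = D with kT = 1
    # stability clamp: deterministic move bounded by a tenth of a node
    max_move = 0.1 * params.node_diameter
    norms = np.linalg.norm(drift, axis=1)
    too_far = norms > max_move
    if np.any(too_far):
        drift[too_far] *= (max_move / norms[too_far])[:, None]
    noise = rng.normal(scale=np.sqrt(2.0 * D * dt), size=state.positions.shape)
    state.positions = state.positions + drift + noise
    state.step += 1
    return state


# --------------------------------------------------------------------------
# remodeling reactions
# --------------------------------------------------------------------------

def apply_remodeling(state: SimulationState, params: SimulationParams,
                     rng: np.random.Generator,
                     recent_fissions: dict[tuple[int, int], int] | None = None,
                     pair_cache: PairCache | None = None
                     ) -> SimulationState:
    """Stochastic fission and fusion reactions for the current step."""
    recent = recent_fissions if recent_fissions is not None else {}

    # fission: per component, delete one random bond with probability
    # proportional to the component's share of all edges
    if params.fission_rate > 0 and state.bonds:
        labels = state.components()
        ba = state.bond_array()
        total_edges = len(ba)
        comp_sizes = np.bincount(labels)
        bond_comp = labels[ba[:, 0]]
        comp_edge_count = np.bincount(bond_comp,
                                      minlength=len(comp_sizes))
        comps = np.nonzero(
            (comp_sizes >= params.min_fission_size)
            & (comp_edge_count > 0))[0]
        if len(comps):
            probs = params.fission_rate * comp_edge_count[comps] / total_edges
            fire = comps[rng.random(len(comps)) < probs]
            for comp in fire:
                comp_bonds = ba[bond_comp == comp]
                # unrealistically small shards are avoided: a bond whose
                # removal would leave a fragment below min_fission_size
                # is not a fission candidate
                order = rng.permutation(len(comp_bonds))
                for idx in order:
                    u, v = int(comp_bonds[idx, 0]), int(comp_bonds[idx, 1])
                    state.remove_bond(u, v)
                    lab = state.components()
                    sizes = np.bincount(lab)
                    if min(sizes[lab[u]], sizes[lab[v]]) \
                            >= params.min_fission_size:
                        key = (min(u, v), max(u, v))
                        recent[key] = state.step
                        state.event_log.append(RemodelingEventLogEntry(
                            state.step, "fission", key[0], key[1]))
                        break
                    state.add_bond(u, v)  # rejected: restore and retry

    # fusion: unbonded pairs within the capture radius
    if params.fusion_rate > 0 and state.n_particles > 1:
        if pair_cache is not None:
            pairs = pair_cache.pairs(state.positions)
        else:
            pairs = cKDTree(state.positions).query_pairs(
                params.fusion_capture_radius, output_type="ndarray")
        if len(pairs):
            d = np.linalg.norm(state.positions[pairs[:, 1]]
                               - state.positions[pairs[:, 0]], axis=1)
            pairs = pairs[d < params.fusion_capture_radius]
        if len(pairs):
            # draw acceptance up front; constraints checked sequentially
            # for the (rare) accepted pairs in random order
            accepted = pairs[rng.random(len(pairs)) < params.fusion_rate]
        else:
            accepted = pairs
        if len(accepted):
            degree, nbrs = state.adjacency()
            degree = degree.copy()
            for idx in rng.permutation(len(accepted)):
                u, v = int(accepted[idx, 0]), int(accepted[idx, 1])
                key = (min(u, v), max(u, v))
                if key in state.bonds:
                    continue
                if degree[u] >= params.max_bonds \
                        or degree[v] >= params.max_bonds:
                    continue
                if nbrs[u] & nbrs[v]:
                    continue  # sharing a neighbor: no trivial triangles
                last = recent.get(key)
                if last is not None \
                        and state.step - last < params.refractory_steps:
                    continue
                state.add_bond(u, v)
                degree[u] += 1
                degree[v] += 1
                nbrs[u] = nbrs[u] | {v}
                nbrs[v] = nbrs[v] | {u}
                state.event_log.append(RemodelingEventLogEntry(
                    state.step, "fusion", key[0], key[1]))
    return state


def mean_fragment_size(state: SimulationState) -> float:
    labels = state.components()
    return float(np.mean(np.bincount(labels)))


# --------------------------------------------------------------------------
# driver
# --------------------------------------------------------------------------

class Simulation:
    """A runnable simulator instance with persistent RNG and state."""

    def __init__(self, params: SimulationParams | None = None,
                 seed: int | None = None):
        self.params = params or SimulationParams()
        self.rng = np.random.default_rng(
            self.params.seed if seed is None else seed)
        topology = generate_initial_network(self.params, self.rng)
        self.state = embed_full_resolution(topology, self.params, self.rng)
        self.recent_fissions: dict[tuple[int, int], int] = {}
        self.pair_cache = PairCache(
            radius=max(self.params.node_diameter,
                       self.params.fusion_capture_radius))

    def equilibrate(self, n_steps: int) -> None:
        """Relax the embedded network without remodeling reactions."""
        for _ in range(n_steps):
            step_dynamics(self.state, self.params, self.rng,
                          self.pair_cache)

    def run(self, n_steps: int, remodeling: bool = True,
            record_every: int | None = None):
        """Advance the simulation; optionally record (step, pos, bonds)."""
        snapshots = []
        if record_every:
            snapshots.append((self.state.step, self.state.positions.copy(),
                              set(self.state.bonds)))
        for i in range(n_steps):
            step_dynamics(self.state, self.params, self.rng,
                          self.pair_cache)
            if remodeling:
                apply_remodeling(self.state, self.params, self.rng,
                                 self.recent_fissions, self.pair_cache)
            if record_every and (i + 1) % record_every == 0:
                snapshots.append((self.state.step,
                                  self.state.positions.copy(),
                                  set(self.state.bonds)))
        return snapshots


def balance_rates(params: SimulationParams,
                  seed: int | None = None,
                  equil_steps: int = 2000,
                  epoch_steps: int = 2000,
                  max_epochs: int = 20,
                  tol: float = 0.05) -> tuple[float, float]:
    """Balance fission and fusion rates toward steady fragment statistics.

    Runs remodeling epochs after an equilibration phase and rescales the
    rates by the ratio of current to initial mean fragment size after each
    epoch, until the per-epoch drift falls below ``tol``.  Returns the
    balanced (fission_rate, fusion_rate); a warning is logged when the
    scheme does not converge within ``max_epochs``.
    """
    if params.fission_rate == 0 and params.fusion_rate == 0:
        return 0.0, 0.0
    from dataclasses import replace
    p = replace(params)
    sim = Simulation(p, seed=seed)
    sim.equilibrate(equil_steps)
    target = mean_fragment_size(sim.state)
    prev = target
    for epoch in range(max_epochs):
        sim.run(epoch_steps, remodeling=True)
        cur = mean_fragment_size(sim.state)
        drift = abs(cur / prev - 1.0)
        # damped update: one epoch may not change the rates by more than 2x
        ratio = float(np.clip(cur / target, 0.5, 2.0))
        p.fission_rate = min(max(p.fission_rate * ratio, 0.0), 1.0)
        p.fusion_rate = min(max(p.fusion_rate / ratio, 0.0), 1.0)
        sim.params = p
        if drift < tol:
            return p.fission_rate, p.fusion_rate
        prev = cur
    log.warning("rate balancing did not converge in %d epochs", max_epochs)
    return p.fission_rate, p.fusion_rate


# --------------------------------------------------------------------------
# export
# --------------------------------------------------------------------------

@dataclass
class ExportedMovie:
    """Simulator frames with ground truth for scoring the tracker."""

    frames: list[SkeletonFrame]
    ground_truth: list[dict[int, int]]   # per frame: node id -> particle id
    events: list[tuple[int, str, int, int]]  # (boundary frame, kind, u, v)
    frame_interval: float                # s
    nominal_msd: float                   # 6 D tau, um^2
    measured_msd: float                  # mean per-frame MSD, um^2


def export_frames(snapshots, params: SimulationParams,
                  sample_interval: int,
                  events: list[RemodelingEventLogEntry] | None = None,
                  rng: np.random.Generator | None = None,
                  shuffle_ids: bool = True) -> ExportedMovie:
    """Convert recorded snapshots (taken every ``sample_interval`` steps)
    into skeleton frames with ground-truth identity maps.

    Node ids are shuffled per frame so exported labels carry no identity
    information; the ground-truth map recovers the particle id of every
    exported node.  Events are assigned to the frame boundary they fall in.
    """
    rng = rng or np.random.default_rng(params.seed + 7)
    tau = sample_interval * params.dt
    frames: list[SkeletonFrame] = []
    gt: list[dict[int, int]] = []
    msds = []
    prev_pos = None
    first_step = snapshots[0][0]
    for fi, (step, pos, bonds) in enumerate(snapshots):
        P = len(pos)
        perm = rng.permutation(P) if shuffle_ids else np.arange(P)
        # perm[particle] = exported node id
        node_ids = np.arange(P)
        order = np.argsort(perm)  # node id -> particle
        positions = pos[order]
        edges = np.array([[perm[u], perm[v]] for u, v in sorted(bonds)],
                         dtype=np.int64).reshape(-1, 2)
        frames.append(SkeletonFrame(
            frame_index=fi, node_ids=node_ids, positions=positions,
            edges=edges, frame_interval=tau))
        gt.append({int(perm[p]): int(p) for p in range(P)})
        if prev_pos is not None:
            msds.append(float(np.mean(
                np.sum((pos - prev_pos) ** 2, axis=1))))
        prev_pos = pos
    ev_out = []
    if events:
        for e in events:
            boundary = (e.step - first_step - 1) // sample_interval
            if 0 <= boundary < len(frames) - 1:
                ev_out.append((int(boundary), e.kind, e.u, e.v))
    return ExportedMovie(
        frames=frames, ground_truth=gt, events=ev_out,
        frame_interval=tau,
        nominal_msd=6.0 * params.diffusivity * tau,
        measured_msd=float(np.mean(msds)) if msds else 0.0)


def tracking_precision(link_maps: list[dict[int, int]],
                       ground_truth: list[dict[int, int]]
                       ) -> tuple[float, int, int]:
    """Fraction of links whose endpoints are the same ground-truth particle.

    Returns (precision, correct links, total links).
    """
    correct = total = 0
    for t, links in enumerate(link_maps):
        gt_t, gt_t1 = ground_truth[t], ground_truth[t + 1]
        for m, n in links.items():
            total += 1
            if gt_t.get(m) == gt_t1.get(n):
                correct += 1
    return (correct / total if total else float("nan")), correct, total
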