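import numpy as np
import pytest

from mitotrack.skeleton import SkeletonFrame


def make_frame(idx, positions, edges, tau=1.0, node_ids=None, **kw):
    positions = np.asarray(positions, dtype=float)
    if node_ids is None:
        node_ids = np.arange(len(positions))
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    return SkeletonFrame(idx, np.asarray(node_ids), positions, edges,
                         tau, **kw)


def path_frame(n, spacing=1.0, idx=0, tau=1.0):
    pos = np.zeros((n, 3))
    pos[:, 0] = np.arange(n) * spacing
    return make_frame(idx, pos, [[i, i + 1] for i in range(n - 1)], tau)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_geometric_frame(rng, n=50, idx=0, tau=1.0, box=10.0,
                           edge_prob=0.06):
    """Small random spatial graph (simple, no self loops)."""
    pos = rng.uniform(0, box, size=(n, 3))
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < edge_prob:
                edges.append([i, j])
    return make_frame(idx, pos, edges or np.zeros((0, 2)), tau)


# --------------------------------------------------------------------------
# independent oracles shared across test modules
# --------------------------------------------------------------------------

def lap_brute_force(link, mask, b):
    """Exhaustive optimum of the padded linking objective.

    Every solution with k links pays k link costs, (n-k)+(m-k)
    alternative costs, and k auxiliary entries at the minimum allowed
    cost (the padded matrix's lower-right block).
    """
    import itertools
    n, m = link.shape
    aux = link[mask].min() if mask.any() else 0.0
    best = np.inf
    for k in range(0, min(n, m) + 1):
        for rsub in itertools.combinations(range(n), k):
            for csub in itertools.permutations(range(m), k):
                if not all(mask[r, c] for r, c in zip(rsub, csub)):
                    continue
                cost = sum(link[r, c] for r, c in zip(rsub, csub))
                cost += b * ((n - k) + (m - k)) + k * aux
                best = min(best, cost)
    return best


def solve_padded_lap(link, mask, b):
    """Padded (u-track style) LAP solve; returns (total, links)."""
    from scipy.optimize import linear_sum_assignment
    from mitotrack.tracking import BLOCK
    n, m = link.shape
    full = np.full((n + m, n + m), BLOCK)
    full[:n, :m] = np.where(mask, link, BLOCK)
    full[np.arange(n), m + np.arange(n)] = b
    full[n + np.arange(m), np.arange(m)] = b
    finite = link[mask]
    if len(finite):
        full[n:, m:][mask.T] = finite.min()
    rows, cols = linear_sum_assignment(full)
    links = [(r, c) for r, c in zip(rows, cols)
             if r < n and c < m and full[r, c] < BLOCK]
    return float(full[rows, cols].sum()), links


def temporal_successors_oracle(tn, t):
    """Diffuse-then-carry successors, re-derived for path enumeration."""
    frame = tn.frames[t]
    corr = tn.correspondence[t]
    adj = {int(v): {int(v)} for v in frame.node_ids}
    for u, v in frame.edges:
        adj[int(u)].add(int(v))
        adj[int(v)].add(int(u))
    return {u: {corr[w] for w in closed if w in corr}
            for u, closed in adj.items()}


def enumerate_time_respecting_paths(tn, s, t0):
    """All time-respecting paths from (t0, s), by exhaustive extension."""
    paths = [[(t0, s)]]
    all_paths = [[(t0, s)]]
    for t in range(t0, tn.n_frames - 1):
        succ = temporal_successors_oracle(tn, t)
        nxt = []
        for p in paths:
            tt, v = p[-1]
            if tt != t:
                continue
            for w in succ.get(v, ()):
                nxt.append(p + [(t + 1, w)])
        all_paths.extend(nxt)
        paths = nxt
    return all_paths
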