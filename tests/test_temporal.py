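"""Temporal-network metrics, token diffusion, betweenness, resilience."""

import itertools

import numpy as np
import pytest

from mitotrack.temporal import (TemporalNetwork, mean_degree_difference,
                                resilience_experiment,
                                simulate_reachability, temporal_betweenness,
                                temporal_intersection)

from conftest import (enumerate_time_respecting_paths as enumerate_paths,
                      make_frame)


def static_tn(edges, n, T, positions=None):
    pos = (np.arange(n * 3, dtype=float).reshape(n, 3)
           if positions is None else positions)
    frames = [make_frame(t, pos, edges if len(edges) else np.zeros((0, 2)))
              for t in range(T)]
    corr = [{i: i for i in range(n)} for _ in range(T - 1)]
    return TemporalNetwork(frames=frames, correspondence=corr)


def random_tn(rng, n=6, T=3, p_edge=0.4, p_link=0.8):
    pos = rng.uniform(0, 5, size=(n, 3))
    frames = []
    for t in range(T):
        edges = [[i, j] for i in range(n) for j in range(i + 1, n)
                 if rng.random() < p_edge]
        frames.append(make_frame(t, pos,
                                 edges if edges else np.zeros((0, 2))))
    corr = []
    for t in range(T - 1):
        c = {i: i for i in range(n) if rng.random() < p_link}
        corr.append(c)
    return TemporalNetwork(frames=frames, correspondence=corr)


class TestScalarMetrics:
    def test_fully_linked_identical_frames(self):
        tn = static_tn([[0, 1], [1, 2]], 3, 3)
        assert temporal_intersection(tn, 1) == 1.0
        assert mean_degree_difference(tn, 1) == 0.0

    def test_no_links_at_all(self):
        tn = static_tn([[0, 1]], 2, 2)
        tn.correspondence[0].clear()
        assert temporal_intersection(tn, 1) == 0.0
        assert np.isnan(mean_degree_difference(tn, 1))

    def test_half_linked(self):
        tn = static_tn([], 10, 2)
        tn.correspondence[0] = {i: i for i in range(5)}
        assert temporal_intersection(tn, 1) == 0.5

    def test_mdd_counts_one_degree_change_among_four(self):
        pos = np.zeros((4, 3))
        pos[:, 0] = np.arange(4)
        f0 = make_frame(0, pos, [[0, 1]])
        f1 = make_frame(1, pos, [[0, 1], [1, 2]])
        tn = TemporalNetwork(frames=[f0, f1],
                             correspondence=[{i: i for i in range(4)}])
        # degrees: node 1: 1->2, node 2: 0->1 -> two changes of 1 each
        assert mean_degree_difference(tn, 1) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_metrics_match_direct_recomputation(self, seed):
        rng = np.random.default_rng(seed)
        tn = random_tn(rng)
        for t in range(1, tn.n_frames):
            corr = tn.correspondence[t - 1]
            nt = len(tn.frames[t])
            expect_ti = len(corr) / nt
            assert temporal_intersection(tn, t) == pytest.approx(expect_ti)
            if corr:
                deg0 = dict(zip(tn.frames[t - 1].node_ids.tolist(),
                                tn.frames[t - 1].degrees.tolist()))
                deg1 = dict(zip(tn.frames[t].node_ids.tolist(),
                                tn.frames[t].degrees.tolist()))
                expect = np.mean([abs(deg1[v] - deg0[u])
                                  for u, v in corr.items()])
                assert mean_degree_difference(tn, t) == pytest.approx(
                    expect)


class TestReachability:
    def test_static_triangle_saturates(self):
        tn = static_tn([[0, 1], [1, 2], [0, 2]], 3, 2)
        reach = simulate_reachability(tn)
        assert reach == {0: 1.0, 1: 1.0, 2: 1.0}

    def test_isolated_nodes_keep_only_their_own_token(self):
        tn = static_tn([], 2, 4)
        reach = simulate_reachability(tn)
        assert reach == {0: 0.5, 1: 0.5}

    def test_path_of_five_after_two_steps(self):
        tn = static_tn([[i, i + 1] for i in range(4)], 5, 2)
        reach = simulate_reachability(tn)
        assert reach[2] == pytest.approx(1.0)
        assert reach[0] == reach[4] == pytest.approx(3 / 5)

    @pytest.mark.parametrize("seed", range(5))
    def test_reachability_matches_path_enumeration_oracle(self, seed):
        """With full correspondences, a node's final token set is exactly
        the set of sources with a time-respecting path to it."""
        rng = np.random.default_rng(seed)
        tn = random_tn(rng, n=6, T=3, p_link=1.0)
        reach = simulate_reachability(tn)
        n = 6
        last = tn.n_frames - 1
        # tokens take one within-frame hop per frame including the last,
        # so paths may end with one extra edge hop in the final frame
        last_adj = {v: {v} for v in range(n)}
        for u, v in tn.frames[last].edges:
            last_adj[int(u)].add(int(v))
            last_adj[int(v)].add(int(u))
        reachable_from = {v: set() for v in range(n)}
        for s in range(n):
            for p in enumerate_paths(tn, s, 0):
                t_end, v_end = p[-1]
                if t_end == last:
                    for w in last_adj[v_end]:
                        reachable_from[w].add(s)
        assert set(reach) == set(range(n))
        for v, r in reach.items():
            assert r == pytest.approx(len(reachable_from[v]) / n)

    def test_token_sets_grow_monotonically(self):
        rng = np.random.default_rng(3)
        tn = random_tn(rng, n=6, T=4)
        # re-run the diffusion keeping intermediate sets; uncorresponded
        # nodes are reseeded with fresh labels as in the implementation
        tokens: dict[int, set] = {}
        next_label = 1000
        for t in range(tn.n_frames):
            for v in tn.frames[t].node_ids:
                if int(v) not in tokens:
                    tokens[int(v)] = {next_label}
                    next_label += 1
            new = {v: set(s) for v, s in tokens.items()}
            for u, v in tn.frames[t].edges:
                new[int(v)] |= tokens[int(u)]
                new[int(u)] |= tokens[int(v)]
            for v in new:
                assert new[v] >= tokens[v]
            tokens = new
            if t < tn.n_frames - 1:
                carried = {v1: tokens[u]
                           for u, v1 in tn.correspondence[t].items()}
                for u, v1 in tn.correspondence[t].items():
                    # carrying preserves the tracked node's token set
                    assert carried[v1] == tokens[u]
                tokens = carried


class TestBetweenness:
    def test_path_middle_node_is_most_central(self):
        tn = static_tn([[0, 1], [1, 2]], 3, 3)
        cent = temporal_betweenness(tn)
        idents = tn.node_identities()
        mid = idents[0][1]
        ends = [idents[0][0], idents[0][2]]
        assert cent[mid] > max(cent[e] for e in ends)

    def test_edgeless_graph_has_zero_centrality(self):
        tn = static_tn([], 4, 3)
        cent = temporal_betweenness(tn)
        assert all(c == 0.0 for c in cent.values())

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_path_enumeration(self, seed):
        """Centrality equals brute-force counting of earliest-arrival
        time-respecting paths on 6-node 3-frame toys."""
        rng = np.random.default_rng(seed)
        tn = random_tn(rng, n=6, T=3, p_link=1.0)
        idents = tn.node_identities()
        cent = temporal_betweenness(tn, start_frames=list(
            range(tn.n_frames - 1)))
        brute = {i: 0.0 for fr in idents for i in fr.values()}
        for t0 in range(tn.n_frames - 1):
            for s in tn.frames[t0].node_ids:
                s = int(s)
                paths = enumerate_paths(tn, s, t0)
                # earliest arrival per identity
                first = {idents[t0][s]: (t0, s)}
                order = sorted(paths, key=len)
                for p in order:
                    t, v = p[-1]
                    ident = idents[t][v]
                    if ident not in first:
                        first[ident] = (t, v)
                for ident, (t_tgt, v_tgt) in first.items():
                    if (t_tgt, v_tgt) == (t0, s):
                        continue
                    tgt_paths = [p for p in paths
                                 if p[-1] == (t_tgt, v_tgt)]
                    for p in tgt_paths:
                        for (tt, vv) in p[1:-1]:
                            brute[idents[tt][vv]] += 1 / len(tgt_paths)
        for i in brute:
            assert cent[i] == pytest.approx(brute[i], abs=1e-9)


class TestResilience:
    def test_zero_removal_changes_nothing(self):
        tn = static_tn([[0, 1], [1, 2]], 3, 3)
        res = resilience_experiment(tn, removal_fraction=0.0)
        assert res["before"] == res["after"]
        assert res["removed"] == []

    def test_invalid_fraction_rejected(self):
        tn = static_tn([[0, 1]], 2, 2)
        with pytest.raises(ValueError):
            resilience_experiment(tn, removal_fraction=1.0)

    def test_removing_barbell_cut_vertex_confines_each_side(self):
        # triangles {0,1,2} and {4,5,6} joined through cut vertex 3
        edges = [[0, 1], [1, 2], [0, 2], [2, 3], [3, 4],
                 [4, 5], [5, 6], [4, 6]]
        tn = static_tn(edges, 7, 6)
        res = resilience_experiment(tn, removal_fraction=1 / 7 + 1e-9,
                                    mode="central")
        assert res["removed"] == [3]
        # each side's nodes reach only their own 3-node side; the reduced
        # network has 6 sources
        for v, r in res["after"].items():
            assert r == pytest.approx(3 / 6)
        assert res["mean_after"] < res["mean_before"]

    def test_central_removal_hurts_at_least_as_much_as_random(self):
        """Averaged over seeds, removing the most central identities
        lowers mean reachability at least as much as random removal."""
        deltas = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            tn = random_tn(rng, n=8, T=4, p_edge=0.25, p_link=0.9)
            c = resilience_experiment(tn, 0.25, "central")
            r = resilience_experiment(tn, 0.25, "random", seed=seed)
            deltas.append(r["mean_after"] - c["mean_after"])
        assert np.mean(deltas) >= -1e-9
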