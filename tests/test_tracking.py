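"""LAP node linking: candidates, cost assembly, solver, corrections,
warnings."""

import itertools

import numpy as np
import pytest

from mitotrack.config import TrackingConfig
from mitotrack.tracking import (AssignmentResult, BLOCK, assemble_cost,
                                apply_corrections, build_candidates,
                                check_warnings, percentile_cost,
                                solve_assignment, track_all)

from conftest import (lap_brute_force, make_frame, path_frame,
                      random_geometric_frame, solve_padded_lap)


def grid_frame(idx, n=5, spacing=5.0, jitter=None, rng=None, tau=1.0):
    """Well-separated singleton nodes on a line."""
    pos = np.zeros((n, 3))
    pos[:, 0] = np.arange(n) * spacing
    if jitter is not None:
        pos = pos + rng.normal(scale=jitter, size=pos.shape)
    return make_frame(idx, pos, np.zeros((0, 2)), tau)


class TestCandidates:
    def test_identical_frames_include_self_at_zero_distance(self):
        f0, f1 = grid_frame(0), grid_frame(1)
        cands = build_candidates(f0, f1, TrackingConfig())
        for i, (idx, dist) in enumerate(cands.candidates):
            assert i in idx
            assert dist[list(idx).index(i)] == pytest.approx(0.0)

    def test_speed_cap_excludes_distant_counterpart(self):
        f0 = make_frame(0, [[0, 0, 0]], np.zeros((0, 2)), tau=3.2)
        f1 = make_frame(1, [[5, 0, 0]], np.zeros((0, 2)), tau=3.2)
        cands = build_candidates(f0, f1,
                                 TrackingConfig(max_node_speed=1.0))
        assert len(cands.candidates[0][0]) == 0  # 5 um > 3.2 um

    def test_candidates_match_brute_force_double_radius_filter(self, rng):
        f0 = random_geometric_frame(rng, n=50, idx=0)
        f1 = random_geometric_frame(rng, n=50, idx=1)
        cfg = TrackingConfig(nn_threshold=10, max_node_speed=1.0)
        cands = build_candidates(f0, f1, cfg)
        # brute force: nn radius within frame 0, speed cap, O(n^2)
        d00 = np.linalg.norm(f0.positions[:, None] - f0.positions[None],
                             axis=2)
        d01 = np.linalg.norm(f0.positions[:, None] - f1.positions[None],
                             axis=2)
        cap = cfg.max_node_speed * f0.frame_interval
        for i in range(50):
            nn10 = np.sort(d00[i])[10]  # row includes self at 0
            radius = min(nn10, cap)
            expect = set(np.nonzero(d01[i] <= radius)[0])
            assert set(cands.candidates[i][0]) == expect


class TestCostAssembly:
    def test_combined_cost_is_distance_times_topology(self):
        f0, f1 = grid_frame(0, n=1), grid_frame(1, n=1)
        cands = build_candidates(f0, f1, TrackingConfig())
        cands.candidates[0] = (np.array([0]), np.array([2.0]))
        cost = assemble_cost(cands, TrackingConfig(), None,
                             [np.array([3.0])])
        assert cost.matrix[0, 0] == pytest.approx(6.0)

    def test_first_frame_alternative_cost_is_twice_minimum(self):
        f0, f1 = grid_frame(0, n=2), grid_frame(1, n=2)
        cands = build_candidates(f0, f1, TrackingConfig())
        cands.candidates = [(np.array([0]), np.array([4.0])),
                            (np.array([1]), np.array([10.0]))]
        cost = assemble_cost(cands, TrackingConfig(topology_exponent=0),
                             None)
        assert cost.alternative_cost == pytest.approx(8.0)

    def test_history_percentile_matches_sort_oracle(self, rng):
        history = rng.exponential(size=200).tolist()
        b = percentile_cost(history, 98.0)
        # sort-based linear-interpolation percentile
        xs = np.sort(history)
        rank = 0.98 * (len(xs) - 1)
        lo, hi = int(np.floor(rank)), int(np.ceil(rank))
        expect = xs[lo] + (rank - lo) * (xs[hi] - xs[lo])
        assert b == pytest.approx(expect)


class TestSolver:
    def test_diagonal_dominant_matrix_links_identity(self):
        f0, f1 = grid_frame(0, n=3), grid_frame(1, n=3)
        cands = build_candidates(f0, f1,
                                 TrackingConfig(topology_exponent=0))
        cost = assemble_cost(cands, TrackingConfig(topology_exponent=0),
                             [1.0] * 100)
        result = solve_assignment(cost, cands)
        assert result.link_map() == {0: 0, 1: 1, 2: 2}

    def test_expensive_candidates_all_terminate(self):
        f0, f1 = grid_frame(0, n=3), grid_frame(1, n=3)
        cands = build_candidates(f0, f1, TrackingConfig())
        for i in range(3):
            idx, dist = cands.candidates[i]
            cands.candidates[i] = (idx, np.full(len(idx), 50.0))
        cfg = TrackingConfig(topology_exponent=0)
        cost = assemble_cost(cands, cfg, [1.0] * 100)  # b = 1 << 50
        result = solve_assignment(cost, cands)
        assert not result.links
        assert result.terminated == [0, 1, 2]
        assert result.initiated == [0, 1, 2]

    @pytest.mark.parametrize("trial", range(50))
    def test_solver_matches_brute_force_on_small_instances(self, trial):
        """Optimal total cost equals exhaustive enumeration over all link
        subsets on random <= 6x6 instances with alternatives."""
        rng = np.random.default_rng(trial)
        n = int(rng.integers(2, 7))
        m = int(rng.integers(2, 7))
        link = rng.uniform(0.1, 1.0, size=(n, m))
        mask = rng.random((n, m)) < 0.7
        b = float(rng.uniform(0.2, 1.0))
        total, links = solve_padded_lap(link, mask, b)
        brute = lap_brute_force(link, mask, b)
        assert total == pytest.approx(brute, abs=1e-9)

    def test_assignment_is_partial_bijection(self, rng):
        f0 = random_geometric_frame(rng, n=30, idx=0)
        f1 = random_geometric_frame(rng, n=30, idx=1)
        cfg = TrackingConfig(topology_exponent=0)
        cands = build_candidates(f0, f1, cfg)
        result = solve_assignment(assemble_cost(cands, cfg, [0.5] * 50),
                                  cands)
        ms = [m for m, _, _ in result.links]
        ns = [n for _, n, _ in result.links]
        assert len(set(ms)) == len(ms)
        assert len(set(ns)) == len(ns)
        assert sorted(ms + result.terminated) == sorted(
            int(v) for v in f0.node_ids)
        assert sorted(ns + result.initiated) == sorted(
            int(v) for v in f1.node_ids)


class TestCorrections:
    def test_rule1_unlinks_overlong_arrow(self):
        # a 12-node segment where one arrow is 10x the others
        n = 12
        f0 = path_frame(n, spacing=0.5, idx=0)
        pos1 = f0.positions.copy()
        pos1[:, 1] += 0.1           # coherent small displacement
        pos1[5, 1] += 1.0           # one long arrow
        f1 = make_frame(1, pos1, f0.edges)
        links = [(i, i, 0.1) for i in range(n)]
        result = AssignmentResult(links=links, terminated=[],
                                  initiated=[], total_cost=0.0)
        out = apply_corrections(result, f0, f1)
        assert ("rule1", 5) in out.corrections
        assert 5 not in out.link_map()
        assert len(out.links) == n - 1

    def test_rule2_unlinks_lone_arrow_into_isolated_segment(self):
        # segment A drifts coherently by 0.2; node 2 alone is linked into
        # a nearby separate segment B (short arrow, so rule 1 passes)
        posA = np.array([[0, 0, 0], [0.5, 0, 0], [1.0, 0, 0],
                         [1.5, 0, 0.]])
        posB = np.array([[0.9, 0.55, 0], [1.4, 0.55, 0],
                         [1.9, 0.55, 0.]])
        pos0 = np.vstack([posA, posB])
        pos1 = np.vstack([posA + [0.2, 0, 0], posB + [0.2, 0, 0]])
        edges = [[0, 1], [1, 2], [2, 3], [4, 5], [5, 6]]
        f0 = make_frame(0, pos0, edges)
        f1 = make_frame(1, pos1, edges)
        links = [(0, 0, 0.1), (1, 1, 0.1), (3, 3, 0.1), (2, 4, 0.5)]
        result = AssignmentResult(links=links, terminated=[],
                                  initiated=[2, 5, 6], total_cost=0.0)
        out = apply_corrections(result, f0, f1)
        assert ("rule2", 2) in out.corrections
        assert 2 not in out.link_map()

    def test_rule3_reassigns_crossing_arrow_to_predicted_position(self):
        # a segment translating by +0.5 in y; node 3's arrow crosses back
        # to node 0's new position while its true counterpart stays free
        n = 10
        f0 = path_frame(n, spacing=0.5, idx=0)
        f1 = make_frame(1, f0.positions + [0, 0.5, 0], f0.edges)
        links = [(i, i, 0.1) for i in range(n) if i not in (0, 3)]
        links.append((3, 0, 0.2))  # crossing arrow, ~108 deg off consensus
        result = AssignmentResult(links=links, terminated=[0],
                                  initiated=[3], total_cost=0.0)
        out = apply_corrections(result, f0, f1)
        assert ("rule3", 3) in out.corrections
        assert out.link_map()[3] == 3  # nearest to predicted position


class TestWarnings:
    def test_low_linked_fraction_warns(self):
        f0 = grid_frame(0, n=100, spacing=1.0)
        f1 = grid_frame(1, n=100, spacing=1.0)
        links = [(i, i, 0.0) for i in range(70)]
        res = AssignmentResult(links=links, terminated=[], initiated=[],
                               total_cost=0.0)
        ws = check_warnings(f0, f1, res, TrackingConfig())
        assert any("linked-fraction" in w for w in ws)

    def test_node_count_fluctuation_warns(self):
        f0 = grid_frame(0, n=100)
        f1 = grid_frame(1, n=130)
        res = AssignmentResult(links=[], terminated=[], initiated=[],
                               total_cost=0.0)
        ws = check_warnings(f0, f1, res, TrackingConfig())
        assert any("fluctuation" in w for w in ws)

    def test_overspeed_link_warns(self):
        f0 = make_frame(0, [[0, 0, 0]], np.zeros((0, 2)), tau=3.2)
        f1 = make_frame(1, [[4, 0, 0]], np.zeros((0, 2)), tau=3.2)
        res = AssignmentResult(links=[(0, 0, 1.0)], terminated=[],
                               initiated=[], total_cost=1.0)
        ws = check_warnings(f0, f1, res, TrackingConfig())
        assert any("speed" in w for w in ws)


class TestTrackAll:
    def test_frozen_frames_track_every_node(self):
        base = path_frame(8, spacing=0.4)
        frames = [make_frame(t, base.positions, base.edges)
                  for t in range(5)]
        result = track_all(frames, TrackingConfig())
        full = [t for t in result.tracks if len(t) == 5]
        assert len(full) == 8
        for t in full:
            assert np.all(t.displacements() == 0)

    def test_unreachable_nodes_never_link(self):
        f0 = make_frame(0, [[0, 0, 0]], np.zeros((0, 2)), tau=1.0)
        f1 = make_frame(1, [[50, 0, 0]], np.zeros((0, 2)), tau=1.0)
        result = track_all([f0, f1], TrackingConfig())
        assert all(len(t) == 1 for t in result.tracks)
        assert len(result.tracks) == 2

    def test_needs_two_frames(self):
        with pytest.raises(ValueError):
            track_all([path_frame(3)], TrackingConfig())
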