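"""Reaction-diffusion network simulator: generation, dynamics, remodeling."""

import numpy as np
import pytest
from scipy import stats

from mitotrack.simulation import (Simulation, SimulationParams,
                                  SimulationState, _er_partition,
                                  apply_remodeling, balance_rates,
                                  compute_forces, embed_full_resolution,
                                  export_frames, generate_initial_network,
                                  mean_fragment_size, step_dynamics)
from mitotrack.validation import free_particle_msd


def degrees_from_edges(edges, n):
    deg = np.zeros(n, dtype=int)
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    return deg


class TestNetworkGeneration:
    def test_node_count_is_exactly_n_with_no_isolated_nodes(self):
        for seed in range(5):
            p = SimulationParams(seed=seed)
            edges = generate_initial_network(p, np.random.default_rng(seed))
            n = 1 + max(max(e) for e in edges)
            assert n == 300
            assert np.all(degrees_from_edges(edges, n) >= 1)

    def test_degree_distribution_matches_er_law(self):
        """Degrees of raw ER partitions follow the analytic binomial law
        conditioned on degree >= 1 (chi-square, alpha = 0.01)."""
        n, mean_deg = 60, 1.0
        rng = np.random.default_rng(7)
        counts = np.zeros(8)
        total = 0
        for _ in range(20):
            edges, kept = _er_partition(n, mean_deg, rng)
            deg = degrees_from_edges(edges, kept)
            for d in deg:
                counts[min(d, 7)] += 1
            total += kept
        p_edge = mean_deg / (n - 1)
        pmf = stats.binom.pmf(np.arange(8), n - 1, p_edge)
        pmf[7] = 1 - pmf[:7].sum()
        cond = pmf[1:] / pmf[1:].sum()  # conditioned on degree >= 1
        expected = total * np.concatenate([[0], cond])
        mask = expected > 5
        chi2 = np.sum((counts[mask] - expected[mask]) ** 2
                      / expected[mask])
        dof = mask.sum() - 1
        assert chi2 < stats.chi2.ppf(0.99, dof)


class TestEmbedding:
    def test_single_edge_becomes_chain_of_bulk_particles(self):
        p = SimulationParams(total_nodes=60)
        rng = np.random.default_rng(0)
        state = embed_full_resolution([(0, 1)], p, rng)
        n_bulk = state.n_particles - 2
        assert 2 <= n_bulk <= 5
        assert len(state.bonds) == n_bulk + 1
        deg = np.zeros(state.n_particles, dtype=int)
        for u, v in state.bonds:
            deg[u] += 1
            deg[v] += 1
        assert sorted(deg.tolist()) == [1, 1] + [2] * n_bulk

    def test_all_positions_inside_box(self):
        p = SimulationParams(seed=3)
        rng = np.random.default_rng(3)
        topo = generate_initial_network(p, rng)
        state = embed_full_resolution(topo, p, rng)
        assert np.all(state.positions >= p.box_lo - 1e-9)
        assert np.all(state.positions <= p.box_hi + 1e-9)

    def test_bulk_counts_uniform_over_2_to_5(self):
        """Bulk nodes per classic edge are uniform on {2,3,4,5}
        (chi-square, alpha = 0.01)."""
        p = SimulationParams()
        rng = np.random.default_rng(11)
        counts = np.zeros(4)
        for rep in range(6):
            topo = generate_initial_network(p, rng)
            state = embed_full_resolution(topo, p, rng)
            n_classic = 1 + max(max(e) for e in topo)
            # recover per-edge bulk counts from degree-2 chain lengths
            from mitotrack.skeleton import SkeletonFrame, to_classic_network
            ba = state.bond_array()
            frame = SkeletonFrame(0, np.arange(state.n_particles),
                                  state.positions, ba, 1.0)
            for chain in to_classic_network(frame).chains:
                if 2 <= chain.bulk_count <= 5:
                    counts[chain.bulk_count - 2] += 1
        expected = counts.sum() / 4
        chi2 = np.sum((counts - expected) ** 2 / expected)
        assert chi2 < stats.chi2.ppf(0.99, 3)


class TestDynamics:
    def test_relaxed_collinear_chain_feels_no_force(self):
        p = SimulationParams()
        d0 = p.node_diameter
        pos = np.array([[i * d0, 0, 0] for i in range(5)])
        state = SimulationState(positions=pos,
                                bonds={(i, i + 1) for i in range(4)})
        F = compute_forces(state, p)
        assert np.allclose(F, 0.0, atol=1e-9)

    def test_zero_diffusivity_keeps_positions_fixed(self):
        p = SimulationParams(diffusivity=0.0)
        d0 = p.node_diameter
        pos = np.array([[i * d0, 0, 0] for i in range(4)])
        state = SimulationState(positions=pos.copy(),
                                bonds={(i, i + 1) for i in range(3)})
        step_dynamics(state, p, np.random.default_rng(0))
        assert np.allclose(state.positions, pos)

    def test_particle_outside_box_is_pushed_inward(self):
        p = SimulationParams()
        pos = np.array([[11.0, 0.0, 0.0]])  # box is +/-10 in x
        state = SimulationState(positions=pos, bonds=set())
        F = compute_forces(state, p)
        assert F[0, 0] < 0
        assert F[0, 1] == F[0, 2] == 0

    def test_free_particle_msd_matches_6_d_tau(self):
        """Unbonded particles reproduce MSD = 6 D tau within 5%
        (100 replicas, 10^4 steps, time+ensemble averaging)."""
        p = SimulationParams()  # D = 0.005, dt = 0.002
        from mitotrack.simulation import SimulationState
        rng = np.random.default_rng(42)
        n, steps = 100, 10_000
        state = SimulationState(positions=np.zeros((n, 3)), bonds=set())
        from dataclasses import replace
        p0 = replace(p, k_repulsion=0.0)
        sample_every = 500
        traj = [state.positions.copy()]
        for s in range(steps):
            step_dynamics(state, p0, rng)
            if (s + 1) % sample_every == 0:
                traj.append(state.positions.copy())
        traj = np.array(traj)
        lag = 1  # 500 steps = 1 s
        diffs = traj[lag:] - traj[:-lag]
        msd = float(np.mean(np.sum(diffs ** 2, axis=-1)))
        theory = 6 * p.diffusivity * sample_every * p.dt
        assert msd == pytest.approx(theory, rel=0.05)

    def test_bonded_network_stays_near_rest_length(self):
        p = SimulationParams(total_nodes=60, seed=5)
        sim = Simulation(p)
        sim.equilibrate(300)
        ba = sim.state.bond_array()
        lengths = np.linalg.norm(sim.state.positions[ba[:, 0]]
                                 - sim.state.positions[ba[:, 1]], axis=1)
        assert abs(lengths.mean() - p.node_diameter) < 0.05
        assert lengths.max() < 2 * p.node_diameter


class TestRemodeling:
    def _chain_state(self, n, spacing=0.35):
        pos = np.array([[i * spacing, 0, 0] for i in range(n)])
        return SimulationState(positions=pos,
                               bonds={(i, i + 1) for i in range(n - 1)})

    def test_small_components_never_fission(self):
        p = SimulationParams(fission_rate=1.0, min_fission_size=4)
        state = self._chain_state(3)
        for _ in range(50):
            apply_remodeling(state, p, np.random.default_rng(0))
        assert len(state.bonds) == 2
        assert not state.event_log

    def test_fusion_within_capture_radius_at_rate_one(self):
        p = SimulationParams(fusion_rate=1.0)
        pos = np.array([[0, 0, 0], [0.35, 0, 0],
                        [0.85, 0, 0], [1.2, 0, 0.]])
        state = SimulationState(positions=pos, bonds={(0, 1), (2, 3)})
        apply_remodeling(state, p, np.random.default_rng(0))
        # ends 1 and 2 are 0.5 um apart < 0.7 um capture radius
        assert (1, 2) in state.bonds
        assert any(e.kind == "fusion" for e in state.event_log)

    def test_bridge_fission_increments_component_count(self):
        p = SimulationParams(fission_rate=1.0)
        state = self._chain_state(8)  # every bond is a bridge
        before = len(np.unique(state.components()))
        rng = np.random.default_rng(1)
        while not state.event_log:
            apply_remodeling(state, p, rng)
        after = len(np.unique(state.components()))
        assert after == before + 1

    def test_particle_count_conserved_through_everything(self):
        p = SimulationParams(total_nodes=60, seed=6,
                             fission_rate=0.05, fusion_rate=0.05)
        sim = Simulation(p)
        n0 = sim.state.n_particles
        sim.equilibrate(100)
        sim.run(400, remodeling=True)
        assert sim.state.n_particles == n0
        assert len(sim.state.event_log) > 0

    def test_fusion_respects_degree_cap(self):
        p = SimulationParams(total_nodes=60, seed=8,
                             fission_rate=0.02, fusion_rate=0.2)
        sim = Simulation(p)
        sim.equilibrate(100)
        sim.run(500, remodeling=True)
        deg, _ = sim.state.adjacency()
        assert deg.max() <= p.max_bonds

    def test_balance_rates_zero_in_zero_out(self):
        p = SimulationParams(total_nodes=60)
        assert balance_rates(p, seed=0) == (0.0, 0.0)

    def test_fission_only_shrinks_mean_fragment_size(self):
        p = SimulationParams(total_nodes=60, seed=9, fission_rate=0.2,
                             fusion_rate=0.0)
        sim = Simulation(p)
        sim.equilibrate(50)
        before = mean_fragment_size(sim.state)
        sim.run(300, remodeling=True)
        assert mean_fragment_size(sim.state) < before

    def test_balanced_run_keeps_fragment_count_drift_small(self):
        """After balancing, the total fragment count drifts < 10% over a
        monitoring epoch."""
        p = SimulationParams(total_nodes=120, seed=10, fission_rate=0.005,
                             fusion_rate=0.005)
        fis, fus = balance_rates(p, seed=10, equil_steps=400,
                                 epoch_steps=600, max_epochs=6)
        from dataclasses import replace
        sim = Simulation(replace(p, fission_rate=fis, fusion_rate=fus),
                         seed=11)
        sim.equilibrate(400)
        counts = []
        for _ in range(2):
            window = []
            for _ in range(12):
                sim.run(50, remodeling=True)
                window.append(len(np.unique(sim.state.components())))
            counts.append(np.mean(window))
        assert abs(counts[1] - counts[0]) / counts[0] < 0.10


class TestExport:
    def test_zero_motion_export_gives_identical_frames(self):
        p = SimulationParams(total_nodes=60, seed=12, diffusivity=0.0)
        sim = Simulation(p)
        snaps = sim.run(200, remodeling=False, record_every=100)
        movie = export_frames(snaps, p, 100, shuffle_ids=False)
        assert len(movie.frames) == 3
        f0 = movie.frames[0]
        for f in movie.frames[1:]:
            assert np.allclose(f.positions, f0.positions)
            assert np.array_equal(f.edges, f0.edges)
        assert movie.measured_msd == pytest.approx(0.0)

    def test_exported_edges_match_simulator_bonds(self):
        p = SimulationParams(total_nodes=60, seed=13)
        sim = Simulation(p)
        sim.equilibrate(50)
        snaps = sim.run(200, remodeling=False, record_every=100)
        movie = export_frames(snaps, p, 100)
        for (_, _, bonds), frame, gt in zip(snaps, movie.frames,
                                            movie.ground_truth):
            back = {tuple(sorted((gt[int(u)], gt[int(v)])))
                    for u, v in frame.edges}
            assert back == bonds

    def test_nominal_msd_anchor(self):
        # D = 0.005 um^2/s at tau = 10 s gives MSD = 0.3 um^2
        p = SimulationParams(total_nodes=60, seed=1, diffusivity=0.005,
                             dt=0.002)
        sim = Simulation(p)
        snaps = sim.run(10_000, remodeling=False, record_every=5000)
        movie = export_frames(snaps, p, 5000)
        assert movie.frame_interval == pytest.approx(10.0)
        assert movie.nominal_msd == pytest.approx(0.3)

    def test_ground_truth_maps_are_consistent_permutations(self):
        p = SimulationParams(total_nodes=60, seed=14)
        sim = Simulation(p)
        snaps = sim.run(100, remodeling=False, record_every=50)
        movie = export_frames(snaps, p, 50)
        for frame, gt in zip(movie.frames, movie.ground_truth):
            assert sorted(gt.keys()) == sorted(
                int(v) for v in frame.node_ids)
            assert sorted(gt.values()) == list(range(len(frame)))


def test_free_particle_helper_matches_law():
    msd, theory = free_particle_msd(400, 1500, seed=5)
    assert msd == pytest.approx(theory, rel=0.08)


def test_generation_terminates_when_one_node_remains():
    """Assemblies that land one node short of N restart instead of
    spinning forever (a 1-node ER partition cannot exist)."""
    # seed 1100 historically reached 299/300 and required a restart
    p = SimulationParams(seed=1100)
    edges = generate_initial_network(p, np.random.default_rng(1100))
    n = 1 + max(max(e) for e in edges)
    assert n == 300
    assert np.all(degrees_from_edges(edges, n) >= 1)
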