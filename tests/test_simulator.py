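"""Simulator: chain statistics, binding Monte Carlo, clusters, determinism."""

import itertools

import numpy as np
import pytest

from bips.simulator import (
    BridgeConfig,
    ChainConfig,
    SimParams,
    SimState,
    discrete_persistence_length,
    init_state,
    integrate,
    largest_cluster,
    run_simulation,
    stiffness_for_persistence_length,
    unwrap_cluster,
    update_binding,
    wlc_mean_square_end_to_end,
)


class TestChainConfig:
    def test_default_stiffness_hits_50nm_persistence_length(self):
        chain = ChainConfig(n_beads=50)
        lp_nm = discrete_persistence_length(chain.kappa) * chain.bead_diameter_nm
        assert lp_nm == pytest.approx(50.0, rel=0.01)
        assert chain.kappa == pytest.approx(5.51, abs=0.1)

    def test_bp_mapping(self):
        chain = ChainConfig(n_beads=100)
        assert chain.bp_per_bead == pytest.approx(10.0 / 0.34)
        assert chain.length_bp == pytest.approx(2941.2, abs=0.1)

    def test_stiffness_solver_inverts_relation(self):
        for lp in (2.0, 5.0, 20.0):
            kappa = stiffness_for_persistence_length(lp)
            assert discrete_persistence_length(kappa) == pytest.approx(lp, rel=1e-9)

    def test_wrong_kappa_rejected(self):
        with pytest.raises(ValueError):
            ChainConfig(n_beads=10, kappa=50.0)  # l_P far from 50 nm


class TestInitState:
    def test_two_bead_bond_near_rest_length(self):
        chain = ChainConfig(n_beads=2)
        state = init_state(chain, None, SimParams(seed=0))
        bond = np.linalg.norm(state.bead_positions[1] - state.bead_positions[0])
        assert bond == pytest.approx(0.97, abs=0.05)

    def test_no_bonds_at_start(self):
        chain = ChainConfig(n_beads=30)
        bridges = BridgeConfig(valence=3)
        state = init_state(chain, bridges, SimParams(seed=5))
        assert state.bond_count.sum() == 0

    def test_wlc_end_to_end_statistics(self):
        # 600 equilibrium-sampled chains of 50 beads vs the closed form
        chain = ChainConfig(n_beads=50, excluded_volume=False)
        r2 = []
        bl = []
        for seed in range(600):
            st = init_state(chain, None, SimParams(seed=seed))
            p = st.bead_positions
            r2.append(((p[-1] - p[0]) ** 2).sum())
            bl.append(np.linalg.norm(np.diff(p, axis=0), axis=1).mean())
        bond = np.mean(bl)
        lp = discrete_persistence_length(chain.kappa, bond)
        theory = wlc_mean_square_end_to_end(49 * bond, lp)
        assert np.mean(r2) == pytest.approx(theory, rel=0.10)

    def test_bridges_not_overlapping_chain(self):
        chain = ChainConfig(n_beads=40)
        bridges = BridgeConfig(valence=2)
        state = init_state(chain, bridges, SimParams(seed=3))
        from scipy.spatial import cKDTree

        tree = cKDTree(np.mod(state.bead_positions, state.box), boxsize=state.box)
        d, _ = tree.query(np.mod(state.bridge_positions, state.box))
        assert d.min() > 0.8  # relaxation may shift things slightly


class TestIntegrate:
    def test_free_bead_msd_matches_diffusion(self):
        # single bead, no bonds: MSD = 6 D t with D = kT/friction = 1
        chain = ChainConfig(n_beads=1)
        params = SimParams(seed=0, timestep=2e-4)
        n_steps = 1500
        t = n_steps * params.timestep
        disp2 = []
        for seed in range(600):
            st = init_state(chain, None, SimParams(seed=seed, timestep=2e-4))
            start = st.positions.copy()
            integrate(st, chain, params, n_steps, seed=seed + 10_000)
            disp2.append(((st.positions - start) ** 2).sum())
        assert np.mean(disp2) == pytest.approx(6.0 * t, rel=0.05)

    def test_tangent_correlation_recovers_persistence_length(self):
        # ensemble of integrated chains; fit the exponential decay of
        # <t_i . t_{i+s}> over separations where the signal dominates the
        # per-chain sampling noise
        chain = ChainConfig(n_beads=80)
        corr = np.zeros(9)
        n_chains = 120
        for seed in range(n_chains):
            params = SimParams(seed=seed, timestep=2e-4)
            st = init_state(chain, None, params)
            integrate(st, chain, params, 3000, seed=seed + 777)
            p = st.bead_positions
            b = np.diff(p, axis=0)
            b /= np.linalg.norm(b, axis=1, keepdims=True)
            for s in range(9):
                corr[s] += (b[: len(b) - s] * b[s:]).sum(axis=1).mean()
        corr /= n_chains
        s = np.arange(1, 9)
        slope = np.polyfit(s, np.log(corr[1:]), 1)[0]
        bond = 0.97
        lp_nm = -bond / slope * chain.bead_diameter_nm
        assert lp_nm == pytest.approx(50.0, rel=0.10)

    def test_identical_seeds_identical_trajectories(self):
        chain = ChainConfig(n_beads=25)
        bridges = BridgeConfig(valence=2)
        outs = []
        for _ in range(2):
            params = SimParams(seed=77, n_steps=6000, timestep=5e-4)
            traj = run_simulation(chain, bridges, params, stride=2000)
            outs.append(traj.snapshots[-1])
        np.testing.assert_array_equal(outs[0].positions, outs[1].positions)
        np.testing.assert_array_equal(outs[0].bond_bead, outs[1].bond_bead)

    def test_overstretched_bond_aborts_with_diagnostic(self):
        chain = ChainConfig(n_beads=2)
        st = init_state(chain, None, SimParams(seed=0))
        st.positions[1] = st.positions[0] + np.array([1.6, 0.0, 0.0])
        with pytest.raises(RuntimeError, match="FENE"):
            integrate(st, chain, SimParams(seed=0), 10)


class TestUpdateBinding:
    def _frozen_state(self, bead_dists, box=40.0):
        """One bridge at the centre, beads at given distances, frozen."""
        n = len(bead_dists)
        pos = np.zeros((n + 1, 3))
        centre = np.full(3, box / 2)
        pos[n] = centre
        for i, d in enumerate(bead_dists):
            angle = 2 * np.pi * i / max(n, 1)
            pos[i] = centre + d * np.array([np.cos(angle), np.sin(angle), 0.0])
        bridges = BridgeConfig(valence=2, binding_energy_kt=0.0)
        state = SimState(
            positions=pos,
            n_beads=n,
            bond_bead=np.full((1, 2), -1, np.int32),
            bond_count=np.zeros(1, np.int32),
            box=box,
        )
        return state, bridges

    def test_zero_energy_occupancy_matches_enumeration(self):
        # with eps = 0 the stationary occupancy is the ideal association
        # equilibrium: enumerate all bond sets within the valence cap
        dists = [1.05, 1.2, 1.4]
        state, bridges = self._frozen_state(dists)
        k, r0 = bridges.link_stiffness, bridges.link_rest_length
        weights = {}
        for size in range(3):
            for subset in itertools.combinations(range(len(dists)), size):
                e = sum(0.5 * k * (dists[i] - r0) ** 2 for i in subset)
                weights[subset] = np.exp(-e)
        z = sum(weights.values())
        expected = sum(len(s) * w for s, w in weights.items()) / z
        samples = []
        for sweep in range(20000):
            update_binding(state, bridges, seed=sweep)
            samples.append(int(state.bond_count[0]))
        assert np.mean(samples[200:]) == pytest.approx(expected, rel=0.05)

    def test_valence_cap_never_violated(self, small_bridged_state):
        state, chain, bridges, params = small_bridged_state
        st = state.copy()
        for sweep in range(300):
            update_binding(st, bridges, seed=sweep)
            assert (st.bond_count <= bridges.valence).max()

    def test_doubly_bound_bridge_raises_local_bridge_density(self):
        # a bridged loop is the nucleation seed: bridge density near the
        # chain exceeds the bulk average once binding equilibrates
        chain = ChainConfig(n_beads=120)
        bridges = BridgeConfig(valence=2)
        params = SimParams(seed=9, timestep=5e-4)
        st = init_state(chain, bridges, params, bridge_placement="near_chain",
                        chain_init="compact")
        integrate(st, chain, params, 60_000, bridges=bridges, seed=4)
        doubly = np.flatnonzero(st.bond_count == 2)
        assert len(doubly) > 0
        from scipy.spatial import cKDTree

        tree = cKDTree(np.mod(st.bead_positions, st.box), boxsize=st.box)
        bulk_density = chain.n_beads / st.box**3
        for b in doubly[:3]:
            centre = np.mod(st.bridge_positions[b], st.box)
            local = tree.query_ball_point(centre, 5.0)
            local_density = len(local) / (4 / 3 * np.pi * 5.0**3)
            assert local_density > 3 * bulk_density


class TestLargestCluster:
    def test_dilute_unbonded_gives_single_particle(self):
        pos = np.array(
            [[5.0, 5, 5], [15, 5, 5], [25, 5, 5], [35, 15, 15]], dtype=float
        )
        state = SimState(
            positions=pos, n_beads=3,
            bond_bead=np.full((1, 2), -1, np.int32),
            bond_count=np.zeros(1, np.int32), box=40.0,
        )
        assert len(largest_cluster(state, r_c=2.5)) == 1

    def test_single_bridge_links_its_two_beads(self):
        pos = np.array(
            [[5.0, 5, 5], [20, 20, 20], [30, 5, 5], [5.9, 5.9, 5]], dtype=float
        )
        bond_bead = np.array([[0, 2]], dtype=np.int32)
        state = SimState(
            positions=pos, n_beads=3,
            bond_bead=bond_bead,
            bond_count=np.array([2], np.int32), box=40.0,
        )
        members = set(largest_cluster(state, r_c=1.5).tolist())
        assert members == {0, 2, 3}

    def test_deterministic(self, small_bridged_state):
        state, *_ = small_bridged_state
        a = largest_cluster(state, 2.5)
        b = largest_cluster(state, 2.5)
        np.testing.assert_array_equal(a, b)

    def test_unwrap_reassembles_across_boundary(self):
        pos = np.array([[0.4, 5, 5], [39.6, 5, 5], [1.5, 5, 5]], dtype=float)
        state = SimState(
            positions=pos, n_beads=2,
            bond_bead=np.array([[0, 1]], np.int32),
            bond_count=np.array([2], np.int32), box=40.0,
        )
        members = largest_cluster(state, r_c=1.5)
        pts = unwrap_cluster(state, members)
        assert np.ptp(pts[:, 0]) < 3.0  # whole, not split across the box
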