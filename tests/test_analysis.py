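"""Observables: Rg, saturation, clusters/ACO, profiles, MSD, regression."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import stickermd as sm
from stickermd.dynamics import BondEventLog, Trajectory
from stickermd.errors import InvalidInputError
from stickermd.polymer_setup import _merge_topologies


class TestRadiusOfGyration:
    def test_symmetric_dumbbell(self):
        pos = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert sm.radius_of_gyration(pos) == pytest.approx(1.0)

    def test_translation_invariant(self):
        rng = np.random.default_rng(0)
        pos = rng.random((40, 3)) * 30
        assert sm.radius_of_gyration(pos + 123.4) == pytest.approx(
            sm.radius_of_gyration(pos)
        )

    def test_single_bead_is_zero(self):
        assert sm.radius_of_gyration([[1.0, 2.0, 3.0]]) == 0.0


def _sticker_chains(n_chains, stickers_per_chain=5):
    """n_chains short chains made entirely of alternating-type stickers."""
    chains = []
    for c in range(n_chains):
        lab = "A" if c % 2 == 0 else "B"
        chains.append(
            (sm.build_chain(sm.BlockTemplate((lab,) * stickers_per_chain, 1)), 1)
        )
    topo = _merge_topologies(chains)
    state = sm.SystemState.empty(topo.n_beads, (1000, 1000, 1000))
    return state, topo


def _dfs_components(n_nodes, edges):
    """Brute-force reachability oracle."""
    adj = {k: set() for k in range(n_nodes)}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen, sizes = set(), []
    for start in range(n_nodes):
        if start in seen:
            continue
        stack, comp = [start], 0
        seen.add(start)
        while stack:
            u = stack.pop()
            comp += 1
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        sizes.append(comp)
    return sorted(sizes)


class TestClusters:
    def test_no_bonds_all_singletons(self):
        state, topo = _sticker_chains(6)
        cs = sm.cluster_components(state, topo)
        assert sorted(cs.sizes.tolist()) == [1]
        assert cs.counts.sum() == 6
        assert cs.aco_normalized == pytest.approx(1.0 / 6)

    def test_linear_trimer_plus_monomer(self):
        """Chains 1-2 and 2-3 bonded, chain 4 free -> sizes {3, 1}."""
        state, topo = _sticker_chains(4)
        s = topo.sticker_indices.reshape(4, -1)  # stickers per chain
        for i, j in [(s[0][0], s[1][0]), (s[1][1], s[2][0])]:
            state.pairing[i] = j
            state.pairing[j] = i
        cs = sm.cluster_components(state, topo)
        got = sorted(np.repeat(cs.sizes, cs.counts).tolist())
        assert got == [1, 3]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dfs_oracle_on_random_pairings(self, seed):
        rng = np.random.default_rng(seed)
        n_chains = int(rng.integers(5, 30))
        state, topo = _sticker_chains(n_chains)
        # random valid matching between A stickers and B stickers
        a_idx = [i for i in topo.sticker_indices if topo.roles[i] == "A"]
        b_idx = [i for i in topo.sticker_indices if topo.roles[i] == "B"]
        rng.shuffle(a_idx)
        rng.shuffle(b_idx)
        n_bonds = int(rng.integers(0, min(len(a_idx), len(b_idx))))
        edges = []
        for i, j in zip(a_idx[:n_bonds], b_idx[:n_bonds]):
            state.pairing[i] = j
            state.pairing[j] = i
            ci, cj = topo.chain_ids[i], topo.chain_ids[j]
            if ci != cj:
                edges.append((int(ci), int(cj)))
        cs = sm.cluster_components(state, topo)
        got = sorted(np.repeat(cs.sizes, cs.counts).tolist())
        assert got == _dfs_components(n_chains, edges)
        assert int((cs.sizes * cs.counts).sum()) == n_chains  # chains conserved


class TestACO:
    def test_all_monomers(self):
        a, norm = sm.aco([1] * 10, 10)
        assert a == pytest.approx(1.0)
        assert norm == pytest.approx(1.0 / 10)

    def test_single_giant_cluster(self):
        a, norm = sm.aco([7], 7)
        assert norm == pytest.approx(1.0)

    def test_hand_example(self):
        a, norm = sm.aco([2, 1, 1], 4)
        assert a == pytest.approx(1.5)
        assert norm == pytest.approx(0.375)

    def test_inconsistent_total_rejected(self):
        with pytest.raises(InvalidInputError):
            sm.aco([2, 2], 5)

    @given(st.lists(st.integers(1, 8), min_size=2, max_size=12))
    def test_bounds_and_merge_monotonicity(self, sizes):
        n = sum(sizes)
        _, norm = sm.aco(sizes, n)
        assert 1.0 / n - 1e-12 <= norm <= 1.0 + 1e-12
        merged = [sizes[0] + sizes[1]] + sizes[2:]
        _, norm_merged = sm.aco(merged, n)
        assert norm_merged >= norm - 1e-12


class TestDissociationSeries:
    def test_empty_log(self):
        counts = sm.dissociation_series(np.array([], dtype=int), window=100, span=500)
        assert counts.tolist() == [0, 0, 0, 0, 0]

    def test_counting(self):
        rec = []
        for s in [10, 20, 900_000, 950_000, 999_999, 1_200_000, 1_900_000]:
            rec.append([s, 1, 0, 1])
        log = BondEventLog(np.array(rec))
        counts = sm.dissociation_series(log, window=1_000_000, span=2_000_000)
        assert counts.tolist() == [5, 2]


class TestRadialProfile:
    def _one_chain_state(self, coords):
        n = coords.shape[0]
        roles = ["A" if k % 5 == 0 else "spacer" for k in range(n)]
        topo = sm.ChainTopology(
            roles=roles,
            chain_ids=np.zeros(n, dtype=np.int64),
            permanent_bonds=np.column_stack([np.arange(n - 1), np.arange(1, n)]),
            angles=np.empty((0, 3), dtype=np.int64),
        )
        state = sm.SystemState.empty(n, (500, 500, 500))
        state.positions = np.mod(coords, 500.0)
        return state, topo

    def test_counts_conserved(self):
        rng = np.random.default_rng(1)
        coords = 250.0 + np.cumsum(rng.normal(scale=3, size=(40, 3)), axis=0)
        state, topo = self._one_chain_state(coords)
        prof = sm.radial_profile(state, topo, [0], bins=8)
        assert prof.sticker_counts.sum() + prof.spacer_counts.sum() == 40

    def test_uniform_ball_is_flat(self):
        """Monte-Carlo oracle: uniform beads in a ball give constant density."""
        rng = np.random.default_rng(2)
        n = 4000
        pts = rng.normal(size=(n, 3))
        pts *= (rng.random(n) ** (1 / 3) * 30.0 / np.linalg.norm(pts, axis=1))[:, None]
        roles = ["spacer"] * n
        topo = sm.ChainTopology(
            roles=roles,
            chain_ids=np.zeros(n, dtype=np.int64),
            permanent_bonds=np.column_stack([np.arange(n - 1), np.arange(1, n)]),
            angles=np.empty((0, 3), dtype=np.int64),
        )
        state = sm.SystemState.empty(n, (500, 500, 500))
        state.positions = np.mod(pts + 250.0, 500.0)
        prof = sm.radial_profile(state, topo, [0], bins=np.linspace(0, 30, 6))
        dens = prof.spacer_density
        expected = n / ((4 / 3) * np.pi * 30.0**3)
        # inner shells have few beads; compare within counting error
        counts = prof.spacer_counts
        for k in range(1, 5):
            tol = 3.5 * np.sqrt(max(counts[k], 1)) / counts[k]
            assert abs(dens[k] / expected - 1.0) < tol

    def test_empty_selection_rejected(self):
        state, topo = self._one_chain_state(np.zeros((5, 3)) + 250.0)
        with pytest.raises(InvalidInputError):
            sm.radial_profile(state, topo, [], bins=4)


def _make_traj(positions, dt=10.0, every=1):
    f, n, _ = positions.shape
    return Trajectory(
        steps=np.arange(f) * every,
        positions=positions,
        images=np.zeros((f, n, 3), dtype=np.int64),
        box=np.array([1e6, 1e6, 1e6]),
        dt=dt,
    )


class TestMSD:
    def test_static_trajectory(self):
        pos = np.zeros((50, 4, 3)) + 5.0
        fit = sm.msd_diffusion(_make_traj(pos))
        assert np.all(fit.msd == 0.0)
        assert fit.D == 0.0

    def test_ballistic_flagged_nonlinear(self):
        t = np.arange(100)[:, None, None]
        pos = np.zeros((100, 1, 3)) + t * np.array([0.3, 0.0, 0.0])
        fit = sm.msd_diffusion(_make_traj(pos))
        # MSD = v^2 t^2: log-log slope ~2 exposes the non-diffusive regime
        assert fit.loglog_slope == pytest.approx(2.0, abs=0.05)

    def test_too_short_trajectory(self):
        with pytest.raises(InvalidInputError):
            sm.msd_diffusion(_make_traj(np.zeros((1, 2, 3))))

    def test_free_langevin_bead_matches_analytic_d(self):
        table, _ = sm.validation.diffusion_scan(
            t_damps=(500.0,), n_beads=120, n_steps=120_000, seed=3
        )
        assert table["D_fit"].iloc[0] == pytest.approx(
            table["D_analytic"].iloc[0], rel=0.15
        )


class TestLinearFit:
    def test_exact_line(self):
        x = np.arange(5.0)
        fit = sm.linear_fit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_y(self):
        fit = sm.linear_fit([0.0, 1.0, 2.0], [3.0, 3.0, 3.0])
        assert fit.slope == 0.0

    def test_degenerate_x_rejected(self):
        with pytest.raises(InvalidInputError):
            sm.linear_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(st.integers(0, 2**31 - 1))
    def test_matches_normal_equations(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=5) * 3
        if np.ptp(x) == 0:
            return
        y = rng.normal(size=5)
        fit = sm.linear_fit(x, y)
        A = np.column_stack([x, np.ones(5)])
        slope, intercept = np.linalg.lstsq(A, y, rcond=None)[0]
        assert fit.slope == pytest.approx(slope, rel=1e-9, abs=1e-9)
        assert fit.intercept == pytest.approx(intercept, rel=1e-9, abs=1e-9)
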