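"""Chain building, packing, and data/restart file round trips."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

import stickermd as sm
from stickermd.errors import IntegrityError, InvalidInputError, PackingError, ParseError


class TestBuildChain:
    def test_two_component_block_expansion(self):
        """One sticker leading each 5-bead block, 10 repeats -> 50-bead chain."""
        tpl = sm.BlockTemplate(
            roles=("A", "spacer", "spacer", "spacer", "spacer"), repeat_count=10
        )
        chain = sm.build_chain(tpl)
        assert chain.n_beads == 50
        assert chain.sticker_indices.size == 10
        assert sum(r == "spacer" for r in chain.roles) == 40
        assert list(chain.sticker_indices) == [5 * k for k in range(10)]
        assert chain.permanent_bonds.shape == (49, 2)
        assert chain.angles.shape == (48, 3)

    def test_degenerate_single_bead(self):
        chain = sm.build_chain(sm.BlockTemplate(roles=("spacer",), repeat_count=1))
        assert chain.n_beads == 1
        assert chain.permanent_bonds.shape == (0, 2)
        assert chain.angles.shape == (0, 3)

    def test_empty_template_rejected(self):
        with pytest.raises(InvalidInputError):
            sm.BlockTemplate(roles=(), repeat_count=1)
        with pytest.raises(InvalidInputError):
            sm.BlockTemplate(roles=("A",), repeat_count=0)

    @pytest.mark.parametrize("repeats", [1, 3, 7, 20])
    def test_length_additive_in_repeats(self, repeats):
        tpl = sm.BlockTemplate(roles=("A", "spacer", "spacer"), repeat_count=repeats)
        chain = sm.build_chain(tpl)
        assert chain.n_beads == 3 * repeats
        assert chain.permanent_bonds.shape[0] == chain.n_beads - 1
        assert chain.angles.shape[0] == chain.n_beads - 2
        # bonds connect consecutive beads only
        assert np.all(np.diff(chain.permanent_bonds, axis=1) == 1)


class TestPackSystem:
    def test_full_two_component_system_counts(self):
        """200 + 200 copies of 50-bead chains in an 800 Å cube -> 20,000 beads."""
        ta, tb = sm.two_component_templates()
        state, topo = sm.pack_system(
            [(sm.build_chain(ta), 200), (sm.build_chain(tb), 200)],
            box=(800.0, 800.0, 800.0),
            seed=11,
        )
        assert state.n_beads == 20_000
        assert topo.n_chains == 400
        assert topo.permanent_bonds.shape[0] == 400 * 49
        assert topo.sticker_indices.size == 4_000
        assert np.all(state.velocities == 0.0)
        assert np.all(state.pairing == -1)
        # min-image separation contract between beads of different chains
        pts = np.mod(state.positions, state.box)
        tree = cKDTree(pts, boxsize=state.box)
        pairs = tree.query_pairs(10.0 - 1e-9, output_type="ndarray")
        cid = topo.chain_ids
        assert np.all(cid[pairs[:, 0]] == cid[pairs[:, 1]]), "inter-chain contact < min_sep"
        # consecutive beads sit at the bond length
        d = state.unwrapped_positions()
        bl = np.linalg.norm(
            d[topo.permanent_bonds[:, 1]] - d[topo.permanent_bonds[:, 0]], axis=1
        )
        assert np.allclose(bl, 10.0, atol=1e-9)

    def test_same_seed_bit_reproducible(self):
        tpl = sm.build_chain(sm.BlockTemplate(("A", "spacer"), 3))
        s1, _ = sm.pack_system([(tpl, 5)], box=(60, 60, 60), seed=9)
        s2, _ = sm.pack_system([(tpl, 5)], box=(60, 60, 60), seed=9)
        assert np.array_equal(s1.positions, s2.positions)
        s3, _ = sm.pack_system([(tpl, 5)], box=(60, 60, 60), seed=10)
        assert not np.array_equal(s1.positions, s3.positions)

    def test_infeasible_density_raises(self):
        bead = sm.build_chain(sm.BlockTemplate(("spacer",), 1))
        with pytest.raises(PackingError):
            sm.pack_system([(bead, 2)], box=(10, 10, 10), min_separation=20.0, seed=0)


class TestDataFile:
    def test_round_trip(self, small_system, params, tmp_path):
        state, topo = small_system
        state.pairing[topo.sticker_indices[0]] = topo.sticker_indices[-1]
        state.pairing[topo.sticker_indices[-1]] = topo.sticker_indices[0]
        path = tmp_path / "sys.data"
        sm.write_data_file(state, topo, params, path)
        s2, t2, p2 = sm.read_data_file(path)
        assert s2.n_beads == state.n_beads
        assert np.array_equal(s2.positions, state.positions)
        assert np.array_equal(s2.images, state.images)
        assert np.array_equal(s2.velocities, state.velocities)
        assert np.array_equal(s2.pairing, state.pairing)
        assert t2.roles == topo.roles
        assert np.array_equal(t2.permanent_bonds, topo.permanent_bonds)
        assert np.array_equal(t2.angles, topo.angles)
        assert np.array_equal(s2.box, state.box)
        for f in ("Kb", "R0_bond", "kappa", "sigma", "Ens", "Rmax", "Es", "R0_stick", "Rcut_stick", "p_on", "p_off"):
            assert getattr(p2, f) == getattr(params, f)

    def test_write_is_deterministic(self, small_system, params, tmp_path):
        state, topo = small_system
        sm.write_data_file(state, topo, params, tmp_path / "a.data")
        sm.write_data_file(state, topo, params, tmp_path / "b.data")
        assert (tmp_path / "a.data").read_bytes() == (tmp_path / "b.data").read_bytes()

    def test_bond_to_missing_atom_raises(self, small_system, params, tmp_path):
        state, topo = small_system
        path = tmp_path / "sys.data"
        sm.write_data_file(state, topo, params, path)
        text = path.read_text()
        lines = text.splitlines()
        k = lines.index("Bonds") + 2
        toks = lines[k].split()
        toks[2] = str(state.n_beads + 5)  # beyond the atom count
        lines[k] = " ".join(toks)
        bad = tmp_path / "bad.data"
        bad.write_text("\n".join(lines) + "\n")
        with pytest.raises(ParseError) as exc:
            sm.read_data_file(bad)
        assert exc.value.line is not None

    def test_mdanalysis_reads_our_data_file(self, small_system, params, tmp_path):
        """Cross-check the dialect against an independent LAMMPS-data reader."""
        mda = pytest.importorskip("MDAnalysis")
        state, topo = small_system
        path = tmp_path / "sys.data"
        sm.write_data_file(state, topo, params, path)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), format="DATA")
        assert len(u.atoms) == state.n_beads
        assert len(u.bonds) == topo.permanent_bonds.shape[0]
        assert len(u.angles) == topo.angles.shape[0]
        np.testing.assert_allclose(
            np.sort(u.atoms.positions[:, 0]),
            np.sort(state.positions[:, 0]),
            atol=1e-4,
        )


class TestRestart:
    def test_round_trip_exact(self, small_system, params, tmp_path):
        state, topo = small_system
        cfg = sm.SimulationConfig(n_steps=200, thermo_every=0, seed_thermostat=1, seed_bonds=2)
        res = sm.run(state, topo, params, cfg)
        state.step = 1_000_000  # emulate a long-run checkpoint label
        path = tmp_path / "x.restart"
        sm.write_restart(state, topo, path, rng=res.rng)
        s2, rng = sm.read_restart(path)
        assert s2.step == 1_000_000
        assert np.array_equal(s2.positions, state.positions)
        assert np.array_equal(s2.velocities, state.velocities)
        assert np.array_equal(s2.images, state.images)
        assert np.array_equal(s2.pairing, state.pairing)
        assert np.array_equal(rng["thermostat"], res.rng["thermostat"])
        assert np.array_equal(rng["bonds"], res.rng["bonds"])

    def test_reload_preserves_energies(self, small_system, params, tmp_path):
        state, topo = small_system
        path = tmp_path / "x.restart"
        sm.write_restart(state, topo, path)
        s2, _ = sm.read_restart(path)
        _, e1 = sm.total_energy_forces(state, topo, params)
        _, e2 = sm.total_energy_forces(s2, topo, params)
        assert e1.E_potential == e2.E_potential

    def test_missing_pairing_section_raises(self, small_system, params, tmp_path):
        state, topo = small_system
        path = tmp_path / "x.restart"
        sm.write_restart(state, topo, path)
        lines = path.read_text().splitlines()
        k = lines.index("pairing")
        bad = lines[:k] + ["end"]
        p2 = tmp_path / "bad.restart"
        p2.write_text("\n".join(bad) + "\n")
        with pytest.raises(IntegrityError):
            sm.read_restart(p2)

    def test_truncated_file_raises(self, small_system, params, tmp_path):
        state, topo = small_system
        path = tmp_path / "x.restart"
        sm.write_restart(state, topo, path)
        text = path.read_text()
        (tmp_path / "trunc.restart").write_text(text[: len(text) // 2])
        with pytest.raises(IntegrityError):
            sm.read_restart(tmp_path / "trunc.restart")
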