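import numpy as np
import pytest
from hypothesis import given, strategies as st

import nanopmf as npf
from nanopmf import energy, mc
from nanopmf.constants import bjerrum_length
from nanopmf.state import MCState


@pytest.fixture()
def small_system():
    cat, an = npf.symmetric_salt(2, 0.01)
    spec = npf.SystemSpec(nanoparticles=npf.build_geometry(2, 25.0, charge=-24.0),
                          cation=cat, anion=an)
    cell = npf.build_cell(spec)
    state = npf.populate_ions(spec, cell, seed=5)
    return spec, cell, state


class TestMinImage:
    def test_identical_positions(self):
        cell = npf.SimulationCell(lengths=np.array([50.0, 60.0, 70.0]))
        d = npf.min_image_displacement(np.zeros(3), np.zeros(3), cell)
        np.testing.assert_array_equal(d, 0.0)

    def test_full_edge_separation_wraps_to_zero(self):
        cell = npf.SimulationCell(lengths=np.array([50.0, 60.0, 70.0]))
        d = npf.min_image_displacement(np.array([25.0, 0.0, 0.0]),
                                       np.array([-25.0, 0.0, 0.0]), cell)
        np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_wraps_beyond_half_edge(self):
        cell = npf.SimulationCell(lengths=np.full(3, 100.0))
        d = npf.min_image_displacement(np.array([30.0, 0.0, 0.0]),
                                       np.array([-30.0, 0.0, 0.0]), cell)
        assert d[0] == pytest.approx(-40.0)

    @given(st.lists(st.floats(-50.0, 50.0), min_size=6, max_size=6))
    def test_components_bounded_by_half_edge(self, coords):
        cell = npf.SimulationCell(lengths=np.full(3, 100.0))
        a = np.array(coords[:3])
        b = np.array(coords[3:])
        d = npf.min_image_displacement(a, b, cell)
        assert np.all(np.abs(d) <= 50.0 + 1e-9)


class TestPairCoulomb:
    def test_zero_charge_gives_zero(self):
        assert npf.pair_coulomb(0.0, 5.0, 3.0, bjerrum_length()) == 0.0

    def test_unit_charges_at_bjerrum_length_give_one_kt(self):
        lb = bjerrum_length()
        assert npf.pair_coulomb(1.0, 1.0, lb, lb) == pytest.approx(1.0)

    def test_divalent_contact_with_nanoparticle(self):
        lb = bjerrum_length()
        u = npf.pair_coulomb(-24.0, 2.0, 12.0, lb)
        assert u == pytest.approx(-48.0 * lb / 12.0)
        assert u == pytest.approx(-28.7, abs=0.1)

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            npf.pair_coulomb(1.0, 1.0, 0.0, bjerrum_length())


class TestHardcore:
    def test_ion_pair_overlap(self, small_system):
        spec, cell, _ = small_system
        pos = np.array([[0.0, 0.0, 30.0], [0.0, 0.0, 33.9]])
        rad = np.full(2, 2.0)
        assert npf.hardcore_overlap(spec, cell, pos, rad)
        pos[1, 2] = 34.1
        assert not npf.hardcore_overlap(spec, cell, pos, rad)

    def test_ion_nanoparticle_contact(self, small_system):
        spec, cell, _ = small_system
        c = spec.nanoparticles.centers[0]
        pos = (c + np.array([0.0, 0.0, 12.1]))[None, :]
        assert not npf.hardcore_overlap(spec, cell, pos, np.full(1, 2.0))
        pos = (c + np.array([0.0, 0.0, 11.9]))[None, :]
        assert npf.hardcore_overlap(spec, cell, pos, np.full(1, 2.0))

    def test_empty_ion_set(self, small_system):
        spec, cell, _ = small_system
        assert not npf.hardcore_overlap(spec, cell, np.empty((0, 3)),
                                        np.empty(0))


class TestTotalEnergy:
    def test_bare_pair_closed_form(self):
        fx = npf.make_fixture("no_ions_pair")
        spec = fx["spec"]
        cell = npf.build_cell(spec)
        state = npf.populate_ions(spec, cell, seed=0, neutralize=False)
        assert state.n_ions == 0
        expected = 576.0 * spec.bjerrum_length / 25.0
        assert npf.total_electrostatic_energy(spec, cell, state) == \
            pytest.approx(expected, rel=1e-12)

    def test_all_zero_charges(self):
        fx = npf.make_fixture("zero_charge")
        spec = fx["spec"]
        cell = npf.build_cell(spec)
        state = npf.populate_ions(spec, cell, seed=0)
        state.valences[:] = 0.0
        assert npf.total_electrostatic_energy(spec, cell, state) == 0.0

    def test_matches_exhaustive_pair_sum(self, small_system):
        spec, cell, state = small_system
        lb = spec.bjerrum_length
        pos = np.vstack([spec.nanoparticles.centers, state.positions])
        q = np.concatenate([np.full(2, spec.nanoparticles.charge),
                            state.valences])
        brute = 0.0
        L = cell.lengths
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                d = pos[i] - pos[j]
                d -= L * np.round(d / L)
                brute += q[i] * q[j] * lb / np.linalg.norm(d)
        assert npf.total_electrostatic_energy(spec, cell, state) == \
            pytest.approx(brute, rel=1e-10)

    def test_overlap_raises(self, small_system):
        spec, cell, state = small_system
        state = state.copy()
        state.positions[1] = state.positions[0] + np.array([0.0, 0.0, 1.0])
        with pytest.raises(ValueError):
            npf.total_electrostatic_energy(spec, cell, state)


class TestMoveDelta:
    def test_null_move_is_zero(self, small_system):
        spec, cell, state = small_system
        du = npf.move_delta_energy(spec, cell, state, 3,
                                   state.positions[3].copy())
        assert du == pytest.approx(0.0, abs=1e-12)

    def test_single_ion_inverse_distance(self):
        cat, an = npf.symmetric_salt(2, 0.0)
        npset = npf.NanoparticleSet(count=1, charge=-24.0)
        spec = npf.SystemSpec(nanoparticles=npset, cation=cat, anion=an)
        cell = npf.SimulationCell(lengths=np.full(3, 200.0))
        state = MCState(positions=np.array([[40.0, 0.0, 0.0]]),
                        valences=np.array([2.0]), radii=np.array([2.0]))
        state.energy = npf.total_electrostatic_energy(spec, cell, state)
        du = npf.move_delta_energy(spec, cell, state, 0,
                                   np.array([20.0, 0.0, 0.0]))
        # halving the distance doubles the (negative) pair energy
        assert du == pytest.approx(state.energy, rel=1e-12)

    def test_matches_full_recompute(self, small_system):
        spec, cell, state = small_system
        rng = np.random.default_rng(17)
        u0 = npf.total_electrostatic_energy(spec, cell, state)
        for _ in range(20):
            i = int(rng.integers(state.n_ions))
            prop = energy.wrap_positions(
                state.positions[i] + rng.normal(scale=5.0, size=3), cell)
            if energy.hardcore_overlap(spec, cell, state.positions,
                                       state.radii, candidate=prop,
                                       candidate_radius=state.radii[i],
                                       exclude_index=i):
                continue
            du = npf.move_delta_energy(spec, cell, state, i, prop)
            state.positions[i] = prop
            u1 = npf.total_electrostatic_energy(spec, cell, state)
            assert du == pytest.approx(u1 - u0, rel=1e-9, abs=1e-9)
            u0 = u1

    def test_index_out_of_range(self, small_system):
        spec, cell, state = small_system
        with pytest.raises(IndexError):
            npf.move_delta_energy(spec, cell, state, state.n_ions,
                                  np.zeros(3))


class TestInvariants:
    def test_incremental_bookkeeping_after_many_moves(self, small_system):
        """Cached energy stays within 1e-6 kT of a full recompute."""
        spec, cell, state = small_system
        driver = mc._ChainDriver(spec, cell, state, 1.0, 4.0)
        driver.run(30_000)  # well over 1e4 accepted moves
        full = npf.total_electrostatic_energy(spec, cell, state)
        assert abs(state.energy - full) < 1e-6

    def test_translation_by_lattice_vector(self, small_system):
        spec, cell, state = small_system
        u0 = npf.total_electrostatic_energy(spec, cell, state)
        shifted = state.copy()
        shifted.positions = energy.wrap_positions(
            shifted.positions + cell.lengths, cell)
        u1 = npf.total_electrostatic_energy(spec, cell, shifted)
        assert u1 == pytest.approx(u0, rel=1e-10)

    def test_global_rotation_with_rotated_geometry(self):
        """Exact rotation invariance when no pair crosses half a box."""
        from scipy.spatial.transform import Rotation

        cat, an = npf.symmetric_salt(2, 0.01)
        base = npf.build_geometry(3, 25.0, charge=-24.0)
        rot = Rotation.random(random_state=3).as_matrix()
        cell = npf.SimulationCell(lengths=np.full(3, 500.0))
        rng = np.random.default_rng(2)
        pos = rng.uniform(-40.0, 40.0, size=(20, 3))
        dist = np.linalg.norm(pos[:, None, :] - base.centers[None, :, :],
                              axis=-1).min(axis=1)
        pos = pos[dist > 12.5][:10]
        vals = np.tile([2.0, -2.0], 5)[:len(pos)]
        state = MCState(positions=pos, valences=vals,
                        radii=np.full(len(pos), 2.0))
        rotated = npf.NanoparticleSet(count=3, charge=-24.0, separation=25.0,
                                      centers=base.centers @ rot.T)
        spec0 = npf.SystemSpec(nanoparticles=base, cation=cat, anion=an)
        spec1 = npf.SystemSpec(nanoparticles=rotated, cation=cat, anion=an)
        state1 = MCState(positions=pos @ rot.T, valences=vals,
                         radii=np.full(len(pos), 2.0))
        u0 = npf.total_electrostatic_energy(spec0, cell, state)
        u1 = npf.total_electrostatic_energy(spec1, cell, state1)
        assert u1 == pytest.approx(u0, rel=1e-10)
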