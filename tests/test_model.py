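"""Unit and property tests for the potential-energy model and forces."""

import numpy as np
import pytest

from dipolemm import (build_dimer, build_monomer, default_parameters,
                      dipole_pair_energy, forces, lj_pair_energy,
                      total_energy)
from dipolemm.builders import BuildRecipe, pack_cluster, pack_liquid_box
from dipolemm.model import (CompiledFF, ConfigurationError, MolecularSystem,
                            ParameterLookupError, SingularGeometryError,
                            energy_forces, merge_systems, K_DIPOLE)

from oracles import K_DD, brute_force_energy, numerical_gradient


# ---------------------------------------------------------------------------
# Pair-level operations
# ---------------------------------------------------------------------------


class TestLJPair:
    def test_minimum_depth(self, ff):
        p = ff.lj_params("C_co2")
        q = ff.lj_params("O_co2")
        rm = p.rv + q.rv
        eps = np.sqrt(p.eps * q.eps)
        assert lj_pair_energy("C_co2", "O_co2", rm, ff) == pytest.approx(-eps)

    def test_zero_beyond_cutoff(self, ff):
        assert lj_pair_energy("C_co2", "C_co2", ff.cut_vdw + 0.01, ff) == 0.0
        assert lj_pair_energy("C_co2", "C_co2", ff.cut_vdw, ff) == 0.0

    def test_symmetric_combining(self, ff):
        for r in (3.0, 3.7, 9.5):
            assert lj_pair_energy("C_co2", "N_amine", r, ff) == \
                lj_pair_energy("N_amine", "C_co2", r, ff)

    def test_unknown_class_raises(self, ff):
        with pytest.raises(ParameterLookupError, match="He_x"):
            lj_pair_energy("He_x", "C_co2", 3.0, ff)

    def test_invalid_distance(self, ff):
        with pytest.raises(ValueError):
            lj_pair_energy("C_co2", "C_co2", 0.0, ff)


class TestDipolePair:
    def test_collinear_head_to_tail(self, ff):
        # mu1 = mu2 = 1 D at 3 A, chi = a1 = a2 = 0: E = K (1-3)/27
        d1 = (np.array([0., 0., -0.5]), np.array([0., 0., 0.5]), 1.0)
        d2 = (np.array([0., 0., 2.5]), np.array([0., 0., 3.5]), 1.0)
        expected = K_DD * (1.0 - 3.0) / 27.0
        assert dipole_pair_energy(d1, d2, ff) == pytest.approx(expected,
                                                               rel=1e-6)
        assert expected == pytest.approx(-1.066, abs=2e-3)

    def test_perpendicular_orientation_vanishes(self, ff):
        d1 = (np.array([0., -0.5, 0.]), np.array([0., 0.5, 0.]), 1.5)
        d2 = (np.array([3., 0., -0.5]), np.array([3., 0., 0.5]), 2.0)
        # axes along y and z, separation along x: chi=90, a1=a2=90
        assert dipole_pair_energy(d1, d2, ff) == pytest.approx(0.0, abs=1e-12)

    def test_prefactor_rederived(self):
        assert K_DIPOLE == pytest.approx(14.3928, abs=1e-2)

    def test_coincident_midpoints_raise(self, ff):
        d1 = (np.array([0., 0., -0.5]), np.array([0., 0., 0.5]), 1.0)
        d2 = (np.array([-0.5, 0., 0.]), np.array([0.5, 0., 0.]), 1.0)
        with pytest.raises(SingularGeometryError):
            dipole_pair_energy(d1, d2, ff)


# ---------------------------------------------------------------------------
# Bonded terms
# ---------------------------------------------------------------------------


class TestBonded:
    def test_equilibrium_is_zero(self, ff):
        from dipolemm import bonded_energy
        co2 = build_monomer("CO2", ff=ff)
        es, eb, et = bonded_energy(co2, ff)
        assert es == pytest.approx(0.0, abs=1e-12)
        assert eb == pytest.approx(0.0, abs=1e-10)
        assert et == 0.0  # CO2 has no torsions

    def test_harmonic_arithmetic(self, ff):
        from dipolemm import bonded_energy
        ff2 = ff.copy()
        ff2.bond_params("C_co2", "O_co2").ks = 300.0
        co2 = build_monomer("CO2", ff=ff2)
        co2.positions[1, 2] += 0.1  # stretch one bond by +0.1 A
        es, _, _ = bonded_energy(co2, ff2)
        assert es == pytest.approx(3.0, rel=1e-9)


# ---------------------------------------------------------------------------
# Whole-system evaluation
# ---------------------------------------------------------------------------


def _random_systems(ff, rng, n=20):
    """Mixed bag of small randomized CO2/MEA systems."""
    out = []
    for k in range(n):
        kind = k % 4
        if kind == 0:
            s, _ = build_dimer(("CO2", "CO2"), "min", ff=ff)
        elif kind == 1:
            s, _ = build_dimer(("MEA", "MEA"), "OHO", ff=ff)
        elif kind == 2:
            s, _ = build_dimer(("CO2", "MEA"), "amino", ff=ff)
        else:
            a = build_monomer("MEA", "gauche_intraHB", ff=ff)
            b = build_monomer("CO2", ff=ff)
            b.positions += rng.uniform(3, 6, size=3)
            s = merge_systems(a, b)
        s.positions = s.positions + rng.normal(scale=0.06,
                                               size=s.positions.shape)
        out.append(s)
    return out


class TestTotalEnergy:
    def test_separated_molecules_no_interaction(self, ff):
        a = build_monomer("CO2", ff=ff)
        b = build_monomer("CO2", ff=ff)
        b.positions = b.positions + np.array([50.0, 0.0, 0.0])
        dec = total_energy(merge_systems(a, b), ff)
        assert dec.lj == 0.0
        assert dec.dipole == 0.0

    def test_isometry_invariance(self, ff, co2_dimer, rng):
        e0 = total_energy(co2_dimer, ff).total
        s = co2_dimer.copy()
        s.positions = s.positions + np.array([7.0, -3.0, 11.0])
        assert abs(total_energy(s, ff).total - e0) < 1e-8
        th = 0.83
        rot = np.array([[np.cos(th), -np.sin(th), 0],
                        [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        s.positions = s.positions @ rot.T
        assert abs(total_energy(s, ff).total - e0) < 1e-8

    def test_matches_brute_force_oracle(self, ff, rng):
        for s in _random_systems(ff, rng, 20):
            dec = total_energy(s, ff)
            ref = brute_force_energy(s, ff)
            assert dec.stretch == pytest.approx(ref["stretch"], abs=1e-9)
            assert dec.bend == pytest.approx(ref["bend"], abs=1e-9)
            assert dec.torsion == pytest.approx(ref["torsion"], abs=1e-9)
            assert dec.lj == pytest.approx(ref["lj"], abs=1e-9)
            assert dec.dipole == pytest.approx(ref["dipole"], abs=1e-9)
            assert dec.total == pytest.approx(ref["total"], abs=1e-8)

    def test_periodic_matches_brute_force(self, ff):
        box = pack_liquid_box(BuildRecipe(species="MEA", count=8,
                                          density=0.35, seed=7), ff=ff)
        dec = total_energy(box, ff)
        ref = brute_force_energy(box, ff)
        assert dec.total == pytest.approx(ref["total"], abs=1e-8)

    def test_decomposition_sums(self, ff, co2_dimer):
        dec = total_energy(co2_dimer, ff)
        parts = (dec.stretch + dec.bend + dec.torsion + dec.lj
                 + dec.dipole + dec.wall)
        assert dec.total == pytest.approx(parts, abs=1e-12)

    def test_periodic_cell_translation_invariance(self, ff):
        box = pack_liquid_box(BuildRecipe(species="MEA", count=8,
                                          density=0.35, seed=7), ff=ff)
        e0 = total_energy(box, ff).total
        moved = box.copy()
        # shift one whole molecule by an integer cell vector
        mask = moved.molecule_index == 3
        moved.positions[mask] += moved.cell * np.array([1.0, -2.0, 1.0])
        assert total_energy(moved, ff).total == pytest.approx(e0, abs=1e-8)

    def test_tiny_cell_rejected(self, ff):
        s = build_monomer("CO2", ff=ff)
        s.cell = np.array([6.0, 6.0, 6.0])
        with pytest.raises(ConfigurationError):
            total_energy(s, ff)


class TestForces:
    def test_equilibrium_monomer_forces_vanish(self, ff):
        from dipolemm import minimize
        res = minimize(build_monomer("CO2", ff=ff), ff, tol=1e-7)
        f = forces(res.system, ff)
        assert np.abs(f).max() < 1e-6

    def test_net_force_zero(self, ff, rng):
        for s in _random_systems(ff, rng, 6):
            f = forces(s, ff)
            assert np.abs(f.sum(axis=0)).max() < 1e-8

    def test_net_torque_zero(self, ff, rng):
        for s in _random_systems(ff, rng, 4):
            f = forces(s, ff)
            tau = np.cross(s.positions, f).sum(axis=0)
            assert np.abs(tau).max() < 1e-8

    def test_matches_finite_differences(self, ff, rng):
        for s in _random_systems(ff, rng, 6):
            g = -forces(s, ff)
            gfd = numerical_gradient(s, ff)
            rel = np.linalg.norm(g - gfd) / max(np.linalg.norm(gfd), 1e-10)
            assert rel < 1e-5

    def test_numba_and_numpy_paths_agree(self, ff, rng):
        for s in _random_systems(ff, rng, 4):
            d1, f1, W1 = energy_forces(s, ff, use_numba=True)
            d2, f2, W2 = energy_forces(s, ff, use_numba=False)
            assert d1.total == pytest.approx(d2.total, abs=1e-10)
            assert np.abs(f1 - f2).max() < 1e-10
            assert W1 == pytest.approx(W2, abs=1e-8)


class TestDipoleConventions:
    def test_bond_direction_swap_changes_nothing(self, ff, rng):
        """Reversing the stored atom order of polar bonds leaves every
        energy unchanged (the dipole's sign convention is canonical)."""
        s, _ = build_dimer(("MEA", "MEA"), "NHN", ff=ff)
        s.positions += rng.normal(scale=0.04, size=s.positions.shape)
        e0 = total_energy(s, ff).total
        flipped = MolecularSystem(
            classes=list(s.classes),
            positions=s.positions.copy(),
            bonds=s.bonds[:, ::-1].copy(),
        )
        assert total_energy(flipped, ff).total == pytest.approx(e0, abs=1e-10)

    def test_neighbor_list_equals_brute_force(self, ff):
        from dipolemm.dynamics import NeighborList
        cl = pack_cluster(BuildRecipe(species="CO2", count=20, radius=8.0,
                                      seed=5), ff=ff)
        comp = CompiledFF(cl, ff)
        nl = NeighborList(cl, comp)
        dec_nl, f_nl, _ = energy_forces(cl, ff, comp, nb_pairs=nl.nb_pairs,
                                        dd_pairs=nl.dd_pairs)
        ref = brute_force_energy(cl, ff)
        assert dec_nl.lj == pytest.approx(ref["lj"], abs=1e-9)
        assert dec_nl.dipole == pytest.approx(ref["dipole"], abs=1e-9)


# ---------------------------------------------------------------------------
# Property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings, HealthCheck
from hypothesis import strategies as st

_coord = st.floats(min_value=-8.0, max_value=8.0, allow_nan=False,
                   allow_infinity=False)


class TestPairProperties:
    @given(r=st.floats(min_value=0.5, max_value=15.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_lj_symmetry_and_taper_sign(self, r):
        ff = default_parameters()
        a = lj_pair_energy("C_co2", "O_hydroxyl", r, ff)
        b = lj_pair_energy("O_hydroxyl", "C_co2", r, ff)
        assert a == b
        if r >= ff.cut_vdw:
            assert a == 0.0

    @given(ax=_coord, ay=_coord, az=_coord, bx=_coord, by=_coord, bz=_coord,
           mu1=st.floats(min_value=-3, max_value=3),
           mu2=st.floats(min_value=-3, max_value=3))
    @settings(max_examples=60, deadline=None, derandomize=True,
              suppress_health_check=[HealthCheck.filter_too_much])
    def test_dipole_pair_invariances(self, ax, ay, az, bx, by, bz, mu1, mu2):
        """Swapping tail/head together with the sign of mu leaves the
        pair energy unchanged; flipping one sign flips the energy."""
        ff = default_parameters()
        t1 = np.array([0.0, 0.0, 0.0])
        h1 = np.array([0.9, 0.1, 0.0])
        t2 = np.array([ax, ay, az])
        h2 = np.array([bx, by, bz])
        sep = np.linalg.norm(0.5 * (t2 + h2) - 0.5 * (t1 + h1))
        if np.linalg.norm(h2 - t2) < 0.2 or sep < 0.5:
            return
        e = dipole_pair_energy((t1, h1, mu1), (t2, h2, mu2), ff)
        e_swap = dipole_pair_energy((t1, h1, mu1), (h2, t2, -mu2), ff)
        e_flip = dipole_pair_energy((t1, h1, mu1), (t2, h2, -mu2), ff)
        assert e == pytest.approx(e_swap, abs=1e-10)
        assert e == pytest.approx(-e_flip, abs=1e-10)


class TestInteractionEnergy:
    def test_separated_fragments_give_zero(self, ff):
        from dipolemm import interaction_energy
        a = build_monomer("CO2", ff=ff)
        b = build_monomer("CO2", ff=ff)
        b.positions = b.positions + np.array([60.0, 0.0, 0.0])
        dimer = merge_systems(a, b)
        eint = interaction_energy(dimer, [0, 1], ff)
        assert eint == pytest.approx(0.0, abs=1e-6)

    def test_calibrated_minimum_dimer(self, ff_cal):
        from dipolemm import build_dimer, interaction_energy
        dimer, _ = build_dimer(("CO2", "CO2"), "min", ff=ff_cal)
        eint = interaction_energy(dimer, [0, 1], ff_cal)
        assert eint == pytest.approx(-1.23, abs=0.02)

    def test_invalid_partition_rejected(self, ff, co2_dimer):
        from dipolemm import interaction_energy
        with pytest.raises(ValueError, match="partition"):
            interaction_energy(co2_dimer, [0, 0], ff)
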