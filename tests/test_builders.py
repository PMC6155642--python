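"""Tests for the structure builders (monomers, dimers, packing, interface)."""

import numpy as np
import pytest

from dipolemm import (build_dimer, build_monomer, carve_cavity,
                      merge_interface, pack_cluster, pack_liquid_box,
                      scale_bond_dipole)
from dipolemm.builders import (MASS_MEA, BuildRecipe, DENS_G_CM3,
                               PackingError, molecule_centers_of_mass)


class TestMonomers:
    def test_co2_geometry(self, ff):
        co2 = build_monomer("CO2", ff=ff)
        assert co2.n_atoms == 3
        p = co2.positions
        r1 = np.linalg.norm(p[1] - p[0])
        r2 = np.linalg.norm(p[2] - p[0])
        assert r1 == pytest.approx(r2, abs=1e-12)
        cos = (p[1] - p[0]) @ (p[2] - p[0]) / (r1 * r2)
        assert np.degrees(np.arccos(np.clip(cos, -1, 1))) == \
            pytest.approx(180.0, abs=1e-9)

    def test_mea_atom_count(self, ff):
        assert build_monomer("MEA", "trans", ff=ff).n_atoms == 11

    def test_gauche_intrahb_geometry(self, ff):
        m = build_monomer("MEA", "gauche_intraHB", ff=ff)
        r = np.linalg.norm(m.positions[4] - m.positions[1])  # N...H(O)
        assert r < 2.5

    def test_unknown_conformer(self, ff):
        with pytest.raises(ValueError, match="conformer"):
            build_monomer("MEA", "cis_nonsense", ff=ff)


class TestDimers:
    def test_parallel_start(self, ff):
        s, cons = build_dimer(("CO2", "CO2"), "parallel", ff=ff)
        p = s.positions
        assert np.linalg.norm(p[3] - p[0]) == pytest.approx(4.0)
        ax1 = p[1] - p[2]
        ax2 = p[4] - p[5]
        cos = ax1 @ ax2 / np.linalg.norm(ax1) / np.linalg.norm(ax2)
        assert abs(cos) == pytest.approx(1.0, abs=1e-9)
        assert len(cons) == 4

    def test_t_type_start(self, ff):
        s, _ = build_dimer(("CO2", "CO2"), "T-type", ff=ff)
        p = s.positions
        ax1 = p[1] - p[2]
        ax2 = p[4] - p[5]
        assert abs(ax1 @ ax2) < 1e-9  # perpendicular axes
        # second C lies on the first molecule's perpendicular bisector
        assert abs((p[3] - p[0]) @ ax1) < 1e-9

    def test_nhn_collinear(self, ff):
        s, cons = build_dimer(("MEA", "MEA"), "NHN", ff=ff)
        p = s.positions
        d_x, d_h, a_y = cons[0].atoms
        v1 = p[d_h] - p[d_x]
        v2 = p[a_y] - p[d_h]
        cos = v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2)
        assert np.degrees(np.arccos(np.clip(cos, -1, 1))) < 1.0

    def test_invalid_label(self, ff):
        with pytest.raises(ValueError):
            build_dimer(("CO2", "CO2"), "sideways", ff=ff)


class TestPacking:
    def test_cluster_respects_min_distance(self, ff):
        cl = pack_cluster(BuildRecipe(species="CO2", count=13, radius=6.0,
                                      seed=4), ff=ff)
        mol = cl.molecule_index
        p = cl.positions
        dmin = np.inf
        for m in range(13):
            a = p[mol == m]
            b = p[mol > m]
            if len(b):
                d = np.linalg.norm(a[:, None] - b[None, :], axis=2).min()
                dmin = min(dmin, d)
        assert dmin >= 2.0

    def test_cluster_deterministic_per_seed(self, ff):
        r = BuildRecipe(species="CO2", count=13, radius=6.0, seed=11)
        a = pack_cluster(r, ff=ff)
        b = pack_cluster(BuildRecipe(species="CO2", count=13, radius=6.0,
                                     seed=11), ff=ff)
        assert np.array_equal(a.positions, b.positions)

    def test_cluster_has_wall(self, ff):
        cl = pack_cluster(BuildRecipe(species="CO2", count=44,
                                      radius=9.1257, seed=1), ff=ff)
        assert cl.wall is not None
        assert cl.wall.radius == pytest.approx(9.1257)
        assert cl.n_atoms == 132

    def test_infeasible_packing_raises(self, ff):
        with pytest.raises(PackingError):
            pack_cluster(BuildRecipe(species="MEA", count=40, radius=4.0,
                                     seed=0), ff=ff)

    def test_box_cell_edge_from_density(self, ff):
        box = pack_liquid_box(BuildRecipe(species="MEA", count=32,
                                          density=1.01, seed=1), ff=ff)
        expected = (32 * MASS_MEA * DENS_G_CM3 / 1.01) ** (1 / 3)
        assert box.cell[0] == pytest.approx(expected, rel=1e-9)
        # density recomputed from the built cell
        rho = 32 * MASS_MEA * DENS_G_CM3 / np.prod(box.cell)
        assert rho == pytest.approx(1.01, rel=1e-3)

    def test_mea128_box_builds(self, ff):
        box = pack_liquid_box(BuildRecipe(species="MEA", count=128,
                                          density=1.01, seed=2), ff=ff)
        assert box.n_atoms == 128 * 11
        from dipolemm.model import total_energy
        assert np.isfinite(total_energy(box, ff).total)


class TestInterface:
    @pytest.fixture(scope="class")
    def box(self, ff):
        return pack_liquid_box(BuildRecipe(species="MEA", count=48,
                                           density=1.01, seed=3), ff=ff)

    def test_zero_radius_removes_nothing(self, box):
        carved, removed = carve_cavity(box, radius=0.0)
        assert removed == 0
        assert carved.n_atoms == box.n_atoms

    def test_carve_postcondition(self, box):
        carved, removed = carve_cavity(box, radius=5.0)
        assert removed > 0
        com = molecule_centers_of_mass(carved)
        d = com - box.cell / 2
        d -= box.cell * np.round(d / box.cell)
        assert np.linalg.norm(d, axis=1).min() >= 5.0

    def test_carve_radius_bound(self, box):
        with pytest.raises(ValueError, match="half the cell"):
            carve_cavity(box, radius=0.6 * box.cell[0])

    def test_merge_bookkeeping(self, ff, box):
        carved, removed = carve_cavity(box, radius=6.0)
        cluster = pack_cluster(BuildRecipe(species="CO2", count=5,
                                           radius=4.0, seed=6), ff=ff)
        merged = merge_interface(cluster, carved, min_dist=1.0)
        assert merged.n_atoms == cluster.n_atoms + carved.n_atoms
        assert merged.wall is None
        assert merged.cell is not None
        # atom conservation through carve + merge
        assert carved.n_atoms + removed * 11 == box.n_atoms


class TestDipoleScaling:
    def test_identity_factor(self, ff):
        out = scale_bond_dipole(ff, ("O_hydroxyl", "H_O"), 1.0)
        assert out.bonds[("O_hydroxyl", "H_O")].mu == \
            ff.bonds[("O_hydroxyl", "H_O")].mu

    def test_scales_only_target_class(self, ff):
        out = scale_bond_dipole(ff, ("O_hydroxyl", "H_O"), 0.1)
        assert out.bonds[("O_hydroxyl", "H_O")].mu == \
            pytest.approx(0.1 * ff.bonds[("O_hydroxyl", "H_O")].mu)
        for key, p in ff.bonds.items():
            if key == ("O_hydroxyl", "H_O"):
                continue
            assert out.bonds[key].mu == p.mu
            assert out.bonds[key].ks == p.ks

    def test_oho_dimer_weakens(self, ff_cal):
        from dipolemm.calibrate import Evaluator
        e_full = Evaluator(ff_cal).dimer("mea_OHO")["total"]
        scaled = scale_bond_dipole(ff_cal, ("O_hydroxyl", "H_O"), 0.1)
        e_scaled = Evaluator(scaled).dimer("mea_OHO")["total"]
        assert e_scaled > e_full  # weaker (less negative) binding

    def test_invalid_inputs(self, ff):
        with pytest.raises(ValueError):
            scale_bond_dipole(ff, ("O_hydroxyl", "H_O"), 0.0)
        with pytest.raises(KeyError):
            scale_bond_dipole(ff, ("O_hydroxyl", "H_N"), 0.5)
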