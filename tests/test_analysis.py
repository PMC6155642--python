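"""Tests for heat capacity, RDFs, and hydrogen-bond histograms."""

import numpy as np
import pytest

from dipolemm import build_monomer
from dipolemm.analysis import (HBHistogram, detect_peak, heat_capacity,
                               intra_hb_histogram, rdf, rdf_from_trajectory,
                               rdf_time_evolution)
from dipolemm.dynamics import (IntegratorSpec, ThermostatSpec, Trajectory,
                               run_md)
from dipolemm.model import KB, MolecularSystem, merge_systems


class TestHeatCapacity:
    def test_constant_energy_gives_zero(self):
        assert heat_capacity([5.0] * 100, 300.0) == 0.0

    def test_two_point_variance(self):
        # samples {0, 2}: population variance 1 (kcal/mol)^2
        cv = heat_capacity([0.0, 2.0], 300.0)
        assert cv == pytest.approx(1.0 / (KB * 300.0 ** 2), rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            heat_capacity([1.0, 2.0], -10.0)
        with pytest.raises(ValueError):
            heat_capacity([1.0], 300.0)

    @staticmethod
    def _chain(ff, n):
        pos = np.zeros((n, 3))
        for i in range(1, n):
            pos[i] = pos[i - 1] + np.array([1.45, 0.9 * (i % 2), 0.1])
        ff2 = ff.copy()
        for p in ff2.lj.values():
            p.eps = 0.0
        ff2.torsions.clear()  # keep the test system purely quadratic
        chain = MolecularSystem(classes=["C_sp3"] * n, positions=pos,
                                bonds=[[i, i + 1] for i in range(n - 1)])
        return chain, ff2

    @staticmethod
    def _canonical_u_samples(chain, ff2, t0, n_segments, seed):
        """Canonical sampling via massive velocity redraws between short
        NVE segments (Andersen-style collisions)."""
        samples = []
        work = chain.copy()
        m = work.masses
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(KB * t0 * 418.4 / m)
        for k in range(n_segments):
            # raw Maxwell-Boltzmann redraw (no rescaling): canonical
            work.velocities = rng.normal(size=(work.n_atoms, 3)) \
                * sigma[:, None]
            traj = run_md(work, ff2,
                          IntegratorSpec(n_steps=600, stride=600, seed=0))
            work = work.copy()
            work.positions = traj.positions[-1]
            if k >= n_segments // 10:
                samples.append(traj.potential[-1])
        return np.array(samples)

    def test_equipartition_on_harmonic_chain(self, ff):
        """Potential-energy Cv of a harmonic chain sampled canonically
        matches (n_modes/2) kB within 10%."""
        n = 8
        chain, ff2 = self._chain(ff, n)
        u = self._canonical_u_samples(chain, ff2, 300.0, 1500, seed=11)
        cv = heat_capacity(u, 300.0)
        n_modes = (n - 1) + (n - 2)  # bonds + angles
        expected = 0.5 * n_modes * KB
        assert cv == pytest.approx(expected, rel=0.10)

    def test_fluctuation_estimator_matches_dU_dT(self, ff):
        """Cv from fluctuations agrees with the numerical derivative of
        <U> across adjacent temperatures."""
        chain, ff2 = self._chain(ff, 6)
        means, cvs = [], []
        for t0 in (260.0, 300.0, 340.0):
            u = self._canonical_u_samples(chain, ff2, t0, 1200, seed=13)
            means.append(u.mean())
            cvs.append(heat_capacity(u, t0))
        dudt = (means[2] - means[0]) / 80.0
        assert cvs[1] == pytest.approx(dudt, rel=0.15)

    def test_peak_detection_grid(self):
        t = np.array([80, 85, 90, 95, 100.0])
        cv = np.array([1.0, 1.2, 3.0, 1.3, 1.1])
        assert detect_peak(t, cv) == 90.0


def _point_system(n, L):
    return MolecularSystem(classes=["C_co2"] * n,
                           positions=np.zeros((n, 3)),
                           bonds=np.zeros((0, 2), dtype=np.int64),
                           cell=[L, L, L])


class TestRDF:
    def test_ideal_gas_is_unity(self):
        rng = np.random.default_rng(5)
        n, L = 300, 18.0
        sys_ = _point_system(n, L)
        frames = [rng.uniform(0, L, size=(n, 3)) for _ in range(60)]
        res = rdf(frames, sys_, ("C_co2", "C_co2"), r_max=8.0, bin_width=0.25)
        sel = (res.r > 1.0)
        assert np.abs(res.g[sel] - 1.0).max() < 0.05

    def test_single_pair_all_mass_in_one_bin(self):
        sys_ = _point_system(2, 20.0)
        d = 3.14
        frames = [np.array([[1.0, 1.0, 1.0], [1.0 + d, 1.0, 1.0]])]
        res = rdf(frames, sys_, ("C_co2", "C_co2"), r_max=6.0, bin_width=0.1)
        assert res.g.sum() == res.g[np.argmin(np.abs(res.r - d))]
        assert res.g[np.argmin(np.abs(res.r - d))] > 0

    def test_empty_selection_raises(self):
        sys_ = _point_system(4, 10.0)
        with pytest.raises(ValueError, match="selection"):
            rdf([np.zeros((4, 3))], sys_, ("N_amine", "C_co2"))

    def test_intermolecular_only(self, ff):
        """Atoms of the same molecule never contribute."""
        m = build_monomer("CO2", ff=ff)
        m2 = build_monomer("CO2", ff=ff)
        m2.positions += np.array([5.0, 0, 0])
        s = merge_systems(m, m2)
        s.cell = np.array([20.0, 20.0, 20.0])
        res = rdf([s.positions], s, ("O_co2", "O_co2"), r_max=4.0,
                  bin_width=0.1)
        # intramolecular O...O at 2*r0 ~ 2.32 A must not appear
        assert res.g[np.argmin(np.abs(res.r - 2.32))] == 0.0

    def test_time_evolution_matches_windowed_rdf(self):
        rng = np.random.default_rng(6)
        n, L = 100, 12.0
        sys_ = _point_system(n, L)
        frames = [rng.uniform(0, L, size=(n, 3)) for _ in range(20)]
        traj = Trajectory(times=np.arange(20.0), potential=np.zeros(20),
                          kinetic=np.zeros(20), temperature=np.zeros(20),
                          pressure=np.zeros(20), volume=np.zeros(20),
                          positions=frames, velocities=[], cells=[None] * 20)
        sys_.cell = np.array([L, L, L])
        t_s, g_s = rdf_time_evolution(traj, sys_, ("C_co2", "C_co2"),
                                      r_probe=3.65, window_length=5.0)
        ref = rdf_from_trajectory(traj, sys_, ("C_co2", "C_co2"), 0.0, 5.0,
                                  r_max=3.65 + 0.5, bin_width=0.1)
        k = np.argmin(np.abs(ref.r - 3.65))
        assert g_s[0] == pytest.approx(ref.g[k])

    def test_static_configuration_constant_series(self):
        n, L = 50, 10.0
        rng = np.random.default_rng(7)
        pos = rng.uniform(0, L, size=(n, 3))
        sys_ = _point_system(n, L)
        sys_.cell = np.array([L, L, L])
        frames = [pos.copy() for _ in range(12)]
        traj = Trajectory(times=np.arange(12.0), potential=np.zeros(12),
                          kinetic=np.zeros(12), temperature=np.zeros(12),
                          pressure=np.zeros(12), volume=np.zeros(12),
                          positions=frames, velocities=[], cells=[None] * 12)
        _, g_s = rdf_time_evolution(traj, sys_, ("C_co2", "C_co2"),
                                    window_length=4.0)
        assert np.ptp(g_s) == 0.0


class TestIntraHB:
    def _traj_of(self, system, n_frames):
        frames = [system.positions.copy() for _ in range(n_frames)]
        z = np.zeros(n_frames)
        return Trajectory(times=np.arange(float(n_frames)), potential=z,
                          kinetic=z, temperature=z, pressure=z, volume=z,
                          positions=frames, velocities=[],
                          cells=[None] * n_frames)

    def test_totals_conserved(self, ff):
        m = build_monomer("MEA", "gauche_intraHB", ff=ff)
        traj = self._traj_of(m, 25)
        hb = intra_hb_histogram(traj, m, n_molecules=1, n_snapshots=20)
        assert hb.total == 1 * 20

    def test_trans_conformer_has_no_short_contacts(self, ff):
        m = build_monomer("MEA", "trans", ff=ff)
        hb = intra_hb_histogram(self._traj_of(m, 10), m, n_molecules=1,
                                n_snapshots=10)
        assert hb.n_below_cutoff == 0

    def test_gauche_conformer_counts_below_cutoff(self, ff):
        m = build_monomer("MEA", "gauche_intraHB", ff=ff)
        hb = intra_hb_histogram(self._traj_of(m, 10), m, n_molecules=1,
                                n_snapshots=10)
        assert hb.n_below_cutoff == 10

    def test_selection_bounds_checked(self, ff):
        m = build_monomer("MEA", "trans", ff=ff)
        with pytest.raises(ValueError, match="molecules"):
            intra_hb_histogram(self._traj_of(m, 10), m, n_molecules=3,
                               n_snapshots=5)
        with pytest.raises(ValueError, match="snapshots"):
            intra_hb_histogram(self._traj_of(m, 4), m, n_molecules=1,
                               n_snapshots=10)
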