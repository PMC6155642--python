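"""Molecular dynamics: velocity-Verlet integration with Berendsen
temperature coupling, Berendsen-style isotropic pressure coupling (NPH:
pressure coupling without a thermostat), periodic boxes and spherical
confinement.

Unit system: positions A, velocities A/ps, time ps, energies kcal/mol,
temperature K, pressure atm.  Temperatures use 3N-3 degrees of freedom
(net momentum is removed at initialization and conserved by the
integrator).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy.spatial import cKDTree

from .model import (ACCEL, CompiledFF, EnergyDecomposition,
                    ForceFieldParameters, KB, MolecularSystem, PRESS_ATM,
                    Wall, energy_forces)


class IntegrationError(RuntimeError):
    def __init__(self, msg, step=None):
        super().__init__(msg)
        self.step = step


@dataclass
class IntegratorSpec:
    dt: float = 0.0005            # ps (0.5 fs)
    n_steps: int = 1000
    stride: int = 10              # sampling stride
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("time step must be positive")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclass
class ThermostatSpec:
    temperature: float            # K
    tau: float = 0.1              # ps

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class BarostatSpec:
    pressure: float               # atm
    tau: float = 1.0              # ps
    compressibility: float = 4.6e-5   # atm^-1
    interval: int = 10            # apply coupling every this many steps


@dataclass
class Trajectory:
    times: np.ndarray                      # ps
    potential: np.ndarray                  # kcal/mol
    kinetic: np.ndarray                    # kcal/mol
    temperature: np.ndarray                # K
    pressure: np.ndarray                   # atm (nan when aperiodic)
    volume: np.ndarray                     # A^3 (nan when aperiodic)
    positions: List[np.ndarray] = field(default_factory=list)
    velocities: List[np.ndarray] = field(default_factory=list)
    cells: List[Optional[np.ndarray]] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.positions)


# ---------------------------------------------------------------------------
# Velocity initialization / thermodynamic state
# ---------------------------------------------------------------------------


def kinetic_energy(system: MolecularSystem) -> float:
    v = system.velocities
    return 0.5 * float(np.sum(system.masses[:, None] * v * v)) / ACCEL


def instantaneous_temperature(system: MolecularSystem) -> float:
    ndof = 3 * system.n_atoms - 3
    return 2.0 * kinetic_energy(system) / (ndof * KB)


def initialize_velocities(system: MolecularSystem, temperature: float,
                          seed: int = 0) -> MolecularSystem:
    """Maxwell-Boltzmann draw, net momentum removed, then rescaled so the
    instantaneous temperature equals the target exactly."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    rng = np.random.default_rng(seed)
    m = system.masses
    sigma = np.sqrt(KB * temperature * ACCEL / m)
    v = rng.normal(size=(system.n_atoms, 3)) * sigma[:, None]
    v -= np.sum(m[:, None] * v, axis=0) / m.sum()
    out = system.copy()
    out.velocities = v
    t_now = instantaneous_temperature(out)
    out.velocities = v * np.sqrt(temperature / t_now)
    return out


def berendsen_factor(t_inst: float, t0: float, dt: float, tau: float) -> float:
    """Weak-coupling velocity scaling factor lambda."""
    if t_inst <= 0:
        raise ValueError("instantaneous temperature must be positive")
    return float(np.sqrt(1.0 + (dt / tau) * (t0 / t_inst - 1.0)))


def pressure_virial(system: MolecularSystem, kinetic: float,
                    virial: float) -> float:
    """Instantaneous pressure (atm) from the atomic virial."""
    if system.cell is None:
        return float("nan")
    vol = float(np.prod(system.cell))
    return (2.0 * kinetic + virial) / (3.0 * vol) * PRESS_ATM


# ---------------------------------------------------------------------------
# Neighbor lists
# ---------------------------------------------------------------------------


class NeighborList:
    """Verlet pair lists (atom pairs and dipole pairs) with a skin,
    rebuilt every ``interval`` steps; exclusions applied at build time."""

    def __init__(self, system: MolecularSystem, comp: CompiledFF,
                 skin: float = 1.0, interval: int = 10):
        self.skin = skin
        self.interval = interval
        self.comp = comp
        n = system.n_atoms
        topo = system.topology
        # encoded (i*n+j, i<j) exclusion keys for fast vectorized filtering
        excl = []
        for i in range(n):
            for j in topo.within2[i]:
                if j > i:
                    excl.append(i * n + j)
        self._n = n
        self._excl_nb = np.array(sorted(excl), dtype=np.int64)
        nd = len(comp.dip_idx)
        allowed = {(int(p), int(q)) for p, q in comp.dd_pairs}
        dd_excl = [p * nd + q for p in range(nd) for q in range(p + 1, nd)
                   if (p, q) not in allowed]
        self._nd = nd
        self._excl_dd = np.array(sorted(dd_excl), dtype=np.int64)
        self.rebuild(system)

    @staticmethod
    def _pairs_within(points: np.ndarray, cutoff: float,
                      cell: Optional[np.ndarray]) -> np.ndarray:
        if cell is not None:
            wrapped = np.mod(points, cell)
            # cKDTree requires strictly < boxsize
            wrapped = np.where(wrapped >= cell, 0.0, wrapped)
            tree = cKDTree(wrapped, boxsize=cell)
        else:
            tree = cKDTree(points)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        return pairs.astype(np.int64)

    def rebuild(self, system: MolecularSystem):
        comp = self.comp
        pos = system.positions
        cell = system.cell
        cand = self._pairs_within(pos, comp.cut_vdw + self.skin, cell)
        if len(cand):
            lo = np.minimum(cand[:, 0], cand[:, 1])
            hi = np.maximum(cand[:, 0], cand[:, 1])
            enc = lo * self._n + hi
            keep = ~np.isin(enc, self._excl_nb, assume_unique=False)
            self.nb_pairs = np.column_stack([lo[keep], hi[keep]])
        else:
            self.nb_pairs = cand.reshape(0, 2)

        dip = comp.dip_idx
        if len(dip):
            mids = 0.5 * (pos[dip[:, 0]] + pos[dip[:, 1]])
            dcand = self._pairs_within(mids, comp.cut_dip + self.skin, cell)
            if len(dcand):
                lo = np.minimum(dcand[:, 0], dcand[:, 1])
                hi = np.maximum(dcand[:, 0], dcand[:, 1])
                enc = lo * self._nd + hi
                keep = ~np.isin(enc, self._excl_dd)
                self.dd_pairs = np.column_stack([lo[keep], hi[keep]])
            else:
                self.dd_pairs = dcand.reshape(0, 2)
        else:
            self.dd_pairs = np.zeros((0, 2), dtype=np.int64)


# ---------------------------------------------------------------------------
# MD stepping
# ---------------------------------------------------------------------------


class MDEngine:
    """Velocity-Verlet propagator with optional thermostat/barostat/wall."""

    def __init__(self, system: MolecularSystem, ff: ForceFieldParameters,
                 integrator: IntegratorSpec,
                 thermostat: Optional[ThermostatSpec] = None,
                 barostat: Optional[BarostatSpec] = None,
                 use_neighbor_list: Optional[bool] = None):
        self.system = system.copy()
        if self.system.velocities is None:
            self.system.velocities = np.zeros_like(self.system.positions)
        self.ff = ff
        self.spec = integrator
        self.thermostat = thermostat
        self.barostat = barostat
        if barostat is not None and system.cell is None:
            raise ValueError("pressure coupling requires a periodic cell")
        self.comp = CompiledFF(self.system, ff)
        if use_neighbor_list is None:
            use_neighbor_list = self.system.n_atoms > 600
        self.nlist = (NeighborList(self.system, self.comp)
                      if use_neighbor_list else None)
        self.step_count = 0
        self._eval()

    def _pairs(self):
        if self.nlist is None:
            return None, None
        return self.nlist.nb_pairs, self.nlist.dd_pairs

    def _eval(self):
        nb, dd = self._pairs()
        dec, f, W = energy_forces(self.system, self.ff, self.comp,
                                  nb_pairs=nb, dd_pairs=dd)
        self.energy = dec
        self.forces = f
        self.virial = W
        return dec, f, W

    def step(self, n: int = 1):
        s = self.system
        dt = self.spec.dt
        m = s.masses[:, None]
        for _ in range(n):
            f = self.forces
            v_half = s.velocities + 0.5 * dt * ACCEL * f / m
            s.positions = s.positions + dt * v_half
            self.step_count += 1
            if self.nlist is not None and \
               self.step_count % self.nlist.interval == 0:
                self.nlist.rebuild(s)
            dec, f_new, W = self._eval()
            s.velocities = v_half + 0.5 * dt * ACCEL * f_new / m
            if not np.isfinite(s.positions).all():
                raise IntegrationError("non-finite coordinates",
                                       step=self.step_count)
            if self.thermostat is not None:
                t_inst = instantaneous_temperature(s)
                lam = berendsen_factor(t_inst, self.thermostat.temperature,
                                       dt, self.thermostat.tau)
                s.velocities = s.velocities * lam
            if self.barostat is not None and \
               self.step_count % self.barostat.interval == 0:
                ke = kinetic_energy(s)
                p_inst = pressure_virial(s, ke, self.virial)
                b = self.barostat
                dt_eff = dt * b.interval
                eta = (1.0 - (dt_eff / b.tau) * b.compressibility
                       * (b.pressure - p_inst)) ** (1.0 / 3.0)
                s.positions = s.positions * eta
                s.cell = s.cell * eta
                # re-cap the effective cutoffs for the new cell
                half = float(s.cell.min()) / 2.0
                self.comp.cut_vdw = min(self.ff.cut_vdw, half)
                self.comp.cut_dip = min(self.ff.cut_dipole, half)
                if self.nlist is not None:
                    self.nlist.rebuild(s)
                self._eval()
        return self.system


def md_step(system: MolecularSystem, ff: ForceFieldParameters,
            integrator: IntegratorSpec,
            thermostat: Optional[ThermostatSpec] = None,
            barostat: Optional[BarostatSpec] = None) -> MolecularSystem:
    """Single velocity-Verlet step (convenience wrapper over MDEngine)."""
    eng = MDEngine(system, ff, integrator, thermostat, barostat)
    eng.step(1)
    return eng.system


def run_md(system: MolecularSystem, ff: ForceFieldParameters,
           integrator: IntegratorSpec,
           thermostat: Optional[ThermostatSpec] = None,
           barostat: Optional[BarostatSpec] = None,
           equilibration_steps: int = 0,
           store_frames: bool = True,
           initialize: Optional[float] = None) -> Trajectory:
    """Equilibrate then sample; frames logged every ``integrator.stride``.

    ``initialize``: draw velocities at this temperature (K) with the
    integrator's seed before the run; otherwise existing velocities are
    used.  The first logged frame is the state right after equilibration.
    """
    work = system
    if initialize is not None:
        work = initialize_velocities(system, initialize, integrator.seed)

    # fused fast path: fixed topology, no barostat, all-pairs evaluation
    if (barostat is None and work.wall is None and work.n_atoms <= 700):
        return _run_md_fused(work, ff, integrator, thermostat,
                             equilibration_steps, store_frames)

    eng = MDEngine(work, ff, integrator, thermostat, barostat)
    if equilibration_steps:
        eng.step(equilibration_steps)
    return _sample_loop(eng, integrator, store_frames)


def _sample_loop(eng: MDEngine, spec: IntegratorSpec, store_frames: bool):
    times, U, K, T, P, V = [], [], [], [], [], []
    frames_p, frames_v, frames_c = [], [], []

    def log(t):
        s = eng.system
        ke = kinetic_energy(s)
        times.append(t)
        U.append(eng.energy.total)
        K.append(ke)
        T.append(instantaneous_temperature(s))
        P.append(pressure_virial(s, ke, eng.virial))
        V.append(float(np.prod(s.cell)) if s.cell is not None else float("nan"))
        if store_frames:
            frames_p.append(s.positions.copy())
            frames_v.append(s.velocities.copy())
            frames_c.append(None if s.cell is None else s.cell.copy())

    log(0.0)
    n_blocks = spec.n_steps // spec.stride
    for b in range(n_blocks):
        eng.step(spec.stride)
        log((b + 1) * spec.stride * spec.dt)
    rem = spec.n_steps - n_blocks * spec.stride
    if rem:
        eng.step(rem)
        log(spec.n_steps * spec.dt)
    return Trajectory(np.array(times), np.array(U), np.array(K),
                      np.array(T), np.array(P), np.array(V),
                      frames_p, frames_v, frames_c)


# ---------------------------------------------------------------------------
# Fused (numba) constant-volume path for small systems
# ---------------------------------------------------------------------------


def _run_md_fused(system, ff, integrator, thermostat,
                  equilibration_steps, store_frames):
    from ._kernels import k_md_nvt

    s = system.copy()
    if s.velocities is None:
        s.velocities = np.zeros_like(s.positions)
    comp = CompiledFF(s, ff)
    cell = s.cell if s.cell is not None else np.ones(3)
    periodic = s.cell is not None
    if s.wall is not None:
        wall_c = np.asarray(s.wall.center, dtype=float)
        wall_r = float(s.wall.radius)
        wall_k = float(s.wall.stiffness)
    else:
        wall_c = np.zeros(3)
        wall_r = -1.0
        wall_k = 0.0
    t0 = thermostat.temperature if thermostat is not None else -1.0
    tau = thermostat.tau if thermostat is not None else 1.0

    def run(n_steps, stride):
        return k_md_nvt(
            s.positions, s.velocities, s.masses, integrator.dt,
            n_steps, stride,
            comp.bond_idx, comp.bond_ks, comp.bond_r0,
            comp.ang_idx, comp.ang_kb, comp.ang_t0,
            comp.tor_idx, comp.tor_v,
            comp.nb_pairs, comp.rv, comp.eps,
            comp.dip_idx, comp.dip_mu, comp.dd_pairs,
            cell, periodic, comp.kdd,
            comp.cut_vdw, comp.cut_dip, comp.taper,
            wall_c, wall_r, wall_k, t0, tau)

    if equilibration_steps:
        pos, vel, *_ = run(equilibration_steps, max(equilibration_steps, 1))
        s.positions = pos
        s.velocities = vel

    stride = integrator.stride
    pos, vel, U, Ksamp, fr_p, fr_v = run(integrator.n_steps, stride)
    s.positions = pos
    s.velocities = vel
    n_log = U.shape[0]
    times = np.arange(n_log) * stride * integrator.dt
    ndof = 3 * s.n_atoms - 3
    T = 2.0 * Ksamp / (ndof * KB)
    P = np.full(n_log, np.nan)
    V = np.full(n_log, float(np.prod(s.cell)) if periodic else np.nan)
    frames_p = [fr_p[i].copy() for i in range(n_log)] if store_frames else []
    frames_v = [fr_v[i].copy() for i in range(n_log)] if store_frames else []
    frames_c = [s.cell.copy() if periodic else None
                for _ in range(n_log)] if store_frames else []
    return Trajectory(times, U, Ksamp, T, P, V, frames_p, frames_v, frames_c)
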