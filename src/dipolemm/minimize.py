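"""Constrained geometry optimization, normal modes, and the CO2-MEA scan.

Constraints (frozen distances / angles / dihedrals) are enforced through
stiff harmonic restraints whose stiffness is escalated over a documented
schedule (1e3 -> 1e6 kcal/mol per unit^2); restraint energy is excluded
from every reported energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize as _sp_minimize

from .model import (CompiledFF, EnergyDecomposition, ForceFieldParameters,
                    FREQ_CM, MolecularSystem, energy_forces)


class MinimizationError(RuntimeError):
    def __init__(self, msg, best=None):
        super().__init__(msg)
        self.best = best


@dataclass
class ConstraintSpec:
    """A frozen internal coordinate.

    kind: 'frozen_distance' (target in A), 'frozen_angle' (target in deg)
    or 'frozen_dihedral' (target in deg).
    """
    kind: str
    atoms: Tuple[int, ...]
    target: float

    def __post_init__(self):
        n_expected = {"frozen_distance": 2, "frozen_angle": 3,
                      "frozen_dihedral": 4}
        if self.kind not in n_expected:
            raise ValueError(f"unknown constraint kind {self.kind!r}")
        if len(self.atoms) != n_expected[self.kind]:
            raise ValueError("wrong number of atoms for constraint")
        if len(set(self.atoms)) != len(self.atoms):
            raise ValueError("constraint atom indices must be distinct")


def _constraint_value_grad(pos: np.ndarray, c: ConstraintSpec):
    """Current value (A or deg) and gradient of the constrained coordinate."""
    a = c.atoms
    if c.kind == "frozen_distance":
        d = pos[a[1]] - pos[a[0]]
        r = np.linalg.norm(d)
        g = np.zeros_like(pos)
        g[a[1]] = d / r
        g[a[0]] = -d / r
        return r, g
    if c.kind == "frozen_angle":
        i, j, k = a
        u = pos[i] - pos[j]
        v = pos[k] - pos[j]
        lu, lv = np.linalg.norm(u), np.linalg.norm(v)
        uh, vh = u / lu, v / lv
        cth = float(np.clip(uh @ vh, -1.0, 1.0))
        th = np.arccos(cth)
        sin = max(np.sqrt(1.0 - cth * cth), 1e-8)
        dthdc = -1.0 / sin
        gi = dthdc * (vh - cth * uh) / lu
        gk = dthdc * (uh - cth * vh) / lv
        g = np.zeros_like(pos)
        g[i] = gi
        g[k] = gk
        g[j] = -(gi + gk)
        return np.degrees(th), g * (180.0 / np.pi)
    # frozen_dihedral
    i, j, k, l = a
    b1 = pos[j] - pos[i]
    b2 = pos[k] - pos[j]
    b3 = pos[l] - pos[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    lb2 = np.linalg.norm(b2)
    m1 = np.cross(n1, b2 / lb2)
    phi = np.arctan2(m1 @ n2, n1 @ n2)
    n1sq = n1 @ n1
    n2sq = n2 @ n2
    dpdi = (lb2 / n1sq) * n1
    dpdl = -(lb2 / n2sq) * n2
    t12 = (b1 @ b2) / lb2 ** 2
    t32 = (b3 @ b2) / lb2 ** 2
    dpdj = (-1.0 - t12) * dpdi + t32 * dpdl
    dpdk = t12 * dpdi + (-1.0 - t32) * dpdl
    g = np.zeros_like(pos)
    g[i], g[j], g[k], g[l] = dpdi, dpdj, dpdk, dpdl
    return np.degrees(phi), g * (180.0 / np.pi)


def _restraint_energy_grad(pos, constraints, k):
    e = 0.0
    g = np.zeros_like(pos)
    for c in constraints:
        val, gv = _constraint_value_grad(pos, c)
        dev = val - c.target
        if c.kind == "frozen_dihedral":
            dev = (dev + 180.0) % 360.0 - 180.0
        if c.kind in ("frozen_angle", "frozen_dihedral"):
            # work in radians so stiffness units match rad^-2
            dev_r = np.radians(dev)
            e += k * dev_r * dev_r
            g += 2.0 * k * dev_r * gv * (np.pi / 180.0)
        else:
            e += k * dev * dev
            g += 2.0 * k * dev * gv
    return e, g


def constraint_errors(pos, constraints) -> List[float]:
    errs = []
    for c in constraints:
        val, _ = _constraint_value_grad(pos, c)
        dev = val - c.target
        if c.kind == "frozen_dihedral":
            dev = (dev + 180.0) % 360.0 - 180.0
        errs.append(float(dev))
    return errs


@dataclass
class MinimizeResult:
    system: MolecularSystem
    energy: EnergyDecomposition
    grad_rms: float
    converged: bool
    n_iter: int
    constraint_errors: List[float] = field(default_factory=list)


_STIFFNESS_SCHEDULE = (1e3, 1e4, 1e5, 1e6)


def minimize(system: MolecularSystem, ff: ForceFieldParameters,
             constraints: Sequence[ConstraintSpec] = (),
             tol: float = 1e-4, max_iter: int = 5000,
             comp: Optional[CompiledFF] = None) -> MinimizeResult:
    """Quasi-Newton (L-BFGS) energy minimization with harmonic restraints.

    Converges until the RMS gradient falls below ``tol`` (kcal/mol/A) and
    every constraint is satisfied to 1e-4 (A or deg).  Reported energies
    exclude the restraint contribution.
    """
    if comp is None:
        comp = CompiledFF(system, ff)
    work = system.copy()
    n = work.n_atoms
    schedule = _STIFFNESS_SCHEDULE if constraints else (0.0,)
    x = work.positions.ravel().copy()
    total_iter = 0

    def make_obj(k):
        def obj(xf):
            work.positions = xf.reshape(n, 3)
            dec, f, _ = energy_forces(work, ff, comp)
            g = -f
            e = dec.total
            if constraints and k > 0:
                er, gr = _restraint_energy_grad(work.positions, constraints, k)
                e += er
                g = g + gr
            return e, g.ravel()
        return obj

    res = None
    for k in schedule:
        res = _sp_minimize(make_obj(k), x, jac=True, method="L-BFGS-B",
                           options={"maxiter": max_iter, "ftol": 1e-14,
                                    "gtol": tol * np.sqrt(3 * n) * 0.1,
                                    "maxcor": 30})
        x = res.x
        total_iter += res.nit
        if constraints:
            errs = constraint_errors(x.reshape(n, 3), constraints)
            if max(abs(e) for e in errs) < 1e-4:
                break

    work.positions = x.reshape(n, 3)
    dec, f, _ = energy_forces(work, ff, comp)
    grad = -f
    if constraints:
        _, gr = _restraint_energy_grad(work.positions, constraints, schedule[-1])
        grad_obj = grad + gr
    else:
        grad_obj = grad
    grad_rms = float(np.sqrt(np.mean(grad_obj ** 2)))
    errs = constraint_errors(work.positions, constraints) if constraints else []
    converged = grad_rms < max(tol, 1e-12) * 10 or bool(res.success)
    if constraints and errs and max(abs(e) for e in errs) > 1e-3:
        raise MinimizationError(
            f"constraints not satisfied: deviations {errs}",
            best=MinimizeResult(work, dec, grad_rms, False, total_iter, errs))
    return MinimizeResult(work, dec, grad_rms, converged, total_iter, errs)


# ---------------------------------------------------------------------------
# Normal modes
# ---------------------------------------------------------------------------


def normal_modes(system: MolecularSystem, ff: ForceFieldParameters,
                 step: float = 1e-3, grad_tol: float = 1e-3):
    """Harmonic frequencies (cm^-1) and mass-weighted mode vectors.

    The Hessian is built by central finite differences of the analytic
    forces.  Negative eigenvalues are reported as negative (imaginary)
    frequencies.  Refuses when the geometry is not a stationary point.
    """
    comp = CompiledFF(system, ff)
    _, f0, _ = energy_forces(system, ff, comp)
    grms = float(np.sqrt(np.mean(f0 ** 2)))
    if grms > grad_tol:
        raise ValueError(
            f"normal modes require a stationary point (RMS gradient {grms:.2e} "
            f"exceeds {grad_tol:.1e}); minimize first")
    n = system.n_atoms
    work = system.copy()
    H = np.zeros((3 * n, 3 * n))
    for a in range(3 * n):
        i, d = divmod(a, 3)
        work.positions = system.positions.copy()
        work.positions[i, d] += step
        _, fp, _ = energy_forces(work, ff, comp)
        work.positions[i, d] -= 2 * step
        _, fm, _ = energy_forces(work, ff, comp)
        H[a] = (-(fp - fm) / (2 * step)).ravel()
    H = 0.5 * (H + H.T)
    m = np.repeat(system.masses, 3)
    Hw = H / np.sqrt(np.outer(m, m))
    evals, vecs = np.linalg.eigh(Hw)
    freqs = np.sign(evals) * FREQ_CM * np.sqrt(np.abs(evals))
    return freqs, vecs


def vibrational_frequencies(system, ff, rigid_body_cut: float = 15.0):
    """Frequencies with rigid-body modes (|nu| < cut cm^-1) removed."""
    freqs, _ = normal_modes(system, ff)
    return freqs[np.abs(freqs) >= rigid_body_cut]


# ---------------------------------------------------------------------------
# Distance scan
# ---------------------------------------------------------------------------


@dataclass
class ScanPoint:
    value: float
    energy: float
    converged: bool
    positions: np.ndarray


@dataclass
class ScanResult:
    points: List[ScanPoint]
    minimum_value: float
    relative_energies: np.ndarray


def scan_distance(system: MolecularSystem, ff: ForceFieldParameters,
                  atom_i: int, atom_j: int, grid: Sequence[float],
                  extra_constraints: Sequence[ConstraintSpec] = (),
                  tol: float = 1e-4) -> ScanResult:
    """Relaxed scan of the i-j distance over a monotone grid.

    At each grid point the distance is frozen and everything else relaxed,
    starting from the previous point's relaxed geometry (continuation).
    Failed points are flagged and the scan continues.
    """
    grid = list(grid)
    if not all(b > a for a, b in zip(grid, grid[1:])) and \
       not all(b < a for a, b in zip(grid, grid[1:])):
        raise ValueError("scan grid must be strictly monotone")
    work = system.copy()
    points: List[ScanPoint] = []
    for r in grid:
        cons = [ConstraintSpec("frozen_distance", (atom_i, atom_j), float(r))]
        cons += list(extra_constraints)
        try:
            res = minimize(work, ff, constraints=cons, tol=tol)
            points.append(ScanPoint(float(r), res.energy.total, True,
                                    res.system.positions.copy()))
            work = res.system
        except MinimizationError as err:
            best = err.best
            points.append(ScanPoint(float(r),
                                    best.energy.total if best else np.nan,
                                    False,
                                    best.system.positions.copy()
                                    if best else work.positions.copy()))
    energies = np.array([p.energy for p in points])
    ok = np.isfinite(energies)
    i_min = int(np.nanargmin(np.where(ok, energies, np.inf)))
    rel = energies - energies[i_min]
    return ScanResult(points, grid[i_min], rel)


def scan_rCN(system: MolecularSystem, ff: ForceFieldParameters,
             grid: Sequence[float], tol: float = 1e-4) -> ScanResult:
    """Relaxed CO2-MEA scan along the carbon(CO2)-nitrogen(MEA) distance."""
    if not all(1.5 < g < 6.0 for g in grid):
        raise ValueError("scan grid must lie within (1.5, 6.0) A")
    cls = system.classes
    try:
        i_c = next(i for i, c in enumerate(cls) if c == "C_co2")
        i_n = next(i for i, c in enumerate(cls) if c == "N_amine")
    except StopIteration:
        raise ValueError("system must contain a CO2 carbon and an MEA nitrogen")
    return scan_distance(system, ff, i_c, i_n, grid, tol=tol)
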