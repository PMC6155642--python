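"""Calibration of the nonbonded parameters against reference energetics.

The engine's free parameters (Lennard-Jones radii/epsilons and bond-dipole
magnitudes) are fitted so that dimer interaction energies, their
electrostatic/vdW decomposition, the CO2 monomer frequencies, and the
CO2-MEA physisorption geometry reproduce a shipped reference set of
benchmark values.

The fit runs in three deterministic stages:

1. closed-form inversion of the CO2 harmonic normal-mode problem
   (stretch constant from the symmetric stretch, bend constant from the
   bend; the antisymmetric stretch is then a parameter-free prediction),
2. bounded least squares of the CO2 nonbonded parameters against the
   three CO2 dimer arrangements,
3. bounded least squares of the MEA nonbonded parameters against the
   hydrogen-bonded MEA dimers and the CO2-MEA binding motifs.

Stages 2-3 use a fixed three-entry multi-start list, so the whole
calibration is reproducible without a random seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .builders import build_dimer, build_monomer
from .minimize import ConstraintSpec, minimize, vibrational_frequencies
from .model import (CLASS_MASS, FREQ_CM, ForceFieldParameters,
                    default_parameters)

# ---------------------------------------------------------------------------
# Reference observables
# ---------------------------------------------------------------------------

OBSERVABLE_KINDS = ("dimer_total", "dimer_component_mumu", "dimer_component_lj",
                    "frequency", "scan_minimum_distance", "context_qm")


@dataclass
class ReferenceObservable:
    kind: str
    recipe: str           # builder recipe ('co2_min', 'mea_OHO', ...)
    target: float
    units: str
    weight: float
    provenance: str

    def __post_init__(self):
        if self.kind not in OBSERVABLE_KINDS:
            raise ValueError(f"unknown observable kind {self.kind!r}")


@dataclass
class ReferenceSet:
    observables: List[ReferenceObservable]

    def __post_init__(self):
        if not self.observables:
            raise ValueError("reference set must be non-empty")
        for o in self.observables:
            if not o.provenance:
                raise ValueError("every reference entry needs a provenance note")

    def select(self, *kinds) -> List[ReferenceObservable]:
        return [o for o in self.observables if o.kind in kinds]


def build_reference_set() -> ReferenceSet:
    """The shipped transcription of the benchmark energetics.

    CO2 dimer interaction energies and their dipole-dipole / LJ components
    for the minimum, parallel (C-C frozen at 4 A) and T-type arrangements;
    CO2 monomer frequencies; MEA dimer (NHN / OHO) totals and components;
    CO2 binding at the amino and hydroxyl motifs of MEA; and the
    physisorption C(CO2)-N(MEA) distance.  The quantum-chemistry binding
    energies are retained as zero-weight context entries.
    """
    path = resources.files("dipolemm.data") / "reference_set.tsv"
    return read_reference_set(path)


def read_reference_set(path) -> ReferenceSet:
    obs = []
    with open(path) as fh:
        header = None
        for raw in fh:
            ln = raw.rstrip("\n")
            if not ln.strip() or ln.lstrip().startswith("#"):
                continue
            parts = ln.split("\t")
            if header is None:
                header = parts
                continue
            rec = dict(zip(header, parts))
            obs.append(ReferenceObservable(
                kind=rec["kind"], recipe=rec["recipe"],
                target=float(rec["target"]), units=rec["units"],
                weight=float(rec["weight"]), provenance=rec["provenance"]))
    return ReferenceSet(obs)


def write_reference_set(path, ref: ReferenceSet):
    with open(path, "w") as fh:
        fh.write("kind\trecipe\ttarget\tunits\tweight\tprovenance\n")
        for o in ref.observables:
            fh.write(f"{o.kind}\t{o.recipe}\t{o.target:g}\t{o.units}\t"
                     f"{o.weight:g}\t{o.provenance}\n")


# ---------------------------------------------------------------------------
# Stage 1: CO2 intramolecular constants (closed form)
# ---------------------------------------------------------------------------


def co2_intramolecular_fit(ff: ForceFieldParameters, nu_bend: float,
                           nu_sym: float) -> Tuple[float, float]:
    """Closed-form harmonic constants for a linear symmetric triatomic.

    With stretch energy ks (r - r0)^2 per bond and bend energy
    kb (theta - pi)^2, the normal modes of O=C=O are

        lambda_sym  = 2 ks / mO
        lambda_as   = 2 ks (1/mO + 2/mC)       (prediction, not fitted)
        lambda_bend = 4 kb (1 + 2 mO/mC) / (mO r0^2)   (doubly degenerate)

    so ks follows from the symmetric stretch and kb from the bend.
    Updates *ff* in place and returns (ks, kb).
    """
    if nu_bend <= 0 or nu_sym <= 0:
        raise ValueError("target frequencies must be positive")
    mO = CLASS_MASS["O_co2"]
    mC = CLASS_MASS["C_co2"]
    lam_sym = (nu_sym / FREQ_CM) ** 2
    ks = 0.5 * lam_sym * mO
    r0 = ff.bond_params("C_co2", "O_co2").r0
    lam_bend = (nu_bend / FREQ_CM) ** 2
    kb = lam_bend * mO * r0 ** 2 / (4.0 * (1.0 + 2.0 * mO / mC))
    if ks <= 0 or kb <= 0:
        raise ValueError("non-physical force constants")
    ff.bond_params("C_co2", "O_co2").ks = ks
    ff.angle_params("O_co2", "C_co2", "O_co2").kb = kb
    return ks, kb


def co2_asym_prediction(nu_sym: float) -> float:
    """Antisymmetric stretch implied by the harmonic mass relation."""
    mO = CLASS_MASS["O_co2"]
    mC = CLASS_MASS["C_co2"]
    return nu_sym * np.sqrt(1.0 + 2.0 * mO / mC)


# ---------------------------------------------------------------------------
# Observable evaluation
# ---------------------------------------------------------------------------

_DIMER_RECIPES = {
    "co2_min": (("CO2", "CO2"), "min"),
    "co2_parallel": (("CO2", "CO2"), "parallel"),
    "co2_T": (("CO2", "CO2"), "T-type"),
    "mea_NHN": (("MEA", "MEA"), "NHN"),
    "mea_OHO": (("MEA", "MEA"), "OHO"),
    "co2_mea_amino": (("CO2", "MEA"), "amino"),
    "co2_mea_hydroxyl": (("CO2", "MEA"), "hydroxyl"),
    # the absorption-pathway scan: amino approach with the extended conformer
    "co2_mea_scan": (("CO2", "MEA"), "amino"),
}


class MinimizationFailed(RuntimeError):
    pass


def _tilt_co2(system, tilt_deg, azim_deg):
    """Rotate the CO2 fragment's position about the MEA motif centre."""
    s = system.copy()
    cls = s.classes
    co2 = [i for i, c in enumerate(cls) if c in ("C_co2", "O_co2")]
    i_c = cls.index("C_co2")
    mea = [i for i in range(s.n_atoms) if i not in co2]
    center = s.positions[mea].mean(axis=0)
    v = s.positions[i_c] - center
    # build an orthonormal frame around the approach vector
    e1 = v / np.linalg.norm(v)
    t = np.array([1.0, 0.0, 0.0])
    if abs(e1 @ t) > 0.9:
        t = np.array([0.0, 1.0, 0.0])
    e2 = t - (t @ e1) * e1
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    th = np.radians(tilt_deg)
    ph = np.radians(azim_deg)
    new_dir = (np.cos(th) * e1
               + np.sin(th) * (np.cos(ph) * e2 + np.sin(ph) * e3))
    shift = center + np.linalg.norm(v) * new_dir - s.positions[i_c]
    s.positions[co2] += shift
    return s


class Evaluator:
    """Computes reference observables for a given parameter set, caching
    the monomer and dimer optimizations within one parameter evaluation."""

    def __init__(self, ff: ForceFieldParameters, tol: float = 2e-5):
        self.ff = ff
        self.tol = tol
        self._mono: Dict[str, object] = {}
        self._dimer: Dict[str, Dict[str, float]] = {}

    def monomer(self, species: str, conformer=None):
        key = f"{species}:{conformer}"
        if key not in self._mono:
            sys_ = build_monomer(species, conformer, ff=self.ff)
            self._mono[key] = minimize(sys_, self.ff, tol=self.tol)
        return self._mono[key]

    def dimer(self, recipe: str) -> Dict[str, float]:
        if recipe in self._dimer:
            return self._dimer[recipe]
        if recipe.startswith("co2_mea"):
            out = self._motif(recipe)
        else:
            species, arrangement = _DIMER_RECIPES[recipe]
            sys_, cons = build_dimer(species, arrangement, ff=self.ff)
            res = minimize(sys_, self.ff, constraints=cons, tol=self.tol)
            dec = res.energy
            monos = [self.monomer(sp, "trans" if sp == "MEA" else None)
                     for sp in species]
            out = {
                "total": dec.total - sum(m.energy.total for m in monos),
                "mumu": dec.dipole - sum(m.energy.dipole for m in monos),
                "lj": dec.lj - sum(m.energy.lj for m in monos),
            }
        self._dimer[recipe] = out
        return out

    #: fixed multi-start list for the motif minimizations: (approach
    #: distance, polar/azimuthal perturbation of the approach direction)
    MOTIF_STARTS = ((2.6, 0.0, 0.0), (3.0, 0.0, 0.0), (3.4, 0.0, 0.0),
                    (3.2, 70.0, 0.0), (3.2, 70.0, 120.0), (3.2, 70.0, 240.0))
    #: grid of the absorption-pathway (extended-conformer) scan, ascending
    #: with continuation exactly like the reported scan protocol
    SCAN_GRID = (2.3, 2.45, 2.6, 2.7, 2.8, 2.95, 3.1, 3.3, 3.5)

    def _motif(self, recipe: str) -> Dict[str, float]:
        if recipe == "co2_mea_scan":
            return self._pathway_scan()
        return self._motif_minimum(recipe)

    def _motif_minimum(self, recipe: str) -> Dict[str, float]:
        """Binding-motif observables: the lowest unconstrained local
        minimum reached from a fixed list of approach starts (distances
        and tilted directions), so secondary contacts of the folded
        conformer are found reproducibly."""
        _, arrangement = _DIMER_RECIPES[recipe]
        conformer = "gauche_intraHB"
        mono = self.monomer("MEA", conformer)
        e_ref = self.monomer("CO2").energy.total + mono.energy.total
        probe = "N_amine" if arrangement == "amino" else "O_hydroxyl"

        best = None
        for d, tilt, azim in self.MOTIF_STARTS:
            start, _ = build_dimer(("CO2", "MEA"), arrangement, ff=self.ff,
                                   approach=d, conformer=conformer)
            if tilt:
                start = _tilt_co2(start, tilt, azim)
            try:
                res = minimize(start, self.ff, tol=self.tol)
            except Exception:
                continue
            if best is None or res.energy.total < best.energy.total:
                best = res
        if best is None:
            raise MinimizationFailed(f"no motif minimum found for {recipe}")
        cls = best.system.classes
        p = best.system.positions
        i_c = cls.index("C_co2")
        i_x = cls.index(probe)
        return {
            "total": best.energy.total - e_ref,
            "mumu": best.energy.dipole - mono.energy.dipole,
            "lj": best.energy.lj - mono.energy.lj,
            "distance": float(np.linalg.norm(p[i_c] - p[i_x])),
        }

    def _pathway_scan(self) -> Dict[str, float]:
        """Absorption-pathway observables: a constrained scan of the
        C(CO2)-N(MEA) distance with the extended conformer, continued
        outward from close approach (the same protocol as the reported
        scan); the minimum location comes from a parabola through the
        grid points around the argmin."""
        conformer = "trans"
        mono = self.monomer("MEA", conformer)
        e_ref = self.monomer("CO2").energy.total + mono.energy.total
        grid = self.SCAN_GRID

        prev, _ = build_dimer(("CO2", "MEA"), "amino", ff=self.ff,
                              conformer=conformer)
        energies, decs = [], []
        for r in grid:
            cls = prev.classes
            i_c = cls.index("C_co2")
            i_x = cls.index("N_amine")
            cons = [ConstraintSpec("frozen_distance", (i_c, i_x), float(r))]
            try:
                res = minimize(prev, self.ff, constraints=cons, tol=self.tol)
            except Exception:
                energies.append(np.nan)
                decs.append(None)
                continue
            prev = res.system
            energies.append(res.energy.total)
            decs.append(res.energy)
        e = np.asarray(energies)
        k = int(np.nanargmin(e))
        k = min(max(k, 1), len(e) - 2)
        x = np.asarray(grid[k - 1:k + 2])
        y = e[k - 1:k + 2]
        if np.any(~np.isfinite(y)):
            r_star, e_star = grid[k], e[k]
        else:
            a, b, c = np.polyfit(x, y, 2)
            if a > 1e-9:
                r_star = float(np.clip(-b / (2 * a), x.min(), x.max()))
                e_star = float(np.polyval([a, b, c], r_star))
            else:
                r_star, e_star = grid[k], e[k]
        dec = decs[int(np.nanargmin(e))]
        return {
            "total": e_star - e_ref,
            "mumu": dec.dipole - mono.energy.dipole,
            "lj": dec.lj - mono.energy.lj,
            "distance": r_star,
        }

    def frequencies(self) -> Dict[str, float]:
        res = self.monomer("CO2")
        freqs = vibrational_frequencies(res.system, self.ff)
        freqs = np.sort(freqs)
        # linear triatomic: bend (x2), symmetric stretch, antisymmetric
        return {"bend": float(freqs[0]), "sym": float(freqs[2]),
                "asym": float(freqs[3])}

    def observable(self, o: ReferenceObservable) -> float:
        if o.kind == "frequency":
            return self.frequencies()[o.recipe.split(":")[1]]
        if o.kind == "scan_minimum_distance":
            return self.dimer(o.recipe)["distance"]
        comp = {"dimer_total": "total", "dimer_component_mumu": "mumu",
                "dimer_component_lj": "lj"}[o.kind]
        return self.dimer(o.recipe)[comp]


# ---------------------------------------------------------------------------
# Stages 2-3: nonbonded least squares
# ---------------------------------------------------------------------------


@dataclass
class FitSettings:
    max_nfev: int = 40              # per stage and start
    diff_step: float = 0.05
    xtol: Optional[float] = None    # disabled: run to ftol or the budget
    ftol: float = 1e-9
    tol_min: float = 2e-5           # inner minimizer tolerance
    #: number of entries of the fixed multi-start list to use (max 3)
    n_starts: int = 3
    stages: Tuple[str, ...] = ("co2", "mea")


@dataclass
class FitResult:
    ff: ForceFieldParameters
    residuals: List[float]
    objective: float
    converged: bool
    n_evaluations: int
    trace: List[dict] = field(default_factory=list)


_CO2_PARAMS = [("lj", "C_co2", "rv"), ("lj", "O_co2", "rv"),
               ("lj", "C_co2", "eps"), ("lj", "O_co2", "eps"),
               ("bond", ("C_co2", "O_co2"), "mu")]
_CO2_BOUNDS = ([1.3, 1.3, 0.005, 0.005, 0.5], [2.6, 2.4, 0.5, 0.5, 4.0])
_CO2_DIPOLE_IDX = [4]

_MEA_PARAMS = [("bond", ("O_hydroxyl", "H_O"), "mu"),
               ("bond", ("N_amine", "H_N"), "mu"),
               ("bond", ("C_sp3", "O_hydroxyl"), "mu"),
               ("bond", ("C_sp3", "N_amine"), "mu"),
               ("lj", "N_amine", "rv"), ("lj", "N_amine", "eps"),
               ("lj", "O_hydroxyl", "rv"), ("lj", "O_hydroxyl", "eps"),
               ("lj", "H_N", "eps"), ("lj", "H_O", "eps")]
_MEA_BOUNDS = ([0.3, 0.3, -3.0, -3.0, 1.2, 0.005, 1.2, 0.005, 0.003, 0.003],
               [4.0, 4.0, 3.0, 3.0, 2.4, 0.5, 2.4, 0.5, 0.25, 0.25])
_MEA_DIPOLE_IDX = [0, 1, 2, 3]
_MEA_XSCALE = [0.3, 0.3, 0.3, 0.3, 0.08, 0.03, 0.08, 0.03, 0.01, 0.01]
_CO2_XSCALE = [0.08, 0.08, 0.02, 0.02, 0.2]

_STAGE_RECIPES = {
    "co2": ("co2_min", "co2_parallel", "co2_T"),
    "mea": ("mea_NHN", "mea_OHO", "co2_mea_amino", "co2_mea_hydroxyl",
            "co2_mea_scan"),
}

#: fixed multi-start list for the MEA stage: full starting vectors over
#: (mu_OH, mu_NH, mu_CO, mu_CN, rv_N, eps_N, rv_O, eps_O, eps_HN, eps_HO).
#: Start 1 encodes the strong-hydroxyl / compact-amine regime that the
#: grid exploration of this landscape identified; starts 2-3 probe the
#: large-amine and plain MM3-like regimes.
_MEA_STARTS = (
    {0: 3.03, 1: 0.70, 2: 0.10, 3: 1.50, 4: 1.30, 5: 0.30, 6: 2.03,
     7: 0.34, 8: 0.034, 9: 0.0066},
    {0: 3.03, 1: 1.52, 2: 0.10, 3: 0.15, 4: 1.83, 5: 0.50, 6: 1.95,
     7: 0.18, 8: 0.025, 9: 0.015},
    {0: 2.2, 1: 1.7},
)
_CO2_STARTS = ({}, {4: 2.3}, {4: 1.2})            # vary the C=O dipole


def _get_param(ff, spec):
    kind, key, name = spec
    obj = ff.lj[key] if kind == "lj" else ff.bonds[key]
    return getattr(obj, name)


def _set_param(ff, spec, value):
    kind, key, name = spec
    obj = ff.lj[key] if kind == "lj" else ff.bonds[key]
    setattr(obj, name, float(value))


def fit_parameters(ref: ReferenceSet,
                   ff0: Optional[ForceFieldParameters] = None,
                   settings: Optional[FitSettings] = None) -> FitResult:
    """Deterministic staged fit of the nonbonded parameters to *ref*."""
    if ff0 is None:
        ff0 = default_parameters()
    if settings is None:
        settings = FitSettings()
    ff = ff0.copy()
    trace: List[dict] = []
    n_eval = 0
    converged = True

    # stage 1: closed-form CO2 intramolecular constants
    freq_targets = {o.recipe.split(":")[1]: o.target
                    for o in ref.select("frequency")}
    if "sym" in freq_targets and "bend" in freq_targets:
        ks, kb = co2_intramolecular_fit(ff, freq_targets["bend"],
                                        freq_targets["sym"])
        trace.append({"stage": "co2_intra", "ks": ks, "kb": kb})

    fit_obs = [o for o in ref.observables
               if o.weight > 0 and o.kind not in ("frequency", "context_qm")]

    for stage in settings.stages:
        specs = _CO2_PARAMS if stage == "co2" else _MEA_PARAMS
        bounds = _CO2_BOUNDS if stage == "co2" else _MEA_BOUNDS
        dip_idx = _CO2_DIPOLE_IDX if stage == "co2" else _MEA_DIPOLE_IDX
        recipes = _STAGE_RECIPES[stage]
        obs = [o for o in fit_obs if o.recipe in recipes]
        if not obs:
            continue
        x0 = np.array([_get_param(ff, s) for s in specs])

        def residuals(x, _obs=obs, _specs=specs):
            nonlocal n_eval
            n_eval += 1
            trial = ff.copy()
            for s, v in zip(_specs, x):
                _set_param(trial, s, v)
            ev = Evaluator(trial, tol=settings.tol_min)
            out = []
            for o in _obs:
                try:
                    v = ev.observable(o)
                except Exception:
                    v = o.target + 100.0  # heavily penalized failed point
                out.append(o.weight * (v - o.target))
            return np.array(out)

        best = None
        starts = (_CO2_STARTS if stage == "co2" else _MEA_STARTS)
        for overrides in starts[:settings.n_starts]:
            xs = x0.copy()
            for k, v in overrides.items():
                xs[k] = v
            xs = np.clip(xs, bounds[0], bounds[1])
            x_scale = _CO2_XSCALE if stage == "co2" else _MEA_XSCALE
            sol = least_squares(residuals, xs, bounds=bounds,
                                diff_step=settings.diff_step,
                                x_scale=x_scale,
                                xtol=settings.xtol, ftol=settings.ftol,
                                max_nfev=settings.max_nfev)
            if best is None or sol.cost < best.cost:
                best = sol
        for s, v in zip(specs, best.x):
            _set_param(ff, s, v)
        trace.append({"stage": stage, "x": best.x.tolist(),
                      "cost": float(best.cost), "nfev": int(best.nfev),
                      "status": int(best.status)})
        converged = converged and best.status > 0

    # final residual report over the full set (aligned one-to-one)
    ev = Evaluator(ff, tol=settings.tol_min)
    residual_list: List[float] = []
    for o in ref.observables:
        if o.kind == "context_qm":
            residual_list.append(float("nan"))
            continue
        try:
            residual_list.append(float(ev.observable(o) - o.target))
        except Exception:
            residual_list.append(float("nan"))
    objective = float(np.nansum([(o.weight * r) ** 2 for o, r in
                                 zip(ref.observables, residual_list)
                                 if np.isfinite(r)]))
    return FitResult(ff=ff, residuals=residual_list, objective=objective,
                     converged=converged, n_evaluations=n_eval, trace=trace)


def calibrated_parameters() -> ForceFieldParameters:
    """Load the shipped calibrated parameter file (output of the fit)."""
    from .io import read_parameters
    path = resources.files("dipolemm.data") / "calibrated_params.txt"
    return read_parameters(path)
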