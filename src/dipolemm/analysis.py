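"""Thermodynamic and structural analysis: heat capacity from canonical
energy fluctuations, phase-transition detection on a temperature grid,
radial distribution functions, and intramolecular hydrogen-bond
histograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .model import KB, ForceFieldParameters, MolecularSystem
from .dynamics import IntegratorSpec, ThermostatSpec, Trajectory, run_md

#: N_A * k_B in kcal/mol/K (energies here are molar)
NA_KB = KB


# ---------------------------------------------------------------------------
# Heat capacity
# ---------------------------------------------------------------------------


def heat_capacity(u_samples: Sequence[float], temperature: float) -> float:
    """Canonical fluctuation estimator C = (<U^2> - <U>^2) / (N_A kB T^2).

    ``u_samples`` are potential energies in kcal/mol; the result is in
    kcal/mol/K per cluster (divide by the molecule count for a
    per-molecule value).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    u = np.asarray(u_samples, dtype=float)
    if u.size < 2:
        raise ValueError("need at least two energy samples")
    var = float(np.mean(u * u) - np.mean(u) ** 2)
    return var / (NA_KB * temperature * temperature)


@dataclass
class HeatCapacityCurve:
    temperatures: np.ndarray
    cv: np.ndarray                       # kcal/mol/K per system
    n_samples: np.ndarray
    peak_temperature: float
    flagged: List[bool] = field(default_factory=list)

    def per_molecule(self, n_molecules: int) -> np.ndarray:
        return self.cv / n_molecules


def detect_peak(temperatures, cv, smooth: bool = True) -> float:
    """Grid argmax, optionally after 3-point boxcar smoothing."""
    t = np.asarray(temperatures, float)
    c = np.asarray(cv, float)
    if smooth and c.size >= 3:
        cs = c.copy()
        cs[1:-1] = (c[:-2] + c[1:-1] + c[2:]) / 3.0
        c = cs
    return float(t[int(np.argmax(c))])


def heat_capacity_scan(builder: Callable[[], MolecularSystem],
                       ff: ForceFieldParameters,
                       temperatures: Sequence[float],
                       n_steps: int, equilibration_steps: int,
                       dt: float = 0.0005, stride: int = 20,
                       seed: int = 0,
                       evaporation_radius: Optional[float] = None,
                       smooth: bool = True) -> HeatCapacityCurve:
    """Independent pre-equilibrated NVT run per grid temperature.

    Each point builds a fresh system (same builder), draws velocities at
    its temperature with a point-specific seed, equilibrates, samples U,
    and applies the fluctuation estimator.  Points where the system
    evaporates (any molecule farther than ``evaporation_radius`` from the
    origin) are flagged.
    """
    temps = list(temperatures)
    if any(b <= a for a, b in zip(temps, temps[1:])):
        raise ValueError("temperature grid must be sorted increasing")
    cvs, counts, flags = [], [], []
    for k, t in enumerate(temps):
        system = builder()
        spec = IntegratorSpec(dt=dt, n_steps=n_steps, stride=stride,
                              seed=seed * 1009 + k)
        traj = run_md(system, ff, spec,
                      thermostat=ThermostatSpec(float(t)),
                      equilibration_steps=equilibration_steps,
                      store_frames=bool(evaporation_radius),
                      initialize=float(t))
        cvs.append(heat_capacity(traj.potential, float(t)))
        counts.append(len(traj.potential))
        flag = False
        if evaporation_radius and traj.positions:
            final = traj.positions[-1]
            flag = bool(np.linalg.norm(final, axis=1).max()
                        > evaporation_radius)
        flags.append(flag)
    peak = detect_peak(temps, cvs, smooth=smooth)
    return HeatCapacityCurve(np.array(temps, float), np.array(cvs),
                             np.array(counts), peak, flags)


# ---------------------------------------------------------------------------
# Radial distribution functions
# ---------------------------------------------------------------------------


@dataclass
class RDFResult:
    r: np.ndarray                 # bin centres, A
    g: np.ndarray
    pair_label: str
    window: Tuple[float, float]   # ps
    n_frames: int
    bin_width: float


def _class_indices(system: MolecularSystem, cls: str) -> np.ndarray:
    return np.array([i for i, c in enumerate(system.classes) if c == cls],
                    dtype=np.int64)


def rdf(frames: Sequence[np.ndarray], system: MolecularSystem,
        pair: Tuple[str, str], r_max: float = 12.0, bin_width: float = 0.1,
        cell: Optional[np.ndarray] = None,
        window: Tuple[float, float] = (0.0, 0.0),
        volume: Optional[float] = None) -> RDFResult:
    """Pair-distance histogram normalized by the ideal-gas shell count.

    ``pair`` selects atom classes (e.g. ('C_co2', 'C_co2')); only
    intermolecular pairs are counted; minimum-image convention applies
    when a cell is given.  The partner density uses the primary-cell
    volume (or ``volume`` for aperiodic systems).
    """
    if not len(frames):
        raise ValueError("empty trajectory window")
    sel_a = _class_indices(system, pair[0])
    sel_b = _class_indices(system, pair[1])
    if sel_a.size == 0 or sel_b.size == 0:
        raise ValueError(f"empty selection for pair {pair}")
    mol = system.molecule_index
    same = pair[0] == pair[1]
    if cell is None:
        cell = system.cell
    if volume is None:
        if cell is None:
            raise ValueError("aperiodic RDF requires an explicit volume")
        volume = float(np.prod(cell))

    edges = np.arange(0.0, r_max + bin_width, bin_width)
    hist = np.zeros(edges.size - 1)
    # intermolecular mask (static over frames)
    ma, mb = mol[sel_a], mol[sel_b]
    inter = ma[:, None] != mb[None, :]
    if same:
        iu = np.triu_indices(sel_a.size, k=1)
    for pos in frames:
        d = pos[sel_a][:, None, :] - pos[sel_b][None, :, :]
        if cell is not None:
            d = d - cell * np.round(d / cell)
        r = np.sqrt(np.sum(d * d, axis=2))
        if same:
            mask = inter[iu]
            rv = r[iu][mask]
        else:
            rv = r[inter]
        hist += np.histogram(rv, bins=edges)[0]

    centers = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 * np.pi * centers ** 2 * bin_width
    n_frames = len(frames)
    if same:
        # pair count normalization: N*(N-1)/2 distinct pairs
        rho_pairs = sel_a.size * (sel_a.size - 1) / 2.0 / volume
        ideal = rho_pairs * shell * n_frames
    else:
        rho_pairs = sel_a.size * sel_b.size / volume
        ideal = rho_pairs * shell * n_frames
    g = np.where(ideal > 0, hist / ideal, 0.0)
    return RDFResult(centers, g, f"{pair[0]}-{pair[1]}", window,
                     n_frames, bin_width)


def rdf_from_trajectory(traj: Trajectory, system: MolecularSystem,
                        pair: Tuple[str, str], t_start: float, t_end: float,
                        r_max: float = 12.0, bin_width: float = 0.1,
                        volume: Optional[float] = None) -> RDFResult:
    """RDF over the trajectory frames with t_start <= t < t_end (ps)."""
    sel = [i for i, t in enumerate(traj.times) if t_start <= t < t_end]
    if not sel:
        raise ValueError("no frames in the requested window")
    frames = [traj.positions[i] for i in sel]
    cell = traj.cells[sel[0]] if traj.cells else system.cell
    return rdf(frames, system, pair, r_max, bin_width, cell=cell,
               window=(t_start, t_end), volume=volume)


def rdf_time_evolution(traj: Trajectory, system: MolecularSystem,
                       pair: Tuple[str, str], r_probe: float = 3.65,
                       window_length: float = 10.0,
                       bin_width: float = 0.1,
                       volume: Optional[float] = None):
    """g(r_probe) evaluated over sequential trajectory windows.

    Returns (window start times, g values at the probe bin).
    """
    t_max = float(traj.times[-1])
    if window_length > t_max + 1e-9:
        raise ValueError("window length exceeds the trajectory span")
    starts, values = [], []
    t0 = 0.0
    while t0 + window_length <= t_max + 1e-9:
        res = rdf_from_trajectory(traj, system, pair, t0, t0 + window_length,
                                  r_max=r_probe + 5 * bin_width,
                                  bin_width=bin_width, volume=volume)
        k = int(np.clip(np.searchsorted(res.r, r_probe) - 0, 0,
                        res.r.size - 1))
        # nearest bin centre to the probe distance
        k = int(np.argmin(np.abs(res.r - r_probe)))
        starts.append(t0)
        values.append(float(res.g[k]))
        t0 += window_length
    return np.array(starts), np.array(values)


# ---------------------------------------------------------------------------
# Intramolecular hydrogen-bond histogram
# ---------------------------------------------------------------------------


@dataclass
class HBHistogram:
    edges: np.ndarray             # A
    counts: np.ndarray
    n_below_cutoff: int
    cutoff: float
    n_molecules: int
    n_snapshots: int

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def intra_hb_histogram(traj: Trajectory, system: MolecularSystem,
                       n_molecules: int = 10, n_snapshots: int = 200,
                       cutoff: float = 2.2, bin_width: float = 0.1,
                       r_max: float = 6.0,
                       molecule_ids: Optional[Sequence[int]] = None
                       ) -> HBHistogram:
    """Histogram of the intramolecular N...H(O) distance in MEA.

    For ``n_molecules`` MEA molecules over ``n_snapshots`` evenly spaced
    trajectory frames, the distance between the amine nitrogen and the
    hydroxyl hydrogen of the *same* molecule is collected.  By default the
    lowest-index MEA molecules are monitored; ``molecule_ids`` selects
    specific molecules (e.g. the ones nearest an interface).
    """
    mol = system.molecule_index
    cls = system.classes
    pairs_by_mol = {}  # molecule id -> (i_N, i_HO)
    for m in range(int(mol.max()) + 1):
        idx = np.nonzero(mol == m)[0]
        i_n = [i for i in idx if cls[i] == "N_amine"]
        i_h = [i for i in idx if cls[i] == "H_O"]
        if i_n and i_h:
            pairs_by_mol[m] = (i_n[0], i_h[0])
    if molecule_ids is not None:
        missing = [m for m in molecule_ids if m not in pairs_by_mol]
        if missing:
            raise ValueError(f"molecules {missing} are not MEA molecules")
        pairs_nm = [pairs_by_mol[m] for m in molecule_ids]
        n_molecules = len(pairs_nm)
    else:
        pairs_nm = list(pairs_by_mol.values())
    if n_molecules > len(pairs_nm):
        raise ValueError(
            f"requested {n_molecules} MEA molecules, trajectory system "
            f"has {len(pairs_nm)}")
    pairs_nm = pairs_nm[:n_molecules]

    n_avail = len(traj.positions)
    if n_snapshots > n_avail:
        raise ValueError(
            f"requested {n_snapshots} snapshots, trajectory has {n_avail}")
    frame_ids = np.linspace(0, n_avail - 1, n_snapshots).astype(int)

    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts = np.zeros(edges.size - 1, dtype=np.int64)
    below = 0
    overflow = 0
    for fi in frame_ids:
        pos = traj.positions[fi]
        for i_n, i_h in pairs_nm:
            r = float(np.linalg.norm(pos[i_n] - pos[i_h]))
            if r < cutoff:
                below += 1
            k = int(r / bin_width)
            if k < counts.size:
                counts[k] += 1
            else:
                overflow += 1
    # keep the bookkeeping exact: fold far-distance events into the last bin
    counts[-1] += overflow
    return HBHistogram(edges, counts, below, cutoff,
                       len(pairs_nm), n_snapshots)
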