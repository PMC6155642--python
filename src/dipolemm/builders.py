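"""Programmatic structure generation: monomers, dimers, clusters, liquid
boxes and the gas-liquid interfacial composite.

Every builder is deterministic given its seed and produces systems whose
internal coordinates start at (or near) the force field's equilibrium
values, so downstream minimization starts inside the intended basin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .minimize import ConstraintSpec
from .model import (BondParams, ForceFieldParameters, MolecularSystem, Wall,
                    CLASS_MASS, canonical_bond, default_parameters,
                    merge_systems)

#: molar masses (amu)
MASS_CO2 = 12.011 + 2 * 15.999
MASS_MEA = 61.084  # HOCH2CH2NH2
#: amu/A^3 -> g/cm^3
DENS_G_CM3 = 1.0 / 0.602214076


class PackingError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Internal-coordinate placement (NeRF)
# ---------------------------------------------------------------------------


def _place(a, b, c, r, theta_deg, phi_deg):
    """Place X bonded to *a* with |X-a|=r, angle(X,a,b)=theta and
    dihedral(X,a,b,c)=phi (X eclipses c at phi=0)."""
    a, b, c = map(np.asarray, (a, b, c))
    e1 = b - a
    e1 = e1 / np.linalg.norm(e1)
    v = c - b
    vp = v - (v @ e1) * e1
    if np.linalg.norm(vp) < 1e-10:
        # collinear reference: pick any perpendicular
        t = np.array([1.0, 0.0, 0.0])
        if abs(e1[0]) > 0.9:
            t = np.array([0.0, 1.0, 0.0])
        vp = t - (t @ e1) * e1
    e2 = vp / np.linalg.norm(vp)
    e3 = np.cross(e1, e2)
    th = np.radians(theta_deg)
    ph = np.radians(phi_deg)
    return a + r * (np.cos(th) * e1
                    + np.sin(th) * (np.cos(ph) * e2 - np.sin(ph) * e3))


# ---------------------------------------------------------------------------
# Monomers
# ---------------------------------------------------------------------------


def build_monomer(species: str, conformer: Optional[str] = None,
                  ff: Optional[ForceFieldParameters] = None) -> MolecularSystem:
    """CO2 (linear, 3 atoms) or MEA (11 atoms; 'trans' or 'gauche_intraHB')."""
    if ff is None:
        ff = default_parameters()
    species = species.upper()
    if species == "CO2":
        r0 = ff.bond_params("C_co2", "O_co2").r0
        pos = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, r0], [0.0, 0.0, -r0]])
        return MolecularSystem(classes=["C_co2", "O_co2", "O_co2"],
                               positions=pos, bonds=[[0, 1], [0, 2]])
    if species != "MEA":
        raise ValueError(f"unknown species {species!r}")

    conformer = conformer or "trans"
    if conformer not in ("trans", "gauche_intraHB"):
        raise ValueError(f"unknown MEA conformer {conformer!r}")
    # dihedrals (H-O-C-C, O-C-C-N); the gauche_intraHB values point the
    # hydroxyl H at the amine lone pair (N...H < 2.5 A before optimization)
    if conformer == "trans":
        tau_hocc, tau_occn = 180.0, 180.0
    else:
        tau_hocc, tau_occn = -40.0, 55.0

    rOH = ff.bond_params("O_hydroxyl", "H_O").r0
    rCO = ff.bond_params("C_sp3", "O_hydroxyl").r0
    rCC = ff.bond_params("C_sp3", "C_sp3").r0
    rCN = ff.bond_params("C_sp3", "N_amine").r0
    rNH = ff.bond_params("N_amine", "H_N").r0
    rCH = ff.bond_params("C_sp3", "H_C").r0

    # order: O(0) H_O(1) C1(2) C2(3) N(4) H_N(5) H_N(6) H_C1a(7) H_C1b(8)
    #        H_C2a(9) H_C2b(10)
    O = np.array([0.0, 0.0, 0.0])
    C1 = np.array([rCO, 0.0, 0.0])
    C2 = _place(C1, O, O + np.array([0.0, 0.0, 1.0]), rCC, 107.5, 0.0)
    H_O = _place(O, C1, C2, rOH, 106.9, tau_hocc)
    N = _place(C2, C1, O, rCN, 109.5, tau_occn)
    H1a = _place(C1, C2, O, rCH, 110.0, 120.0)
    H1b = _place(C1, C2, O, rCH, 110.0, -120.0)
    H2a = _place(C2, N, C1, rCH, 110.0, 120.0)
    H2b = _place(C2, N, C1, rCH, 110.0, -120.0)
    HN1 = _place(N, C2, C1, rNH, 112.0, 60.0)
    HN2 = _place(N, C2, C1, rNH, 112.0, -60.0)

    classes = ["O_hydroxyl", "H_O", "C_sp3", "C_sp3", "N_amine",
               "H_N", "H_N", "H_C", "H_C", "H_C", "H_C"]
    pos = np.array([O, H_O, C1, C2, N, HN1, HN2, H1a, H1b, H2a, H2b])
    bonds = [[0, 1], [0, 2], [2, 3], [3, 4], [4, 5], [4, 6],
             [2, 7], [2, 8], [3, 9], [3, 10]]
    return MolecularSystem(classes=classes, positions=pos, bonds=bonds)


MEA_ATOM = {"O": 0, "H_O": 1, "C1": 2, "C2": 3, "N": 4,
            "H_N1": 5, "H_N2": 6}


def _rotate(pos, axis, angle_deg, origin=None):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    th = np.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    Rm = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
    if origin is None:
        origin = np.zeros(3)
    return (pos - origin) @ Rm.T + origin


# ---------------------------------------------------------------------------
# Dimers
# ---------------------------------------------------------------------------


@dataclass
class DimerArrangement:
    label: str
    constraints: List[ConstraintSpec]


def build_dimer(species: Tuple[str, str], arrangement: str,
                ff: Optional[ForceFieldParameters] = None,
                approach: float = 2.8,
                conformer: str = "gauche_intraHB"
                ) -> Tuple[MolecularSystem, List[ConstraintSpec]]:
    """A labelled dimer start plus the constraints that define it.

    (CO2, CO2): 'min' (slipped parallel, unconstrained), 'parallel'
    (C-C frozen at 4.0 A, axes kept parallel), 'T-type' (one axis pointing
    at the other's midpoint, axes perpendicular).
    (MEA, MEA): 'NHN' / 'OHO' (donor X-H...X angle frozen at 180 deg).
    (CO2, MEA): 'amino' / 'hydroxyl' binding-motif starts (unconstrained).
    """
    if ff is None:
        ff = default_parameters()
    sp = tuple(s.upper() for s in species)

    if sp == ("CO2", "CO2"):
        a = build_monomer("CO2", ff=ff)
        b = build_monomer("CO2", ff=ff)
        if arrangement == "min":
            # slipped-parallel start: axes parallel (z), offset in x and z
            b.positions = b.positions + np.array([3.2, 0.0, 1.5])
            sys_ = merge_systems(a, b)
            return sys_, []
        if arrangement == "parallel":
            b.positions = b.positions + np.array([4.0, 0.0, 0.0])
            sys_ = merge_systems(a, b)
            cons = [
                ConstraintSpec("frozen_distance", (0, 3), 4.0),
                ConstraintSpec("frozen_angle", (1, 0, 3), 90.0),
                ConstraintSpec("frozen_angle", (4, 3, 0), 90.0),
                ConstraintSpec("frozen_dihedral", (1, 0, 3, 4), 0.0),
            ]
            return sys_, cons
        if arrangement in ("T-type", "t-type", "T"):
            # molecule b axis along x, pointing its O at a's C
            b.positions = np.array([[3.5, 0.0, 0.0],
                                    [3.5 + 1.16, 0.0, 0.0],
                                    [3.5 - 1.16, 0.0, 0.0]])
            r0 = ff.bond_params("C_co2", "O_co2").r0
            b.positions[1, 0] = 3.5 + r0
            b.positions[2, 0] = 3.5 - r0
            sys_ = merge_systems(a, b)
            cons = [
                ConstraintSpec("frozen_angle", (1, 0, 3), 90.0),  # a axis perp
                ConstraintSpec("frozen_angle", (0, 3, 4), 180.0),  # b points at a
            ]
            return sys_, cons
        raise ValueError(f"unknown (CO2)2 arrangement {arrangement!r}")

    if sp == ("MEA", "MEA"):
        if arrangement not in ("NHN", "OHO"):
            raise ValueError(f"unknown (MEA)2 arrangement {arrangement!r}")
        don = build_monomer("MEA", "trans", ff=ff)
        acc = build_monomer("MEA", "trans", ff=ff)
        if arrangement == "NHN":
            d_x, d_h = MEA_ATOM["N"], MEA_ATOM["H_N1"]
            a_y = MEA_ATOM["N"]
            r_hy = 2.2
        else:
            d_x, d_h = MEA_ATOM["O"], MEA_ATOM["H_O"]
            a_y = MEA_ATOM["O"]
            r_hy = 1.9
        # orient acceptor so its acceptor atom sits on the donor X-H axis
        u = don.positions[d_h] - don.positions[d_x]
        u /= np.linalg.norm(u)
        target = don.positions[d_h] + r_hy * u
        shift = target - acc.positions[a_y]
        acc.positions = acc.positions + shift
        # rotate acceptor about the acceptor atom to move its bulk away
        # from the donor (reduce steric clash in the start)
        acc.positions = _rotate(acc.positions, np.array([0.0, 1.0, 0.0]),
                                120.0, origin=acc.positions[a_y])
        sys_ = merge_systems(don, acc)
        cons = [ConstraintSpec("frozen_angle",
                               (d_x, d_h, 11 + a_y), 180.0)]
        return sys_, cons

    if sp in (("CO2", "MEA"), ("MEA", "CO2")):
        # binding-motif complexes default to the intramolecular-HB
        # (global-minimum) conformer, whose folded shape lets CO2 contact
        # the full binding motif; the absorption-pathway scan passes the
        # extended conformer for a clean amino approach
        mea = build_monomer("MEA", conformer, ff=ff)
        co2 = build_monomer("CO2", ff=ff)
        if arrangement == "amino":
            site = mea.positions[MEA_ATOM["N"]]
            # approach along the amine lone pair (opposite the N-H bisector)
            h1 = mea.positions[MEA_ATOM["H_N1"]]
            h2 = mea.positions[MEA_ATOM["H_N2"]]
            c2 = mea.positions[MEA_ATOM["C2"]]
            lone = site - ((h1 + h2 + c2) / 3.0)
            lone /= np.linalg.norm(lone)
            c_pos = site + approach * lone
        elif arrangement == "hydroxyl":
            site = mea.positions[MEA_ATOM["O"]]
            h = mea.positions[MEA_ATOM["H_O"]]
            c1 = mea.positions[MEA_ATOM["C1"]]
            lone = site - 0.5 * (h + c1)
            lone /= np.linalg.norm(lone)
            c_pos = site + approach * lone
        else:
            raise ValueError(f"unknown CO2-MEA arrangement {arrangement!r}")
        # orient CO2 axis perpendicular to the approach vector
        perp = np.cross(lone, np.array([0.0, 0.0, 1.0]))
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(lone, np.array([0.0, 1.0, 0.0]))
        perp /= np.linalg.norm(perp)
        r0 = ff.bond_params("C_co2", "O_co2").r0
        co2.positions = np.array([c_pos, c_pos + r0 * perp, c_pos - r0 * perp])
        sys_ = merge_systems(mea, co2)
        return sys_, []

    raise ValueError(f"unsupported species pair {species!r}")


# ---------------------------------------------------------------------------
# Packing
# ---------------------------------------------------------------------------


@dataclass
class BuildRecipe:
    species: str
    count: int
    density: Optional[float] = None      # g/cm^3
    radius: Optional[float] = None       # A (spherical builds)
    seed: int = 0
    #: minimum atom-atom distance between molecules; resolved per builder
    #: when None (2.0 A for gas-phase clusters, 1.5 A for liquid boxes,
    #: where crystal-like interlocking at full density is tighter)
    min_dist: Optional[float] = None
    conformer: Optional[str] = None
    wall_stiffness: float = 100.0

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if (self.density is None) == (self.radius is None):
            raise ValueError("specify exactly one of density or radius")


def _random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _mol_mass(species: str) -> float:
    return MASS_CO2 if species.upper() == "CO2" else MASS_MEA


def _small_rotation(rng, max_deg: float) -> np.ndarray:
    ax = rng.normal(size=3)
    ax /= np.linalg.norm(ax)
    th = np.radians(rng.uniform(-max_deg, max_deg))
    K = np.array([[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]], [-ax[1], ax[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def _repair_contacts(coords, centers, tp, rng, min_dist, cell,
                     sweeps: int = 3, tries: int = 40):
    """Re-orient molecules involved in close contacts (deterministic per
    rng state): each offender tries random orientations, keeping the one
    that maximizes its closest intermolecular distance."""
    n_mol = len(coords)

    def closest(k, pos_k):
        best = np.inf
        for j in range(n_mol):
            if j == k:
                continue
            d = pos_k[:, None, :] - coords[j][None, :, :]
            if cell is not None:
                d = d - cell * np.round(d / cell)
            best = min(best, float(np.min(np.sum(d * d, axis=2))))
        return np.sqrt(best)

    for _ in range(sweeps):
        offenders = [k for k in range(n_mol)
                     if closest(k, coords[k]) < min_dist]
        if not offenders:
            break
        for k in offenders:
            best_pos = coords[k]
            best_d = closest(k, best_pos)
            for _t in range(tries):
                cand = tp @ _random_rotation(rng).T + centers[k] \
                    + rng.uniform(-0.3, 0.3, size=3)
                d = closest(k, cand)
                if d > best_d:
                    best_pos, best_d = cand, d
                    if best_d >= min_dist:
                        break
            coords[k] = best_pos
    return coords


def _min_intermolecular(all_pos: np.ndarray, atoms_per_mol: int,
                        cell=None) -> float:
    n_mol = all_pos.shape[0] // atoms_per_mol
    best = np.inf
    for i in range(n_mol):
        a = all_pos[i * atoms_per_mol:(i + 1) * atoms_per_mol]
        b = all_pos[(i + 1) * atoms_per_mol:]
        if not len(b):
            break
        d = a[:, None, :] - b[None, :, :]
        if cell is not None:
            d = d - cell * np.round(d / cell)
        best = min(best, float(np.sqrt(np.sum(d * d, axis=2).min())))
    return best


def _pack(template: MolecularSystem, count: int, rng, min_dist: float,
          sites: np.ndarray, jitter: float, cell=None,
          max_attempts: int = 400):
    """Sequential insertion of randomly rotated rigid copies of *template*
    at jittered lattice sites (rejection below min_dist)."""
    tpl = template.positions - template.positions.mean(axis=0)
    accepted = []
    all_pos = None
    order = rng.permutation(len(sites))
    for k in range(count):
        site = sites[order[k]]
        ok = False
        for _att in range(max_attempts):
            R = _random_rotation(rng)
            center = site + rng.uniform(-jitter, jitter, size=3)
            cand = tpl @ R.T + center
            if all_pos is not None:
                d = all_pos[:, None, :] - cand[None, :, :]
                if cell is not None:
                    d = d - cell * np.round(d / cell)
                if np.min(np.sum(d * d, axis=2)) < min_dist * min_dist:
                    continue
            accepted.append(cand)
            all_pos = cand if all_pos is None else np.vstack([all_pos, cand])
            ok = True
            break
        if not ok:
            raise PackingError(
                f"could not insert molecule {len(accepted) + 1}/{count}; "
                "increase the radius/cell or lower min_dist")
    return accepted


def _replicate(template: MolecularSystem, coords: List[np.ndarray],
               cell=None, wall=None) -> MolecularSystem:
    n = template.n_atoms
    classes = list(template.classes) * len(coords)
    bonds = np.vstack([template.bonds + i * n for i in range(len(coords))])
    pos = np.vstack(coords)
    return MolecularSystem(classes=classes, positions=pos, bonds=bonds,
                           cell=cell, wall=wall,
                           velocities=np.zeros((len(classes), 3)))


def pack_cluster(recipe: BuildRecipe,
                 ff: Optional[ForceFieldParameters] = None) -> MolecularSystem:
    """Spherical cluster with a one-sided harmonic confining wall.

    The radius comes from the recipe directly, or from the target density.
    """
    if ff is None:
        ff = default_parameters()
    rng = np.random.default_rng(recipe.seed)
    if recipe.radius is not None:
        radius = float(recipe.radius)
    else:
        mass = recipe.count * _mol_mass(recipe.species)
        vol = mass * DENS_G_CM3 / recipe.density
        radius = (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)
    min_dist = 2.0 if recipe.min_dist is None else recipe.min_dist
    tpl = build_monomer(recipe.species, recipe.conformer, ff=ff)

    # lattice sites inside the sphere, spacing set so enough sites exist
    r_eff = max(radius - 0.5, 0.5)
    spacing = (4.0 / 3.0 * np.pi * r_eff ** 3 / (1.6 * recipe.count)) ** (1 / 3)
    grid = np.arange(-r_eff, r_eff + spacing, spacing)
    pts = np.array(np.meshgrid(grid, grid, grid)).reshape(3, -1).T
    pts = pts[np.linalg.norm(pts, axis=1) <= r_eff]
    if len(pts) < recipe.count:
        raise PackingError("sphere too small for requested count")
    coords = _pack(tpl, recipe.count, rng, min_dist, pts,
                   jitter=0.25 * spacing)
    wall = Wall(center=np.zeros(3), radius=radius,
                stiffness=recipe.wall_stiffness)
    return _replicate(tpl, coords, wall=wall)


def pack_liquid_box(recipe: BuildRecipe,
                    ff: Optional[ForceFieldParameters] = None
                    ) -> MolecularSystem:
    """Cubic periodic box at the recipe density."""
    if ff is None:
        ff = default_parameters()
    if recipe.density is None:
        raise ValueError("liquid box build requires a density")
    rng = np.random.default_rng(recipe.seed)
    mass = recipe.count * _mol_mass(recipe.species)
    vol = mass * DENS_G_CM3 / recipe.density
    edge = vol ** (1.0 / 3.0)
    cell = np.array([edge, edge, edge])
    min_dist = 1.5 if recipe.min_dist is None else recipe.min_dist
    tpl = build_monomer(recipe.species, recipe.conformer, ff=ff)

    # crystal-like start: molecules aligned with the cell diagonal on a
    # checkerboard sublattice (interlocks elongated molecules at liquid
    # density; the arrangement disorders during equilibration)
    tp = tpl.positions - tpl.positions.mean(axis=0)
    _, _, vt = np.linalg.svd(tp)
    axis = vt[0]
    diag = np.ones(3) / np.sqrt(3.0)
    v = np.cross(axis, diag)
    c = float(axis @ diag)
    if abs(1.0 + c) < 1e-12:
        R0 = -np.eye(3)
    else:
        K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R0 = np.eye(3) + K + K @ K / (1.0 + c)
    tp = tp @ R0.T

    def _mi(d):
        return d - cell * np.round(d / cell)

    def _spread_sites(pts, start_idx):
        chosen = [start_idx]
        d2 = np.sum(_mi(pts - pts[start_idx]) ** 2, axis=1)
        for _ in range(recipe.count - 1):
            nxt = int(np.argmax(d2))
            chosen.append(nxt)
            d2 = np.minimum(d2, np.sum(_mi(pts - pts[nxt]) ** 2, axis=1))
        return np.array(chosen)

    nat = tpl.n_atoms
    # candidate lattice resolutions: the count is spread over the lattice
    # by farthest-point selection, which reduces to an fcc-like sublattice
    # when it half-fills a cubic grid
    n_est = (2.0 * recipe.count) ** (1.0 / 3.0)
    options = sorted({int(np.floor(n_est)), int(np.ceil(n_est)),
                      int(np.ceil(recipe.count ** (1.0 / 3.0)))})
    options = [n for n in options if n >= 1 and n ** 3 >= recipe.count]
    if not options:
        options = [int(np.ceil(recipe.count ** (1.0 / 3.0)))]

    best_coords, best_dmin = None, -1.0
    for n_side in options:
        spacing = edge / n_side
        grid = (np.arange(n_side) + 0.5) * spacing
        pts = np.array(np.meshgrid(grid, grid, grid)).reshape(3, -1).T
        if (n_side ** 3 + 1) // 2 >= recipe.count:
            # enough checkerboard (fcc-like) sites: restrict to one parity
            ijk = np.rint(pts / spacing - 0.5).astype(int)
            pts = pts[ijk.sum(axis=1) % 2 == 0]
        for _attempt in range(4):
            order = _spread_sites(pts, int(rng.integers(len(pts))))
            centers = [p + rng.uniform(-0.05, 0.05, size=3)
                       for p in pts[order]]
            coords = [tp @ _small_rotation(rng, 5.0).T + c for c in centers]
            coords = _repair_contacts(coords, centers, tp, rng, min_dist,
                                      cell)
            dmin = _min_intermolecular(np.vstack(coords), nat, cell)
            if dmin > best_dmin:
                best_coords, best_dmin = coords, dmin
            if best_dmin >= min_dist:
                break
        if best_dmin >= min_dist:
            break
    if best_dmin < min_dist:
        raise PackingError(
            f"packed box violates the minimum distance "
            f"({best_dmin:.2f} < {min_dist} A); lower min_dist or density")
    return _replicate(tpl, best_coords, cell=cell)


# ---------------------------------------------------------------------------
# Interface construction
# ---------------------------------------------------------------------------


def molecule_centers_of_mass(system: MolecularSystem) -> np.ndarray:
    mol = system.molecule_index
    m = system.masses
    n_mol = system.n_molecules
    com = np.zeros((n_mol, 3))
    tot = np.zeros(n_mol)
    np.add.at(com, mol, system.positions * m[:, None])
    np.add.at(tot, mol, m)
    return com / tot[:, None]


def carve_cavity(box: MolecularSystem, radius: float = 9.5
                 ) -> Tuple[MolecularSystem, int]:
    """Remove every molecule whose centre of mass lies within *radius* of
    the cell centre.  Velocities of the survivors are preserved."""
    if box.cell is None:
        raise ValueError("carve_cavity requires a periodic box")
    if radius > box.cell.min() / 2.0:
        raise ValueError("cavity radius exceeds half the cell edge")
    center = box.cell / 2.0
    com = molecule_centers_of_mass(box)
    d = com - center
    d = d - box.cell * np.round(d / box.cell)
    keep_mol = np.nonzero(np.linalg.norm(d, axis=1) >= radius)[0]
    removed = box.n_molecules - keep_mol.size
    mask = np.isin(box.molecule_index, keep_mol)
    idx = np.nonzero(mask)[0]
    remap = -np.ones(box.n_atoms, dtype=int)
    remap[idx] = np.arange(idx.size)
    bsel = np.all(mask[box.bonds], axis=1)
    vel = box.velocities[idx] if box.velocities is not None else None
    out = MolecularSystem(
        classes=[box.classes[i] for i in idx],
        positions=box.positions[idx].copy(),
        bonds=remap[box.bonds[bsel]],
        cell=box.cell.copy(),
        velocities=vel,
    )
    return out, removed


def merge_interface(cluster: MolecularSystem, carved: MolecularSystem,
                    min_dist: float = 1.8) -> MolecularSystem:
    """Centre the (wall-free) cluster inside the carved box's cavity and
    concatenate, carrying velocities over from both parents."""
    if carved.cell is None:
        raise ValueError("carved box must be periodic")
    clus = cluster.copy()
    clus.wall = None
    clus.positions = clus.positions - clus.positions.mean(axis=0) \
        + carved.cell / 2.0
    merged = merge_systems(clus, carved, cell=carved.cell.copy())
    # steric check across the two parents (minimum image)
    a = merged.positions[:clus.n_atoms]
    b = merged.positions[clus.n_atoms:]
    d = a[:, None, :] - b[None, :, :]
    d = d - carved.cell * np.round(d / carved.cell)
    dmin = np.sqrt(np.min(np.sum(d * d, axis=2)))
    if dmin < min_dist:
        raise ValueError(
            f"steric clash on merge: closest CO2-MEA contact {dmin:.2f} A "
            f"< {min_dist} A")
    return merged


# ---------------------------------------------------------------------------
# Dipole scaling (the hydroxyl control experiment)
# ---------------------------------------------------------------------------


def scale_bond_dipole(ff: ForceFieldParameters, bond_class=("O_hydroxyl", "H_O"),
                      factor: float = 0.1) -> ForceFieldParameters:
    """Copy of *ff* with one bond class's dipole magnitude scaled."""
    if not 0.0 < factor <= 1.0:
        raise ValueError("factor must be in (0, 1]")
    key = canonical_bond(*bond_class)
    if key not in ff.bonds:
        raise KeyError(f"unknown bond class {key}")
    out = ff.copy()
    out.bonds[key].mu *= factor
    return out
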