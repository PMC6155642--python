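"""File formats: XYZ / extended XYZ, parameter files, reference files,
TSV tables and multi-frame trajectories.

All formats are plain text.  Extended XYZ carries an orthorhombic cell
(``Lattice="lx 0 0 0 ly 0 0 0 lz"``) and per-atom force-field class labels
in the comment-line ``Properties`` convention, so geometry round trips are
lossless to 1e-6 A and metadata exactly.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np

from .model import (AngleParams, BondParams, CLASS_ELEMENT, ForceFieldParameters,
                    LJParams, MolecularSystem, TorsionParams)


class ParseError(ValueError):
    def __init__(self, msg, line=None):
        if line is not None:
            msg = f"line {line}: {msg}"
        super().__init__(msg)
        self.line = line


# ---------------------------------------------------------------------------
# XYZ / extended XYZ
# ---------------------------------------------------------------------------

_ELEMENT_DEFAULT_CLASS = {"C": "C_sp3", "N": "N_amine", "O": "O_hydroxyl",
                          "H": "H_C"}


def write_xyz(path, system: MolecularSystem, comment: str = "",
              extended: bool = True, append: bool = False):
    """Write (extended) XYZ.  Extended form stores the cell and atom classes."""
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        _write_xyz_fh(fh, system, comment, extended)


def _write_xyz_fh(fh, system, comment="", extended=True):
    fh.write(f"{system.n_atoms}\n")
    if extended:
        parts = []
        if system.cell is not None:
            lx, ly, lz = system.cell
            parts.append(f'Lattice="{lx:.10g} 0 0 0 {ly:.10g} 0 0 0 {lz:.10g}"')
        parts.append("Properties=species:S:1:pos:R:3:ffclass:S:1")
        if comment:
            parts.append(f'Comment="{comment}"')
        fh.write(" ".join(parts) + "\n")
    else:
        fh.write(comment.replace("\n", " ") + "\n")
    els = system.elements
    for el, cls, p in zip(els, system.classes, system.positions):
        fh.write(f"{el:2s} {p[0]:18.10f} {p[1]:18.10f} {p[2]:18.10f}")
        if extended:
            fh.write(f"  {cls}")
        fh.write("\n")


def read_xyz(path, bonds=None, require_cell: bool = False) -> MolecularSystem:
    """Read one (extended) XYZ frame.

    ``bonds`` may supply topology (plain XYZ carries none); when omitted,
    bonds are inferred for known monomer layouts by distance (< 1.8 A).
    """
    with open(path) as fh:
        frames = _read_xyz_fh(fh, bonds, require_cell, first_only=True)
    return frames[0]


def _read_xyz_fh(fh, bonds=None, require_cell=False, first_only=False):
    frames = []
    lineno = 0
    while True:
        header = fh.readline()
        lineno += 1
        if not header.strip():
            break
        try:
            nat = int(header.split()[0])
        except ValueError:
            raise ParseError(f"expected atom count, got {header!r}", lineno)
        comment = fh.readline()
        lineno += 1
        cell = None
        if 'Lattice="' in comment:
            lat = comment.split('Lattice="')[1].split('"')[0].split()
            if len(lat) != 9:
                raise ParseError("malformed Lattice entry", lineno)
            vals = [float(x) for x in lat]
            cell = np.array([vals[0], vals[4], vals[8]])
        has_class = "ffclass" in comment
        classes, pos = [], []
        for _ in range(nat):
            ln = fh.readline()
            lineno += 1
            parts = ln.split()
            if len(parts) < 4:
                raise ParseError(f"malformed atom record {ln!r}", lineno)
            el = parts[0]
            try:
                xyz = [float(v) for v in parts[1:4]]
            except ValueError:
                raise ParseError(f"non-numeric coordinate in {ln!r}", lineno)
            if has_class and len(parts) >= 5:
                classes.append(parts[4])
            else:
                if el not in _ELEMENT_DEFAULT_CLASS:
                    raise ParseError(f"unknown element {el!r}", lineno)
                classes.append(_ELEMENT_DEFAULT_CLASS[el])
            pos.append(xyz)
        if require_cell and cell is None:
            raise ParseError("periodic system requires a Lattice cell line",
                             lineno)
        b = bonds if bonds is not None else _infer_bonds(np.array(pos), classes)
        frames.append(MolecularSystem(classes=classes, positions=np.array(pos),
                                      bonds=b, cell=cell))
        if first_only:
            break
    if not frames:
        raise ParseError("empty XYZ file")
    return frames


def _infer_bonds(pos: np.ndarray, classes) -> np.ndarray:
    """Distance-based bond inference (covalent contacts < 1.8 A, H <= 1.3 A)."""
    n = pos.shape[0]
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            r = float(np.linalg.norm(pos[i] - pos[j]))
            hi = classes[i].startswith("H") or classes[j].startswith("H")
            if (hi and r < 1.3) or (not hi and r < 1.8):
                out.append((i, j))
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def read_trajectory_xyz(path, bonds=None) -> List[MolecularSystem]:
    with open(path) as fh:
        return _read_xyz_fh(fh, bonds)


# ---------------------------------------------------------------------------
# Parameter file
# ---------------------------------------------------------------------------


def write_parameters(path, ff: ForceFieldParameters, header: str = ""):
    """Plain-text key-value parameter file, one record per (class, parameter)."""
    with open(path, "w") as fh:
        fh.write("# dipolemm force-field parameter file\n")
        for ln in header.splitlines():
            fh.write(f"# {ln}\n")
        for (a, b), p in ff.bonds.items():
            fh.write(f"bond {a} {b} ks {p.ks:.17g}\n")
            fh.write(f"bond {a} {b} r0 {p.r0:.17g}\n")
            fh.write(f"bond {a} {b} mu {p.mu:.17g}\n")
        for (a, b, c), p in ff.angles.items():
            fh.write(f"angle {a} {b} {c} kb {p.kb:.17g}\n")
            fh.write(f"angle {a} {b} {c} theta0 {p.theta0:.17g}\n")
        for key, p in ff.torsions.items():
            k = " ".join(key)
            fh.write(f"torsion {k} v1 {p.v1:.17g}\n")
            fh.write(f"torsion {k} v2 {p.v2:.17g}\n")
            fh.write(f"torsion {k} v3 {p.v3:.17g}\n")
        for c, p in ff.lj.items():
            fh.write(f"lj {c} rv {p.rv:.17g}\n")
            fh.write(f"lj {c} eps {p.eps:.17g}\n")
        for k in ("dielectric", "cut_vdw", "cut_dipole", "taper_width"):
            fh.write(f"global {k} {getattr(ff, k):.17g}\n")


def read_parameters(path) -> ForceFieldParameters:
    ff = ForceFieldParameters()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            ln = raw.split("#")[0].strip()
            if not ln:
                continue
            parts = ln.split()
            try:
                kind = parts[0]
                if kind == "bond":
                    a, b, name, val = parts[1], parts[2], parts[3], float(parts[4])
                    p = ff.bonds.setdefault((a, b), BondParams(0.0, 1.0))
                    setattr(p, name, val)
                elif kind == "angle":
                    key = (parts[1], parts[2], parts[3])
                    p = ff.angles.setdefault(key, AngleParams(0.0, 109.5))
                    setattr(p, parts[4], float(parts[5]))
                elif kind == "torsion":
                    nk = len(parts) - 3
                    key = tuple(parts[1:1 + nk])
                    p = ff.torsions.setdefault(key, TorsionParams())
                    setattr(p, parts[-2], float(parts[-1]))
                elif kind == "lj":
                    p = ff.lj.setdefault(parts[1], LJParams(1.5, 0.02))
                    setattr(p, parts[2], float(parts[3]))
                elif kind == "global":
                    setattr(ff, parts[1], float(parts[2]))
                else:
                    raise ValueError(f"unknown record kind {kind!r}")
            except (IndexError, ValueError) as err:
                raise ParseError(str(err), lineno)
    return ff


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def write_tsv(path, columns: dict, meta: Optional[dict] = None):
    """Header + numeric columns; ``meta`` entries become '# key: value' lines."""
    keys = list(columns)
    arrs = [np.asarray(columns[k]) for k in keys]
    with open(path, "w") as fh:
        if meta:
            for k, v in meta.items():
                fh.write(f"# {k}: {v}\n")
        fh.write("\t".join(keys) + "\n")
        for row in zip(*arrs):
            fh.write("\t".join(f"{v:.10g}" if isinstance(v, (int, float, np.floating))
                               else str(v) for v in row) + "\n")


def read_tsv(path) -> dict:
    import pandas as pd
    df = pd.read_csv(path, sep="\t", comment="#")
    return {c: df[c].to_numpy() for c in df.columns}


def write_trajectory_xyz(path, trajectory, system: MolecularSystem,
                         comment: str = ""):
    """Multi-frame extended XYZ from a Trajectory (positions + cells)."""
    work = system.copy()
    with open(path, "w") as fh:
        for k, pos in enumerate(trajectory.positions):
            work.positions = pos
            work.cell = trajectory.cells[k] if trajectory.cells else None
            label = f"{comment} t={trajectory.times[k]:g} ps".strip()
            _write_xyz_fh(fh, work, comment=label)
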