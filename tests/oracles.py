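"""Independent brute-force oracles used by the test suite.

Everything here is written as plain double loops from the closed-form
definitions (no neighbor lists, no vectorization, no code shared with the
package's evaluation paths).
"""

import numpy as np

# independently derived constants
KCAL_PER_J_MOL = 1.0 / 4184.0
COULOMB_KCAL_A = 332.063713      # e^2/A in kcal/mol
DEBYE = 0.20819434               # e*A per Debye
K_DD = COULOMB_KCAL_A * DEBYE ** 2


def smoothstep(r, cutoff, width):
    if r >= cutoff:
        return 0.0
    if r <= cutoff - width:
        return 1.0
    x = (r - (cutoff - width)) / width
    return 1.0 - x * x * (3.0 - 2.0 * x)


def min_image(d, cell):
    if cell is None:
        return d
    return d - cell * np.round(d / cell)


def brute_force_energy(system, ff):
    """Full decomposed energy by explicit double loops."""
    pos = system.positions
    cls = system.classes
    cell = system.cell
    topo = system.topology
    n = system.n_atoms

    cut_vdw, cut_dip, w = ff.cut_vdw, ff.cut_dipole, ff.taper_width
    if cell is not None:
        half = float(min(cell)) / 2.0
        cut_vdw = min(cut_vdw, half)
        cut_dip = min(cut_dip, half)

    e_stretch = 0.0
    for i, j in system.bonds:
        p = ff.bond_params(cls[i], cls[j])
        r = np.linalg.norm(min_image(pos[j] - pos[i], None))
        e_stretch += p.ks * (r - p.r0) ** 2

    e_bend = 0.0
    for i, j, k in topo.angles:
        p = ff.angle_params(cls[i], cls[j], cls[k])
        u = pos[i] - pos[j]
        v = pos[k] - pos[j]
        c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        th = np.degrees(np.arccos(np.clip(c, -1, 1)))
        e_bend += p.kb * np.radians(th - p.theta0) ** 2

    e_tors = 0.0
    for a, b, c_, d in topo.torsions:
        p = ff.torsion_params(cls[a], cls[b], cls[c_], cls[d])
        b1, b2, b3 = pos[b] - pos[a], pos[c_] - pos[b], pos[d] - pos[c_]
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        m1 = np.cross(n1, b2 / np.linalg.norm(b2))
        phi = np.arctan2(np.dot(m1, n2), np.dot(n1, n2))
        e_tors += (0.5 * p.v1 * (1 + np.cos(phi))
                   + 0.5 * p.v2 * (1 - np.cos(2 * phi))
                   + 0.5 * p.v3 * (1 + np.cos(3 * phi)))

    # atom-pair exclusions: within two bonds
    e_lj = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if j in topo.within2[i]:
                continue
            pi, pj = ff.lj_params(cls[i]), ff.lj_params(cls[j])
            d = min_image(pos[j] - pos[i], cell)
            r = np.linalg.norm(d)
            if r >= cut_vdw:
                continue
            rm = pi.rv + pj.rv
            eps = np.sqrt(pi.eps * pj.eps)
            e_lj += eps * ((rm / r) ** 12 - 2 * (rm / r) ** 6) \
                * smoothstep(r, cut_vdw, w)

    # dipole pairs
    dips = topo.dipole_bonds
    mus = [ff.bond_params(cls[a], cls[b]).mu for a, b in dips]
    e_dd = 0.0
    for p in range(len(dips)):
        for q in range(p + 1, len(dips)):
            ap, bp = dips[p]
            aq, bq = dips[q]
            if aq in (topo.within2[ap] | topo.within2[bp]) or \
               bq in (topo.within2[ap] | topo.within2[bp]):
                continue
            up = pos[bp] - pos[ap]
            up = up / np.linalg.norm(up)
            uq = pos[bq] - pos[aq]
            uq = uq / np.linalg.norm(uq)
            mp = 0.5 * (pos[ap] + pos[bp])
            mq = 0.5 * (pos[aq] + pos[bq])
            R = min_image(mq - mp, cell)
            r = np.linalg.norm(R)
            if r >= cut_dip:
                continue
            rhat = R / r
            orient = np.dot(up, uq) - 3 * np.dot(up, rhat) * np.dot(uq, rhat)
            e_dd += (K_DD / ff.dielectric * mus[p] * mus[q] * orient / r ** 3
                     * smoothstep(r, cut_dip, w))

    e_wall = 0.0
    if system.wall is not None:
        for i in range(n):
            r = np.linalg.norm(pos[i] - system.wall.center)
            if r > system.wall.radius:
                e_wall += system.wall.stiffness * (r - system.wall.radius) ** 2

    return {"stretch": e_stretch, "bend": e_bend, "torsion": e_tors,
            "lj": e_lj, "dipole": e_dd, "wall": e_wall,
            "total": e_stretch + e_bend + e_tors + e_lj + e_dd + e_wall}


def numerical_gradient(system, ff, h=1e-5):
    from dipolemm.model import total_energy
    g = np.zeros_like(system.positions)
    work = system.copy()
    for i in range(system.n_atoms):
        for d in range(3):
            work.positions = system.positions.copy()
            work.positions[i, d] += h
            ep = total_energy(work, ff).total
            work.positions[i, d] -= 2 * h
            em = total_energy(work, ff).total
            g[i, d] = (ep - em) / (2 * h)
    return g


def diatomic_frequency(ks, m1, m2):
    """Closed-form nu (cm^-1) for E = ks (r - r0)^2: k = 2 ks."""
    mu_red = m1 * m2 / (m1 + m2)          # amu
    k_si = 2.0 * ks * 4184.0 / (1e-20 * 6.02214076e23)   # J/m^2 per molecule
    mu_si = mu_red * 1e-3 / 6.02214076e23
    omega = np.sqrt(k_si / mu_si)
    return omega / (2 * np.pi * 2.99792458e10)
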