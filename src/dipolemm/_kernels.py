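"""Numba-compiled evaluation kernels for the potential and its forces.

These mirror the vectorized numpy implementations in ``model`` term by
term (same taper, same exclusions) and are the default execution path;
the numpy path remains as an in-package reference.  All kernels return
``(energy, gradient, virial)`` with the virial accumulated from
image-consistent local coordinates so pressure is well defined under
periodic boundaries.
"""

import numpy as np
from numba import njit

_NOPY = {"cache": True, "fastmath": False}


@njit(**_NOPY)
def k_taper(r, r_cut, width):
    """C1 cubic smoothstep: value and derivative at distance r."""
    if r >= r_cut:
        return 0.0, 0.0
    on = r_cut - width
    if r <= on:
        return 1.0, 0.0
    x = (r - on) / width
    return 1.0 - x * x * (3.0 - 2.0 * x), -6.0 * x * (1.0 - x) / width


@njit(**_NOPY)
def k_bonded(pos, bond_idx, bond_ks, bond_r0,
             ang_idx, ang_kb, ang_t0, tor_idx, tor_v):
    n = pos.shape[0]
    g = np.zeros((n, 3))
    e_s = 0.0
    e_b = 0.0
    e_t = 0.0
    W = 0.0

    for m in range(bond_idx.shape[0]):
        i = bond_idx[m, 0]
        j = bond_idx[m, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[m]
        e_s += bond_ks[m] * dr * dr
        dEdr = 2.0 * bond_ks[m] * dr
        fx = dEdr * dx / r
        fy = dEdr * dy / r
        fz = dEdr * dz / r
        g[j, 0] += fx
        g[j, 1] += fy
        g[j, 2] += fz
        g[i, 0] -= fx
        g[i, 1] -= fy
        g[i, 2] -= fz
        W -= dEdr * r

    for m in range(ang_idx.shape[0]):
        i = ang_idx[m, 0]
        j = ang_idx[m, 1]
        k = ang_idx[m, 2]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        vx = pos[k, 0] - pos[j, 0]
        vy = pos[k, 1] - pos[j, 1]
        vz = pos[k, 2] - pos[j, 2]
        lu = np.sqrt(ux * ux + uy * uy + uz * uz)
        lv = np.sqrt(vx * vx + vy * vy + vz * vz)
        ux /= lu
        uy /= lu
        uz /= lu
        vx /= lv
        vy /= lv
        vz /= lv
        c = ux * vx + uy * vy + uz * vz
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        th = np.arccos(c)
        dth = th - ang_t0[m]
        e_b += ang_kb[m] * dth * dth
        sin = np.sqrt(max(1.0 - c * c, 0.0))
        if sin < 1e-8:
            ratio = -1.0
        else:
            ratio = dth / sin
        dEdc = -2.0 * ang_kb[m] * ratio
        gix = dEdc * (vx - c * ux) / lu
        giy = dEdc * (vy - c * uy) / lu
        giz = dEdc * (vz - c * uz) / lu
        gkx = dEdc * (ux - c * vx) / lv
        gky = dEdc * (uy - c * vy) / lv
        gkz = dEdc * (uz - c * vz) / lv
        g[i, 0] += gix
        g[i, 1] += giy
        g[i, 2] += giz
        g[k, 0] += gkx
        g[k, 1] += gky
        g[k, 2] += gkz
        g[j, 0] -= gix + gkx
        g[j, 1] -= giy + gky
        g[j, 2] -= giz + gkz
        W -= (gix * ux + giy * uy + giz * uz) * lu
        W -= (gkx * vx + gky * vy + gkz * vz) * lv

    for m in range(tor_idx.shape[0]):
        a = tor_idx[m, 0]
        b = tor_idx[m, 1]
        c_ = tor_idx[m, 2]
        d = tor_idx[m, 3]
        b1 = pos[b] - pos[a]
        b2 = pos[c_] - pos[b]
        b3 = pos[d] - pos[c_]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        lb2 = np.sqrt(b2[0] * b2[0] + b2[1] * b2[1] + b2[2] * b2[2])
        m1 = np.cross(n1, b2 / lb2)
        x = n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2]
        y = m1[0] * n2[0] + m1[1] * n2[1] + m1[2] * n2[2]
        phi = np.arctan2(y, x)
        v1 = tor_v[m, 0]
        v2 = tor_v[m, 1]
        v3 = tor_v[m, 2]
        e_t += (0.5 * v1 * (1.0 + np.cos(phi))
                + 0.5 * v2 * (1.0 - np.cos(2.0 * phi))
                + 0.5 * v3 * (1.0 + np.cos(3.0 * phi)))
        dEdphi = (-0.5 * v1 * np.sin(phi) + v2 * np.sin(2.0 * phi)
                  - 1.5 * v3 * np.sin(3.0 * phi))
        n1sq = n1[0] * n1[0] + n1[1] * n1[1] + n1[2] * n1[2]
        n2sq = n2[0] * n2[0] + n2[1] * n2[1] + n2[2] * n2[2]
        dpda = (lb2 / n1sq) * n1
        dpdd = -(lb2 / n2sq) * n2
        t12 = (b1[0] * b2[0] + b1[1] * b2[1] + b1[2] * b2[2]) / (lb2 * lb2)
        t32 = (b3[0] * b2[0] + b3[1] * b2[1] + b3[2] * b2[2]) / (lb2 * lb2)
        dpdb = (-1.0 - t12) * dpda + t32 * dpdd
        dpdc = t12 * dpda + (-1.0 - t32) * dpdd
        for q in range(3):
            g[a, q] += dEdphi * dpda[q]
            g[b, q] += dEdphi * dpdb[q]
            g[c_, q] += dEdphi * dpdc[q]
            g[d, q] += dEdphi * dpdd[q]
        W -= dEdphi * (dpdb[0] * b1[0] + dpdb[1] * b1[1] + dpdb[2] * b1[2])
        W -= dEdphi * (dpdc[0] * (b1[0] + b2[0]) + dpdc[1] * (b1[1] + b2[1])
                       + dpdc[2] * (b1[2] + b2[2]))
        W -= dEdphi * (dpdd[0] * (b1[0] + b2[0] + b3[0])
                       + dpdd[1] * (b1[1] + b2[1] + b3[1])
                       + dpdd[2] * (b1[2] + b2[2] + b3[2]))

    return e_s, e_b, e_t, g, W


@njit(**_NOPY)
def k_lj(pos, pairs, rv, eps, cell, periodic, cut, taper_w):
    n = pos.shape[0]
    g = np.zeros((n, 3))
    e = 0.0
    W = 0.0
    for m in range(pairs.shape[0]):
        i = pairs[m, 0]
        j = pairs[m, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        if periodic:
            dx -= cell[0] * np.rint(dx / cell[0])
            dy -= cell[1] * np.rint(dy / cell[1])
            dz -= cell[2] * np.rint(dz / cell[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= cut * cut:
            continue
        r = np.sqrt(r2)
        rm = rv[i] + rv[j]
        ep = np.sqrt(eps[i] * eps[j])
        x2 = (rm / r) * (rm / r)
        x6 = x2 * x2 * x2
        x12 = x6 * x6
        e0 = ep * (x12 - 2.0 * x6)
        de0 = -12.0 * ep * (x12 - x6) / r
        s, ds = k_taper(r, cut, taper_w)
        e += e0 * s
        dEdr = de0 * s + e0 * ds
        fx = dEdr * dx / r
        fy = dEdr * dy / r
        fz = dEdr * dz / r
        g[j, 0] += fx
        g[j, 1] += fy
        g[j, 2] += fz
        g[i, 0] -= fx
        g[i, 1] -= fy
        g[i, 2] -= fz
        W -= dEdr * r
    return e, g, W


@njit(**_NOPY)
def k_dipole(pos, dip_idx, dip_mu, dpairs, cell, periodic, kdd, cut, taper_w):
    n = pos.shape[0]
    nd = dip_idx.shape[0]
    g = np.zeros((n, 3))
    e = 0.0
    W = 0.0
    # precompute unit vectors, lengths, midpoints
    u = np.empty((nd, 3))
    ln = np.empty(nd)
    mid = np.empty((nd, 3))
    for p in range(nd):
        a = dip_idx[p, 0]
        b = dip_idx[p, 1]
        lx = pos[b, 0] - pos[a, 0]
        ly = pos[b, 1] - pos[a, 1]
        lz = pos[b, 2] - pos[a, 2]
        l = np.sqrt(lx * lx + ly * ly + lz * lz)
        ln[p] = l
        u[p, 0] = lx / l
        u[p, 1] = ly / l
        u[p, 2] = lz / l
        mid[p, 0] = 0.5 * (pos[a, 0] + pos[b, 0])
        mid[p, 1] = 0.5 * (pos[a, 1] + pos[b, 1])
        mid[p, 2] = 0.5 * (pos[a, 2] + pos[b, 2])

    for m in range(dpairs.shape[0]):
        p = dpairs[m, 0]
        q = dpairs[m, 1]
        Rx = mid[q, 0] - mid[p, 0]
        Ry = mid[q, 1] - mid[p, 1]
        Rz = mid[q, 2] - mid[p, 2]
        if periodic:
            Rx -= cell[0] * np.rint(Rx / cell[0])
            Ry -= cell[1] * np.rint(Ry / cell[1])
            Rz -= cell[2] * np.rint(Rz / cell[2])
        r2 = Rx * Rx + Ry * Ry + Rz * Rz
        if r2 >= cut * cut:
            continue
        r = np.sqrt(r2)
        A = u[p, 0] * u[q, 0] + u[p, 1] * u[q, 1] + u[p, 2] * u[q, 2]
        B1 = u[p, 0] * Rx + u[p, 1] * Ry + u[p, 2] * Rz
        B2 = u[q, 0] * Rx + u[q, 1] * Ry + u[q, 2] * Rz
        C = kdd * dip_mu[p] * dip_mu[q]
        r3 = r2 * r
        r5 = r3 * r2
        r7 = r5 * r2
        e0 = C * (A / r3 - 3.0 * B1 * B2 / r5)
        s, ds = k_taper(r, cut, taper_w)
        e += e0 * s
        cA = C * (-3.0 * A / r5 + 15.0 * B1 * B2 / r7)
        cB = 3.0 * C / r5
        edsr = e0 * ds / r
        gRx = s * (cA * Rx - cB * (B2 * u[p, 0] + B1 * u[q, 0])) + edsr * Rx
        gRy = s * (cA * Ry - cB * (B2 * u[p, 1] + B1 * u[q, 1])) + edsr * Ry
        gRz = s * (cA * Rz - cB * (B2 * u[p, 2] + B1 * u[q, 2])) + edsr * Rz
        Cs = C * s
        gupx = Cs * (u[q, 0] / r3 - 3.0 * B2 * Rx / r5)
        gupy = Cs * (u[q, 1] / r3 - 3.0 * B2 * Ry / r5)
        gupz = Cs * (u[q, 2] / r3 - 3.0 * B2 * Rz / r5)
        guqx = Cs * (u[p, 0] / r3 - 3.0 * B1 * Rx / r5)
        guqy = Cs * (u[p, 1] / r3 - 3.0 * B1 * Ry / r5)
        guqz = Cs * (u[p, 2] / r3 - 3.0 * B1 * Rz / r5)

        ap = dip_idx[p, 0]
        bp = dip_idx[p, 1]
        aq = dip_idx[q, 0]
        bq = dip_idx[q, 1]
        # midpoint part
        g[ap, 0] -= 0.5 * gRx
        g[ap, 1] -= 0.5 * gRy
        g[ap, 2] -= 0.5 * gRz
        g[bp, 0] -= 0.5 * gRx
        g[bp, 1] -= 0.5 * gRy
        g[bp, 2] -= 0.5 * gRz
        g[aq, 0] += 0.5 * gRx
        g[aq, 1] += 0.5 * gRy
        g[aq, 2] += 0.5 * gRz
        g[bq, 0] += 0.5 * gRx
        g[bq, 1] += 0.5 * gRy
        g[bq, 2] += 0.5 * gRz
        # orientation part: project out the axis component, scale by 1/L
        dotp = gupx * u[p, 0] + gupy * u[p, 1] + gupz * u[p, 2]
        ppx = (gupx - dotp * u[p, 0]) / ln[p]
        ppy = (gupy - dotp * u[p, 1]) / ln[p]
        ppz = (gupz - dotp * u[p, 2]) / ln[p]
        dotq = guqx * u[q, 0] + guqy * u[q, 1] + guqz * u[q, 2]
        pqx = (guqx - dotq * u[q, 0]) / ln[q]
        pqy = (guqy - dotq * u[q, 1]) / ln[q]
        pqz = (guqz - dotq * u[q, 2]) / ln[q]
        g[ap, 0] -= ppx
        g[ap, 1] -= ppy
        g[ap, 2] -= ppz
        g[bp, 0] += ppx
        g[bp, 1] += ppy
        g[bp, 2] += ppz
        g[aq, 0] -= pqx
        g[aq, 1] -= pqy
        g[aq, 2] -= pqz
        g[bq, 0] += pqx
        g[bq, 1] += pqy
        g[bq, 2] += pqz

        W -= gRx * Rx + gRy * Ry + gRz * Rz
        W -= (ppx * u[p, 0] + ppy * u[p, 1] + ppz * u[p, 2]) * ln[p]
        W -= (pqx * u[q, 0] + pqy * u[q, 1] + pqz * u[q, 2]) * ln[q]
    return e, g, W


@njit(**_NOPY)
def k_wall(pos, center, radius, kw):
    n = pos.shape[0]
    g = np.zeros((n, 3))
    e = 0.0
    if radius <= 0.0:
        return e, g
    for i in range(n):
        dx = pos[i, 0] - center[0]
        dy = pos[i, 1] - center[1]
        dz = pos[i, 2] - center[2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r > radius:
            dr = r - radius
            e += kw * dr * dr
            f = 2.0 * kw * dr / r
            g[i, 0] += f * dx
            g[i, 1] += f * dy
            g[i, 2] += f * dz
    return e, g


@njit(**_NOPY)
def k_md_nvt(pos0, vel0, masses, dt, n_steps, stride,
             bond_idx, bond_ks, bond_r0, ang_idx, ang_kb, ang_t0,
             tor_idx, tor_v, nb_pairs, rv, eps, dip_idx, dip_mu, dd_pairs,
             cell, periodic, kdd, cut_vdw, cut_dip, taper_w,
             wall_c, wall_r, wall_k, t_target, tau):
    """Fused velocity-Verlet NVT/NVE loop (static all-pair lists).

    Logs potential/kinetic energy and full frames every ``stride`` steps
    (including the initial state).  ``t_target < 0`` disables the
    Berendsen thermostat (NVE).
    """
    ACCEL = 418.4
    KB = 1.380649e-23 * 6.02214076e23 / 4184.0
    n = pos0.shape[0]
    pos = pos0.copy()
    vel = vel0.copy()
    ndof = 3.0 * n - 3.0

    n_blocks = n_steps // stride
    n_log = n_blocks + 1
    U = np.empty(n_log)
    K = np.empty(n_log)
    fr_p = np.empty((n_log, n, 3))
    fr_v = np.empty((n_log, n, 3))

    es, eb, et, g1, _ = k_bonded(pos, bond_idx, bond_ks, bond_r0,
                                 ang_idx, ang_kb, ang_t0, tor_idx, tor_v)
    el, g2, _ = k_lj(pos, nb_pairs, rv, eps, cell, periodic, cut_vdw, taper_w)
    ed, g3, _ = k_dipole(pos, dip_idx, dip_mu, dd_pairs, cell, periodic,
                         kdd, cut_dip, taper_w)
    ew, g4 = k_wall(pos, wall_c, wall_r, wall_k)
    g = g1 + g2 + g3 + g4
    e_pot = es + eb + et + el + ed + ew

    ke = 0.0
    for i in range(n):
        ke += masses[i] * (vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
    ke = 0.5 * ke / ACCEL
    U[0] = e_pot
    K[0] = ke
    fr_p[0] = pos
    fr_v[0] = vel
    log_i = 1

    for step in range(1, n_steps + 1):
        for i in range(n):
            a = 0.5 * dt * ACCEL / masses[i]
            vel[i, 0] -= a * g[i, 0]
            vel[i, 1] -= a * g[i, 1]
            vel[i, 2] -= a * g[i, 2]
            pos[i, 0] += dt * vel[i, 0]
            pos[i, 1] += dt * vel[i, 1]
            pos[i, 2] += dt * vel[i, 2]
        es, eb, et, g1, _ = k_bonded(pos, bond_idx, bond_ks, bond_r0,
                                     ang_idx, ang_kb, ang_t0, tor_idx, tor_v)
        el, g2, _ = k_lj(pos, nb_pairs, rv, eps, cell, periodic,
                         cut_vdw, taper_w)
        ed, g3, _ = k_dipole(pos, dip_idx, dip_mu, dd_pairs, cell, periodic,
                             kdd, cut_dip, taper_w)
        ew, g4 = k_wall(pos, wall_c, wall_r, wall_k)
        g = g1 + g2 + g3 + g4
        e_pot = es + eb + et + el + ed + ew
        ke = 0.0
        for i in range(n):
            a = 0.5 * dt * ACCEL / masses[i]
            vel[i, 0] -= a * g[i, 0]
            vel[i, 1] -= a * g[i, 1]
            vel[i, 2] -= a * g[i, 2]
            ke += masses[i] * (vel[i, 0] ** 2 + vel[i, 1] ** 2
                               + vel[i, 2] ** 2)
        ke = 0.5 * ke / ACCEL
        if t_target > 0.0:
            t_inst = 2.0 * ke / (ndof * KB)
            lam = np.sqrt(1.0 + (dt / tau) * (t_target / t_inst - 1.0))
            for i in range(n):
                vel[i, 0] *= lam
                vel[i, 1] *= lam
                vel[i, 2] *= lam
            ke = ke * lam * lam
        if step % stride == 0 and log_i < n_log:
            U[log_i] = e_pot
            K[log_i] = ke
            fr_p[log_i] = pos
            fr_v[log_i] = vel
            log_i += 1
    return pos, vel, U, K, fr_p, fr_v
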