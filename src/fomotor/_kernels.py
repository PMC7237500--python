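"""Numba kernels: force evaluation and the BAOAB Langevin stage.

All arrays are float64/int64; coordinates in nm, energies in kcal/mol.
The kernels are deliberately monolithic so that one MD stage (10^4-10^5
steps) runs without crossing the Python boundary.
"""

import numpy as np
from numba import njit

COULOMB_K = 33.20637   # kcal*nm/(mol*e^2)


@njit(cache=True, fastmath=True)
def _forces(x, f,
            bonds, bond_k, bond_r0,
            angles, angle_k, angle_t0,
            dihes, dihe_k1, dihe_k3, dihe_p0,
            contacts, con_eps, con_r0,
            ev_act, ev_act_n, ev_pairs, ev_sigma, ev_eps,
            q, cpairs, dielectric,
            mem_sites, mem_w, mem_nsc, mem_d, mem_eps,
            lvl_beads, lvl_ptr, lvl_cz, k_ring,
            ring_beads, ring_zref, k_zcom,
            anchor_beads, anchor_ref, k_anchor,
            torque_beads, torque_kcal):
    """Fill ``f`` with forces; return (e_non_es, e_coulomb, e_membrane, e_restraint).

    ``mem_w`` holds |q| of each membrane-feeling site (1 for a deprotonated
    carrier, 0 for a protonated one); ``mem_nsc`` is a (2, 2) array with the
    in-plane normal (nx, ny) of each border plane, pointing into the lipid.
    ``torque_kcal`` is the applied torque in kcal/mol (per radian), positive
    = hydrolysis (clockwise) direction.
    """
    n = x.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    e_non = 0.0
    e_coul = 0.0
    e_mem = 0.0
    e_res = 0.0

    # ---- bonds ----
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[b]
        e_non += bond_k[b] * dr * dr
        fm = -2.0 * bond_k[b] * dr / r
        f[j, 0] += fm * dx
        f[j, 1] += fm * dy
        f[j, 2] += fm * dz
        f[i, 0] -= fm * dx
        f[i, 1] -= fm * dy
        f[i, 2] -= fm * dz

    # ---- angles (harmonic in theta, sin clamped) ----
    for a in range(angles.shape[0]):
        i = angles[a, 0]
        j = angles[a, 1]
        k = angles[a, 2]
        ax = x[i, 0] - x[j, 0]
        ay = x[i, 1] - x[j, 1]
        az = x[i, 2] - x[j, 2]
        bx = x[k, 0] - x[j, 0]
        by = x[k, 1] - x[j, 1]
        bz = x[k, 2] - x[j, 2]
        ra = np.sqrt(ax * ax + ay * ay + az * az)
        rb = np.sqrt(bx * bx + by * by + bz * bz)
        ct = (ax * bx + ay * by + az * bz) / (ra * rb)
        if ct > 1.0:
            ct = 1.0
        if ct < -1.0:
            ct = -1.0
        th = np.arccos(ct)
        st = np.sqrt(1.0 - ct * ct)
        if st < 0.05:
            st = 0.05
        dth = th - angle_t0[a]
        e_non += angle_k[a] * dth * dth
        coef = 2.0 * angle_k[a] * dth / st
        # F_i = (2k dtheta / sin) * (b/(ra rb) - ct a/ra^2), likewise for k
        fix = coef * (bx / rb - ct * ax / ra) / ra
        fiy = coef * (by / rb - ct * ay / ra) / ra
        fiz = coef * (bz / rb - ct * az / ra) / ra
        fkx = coef * (ax / ra - ct * bx / rb) / rb
        fky = coef * (ay / ra - ct * by / rb) / rb
        fkz = coef * (az / ra - ct * bz / rb) / rb
        f[i, 0] += fix
        f[i, 1] += fiy
        f[i, 2] += fiz
        f[k, 0] += fkx
        f[k, 1] += fky
        f[k, 2] += fkz
        f[j, 0] -= fix + fkx
        f[j, 1] -= fiy + fky
        f[j, 2] -= fiz + fkz

    # ---- dihedrals: k1(1-cos(p-p0)) + k3(1-cos(3(p-p0))) ----
    for d in range(dihes.shape[0]):
        i = dihes[d, 0]
        j = dihes[d, 1]
        k = dihes[d, 2]
        l = dihes[d, 3]
        b1x = x[j, 0] - x[i, 0]
        b1y = x[j, 1] - x[i, 1]
        b1z = x[j, 2] - x[i, 2]
        b2x = x[k, 0] - x[j, 0]
        b2y = x[k, 1] - x[j, 1]
        b2z = x[k, 2] - x[j, 2]
        b3x = x[l, 0] - x[k, 0]
        b3y = x[l, 1] - x[k, 1]
        b3z = x[l, 2] - x[k, 2]
        # n1 = b1 x b2 ; n2 = b2 x b3
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        b2n = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        if n1sq < 1e-12 or n2sq < 1e-12:
            continue
        cosp = (n1x * n2x + n1y * n2y + n1z * n2z) / np.sqrt(n1sq * n2sq)
        sinp = (n1x * b3x + n1y * b3y + n1z * b3z) * b2n / np.sqrt(n1sq * n2sq)
        p = np.arctan2(sinp, cosp)
        dp = p - dihe_p0[d]
        e_non += dihe_k1[d] * (1.0 - np.cos(dp)) + dihe_k3[d] * (1.0 - np.cos(3.0 * dp))
        dV = dihe_k1[d] * np.sin(dp) + 3.0 * dihe_k3[d] * np.sin(3.0 * dp)
        # dphi/dr_i = -(|b2|/|n1|^2) n1 ; dphi/dr_l = (|b2|/|n2|^2) n2
        ax_ = -b2n / n1sq * n1x
        ay_ = -b2n / n1sq * n1y
        az_ = -b2n / n1sq * n1z
        bx_ = b2n / n2sq * n2x
        by_ = b2n / n2sq * n2y
        bz_ = b2n / n2sq * n2z
        dot12 = b1x * b2x + b1y * b2y + b1z * b2z
        dot32 = b3x * b2x + b3y * b2y + b3z * b2z
        c12 = dot12 / (b2n * b2n)
        c32 = dot32 / (b2n * b2n)
        f[i, 0] -= dV * ax_
        f[i, 1] -= dV * ay_
        f[i, 2] -= dV * az_
        f[j, 0] -= dV * (-(1.0 + c12) * ax_ + c32 * bx_)
        f[j, 1] -= dV * (-(1.0 + c12) * ay_ + c32 * by_)
        f[j, 2] -= dV * (-(1.0 + c12) * az_ + c32 * bz_)
        f[k, 0] -= dV * (c12 * ax_ - (1.0 + c32) * bx_)
        f[k, 1] -= dV * (c12 * ay_ - (1.0 + c32) * by_)
        f[k, 2] -= dV * (c12 * az_ - (1.0 + c32) * bz_)
        f[l, 0] -= dV * bx_
        f[l, 1] -= dV * by_
        f[l, 2] -= dV * bz_

    # ---- native contacts: 10-12 well, minimum at r0, depth eps ----
    for c in range(contacts.shape[0]):
        i = contacts[c, 0]
        j = contacts[c, 1]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        s = con_r0[c] / r
        s2 = s * s
        s10 = s2 * s2 * s2 * s2 * s2
        s12 = s10 * s2
        e_non += con_eps[c] * (5.0 * s12 - 6.0 * s10)
        # dV/dr = -60*eps/r * (s12 - s10); force on j = -dV/dr * (dx/r)
        fm = 60.0 * con_eps[c] * (s12 - s10) / r2
        f[j, 0] += fm * dx
        f[j, 1] += fm * dy
        f[j, 2] += fm * dz
        f[i, 0] -= fm * dx
        f[i, 1] -= fm * dy
        f[i, 2] -= fm * dz

    # ---- excluded volume (a-subunit <-> ring), truncated/shifted r^-12 ----
    for a in range(ev_act_n):
        p = ev_act[a]
        i = ev_pairs[p, 0]
        j = ev_pairs[p, 1]
        sig = ev_sigma[p]
        rc = 2.0 * sig
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc * rc:
            continue
        r = np.sqrt(r2)
        s = sig / r
        s2 = s * s
        s12 = s2 * s2 * s2 * s2 * s2 * s2
        e_non += ev_eps * (s12 - 1.0 / 4096.0)   # (1/2)^12 shift
        fm = 12.0 * ev_eps * s12 / r2
        f[j, 0] += fm * dx
        f[j, 1] += fm * dy
        f[j, 2] += fm * dz
        f[i, 0] -= fm * dx
        f[i, 1] -= fm * dy
        f[i, 2] -= fm * dz

    # ---- Coulomb, uniform dielectric, no cutoff ----
    for c in range(cpairs.shape[0]):
        i = cpairs[c, 0]
        j = cpairs[c, 1]
        qq = q[i] * q[j]
        if qq == 0.0:
            continue
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        e = COULOMB_K * qq / (dielectric * r)
        e_coul += e
        fm = e / r2
        f[j, 0] += fm * dx
        f[j, 1] += fm * dy
        f[j, 2] += fm * dz
        f[i, 0] -= fm * dx
        f[i, 1] -= fm * dy
        f[i, 2] -= fm * dz

    # ---- implicit membrane penalty on deprotonated carriers ----
    for s in range(mem_sites.shape[0]):
        w = mem_w[s]
        if w == 0.0:
            continue
        i = mem_sites[s]
        # border-plane normal coordinates (linear in x, y)
        best = -1.0e30
        bb = 0
        for b in range(2):
            xb = mem_nsc[b, 0] * x[i, 0] + mem_nsc[b, 1] * x[i, 1]
            if xb > best:
                best = xb
                bb = b
        if best <= 0.0:
            v = 0.0
            dv = 0.0
        elif best >= mem_d:
            v = 1.0
            dv = 0.0
        else:
            v = 0.5 * (1.0 - np.cos(np.pi * best / mem_d))
            dv = 0.5 * np.pi / mem_d * np.sin(np.pi * best / mem_d)
        e_mem += mem_eps * w * v
        if dv != 0.0:
            f[i, 0] -= mem_eps * w * dv * mem_nsc[bb, 0]
            f[i, 1] -= mem_eps * w * dv * mem_nsc[bb, 1]

    # ---- ring-axis restraint: per level, radius about a z-axis center ----
    for lv in range(lvl_ptr.shape[0] - 1):
        lo = lvl_ptr[lv]
        hi = lvl_ptr[lv + 1]
        nlev = hi - lo
        if nlev == 0:
            continue
        cz = lvl_cz[lv]
        dbar = 0.0
        for a in range(lo, hi):
            i = lvl_beads[a]
            dx = x[i, 0]
            dy = x[i, 1]
            dz = x[i, 2] - cz
            dbar += np.sqrt(dx * dx + dy * dy + dz * dz)
        dbar /= nlev
        for a in range(lo, hi):
            i = lvl_beads[a]
            dx = x[i, 0]
            dy = x[i, 1]
            dz = x[i, 2] - cz
            di = np.sqrt(dx * dx + dy * dy + dz * dz)
            dd = di - dbar
            e_res += k_ring * dd * dd
            fm = -2.0 * k_ring * dd / di
            f[i, 0] += fm * dx
            f[i, 1] += fm * dy
            f[i, 2] += fm * dz

    # ---- weak center-of-mass z restraint on the ring ----
    if ring_beads.shape[0] > 0 and k_zcom > 0.0:
        zc = 0.0
        for a in range(ring_beads.shape[0]):
            zc += x[ring_beads[a], 2]
        zc /= ring_beads.shape[0]
        dz = zc - ring_zref
        e_res += k_zcom * ring_beads.shape[0] * dz * dz
        fm = -2.0 * k_zcom * dz
        for a in range(ring_beads.shape[0]):
            f[ring_beads[a], 2] += fm

    # ---- a-subunit anchors ----
    for a in range(anchor_beads.shape[0]):
        i = anchor_beads[a]
        dx = x[i, 0] - anchor_ref[a, 0]
        dy = x[i, 1] - anchor_ref[a, 1]
        dz = x[i, 2] - anchor_ref[a, 2]
        e_res += k_anchor * (dx * dx + dy * dy + dz * dz)
        f[i, 0] -= 2.0 * k_anchor * dx
        f[i, 1] -= 2.0 * k_anchor * dy
        f[i, 2] -= 2.0 * k_anchor * dz

    # ---- external torque (positive = hydrolysis = clockwise) ----
    if torque_kcal != 0.0 and torque_beads.shape[0] > 0:
        nt = torque_beads.shape[0]
        for a in range(nt):
            i = torque_beads[a]
            rho2 = x[i, 0] * x[i, 0] + x[i, 1] * x[i, 1]
            rho = np.sqrt(rho2)
            fm = torque_kcal / (nt * rho)
            # clockwise tangent = (y, -x)/rho
            f[i, 0] += fm * x[i, 1] / rho
            f[i, 1] += -fm * x[i, 0] / rho

    return e_non, e_coul, e_mem, e_res


@njit(cache=True, fastmath=True)
def _rebuild_ev(x, ev_pairs, ev_act, list_cut):
    n = 0
    c2 = list_cut * list_cut
    for p in range(ev_pairs.shape[0]):
        i = ev_pairs[p, 0]
        j = ev_pairs[p, 1]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        if dx * dx + dy * dy + dz * dz < c2:
            ev_act[n] = p
            n += 1
    return n


@njit(cache=True, fastmath=True)
def baoab_stage(x, v, nsteps, dt, gamma, kbt, mass, seed, rebuild_every,
                list_cut,
                bonds, bond_k, bond_r0,
                angles, angle_k, angle_t0,
                dihes, dihe_k1, dihe_k3, dihe_p0,
                contacts, con_eps, con_r0,
                ev_pairs, ev_sigma, ev_eps,
                q, cpairs, dielectric,
                mem_sites, mem_w, mem_nsc, mem_d, mem_eps,
                lvl_beads, lvl_ptr, lvl_cz, k_ring,
                ring_beads, ring_zref, k_zcom,
                anchor_beads, anchor_ref, k_anchor,
                torque_beads, torque_kcal):
    """Advance (x, v) in place by ``nsteps`` of BAOAB Langevin dynamics.

    gamma == 0 reduces exactly to velocity Verlet (NVE).  Returns
    (kinetic-energy sum over sampled steps, number of samples) so the caller
    can form a kinetic temperature without storing a trajectory.
    """
    np.random.seed(seed)
    n = x.shape[0]
    f = np.zeros((n, 3))
    ev_act = np.empty(ev_pairs.shape[0], dtype=np.int64)
    ev_n = _rebuild_ev(x, ev_pairs, ev_act, list_cut)
    _forces(x, f, bonds, bond_k, bond_r0, angles, angle_k, angle_t0,
            dihes, dihe_k1, dihe_k3, dihe_p0, contacts, con_eps, con_r0,
            ev_act, ev_n, ev_pairs, ev_sigma, ev_eps,
            q, cpairs, dielectric, mem_sites, mem_w, mem_nsc, mem_d, mem_eps,
            lvl_beads, lvl_ptr, lvl_cz, k_ring, ring_beads, ring_zref, k_zcom,
            anchor_beads, anchor_ref, k_anchor, torque_beads, torque_kcal)
    if gamma > 0.0:
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt((1.0 - c1 * c1) * kbt / mass)
    else:
        c1 = 1.0
        c2 = 0.0
    hdt = 0.5 * dt
    ke_sum = 0.0
    ke_n = 0
    for step in range(nsteps):
        # B
        for i in range(n):
            v[i, 0] += hdt * f[i, 0] / mass
            v[i, 1] += hdt * f[i, 1] / mass
            v[i, 2] += hdt * f[i, 2] / mass
        # A
        for i in range(n):
            x[i, 0] += hdt * v[i, 0]
            x[i, 1] += hdt * v[i, 1]
            x[i, 2] += hdt * v[i, 2]
        # O
        if gamma > 0.0:
            xi = np.random.standard_normal((n, 3))
            for i in range(n):
                v[i, 0] = c1 * v[i, 0] + c2 * xi[i, 0]
                v[i, 1] = c1 * v[i, 1] + c2 * xi[i, 1]
                v[i, 2] = c1 * v[i, 2] + c2 * xi[i, 2]
        # A
        for i in range(n):
            x[i, 0] += hdt * v[i, 0]
            x[i, 1] += hdt * v[i, 1]
            x[i, 2] += hdt * v[i, 2]
        if (step + 1) % rebuild_every == 0:
            ev_n = _rebuild_ev(x, ev_pairs, ev_act, list_cut)
        _forces(x, f, bonds, bond_k, bond_r0, angles, angle_k, angle_t0,
                dihes, dihe_k1, dihe_k3, dihe_p0, contacts, con_eps, con_r0,
                ev_act, ev_n, ev_pairs, ev_sigma, ev_eps,
                q, cpairs, dielectric, mem_sites, mem_w, mem_nsc, mem_d,
                mem_eps, lvl_beads, lvl_ptr, lvl_cz, k_ring,
                ring_beads, ring_zref, k_zcom,
                anchor_beads, anchor_ref, k_anchor, torque_beads, torque_kcal)
        # B
        ke = 0.0
        for i in range(n):
            v[i, 0] += hdt * f[i, 0] / mass
            v[i, 1] += hdt * f[i, 1] / mass
            v[i, 2] += hdt * f[i, 2] / mass
            ke += v[i, 0] * v[i, 0] + v[i, 1] * v[i, 1] + v[i, 2] * v[i, 2]
        ke_sum += 0.5 * mass * ke
        ke_n += 1
    return ke_sum, ke_n
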