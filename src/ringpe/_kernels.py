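"""Numba kernels for the production MD path.

These kernels assume the physical layout of a ring-PE system: the first
``n_mono`` particles form a closed ring (harmonic bonds + cosine bending
between consecutive triples); every particle takes part in the repulsive
LJ excluded volume and, if charged, in the Debye-Hueckel sum.

Neighbour search uses a cell list with a Verlet skin when the interaction
range is small against the box, and falls back to all pairs otherwise
(at very low salt the DH cutoff approaches L/2 and cells buy nothing).
The integrator is the BAOAB splitting of Langevin dynamics; with zero
friction it reduces exactly to velocity Verlet.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

#: Verlet skin added to the interaction range when building pair lists
DEFAULT_SKIN = 0.45


@njit(cache=True, inline="always")
def _min_image(x: float, L: float) -> float:
    return x - L * math.floor(x / L + 0.5)


@njit(cache=True, inline="always")
def _min_image_f(x: float, L: float, inv_l: float) -> float:
    return x - L * math.floor(x * inv_l + 0.5)


@njit(cache=True, fastmath=True)
def build_pairs(pos, L, r_list):
    """Half pair list (i < j) of particles closer than ``r_list``.

    Uses a linked cell list when at least 3 cells fit per box edge,
    otherwise enumerates all pairs.
    """
    n = pos.shape[0]
    ncell = int(L / r_list)
    r2max = r_list * r_list

    if ncell < 3 or n < 64:
        # all-pairs fallback
        cap = n * (n - 1) // 2
        pi = np.empty(cap, np.int64)
        pj = np.empty(cap, np.int64)
        m = 0
        for i in range(n - 1):
            for j in range(i + 1, n):
                dx = _min_image(pos[i, 0] - pos[j, 0], L)
                dy = _min_image(pos[i, 1] - pos[j, 1], L)
                dz = _min_image(pos[i, 2] - pos[j, 2], L)
                if dx * dx + dy * dy + dz * dz < r2max:
                    pi[m] = i
                    pj[m] = j
                    m += 1
        return pi[:m].copy(), pj[:m].copy()

    if ncell > 64:
        ncell = 64
    cell_w = L / ncell
    ncell3 = ncell * ncell * ncell
    head = np.full(ncell3, -1, np.int64)
    nxt = np.full(n, -1, np.int64)
    cx = np.empty(n, np.int64)
    cy = np.empty(n, np.int64)
    cz = np.empty(n, np.int64)
    for i in range(n):
        a = int((pos[i, 0] % L) / cell_w) % ncell
        b = int((pos[i, 1] % L) / cell_w) % ncell
        c = int((pos[i, 2] % L) / cell_w) % ncell
        cx[i], cy[i], cz[i] = a, b, c
        idx = (a * ncell + b) * ncell + c
        nxt[i] = head[idx]
        head[idx] = i

    # count pass
    total = 0
    for i in range(n):
        for ox in range(-1, 2):
            for oy in range(-1, 2):
                for oz in range(-1, 2):
                    a = (cx[i] + ox) % ncell
                    b = (cy[i] + oy) % ncell
                    c = (cz[i] + oz) % ncell
                    j = head[(a * ncell + b) * ncell + c]
                    while j >= 0:
                        if j > i:
                            dx = _min_image(pos[i, 0] - pos[j, 0], L)
                            dy = _min_image(pos[i, 1] - pos[j, 1], L)
                            dz = _min_image(pos[i, 2] - pos[j, 2], L)
                            if dx * dx + dy * dy + dz * dz < r2max:
                                total += 1
                        j = nxt[j]
    # fill pass
    pi = np.empty(total, np.int64)
    pj = np.empty(total, np.int64)
    m = 0
    for i in range(n):
        for ox in range(-1, 2):
            for oy in range(-1, 2):
                for oz in range(-1, 2):
                    a = (cx[i] + ox) % ncell
                    b = (cy[i] + oy) % ncell
                    c = (cz[i] + oz) % ncell
                    j = head[(a * ncell + b) * ncell + c]
                    while j >= 0:
                        if j > i:
                            dx = _min_image(pos[i, 0] - pos[j, 0], L)
                            dy = _min_image(pos[i, 1] - pos[j, 1], L)
                            dz = _min_image(pos[i, 2] - pos[j, 2], L)
                            if dx * dx + dy * dy + dz * dz < r2max:
                                pi[m] = i
                                pj[m] = j
                                m += 1
                        j = nxt[j]
    return pi, pj


# exp(-t) lookup for the DH sum, t in [0, 5] (r <= 5 lambda_D); third-order
# Taylor correction about the lower node keeps the relative error < 1e-13
_EXP_N = 4096
_EXP_DT = 5.0 / _EXP_N
_EXP_INV_DT = 1.0 / _EXP_DT
_EXP_TABLE = np.exp(-np.arange(_EXP_N + 4) * _EXP_DT)


@njit(cache=True, inline="always")
def _exp_neg(t: float) -> float:
    k = int(t * _EXP_INV_DT)
    d = t - k * _EXP_DT
    return _EXP_TABLE[k] * (1.0 - d * (1.0 - 0.5 * d * (1.0 - 0.3333333333333333 * d)))


@njit(cache=True, fastmath=True)
def compute_forces(pos, charges, n_mono, L,
                   eps, sigma, rc_lj, k_bond, r0, bend,
                   lam_b, lam_d, rc_dh, pi, pj, F):
    """Fill ``F`` with forces; return (e_lj, e_bond, e_angle, e_dh).

    Pair interactions run over the supplied half pair list; ring bonds
    and angles are implicit on the first ``n_mono`` particles.
    """
    n = pos.shape[0]
    for i in range(n):
        F[i, 0] = 0.0
        F[i, 1] = 0.0
        F[i, 2] = 0.0
    e_lj = 0.0
    e_dh = 0.0
    rc_lj2 = rc_lj * rc_lj
    rc_dh2 = rc_dh * rc_dh
    inv_ld = 1.0 / lam_d if lam_d > 0 and np.isfinite(lam_d) else 0.0

    for m in range(pi.shape[0]):
        i = pi[m]
        j = pj[m]
        dx = _min_image(pos[i, 0] - pos[j, 0], L)
        dy = _min_image(pos[i, 1] - pos[j, 1], L)
        dz = _min_image(pos[i, 2] - pos[j, 2], L)
        r2 = dx * dx + dy * dy + dz * dz
        f_over_r = 0.0
        if r2 < rc_lj2:
            inv_r2 = 1.0 / r2
            sr6 = (sigma * sigma * inv_r2) ** 3
            e_lj += 4.0 * eps * (sr6 * sr6 - sr6)
            f_over_r += 24.0 * eps * (2.0 * sr6 * sr6 - sr6) * inv_r2
        qq = charges[i] * charges[j]
        if qq != 0.0 and r2 < rc_dh2:
            r = math.sqrt(r2)
            e = lam_b * qq * _exp_neg(r * inv_ld) / r
            e_dh += e
            f_over_r += e * (1.0 / r + inv_ld) / r
        if f_over_r != 0.0:
            fx = f_over_r * dx
            fy = f_over_r * dy
            fz = f_over_r * dz
            F[i, 0] += fx
            F[i, 1] += fy
            F[i, 2] += fz
            F[j, 0] -= fx
            F[j, 1] -= fy
            F[j, 2] -= fz

    e_bond = 0.0
    e_angle = 0.0
    if n_mono >= 3:
        for i in range(n_mono):
            j = (i + 1) % n_mono
            dx = _min_image(pos[j, 0] - pos[i, 0], L)
            dy = _min_image(pos[j, 1] - pos[i, 1], L)
            dz = _min_image(pos[j, 2] - pos[i, 2], L)
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            e_bond += 0.5 * k_bond * (r - r0) ** 2
            fmag = -k_bond * (r - r0) / r  # along d, on j
            F[j, 0] += fmag * dx
            F[j, 1] += fmag * dy
            F[j, 2] += fmag * dz
            F[i, 0] -= fmag * dx
            F[i, 1] -= fmag * dy
            F[i, 2] -= fmag * dz
        if bend != 0.0:
            for jmid in range(n_mono):
                i = (jmid - 1) % n_mono
                k = (jmid + 1) % n_mono
                ax = _min_image(pos[i, 0] - pos[jmid, 0], L)
                ay = _min_image(pos[i, 1] - pos[jmid, 1], L)
                az = _min_image(pos[i, 2] - pos[jmid, 2], L)
                bx = _min_image(pos[k, 0] - pos[jmid, 0], L)
                by = _min_image(pos[k, 1] - pos[jmid, 1], L)
                bz = _min_image(pos[k, 2] - pos[jmid, 2], L)
                na = math.sqrt(ax * ax + ay * ay + az * az)
                nb = math.sqrt(bx * bx + by * by + bz * bz)
                inv_ab = 1.0 / (na * nb)
                ct = (ax * bx + ay * by + az * bz) * inv_ab
                if ct > 1.0:
                    ct = 1.0
                elif ct < -1.0:
                    ct = -1.0
                e_angle += bend * (1.0 + ct)
                inv_a2 = 1.0 / (na * na)
                inv_b2 = 1.0 / (nb * nb)
                fix = -bend * (bx * inv_ab - ct * ax * inv_a2)
                fiy = -bend * (by * inv_ab - ct * ay * inv_a2)
                fiz = -bend * (bz * inv_ab - ct * az * inv_a2)
                fkx = -bend * (ax * inv_ab - ct * bx * inv_b2)
                fky = -bend * (ay * inv_ab - ct * by * inv_b2)
                fkz = -bend * (az * inv_ab - ct * bz * inv_b2)
                F[i, 0] += fix
                F[i, 1] += fiy
                F[i, 2] += fiz
                F[k, 0] += fkx
                F[k, 1] += fky
                F[k, 2] += fkz
                F[jmid, 0] -= fix + fkx
                F[jmid, 1] -= fiy + fky
                F[jmid, 2] -= fiz + fkz
    return e_lj, e_bond, e_angle, e_dh


_SQRT12 = math.sqrt(12.0)
_INV_2_53 = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=True, inline="always")
def _xorshift(state):
    """xorshift64* step; returns (new_state, uniform in [0, 1))."""
    s = state
    s ^= s >> np.uint64(12)
    s ^= s << np.uint64(25)
    s ^= s >> np.uint64(27)
    x = s * np.uint64(2685821657736338717)
    return s, (x >> np.uint64(11)) * _INV_2_53


@njit(cache=True, fastmath=True)
def run_langevin(pos, vel, charges, n_mono, L,
                 dt, xi, temperature, n_steps, seed,
                 eps, sigma, rc_lj, k_bond, r0, bend,
                 lam_b, lam_d, rc_dh, skin):
    """Advance the system ``n_steps`` BAOAB steps in place.

    Returns (sum of kinetic energies over steps, e_lj, e_bond, e_angle,
    e_dh) with the potential terms taken at the final configuration.
    The pair list is rebuilt whenever any particle has moved more than
    skin/2 since the last build.

    Thermostat noise is a matched-variance uniform deviate from an
    inline xorshift64* stream; the OU velocity recursion averages over
    ~2/(xi dt) consecutive deviates, so stationary velocities are
    Gaussian to within an excess kurtosis of order xi dt.
    """
    n = pos.shape[0]
    # seed scrambling (splitmix-style) so nearby seeds give unrelated streams
    state = np.uint64(seed) * np.uint64(6364136223846793005) + np.uint64(1442695040888963407)
    for _ in range(4):
        state, _u = _xorshift(state)
    if state == np.uint64(0):
        state = np.uint64(88172645463325252)

    r_cut = rc_lj
    if rc_dh > r_cut:
        r_cut = rc_dh
    if r_cut > L / 2.0:
        r_cut = L / 2.0
    r_list = r_cut + skin
    pi, pj = build_pairs(pos, L, r_list)
    disp = np.zeros((n, 3))
    F = np.zeros((n, 3))
    e_lj, e_bond, e_angle, e_dh = compute_forces(
        pos, charges, n_mono, L, eps, sigma, rc_lj, k_bond, r0, bend,
        lam_b, lam_d, rc_dh, pi, pj, F)

    if xi > 0.0:
        c1 = math.exp(-xi * dt)
        c2 = math.sqrt(temperature * (1.0 - c1 * c1))
    else:
        c1 = 1.0
        c2 = 0.0
    half_dt = 0.5 * dt
    max_disp2 = (0.5 * skin) ** 2
    sum_ke = 0.0

    for _ in range(n_steps):
        # B (half kick) + A + O + A fused per particle
        needs_rebuild = False
        for i in range(n):
            for d in range(3):
                v = vel[i, d] + half_dt * F[i, d]
                step = half_dt * v
                if c2 > 0.0:
                    state, u = _xorshift(state)
                    v = c1 * v + c2 * _SQRT12 * (u - 0.5)
                step += half_dt * v
                vel[i, d] = v
                x = pos[i, d] + step
                pos[i, d] = x - L * math.floor(x / L)
                disp[i, d] += step
            if (disp[i, 0] ** 2 + disp[i, 1] ** 2 + disp[i, 2] ** 2) > max_disp2:
                needs_rebuild = True
        if needs_rebuild:
            pi, pj = build_pairs(pos, L, r_list)
            for i in range(n):
                disp[i, 0] = 0.0
                disp[i, 1] = 0.0
                disp[i, 2] = 0.0
        e_lj, e_bond, e_angle, e_dh = compute_forces(
            pos, charges, n_mono, L, eps, sigma, rc_lj, k_bond, r0, bend,
            lam_b, lam_d, rc_dh, pi, pj, F)
        ke = 0.0
        for i in range(n):
            for d in range(3):
                vel[i, d] += half_dt * F[i, d]
                ke += vel[i, d] * vel[i, d]
        sum_ke += 0.5 * ke
        if not np.isfinite(ke):
            return -1.0, e_lj, e_bond, e_angle, e_dh
    return sum_ke, e_lj, e_bond, e_angle, e_dh
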