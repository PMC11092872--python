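"""Numba-compiled inner loops for the minimal-model production runs.

The minimal model couples the box-spanning polymer (bond
addition/removal/kink moves) to a single-species lattice-gas bulk
(Metropolis spin flips).  The pure-Python engines implement the identical
move set and energies; these kernels exist so that the lattice sizes and
sweep counts of the production study conditions run in seconds rather
than hours.  Cross-agreement between kernel and pure-Python engines on
small systems is a tested invariant.

Chain representation: wrapped integer coordinates in fixed-capacity
arrays; entry 0 and entry n-1 both sit on the anchor site (the chain winds
once around the box in z).  ``N_p``, the number of distinct occupied
sites, is ``n - 1``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_DIRS = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                  [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=np.int64)


@njit(cache=True)
def _nn_poly(poly, L, i, j, k):
    c = 0
    c += poly[(i + 1) % L, j, k]
    c += poly[(i - 1) % L, j, k]
    c += poly[i, (j + 1) % L, k]
    c += poly[i, (j - 1) % L, k]
    c += poly[i, j, (k + 1) % L]
    c += poly[i, j, (k - 1) % L]
    return c


@njit(cache=True)
def _nn_gas(gas, L, i, j, k):
    c = 0
    c += gas[(i + 1) % L, j, k]
    c += gas[(i - 1) % L, j, k]
    c += gas[i, (j + 1) % L, k]
    c += gas[i, (j - 1) % L, k]
    c += gas[i, j, (k + 1) % L]
    c += gas[i, j, (k - 1) % L]
    return c


@njit(cache=True)
def _polymer_attempt(L, x, y, z, n, poly, gas, mu_p, v_p, j_int,
                     p_kink, n_max, n_min):
    """One bond-translation attempt.  Returns (new_n, accepted_kind).

    accepted_kind: -1 rejected, 0 addition, 1 removal, 2 kink.
    """
    N = n - 1  # distinct occupied sites
    p_add = (N + 2) / (2.0 * (1 + N)) * (1.0 - p_kink)
    p_rem = N / (2.0 * (1 + N)) * (1.0 - p_kink)
    u = np.random.random()
    if u < p_add:
        want = 0
    elif u < p_add + p_rem:
        want = 1
    else:
        want = 2

    nb = n - 1  # bonds
    jb = np.random.randint(0, nb)
    bx, by, bz = x[jb], y[jb], z[jb]
    cx, cy, cz = x[jb + 1], y[jb + 1], z[jb + 1]
    # bond axis from minimal-image difference
    dx0, dy0, dz0 = cx - bx, cy - by, cz - bz
    if dx0 > L // 2:
        dx0 -= L
    elif dx0 < -(L // 2):
        dx0 += L
    if dy0 > L // 2:
        dy0 -= L
    elif dy0 < -(L // 2):
        dy0 += L
    if dz0 > L // 2:
        dz0 -= L
    elif dz0 < -(L // 2):
        dz0 += L
    if dx0 != 0:
        axis = 0
    elif dy0 != 0:
        axis = 1
    else:
        axis = 2
    r = np.random.randint(0, 4)
    # the 4 direction indices excluding 2*axis and 2*axis+1
    di = r if r < 2 * axis else r + 2
    dxx, dyy, dzz = _DIRS[di, 0], _DIRS[di, 1], _DIRS[di, 2]

    tbx, tby, tbz = (bx + dxx) % L, (by + dyy) % L, (bz + dzz) % L
    tcx, tcy, tcz = (cx + dxx) % L, (cy + dyy) % L, (cz + dzz) % L

    hits_prev = False
    if jb >= 1:
        px, py, pz = x[jb - 1], y[jb - 1], z[jb - 1]
        if (px == tbx and py == tby and pz == tbz) or \
           (px == tcx and py == tcy and pz == tcz):
            hits_prev = True
    hits_next = False
    if jb + 2 < n:
        qx, qy, qz = x[jb + 2], y[jb + 2], z[jb + 2]
        if (qx == tbx and qy == tby and qz == tbz) or \
           (qx == tcx and qy == tcy and qz == tcz):
            hits_next = True

    if hits_prev and hits_next:
        kind = 1
    elif hits_prev or hits_next:
        kind = 2
    else:
        kind = 0
    if kind != want:
        return n, -1

    if kind == 0:  # addition of tb, tc between jb and jb+1
        if N + 2 >= n_max:
            return n, -1
        if poly[tbx, tby, tbz] == 1 or poly[tcx, tcy, tcz] == 1:
            return n, -1
        c1 = _nn_poly(poly, L, tbx, tby, tbz)
        c2 = _nn_poly(poly, L, tcx, tcy, tcz) + 1  # tb-tc bond
        dE = -2.0 * (mu_p + v_p) + v_p * (c1 + c2) \
            - j_int * (gas[tbx, tby, tbz] + gas[tcx, tcy, tcz])
        fwd = p_add / (4.0 * nb)
        rev = (N + 2) / (2.0 * (3 + N)) * (1.0 - p_kink) / (4.0 * (nb + 2))
        A = (rev / fwd) * np.exp(-dE)
        if A >= 1.0 or np.random.random() < A:
            for idx in range(n - 1, jb, -1):
                x[idx + 2] = x[idx]
                y[idx + 2] = y[idx]
                z[idx + 2] = z[idx]
            x[jb + 1], y[jb + 1], z[jb + 1] = tbx, tby, tbz
            x[jb + 2], y[jb + 2], z[jb + 2] = tcx, tcy, tcz
            poly[tbx, tby, tbz] = 1
            poly[tcx, tcy, tcz] = 1
            return n + 2, 0
        return n, -1

    if kind == 1:  # removal of monomers jb, jb+1
        if N - 2 < n_min:
            return n, -1
        cu = _nn_poly(poly, L, bx, by, bz)
        cv = _nn_poly(poly, L, cx, cy, cz)
        dE = 2.0 * (mu_p + v_p) - v_p * (cu + cv - 1) \
            + j_int * (gas[bx, by, bz] + gas[cx, cy, cz])
        fwd = p_rem / (4.0 * nb)
        rev = N / (2.0 * (N - 1)) * (1.0 - p_kink) / (4.0 * (nb - 2))
        A = (rev / fwd) * np.exp(-dE)
        if A >= 1.0 or np.random.random() < A:
            poly[bx, by, bz] = 0
            poly[cx, cy, cz] = 0
            for idx in range(jb, n - 2):
                x[idx] = x[idx + 2]
                y[idx] = y[idx + 2]
                z[idx] = z[idx + 2]
            return n - 2, 1
        return n, -1

    # kink: the monomer on the intersected side hops to the diagonal site
    if hits_prev:
        moved = jb
        tx, ty, tz = tcx, tcy, tcz
    else:
        moved = jb + 1
        tx, ty, tz = tbx, tby, tbz
    if moved == 0 or moved == n - 1:
        return n, -1  # pinned terminals never move
    if poly[tx, ty, tz] == 1:
        return n, -1
    ox, oy, oz = x[moved], y[moved], z[moved]
    dE = v_p * (_nn_poly(poly, L, tx, ty, tz) - _nn_poly(poly, L, ox, oy, oz)) \
        - j_int * (gas[tx, ty, tz] - gas[ox, oy, oz])
    if dE <= 0.0 or np.random.random() < np.exp(-dE):
        poly[ox, oy, oz] = 0
        poly[tx, ty, tz] = 1
        x[moved], y[moved], z[moved] = tx, ty, tz
        return n, 2
    return n, -1


@njit(cache=True)
def _gas_attempt(L, gas, poly, mu_b, j_bulk, j_int, ng):
    i = np.random.randint(0, L)
    j = np.random.randint(0, L)
    k = np.random.randint(0, L)
    base = -mu_b - j_bulk * _nn_gas(gas, L, i, j, k) - j_int * poly[i, j, k]
    if gas[i, j, k] == 1:
        dE = -base
        if dE <= 0.0 or np.random.random() < np.exp(-dE):
            gas[i, j, k] = 0
            return ng - 1, True
        return ng, False
    dE = base
    if dE <= 0.0 or np.random.random() < np.exp(-dE):
        gas[i, j, k] = 1
        return ng + 1, True
    return ng, False


@njit(cache=True)
def run_minimal(L, x, y, z, n, gas, mu_p, v_p, mu_b, j_bulk, j_int,
                p_kink, n_max, n_min, n_sweeps, n_equil, cadence, seed):
    """Interleaved polymer + lattice-gas sweeps with periodic measurement.

    One sweep = N_p polymer move attempts followed by L^3 spin-flip
    attempts.  Measurements (after ``n_equil`` sweeps, every ``cadence``)
    record sweep index, N_p, Rg^2 (contour-unwrapped), contact count, gas
    occupancy, on-polymer gas count and the on/off-polymer density
    difference.  Returns (table, n_final, acceptance counters).
    """
    np.random.seed(seed)
    poly = np.zeros((L, L, L), dtype=np.uint8)
    for idx in range(n - 1):  # anchor marked once
        poly[x[idx], y[idx], z[idx]] = 1
    ng = 0
    for i in range(L):
        for j in range(L):
            for k in range(L):
                ng += gas[i, j, k]

    n_meas = 0
    for s in range(n_sweeps):
        if s >= n_equil and (s - n_equil) % cadence == 0:
            n_meas += 1
    out = np.zeros((n_meas, 7))
    acc = np.zeros(4, dtype=np.int64)  # add, rem, kink, flip
    att = np.zeros(4, dtype=np.int64)

    m = 0
    vol = L * L * L
    for sweep in range(n_sweeps):
        n_att = n - 1
        for _ in range(n_att):
            n_new, kind = _polymer_attempt(L, x, y, z, n, poly, gas, mu_p,
                                           v_p, j_int, p_kink, n_max, n_min)
            att[0] += 1
            if kind >= 0:
                acc[kind] += 1
            n = n_new
        for _ in range(vol):
            ng, ok = _gas_attempt(L, gas, poly, mu_b, j_bulk, j_int, ng)
            att[3] += 1
            if ok:
                acc[3] += 1
        if sweep >= n_equil and (sweep - n_equil) % cadence == 0:
            # contacts over distinct sites
            contacts = 0
            for idx in range(n - 1):
                contacts += _nn_poly(poly, L, x[idx], y[idx], z[idx])
            contacts //= 2
            # unwrapped coordinates for Rg
            ux, uy, uz = float(x[0]), float(y[0]), float(z[0])
            pxs = np.zeros((n, 3))
            pxs[0, 0], pxs[0, 1], pxs[0, 2] = ux, uy, uz
            for idx in range(1, n):
                ddx = x[idx] - x[idx - 1]
                ddy = y[idx] - y[idx - 1]
                ddz = z[idx] - z[idx - 1]
                if ddx > L // 2:
                    ddx -= L
                elif ddx < -(L // 2):
                    ddx += L
                if ddy > L // 2:
                    ddy -= L
                elif ddy < -(L // 2):
                    ddy += L
                if ddz > L // 2:
                    ddz -= L
                elif ddz < -(L // 2):
                    ddz += L
                ux += ddx
                uy += ddy
                uz += ddz
                pxs[idx, 0], pxs[idx, 1], pxs[idx, 2] = ux, uy, uz
            mx = pxs[:, 0].mean()
            my = pxs[:, 1].mean()
            mz = pxs[:, 2].mean()
            rg2 = 0.0
            for idx in range(n):
                rg2 += ((pxs[idx, 0] - mx) ** 2 + (pxs[idx, 1] - my) ** 2
                        + (pxs[idx, 2] - mz) ** 2)
            rg2 /= n
            g_on = 0
            for idx in range(n - 1):
                g_on += gas[x[idx], y[idx], z[idx]]
            n_p = n - 1
            rho_on = g_on / n_p
            rho_far = (ng - g_on) / (vol - n_p)
            out[m, 0] = sweep
            out[m, 1] = n_p
            out[m, 2] = rg2
            out[m, 3] = contacts
            out[m, 4] = ng
            out[m, 5] = g_on
            out[m, 6] = rho_on - rho_far
            m += 1
    return out, n, acc, att
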