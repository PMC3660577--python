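"""Numba kernels for the triaxial closure solver.

The hot path of a trajectory is the closure solve (hundreds of thousands of
calls), so the grid scan, bisection refinement, solution reconstruction and
rebuild verification all run inside one compiled kernel.  The maths mirrors
the description in :mod:`kicloop.closure`; scalar helpers reimplement the
NeRF placement and dihedral formulas from :mod:`kicloop.geometry` (the
Python versions remain the reference implementation in tests).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_TAU_GRID = 512
_BISECT_ITERS = 52
MAX_SOLUTIONS = 16

_BOND_C_O = 1.231
_ANGLE_CA_C_O = 120.1
_DEG = 180.0 / np.pi


@njit(cache=True, inline="always")
def _dot(a, b):
    return a[0] * b[0] + a[1] * b[1] + a[2] * b[2]


@njit(cache=True, inline="always")
def _cross(a, b):
    out = np.empty(3)
    out[0] = a[1] * b[2] - a[2] * b[1]
    out[1] = a[2] * b[0] - a[0] * b[2]
    out[2] = a[0] * b[1] - a[1] * b[0]
    return out


@njit(cache=True, inline="always")
def _norm(a):
    return np.sqrt(_dot(a, a))


@njit(cache=True, inline="always")
def _unit(a):
    n = _norm(a)
    return a / n


@njit(cache=True)
def _place(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF placement; see geometry.place_atom."""
    ang = angle_deg / _DEG
    tor = torsion_deg / _DEG
    sa = np.sin(ang)
    d0 = -bond * np.cos(ang)
    d1 = bond * sa * np.cos(tor)
    d2 = -bond * sa * np.sin(tor)
    bc = _unit(c - b)
    n = _unit(_cross(b - a, bc))
    m = _cross(n, bc)
    out = np.empty(3)
    for k in range(3):
        out[k] = c[k] + bc[k] * d0 + m[k] * d1 + n[k] * d2
    return out


@njit(cache=True)
def _dihedral(p0, p1, p2, p3):
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = _cross(b0, b1)
    n2 = _cross(b1, b2)
    m1 = _cross(n1, b1 / _norm(b1))
    x = _dot(n1, n2)
    y = _dot(m1, n2)
    ang = np.arctan2(y, x) * _DEG
    return 180.0 - (180.0 - ang) % 360.0


@njit(cache=True, inline="always")
def _rot_about(axis, ang, v):
    """Rotate v about unit axis by ang (radians), Rodrigues."""
    c = np.cos(ang)
    s = np.sin(ang)
    d = _dot(axis, v)
    out = np.empty(3)
    out[0] = v[0] * c + (axis[1] * v[2] - axis[2] * v[1]) * s + axis[0] * d * (1.0 - c)
    out[1] = v[1] * c + (axis[2] * v[0] - axis[0] * v[2]) * s + axis[1] * d * (1.0 - c)
    out[2] = v[2] * c + (axis[0] * v[1] - axis[1] * v[0]) * s + axis[2] * d * (1.0 - c)
    return out


@njit(cache=True)
def _rotation_between(a, b):
    """3x3 matrix taking unit vector a to unit vector b."""
    v = _cross(a, b)
    c = _dot(a, b)
    R = np.empty((3, 3))
    if c < -1.0 + 1e-12:
        ref = np.zeros(3)
        ref[0] = 1.0
        axis = _cross(a, ref)
        if _norm(axis) < 1e-8:
            ref[0] = 0.0
            ref[1] = 1.0
            axis = _cross(a, ref)
        axis = _unit(axis)
        for i in range(3):
            for j in range(3):
                R[i, j] = 2.0 * axis[i] * axis[j] - (1.0 if i == j else 0.0)
        return R
    K = np.zeros((3, 3))
    K[0, 1], K[0, 2] = -v[2], v[1]
    K[1, 0], K[1, 2] = v[2], -v[0]
    K[2, 0], K[2, 1] = -v[1], v[0]
    KK = K @ K
    for i in range(3):
        for j in range(3):
            R[i, j] = (1.0 if i == j else 0.0) + K[i, j] + KK[i, j] / (1.0 + c)
    return R


@njit(cache=True)
def _cone_solve(A, B, C, sign):
    """alpha with A cos(alpha) + B sin(alpha) = C; nan if none."""
    hyp = np.hypot(A, B)
    if hyp < 1e-15:
        return np.nan
    ratio = C / hyp
    if ratio > 1.0 or ratio < -1.0:
        return np.nan
    return np.arctan2(B, A) + sign * np.arccos(ratio)


# packed-parameter layout for the scalarised residual (see kernel below):
# 0 n_hat, 3 c1_hat, 6 c2_hat, 9 vNs=N_s-P1, 12 vCe=C_e-P1, 15 P13=P3-P1,
# 18 wp1, 21 cxw1, 24 wp2, 27 cxw2, 30 w_Nm, 33 w_Ne (all 3-vectors);
# 36 w_par1, 37 w_par2, 38 |w_Cs|cos_ts, 39 |w_Cm|cos_tm, 40 cos_te,
# 41 1/|vNs|, 42 r1, 43 r2
_PP_LEN = 44


@njit(cache=True, inline="always")
def _rot_s(ax, ay, az, ct, st, vx, vy, vz):
    """Rotate (vx,vy,vz) about unit axis (ax,ay,az); ct/st = cos/sin angle."""
    d = ax * vx + ay * vy + az * vz
    ox = vx * ct + (ay * vz - az * vy) * st + ax * d * (1.0 - ct)
    oy = vy * ct + (az * vx - ax * vz) * st + ay * d * (1.0 - ct)
    oz = vz * ct + (ax * vy - ay * vx) * st + az * d * (1.0 - ct)
    return ox, oy, oz


@njit(cache=True, inline="always")
def _cone_solve_s(A, B, C, sign):
    hyp = np.hypot(A, B)
    if hyp < 1e-15:
        return np.nan
    ratio = C / hyp
    if ratio > 1.0 or ratio < -1.0:
        return np.nan
    return np.arctan2(B, A) + sign * np.arccos(ratio)


@njit(cache=True)
def _residual_fast(tau, s1, s2, pp):
    """Scalarised residual of the last pivot's constraint; (g, a1, a2)."""
    ct = np.cos(tau)
    st = -np.sin(tau)  # rotation by -tau
    u0x, u0y, u0z = _rot_s(pp[0], pp[1], pp[2], ct, st, pp[9], pp[10], pp[11])
    inv = pp[41]
    u0x *= inv
    u0y *= inv
    u0z *= inv
    A = u0x * pp[18] + u0y * pp[19] + u0z * pp[20]
    B = u0x * pp[21] + u0y * pp[22] + u0z * pp[23]
    C = pp[38] - pp[36] * (u0x * pp[3] + u0y * pp[4] + u0z * pp[5])
    a1 = _cone_solve_s(A, B, C, s1)
    if np.isnan(a1):
        return np.nan, np.nan, np.nan
    c1 = np.cos(a1)
    sn1 = np.sin(a1)
    nmx, nmy, nmz = _rot_s(pp[3], pp[4], pp[5], c1, sn1, pp[30], pp[31], pp[32])
    # u1 = rot(w_Nm) - r1 * c1_hat, normalised
    u1x = nmx - pp[42] * pp[3]
    u1y = nmy - pp[42] * pp[4]
    u1z = nmz - pp[42] * pp[5]
    inv1 = 1.0 / np.sqrt(u1x * u1x + u1y * u1y + u1z * u1z)
    u1x *= inv1
    u1y *= inv1
    u1z *= inv1
    A2 = u1x * pp[24] + u1y * pp[25] + u1z * pp[26]
    B2 = u1x * pp[27] + u1y * pp[28] + u1z * pp[29]
    C2 = pp[39] - pp[37] * (u1x * pp[6] + u1y * pp[7] + u1z * pp[8])
    a2 = _cone_solve_s(A2, B2, C2, s2)
    if np.isnan(a2):
        return np.nan, np.nan, np.nan
    c2 = np.cos(a2)
    sn2 = np.sin(a2)
    nex, ney, nez = _rot_s(pp[6], pp[7], pp[8], c2, sn2, pp[33], pp[34], pp[35])
    vex = nex - pp[43] * pp[6]
    vey = ney - pp[43] * pp[7]
    vez = nez - pp[43] * pp[8]
    dex, dey, dez = _rot_s(pp[0], pp[1], pp[2], ct, st, pp[12], pp[13], pp[14])
    dex -= pp[15]
    dey -= pp[16]
    dez -= pp[17]
    dot = vex * dex + vey * dey + vez * dez
    nv = np.sqrt(vex * vex + vey * vey + vez * vez)
    nd = np.sqrt(dex * dex + dey * dey + dez * dez)
    return dot / (nv * nd) - pp[40], a1, a2


@njit(cache=True)
def _body_atoms(first, last, phi, psi, omega, theta,
                b_nca, b_cac, b_cn, a_cacn, a_cnca):
    """Local coordinates of the rigid piece CA(first)..CA(last).

    Returns (L, 3, 3): per residue first..last the N, CA, C positions
    (N of ``first`` and C of ``last`` are unused and left at zero).
    """
    L = last - first + 1
    out = np.zeros((L, 3, 3))
    f = first - 1
    # seed: CA(first) at origin, C(first) on x, N(first+1) in the xy-plane
    out[0, 2, 0] = b_cac[f]
    ang = a_cacn[f] / _DEG
    out[1, 0, 0] = out[0, 2, 0] - b_cn[f] * np.cos(ang)
    out[1, 0, 1] = b_cn[f] * np.sin(ang)
    for resi in range(first + 1, last + 1):
        i = resi - 1
        k = resi - first
        out[k, 1] = _place(out[k - 1, 1], out[k - 1, 2], out[k, 0],
                           b_nca[i], a_cnca[i], omega[i])
        if resi == last:
            break
        out[k, 2] = _place(out[k - 1, 2], out[k, 0], out[k, 1],
                           b_cac[i], theta[i], phi[i])
        out[k + 1, 0] = _place(out[k, 0], out[k, 1], out[k, 2],
                               b_cn[i], a_cacn[i], psi[i])
    return out


@njit(cache=True)
def solve_closure_kernel(s, m, e, coords, phi, psi, omega, theta,
                         b_nca, b_cac, b_cn, a_cacn, a_cnca, anchor_tol):
    """Full triaxial solve for pivots (s, m, e), 1-based.

    Returns (pivot torsions (16, 6), rebuilt coords (16, L, 4, 3),
    n_solutions, status) where status is 0 on a regular solve and 1 when the
    geometry was degenerate/infeasible (empty solution set).
    """
    L = e - s + 1
    torsions = np.zeros((MAX_SOLUTIONS, 6))
    sol_coords = np.zeros((MAX_SOLUTIONS, L, 4, 3))
    # --- anchors from the flanking residues
    N_s = _place(coords[s - 2, 0], coords[s - 2, 1], coords[s - 2, 2],
                 b_cn[s - 2], a_cacn[s - 2], psi[s - 2])
    CA_s = _place(coords[s - 2, 1], coords[s - 2, 2], N_s,
                  b_nca[s - 1], a_cnca[s - 1], omega[s - 1])
    C_e = _place(coords[e, 2], coords[e, 1], coords[e, 0],
                 b_cn[e - 1], a_cnca[e], phi[e])
    CA_e = _place(coords[e, 1], coords[e, 0], C_e,
                  b_cac[e - 1], a_cacn[e - 1], omega[e])
    # --- rigid bodies and the pivot triangle
    body1 = _body_atoms(s, m, phi, psi, omega, theta,
                        b_nca, b_cac, b_cn, a_cacn, a_cnca)
    body2 = _body_atoms(m, e, phi, psi, omega, theta,
                        b_nca, b_cac, b_cn, a_cacn, a_cnca)
    ch1 = body1[m - s, 1] - body1[0, 1]
    ch2 = body2[e - m, 1] - body2[0, 1]
    r1 = _norm(ch1)
    r2 = _norm(ch2)
    P1 = CA_s
    P3 = CA_e
    r3 = _norm(P3 - P1)
    if r3 < 1e-6:
        return torsions, sol_coords, 0, 1
    h = (r1 * r1 - r2 * r2 + r3 * r3) / (2.0 * r3)
    rc_sq = r1 * r1 - h * h
    if rc_sq <= 1e-12:
        return torsions, sol_coords, 0, 1
    rc = np.sqrt(rc_sq)
    n_hat = (P3 - P1) / r3
    seed = np.zeros(3)
    if abs(n_hat[0]) > 0.9:
        seed[1] = 1.0
    else:
        seed[0] = 1.0
    u = _unit(seed - _dot(seed, n_hat) * n_hat)
    CM0 = P1 + h * n_hat + rc * u
    c1_hat = (CM0 - P1) / r1
    c2_hat = (P3 - CM0) / r2
    R01 = _rotation_between(ch1 / r1, c1_hat)
    R02 = _rotation_between(ch2 / r2, c2_hat)
    w_Cs = R01 @ body1[0, 2]
    w_Nm = R01 @ body1[m - s, 0]
    w_Cm = R02 @ body2[0, 2]
    w_Ne = R02 @ body2[e - m, 0]
    cos_ts = np.cos(theta[s - 1] / _DEG)
    cos_tm = np.cos(theta[m - 1] / _DEG)
    cos_te = np.cos(theta[e - 1] / _DEG)

    # pack the per-problem constants for the scalarised residual
    pp = np.empty(_PP_LEN)
    w_par1 = _dot(w_Cs, c1_hat)
    wp1 = w_Cs - w_par1 * c1_hat
    cxw1 = _cross(c1_hat, wp1)
    w_par2 = _dot(w_Cm, c2_hat)
    wp2 = w_Cm - w_par2 * c2_hat
    cxw2 = _cross(c2_hat, wp2)
    vNs = N_s - P1
    for k in range(3):
        pp[0 + k] = n_hat[k]
        pp[3 + k] = c1_hat[k]
        pp[6 + k] = c2_hat[k]
        pp[9 + k] = vNs[k]
        pp[12 + k] = C_e[k] - P1[k]
        pp[15 + k] = P3[k] - P1[k]
        pp[18 + k] = wp1[k]
        pp[21 + k] = cxw1[k]
        pp[24 + k] = wp2[k]
        pp[27 + k] = cxw2[k]
        pp[30 + k] = w_Nm[k]
        pp[33 + k] = w_Ne[k]
    pp[36] = w_par1
    pp[37] = w_par2
    pp[38] = _norm(w_Cs) * cos_ts
    pp[39] = _norm(w_Cm) * cos_tm
    pp[40] = cos_te
    pp[41] = 1.0 / _norm(vNs)
    pp[42] = r1
    pp[43] = r2

    # --- grid scan + bisection per branch combination
    two_pi = 2.0 * np.pi
    step = two_pi / _TAU_GRID
    n_found = 0
    gvals = np.empty(_TAU_GRID)
    phi_l = phi.copy()
    psi_l = psi.copy()
    for bi in range(4):
        s1 = 1.0 if bi < 2 else -1.0
        s2 = 1.0 if bi % 2 == 0 else -1.0
        for k in range(_TAU_GRID):
            g, _, _ = _residual_fast(k * step, s1, s2, pp)
            gvals[k] = g
        n_cand = 0
        cand = np.empty(2 * _TAU_GRID)
        for k in range(_TAU_GRID):
            g0 = gvals[k]
            g1 = gvals[(k + 1) % _TAU_GRID]
            d0 = np.isfinite(g0)
            d1 = np.isfinite(g1)
            if d0 and d1 and g0 != 0.0 and (g0 > 0) != (g1 > 0):
                # ordinary bracket: bisect the sign change
                lo = k * step
                hi = lo + step
                glo = g0
                for _ in range(_BISECT_ITERS):
                    mid = 0.5 * (lo + hi)
                    gm, _, _ = _residual_fast(mid, s1, s2, pp)
                    if not np.isfinite(gm):
                        break
                    if (gm > 0) == (glo > 0):
                        lo = mid
                        glo = gm
                    else:
                        hi = mid
                cand[n_cand] = 0.5 * (lo + hi)
                n_cand += 1
            elif d0 != d1:
                # branch endpoint inside the cell: a cone equation becomes
                # tangent here and a root can sit at/near the boundary.
                # Locate the boundary by bisecting on definedness, then
                # check the defined-side residual.
                lo = k * step
                hi = lo + step
                for _ in range(_BISECT_ITERS):
                    mid = 0.5 * (lo + hi)
                    gm, _, _ = _residual_fast(mid, s1, s2, pp)
                    if np.isfinite(gm) == d0:
                        lo = mid
                    else:
                        hi = mid
                tb = lo if d0 else hi
                gb, _, _ = _residual_fast(tb, s1, s2, pp)
                if not np.isfinite(gb):
                    continue
                gref = g0 if d0 else g1
                tref = k * step if d0 else (k + 1) * step
                if gref != 0.0 and (gb > 0) != (gref > 0):
                    lo2 = tb
                    hi2 = tref
                    glo2 = gb
                    for _ in range(_BISECT_ITERS):
                        mid = 0.5 * (lo2 + hi2)
                        gm, _, _ = _residual_fast(mid, s1, s2, pp)
                        if not np.isfinite(gm):
                            break
                        if (gm > 0) == (glo2 > 0):
                            lo2 = mid
                            glo2 = gm
                        else:
                            hi2 = mid
                    cand[n_cand] = 0.5 * (lo2 + hi2)
                    n_cand += 1
                elif abs(gb) < 1e-9:
                    cand[n_cand] = tb
                    n_cand += 1
        for ci in range(n_cand):
            tau = cand[ci]
            g, a1, a2 = _residual_fast(tau, s1, s2, pp)
            if not np.isfinite(g) or abs(g) > 1e-7:
                continue
            # --- atoms needed for the six pivot torsions, in the lab frame
            # body1 atom -> P1 + rot(n_hat, tau, rot(c1_hat, a1, R01 x) )
            # body2 atom -> P1 + rot(n_hat, tau, CM0 + rot(c2_hat, a2, R02 x) - P1)
            C_s_lab = P1 + _rot_about(n_hat, tau, _rot_about(c1_hat, a1, R01 @ body1[0, 2]))
            N_s1_lab = P1 + _rot_about(n_hat, tau, _rot_about(c1_hat, a1, R01 @ body1[1, 0]))
            C_m1_lab = P1 + _rot_about(n_hat, tau, _rot_about(c1_hat, a1, R01 @ body1[m - s - 1, 2]))
            N_m_lab = P1 + _rot_about(n_hat, tau, _rot_about(c1_hat, a1, R01 @ body1[m - s, 0]))
            CA_m_lab = P1 + _rot_about(n_hat, tau, CM0 - P1)
            C_m_lab = P1 + _rot_about(n_hat, tau, CM0 + _rot_about(c2_hat, a2, R02 @ body2[0, 2]) - P1)
            N_m1_lab = P1 + _rot_about(n_hat, tau, CM0 + _rot_about(c2_hat, a2, R02 @ body2[1, 0]) - P1)
            C_e1_lab = P1 + _rot_about(n_hat, tau, CM0 + _rot_about(c2_hat, a2, R02 @ body2[e - m - 1, 2]) - P1)
            N_e_lab = P1 + _rot_about(n_hat, tau, CM0 + _rot_about(c2_hat, a2, R02 @ body2[e - m, 0]) - P1)
            piv = np.empty(6)
            piv[0] = _dihedral(coords[s - 2, 2], N_s, CA_s, C_s_lab)
            piv[1] = _dihedral(N_s, CA_s, C_s_lab, N_s1_lab)
            piv[2] = _dihedral(C_m1_lab, N_m_lab, CA_m_lab, C_m_lab)
            piv[3] = _dihedral(N_m_lab, CA_m_lab, C_m_lab, N_m1_lab)
            piv[4] = _dihedral(C_e1_lab, N_e_lab, CA_e, C_e)
            piv[5] = _dihedral(N_e_lab, CA_e, C_e, coords[e, 0])
            # --- dedupe against already accepted roots
            dup = False
            for q in range(n_found):
                worst = 0.0
                for t in range(6):
                    d = abs(180.0 - (180.0 - (piv[t] - torsions[q, t])) % 360.0)
                    if d > worst:
                        worst = d
                if worst < 1e-3:
                    dup = True
                    break
            if dup:
                continue
            # --- honest verification: rebuild the sub-segment from internal
            # coordinates with the solved pivots and check the anchors
            phi_l[s - 1], psi_l[s - 1] = piv[0], piv[1]
            phi_l[m - 1], psi_l[m - 1] = piv[2], piv[3]
            phi_l[e - 1], psi_l[e - 1] = piv[4], piv[5]
            pN = coords[s - 2, 0].copy()
            pCA = coords[s - 2, 1].copy()
            pC = coords[s - 2, 2].copy()
            reb = np.zeros((L, 4, 3))
            ok = True
            for resi in range(s, e + 1):
                i = resi - 1
                k2 = resi - s
                Ni = _place(pN, pCA, pC, b_cn[i - 1], a_cacn[i - 1], psi_l[i - 1])
                CAi = _place(pCA, pC, Ni, b_nca[i], a_cnca[i], omega[i])
                Ci = _place(pC, Ni, CAi, b_cac[i], theta[i], phi_l[i])
                reb[k2, 0] = Ni
                reb[k2, 1] = CAi
                reb[k2, 2] = Ci
                pN, pCA, pC = Ni, CAi, Ci
            N_next = _place(pN, pCA, pC, b_cn[e - 1], a_cacn[e - 1], psi_l[e - 1])
            CA_next = _place(pCA, pC, N_next, b_nca[e], a_cnca[e], omega[e])
            C_next = _place(pC, N_next, CA_next, b_cac[e], theta[e], phi[e])
            dev = _norm(N_next - coords[e, 0])
            d2 = _norm(CA_next - coords[e, 1])
            d3 = _norm(C_next - coords[e, 2])
            if d2 > dev:
                dev = d2
            if d3 > dev:
                dev = d3
            if dev > anchor_tol:
                continue
            # carbonyl oxygens in the peptide plane
            for resi in range(s, e + 1):
                k2 = resi - s
                if resi < e:
                    nextN = reb[k2 + 1, 0]
                else:
                    nextN = coords[e, 0]
                reb[k2, 3] = _place(nextN, reb[k2, 1], reb[k2, 2],
                                    _BOND_C_O, _ANGLE_CA_C_O, 180.0)
            torsions[n_found] = piv
            sol_coords[n_found] = reb
            n_found += 1
            if n_found == MAX_SOLUTIONS:
                return torsions, sol_coords, n_found, 0
    return torsions, sol_coords, n_found, 0


@njit(cache=True)
def repulsive_kernel(coords, s, e, radii, scale, env_xyz, env_rad, k_rep):
    """Soft-sphere repulsion of segment s..e (1-based) vs non-adjacent
    residues and environment spheres; segment-internal pairs counted once."""
    n = coords.shape[0]
    total = 0.0
    for i in range(s - 1, e):
        for ai in range(4):
            xi = coords[i, ai, 0]
            yi = coords[i, ai, 1]
            zi = coords[i, ai, 2]
            ri = radii[ai] * scale
            for j in range(n):
                if j - i < 2 and i - j < 2:
                    continue
                factor = 0.5 if (s - 1 <= j < e) else 1.0
                for aj in range(4):
                    rsum = ri + radii[aj] * scale
                    dx = xi - coords[j, aj, 0]
                    dy = yi - coords[j, aj, 1]
                    dz = zi - coords[j, aj, 2]
                    d2 = dx * dx + dy * dy + dz * dz
                    if d2 < rsum * rsum:
                        d = np.sqrt(d2)
                        t = 1.0 - d / rsum
                        total += factor * k_rep * t * t
            for mI in range(env_xyz.shape[0]):
                rsum = ri + env_rad[mI] * scale
                dx = xi - env_xyz[mI, 0]
                dy = yi - env_xyz[mI, 1]
                dz = zi - env_xyz[mI, 2]
                d2 = dx * dx + dy * dy + dz * dz
                if d2 < rsum * rsum:
                    d = np.sqrt(d2)
                    t = 1.0 - d / rsum
                    total += k_rep * t * t
    return total


@njit(cache=True)
def bump_kernel(seg_xyz, coords, s, e, radii, env_xyz, env_rad, factor):
    """True if any (moved sub-segment atom, non-adjacent backbone atom or
    environment sphere) pair violates d^2 >= factor * (r1+r2)^2.

    seg_xyz: (L*4, 3) moved coordinates of residues s..e (1-based).
    """
    n = coords.shape[0]
    L4 = seg_xyz.shape[0]
    for p in range(L4):
        i = s - 1 + p // 4
        ai = p % 4
        ri = radii[ai]
        xi = seg_xyz[p, 0]
        yi = seg_xyz[p, 1]
        zi = seg_xyz[p, 2]
        for j in range(n):
            if j - i < 2 and i - j < 2:
                continue
            in_seg = s - 1 <= j < e
            for aj in range(4):
                rsum = ri + radii[aj]
                if in_seg:
                    q = (j - (s - 1)) * 4 + aj
                    dx = xi - seg_xyz[q, 0]
                    dy = yi - seg_xyz[q, 1]
                    dz = zi - seg_xyz[q, 2]
                else:
                    dx = xi - coords[j, aj, 0]
                    dy = yi - coords[j, aj, 1]
                    dz = zi - coords[j, aj, 2]
                d2 = dx * dx + dy * dy + dz * dz
                if d2 < factor * rsum * rsum:
                    return True
        for mI in range(env_xyz.shape[0]):
            rsum = ri + env_rad[mI]
            dx = xi - env_xyz[mI, 0]
            dy = yi - env_xyz[mI, 1]
            dz = zi - env_xyz[mI, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < factor * rsum * rsum:
                return True
    return False
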