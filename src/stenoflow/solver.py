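"""Explicit 1D pulse-wave solver for the arterial tree.

Numerics
--------
The 1D continuity / momentum system

    dA/dt + dQ/dx = 0
    dQ/dt + d(Q^2/A)/dx + (A/rho) dP/dx = f,   f = -2(gamma_v+2) pi mu Q/(rho A)

is advanced with a two-step MacCormack predictor-corrector
(Lax-Wendroff class, second order, CFL-limited).  The wall law is the
Langewouters arctangent relation evaluated per node; an optional
Kelvin-Voigt term adds ``visc * (dA/dt)/A`` to the elastic pressure.

Boundaries are coupled through linearized characteristics:

* branch junctions enforce exact flow conservation and continuity of
  total pressure P + rho u^2 / 2, solved per step by a local Newton
  iteration;
* terminal segments end in three-element Windkessels;
* the root is driven either by a prescribed inflow waveform or by the
  left ventricle through the dynamic stenotic-valve model.

Everything inside the time loop is numba-compiled and runs in CGS
units; the :class:`Engine` wrapper converts from/to clinical units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .network import ArterialTree, amax_from_reference
from .units import MMHG, MU_BLOOD, RHO_BLOOD

# status codes returned by the kernel
OK = 0
ERR_CFL = 1
ERR_AREA = 2
ERR_JUNCTION = 3

#: default velocity-profile parameter (Womersley-like flat profile);
#: gamma_v = 2 recovers Poiseuille friction
GAMMA_V = 9.0


# ----------------------------------------------------------------------
# low-level wall-law helpers (CGS, njit so the kernel can inline them)
# ----------------------------------------------------------------------
@njit(cache=True, inline="always")
def _lang_area(p, amax, p0, p1):
    return amax * (0.5 + np.arctan((p - p0) / p1) / np.pi)


@njit(cache=True, inline="always")
def _lang_pressure(a, amax, p0, p1):
    return p0 + p1 * np.tan(np.pi * (a / amax - 0.5))


@njit(cache=True, inline="always")
def _lang_dadp(p, amax, p0, p1):
    xi = (p - p0) / p1
    return amax / (np.pi * p1 * (1.0 + xi * xi))


@njit(cache=True, inline="always")
def _wave_speed(a, amax, p0, p1, rho):
    # c^2 = A/(rho dA/dP), evaluated at the pressure implied by A
    p = _lang_pressure(a, amax, p0, p1)
    return np.sqrt(a / (rho * _lang_dadp(p, amax, p0, p1)))


@njit(cache=True)
def _solve_linear(M, b, n):
    """Gaussian elimination with partial pivoting, solution left in b (n <= 4)."""
    for col in range(n):
        piv = col
        best = abs(M[col, col])
        for r in range(col + 1, n):
            if abs(M[r, col]) > best:
                best = abs(M[r, col])
                piv = r
        if best == 0.0:
            return False
        if piv != col:
            for c in range(n):
                tmp = M[col, c]
                M[col, c] = M[piv, c]
                M[piv, c] = tmp
            tmp = b[col]
            b[col] = b[piv]
            b[piv] = tmp
        for r in range(col + 1, n):
            fac = M[r, col] / M[col, col]
            for c in range(col, n):
                M[r, c] -= fac * M[col, c]
            b[r] -= fac * b[col]
    for r in range(n - 1, -1, -1):
        s = b[r]
        for c in range(r + 1, n):
            s -= M[r, c] * b[c]
        b[r] = s / M[r, r]
    return True


# ----------------------------------------------------------------------
# exact Riemann invariants for the arctangent wall law
#
# The invariant increment is dW = u +- (c/A) dA.  For the Langewouters
# law, (c/A) dA = sqrt(pi*P1/rho) * da / (sqrt(a) * sin(pi*a)) with
# a = A/Amax, so W = u +- s*PHI(a) where s = sqrt(pi*P1/rho) and PHI is
# a universal shape function tabulated once below.
# ----------------------------------------------------------------------
def _build_phi_table(n_grid: int = 4096, n_fine: int = 200001):
    a_fine = np.linspace(0.004, 0.996, n_fine)
    integrand = 1.0 / (np.sqrt(a_fine) * np.sin(np.pi * a_fine))
    from scipy.integrate import cumulative_trapezoid
    cum = cumulative_trapezoid(integrand, a_fine, initial=0.0)
    cum -= np.interp(0.5, a_fine, cum)  # PHI(1/2) = 0
    grid = np.linspace(0.005, 0.995, n_grid)
    return grid, np.interp(grid, a_fine, cum)

_PHI_GRID, _PHI_VAL = _build_phi_table()
_PHI_A0 = float(_PHI_GRID[0])
_PHI_DA = float(_PHI_GRID[1] - _PHI_GRID[0])


@njit(cache=True, inline="always")
def _phi(a):
    """Shape function PHI(a) of the exact invariant (linear interpolation)."""
    x = (a - _PHI_A0) / _PHI_DA
    if x <= 0.0:
        return _PHI_VAL[0]
    n = _PHI_VAL.shape[0]
    if x >= n - 1:
        return _PHI_VAL[n - 1]
    i = int(x)
    f = x - i
    return (1.0 - f) * _PHI_VAL[i] + f * _PHI_VAL[i + 1]


@njit(cache=True)
def _junction_newton(wp, sp_, amax_p, p0_p, p1_p,
                     wc, sc_, amax_c, p0_c, p1_c, nchild,
                     a_init_p, a_init_c, rho, maxit):
    """Solve one junction with exact characteristic closures.

    Unknowns: the areas at the parent end and child starts.  Closures:
        u_p = wp - s_p*PHI(a_p)      (forward invariant from the parent)
        u_j = wc_j + s_j*PHI(a_j)    (backward invariant from child j)
    Equations: exact mass conservation A_p u_p = sum A_j u_j and
    continuity of total pressure P + rho u^2/2, Newton-iterated to
    1e-10 relative with damped steps.
    Returns (ok, A_p, A_c[3], u_p, u_c[3]).
    """
    n = nchild + 1
    x = np.empty(4)
    x[0] = a_init_p
    for j in range(nchild):
        x[1 + j] = a_init_c[j]
    M = np.empty((4, 4))
    b = np.empty(4)
    uc = np.empty(3)
    for _ in range(maxit):
        ap = x[0]
        up = wp - sp_ * _phi(ap / amax_p)
        pp = _lang_pressure(ap, amax_p, p0_p, p1_p)
        cp = _wave_speed(ap, amax_p, p0_p, p1_p, rho)
        r0 = ap * up
        for j in range(nchild):
            aj = x[1 + j]
            uc[j] = wc[j] + sc_[j] * _phi(aj / amax_c[j])
            r0 -= aj * uc[j]
        b[0] = -r0
        delta_ok = abs(r0) < 1e-10 * (abs(ap * up) + 1.0)
        for j in range(nchild):
            aj = x[1 + j]
            pj = _lang_pressure(aj, amax_c[j], p0_c[j], p1_c[j])
            rj = pp + 0.5 * rho * up * up - pj - 0.5 * rho * uc[j] * uc[j]
            b[1 + j] = -rj
            if abs(rj) >= 1e-10 * (abs(pp) + 1.0):
                delta_ok = False
        if delta_ok:
            return True, x[0], x[1], x[2], x[3], up, uc[0], uc[1], uc[2]
        # Jacobian: du_p/dA_p = -c_p/A_p, du_j/dA_j = +c_j/A_j
        for r in range(4):
            for c in range(4):
                M[r, c] = 0.0
        M[0, 0] = up - cp
        dpp = 1.0 / _lang_dadp(pp, amax_p, p0_p, p1_p)
        for j in range(nchild):
            aj = x[1 + j]
            cj = _wave_speed(aj, amax_c[j], p0_c[j], p1_c[j], rho)
            pj = _lang_pressure(aj, amax_c[j], p0_c[j], p1_c[j])
            dpj = 1.0 / _lang_dadp(pj, amax_c[j], p0_c[j], p1_c[j])
            M[0, 1 + j] = -(uc[j] + cj)
            M[1 + j, 0] = dpp - rho * up * cp / ap
            M[1 + j, 1 + j] = -dpj - rho * uc[j] * cj / aj
        if not _solve_linear(M, b, n):
            return False, x[0], x[1], x[2], x[3], 0.0, 0.0, 0.0, 0.0
        # damped update keeping areas in the valid wall-law range
        scale = 1.0
        for _try in range(12):
            ok = 0.015 * amax_p < x[0] + scale * b[0] < 0.985 * amax_p
            if ok:
                for j in range(nchild):
                    aj = x[1 + j] + scale * b[1 + j]
                    if not (0.015 * amax_c[j] < aj < 0.985 * amax_c[j]):
                        ok = False
                        break
            if ok:
                break
            scale *= 0.5
        x[0] += scale * b[0]
        for j in range(nchild):
            x[1 + j] += scale * b[1 + j]
    return False, x[0], x[1], x[2], x[3], 0.0, 0.0, 0.0, 0.0


@njit(cache=True)
def _terminal_flux_newton(q0, a_t, flast, alpha, amax_t, p0_t, p1_t,
                          pc, r1, r2, ct, dt, maxit):
    """Terminal flux against the three-element Windkessel.

    Solves g(Q) = P_wall(A + alpha (F_last - Q)) - Pc'(Q) - Q R1 = 0
    with the compartment pressure advanced implicitly,
    Pc' = (Pc + dt Q/Ct)/(1 + dt/(R2 Ct)).  Returns (ok, Q, Pc').
    """
    gamma = (dt / ct) / (1.0 + dt / (r2 * ct))
    q = q0
    for _ in range(maxit):
        a = a_t + alpha * (flast - q)
        if a < 0.02 * amax_t or a > 0.98 * amax_t:
            return False, q, pc
        p = _lang_pressure(a, amax_t, p0_t, p1_t)
        pc_new = (pc + dt * q / ct) / (1.0 + dt / (r2 * ct))
        g = p - pc_new - q * r1
        if abs(g) < 1e-10 * (abs(p) + 1.0):
            return True, q, pc_new
        dg = -alpha / _lang_dadp(p, amax_t, p0_t, p1_t) - gamma - r1
        step = -g / dg
        scale = 1.0
        for _try in range(12):
            a_try = a_t + alpha * (flast - (q + scale * step))
            if 0.02 * amax_t < a_try < 0.98 * amax_t:
                break
            scale *= 0.5
        q += scale * step
    return False, q, pc


@njit(cache=True)
def _normalized_elastance(tau, n1, n2, tau2, kcurve, period):
    tau = tau % period
    h1 = tau**n1 / (1.0 + tau**n1)
    h2 = 1.0 / (1.0 + (tau / tau2) ** n2)
    en = kcurve * h1 * h2
    if en > 1.0:
        en = 1.0
    if en < 0.0:
        en = 0.0
    return en


@njit(cache=True)
def _advance_cycle(
    # mesh
    A, Q, Aprev, amax, p0d, p1d, viscd, node_seg,
    seg_start, seg_n, seg_dx,
    jn_parent, jn_nchild, jn_children,
    term_node, term_r1, term_r2, term_ct, term_pc,
    # physics constants
    rho, mu, gamma_v, dt, n_steps, t_offset,
    # mode: 0 = prescribed inflow, 1 = LV + valve
    mode, qin_series,
    # LV (CGS pressures/elastances) and valve parameters
    lv_state,  # [V, zeta, Qav]
    ees_d, eed_d, t_hp, t_max, vd, p_atr_d, r_mitral_d,
    en_n1, en_n2, en_tau2, en_k, en_period,
    ames, leff, ao, kt, kvo_d, kvc_d, zeta_min, backflow,
    # outputs (length n_steps; qmean_node has one entry per node)
    rec_plv, rec_proot, rec_qav, rec_zeta, rec_vlv, qmean_node,
    # per-cycle scalars out: sv, map_sum, qin_vol, qout_vol, pmax, pmin,
    #                        p_ed, cfl_max, vmin, vmax
    out_scalars,
):
    nseg = seg_start.shape[0]
    nnode = A.shape[0]
    njn = jn_parent.shape[0]
    nterm = term_node.shape[0]
    fric_c = -2.0 * (gamma_v + 2.0) * np.pi * mu

    As = np.empty(nnode)
    Qs = np.empty(nnode)
    Ps = np.empty(nnode)
    P = np.empty(nnode)
    Anew = np.empty(nnode)
    Qnew = np.empty(nnode)
    Ffirst = np.empty(nseg)  # effective interface flux next to each segment start
    Flast = np.empty(nseg)  # ... and next to each segment end

    qj = np.empty(3)
    a_ch = np.empty(3)
    amx = np.empty(3)
    p0c = np.empty(3)
    p1c = np.empty(3)
    wch = np.empty(3)
    cch = np.empty(3)
    pin = np.empty(3)

    V = lv_state[0]
    zeta = lv_state[1]
    qav = lv_state[2]

    sv = 0.0
    map_sum = 0.0
    qin_vol = 0.0
    qout_vol = 0.0
    pmax = -1e30
    pmin = 1e30
    cfl_max = 0.0
    vmin = 1e30
    vmax = -1e30
    p_ed = 0.0

    for step in range(n_steps):
        t = t_offset + step * dt

        # --- nodal pressures (elastic + optional viscoelastic) ------------
        for i in range(nnode):
            ratio = A[i] / amax[i]
            if ratio <= 0.01 or ratio >= 0.99:
                out_scalars[10] = ERR_AREA
                out_scalars[11] = node_seg[i]
                out_scalars[12] = t
                return V, zeta, qav
            P[i] = _lang_pressure(A[i], amax[i], p0d[i], p1d[i])
            if viscd[i] != 0.0:
                P[i] += viscd[i] * (A[i] - Aprev[i]) / (dt * A[i])

        # --- CFL monitor ---------------------------------------------------
        for s in range(nseg):
            i0 = seg_start[s]
            for i in range(i0, i0 + seg_n[s]):
                c = _wave_speed(A[i], amax[i], p0d[i], p1d[i], rho)
                w = (abs(Q[i] / A[i]) + c) * dt / seg_dx[s]
                if w > cfl_max:
                    cfl_max = w
        if cfl_max > 1.0:
            out_scalars[10] = ERR_CFL
            out_scalars[11] = -1.0
            out_scalars[12] = t
            return V, zeta, qav

        for i in range(nnode):
            Anew[i] = A[i]
            Qnew[i] = Q[i]

        # --- MacCormack interior update ------------------------------------
        for s in range(nseg):
            i0 = seg_start[s]
            n = seg_n[s]
            dx = seg_dx[s]
            # predictor (forward differences) on i0 .. i0+n-2
            for i in range(i0, i0 + n - 1):
                fa1 = Q[i + 1]
                fa0 = Q[i]
                fq1 = Q[i + 1] * Q[i + 1] / A[i + 1]
                fq0 = Q[i] * Q[i] / A[i]
                src = fric_c * Q[i] / (rho * A[i]) + \
                    -(A[i] / rho) * (P[i + 1] - P[i]) / dx
                As[i] = A[i] - dt / dx * (fa1 - fa0)
                Qs[i] = Q[i] - dt / dx * (fq1 - fq0) + dt * src
                if As[i] <= 0.011 * amax[i] or As[i] >= 0.989 * amax[i]:
                    out_scalars[10] = ERR_AREA
                    out_scalars[11] = node_seg[i]
                    out_scalars[12] = t
                    return V, zeta, qav
                Ps[i] = _lang_pressure(As[i], amax[i], p0d[i], p1d[i])
            # corrector (backward differences) on interior i0+1 .. i0+n-2
            for i in range(i0 + 1, i0 + n - 1):
                fa1 = Qs[i]
                fa0 = Qs[i - 1]
                fq1 = Qs[i] * Qs[i] / As[i]
                fq0 = Qs[i - 1] * Qs[i - 1] / As[i - 1]
                src = fric_c * Qs[i] / (rho * As[i]) + \
                    -(As[i] / rho) * (Ps[i] - Ps[i - 1]) / dx
                Anew[i] = 0.5 * (A[i] + As[i] - dt / dx * (fa1 - fa0))
                Qnew[i] = 0.5 * (Q[i] + Qs[i] - dt / dx * (fq1 - fq0) + dt * src)
            # effective continuity fluxes at the interfaces adjoining the
            # boundary half-cells (consistent with the corrector stencil)
            Ffirst[s] = 0.5 * (Q[i0 + 1] + Qs[i0])
            Flast[s] = 0.5 * (Q[i0 + n - 1] + Qs[i0 + n - 2])

        # --- root boundary (conservative half-cell) ------------------------
        if mode == 0:
            q_root = qin_series[step]
            qin_vol += q_root * dt
        else:
            # left ventricle pressure at current time
            tau = (t % t_hp) / t_max
            en = _normalized_elastance(tau, en_n1, en_n2, en_tau2, en_k, en_period)
            E = (ees_d - eed_d) * en + eed_d
            p_lv = E * (V - vd)
            p_in = P[0]
            dp = p_lv - p_in
            zf = zeta if zeta > zeta_min else zeta_min
            aeff = ames * zf
            beta = kt * 0.5 * rho * (1.0 / aeff - 1.0 / ao) ** 2
            if leff > 0.0:
                L = rho * leff / aeff
                qav = (qav + dt * dp / L) / (1.0 + dt * beta * abs(qav) / L)
            elif beta > 0.0:
                qav = np.sign(dp) * np.sqrt(abs(dp) / beta)
            if zeta <= zeta_min and dp < 0.0:
                qav = 0.0
            if backflow == 0 and qav < 0.0:
                qav = 0.0  # pure stenosis: no regurgitant conduction
            # valve state (opening for dp >= 0, closing otherwise)
            if dp >= 0.0:
                zeta = zeta + dt * (1.0 - zeta) * kvo_d * dp
            else:
                zeta = zeta + dt * zeta * kvc_d * dp
            if zeta < 0.0:
                zeta = 0.0
            if zeta > 1.0:
                zeta = 1.0
            # LV volume balance with diode mitral inflow
            q_mit = (p_atr_d - p_lv) / r_mitral_d
            if q_mit < 0.0:
                q_mit = 0.0
            V = V + dt * (q_mit - qav)
            qin_vol += q_mit * dt
            q_root = qav

        # half-cell mass balance fixes the root area; flow is the BC value
        Anew[0] = A[0] + (2.0 * dt / seg_dx[0]) * (q_root - Ffirst[0])
        Qnew[0] = q_root

        # --- junctions: exact-invariant characteristic coupling ------------
        # Invariants are evaluated at the characteristic foot (distance
        # (u+-c)*dt inside the segment), interpolated between the boundary
        # node and its neighbour; sampling the neighbour alone biases the
        # mean junction flux by O(dx).
        for j in range(njn):
            ip = jn_parent[j]
            sp = node_seg[ip]
            s_par = np.sqrt(np.pi * p1d[ip] / rho)
            c_b = _wave_speed(A[ip], amax[ip], p0d[ip], p1d[ip], rho)
            frac = (Q[ip] / A[ip] + c_b) * dt / seg_dx[sp]
            if frac > 1.0:
                frac = 1.0
            if frac < 0.0:
                frac = 0.0
            w_at_b = Q[ip] / A[ip] + s_par * _phi(A[ip] / amax[ip])
            w_at_n = Q[ip - 1] / A[ip - 1] + s_par * _phi(A[ip - 1] / amax[ip - 1])
            wpar = (1.0 - frac) * w_at_b + frac * w_at_n
            k = jn_nchild[j]
            for jj in range(k):
                ic = jn_children[j, jj]
                s_c = np.sqrt(np.pi * p1d[ic] / rho)
                c_cb = _wave_speed(A[ic], amax[ic], p0d[ic], p1d[ic], rho)
                frc = (c_cb - Q[ic] / A[ic]) * dt / seg_dx[node_seg[ic]]
                if frc > 1.0:
                    frc = 1.0
                if frc < 0.0:
                    frc = 0.0
                w_cb = Q[ic] / A[ic] - s_c * _phi(A[ic] / amax[ic])
                w_cn = Q[ic + 1] / A[ic + 1] - s_c * _phi(A[ic + 1] / amax[ic + 1])
                wch[jj] = (1.0 - frc) * w_cb + frc * w_cn
                cch[jj] = s_c
                a_ch[jj] = A[ic]
                amx[jj] = amax[ic]
                p0c[jj] = p0d[ic]
                p1c[jj] = p1d[ic]
                pin[jj] = A[ic]
            ok, ap_n, ac1, ac2, ac3, up, u1, u2, u3 = _junction_newton(
                wpar, s_par, amax[ip], p0d[ip], p1d[ip],
                wch, cch, amx, p0c, p1c, k,
                A[ip], pin, rho, 50)
            if not ok:
                out_scalars[10] = ERR_JUNCTION
                out_scalars[11] = node_seg[ip]
                out_scalars[12] = t
                out_scalars[13] = A[ip]
                out_scalars[14] = amax[ip]
                out_scalars[15] = Flast[sp]
                out_scalars[16] = Q[ip]
                out_scalars[17] = P[ip]
                out_scalars[18] = qj[0]
                out_scalars[19] = qj[1]
                out_scalars[20] = qj[2]
                out_scalars[22] = p0d[ip]
                out_scalars[23] = p1d[ip]
                for jj in range(k):
                    out_scalars[24 + jj] = a_ch[jj]
                    out_scalars[33 + jj] = amx[jj]
                    out_scalars[36 + jj] = p0c[jj]
                    out_scalars[39 + jj] = p1c[jj]
                    out_scalars[42 + jj] = Q[jn_children[j, jj]]
                return V, zeta, qav
            # fluxes from the characteristic solve; boundary areas advance
            # by half-cell mass balance so volume is conserved exactly (the
            # stored areas feed back into the next step's invariants)
            qp = 0.0
            for jj in range(k):
                ic = jn_children[j, jj]
                if jj == 0:
                    aj, uj = ac1, u1
                elif jj == 1:
                    aj, uj = ac2, u2
                else:
                    aj, uj = ac3, u3
                qj[jj] = aj * uj
                qp += qj[jj]
                sc_seg = node_seg[ic]
                Anew[ic] = A[ic] + (2.0 * dt / seg_dx[sc_seg]) * (qj[jj] - Ffirst[sc_seg])
                Qnew[ic] = qj[jj]
            Anew[ip] = A[ip] + (2.0 * dt / seg_dx[sp]) * (Flast[sp] - qp)
            Qnew[ip] = qp

        # --- terminal Windkessels (conservative flux coupling) -------------
        for m in range(nterm):
            it = term_node[m]
            st = node_seg[it]
            alpha = 2.0 * dt / seg_dx[st]
            ok, q_t, pc_new = _terminal_flux_newton(
                Q[it], A[it], Flast[st], alpha, amax[it], p0d[it], p1d[it],
                term_pc[m], term_r1[m], term_r2[m], term_ct[m], dt, 50)
            if not ok:
                out_scalars[10] = ERR_JUNCTION
                out_scalars[11] = node_seg[it]
                out_scalars[12] = t
                return V, zeta, qav
            term_pc[m] = pc_new
            Anew[it] = A[it] + alpha * (Flast[st] - q_t)
            Qnew[it] = q_t
            qout_vol += q_t * dt

        # --- swap ---------------------------------------------------------
        for i in range(nnode):
            Aprev[i] = A[i]
            A[i] = Anew[i]
            Q[i] = Qnew[i]
            qmean_node[i] += Q[i] / n_steps

        # --- record (state after the step, clinical-facing arrays in CGS) --
        t_new = t + dt
        if mode == 1:
            tau = (t_new % t_hp) / t_max
            en = _normalized_elastance(tau, en_n1, en_n2, en_tau2, en_k, en_period)
            E = (ees_d - eed_d) * en + eed_d
            p_lv_rec = E * (V - vd)
        else:
            p_lv_rec = 0.0
        p_root_rec = _lang_pressure(A[0], amax[0], p0d[0], p1d[0])
        rec_plv[step] = p_lv_rec
        rec_proot[step] = p_root_rec
        rec_qav[step] = Q[0] if mode == 0 else qav
        rec_zeta[step] = zeta
        rec_vlv[step] = V
        sv += (qav if mode == 1 else Q[0]) * dt
        map_sum += p_root_rec
        if p_root_rec > pmax:
            pmax = p_root_rec
        if p_root_rec < pmin:
            pmin = p_root_rec
        if V < vmin:
            vmin = V
        if V > vmax:
            vmax = V
        p_ed = p_lv_rec

    out_scalars[0] = sv
    out_scalars[1] = map_sum / n_steps
    out_scalars[2] = qin_vol
    out_scalars[3] = qout_vol
    out_scalars[4] = pmax
    out_scalars[5] = pmin
    out_scalars[6] = p_ed
    out_scalars[7] = cfl_max
    out_scalars[8] = vmin
    out_scalars[9] = vmax
    out_scalars[10] = OK
    return V, zeta, qav


# ----------------------------------------------------------------------
# python-facing mesh + engine
# ----------------------------------------------------------------------
@dataclass
class Mesh:
    """Flat-array discretization of an :class:`ArterialTree` (CGS)."""

    seg_ids: list
    seg_start: np.ndarray
    seg_n: np.ndarray
    seg_dx: np.ndarray
    node_seg: np.ndarray
    amax: np.ndarray
    p0d: np.ndarray
    p1d: np.ndarray
    viscd: np.ndarray
    a_ref: np.ndarray
    jn_parent: np.ndarray
    jn_nchild: np.ndarray
    jn_children: np.ndarray
    term_node: np.ndarray
    term_seg: list
    term_r1: np.ndarray
    term_r2: np.ndarray
    term_ct: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.amax.shape[0]


def discretize(tree: ArterialTree, dx_target: float = 1.5) -> Mesh:
    """Discretize a tree into per-node flat arrays (CGS units).

    Each segment gets at least 3 nodes; dx is the segment length divided
    by the node count minus one.  Junction tables map parent end nodes
    to child start nodes in depth-first order from the root.
    """
    order: list[int] = []
    stack = [tree.root.id]
    while stack:
        sid = stack.pop()
        order.append(sid)
        stack.extend(reversed(tree.segments[sid].children))

    seg_start, seg_n, seg_dx, node_seg = [], [], [], []
    amax, p0d, p1d, viscd, a_ref = [], [], [], [], []
    pos = 0
    seg_index = {}
    for k, sid in enumerate(order):
        s = tree.segments[sid]
        n = max(3, int(round(s.length / dx_target)) + 1)
        seg_index[sid] = k
        seg_start.append(pos)
        seg_n.append(n)
        seg_dx.append(s.length / (n - 1))
        x = np.linspace(0.0, 1.0, n)
        aref = s.area_prox + (s.area_dist - s.area_prox) * x
        am = amax_from_reference(aref, s.p0, s.p1)
        amax.extend(am)
        a_ref.extend(aref)
        p0d.extend([s.p0 * MMHG] * n)
        p1d.extend([s.p1 * MMHG] * n)
        viscd.extend([s.visc_coeff * MMHG] * n)
        node_seg.extend([k] * n)
        pos += n

    jn_parent, jn_nchild, jn_children = [], [], []
    term_node, term_seg, term_r1, term_r2, term_ct = [], [], [], [], []
    for k, sid in enumerate(order):
        s = tree.segments[sid]
        end_node = seg_start[k] + seg_n[k] - 1
        if s.children:
            jn_parent.append(end_node)
            jn_nchild.append(len(s.children))
            row = [0, 0, 0]
            for j, cid in enumerate(s.children):
                row[j] = seg_start[seg_index[cid]]
            jn_children.append(row)
        else:
            t = s.terminal
            term_node.append(end_node)
            term_seg.append(sid)
            term_r1.append(t.r1 * MMHG)
            term_r2.append(t.r2 * MMHG)
            term_ct.append(t.ct / MMHG)

    return Mesh(
        seg_ids=order,
        seg_start=np.asarray(seg_start, dtype=np.int64),
        seg_n=np.asarray(seg_n, dtype=np.int64),
        seg_dx=np.asarray(seg_dx, dtype=np.float64),
        node_seg=np.asarray(node_seg, dtype=np.int64),
        amax=np.asarray(amax, dtype=np.float64),
        p0d=np.asarray(p0d, dtype=np.float64),
        p1d=np.asarray(p1d, dtype=np.float64),
        viscd=np.asarray(viscd, dtype=np.float64),
        a_ref=np.asarray(a_ref, dtype=np.float64),
        jn_parent=np.asarray(jn_parent, dtype=np.int64),
        jn_nchild=np.asarray(jn_nchild, dtype=np.int64),
        jn_children=np.asarray(jn_children, dtype=np.int64).reshape(-1, 3),
        term_node=np.asarray(term_node, dtype=np.int64),
        term_seg=term_seg,
        term_r1=np.asarray(term_r1, dtype=np.float64),
        term_r2=np.asarray(term_r2, dtype=np.float64),
        term_ct=np.asarray(term_ct, dtype=np.float64),
    )


class Engine:
    """Stateful time integrator over one mesh.

    Parameters
    ----------
    tree:
        Validated arterial geometry.
    dx_target:
        Requested spatial step, cm.
    cfl:
        Safety factor for the fixed time step, chosen against the fastest
        wave speed expected during systole (evaluated at ``p_headroom``).
    p_init:
        Uniform initial pressure, mmHg.
    """

    def __init__(self, tree: ArterialTree, dx_target: float = 1.5, cfl: float = 0.5,
                 p_init: float = 80.0, p_headroom: float = 220.0,
                 gamma_v: float = GAMMA_V, rho: float = RHO_BLOOD, mu: float = MU_BLOOD):
        self.tree = tree
        self.mesh = discretize(tree, dx_target)
        self.rho = rho
        self.mu = mu
        self.gamma_v = gamma_v
        m = self.mesh
        ph = p_headroom * MMHG
        c_hi = np.sqrt(
            np.maximum(m.amax * (0.5 + np.arctan((ph - m.p0d) / m.p1d) / np.pi), 1e-12)
            / (rho * m.amax / (np.pi * m.p1d * (1.0 + ((ph - m.p0d) / m.p1d) ** 2)))
        )
        w_max = float(np.max(c_hi)) + 250.0  # headroom for advective speed, cm/s
        dx_min = float(np.min(m.seg_dx))
        self.dt_max = cfl * dx_min / w_max
        self.reset(p_init)

    def reset(self, p_init: float = 80.0) -> None:
        m = self.mesh
        pd = p_init * MMHG
        self.A = m.amax * (0.5 + np.arctan((pd - m.p0d) / m.p1d) / np.pi)
        self.Aprev = self.A.copy()
        self.Q = np.zeros(m.n_nodes)
        self.term_pc = np.full(m.term_node.shape[0], pd)
        self.time = 0.0

    def steps_for(self, period: float) -> tuple[int, float]:
        n = int(np.ceil(period / self.dt_max))
        return n, period / n

    def run_cycle(self, *, mode: int, period: float, cardiac=None, valve=None,
                  lv_state=None, qin_series=None) -> dict:
        """Advance one period; returns recorded waveforms and cycle metrics.

        ``mode=0`` drives the root with ``qin_series`` (mL/s, one entry
        per step); ``mode=1`` couples the LV + valve, with ``lv_state``
        a mutable [V (mL), zeta, Q_av (mL/s)] triple.
        """
        m = self.mesh
        n_steps, dt = self.steps_for(period)
        if mode == 0:
            if qin_series is None or len(qin_series) != n_steps:
                raise ValueError(f"qin_series must have length {n_steps}")
            qin = np.asarray(qin_series, dtype=np.float64)
            lv = np.zeros(3)
            cpar = dict(ees_d=1.0, eed_d=0.5, t_hp=period, t_max=period / 3,
                        vd=0.0, p_atr_d=0.0, r_mitral_d=1.0,
                        en_n1=1.32, en_n2=21.9, en_tau2=1.0, en_k=1.0, en_period=3.0,
                        ames=1.0, leff=1.0, ao=2.0, kt=1.5, kvo_d=1.0, kvc_d=1.0,
                        zeta_min=1e-4, backflow=1)
        else:
            if cardiac is None or valve is None or lv_state is None:
                raise ValueError("mode=1 requires cardiac, valve and lv_state")
            qin = np.zeros(n_steps)
            lv = np.asarray(lv_state, dtype=np.float64)
            curve = cardiac.curve
            p_atr = cardiac.atrial_pressure if cardiac.atrial_pressure is not None \
                else cardiac.lvedp
            ao = valve.ao if valve.ao is not None else float(self.mesh.a_ref[0])
            cpar = dict(
                ees_d=cardiac.ees * MMHG, eed_d=cardiac.eed * MMHG,
                t_hp=cardiac.t_hp, t_max=cardiac.t_max, vd=cardiac.vd,
                p_atr_d=p_atr * MMHG, r_mitral_d=cardiac.mitral_resistance * MMHG,
                en_n1=curve.n1, en_n2=curve.n2, en_tau2=curve.tau2,
                en_k=curve.k, en_period=curve.period,
                ames=valve.ames, leff=valve.leff, ao=ao, kt=valve.kt,
                kvo_d=valve.kvo / MMHG, kvc_d=valve.kvc / MMHG,
                zeta_min=valve.zeta_min,
                backflow=1 if valve.allow_backflow else 0)

        rec = {k: np.empty(n_steps) for k in ("plv", "proot", "qav", "zeta", "vlv")}
        qmean_node = np.zeros(m.n_nodes)
        out = np.zeros(45)
        v, z, q = _advance_cycle(
            self.A, self.Q, self.Aprev, m.amax, m.p0d, m.p1d, m.viscd, m.node_seg,
            m.seg_start, m.seg_n, m.seg_dx,
            m.jn_parent, m.jn_nchild, m.jn_children,
            m.term_node, m.term_r1, m.term_r2, m.term_ct, self.term_pc,
            self.rho, self.mu, self.gamma_v, dt, n_steps, self.time,
            mode, qin,
            lv,
            cpar["ees_d"], cpar["eed_d"], cpar["t_hp"], cpar["t_max"], cpar["vd"],
            cpar["p_atr_d"], cpar["r_mitral_d"],
            cpar["en_n1"], cpar["en_n2"], cpar["en_tau2"], cpar["en_k"], cpar["en_period"],
            cpar["ames"], cpar["leff"], cpar["ao"], cpar["kt"],
            cpar["kvo_d"], cpar["kvc_d"], cpar["zeta_min"], cpar["backflow"],
            rec["plv"], rec["proot"], rec["qav"], rec["zeta"], rec["vlv"],
            qmean_node, out,
        )
        status = int(out[10])
        if status != OK:
            names = {ERR_CFL: "CFL violation", ERR_AREA: "area out of range",
                     ERR_JUNCTION: "junction iteration failed"}
            detail = ""
            if status == ERR_JUNCTION:
                detail = (f"; A={out[13]:.4f}/{out[14]:.4f}, Flast={out[15]:.1f}, "
                          f"Q={out[16]:.1f}, P={out[17]/MMHG:.1f} mmHg, "
                          f"qj=({out[18]:.1f}, {out[19]:.1f}, {out[20]:.1f})")
            raise RuntimeError(
                f"solver aborted: {names.get(status, status)} "
                f"(segment index {int(out[11])}, t = {out[12]:.4f} s){detail}")
        self.time += n_steps * dt
        if lv_state is not None and mode == 1:
            lv_state[0], lv_state[1], lv_state[2] = v, z, q
        return {
            "dt": dt,
            "n_steps": n_steps,
            "time": self.time,
            "p_lv": rec["plv"] / MMHG,
            "p_root": rec["proot"] / MMHG,
            "q_av": rec["qav"],
            "zeta": rec["zeta"],
            "v_lv": rec["vlv"],
            "sv": out[0],
            "map": out[1] / MMHG,
            "qin_vol": out[2],
            "qout_vol": out[3],
            "sbp": out[4] / MMHG,
            "dbp": out[5] / MMHG,
            "p_ed": out[6] / MMHG,
            "cfl_max": out[7],
            "v_min": out[8],
            "v_max": out[9],
            "q_mean_node": qmean_node,
        }


def junction_couple(parent: dict, children: list[dict], rho: float = RHO_BLOOD) -> dict:
    """Solve a single junction coupling problem (clinical-unit interface).

    ``parent``/``children`` carry the characteristic data of the
    adjoining segment ends: ``a`` (cm^2), ``q`` (mL/s), ``amax``, ``p0``,
    ``p1`` (mmHg).  Returns per-side pressures (mmHg) and flows (mL/s)
    satisfying exact mass conservation and total-pressure continuity.
    """
    def _prep(d):
        return (d["a"], d["q"], d["amax"], d["p0"] * MMHG, d["p1"] * MMHG)

    ap, qp, amaxp, p0p, p1p = _prep(parent)
    s_p = np.sqrt(np.pi * p1p / rho)
    wp = qp / ap + s_p * _phi(ap / amaxp)
    k = len(children)
    if not 1 <= k <= 3:
        raise ValueError("1 to 3 children supported")
    wc = np.zeros(3)
    sc = np.ones(3)
    amx = np.ones(3)
    p0c = np.zeros(3)
    p1c = np.ones(3)
    a_in = np.ones(3)
    for j, ch in enumerate(children):
        a, q, am, p0, p1 = _prep(ch)
        s_c = np.sqrt(np.pi * p1 / rho)
        wc[j] = q / a - s_c * _phi(a / am)
        sc[j], amx[j], p0c[j], p1c[j], a_in[j] = s_c, am, p0, p1, a
    ok, ap_n, ac1, ac2, ac3, up, u1, u2, u3 = _junction_newton(
        wp, s_p, amaxp, p0p, p1p, wc, sc, amx, p0c, p1c, k, ap, a_in, rho, 50)
    if not ok:
        raise RuntimeError("junction iteration failed to converge")
    acs = [ac1, ac2, ac3][:k]
    ucs = [u1, u2, u3][:k]
    q_children = [acs[j] * ucs[j] for j in range(k)]
    out = {
        "parent": {"p": _lang_pressure(ap_n, amaxp, p0p, p1p) / MMHG,
                   "q": float(sum(q_children)), "a": ap_n},
        "children": [],
    }
    for j in range(k):
        out["children"].append({
            "p": _lang_pressure(acs[j], amx[j], p0c[j], p1c[j]) / MMHG,
            "q": q_children[j], "a": acs[j]})
    return out
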