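"""Compiled numerical core for the planar chain dynamics.

Everything here operates on flat arrays prepared by
:class:`whipneck.dynamics.CompiledModel`:

* one moving body per generalized coordinate, chain-ordered above the
  driven base (T1);
* revolute coordinates are relative rotations from the initial posture,
  the optional prismatic coordinate is the slider elongation in metres;
* the base motion is given as cubic-polynomial piecewise splines
  (value/velocity/acceleration are evaluated from the same interpolant).

The equations of motion are assembled by projecting Newton-Euler onto
the joint coordinates: ``M(q) qdd = Q(q, qd, t)`` with
``M = sum m_i J_i^T J_i + I_i w_i w_i^T`` where ``J_i`` is the CG
Jacobian and ``w_i`` the angle Jacobian of body ``i``, and ``Q``
collects gravity, spring/damper joint loads, static preloads and the
prescribed-support convection terms.

Angles are flexion-positive (local-to-global rotation
``R = [[c, s], [-s, c]]``, ``dR/dtheta = [[-s, c], [-c, -s]]``,
``d2R/dtheta2 = -R``); planar moments use the matching scalar cross
product ``cross(r, F) = r_z F_x - r_x F_z``.
"""

import numpy as np
from numba import njit

# state layout: y = [q (n), qd (n), D, W]
#   D = cumulative damper dissipation (J)
#   W = cumulative work done by the prescribed support (J)


@njit(cache=True)
def ppval(breaks, coef, t):
    """Evaluate a cubic piecewise polynomial and its two derivatives.

    ``coef`` has shape (4, m), highest power first (scipy PPoly layout).
    """
    m = coef.shape[1]
    i = np.searchsorted(breaks, t, side="right") - 1
    if i < 0:
        i = 0
    if i > m - 1:
        i = m - 1
    s = t - breaks[i]
    c0 = coef[0, i]
    c1 = coef[1, i]
    c2 = coef[2, i]
    c3 = coef[3, i]
    f = ((c0 * s + c1) * s + c2) * s + c3
    fp = (3.0 * c0 * s + 2.0 * c1) * s + c2
    fpp = 6.0 * c0 * s + 2.0 * c1
    return f, fp, fpp


@njit(cache=True)
def eval_full(t, q, qd,
              S, G, U, mass, inertia, phi0, is_prism,
              A1, B1, A2, B2, Cd, kv, cv, prism_idx, tau0,
              m0, I0, G0, O0,
              xb, xc, zb, zc, rb, rc, grav):
    """One full evaluation of the chain state.

    Returns the joint accelerations together with every per-body channel
    needed for outputs and the energy ledger.
    """
    n = q.shape[0]

    # ---- prescribed base ----
    bx, bvx, bax = ppval(xb, xc, t)
    bz, bvz, baz = ppval(zb, zc, t)
    th_b, om_b, al_b = ppval(rb, rc, t)

    Obx = O0[0] + bx
    Obz = O0[1] + bz
    cb = np.cos(th_b)
    sb = np.sin(th_b)
    # base CG kinematics (needed for energies and the support reaction)
    RG0x = cb * G0[0] + sb * G0[1]
    RG0z = -sb * G0[0] + cb * G0[1]
    RpG0x = -sb * G0[0] + cb * G0[1]
    RpG0z = -cb * G0[0] - sb * G0[1]
    r0x = Obx + RG0x
    r0z = Obz + RG0z
    v0x = bvx + om_b * RpG0x
    v0z = bvz + om_b * RpG0z
    a0x = bax + al_b * RpG0x - om_b * om_b * RG0x
    a0z = baz + al_b * RpG0z - om_b * om_b * RG0z

    # ---- chain recursion ----
    theta = np.empty(n)
    omega = np.empty(n)
    albias = np.empty(n)
    Opos = np.empty((n, 2))
    rcg = np.empty((n, 2))
    vcg = np.empty((n, 2))
    Jall = np.empty((n, 2, n))
    gall = np.empty((n, 2))
    wall = np.zeros((n, n))
    Mm = np.zeros((n, n))
    Q = np.zeros(n)

    th_p = th_b
    om_p = om_b
    ab_p = al_b
    Ox = Obx
    Oz = Obz
    Vx = bvx
    Vz = bvz
    gOx = bax
    gOz = baz
    wp = np.zeros(n)
    JOp = np.zeros((2, n))

    for k in range(n):
        c = np.cos(th_p)
        s = np.sin(th_p)
        if is_prism[k] == 1:
            dx = S[k, 0] + q[k] * U[k, 0]
            dz = S[k, 1] + q[k] * U[k, 1]
        else:
            dx = S[k, 0]
            dz = S[k, 1]
        Rdx = c * dx + s * dz
        Rdz = -s * dx + c * dz
        Rpdx = -s * dx + c * dz
        Rpdz = -c * dx - s * dz

        Okx = Ox + Rdx
        Okz = Oz + Rdz
        Vkx = Vx + om_p * Rpdx
        Vkz = Vz + om_p * Rpdz
        JOk = np.empty((2, n))
        for j in range(n):
            JOk[0, j] = JOp[0, j] + Rpdx * wp[j]
            JOk[1, j] = JOp[1, j] + Rpdz * wp[j]
        gOkx = gOx + ab_p * Rpdx - om_p * om_p * Rdx
        gOkz = gOz + ab_p * Rpdz - om_p * om_p * Rdz

        if is_prism[k] == 1:
            Rux = c * U[k, 0] + s * U[k, 1]
            Ruz = -s * U[k, 0] + c * U[k, 1]
            Rpux = -s * U[k, 0] + c * U[k, 1]
            Rpuz = -c * U[k, 0] - s * U[k, 1]
            Vkx += qd[k] * Rux
            Vkz += qd[k] * Ruz
            JOk[0, k] += Rux
            JOk[1, k] += Ruz
            gOkx += 2.0 * om_p * qd[k] * Rpux
            gOkz += 2.0 * om_p * qd[k] * Rpuz
            th_k = th_p
            om_k = om_p
            ab_k = ab_p
            wk = wp.copy()
        else:
            th_k = th_p + phi0[k] + q[k]
            om_k = om_p + qd[k]
            ab_k = ab_p
            wk = wp.copy()
            wk[k] += 1.0

        ck = np.cos(th_k)
        sk = np.sin(th_k)
        RGx = ck * G[k, 0] + sk * G[k, 1]
        RGz = -sk * G[k, 0] + ck * G[k, 1]
        RpGx = -sk * G[k, 0] + ck * G[k, 1]
        RpGz = -ck * G[k, 0] - sk * G[k, 1]
        rx = Okx + RGx
        rz = Okz + RGz
        vx = Vkx + om_k * RpGx
        vz = Vkz + om_k * RpGz
        gx = gOkx + ab_k * RpGx - om_k * om_k * RGx
        gz = gOkz + ab_k * RpGz - om_k * om_k * RGz

        for j in range(n):
            Jall[k, 0, j] = JOk[0, j] + RpGx * wk[j]
            Jall[k, 1, j] = JOk[1, j] + RpGz * wk[j]
        gall[k, 0] = gx
        gall[k, 1] = gz
        theta[k] = th_k
        omega[k] = om_k
        albias[k] = ab_k
        Opos[k, 0] = Okx
        Opos[k, 1] = Okz
        rcg[k, 0] = rx
        rcg[k, 1] = rz
        vcg[k, 0] = vx
        vcg[k, 1] = vz
        for j in range(n):
            wall[k, j] = wk[j]

        mk = mass[k]
        Ik = inertia[k]
        for i in range(n):
            Jxi = Jall[k, 0, i]
            Jzi = Jall[k, 1, i]
            Q[i] += -mk * (Jxi * gx + Jzi * gz) - mk * grav * Jzi \
                - Ik * wk[i] * ab_k
            for j in range(i, n):
                Mm[i, j] += mk * (Jxi * Jall[k, 0, j] + Jzi * Jall[k, 1, j]) \
                    + Ik * wk[i] * wk[j]

        # child becomes parent
        th_p = th_k
        om_p = om_k
        ab_p = ab_k
        Ox = Okx
        Oz = Okz
        Vx = Vkx
        Vz = Vkz
        gOx = gOkx
        gOz = gOkz
        wp = wk
        JOp = JOk

    for i in range(n):
        for j in range(i):
            Mm[i, j] = Mm[j, i]

    # ---- joint spring/damper/preload loads and energy terms ----
    Pdamp = 0.0
    Vspring = 0.0
    for k in range(n):
        if is_prism[k] == 1:
            Q[k] += -(kv * q[k] + cv * qd[k]) + tau0[k]
            Pdamp += cv * qd[k] * qd[k]
            Vspring += 0.5 * kv * q[k] * q[k] - tau0[k] * q[k]
        else:
            th = q[k]
            if th >= 0.0:
                Ms = A2[k] * (np.exp(B2[k] * th) - 1.0)
                if A2[k] != 0.0:
                    Vspring += A2[k] * ((np.exp(B2[k] * th) - 1.0) / B2[k] - th)
            else:
                Ms = A1[k] * (np.exp(B1[k] * th) - 1.0)
                if A1[k] != 0.0:
                    Vspring += A1[k] * ((np.exp(B1[k] * th) - 1.0) / B1[k] - th)
            Q[k] += -Ms - Cd[k] * qd[k] + tau0[k]
            Pdamp += Cd[k] * qd[k] * qd[k]
            Vspring += -tau0[k] * q[k]

    qdd = np.linalg.solve(Mm, Q)

    # ---- per-body accelerations ----
    acg = np.empty((n, 2))
    alpha = np.empty(n)
    for k in range(n):
        ax = gall[k, 0]
        az = gall[k, 1]
        al = albias[k]
        for j in range(n):
            ax += Jall[k, 0, j] * qdd[j]
            az += Jall[k, 1, j] * qdd[j]
            al += wall[k, j] * qdd[j]
        acg[k, 0] = ax
        acg[k, 1] = az
        alpha[k] = al

    # ---- energy ledger ----
    Tkin = 0.5 * m0 * (v0x * v0x + v0z * v0z) + 0.5 * I0 * om_b * om_b
    Vpot = Vspring + m0 * grav * r0z
    for k in range(n):
        Tkin += 0.5 * mass[k] * (vcg[k, 0] ** 2 + vcg[k, 1] ** 2) \
            + 0.5 * inertia[k] * omega[k] ** 2
        Vpot += mass[k] * grav * rcg[k, 1]

    # support reaction: force plus couple acting on the driven base body
    Fsx = m0 * a0x
    Fsz = m0 * (a0z + grav)
    Ls = I0 * al_b + m0 * (r0z * a0x - r0x * a0z) - m0 * grav * r0x
    for k in range(n):
        Fsx += mass[k] * acg[k, 0]
        Fsz += mass[k] * (acg[k, 1] + grav)
        Ls += inertia[k] * alpha[k] \
            + mass[k] * (rcg[k, 1] * acg[k, 0] - rcg[k, 0] * acg[k, 1]) \
            - mass[k] * grav * rcg[k, 0]
    # couple = total moment minus the moment of the support force
    Msup = Ls - (Obz * Fsx - Obx * Fsz)
    Pin = Fsx * bvx + Fsz * bvz + Msup * om_b

    return (qdd, acg, alpha, theta, omega, Opos, rcg, vcg,
            Tkin, Vpot, Pdamp, Pin, Fsx, Fsz,
            bx, bz, bvx, bvz, bax, baz, th_b, om_b, al_b,
            Mm, Q)


@njit(cache=True)
def rhs(t, y,
        S, G, U, mass, inertia, phi0, is_prism,
        A1, B1, A2, B2, Cd, kv, cv, prism_idx, tau0,
        m0, I0, G0, O0,
        xb, xc, zb, zc, rb, rc, grav):
    n = (y.shape[0] - 2) // 2
    q = y[:n]
    qd = y[n:2 * n]
    out = eval_full(t, q, qd,
                    S, G, U, mass, inertia, phi0, is_prism,
                    A1, B1, A2, B2, Cd, kv, cv, prism_idx, tau0,
                    m0, I0, G0, O0,
                    xb, xc, zb, zc, rb, rc, grav)
    qdd = out[0]
    Pdamp = out[10]
    Pin = out[11]
    ydot = np.empty_like(y)
    for i in range(n):
        ydot[i] = qd[i]
        ydot[n + i] = qdd[i]
    ydot[2 * n] = Pdamp
    ydot[2 * n + 1] = Pin
    return ydot


# Dormand-Prince 4(5) coefficients (the classic RK45 embedded pair).
_DP_C = np.array([0.0, 1.0 / 5.0, 3.0 / 10.0, 4.0 / 5.0, 8.0 / 9.0, 1.0, 1.0])
_DP_A = np.array([
    [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
    [1.0 / 5.0, 0.0, 0.0, 0.0, 0.0, 0.0],
    [3.0 / 40.0, 9.0 / 40.0, 0.0, 0.0, 0.0, 0.0],
    [44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0, 0.0, 0.0, 0.0],
    [19372.0 / 6561.0, -25360.0 / 2187.0, 64448.0 / 6561.0,
     -212.0 / 729.0, 0.0, 0.0],
    [9017.0 / 3168.0, -355.0 / 33.0, 46732.0 / 5247.0, 49.0 / 176.0,
     -5103.0 / 18656.0, 0.0],
])
_DP_B5 = np.array([35.0 / 384.0, 0.0, 500.0 / 1113.0, 125.0 / 192.0,
                   -2187.0 / 6784.0, 11.0 / 84.0, 0.0])
_DP_B4 = np.array([5179.0 / 57600.0, 0.0, 7571.0 / 16695.0, 393.0 / 640.0,
                   -92097.0 / 339200.0, 187.0 / 2100.0, 1.0 / 40.0])


@njit(cache=True)
def integrate(t_out, y0,
              S, G, U, mass, inertia, phi0, is_prism,
              A1, B1, A2, B2, Cd, kv, cv, prism_idx, tau0,
              m0, I0, G0, O0,
              xb, xc, zb, zc, rb, rc, grav,
              rtol, atol, max_step):
    """Adaptive Dormand-Prince 4(5) landing exactly on the output times.

    Returns ``(Y, status, t_fail)``: status 0 on success, 1 if the step
    size collapsed (``t_fail`` is the failing time).
    """
    nyd = y0.shape[0]
    nout = t_out.shape[0]
    Y = np.empty((nout, nyd))
    Y[0] = y0
    y = y0.copy()
    t = t_out[0]
    h = min(1e-4, max_step)

    k = np.empty((7, nyd))
    k[0] = rhs(t, y, S, G, U, mass, inertia, phi0, is_prism,
               A1, B1, A2, B2, Cd, kv, cv, prism_idx, tau0,
               m0, I0, G0, O0, xb, xc, zb, zc, rb, rc, grav)

    for idx in range(1, nout):
        t_target = t_out[idx]
        while t < t_target - 1e-13:
            hs = h
            if t + hs > t_target:
                hs = t_target - t
            for stage in range(1, 7):
                yk = y.copy()
                for m in range(stage):
                    if stage < 6:
                        a = _DP_A[stage, m]
                    else:
                        a = _DP_B5[m]
                    if a != 0.0:
                        for i in range(nyd):
                            yk[i] += hs * a * k[m, i]
                k[stage] = rhs(t + _DP_C[stage] * hs, yk,
                               S, G, U, mass, inertia, phi0, is_prism,
                               A1, B1, A2, B2, Cd, kv, cv, prism_idx, tau0,
                               m0, I0, G0, O0, xb, xc, zb, zc, rb, rc, grav)
            # 5th-order solution (already the argument of the FSAL stage)
            y5 = y.copy()
            for m in range(7):
                if _DP_B5[m] != 0.0:
                    for i in range(nyd):
                        y5[i] += hs * _DP_B5[m] * k[m, i]
            errn = 0.0
            for i in range(nyd):
                e = 0.0
                for m in range(7):
                    e += hs * (_DP_B5[m] - _DP_B4[m]) * k[m, i]
                sc = atol + rtol * max(abs(y[i]), abs(y5[i]))
                errn += (e / sc) ** 2
            errn = np.sqrt(errn / nyd)

            if errn <= 1.0:
                t = t + hs
                y = y5
                k[0] = k[6]
                if errn == 0.0:
                    fac = 5.0
                else:
                    fac = min(5.0, max(0.2, 0.9 * errn ** -0.2))
                h = min(max_step, hs * fac)
            else:
                h = hs * max(0.1, 0.9 * errn ** -0.2)
                if h < 1e-12:
                    return Y, 1, t
        Y[idx] = y
    return Y, 0, 0.0
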