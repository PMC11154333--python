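"""Independent oracles for the dynamics, OC loads and HIC.

Each oracle derives the same quantity as the production code through a
different formulation:

* :func:`double_pendulum_oracle` — symbolic Euler-Lagrange equations of
  a two-moving-body chain (sympy), with the prescribed base motion
  entering through substituted spline values.  Checks the projected
  Newton-Euler assembly.
* :func:`oc_loads_lagrange` — absolute-coordinate formulation of the
  full chain: each body carries free planar coordinates, every joint is
  imposed as an acceleration-level Lagrange-multiplier constraint, and
  the multipliers of the head joint ARE the occipital-condyle reaction
  forces.  Checks the inverse-dynamics OC loads.
* :func:`hic_bruteforce` — O(n^2) exhaustive window search sharing the
  cumulative-trapezoid array with the production implementation, so
  agreement can be asserted bit-exactly.
"""

from __future__ import annotations

import math

import numpy as np

from whipneck.dynamics import compile_model
from whipneck.model import DEG, MM, BodySegment, NeckModel
from whipneck import presets


# -- reduced chains for the symbolic oracle --------------------------------------


def body_from_table(name: str) -> BodySegment:
    m, ixx, iyy, izz, sx, sz, gx, gz, th = presets.BODY_TABLE[name]
    return BodySegment(name=name, mass=m, inertia_yy=iyy, inertia_xx=ixx,
                       inertia_zz=izz, offset_S=(sx, sz), cg_local=(gx, gz),
                       theta0=th)


def make_two_body_model(gravity: bool = True) -> NeckModel:
    """T1 base plus C7 and C6 with the published initial joint laws."""
    from whipneck.model import TorsionalJointParams
    joints = {}
    for jname in ("C7/T1", "C6/C7"):
        a1, b1, a2, b2 = presets.STIFFNESS_INITIAL[jname]
        joints[jname] = TorsionalJointParams(
            jname, A1=a1, B1=b1, A2=a2, B2=b2,
            C=presets.DAMPING_INITIAL_NMS_PER_RAD)
    bodies = tuple(body_from_table(n) for n in ("T1", "C7", "C6"))
    return NeckModel(bodies=bodies, joints=joints, gravity_enabled=gravity,
                     name="oracle-two-body")


class DoublePendulumOracle:
    """Symbolic Euler-Lagrange EOM of the two-moving-body chain.

    Built once (sympy derivation + lambdify); evaluation substitutes the
    base-motion spline values, solves the symbolic 2x2 system and
    returns the joint accelerations.
    """

    def __init__(self, model: NeckModel):
        import sympy as sp

        if model.n_coordinates != 2 or model.prismatic is not None:
            raise ValueError("oracle expects a two-revolute chain")
        base, b1, b2 = model.bodies
        cm = compile_model(model)
        self.model = model
        self.cm = cm

        t = sp.Symbol("t")
        q1f, q2f = sp.Function("q1")(t), sp.Function("q2")(t)
        xbf, zbf = sp.Function("xb")(t), sp.Function("zb")(t)
        thb = sp.Float(base.theta0 * DEG, 30)

        def R(th):
            return sp.Matrix([[sp.cos(th), sp.sin(th)],
                              [-sp.sin(th), sp.cos(th)]])

        S1 = sp.Matrix([b1.offset_S[0] * MM, b1.offset_S[1] * MM])
        S2 = sp.Matrix([b2.offset_S[0] * MM, b2.offset_S[1] * MM])
        G1 = sp.Matrix([b1.cg_local[0] * MM, b1.cg_local[1] * MM])
        G2 = sp.Matrix([b2.cg_local[0] * MM, b2.cg_local[1] * MM])
        O0 = sp.Matrix([model.t1_origin_mm[0] * MM,
                        model.t1_origin_mm[1] * MM])

        phi1 = sp.Float((b1.theta0 - base.theta0) * DEG, 30)
        phi2 = sp.Float((b2.theta0 - b1.theta0) * DEG, 30)
        th1 = thb + phi1 + q1f
        th2 = th1 + phi2 + q2f

        Ob = O0 + sp.Matrix([xbf, zbf])
        O1 = Ob + R(thb) @ S1
        cg1 = O1 + R(th1) @ G1
        O2 = O1 + R(th1) @ S2
        cg2 = O2 + R(th2) @ G2

        g = sp.Float(model.gravity, 30) if model.gravity_enabled else sp.Integer(0)
        v1, v2 = cg1.diff(t), cg2.diff(t)
        T = (sp.Rational(1, 2) * b1.mass * (v1.T @ v1)[0]
             + sp.Rational(1, 2) * b2.mass * (v2.T @ v2)[0]
             + sp.Rational(1, 2) * b1.inertia_yy * sp.diff(th1, t) ** 2
             + sp.Rational(1, 2) * b2.inertia_yy * sp.diff(th2, t) ** 2)
        Vg = b1.mass * g * cg1[1] + b2.mass * g * cg2[1]

        def Uspring(jp, q):
            ue = jp.A1 * ((sp.exp(jp.B1 * q) - 1) / jp.B1 - q)
            uf = jp.A2 * ((sp.exp(jp.B2 * q) - 1) / jp.B2 - q)
            return sp.Piecewise((ue, q < 0), (uf, True))

        j1 = model.joints[model.joint_of_body(b1.name)]
        j2 = model.joints[model.joint_of_body(b2.name)]
        Us = Uspring(j1, q1f) + Uspring(j2, q2f)

        # gravity preload: static equilibrium of the initial posture
        tau = sp.Matrix([sp.diff(Vg, q1f), sp.diff(Vg, q2f)])
        subs0 = {q1f: 0, q2f: 0, xbf: 0, zbf: 0}
        self.tau0 = np.array([float(tau[0].subs(subs0)),
                              float(tau[1].subs(subs0))])
        tau01, tau02 = (sp.Float(self.tau0[0], 30), sp.Float(self.tau0[1], 30))

        L = T - Vg - Us + tau01 * q1f + tau02 * q2f
        eqs = []
        for qf, Cd, qdot in ((q1f, j1.C, sp.diff(q1f, t)),
                             (q2f, j2.C, sp.diff(q2f, t))):
            eqs.append(sp.diff(sp.diff(L, sp.diff(qf, t)), t)
                       - sp.diff(L, qf) + Cd * qdot)

        q1, q2, qd1, qd2, qdd1, qdd2 = sp.symbols(
            "q1_ q2_ qd1_ qd2_ qdd1_ qdd2_")
        xb, xbd, xbdd, zb, zbd, zbdd = sp.symbols(
            "xb_ xbd_ xbdd_ zb_ zbd_ zbdd_")
        rep = [
            (sp.Derivative(q1f, (t, 2)), qdd1),
            (sp.Derivative(q2f, (t, 2)), qdd2),
            (sp.Derivative(xbf, (t, 2)), xbdd),
            (sp.Derivative(zbf, (t, 2)), zbdd),
            (sp.Derivative(q1f, t), qd1), (sp.Derivative(q2f, t), qd2),
            (sp.Derivative(xbf, t), xbd), (sp.Derivative(zbf, t), zbd),
            (q1f, q1), (q2f, q2), (xbf, xb), (zbf, zb),
        ]
        eqs = [e.subs(rep) for e in eqs]
        A, rhs = sp.linear_eq_to_matrix(eqs, [qdd1, qdd2])
        args = (q1, q2, qd1, qd2, xb, xbd, xbdd, zb, zbd, zbdd)
        self._A = sp.lambdify(args, A, "numpy")
        self._rhs = sp.lambdify(args, rhs, "numpy")

    def qdd(self, t, q, qd, motion) -> np.ndarray:
        x, z = motion.displacement(t)
        xd, zd = motion.velocity(t)
        xdd, zdd = motion.acceleration(t)
        args = (q[0], q[1], qd[0], qd[1],
                float(x), float(xd), float(xdd),
                float(z), float(zd), float(zdd))
        A = np.asarray(self._A(*args), dtype=float)
        rhs = np.asarray(self._rhs(*args), dtype=float).ravel()
        return np.linalg.solve(A, rhs)


# -- absolute-coordinate Lagrange-multiplier OC loads ----------------------------


def _rot(th):
    c, s = math.cos(th), math.sin(th)
    return np.array([[c, s], [-s, c]])


def _drot(th):
    c, s = math.cos(th), math.sin(th)
    return np.array([[-s, c], [-c, -s]])


def oc_loads_lagrange(model: NeckModel, result, motion):
    """OC loads from the absolute-coordinate constrained formulation.

    Coordinates: (x_cg, z_cg, theta) per moving body, plus the slider
    elongation when present.  Joints are acceleration-level constraints
    ``A ydd = b``; the bordered KKT system ``[[M, -A^T], [A, 0]]`` is
    solved at every output sample and the multipliers of the head
    position constraint are the global OC reaction forces on the head.
    Returns ``(fx, fz, my)`` in the head frame, like the production
    channels.
    """
    cm = compile_model(model)
    n = cm.n
    has_e = cm.prism_idx >= 0
    ncoord = 3 * n + (1 if has_e else 0)
    # constraint rows: 2 per body position + 1 angle row for the slider body
    nconstr = 2 * n + (1 if has_e else 0)
    g = cm.grav
    head = cm.head_idx
    m_out = len(result.time)
    fx = np.empty(m_out)
    fz = np.empty(m_out)
    my = np.empty(m_out)

    M = np.zeros(ncoord)
    for k in range(n):
        M[3 * k] = cm.mass[k]
        M[3 * k + 1] = cm.mass[k]
        M[3 * k + 2] = cm.inertia[k]

    for i, t in enumerate(result.time):
        th = result.body_angle[i]
        om = result.body_omega[i]
        q = result.q[i]
        qd = result.qd[i]
        e = q[cm.prism_idx] if has_e else 0.0
        ed = qd[cm.prism_idx] if has_e else 0.0

        A = np.zeros((nconstr, ncoord))
        b = np.zeros(nconstr)
        Q = np.zeros(ncoord)

        # joint moments on each revolute coordinate (spring+damper+preload)
        Mj = np.zeros(n)
        for k in range(n):
            if cm.is_prism[k]:
                continue
            A1, B1, A2, B2 = cm.A1[k], cm.B1[k], cm.A2[k], cm.B2[k]
            spring = (A1 * (math.exp(B1 * q[k]) - 1.0) if q[k] < 0
                      else A2 * (math.exp(B2 * q[k]) - 1.0))
            Mj[k] = -(spring + cm.Cd[k] * qd[k]) + cm.tau0[k]

        row = 0
        for k in range(n):
            Gk = cm.G[k]
            Sk = cm.S[k]
            # child-side terms of g = cg_k - R(th_k) G_k - (parent joint pos)
            A[row:row + 2, 3 * k:3 * k + 2] = np.eye(2)
            A[row:row + 2, 3 * k + 2] = -_drot(th[k]) @ Gk
            # child Adot*ydot term: -R''(th_k) om^2 G_k, with R'' = -R
            b[row:row + 2] = -(_rot(th[k]) @ Gk) * om[k] ** 2
            if k == 0:
                # parent is the driven base: g -= O_b(t) + R(th_b) S_k
                xdd, zdd = motion.acceleration(t)
                b[row:row + 2] += np.array([float(xdd), float(zdd)])
            else:
                p = k - 1
                Gp = cm.G[p]
                if cm.is_prism[k]:
                    # slider body: joint position = cg_p - R G_p + R(S + e u)
                    vec = Gp - Sk - e * cm.U[k]
                    A[row:row + 2, 3 * p:3 * p + 2] = -np.eye(2)
                    A[row:row + 2, 3 * p + 2] = _drot(th[p]) @ vec
                    A[row:row + 2, 3 * n] = -_rot(th[p]) @ cm.U[k]
                    # Adot*ydot parent part: R''om^2 vec - 2 R' om ed u
                    ad = (-_rot(th[p]) @ vec) * om[p] ** 2 \
                        - 2.0 * om[p] * ed * (_drot(th[p]) @ cm.U[k])
                    b[row:row + 2] -= ad
                else:
                    vec = Gp - Sk
                    A[row:row + 2, 3 * p:3 * p + 2] = -np.eye(2)
                    A[row:row + 2, 3 * p + 2] = _drot(th[p]) @ vec
                    ad = (-_rot(th[p]) @ vec) * om[p] ** 2
                    b[row:row + 2] -= ad
            row += 2
            if cm.is_prism[k]:
                # slider keeps the parent's orientation
                A[row, 3 * k + 2] = 1.0
                A[row, 3 * (k - 1) + 2] = -1.0
                row += 1

        # applied forces: gravity + joint torques (+ slider force on e)
        for k in range(n):
            Q[3 * k + 1] = -cm.mass[k] * g
            if not cm.is_prism[k]:
                Q[3 * k + 2] += Mj[k]
                parent = k - 1
                if parent >= 0:
                    Q[3 * parent + 2] -= Mj[k]
        if has_e:
            Q[3 * n] = -(cm.kv * e + cm.cv * ed) + cm.tau0[cm.prism_idx]

        K = np.zeros((ncoord + nconstr, ncoord + nconstr))
        K[:ncoord, :ncoord] = np.diag(M)
        K[:ncoord, ncoord:] = -A.T
        K[ncoord:, :ncoord] = A
        rhs = np.concatenate([Q, b])
        sol = np.linalg.solve(K, rhs)
        lam = sol[ncoord:]
        # multipliers of the head position rows = global OC force on head
        head_row = 2 * head + (1 if (has_e and head > cm.prism_idx) else 0)
        F = lam[head_row:head_row + 2]
        c, s = math.cos(th[head]), math.sin(th[head])
        fx[i] = c * F[0] - s * F[1]
        fz[i] = s * F[0] + c * F[1]
        my[i] = Mj[head]
    return fx, fz, my


# -- brute-force HIC -------------------------------------------------------------


def hic_bruteforce(time, a_resultant_g, max_window: float = 0.036):
    """Exhaustive O(n^2) sliding-window search sharing the production
    cumulative-trapezoid array, for bit-exact comparison."""
    time = np.asarray(time, dtype=float)
    a = np.asarray(a_resultant_g, dtype=float)
    dt = time[1] - time[0]
    n = len(time)
    ct = np.concatenate([[0.0], np.cumsum(0.5 * (a[1:] + a[:-1]) * dt)])
    kmax = min(n - 1, int(np.floor(max_window / dt + 1e-9)))
    best = 0.0
    best_pair = (time[0], time[0])
    for i in range(n - 1):
        for j in range(i + 1, min(i + kmax, n - 1) + 1):
            span = (j - i) * dt
            avg = (ct[j] - ct[i]) / span
            # same IEEE-deterministic 2.5-power as the production code
            val = span * (avg * avg * math.sqrt(avg))
            if val > best:
                best = val
                best_pair = (time[i], time[j])
    return best, best_pair[0], best_pair[1]
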