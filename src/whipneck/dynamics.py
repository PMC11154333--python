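"""Forward dynamics of the chain under prescribed T1 motion.

The base vertebra T1 is kinematically driven (support excitation): its
translation, and optionally its rotation, follow twice-differentiable
interpolants of the input time series.  The remaining bodies respond
through the joint springs and dampers.  Joint coordinates are measured
from the seated initial posture, so every spring moment is zero at
``t = 0``; when gravity is enabled, constant joint preload moments are
added so that the initial posture is a static equilibrium (a seated
occupant is at rest before the impact).

Occipital-condyle (OC) loads are recovered by inverse dynamics of the
head alone (Newton-Euler with the head's known CG and angular
accelerations) and expressed in the head's local frame: Fx anterior
shear, Fz superior normal, My the internal flexion-positive moment
transmitted at the OC joint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline

from . import _kernel
from .model import DEG, MM, NeckModel, rotation_matrix

__all__ = [
    "PrescribedMotion",
    "SimulationResult",
    "CompiledModel",
    "compile_model",
    "spring_moment",
    "damper_moment",
    "translational_force",
    "assemble_eom",
    "simulate",
    "oc_loads",
]

G_STANDARD = 9.81  # m/s^2, used to report accelerations in g


class IntegrationError(RuntimeError):
    """Raised when the adaptive integrator's step size collapses."""

    def __init__(self, t_fail: float):
        super().__init__(f"integration failed near t = {t_fail:.6f} s "
                         "(step size collapse)")
        self.t_fail = t_fail


# -- constitutive laws (scalar helpers; the kernel re-implements them) ---------


def spring_moment(params, theta_rel):
    """Torsional spring moment ``A (exp(B*theta) - 1)`` (Nm).

    Extension branch (A1, B1) for ``theta_rel < 0``, flexion branch
    (A2, B2) for ``theta_rel >= 0``; continuous and zero at zero.
    """
    th = np.asarray(theta_rel, dtype=float)
    ext = params.A1 * (np.exp(params.B1 * th) - 1.0)
    fle = params.A2 * (np.exp(params.B2 * th) - 1.0)
    out = np.where(th < 0.0, ext, fle)
    return float(out) if out.ndim == 0 else out


def damper_moment(params, theta_dot):
    """Magnitude of the resisting viscous moment ``C * theta_dot`` (Nm)."""
    return params.C * np.asarray(theta_dot, dtype=float) * 1.0


def translational_force(params, elongation, elongation_rate):
    """Restoring force ``kv e + cv de/dt`` of the slider element (N)."""
    return params.kv * np.asarray(elongation, dtype=float) \
        + params.cv * np.asarray(elongation_rate, dtype=float)


# -- prescribed base motion ----------------------------------------------------


@dataclass
class PrescribedMotion:
    """T1 support excitation: displacement (and optional extra rotation).

    Channels are sampled on a strictly increasing time grid and start at
    zero; velocities and accelerations are taken from the cubic-spline
    interpolant, never from raw differencing.
    """

    time: np.ndarray           # s
    x: np.ndarray              # m, anterior displacement
    z: np.ndarray              # m, superior displacement
    rotation: Optional[np.ndarray] = None  # rad, added to theta0_T1

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.time.ndim != 1 or self.time.size < 4:
            raise ValueError("need at least 4 time samples")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        for name, ch in (("x", self.x), ("z", self.z)):
            if ch.shape != self.time.shape:
                raise ValueError(f"channel {name} does not match the time grid")
        if abs(self.x[0]) > 1e-12 or abs(self.z[0]) > 1e-12:
            raise ValueError("displacements must start at 0 at t = 0")
        if self.rotation is not None:
            self.rotation = np.asarray(self.rotation, dtype=float)
            if self.rotation.shape != self.time.shape:
                raise ValueError("rotation channel does not match the grid")
        self._sx = CubicSpline(self.time, self.x)
        self._sz = CubicSpline(self.time, self.z)
        self._sr = (CubicSpline(self.time, self.rotation)
                    if self.rotation is not None else None)

    @property
    def t_end(self) -> float:
        return float(self.time[-1])

    def displacement(self, t):
        return self._sx(t), self._sz(t)

    def velocity(self, t):
        return self._sx(t, 1), self._sz(t, 1)

    def acceleration(self, t):
        return self._sx(t, 2), self._sz(t, 2)

    @classmethod
    def stationary(cls, t_end: float = 1.0) -> "PrescribedMotion":
        t = np.linspace(0.0, t_end, 8)
        return cls(time=t, x=np.zeros_like(t), z=np.zeros_like(t))

    def _splines_si(self, theta0: float):
        """PPoly (breaks, coeffs) triplets for the kernel; the rotation
        spline stores the absolute base angle."""
        xb, xc = self._sx.x, self._sx.c
        zb, zc = self._sz.x, self._sz.c
        if self._sr is not None:
            rb, rc = self._sr.x, self._sr.c.copy()
            rc[3] = rc[3] + theta0
        else:
            rb = np.array([self.time[0], self.time[-1]])
            rc = np.zeros((4, 1))
            rc[3, 0] = theta0
        return (np.ascontiguousarray(xb), np.ascontiguousarray(xc),
                np.ascontiguousarray(zb), np.ascontiguousarray(zc),
                np.ascontiguousarray(rb), np.ascontiguousarray(rc))


# -- compiled model ------------------------------------------------------------


class CompiledModel:
    """SI array form of a :class:`NeckModel` consumed by the kernel.

    Building it also solves for the gravity preload moments and verifies
    that the generalized mass matrix is positive definite at the initial
    state (a massless slider body must not make it singular).
    """

    def __init__(self, model: NeckModel):
        self.model = model
        moving = model.bodies[1:]
        base = model.bodies[0]
        n = len(moving)
        self.n = n
        self.S = np.array([[b.offset_S[0] * MM, b.offset_S[1] * MM]
                           for b in moving])
        self.G = np.array([[b.cg_local[0] * MM, b.cg_local[1] * MM]
                           for b in moving])
        self.mass = np.array([b.mass for b in moving])
        self.inertia = np.array([b.inertia_yy for b in moving])
        self.is_prism = np.array([1 if b.name == "Ca" else 0 for b in moving],
                                 dtype=np.uint8)
        self.U = np.zeros((n, 2))
        self.prism_idx = -1
        kv = cv = 0.0
        if model.prismatic is not None:
            self.prism_idx = int(np.argmax(self.is_prism))
            self.U[self.prism_idx] = model.prismatic.axis
            kv, cv = model.prismatic.kv, model.prismatic.cv
        self.kv, self.cv = kv, cv
        # relative initial angles (rad); zero for the prismatic slot
        phi0 = []
        prev = base.theta0
        for b in moving:
            phi0.append(0.0 if b.name == "Ca" else (b.theta0 - prev) * DEG)
            prev = b.theta0
        self.phi0 = np.array(phi0)
        # per-coordinate torsional laws (zeros at the prismatic slot)
        self.A1 = np.zeros(n)
        self.B1 = np.zeros(n)
        self.A2 = np.zeros(n)
        self.B2 = np.zeros(n)
        self.Cd = np.zeros(n)
        for k, b in enumerate(moving):
            jname = model.joint_of_body(b.name)
            if jname is None:
                continue
            jp = model.joints[jname]
            self.A1[k], self.B1[k] = jp.A1, jp.B1
            self.A2[k], self.B2[k] = jp.A2, jp.B2
            self.Cd[k] = jp.C
        self.m0 = base.mass
        self.I0 = base.inertia_yy
        self.G0 = np.array([base.cg_local[0] * MM, base.cg_local[1] * MM])
        self.O0 = np.array(model.t1_origin_mm) * MM
        self.theta0 = base.theta0 * DEG
        self.grav = model.gravity if model.gravity_enabled else 0.0
        self.body_names = tuple(b.name for b in moving)
        # reduced test chains have no head body; treat the tip as "head"
        self.head_idx = (self.body_names.index("C0")
                         if "C0" in self.body_names else n - 1)

        # gravity preload: cancel the static generalized forces at q = 0
        self.tau0 = np.zeros(n)
        still = PrescribedMotion.stationary()
        if self.grav != 0.0:
            out = self._eval(0.0, np.zeros(n), np.zeros(n), still)
            self.tau0 = -np.asarray(out[24])  # generalized force at rest
        # positive-definiteness check at the initial state
        Mmat = self.mass_matrix(np.zeros(n), still, 0.0)
        try:
            np.linalg.cholesky(Mmat)
        except np.linalg.LinAlgError as exc:
            raise ValueError("generalized mass matrix is singular at the "
                             "initial state (invalid massless "
                             "configuration)") from exc

    # -- kernel plumbing -------------------------------------------------------

    def _args(self, motion: PrescribedMotion):
        xb, xc, zb, zc, rb, rc = motion._splines_si(self.theta0)
        return (self.S, self.G, self.U, self.mass, self.inertia, self.phi0,
                self.is_prism, self.A1, self.B1, self.A2, self.B2, self.Cd,
                self.kv, self.cv, self.prism_idx, self.tau0,
                self.m0, self.I0, self.G0, self.O0,
                xb, xc, zb, zc, rb, rc, self.grav)

    def _eval(self, t, q, qd, motion):
        return _kernel.eval_full(t, np.asarray(q, float), np.asarray(qd, float),
                                 *self._args(motion))

    def mass_matrix(self, q, motion: PrescribedMotion, t: float = 0.0):
        """Generalized mass matrix ``M(q)`` at one state."""
        n = self.n
        q = np.asarray(q, float)
        out = self._eval(t, q, np.zeros(n), motion)
        return np.asarray(out[23])


def compile_model(model: NeckModel) -> CompiledModel:
    return CompiledModel(model)


def assemble_eom(model, q, qd, t, motion: PrescribedMotion,
                 compiled: Optional[CompiledModel] = None) -> np.ndarray:
    """Joint accelerations ``qdd`` solving ``M(q) qdd = Q(q, qd, t)``."""
    cm = compiled if compiled is not None else compile_model(model)
    q = np.asarray(q, dtype=float)
    qd = np.asarray(qd, dtype=float)
    if q.shape != (cm.n,) or qd.shape != (cm.n,):
        raise ValueError(f"expected {cm.n} coordinates")
    return np.asarray(cm._eval(t, q, qd, motion)[0])


# -- simulation results --------------------------------------------------------


@dataclass
class SimulationResult:
    """Time-gridded output channels of one forward simulation."""

    time: np.ndarray                 # (m,) s
    q: np.ndarray                    # (m, n) rad (prismatic slot: m)
    qd: np.ndarray                   # (m, n)
    qdd: np.ndarray                  # (m, n), evaluated from the EOM
    body_names: tuple                # moving bodies, chain order
    body_angle: np.ndarray           # (m, nb) rad, absolute
    body_omega: np.ndarray           # (m, nb) rad/s
    body_alpha: np.ndarray           # (m, nb) rad/s^2
    body_origin: np.ndarray          # (m, nb, 2) m, frame origins (joints)
    body_cg: np.ndarray              # (m, nb, 2) m
    body_cg_acc: np.ndarray          # (m, nb, 2) m/s^2
    t1_origin: np.ndarray            # (m, 2) m, recovered base trajectory
    t1_angle: np.ndarray             # (m,) rad
    head_acc: np.ndarray             # (m, 2) m/s^2
    head_acc_resultant_g: np.ndarray  # (m,) g
    oc_fx: np.ndarray                # (m,) N, head frame, anterior shear
    oc_fz: np.ndarray                # (m,) N, head frame, superior normal
    oc_my: np.ndarray                # (m,) Nm, flexion-positive
    kinetic: np.ndarray              # (m,) J
    potential: np.ndarray            # (m,) J (gravity + springs + preload)
    dissipated: np.ndarray           # (m,) J, cumulative damper loss
    work_input: np.ndarray           # (m,) J, cumulative support work
    model: NeckModel = field(repr=False, default=None)

    @property
    def head_index(self) -> int:
        if "C0" in self.body_names:
            return self.body_names.index("C0")
        return len(self.body_names) - 1  # reduced chains: the tip

    def angle_channel(self, body: str) -> np.ndarray:
        if body == "T1":
            return self.t1_angle
        return self.body_angle[:, self.body_names.index(body)]

    def oc_displacement_rel_t1(self) -> np.ndarray:
        """OC joint-point displacement relative to T1, minus its initial
        value; shape (m, 2)."""
        rel = self.body_origin[:, self.head_index, :] - self.t1_origin
        return rel - rel[0]

    def energy_residual(self) -> np.ndarray:
        """Work-energy closure ``(T + V) - (T+V)(0) - W + D`` (J)."""
        e = self.kinetic + self.potential
        return e - e[0] - self.work_input + self.dissipated

    def energy_residual_rel(self) -> float:
        """Max energy residual relative to the energy scale of the run."""
        scale = max(np.max(np.abs(self.kinetic + self.potential
                                  - self.kinetic[0] - self.potential[0])),
                    np.max(np.abs(self.work_input)),
                    np.max(self.dissipated), 1e-12)
        return float(np.max(np.abs(self.energy_residual())) / scale)


def simulate(model: NeckModel, motion: PrescribedMotion, t_end: float,
             output_rate: float = 10_000.0, rtol: float = 1e-8,
             atol: float = 1e-10,
             compiled: Optional[CompiledModel] = None) -> SimulationResult:
    """Integrate the chain over ``[0, t_end]``.

    ``qdd`` and all derived accelerations are obtained by evaluating the
    equations of motion at the output times, never by differencing.
    """
    if output_rate <= 0:
        raise ValueError("output_rate must be positive")
    if t_end > motion.t_end + 1e-12:
        raise ValueError(f"t_end = {t_end} exceeds the prescribed-motion "
                         f"coverage ({motion.t_end} s)")
    cm = compiled if compiled is not None else compile_model(model)
    n = cm.n
    m_out = int(round(t_end * output_rate)) + 1
    t_out = np.arange(m_out) / output_rate
    t_out[-1] = min(t_out[-1], t_end)
    y0 = np.zeros(2 * n + 2)
    args = cm._args(motion)
    Y, status, t_fail = _kernel.integrate(
        t_out, y0, *args, rtol, atol, 1.0 / output_rate)
    if status != 0:
        raise IntegrationError(t_fail)

    q = Y[:, :n]
    qd = Y[:, n:2 * n]
    D = Y[:, 2 * n]
    W = Y[:, 2 * n + 1]

    m = len(t_out)
    qdd = np.empty((m, n))
    body_angle = np.empty((m, n))
    body_omega = np.empty((m, n))
    body_alpha = np.empty((m, n))
    body_origin = np.empty((m, n, 2))
    body_cg = np.empty((m, n, 2))
    body_cg_acc = np.empty((m, n, 2))
    t1_origin = np.empty((m, 2))
    t1_angle = np.empty(m)
    kin = np.empty(m)
    pot = np.empty(m)
    for i, t in enumerate(t_out):
        out = _kernel.eval_full(t, q[i], qd[i], *args)
        (qdd_i, acg, alpha, theta, omega, Opos, rcg, _vcg,
         Tk, Vp, _Pd, _Pi, _Fsx, _Fsz,
         bxv, bzv, *_rest) = out
        th_b = out[20]
        qdd[i] = qdd_i
        body_angle[i] = theta
        body_omega[i] = omega
        body_alpha[i] = alpha
        body_origin[i] = Opos
        body_cg[i] = rcg
        body_cg_acc[i] = acg
        t1_origin[i] = cm.O0 + np.array([bxv, bzv])
        t1_angle[i] = th_b
        kin[i] = Tk
        pot[i] = Vp

    h = cm.head_idx
    head_acc = body_cg_acc[:, h, :]
    res_g = np.hypot(head_acc[:, 0], head_acc[:, 1]) / G_STANDARD

    result = SimulationResult(
        time=t_out, q=q, qd=qd, qdd=qdd, body_names=cm.body_names,
        body_angle=body_angle, body_omega=body_omega, body_alpha=body_alpha,
        body_origin=body_origin, body_cg=body_cg, body_cg_acc=body_cg_acc,
        t1_origin=t1_origin, t1_angle=t1_angle,
        head_acc=head_acc, head_acc_resultant_g=res_g,
        oc_fx=np.zeros(m), oc_fz=np.zeros(m), oc_my=np.zeros(m),
        kinetic=kin, potential=pot, dissipated=D, work_input=W,
        model=model)
    fx, fz, my = oc_loads(model, result)
    result.oc_fx, result.oc_fz, result.oc_my = fx, fz, my
    return result


def oc_loads(model: NeckModel, result: SimulationResult):
    """Occipital-condyle loads by inverse dynamics of the head body.

    Newton-Euler on the head alone: the joint reaction force is
    ``F = m_head (a_cg - g)``; the internal moment transmitted at the OC
    revolute (spring + damper + preload) follows from the angular
    equation ``I alpha = My + cross(p_oc - r_cg, F)``.  Forces are
    returned in the head local frame (Fx anterior, Fz superior), the
    moment is flexion-positive.
    """
    if result.body_cg_acc is None:
        raise ValueError("missing acceleration channels")
    # reduced test chains have no head body; the tip plays its role
    head_name = "C0" if "C0" in result.body_names else result.body_names[-1]
    h = result.body_names.index(head_name)
    head = model.body(head_name)
    mh, Ih = head.mass, head.inertia_yy
    g = model.gravity if model.gravity_enabled else 0.0
    acc = result.body_cg_acc[:, h, :]
    Fg = np.empty_like(acc)
    Fg[:, 0] = mh * acc[:, 0]
    Fg[:, 1] = mh * (acc[:, 1] + g)
    lever = result.body_origin[:, h, :] - result.body_cg[:, h, :]
    my = Ih * result.body_alpha[:, h] \
        - (lever[:, 1] * Fg[:, 0] - lever[:, 0] * Fg[:, 1])
    th = result.body_angle[:, h]
    c, s = np.cos(th), np.sin(th)
    # global -> head local: R(theta)^T for R = [[c, s], [-s, c]]
    fx = c * Fg[:, 0] - s * Fg[:, 1]
    fz = s * Fg[:, 0] + c * Fg[:, 1]
    return fx, fz, my
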