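"""Domain types and builders for the planar head-neck multibody chain.

The model is a serial chain of rigid bodies in the sagittal plane:
the first thoracic vertebra T1 (the driven base), the seven cervical
vertebrae C7..C1 and the head C0, optionally with a massless auxiliary
slider body Ca between C1 and the head.  Consecutive bodies are joined
by revolute joints equipped with nonlinear torsional springs
``M = A (exp(B*theta) - 1)`` and linear torsional dampers; the optional
C1-Ca element is a linear translational spring-damper.

Coordinate conventions
----------------------
* Global X is anterior (the direction of the sled acceleration), global
  Z is superior.
* Body angles are measured from the horizontal and are positive in
  flexion (forward rotation), so the local-to-global rotation matrix is
  ``R(theta) = [[cos, sin], [-sin, cos]]``.
* Joint coordinates are relative rotations measured from the seated
  initial posture, so all spring moments vanish at ``q = 0``.

Published table values are stored in mm and degrees; every quantity a
built model hands to the dynamics layer is SI (m, kg, s, rad).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import yaml

from . import presets

__all__ = [
    "BodySegment",
    "TorsionalJointParams",
    "TranslationalElementParams",
    "NeckModel",
    "build_model",
    "forward_kinematics",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
]

MM = 1e-3
DEG = math.pi / 180.0


def rotation_matrix(theta: float) -> np.ndarray:
    """Local-to-global rotation for a flexion-positive angle (rad)."""
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, s], [-s, c]])


@dataclass(frozen=True)
class BodySegment:
    """One rigid body of the chain, in published table units (mm, deg)."""

    name: str
    mass: float                      # kg
    inertia_yy: float                # kg m^2, about the out-of-plane axis
    offset_S: tuple[float, float]    # origin in the parent frame, mm
    cg_local: tuple[float, float]    # centre of mass in own frame, mm
    theta0: float                    # initial absolute angle, deg
    inertia_xx: float = 0.0          # stored for completeness, unused (planar)
    inertia_zz: float = 0.0

    def __post_init__(self) -> None:
        if self.mass < 0 or (self.mass == 0 and self.name != "Ca"):
            raise ValueError(f"body {self.name}: mass must be positive "
                             "(zero is allowed only for Ca)")
        if self.inertia_yy < 0 or (self.inertia_yy == 0 and self.name != "Ca"):
            raise ValueError(f"body {self.name}: inertia_yy must be positive "
                             "(zero is allowed only for Ca)")
        if self.name == "T1" and self.offset_S != (0.0, 0.0):
            raise ValueError("T1 is the base body and has no parent offset")


@dataclass(frozen=True)
class TorsionalJointParams:
    """Nonlinear torsional spring plus linear damper of one revolute joint.

    The moment-rotation law is ``M = A1 (exp(B1*theta) - 1)`` in extension
    (``theta < 0``) and ``M = A2 (exp(B2*theta) - 1)`` in flexion
    (``theta >= 0``); both branches vanish and join continuously at zero.
    An all-zero (A, B) pair disables the corresponding spring, which is
    useful for reduced test chains; the published presets always carry the
    strict sign pattern A1 < 0 < A2, B1 < 0 < B2.
    """

    joint_name: str
    A1: float  # Nm
    B1: float  # dimensionless
    A2: float  # Nm
    B2: float  # dimensionless
    C: float   # Nms/rad

    def __post_init__(self) -> None:
        if not (self.A1 < 0 < self.A2 and self.B1 < 0 < self.B2) and not (
            self.A1 == self.B1 == self.A2 == self.B2 == 0.0
        ):
            raise ValueError(
                f"joint {self.joint_name}: expected A1 < 0, B1 < 0, "
                "A2 > 0, B2 > 0 (or an all-zero disabled spring)")
        if self.C < 0:
            raise ValueError(f"joint {self.joint_name}: damping C must be >= 0")


@dataclass(frozen=True)
class TranslationalElementParams:
    """Linear spring-damper acting along the C1 -> Ca slider axis."""

    kv: float                        # N/m
    cv: float                        # Ns/m
    anchor: tuple[str, str] = ("C1", "Ca")
    axis: tuple[float, float] = (0.0, 1.0)  # unit vector in C1's frame

    def __post_init__(self) -> None:
        if self.kv <= 0:
            raise ValueError("prismatic stiffness kv must be positive")
        if self.cv < 0:
            raise ValueError("prismatic damping cv must be >= 0")
        n = math.hypot(*self.axis)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("prismatic axis must have unit norm")


@dataclass(frozen=True)
class NeckModel:
    """The assembled chain: bodies in order (base first) plus joint laws."""

    bodies: tuple[BodySegment, ...]
    joints: dict[str, TorsionalJointParams]
    prismatic: Optional[TranslationalElementParams] = None
    t1_origin_mm: tuple[float, float] = presets.T1_GLOBAL_ORIGIN_MM
    gravity_enabled: bool = True
    gravity: float = presets.GRAVITY_M_PER_S2
    name: str = "custom"

    def __post_init__(self) -> None:
        names = [b.name for b in self.bodies]
        if len(set(names)) != len(names):
            raise ValueError("duplicate body names")
        if self.prismatic is not None and "Ca" not in names:
            raise ValueError("a prismatic element requires the Ca body")
        if "Ca" in names and self.prismatic is None:
            raise ValueError("the Ca body requires a prismatic element")
        expected = list(presets.CHAIN_ORDER)
        if set(names) >= set(expected):
            # full chain: enforce the canonical ordering, with Ca (when
            # present) spliced between C1 and the head
            full = expected[:-1] + (["Ca"] if "Ca" in names else []) + ["C0"]
            if names != full:
                raise ValueError(f"chain order must be {full}, got {names}")

    # -- convenience accessors -------------------------------------------------

    @property
    def body_names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.bodies)

    @property
    def n_coordinates(self) -> int:
        """One coordinate per moving body (revolute angle or slider offset)."""
        return len(self.bodies) - 1

    def body(self, name: str) -> BodySegment:
        for b in self.bodies:
            if b.name == name:
                return b
        raise KeyError(name)

    def total_mass(self, include_base: bool = True) -> float:
        return sum(b.mass for b in self.bodies if include_base or b.name != "T1")

    def joint_of_body(self, name: str) -> Optional[str]:
        """Joint name of the revolute coordinate that carries this body."""
        i = self.body_names.index(name)
        if i == 0:
            return None
        parent = self.body_names[i - 1]
        if name == "Ca":
            return None  # prismatic coordinate
        if name == "C0" and parent == "Ca":
            return "C0/C1"  # relocated joint keeps its original name
        return f"{name}/{parent}"

    def with_parameter(self, variable: str, value: float) -> "NeckModel":
        """Return a copy with one design variable replaced.

        ``variable`` is either ``"<joint>.<coeff>"`` with coeff in
        {A1, B1, A2, B2, C}, or ``"kv"`` / ``"cv"``.
        """
        if variable in ("kv", "cv"):
            if self.prismatic is None:
                raise ValueError("model has no prismatic element")
            return replace(self, joints=dict(self.joints),
                           prismatic=replace(self.prismatic, **{variable: value}))
        joint, _, coeff = variable.partition(".")
        if joint not in self.joints or coeff not in ("A1", "B1", "A2", "B2", "C"):
            raise KeyError(variable)
        joints = dict(self.joints)
        joints[joint] = replace(joints[joint], **{coeff: value})
        return replace(self, joints=joints)

    def get_parameter(self, variable: str) -> float:
        if variable in ("kv", "cv"):
            if self.prismatic is None:
                raise ValueError("model has no prismatic element")
            return getattr(self.prismatic, variable)
        joint, _, coeff = variable.partition(".")
        if joint not in self.joints or coeff not in ("A1", "B1", "A2", "B2", "C"):
            raise KeyError(variable)
        return getattr(self.joints[joint], coeff)

    def config_hash(self) -> str:
        payload = yaml.safe_dump(model_to_dict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# -- builders ------------------------------------------------------------------


def _body_from_table(name: str) -> BodySegment:
    m, ixx, iyy, izz, sx, sz, gx, gz, th = presets.BODY_TABLE[name]
    return BodySegment(name=name, mass=m, inertia_yy=iyy, inertia_xx=ixx,
                       inertia_zz=izz, offset_S=(sx, sz), cg_local=(gx, gz),
                       theta0=th)


def _ca_bodies() -> tuple[BodySegment, BodySegment]:
    """The massless slider Ca and the head re-seated on it.

    Ca shares C1's orientation; the relocated head revolute keeps its
    original position, so the head offset in Ca's frame is the original
    C1-frame offset minus Ca's offset.
    """
    c1_theta = presets.BODY_TABLE["C1"][8]
    head = _body_from_table("C0")
    cax, caz = presets.CA_OFFSET_MM
    ca = BodySegment(name="Ca", mass=0.0, inertia_yy=0.0,
                     offset_S=(cax, caz), cg_local=(0.0, 0.0), theta0=c1_theta)
    head_offset = (head.offset_S[0] - cax, head.offset_S[1] - caz)
    return ca, replace(head, offset_S=head_offset)


def build_model(preset: str, variant: str = "baseline") -> NeckModel:
    """Assemble a preset chain.

    Parameters
    ----------
    preset:
        ``"V1-initial"`` (experimental stiffness, uniform 1.8 Nms/rad
        damping) or ``"V5B-final"`` (identified coefficients with the
        prismatic element).
    variant:
        ``"baseline"`` (8 revolute joints) or ``"with_prismatic"``
        (adds the Ca slider).  The final preset exists only with the
        prismatic element; the initial preset defaults to baseline but
        may be built with the slider at its trial values (10 kN/m,
        100 Ns/m), which is the starting point of the modified-model
        identification.
    """
    if preset not in presets.PRESET_NAMES:
        raise ValueError(f"unknown preset {preset!r}; "
                         f"expected one of {presets.PRESET_NAMES}")
    if variant not in ("baseline", "with_prismatic"):
        raise ValueError(f"unknown variant {variant!r}")
    if preset == "V5B-final" and variant != "with_prismatic":
        raise ValueError("the V5B-final preset includes the prismatic "
                         "element; request variant='with_prismatic'")

    if preset == "V1-initial":
        joints = {
            j: TorsionalJointParams(j, *presets.STIFFNESS_INITIAL[j],
                                    C=presets.DAMPING_INITIAL_NMS_PER_RAD)
            for j in presets.JOINT_ORDER
        }
        kv = presets.PRISMATIC_KV_INITIAL_N_PER_M
        cv = presets.PRISMATIC_CV_INITIAL_NS_PER_M
    else:
        joints = {
            j: TorsionalJointParams(j, *presets.STIFFNESS_FINAL[j])
            for j in presets.JOINT_ORDER
        }
        kv = presets.PRISMATIC_KV_FINAL_N_PER_M
        cv = presets.PRISMATIC_CV_FINAL_NS_PER_M

    bodies = [_body_from_table(n) for n in presets.CHAIN_ORDER[:-1]]
    prismatic = None
    if variant == "with_prismatic":
        ca, head = _ca_bodies()
        bodies += [ca, head]
        sx, sz = presets.CA_OFFSET_MM
        n = math.hypot(sx, sz)
        prismatic = TranslationalElementParams(kv=kv, cv=cv,
                                               axis=(sx / n, sz / n))
    else:
        bodies.append(_body_from_table("C0"))

    model = NeckModel(bodies=tuple(bodies), joints=joints,
                      prismatic=prismatic, name=f"{preset}:{variant}")
    # A massless slider must not make the generalized mass matrix singular;
    # compiling the model verifies positive definiteness at the initial state.
    from .dynamics import compile_model
    compile_model(model)
    return model


# -- forward kinematics --------------------------------------------------------


def forward_kinematics(model: NeckModel, q) -> dict[str, dict]:
    """Global pose of every body for joint coordinates ``q``.

    ``q`` holds one relative rotation (rad) per revolute joint, ordered
    bottom-up, plus the slider offset (m) in the Ca slot when the
    prismatic element is present; ``q = 0`` is the seated initial
    posture.  Returns ``{body: {"origin": (2,) m, "cg": (2,) m,
    "angle": rad}}``.
    """
    q = np.asarray(q, dtype=float)
    if q.shape != (model.n_coordinates,):
        raise ValueError(f"expected {model.n_coordinates} joint coordinates, "
                         f"got shape {q.shape}")
    out: dict[str, dict] = {}
    base = model.bodies[0]
    theta = base.theta0 * DEG
    origin = np.asarray(model.t1_origin_mm) * MM
    out[base.name] = {
        "origin": origin,
        "cg": origin + rotation_matrix(theta) @ (np.asarray(base.cg_local) * MM),
        "angle": theta,
    }
    prev_theta0 = base.theta0
    for k, body in enumerate(model.bodies[1:]):
        R_parent = rotation_matrix(theta)
        if body.name == "Ca":
            axis = np.asarray(model.prismatic.axis)
            d = np.asarray(body.offset_S) * MM + q[k] * axis
            origin = origin + R_parent @ d
            # translation joint: orientation follows the parent
        else:
            origin = origin + R_parent @ (np.asarray(body.offset_S) * MM)
            theta = theta + (body.theta0 - prev_theta0) * DEG + q[k]
        prev_theta0 = body.theta0
        out[body.name] = {
            "origin": origin,
            "cg": origin + rotation_matrix(theta) @ (np.asarray(body.cg_local) * MM),
            "angle": theta,
        }
    return out


# -- config round-trip ---------------------------------------------------------


def model_to_dict(model: NeckModel) -> dict:
    d: dict = {
        "bodies": {
            b.name: {
                "mass_kg": b.mass,
                "inertia_yy_kgm2": b.inertia_yy,
                "inertia_xx_kgm2": b.inertia_xx,
                "inertia_zz_kgm2": b.inertia_zz,
                "offset_S_mm": list(b.offset_S),
                "cg_mm": list(b.cg_local),
                "theta0_deg": b.theta0,
            }
            for b in model.bodies
        },
        "body_order": list(model.body_names),
        "joints": {
            j.joint_name: {"A1_Nm": j.A1, "B1": j.B1, "A2_Nm": j.A2,
                           "B2": j.B2, "C_Nms_per_rad": j.C}
            for j in model.joints.values()
        },
        "options": {
            "t1_origin_mm": list(model.t1_origin_mm),
            "gravity_enabled": model.gravity_enabled,
            "gravity_m_per_s2": model.gravity,
            "name": model.name,
        },
    }
    if model.prismatic is not None:
        p = model.prismatic
        d["prismatic"] = {"kv_N_per_m": p.kv, "cv_Ns_per_m": p.cv,
                          "anchor": list(p.anchor), "axis": list(p.axis)}
    return d


def model_from_dict(d: dict) -> NeckModel:
    bodies = tuple(
        BodySegment(
            name=name,
            mass=bd["mass_kg"],
            inertia_yy=bd["inertia_yy_kgm2"],
            inertia_xx=bd.get("inertia_xx_kgm2", 0.0),
            inertia_zz=bd.get("inertia_zz_kgm2", 0.0),
            offset_S=tuple(bd["offset_S_mm"]),
            cg_local=tuple(bd["cg_mm"]),
            theta0=bd["theta0_deg"],
        )
        for name in d["body_order"]
        for bd in (d["bodies"][name],)
    )
    joints = {
        name: TorsionalJointParams(name, A1=jd["A1_Nm"], B1=jd["B1"],
                                   A2=jd["A2_Nm"], B2=jd["B2"],
                                   C=jd["C_Nms_per_rad"])
        for name, jd in d["joints"].items()
    }
    prismatic = None
    if "prismatic" in d:
        pd = d["prismatic"]
        prismatic = TranslationalElementParams(
            kv=pd["kv_N_per_m"], cv=pd["cv_Ns_per_m"],
            anchor=tuple(pd["anchor"]), axis=tuple(pd["axis"]))
    opts = d.get("options", {})
    return NeckModel(
        bodies=bodies, joints=joints, prismatic=prismatic,
        t1_origin_mm=tuple(opts.get("t1_origin_mm",
                                    presets.T1_GLOBAL_ORIGIN_MM)),
        gravity_enabled=opts.get("gravity_enabled", True),
        gravity=opts.get("gravity_m_per_s2", presets.GRAVITY_M_PER_S2),
        name=opts.get("name", "custom"),
    )


def save_model(model: NeckModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=True)


def load_model(path) -> NeckModel:
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))
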