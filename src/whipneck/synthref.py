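"""Synthetic reference generation.

The identification pipeline needs reference kinematics of a trusted
occupant model under the rigid-seat rear-impact sled scenario
(12 g peak, delta-V = 10 km/h).  This module generates that scenario
parametrically: a canonical crash pulse fully determined by its peak
and velocity change, the T1 base motion obtained by double integration
of the pulse, and reference kinematics produced by simulating a chain
model with known ("true") parameters, optionally with seeded Gaussian
channel noise.  Because the generating parameters are known, parameter
recovery can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid

from . import presets
from .dynamics import PrescribedMotion, simulate
from .model import NeckModel

__all__ = [
    "CrashPulse",
    "ReferenceKinematics",
    "generate_pulse",
    "pulse_to_motion",
    "generate_reference",
]

G = 9.81


@dataclass
class CrashPulse:
    """Platform acceleration pulse of a rear-end impact."""

    shape: str                 # "haversine" or "trapezoid"
    peak: float                # g
    delta_v: float             # m/s
    onset: float               # s
    duration: float            # s
    time: np.ndarray           # s
    acceleration: np.ndarray   # m/s^2

    def integral(self) -> float:
        return float(np.trapezoid(self.acceleration, self.time))


def generate_pulse(peak: float, delta_v: float, shape: str = "haversine",
                   onset: float = 0.0, grid_dt: float = 1e-4) -> CrashPulse:
    """Canonical pulse with the requested peak (g) and velocity change.

    For the haversine ``a(t) = (peak/2)(1 - cos(2 pi t / T))`` the mean
    equals half the peak, so the duration is the closed form
    ``T = 2 delta_v / (peak * g)``.  The trapezoid uses 20% ramps on
    each side.  A zero delta-V yields an identically zero pulse.
    """
    if delta_v < 0:
        raise ValueError("delta_v must be non-negative")
    if delta_v == 0.0:
        t = np.arange(0.0, max(onset, 0.01) + grid_dt, grid_dt)
        return CrashPulse(shape, peak=0.0, delta_v=0.0, onset=onset,
                          duration=0.0, time=t,
                          acceleration=np.zeros_like(t))
    if peak <= 0:
        raise ValueError("peak must be positive for a nonzero delta_v")
    peak_ms2 = peak * G
    if shape == "haversine":
        duration = 2.0 * delta_v / peak_ms2
    elif shape == "trapezoid":
        ramp = 0.2
        duration = delta_v / (peak_ms2 * (1.0 - ramp))
    else:
        raise ValueError(f"unknown pulse shape {shape!r}")
    t = np.arange(0.0, onset + duration + grid_dt, grid_dt)
    # land exactly on the pulse end to keep the quadrature clean
    if t[-1] < onset + duration:
        t = np.append(t, onset + duration)
    a = np.zeros_like(t)
    s = (t - onset) / duration
    inside = (s >= 0.0) & (s <= 1.0)
    if shape == "haversine":
        a[inside] = 0.5 * peak_ms2 * (1.0 - np.cos(2.0 * np.pi * s[inside]))
    else:
        ramp = 0.2
        si = s[inside]
        prof = np.minimum(np.minimum(si / ramp, (1.0 - si) / ramp), 1.0)
        a[inside] = peak_ms2 * np.clip(prof, 0.0, 1.0)
        # rescale so the trapezoidal integral matches delta_v exactly
        integ = np.trapezoid(a, t)
        a *= delta_v / integ
    return CrashPulse(shape=shape, peak=peak, delta_v=delta_v, onset=onset,
                      duration=duration, time=t, acceleration=a)


def pulse_to_motion(pulse: CrashPulse, t_end: float) -> PrescribedMotion:
    """Double-integrate the platform pulse into T1 anterior displacement.

    After the pulse the base coasts at delta-V.  Vertical displacement is
    zero: the synthetic scenario drives T1 in translation only.
    """
    if t_end < pulse.time[-1]:
        raise ValueError("t_end must cover the pulse span")
    t = pulse.time
    if t[-1] < t_end:
        # extend the grid at the pulse resolution
        dt = t[1] - t[0] if len(t) > 1 else 1e-4
        ext = np.arange(t[-1] + dt, t_end + dt, dt)
        if len(ext) == 0 or ext[-1] < t_end:
            ext = np.append(ext, t_end)
        t = np.concatenate([t, ext])
    a = np.zeros_like(t)
    a[:len(pulse.acceleration)] = pulse.acceleration
    v = cumulative_trapezoid(a, t, initial=0.0)
    x = cumulative_trapezoid(v, t, initial=0.0)
    return PrescribedMotion(time=t, x=x, z=np.zeros_like(t))


@dataclass
class ReferenceKinematics:
    """Target channels for identification: per-body absolute angles and
    the OC-point displacement relative to T1."""

    time: np.ndarray                      # s
    angles: dict                          # body -> (m,) rad, absolute
    oc_displacement: np.ndarray           # (m, 2) m, relative to T1
    motion: PrescribedMotion = field(repr=False, default=None)
    true_model: Optional[NeckModel] = field(repr=False, default=None)
    noise_sd: float = 0.0
    seed: Optional[int] = None

    def angle(self, body: str) -> np.ndarray:
        return self.angles[body]

    @property
    def bodies(self) -> tuple:
        return tuple(self.angles.keys())


def generate_reference(true_model: NeckModel, motion: PrescribedMotion,
                       noise_sd: float = 0.0, seed: Optional[int] = None,
                       t_end: Optional[float] = None,
                       output_rate: float = 10_000.0,
                       rtol: float = 1e-8) -> ReferenceKinematics:
    """Simulate a known model and expose its channels as the reference.

    ``noise_sd`` adds independent Gaussian noise (rad on angle channels,
    m on OC displacements), drawn from a seeded generator so references
    are reproducible.
    """
    t_end = motion.t_end if t_end is None else t_end
    res = simulate(true_model, motion, t_end, output_rate=output_rate,
                   rtol=rtol)
    rng = np.random.default_rng(seed)
    angles = {}
    for name in res.body_names:
        if name == "Ca":
            continue
        ch = res.angle_channel(name).copy()
        if noise_sd > 0.0:
            ch += rng.normal(0.0, noise_sd, size=ch.shape)
        angles[name] = ch
    oc = res.oc_displacement_rel_t1().copy()
    if noise_sd > 0.0:
        oc += rng.normal(0.0, noise_sd, size=oc.shape)
    return ReferenceKinematics(time=res.time, angles=angles,
                               oc_displacement=oc, motion=motion,
                               true_model=true_model, noise_sd=noise_sd,
                               seed=seed)


def lab_sled_motion(t_end: float = 0.3) -> PrescribedMotion:
    """The default study scenario: 12 g, delta-V = 10 km/h haversine."""
    pulse = generate_pulse(presets.LAB_PULSE_PEAK_G,
                           presets.LAB_PULSE_DELTA_V_KMH / 3.6)
    return pulse_to_motion(pulse, t_end)
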