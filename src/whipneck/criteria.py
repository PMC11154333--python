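"""Head and neck injury criteria.

HIC (Head Injury Criterion): the maximum over all sliding windows
``(t1, t2)`` of ``(t2 - t1) * [mean resultant head acceleration]^2.5``
with the acceleration in g and time in seconds.  Without direct head
contact the window is capped at 36 ms (HIC36).  The window search runs
over grid-point pairs using cumulative trapezoidal sums, which is
algebraically identical to the O(n^2) exhaustive search.

Nkm: a linear combination of the normalized occipital-condyle shear
force Fx(t) and sagittal bending moment My(t),
``Nkm(t) = Fx/Fint + My/Mint``.  Four load cases exist, indexed by the
moment sense (f flexion / e extension) and the shear direction
(a anterior / p posterior); each time sample contributes only to the
cases matching the signs of its force and moment.  The normalization
constants are Fint = +/-845 N and Mint = 88.1 Nm (flexion) or
-47.5 Nm (extension).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import presets

__all__ = ["CriteriaResult", "hic", "nkm", "hic_deviation",
           "evaluate_criteria"]


@dataclass
class CriteriaResult:
    """Injury-criteria summary of one run."""

    hic36: float
    hic_window: tuple            # (t1, t2) s
    n_ep: float
    n_fp: float
    n_ea: float
    n_fa: float
    n_ep_time: float = float("nan")
    n_fp_time: float = float("nan")
    n_ea_time: float = float("nan")
    n_fa_time: float = float("nan")
    constants: dict = field(default_factory=lambda: {
        "Fint_N": presets.NKM_FINT_N,
        "Mint_flexion_Nm": presets.NKM_MINT_FLEXION_NM,
        "Mint_extension_Nm": -presets.NKM_MINT_EXTENSION_NM,
    })

    def __post_init__(self) -> None:
        for name in ("hic36", "n_ep", "n_fp", "n_ea", "n_fa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        t1, t2 = self.hic_window
        if t2 - t1 > 0.036 + 1e-12:
            raise ValueError("HIC36 window exceeds 36 ms")

    def as_dict(self) -> dict:
        return {
            "hic36": self.hic36,
            "hic_t1_s": self.hic_window[0],
            "hic_t2_s": self.hic_window[1],
            "n_ep": self.n_ep, "n_fp": self.n_fp,
            "n_ea": self.n_ea, "n_fa": self.n_fa,
        }


def _check_uniform(time: np.ndarray) -> float:
    dt = np.diff(time)
    if len(dt) == 0 or dt[0] <= 0:
        raise ValueError("need at least two increasing time samples")
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValueError("HIC requires a uniform time grid")
    return float(dt[0])


def hic(time: np.ndarray, a_resultant_g: np.ndarray,
        max_window: float = 0.036):
    """Head Injury Criterion over windows up to ``max_window`` seconds.

    Parameters are the uniform time grid (s) and the non-negative
    resultant head CG acceleration (g).  Returns ``(value, t1, t2)``.
    """
    time = np.asarray(time, dtype=float)
    a = np.asarray(a_resultant_g, dtype=float)
    if a.shape != time.shape:
        raise ValueError("acceleration and time grids differ")
    if np.any(a < 0):
        raise ValueError("resultant acceleration must be non-negative")
    dt = _check_uniform(time)
    n = len(time)
    # cumulative trapezoid: ct[i] = integral of a over [t0, t_i]
    ct = np.concatenate([[0.0], np.cumsum(0.5 * (a[1:] + a[:-1]) * dt)])
    kmax = min(n - 1, int(np.floor(max_window / dt + 1e-9)))
    best = 0.0
    best_pair = (time[0], time[0])
    for k in range(1, kmax + 1):
        span = k * dt
        avg = (ct[k:] - ct[:-k]) / span
        # avg^2.5 as avg*avg*sqrt(avg): multiplication and sqrt are
        # correctly rounded by IEEE 754, so the result is bit-identical
        # whether evaluated on arrays or scalars (pow is not)
        vals = span * (avg * avg * np.sqrt(avg))
        i = int(np.argmax(vals))
        if vals[i] > best:
            best = float(vals[i])
            best_pair = (time[i], time[i + k])
    return best, best_pair[0], best_pair[1]


def nkm(time: np.ndarray, fx: np.ndarray, my: np.ndarray,
        fint: float = presets.NKM_FINT_N,
        mint_flexion: float = presets.NKM_MINT_FLEXION_NM,
        mint_extension: float = presets.NKM_MINT_EXTENSION_NM):
    """Four-case Nkm maxima from OC shear (N, anterior > 0) and sagittal
    moment (Nm, flexion > 0) sharing one time grid.

    Returns ``{case: (max value, time of max)}`` for cases
    ``n_fa, n_fp, n_ea, n_ep``.
    """
    time = np.asarray(time, dtype=float)
    fx = np.asarray(fx, dtype=float)
    my = np.asarray(my, dtype=float)
    if fx.shape != time.shape or my.shape != time.shape:
        raise ValueError("channel grids differ")
    fa = np.maximum(fx, 0.0) / fint
    fp = np.maximum(-fx, 0.0) / fint
    mf = np.maximum(my, 0.0) / mint_flexion
    me = np.maximum(-my, 0.0) / mint_extension
    series = {
        "n_fa": fa + mf,
        "n_fp": fp + mf,
        "n_ea": fa + me,
        "n_ep": fp + me,
    }
    out = {}
    for case, s in series.items():
        i = int(np.argmax(s))
        out[case] = (float(s[i]), float(time[i]))
    return out


def hic_deviation(hic_model: float, hic_reference: float) -> float:
    """Signed relative deviation of a model HIC from its reference (%)."""
    if hic_reference == 0:
        raise ValueError("reference HIC must be nonzero")
    return 100.0 * (hic_model - hic_reference) / hic_reference


def evaluate_criteria(result, max_window: float = 0.036) -> CriteriaResult:
    """Injury criteria of a :class:`whipneck.dynamics.SimulationResult`."""
    value, t1, t2 = hic(result.time, result.head_acc_resultant_g,
                        max_window=max_window)
    cases = nkm(result.time, result.oc_fx, result.oc_my)
    return CriteriaResult(
        hic36=value, hic_window=(t1, t2),
        n_ep=cases["n_ep"][0], n_fp=cases["n_fp"][0],
        n_ea=cases["n_ea"][0], n_fa=cases["n_fa"][0],
        n_ep_time=cases["n_ep"][1], n_fp_time=cases["n_fp"][1],
        n_ea_time=cases["n_ea"][1], n_fa_time=cases["n_fa"][1])
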