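"""Sequential parameter identification of the joint constitutive laws.

The multiobjective fit (one RMS objective per body angle, plus an
occipital-displacement objective for the slider-equipped model) is
solved as a sequence of single-objective bounded optimizations: starting
at the bottom vertebra, each step minimizes one body's RMS deviation
over the few design variables that dominate it, and the whole sequence
is repeated until the improvements become negligible.

Design variables are the spring coefficients A1, B1, A2, B2 and the
damping C of each joint (40 variables), plus kv and cv when the
prismatic element is present (42).  Each variable is boxed to +/-25% of
its value in the starting model.  The optimizer is a bounded
quasi-Newton method (L-BFGS-B) with central finite-difference gradients
(relative step 1e-3); any bounded gradient-based local optimizer
fulfils the same contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import minimize

from .dynamics import simulate
from .model import NeckModel
from .synthref import ReferenceKinematics

__all__ = [
    "DesignVariable", "DesignVector", "IdentificationStep",
    "IdentificationSchedule", "rms_deviation", "sensitivity_analysis",
    "identify_step", "sequential_identify", "bottom_up_schedule",
    "table3_sequences", "table4_schedule", "save_schedule", "load_schedule",
    "IdentifySettings",
]

JOINT_COEFFS = ("A1", "B1", "A2", "B2", "C")
BOUND_FRACTION = 0.25


@dataclass
class IdentifySettings:
    """Numerical settings of the identification simulations."""

    rtol: float = 1e-6
    atol: float = 1e-9
    fd_step: float = 1e-3        # relative, central differences
    maxiter: int = 30
    # RMS objectives can be tiny (rad scale); keep the stagnation
    # threshold far below them or L-BFGS-B stops on its first iterate
    ftol: float = 1e-14


@dataclass(frozen=True)
class DesignVariable:
    name: str          # "<joint>.<coeff>", "kv" or "cv"
    value: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (min(self.lower, self.upper) <= self.value
                <= max(self.lower, self.upper)):
            raise ValueError(f"{self.name}: bounds do not bracket the value")


@dataclass
class DesignVector:
    """The identifiable parameters with their +/-25% boxes."""

    variables: tuple
    provenance: str = ""

    @classmethod
    def from_model(cls, model: NeckModel,
                   fraction: float = BOUND_FRACTION) -> "DesignVector":
        entries = []
        for joint in model.joints:
            for coeff in JOINT_COEFFS:
                name = f"{joint}.{coeff}"
                v = model.get_parameter(name)
                lo, hi = sorted((v * (1 - fraction), v * (1 + fraction)))
                entries.append(DesignVariable(name, v, lo, hi))
        if model.prismatic is not None:
            for name in ("kv", "cv"):
                v = model.get_parameter(name)
                lo, hi = sorted((v * (1 - fraction), v * (1 + fraction)))
                entries.append(DesignVariable(name, v, lo, hi))
        return cls(variables=tuple(entries), provenance=model.name)

    def __len__(self) -> int:
        return len(self.variables)

    def names(self) -> tuple:
        return tuple(v.name for v in self.variables)

    def bounds_of(self, name: str) -> tuple:
        for v in self.variables:
            if v.name == name:
                return (v.lower, v.upper)
        raise KeyError(name)


@dataclass(frozen=True)
class IdentificationStep:
    objective: str                # "RMS_C7" .. "RMS_C0" or "RMS_OC"
    variables: tuple              # design-variable names active in the step


@dataclass
class IdentificationSchedule:
    """One optimization sequence: ordered single-objective steps."""

    steps: tuple
    name: str = ""

    def validate(self, design: DesignVector) -> None:
        names = set(design.names())
        for step in self.steps:
            missing = set(step.variables) - names
            if missing:
                raise ValueError(f"step {step.objective}: unknown design "
                                 f"variables {sorted(missing)}")


# -- objectives ------------------------------------------------------------------


def rms_deviation(sim_channel, ref_channel,
                  sim_time=None, ref_time=None) -> float:
    """Root-mean-square deviation between two channels.

    If both time grids are given, the simulated channel is resampled
    onto the reference grid by linear interpolation first.
    """
    sim = np.asarray(sim_channel, dtype=float)
    ref = np.asarray(ref_channel, dtype=float)
    if sim_time is not None and ref_time is not None:
        sim = np.interp(ref_time, sim_time, sim)
    if sim.shape != ref.shape:
        raise ValueError("channels do not share a grid and no time "
                         "vectors were given for resampling")
    if sim.size == 0:
        raise ValueError("empty overlap")
    return float(np.sqrt(np.mean((sim - ref) ** 2)))


def _objective_bodies(model: NeckModel) -> tuple:
    return tuple(n for n in model.body_names if n not in ("T1", "Ca"))


def objective_labels(model: NeckModel) -> tuple:
    labels = tuple(f"RMS_{n}" for n in _objective_bodies(model))
    if model.prismatic is not None:
        labels = labels + ("RMS_OC",)
    return labels


def evaluate_objectives(model: NeckModel, reference: ReferenceKinematics,
                        settings: Optional[IdentifySettings] = None) -> dict:
    """All RMS objectives of one model against the reference."""
    settings = settings or IdentifySettings()
    rate = 1.0 / float(np.mean(np.diff(reference.time)))
    res = simulate(model, reference.motion, float(reference.time[-1]),
                   output_rate=rate, rtol=settings.rtol, atol=settings.atol)
    out = {}
    for name in _objective_bodies(model):
        out[f"RMS_{name}"] = rms_deviation(
            res.angle_channel(name), reference.angle(name),
            sim_time=res.time, ref_time=reference.time)
    if model.prismatic is not None:
        oc = res.oc_displacement_rel_t1()
        dx = np.interp(reference.time, res.time, oc[:, 0]) \
            - reference.oc_displacement[:, 0]
        dz = np.interp(reference.time, res.time, oc[:, 1]) \
            - reference.oc_displacement[:, 1]
        out["RMS_OC"] = float(np.sqrt(np.mean(dx ** 2 + dz ** 2)))
    return out


def _single_objective(model, reference, objective, settings) -> float:
    return evaluate_objectives(model, reference, settings)[objective]


def _apply(model: NeckModel, names: Sequence[str],
           values: Sequence[float]) -> NeckModel:
    for name, v in zip(names, values):
        model = model.with_parameter(name, float(v))
    return model


# -- sensitivity screening -------------------------------------------------------


def sensitivity_analysis(model: NeckModel, reference: ReferenceKinematics,
                         perturbation: float = 0.25,
                         variables: Optional[Sequence[str]] = None,
                         settings: Optional[IdentifySettings] = None
                         ) -> pd.DataFrame:
    """Influence table: relative RMS change per design variable.

    Each variable is scaled by ``(1 + perturbation)`` in turn and every
    objective is re-evaluated; the table holds
    ``(RMS_perturbed - RMS_baseline) / RMS_baseline``.  A simulation
    failure under a perturbation is recorded as NaN, not raised.
    """
    settings = settings or IdentifySettings()
    design = DesignVector.from_model(model)
    names = list(variables) if variables is not None else list(design.names())
    base = evaluate_objectives(model, reference, settings)
    rows = {}
    for name in names:
        v0 = model.get_parameter(name)
        try:
            pert = evaluate_objectives(
                model.with_parameter(name, v0 * (1.0 + perturbation)),
                reference, settings)
            rows[name] = {k: (pert[k] - base[k]) / max(base[k], 1e-15)
                          for k in base}
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"sensitivity simulation failed for {name}: {exc}")
            rows[name] = {k: np.nan for k in base}
    return pd.DataFrame.from_dict(rows, orient="index")


def build_schedule_from_sensitivity(table: pd.DataFrame, model: NeckModel,
                                    threshold: float = 0.01
                                    ) -> IdentificationSchedule:
    """Bottom-up schedule whose steps include every variable whose 25%
    perturbation changes that step's objective by more than ``threshold``."""
    steps = []
    for label in objective_labels(model):
        if label not in table.columns:
            continue
        mask = table[label].abs() > threshold
        chosen = tuple(table.index[mask])
        if chosen:
            steps.append(IdentificationStep(label, chosen))
    return IdentificationSchedule(tuple(steps), name="sensitivity-derived")


# -- single-step optimization ----------------------------------------------------


def identify_step(model: NeckModel, reference: ReferenceKinematics,
                  objective: str, variables: Sequence[str],
                  bounds: Optional[dict] = None,
                  settings: Optional[IdentifySettings] = None):
    """Minimize one RMS objective over a subset of design variables.

    Bounded local optimization with central finite-difference gradients;
    parameters are optimized as ratios to their starting values so the
    box is ``[0.75, 1.25]`` in scaled space by default.  Returns
    ``(updated model, history)`` where the history records the RMS
    trajectory and a warning flag; the final objective never exceeds the
    starting one (the best iterate is kept).
    """
    settings = settings or IdentifySettings()
    variables = list(variables)
    start = np.array([model.get_parameter(v) for v in variables])
    if np.any(start == 0.0):
        raise ValueError("zero-valued design variables cannot be scaled")
    if bounds is None:
        design = DesignVector.from_model(model)
        bounds = {v: design.bounds_of(v) for v in variables}
    lo = np.array([bounds[v][0] for v in variables]) / start
    hi = np.array([bounds[v][1] for v in variables]) / start
    lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)

    best = {"f": np.inf, "x": np.ones(len(variables))}
    history = []

    def fun(x):
        m = _apply(model, variables, start * x)
        f = _single_objective(m, reference, objective, settings)
        if f < best["f"]:
            best["f"], best["x"] = f, x.copy()
        return f

    def jac(x):
        g = np.empty(len(x))
        for i in range(len(x)):
            h = settings.fd_step * max(abs(x[i]), 1e-6)
            xp, xm = x.copy(), x.copy()
            xp[i] = min(x[i] + h, hi[i])
            xm[i] = max(x[i] - h, lo[i])
            denom = xp[i] - xm[i]
            g[i] = (fun(xp) - fun(xm)) / denom if denom > 0 else 0.0
        return g

    x0 = np.clip(np.ones(len(variables)), lo, hi)
    f0 = fun(x0)
    history.append(f0)
    warn = False
    try:
        opt = minimize(fun, x0, jac=jac, method="L-BFGS-B",
                       bounds=list(zip(lo, hi)),
                       callback=lambda xk: history.append(fun(xk)),
                       options={"maxiter": settings.maxiter,
                                "ftol": settings.ftol, "gtol": 1e-10})
        warn = not opt.success and "ABNORMAL" in str(opt.message).upper()
    except Exception as exc:  # optimizer failure: keep the best iterate
        warnings.warn(f"optimizer failed on {objective}: {exc}")
        warn = True
    x_best = np.clip(best["x"], lo, hi)
    updated = _apply(model, variables, start * x_best)
    return updated, {"objective": objective, "variables": tuple(variables),
                     "rms_initial": f0, "rms_final": min(best["f"], f0),
                     "history": history, "warning": warn}


# -- outer sequential loop -------------------------------------------------------


def sequential_identify(model: NeckModel, reference: ReferenceKinematics,
                        schedule, max_sequences: int = 6, tol: float = 0.01,
                        settings: Optional[IdentifySettings] = None):
    """Run the schedule's steps in order; repeat until converged.

    ``schedule`` is one :class:`IdentificationSchedule` (repeated every
    sequence) or a list of them (sequence i uses schedule ``i``, the
    last one repeating if more sequences are needed).  Convergence: no
    objective improves by more than ``tol`` (relative) over the previous
    sequence.  Returns ``(final model, trace)`` where the trace holds
    the full RMS table after every sequence (sequence 0 = start).
    """
    settings = settings or IdentifySettings()
    if isinstance(schedule, IdentificationSchedule):
        schedules = [schedule]
    else:
        schedules = list(schedule)
    design = DesignVector.from_model(model)
    for s in schedules:
        s.validate(design)
    bounds = {v.name: (v.lower, v.upper) for v in design.variables}

    trace = [dict(sequence=0, **evaluate_objectives(model, reference,
                                                    settings))]
    current = model
    for seq in range(1, max_sequences + 1):
        sched = schedules[min(seq - 1, len(schedules) - 1)]
        for step in sched.steps:
            current, hist = identify_step(
                current, reference, step.objective, step.variables,
                bounds={v: bounds[v] for v in step.variables},
                settings=settings)
        row = dict(sequence=seq,
                   **evaluate_objectives(current, reference, settings))
        trace.append(row)
        prev = trace[-2]
        improvements = [
            (prev[k] - row[k]) / max(prev[k], 1e-15)
            for k in row if k != "sequence"
        ]
        if max(improvements) < tol:
            break
    return current, trace


# -- published schedules ---------------------------------------------------------


def bottom_up_schedule(model: NeckModel,
                       coeffs: Sequence[str] = ("A1", "B1", "A2", "B2", "C")
                       ) -> IdentificationSchedule:
    """One step per body, bottom-up, over that body's joint coefficients."""
    steps = []
    for name in _objective_bodies(model):
        joint = model.joint_of_body(name)
        steps.append(IdentificationStep(
            f"RMS_{name}", tuple(f"{joint}.{c}" for c in coeffs)))
    return IdentificationSchedule(tuple(steps), name="bottom-up")


def _steps(rows) -> IdentificationSchedule:
    return IdentificationSchedule(
        tuple(IdentificationStep(obj, tuple(vs)) for obj, vs in rows))


def table3_sequences() -> list:
    """The four published baseline-model sequences (variables per step)."""
    seq1 = _steps([
        ("RMS_C7", ["C7/T1.A2", "C7/T1.B2", "C7/T1.C"]),
        ("RMS_C6", ["C6/C7.A1", "C6/C7.B1", "C6/C7.C"]),
        ("RMS_C5", ["C5/C6.A2", "C5/C6.B2", "C5/C6.C"]),
        ("RMS_C4", ["C4/C5.A2", "C4/C5.B2", "C4/C5.C"]),
        ("RMS_C3", ["C3/C4.A2", "C3/C4.B2", "C3/C4.C"]),
        ("RMS_C2", ["C2/C3.A2", "C2/C3.B2", "C2/C3.C"]),
        ("RMS_C1", ["C1/C2.A2", "C1/C2.B2", "C1/C2.C"]),
        ("RMS_C0", ["C0/C1.A1", "C0/C1.B1", "C0/C1.B2", "C0/C1.C"]),
    ])
    seq2 = _steps([
        ("RMS_C7", ["C7/T1.A2", "C7/T1.B2", "C7/T1.C"]),
        ("RMS_C6", ["C6/C7.A2", "C6/C7.B2", "C6/C7.C"]),
        ("RMS_C5", ["C5/C6.A2", "C5/C6.B2", "C5/C6.C"]),
        ("RMS_C4", ["C4/C5.A2", "C4/C5.B2", "C4/C5.C"]),
        ("RMS_C3", ["C3/C4.A2", "C3/C4.B2", "C3/C4.C"]),
        ("RMS_C2", ["C2/C3.A2", "C2/C3.B2", "C2/C3.C"]),
        ("RMS_C1", ["C1/C2.A2", "C1/C2.B2", "C1/C2.C"]),
        ("RMS_C0", ["C0/C1.B1", "C0/C1.A2", "C0/C1.B2", "C0/C1.C"]),
    ])
    seq3 = _steps([
        ("RMS_C7", ["C7/T1.A2", "C7/T1.B2", "C7/T1.C"]),
        ("RMS_C6", ["C6/C7.A2", "C6/C7.B2", "C6/C7.C"]),
        ("RMS_C5", ["C5/C6.A1", "C5/C6.A2", "C5/C6.B2", "C5/C6.C"]),
        ("RMS_C4", ["C4/C5.A2", "C4/C5.B2", "C4/C5.C"]),
        ("RMS_C3", ["C3/C4.A2", "C3/C4.B2"]),
        ("RMS_C2", ["C2/C3.A2", "C2/C3.B2", "C2/C3.C"]),
        ("RMS_C1", ["C1/C2.A2", "C1/C2.B2", "C1/C2.C"]),
        ("RMS_C0", ["C0/C1.A2", "C0/C1.B2", "C0/C1.C"]),
    ])
    seq4 = _steps([
        ("RMS_C7", ["C7/T1.A2", "C7/T1.B2"]),
        ("RMS_C6", ["C6/C7.A2", "C6/C7.B2", "C6/C7.C"]),
        ("RMS_C5", ["C5/C6.A2", "C5/C6.B2", "C5/C6.C"]),
        ("RMS_C4", ["C4/C5.A2", "C4/C5.B2"]),
        ("RMS_C3", ["C3/C4.A2", "C3/C4.B2", "C3/C4.C"]),
        ("RMS_C2", ["C2/C3.A2", "C2/C3.B2", "C2/C3.C"]),
        ("RMS_C1", ["C1/C2.A2", "C1/C2.B2", "C1/C2.C"]),
        ("RMS_C0", ["C0/C1.A2", "C0/C1.B2", "C0/C1.C"]),
    ])
    for i, s in enumerate((seq1, seq2, seq3, seq4), start=1):
        s.name = f"baseline-seq{i}"
    return [seq1, seq2, seq3, seq4]


def table4_schedule() -> IdentificationSchedule:
    """The modified-model sequence: three OC-displacement steps, then the
    head-rotation step."""
    b2 = [f"{j}.B2" for j in
          ("C7/T1", "C6/C7", "C5/C6", "C4/C5", "C3/C4")]
    b2_full = b2 + ["C2/C3.B2", "C1/C2.B2"]
    sched = _steps([
        ("RMS_OC", ["kv"] + b2),
        ("RMS_OC", ["kv"] + b2_full),
        ("RMS_OC", ["kv"]),
        ("RMS_C0", ["C0/C1.A2", "C0/C1.B2"]),
    ])
    sched.name = "modified-model"
    return sched


# -- schedule files --------------------------------------------------------------


def save_schedule(schedule: IdentificationSchedule, path) -> None:
    doc = {"name": schedule.name,
           "steps": [{"objective": s.objective,
                      "variables": list(s.variables)} for s in schedule.steps]}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_schedule(path) -> IdentificationSchedule:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return IdentificationSchedule(
        tuple(IdentificationStep(s["objective"], tuple(s["variables"]))
              for s in doc["steps"]),
        name=doc.get("name", ""))
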