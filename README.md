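# whipneck

Efficient planar head-neck multibody model for rear-impact (whiplash)
simulation, injury-criteria evaluation and joint-parameter
identification.

`whipneck` models the cervical spine as a sagittal chain of rigid
bodies — T1 (kinematically driven base), the seven cervical vertebrae
C7…C1 and the head — linked by revolute joints with nonlinear
exponential torsional springs and linear dampers, optionally extended
by a prismatic slider between C1 and the head that captures axial head
translation during the retraction phase. On top of the forward
dynamics it provides:

* **Injury criteria** — HIC36 (exact accelerated sliding-window
  search) and the four Nkm load cases from occipital-condyle loads
  recovered by inverse dynamics.
* **Synthetic reference generation** — canonical crash pulses
  (haversine/trapezoid, parameterized by peak and ΔV), T1 base motion
  by double integration, and reference kinematics from a
  known-parameter model with optional seeded noise, so parameter
  recovery can be measured exactly.
* **Sequential identification** — the multiobjective channel fit
  decomposed into bounded single-objective steps (bottom-up per body),
  with ±25 % design boxes, sensitivity screening and published step
  schedules as presets.
* **Artifact plumbing** — unit-suffixed channel CSVs with provenance
  blocks, YAML model/schedule round-trips, run reports and a CLI.

The integrator is a numba-compiled adaptive Dormand-Prince 4(5)
scheme; a 300 ms run at 10 kHz output takes well under a second, which
is what makes identification (thousands of simulations) practical on
one CPU. Every run carries an energy ledger (kinetic + potential vs
support work − dissipation) that typically closes to ~1e-12 relative.

## Worked example

```python
from whipneck import build_model, simulate, lab_sled_motion, evaluate_criteria

model = build_model("V5B-final", "with_prismatic")  # identified preset
motion = lab_sled_motion(0.3)          # 12 g, ΔV = 10 km/h haversine sled
result = simulate(model, motion, t_end=0.3)
crit = evaluate_criteria(result)

print(f"HIC36      = {crit.hic36:.2f}")
print(f"Nea        = {crit.n_ea:.3f}")
print(f"peak a_res = {result.head_acc_resultant_g.max():.2f} g")
print(f"energy residual (rel) = {result.energy_residual_rel():.1e}")
```

prints

```
HIC36      = 0.30
Nea        = 0.331
peak a_res = 3.21 g
energy residual (rel) = 1.2e-12
```

(Absolute criteria values depend on the T1 excitation; the synthetic
sled scenario drives T1 in pure translation, so they are not
comparable to criteria measured with full-body occupant models — see
`docs/methods.md`.)

Identify joint parameters from a synthetic reference:

```python
from whipneck import (DesignVector, bottom_up_schedule, generate_reference,
                      sequential_identify)

true = build_model("V1-initial")
reference = generate_reference(true, motion, t_end=0.3, output_rate=2000)
start = true.with_parameter("C7/T1.A1", 1.2 * true.get_parameter("C7/T1.A1"))
fitted, trace = sequential_identify(start, reference,
                                    bottom_up_schedule(start))
```

Command line:

```bash
whipneck model --preset V5B-final                      # inspect a preset
whipneck simulate --preset V1-initial --variant baseline \
    --t-end 0.3 --out run.csv --degrees
whipneck criteria run.csv                              # HIC36 + Nkm
whipneck report --preset V5B-final --out report.txt    # summary + channels
whipneck --seed 7 synth-ref --noise-sd 1e-3 --out ref.csv
```

## Layout

```
src/whipneck/
  presets.py    published body/joint parameter tables
  model.py      chain definition, validation, kinematics, YAML round-trip
  dynamics.py   prescribed motion, EOM assembly, simulation, OC loads
  _kernel.py    numba-compiled recursion + DP45 integrator
  criteria.py   HIC36 and Nkm
  synthref.py   crash pulses and synthetic references
  identify.py   RMS objectives, sensitivity, sequential identification
  io.py         channel CSVs and run reports
  cli.py        `whipneck` command group
tests/          pytest suite incl. independent oracles (tests/oracles.py)
scripts/        acceptance.py
docs/           methods.md — conventions, assumptions, limitations
```
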