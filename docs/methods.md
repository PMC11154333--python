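# Methods

This note records the modeling conventions, numerical choices and known
limitations of `whipneck`. It is written for users who need to judge
whether the model's assumptions fit their application.

## Model

The cervical spine is modeled as a planar (sagittal) chain of nine
rigid bodies — the first thoracic vertebra T1 at the base, the seven
cervical vertebrae C7…C1, and the head C0 — connected by revolute
joints. T1 is kinematically driven (support excitation): its
translation, and optionally its rotation, follow prescribed
twice-differentiable splines. Each joint carries a nonlinear torsional
spring

    M(θ) = A1 (exp(B1 θ) − 1)   for θ < 0   (extension)
    M(θ) = A2 (exp(B2 θ) − 1)   for θ ≥ 0   (flexion)

with A1, B1 < 0 < A2, B2, plus a linear torsional damper C. The
modified variant inserts a massless carrier body between C1 and the
head with a prismatic (slider) degree of freedom along the C1→head
axis, restrained by a linear spring-damper (kv, cv); this reproduces
the axial head translation seen during the retraction phase of a rear
impact.

Two parameter presets ship with the package: `V1-initial`
(literature-derived joint stiffness, uniform 1.8 Nms/rad damping,
revolute-only) and `V5B-final` (identified coefficients including the
slider at kv = 1620 N/m, cv = 100 Ns/m).

## Conventions

* Global axes: X anterior, Z superior. Angles are positive in flexion
  (forward rotation); the seated initial posture has negative absolute
  angles (T1 at −26°, head at −13°).
* Body tables store the joint position S of each body in its parent's
  frame and the center of mass G in the body's own frame, both in mm;
  angles in degrees. All dynamics run in SI units.
* Generalized coordinates are the relative joint rotations measured
  from the initial posture (plus the slider elongation), so q = 0 at
  t = 0 and every spring is relaxed there.
* The head CG offset is stored as (27, 43) mm; one published source
  table mixes units in this cell and the 43 mm reading is the only one
  consistent with the head's inertia and standard anthropometry.

## Gravity and preload

A seated occupant is at rest before the impact, but the exponential
springs are far too soft to hold the posture against gravity. Constant
joint preload moments τ0 are therefore computed at build time so that
the initial posture is an exact static equilibrium (verified to
machine precision). Disabling gravity disables the preload with it.
The preload enters the potential-energy ledger as −τ0·q, so the
work-energy balance closes exactly. The preloaded posture is an
unstable equilibrium in the large: in long simulations past the pulse
the head eventually topples into deep extension. This is the correct
behavior of the constitutive law, not a solver artifact; the model is
intended for the first few hundred milliseconds of a crash event.

## Dynamics and integration

The equations of motion are assembled by projected Newton-Euler
recursion with analytic Jacobians, M(q) q̈ = Q(q, q̇, t), and
integrated by an adaptive Dormand-Prince 4(5) scheme (compiled with
numba) that steps exactly onto the uniform output grid. Defaults:
rtol 1e-8, atol 1e-10, 10 kHz output. The state carries two extra
quadratures — cumulative damper dissipation D and support-reaction
work W — so every run can verify the ledger

    (T + V)(t) − (T + V)(0) = W(t) − D(t).

Typical closure is 1e-12 relative or better over a 300 ms run; the
test suite enforces 1e-5 at every sample and cross-checks the
integrator against an independent reference solver and the assembled
equations against a symbolically derived two-body closed form.

Occipital-condyle loads are recovered by inverse dynamics of the head
alone and reported in the head frame (Fx anterior shear, Fz superior
normal, My flexion-positive). They are validated against an
independent absolute-coordinate formulation in which joint reactions
appear as Lagrange multipliers (agreement ≤ 1e-6 N).

## Injury criteria

HIC36 is the maximum over windows up to 36 ms of
(t2−t1)·[mean resultant head acceleration in g]^2.5, computed with a
cumulative-trapezoid accelerated window search that is exactly
equivalent to the exhaustive O(n²) search. Nkm combines the
normalized OC shear and sagittal moment, Fx/Fint + My/Mint, into four
sign-gated cases (Nfa, Nfp, Nea, Nep) with Fint = 845 N and
Mint = 88.1 Nm (flexion) / −47.5 Nm (extension).

## Synthetic reference scenario

Reference kinematics for identification are generated, not measured:
a canonical haversine crash pulse with 12 g peak and ΔV = 10 km/h
(duration 2ΔV/(peak·g) ≈ 47.2 ms) is double-integrated into a T1
anterior translation; a model with known parameters is simulated under
it; per-body absolute angles and the OC displacement relative to T1
become the reference channels, optionally with seeded Gaussian noise.
Because the generating parameters are known, parameter recovery is
measurable exactly. The real-world counterpart of this scenario used
a proprietary full-body occupant model whose T1 trajectory is not
public; absolute criteria values therefore depend on the synthetic
scenario and only deviation arithmetic is comparable across
implementations.

## Identification

The multiobjective fit (one angle-RMS objective per body plus an
OC-displacement objective for the slider model) is decomposed into
sequences of single-objective bounded optimizations, bottom-up from
C7 to the head, repeated until improvements fall below 1 %. Design
variables are the 40 joint coefficients plus kv, cv; each is boxed to
±25 % of its value at the start of the identification. The optimizer
is L-BFGS-B on ratio-scaled variables with central finite-difference
gradients (any bounded gradient-based local method satisfies the same
contract); the best iterate is retained, so a step never ends worse
than it started. Published step schedules for both model variants are
available as data presets, alongside a sensitivity screening that
tabulates the RMS influence of a 25 % perturbation of every variable.

Identification-grade simulations run at reduced tolerance
(rtol 1e-6, 2 kHz output), which differs from the high-accuracy
solution by ~4e-6 rad while being an order of magnitude faster.

## Limitations

* Planar model: no lateral bending, axial rotation or out-of-plane
  coupling; muscle activation and soft-tissue contact are not modeled.
* Fixed revolute centers approximate the moving instantaneous axes of
  rotation of the intervertebral joints.
* **Extension-only identifiability.** Under the rear-impact scenario
  the two lowest joints (C7/T1, C6/C7) remain in extension for the
  entire event, so their flexion coefficients A2, B2 never influence
  the motion and cannot be recovered from this reference by any
  optimizer; their damping C acts on a signal dominated by the much
  stiffer extension branch and is only weakly identifiable. Upper
  joints flex a few degrees during the retraction (S-shape) phase and
  do constrain their flexion branch. Recovering flexion parameters of
  the lower joints requires a scenario (e.g. frontal impact) that
  actually flexes them.
* **Sequential decomposition is not per-body monotone.** Each
  identification step minimizes a single body's RMS; later steps can
  degrade already-fitted channels through dynamic coupling (upper
  joint torques react on lower bodies). Convergence is driven by the
  outer repetition of sequences, not by monotone per-step progress.
* The model is validated for short transients; long-horizon behavior
  is dominated by the unstable gravity equilibrium discussed above.
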