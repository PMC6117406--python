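# Methods

`lvmech` simulates the systolic mechanics of a single idealized human left
ventricle (LV) and asks how transmural redistribution of myofiber
contractility changes ejection fraction (EF), torsion, strain and chamber
shape — in particular, whether increased subepicardial contractility can
compensate for a non-contracting subendocardium and preserve EF (an
HFpEF-like phenotype), while an uncompensated subendocardial insult
produces HFrEF.

## Geometry

The LV is a truncated thick-walled prolate ellipsoid of revolution.  The
long axis is z (base above the equator at z = h, apex at the −z pole); the
basal plane cuts both surfaces at the same height.  From echo scalars the
end-diastolic (ED) surfaces are back-calculated: the endocardial short
semi-axis is half the internal diameter (default 4.6 cm), the epicardial
offset is the mean of the posterior and septal wall thicknesses (default
0.9 cm), and the endocardial long semi-axis is solved so the truncated
cavity volume equals the measured EDV (53 ml).  Because EDV and diameter
fix the cavity height, the truncation plane is parameterized by the
fraction `truncation_height = f * c` with f = 0.5 by default
(config-exposed); for the reference subject this gives a cavity
height/diameter ratio of ≈ 0.93.

The stress-free reference is obtained following the single-point unloading
recipe: the unloaded cavity volume comes from the Klotz regression
V0 = EDV (0.6 − 0.006 EDP), the endocardial surface (and the truncation
height) is shrunk affinely to V0, and the epicardial surface is rescaled
so the myocardial wall volume is conserved to < 0.1% (mass preservation).
No inverse finite-element unloading is attempted — the affine recipe is
the model definition here.

### Mesh

A structured shell of 8-node hexahedra: exactly eight transmural element
layers (equal thickness in the reference configuration), `n_circ`
azimuthal and `n_long` longitudinal elements.  Layers 1–3 / 4–5 / 6–8 form
the subendocardial / midmyocardial / subepicardial regions.  The apical
pole is left open by half of one longitudinal increment instead of using
collapsed elements, so every hexahedron has a strictly positive Jacobian;
the cavity surface is closed by flat basal and apical caps for volume
evaluation and pressure loading.  The discrete cavity volume converges to
the analytic truncated-ellipsoid volume at second order under refinement
(−12% at 8×8×6, −5.8% at 8×12×8, −1.5% at 8×24×16); the passive-parameter
fit and the volume-controlled diastole absorb this discretization bias, so
calibrated quantities (EF, T_max) are meaningful at coarse resolution.

### Fibers

Rule-based: at each element centroid a local orthonormal triad
(circumferential e_c, longitudinal e_l, radial e_r) is built from the
element's own edges; the helix angle interpolates linearly in transmural
depth d (layer midpoint) from +60° at the endocardium to −60° at the
epicardium, f0 = cos(α) e_c + sin(α) e_l.  The sheet direction is the
radial direction orthogonalized against the fiber (identically e_r here),
so the sheet-type energy terms act transmurally.

## Constitutive model

Passive: Holzapfel–Ogden orthotropic hyperelasticity with isochoric
invariants in the deviatoric part and the volumetric penalty
Ψ_vol = (1/D)((J²−1)/2 − ln J), D = 2/K, bulk modulus K = 1 MPa by default
(near-incompressible penalty; config-exposed).  The fiber/sheet
exponential terms act only in tension (Ī₄ > 1).  The default constants are
the named set `paper_table1` (a = 6.832e−4 MPa, b = 7.541,
a_f = 2.252e−3 MPa, b_f = 14.471, a_s = 3.127e−4 MPa, b_s = 12.548,
a_fs = 1.837e−4 MPa, b_fs = 3.088).

Active: a time-varying elastance law with length-dependent calcium
sensitivity,
T0 = T_max · Ca0² / (Ca0² + ECa50²) · Ct, with Ct = (1 − cos ω)/2 ramping
over [0, t0] and relaxing over the length-dependent duration tr = m·l + b;
ECa50 = Ca0_max / sqrt(exp(B(l − l0)) − 1) and l = lR·sqrt(2 Eff + 1).
Constants (µM, µm, s): Ca0 = Ca0_max = 4.35, B = 4.75 µm⁻¹, l0 = 1.58,
m = 1.0489 s/µm, b = −1.429 s, t0 = 0.2 s — the standard values of this
law's lineage.  The slack sarcomere length is lR = 1.95 µm, the human
value (the frequently quoted 1.85 µm comes from rat trabeculae); anchored
at the Klotz-unloaded reference this puts the model's sarcomere operating
range at ≈ 2.2 µm (end diastole) to ≈ 1.7 µm (end systole), the
physiological window, and keeps the compensated scenarios on the
ascending limb of the length–tension relation.  This choice matters:
because exp(B(l − l0)) − 1 is steep near l0, moving lR by ∓0.05 µm moves
the calibrated contractility by roughly ±30%, and with lR = 1.85 µm
end-systolic sarcomeres would sit at the zero-tension length, where no
amount of subepicardial tension can restore the baseline end-systolic
volume.  All constants are config-exposed.  The
active second Piola–Kirchhoff stress is T0 f0⊗f0 / I4f (fiber direction
only, no cross-fiber fraction), so the Cauchy fiber stress magnitude is
T0 λ_f / J.  Total stress is the sum of passive and active parts.
Activation timing is homogeneous across the wall.

## Finite-element solver

Total-Lagrangian quasi-statics; 8-node hexahedra with 2×2×2 Gauss
quadrature.  Volumetric locking at K = 1 MPa is avoided by mean dilatation
(B-bar): the volumetric pressure at all Gauss points of an element is
evaluated from the element-average Jacobian.  The element residual is the
exact gradient of this mean-dilatation energy plus the (non-potential)
active stress; element tangents are forward finite differences of the
exact residual (step 1e−7), so B-bar and active couplings are consistent
by construction, and an independent central-difference oracle checks them
in the tests.  A compiled (numba) kernel and a vectorized numpy
implementation of the element loop are kept in lockstep by an equivalence
test.

Cavity pressure is applied as a fluid-cavity load: the virtual work p·δV
of the closed cavity (lateral endocardium plus basal/apical caps), i.e.
the follower force p·∂V/∂u with the analytic cavity-volume gradient; the
load stiffness is the analytic volume Hessian.  This choice is exactly
energy-consistent with the divergence-theorem cavity volume — external
pressure work equals stored strain energy to < 1% over a passive inflation
— and it loads the valve plane the way a pressurized cavity does.

Boundary conditions: all basal-plane nodes are fixed longitudinally; the
mean in-plane translation and mean long-axis rotation of the endocardial
annulus are tied to the fixed base center by linear multipoint constraints
(Lagrange multipliers).  Together these remove exactly the six rigid-body
modes while leaving annular inflation free.

Nonlinear solves use damped Newton with Deuflhard's affine-invariant
(natural) monotonicity test — scale-invariant, which matters because the
augmented systems mix force rows with a volume or Windkessel constraint
row.  The tangent is frozen within (and reused across) steps and refreshed
automatically when the contraction rate degrades; verification tests use
full Newton (near-quadratic convergence).  Load/time increments bisect up
to 8 times on failure.  Convergence: relative force residual ≤ 1e−8
(1e−7/1e−6 during fitting, where ml-level volume accuracy is ample) and
cavity-volume constraint ≤ 1e−6·V.  Volume-constrained and
Windkessel-coupled solves carry the cavity pressure as a bordered unknown
in the sparse (LU) system.  Assembly order is deterministic; identical
configs reproduce identical outputs bitwise.

## Beat protocol

Diastole is volume-controlled: the cavity is inflated from the unloaded
state to the measured EDV (53 ml), so the beat's EDV is exactly the echo
value and the model EDP (≈ the measured 14.3 mmHg after the passive fit)
is a fit-quality readout.  Activation then starts (t = 0).  While cavity
pressure is below the aortic opening pressure (80 mmHg) the volume is held
at EDV (isovolumic contraction, pressure unknown; |ΔV| ≤ 0.1 ml).
Ejection couples the cavity to a two-element Windkessel (peripheral
resistance R, compliance C, backward Euler; the open valve is lossless).
End systole is the instant outflow returns to zero (valve closure); ESV
and ESP are recorded there.  If peak pressure never reaches the opening
pressure the beat is flagged no-ejection and EF = 0.  The default time
step is 7.5 ms (≈ 50 increments per beat including the diastolic steps);
ESV is insensitive to the step because outflow vanishes at end systole.

Afterload: R and C are not measured quantities here.  The defaults
(R = 0.55 mmHg·s/ml, C = 0.30 ml/mmHg) are fixed a priori and frozen for
all six scenarios, so scenario-to-scenario differences emerge from
mechanics, not retuning.  An optional mode (``calibrate_afterload``)
adjusts R once toward a target baseline ESP and recalibrates
contractility; it is off by default because, with a two-element
Windkessel, pushing the end-systolic pressure toward its published value
inflates the calibrated contractility scale severalfold — the printed ESP
belongs to a richer circulation model than a two-element Windkessel can
imitate.  ESP values are therefore interpreted qualitatively (ordering),
not as targets.

## Calibration

Passive fit: the eight HO constants are fitted with SLSQP so the FE
passive inflation matches the single-point Klotz EDPVR
(P = 28.2·Vn^2.79 mmHg, Vn normalized between V0 and V30) at eight evenly
spaced pressures in (0, EDP].  Because an eight-parameter exponential fit
to one curve is not unique, fit quality is judged by curve mismatch (RMS
volume error ≤ 2% of EDV), never by parameter values.  A one-dimensional
prescale of the four a-type moduli (secant on V(EDP)) supplies the SLSQP
start; parameters are optimized as multiples of the default set within
bounds [1e−6, 1e−1] MPa (a-type) and [0.1, 30] (b-type).  Successive
evaluations warm-start from the previous equilibria.  The fit runs on the
8×8×6 mesh and the fitted parameters are then frozen for the scenario mesh
(single-fit workflow, no per-scenario refits).

Contractility: uniform T_max is calibrated by a bracketed secant root-find
so the baseline beat's ESV hits the measured 24.8 ml within 0.2 ml;
scenario 3 recalibrates the subepicardial T_max the same way with the
subendocardium silenced and the midwall at baseline.  Diastole is
contractility-independent, so all trial beats share one ED state.

## Scenarios and outcome measures

Six scenarios share geometry, passive parameters, activation timing and
afterload, differing only in per-region T_max: (1) uniform baseline;
(2) subendocardium zero; (3) as 2 with subepicardium recalibrated;
(4) all regions at half baseline; (5) subendocardium only; (6)
subepicardium zero.

EF = 100(EDV − ESV)/EDV.  Torsion is the size-normalized twist
τ = (Ø_apex − Ø_base)(ρ_apex + ρ_base)/(2D) with ring rotations positive
counterclockwise as seen from the apex, evaluated on the basal annulus and
the most apical complete endocardial node ring (the pole is singular);
ρ are deformed ring radii, D the deformed axial ring distance.  Global
strains are ED-referenced per-element Green–Lagrange strains at end
systole, expressed along the ED-pushed-forward local directions and
volume-weighted with ED element volumes (the clinical, echo-like
convention).  The ES sphericity index is the deformed cavity long-axis
length (basal plane to apex) over the maximal short-axis ring diameter.
Transmural profiles are layer-wise volume-weighted means of ED-referenced
fiber strain and total Cauchy fiber stress.  Because the strain definition
underlying the published global-strain magnitudes is not fully specified,
strain outputs are interpreted by sign and ordering, not by magnitude
equality.

## What the synthetic patient generator does and does not emulate

`sample_patient` draws echo-like scalars (EDV, E/e′, ESV fraction,
diameter, wall thicknesses) from truncated normal-subject distributions
(EDV ~ N(53, 8) ml, E/e′ ~ N(8, 2), thickness ~ N(0.9, 0.1) cm, ...), with
EDP derived from E/e′ via the linear estimator P = 1.9 + 1.24·E/e′.  The
fixed reference subject (EDV 53 ml, EDP 14.3 mmHg, ESV 24.8 ml) is the
study's patient; diameter and thicknesses for that subject are textbook
normal values because they are not part of the study record.  The
generator produces internally consistent scalar records only — no images,
no regional wall-motion abnormality, no diseased-population tails — so
passing tests demonstrate pipeline correctness across a plausible normal
range, not robustness to pathological geometry.

## Problem sizes and numerical choices

Default resolutions: 8×8×6 (384 hexahedra) for the passive fit and 8×12×8
(768 hexahedra, ≈ 2 900 unknowns) for calibration and scenario beats; both
are config fields, and refinement studies in the test suite check the
expected convergence behavior.  These sizes keep a full six-scenario study
(fit + two calibrations + six beats) within tens of minutes on one core
while leaving the calibrated quantities stable: EF is anchored by the ESV
calibration, which tracks the same discrete volume measure used in the
beats.

Degenerate inputs are rejected early (wall thickness ≥ cavity radius,
EDP ≥ 100 mmHg in the V0 regression, non-positive E/e′, V0 outside
(0, EDV]); inverted elements at Gauss points signal step rejection and
trigger load bisection rather than a crash; exponential overflow in trial
Newton states is capped (argument ≤ 60) so line searches see finite
residuals.

## Fidelity to the published scenario table

An independent solver on an under-specified geometry cannot match the
published table line by line, and this implementation does not.  What it
reproduces by construction or robustly: the baseline beat (EF anchored by
the ESV calibration), the large EF drop when the subendocardium is
silenced, a baseline contractility calibrating to the published order
(≈ 0.075 MPa vs 0.086 MPa), the torsion ordering (insult raises twist,
compensation raises it further, silencing the outer layers reverses its
sign), and the passive EDPVR fit.  What it does not reproduce: the
*complete* recovery of EF by subepicardial compensation — in this model
the end-systolic volume saturates a few ml short of the baseline target
no matter how strong the outer layers are made, so the recovery is
partial (EF ≈ 47% vs 53%) and the recalibrated subepicardial
contractility is far above the published 0.117 MPa; the near-total EF
collapse of the graded scenarios (halved contractility, inner-layers-only,
outer-layers-silenced), which in the published model eject almost nothing
while here they retain 19–40% EF; the baseline torsion magnitude and
sign (small and negative here vs +24.7°); and the direction of the
end-systolic sphericity change under the subendocardial insult.  The
graded-scenario collapse in particular appears to require a system poised
so that halving contractility drops peak pressure to the valve-opening
threshold — a knife-edge the unstated activation constants and
circulation of the original model evidently realized and that this
combination of the documented constants and a two-element Windkessel does
not.  These gaps are reported as measured; no parameter is adjusted
per scenario.

## Known limitations

- Idealized rotationally symmetric geometry; no septum/free-wall
  distinction, no right ventricle or atria, no regional wall thickness
  variation.
- The circulation is a two-element Windkessel behind an opening pressure;
  no closed loop, no atrial kick, no valve dynamics — ESP magnitudes are
  afterload-model-dependent.
- Homogeneous activation timing; no electrophysiological sequence.
- Quasi-static mechanics; no inertia, viscoelasticity or active
  cross-bridge kinetics.
- The affine unloading recipe and the rule-based fiber field are model
  definitions, not patient-specific reconstructions.
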