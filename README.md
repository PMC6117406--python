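# lvmech

Finite-element mechanics of an idealized human left ventricle (LV), built
to ask a focused physiological question: **can increased subepicardial
contractility compensate for a non-contracting subendocardium and
preserve the ejection fraction?** That compensation pattern is a candidate
mechanism for heart failure with preserved ejection fraction (HFpEF),
while the uncompensated subendocardial insult produces the reduced-EF
phenotype (HFrEF).

The package is aimed at cardiac-mechanics researchers who want a small,
fully inspectable, pure-Python (numpy/scipy/numba) ventricular model: no
commercial FE solver, every modeling ingredient exposed as a config field,
and a deterministic end-to-end pipeline from echo-style scalar
measurements to a scenario results table.

## The model in brief

* **Geometry** — a truncated thick-walled prolate ellipsoid back-calculated
  from echo scalars (EDV, internal diameter, wall thicknesses), unloaded to
  the Klotz regression volume `V0 = EDV(0.6 − 0.006 EDP)` with wall-mass
  conservation, and meshed into 8-node hexahedra with exactly eight
  transmural layers (subendocardium = layers 1–3, midmyocardium = 4–5,
  subepicardium = 6–8).
* **Fibers** — rule-based helix angle, linear in wall depth from +60° at
  the endocardium to −60° at the epicardium.
* **Passive tissue** — Holzapfel–Ogden orthotropic hyperelasticity
  (isochoric invariants, tension-only fiber/sheet terms, volumetric
  penalty with `D = 2/K`), with the eight constants fitted by SLSQP so the
  model's passive inflation matches the single-point Klotz end-diastolic
  pressure–volume relation `P = 28.2·Vn^2.79` mmHg.
* **Active tissue** — time-varying elastance with length-dependent calcium
  sensitivity, `T0 = T_max·Ca0²/(Ca0² + ECa50²)·Ct(t)`, acting along the
  fiber direction; `T_max` is the per-region contractility dial.
* **Beat** — volume-controlled diastole to the measured EDV, isovolumic
  contraction, ejection against a two-element Windkessel behind an
  80 mmHg opening pressure, end systole at zero outflow.
* **Outcomes** — EF, size-normalized torsion
  `τ = (Ø_apex − Ø_base)(ρ_apex + ρ_base)/(2D)`, ED-referenced global
  strains (E_l, E_c, E_r), ES sphericity index, and transmural fiber
  strain/stress profiles.

Six scenarios share everything except the per-region `T_max`:
(1) uniform baseline calibrated to the measured ESV; (2) subendocardium
silenced; (3) as 2 with the subepicardium recalibrated toward the baseline
ESV; (4) everything halved; (5) subendocardium only; (6) subepicardium
silenced.

See `docs/methods.md` for assumptions, numerical choices, parameter
tables, and known limitations — including an honest account of where this
independent implementation does and does not reproduce the published
scenario table.

## Worked example

```python
from lvmech import paper_patient, klotz_unloaded_volume
from lvmech.pipeline import PipelineConfig, run_pipeline

p = paper_patient()
print(p.edv, p.edp, p.esv)          # 53.0 14.3 24.8
print(klotz_unloaded_volume(p.edv, p.edp))  # 27.2526

result = run_pipeline(PipelineConfig(), outdir="out")
print(result.table[["ef_percent", "esv_ml", "torsion_deg"]].round(1))
```

On the default coarse mesh (8×12×8 hexahedra) this prints, after the
passive fit and the two contractility calibrations:

```
          ef_percent  esv_ml  torsion_deg
scenario
1               53.5    24.6         -5.5
2               36.9    33.5          5.7
3               46.9    28.1          8.3
4               36.9    33.5         -6.2
5               18.9    43.0        -19.8
6               39.7    31.9        -11.1
```

Reading the table: the calibrated baseline reproduces the subject's EF of
53% (scenario 1, by construction of the ESV calibration; the calibrated
uniform T_max is 0.076 MPa).  Silencing the subendocardium drops EF by
~17 points into the reduced-EF range and shifts torsion upward
(scenario 2); boosting the subepicardium recovers a large part of that
loss and raises torsion further (scenario 3) — the compensation direction
of the HFpEF hypothesis, though in this model the outer layers cannot
restore the baseline ESV completely, and the graded scenarios (4–6)
retain considerably more EF than the published model (both discussed
candidly in `docs/methods.md`).  Silencing the midmyocardium and
subepicardium drives the twist strongly negative (scenarios 5–6).

`out/` then contains `metrics.csv` (the scenario table), per-scenario PV
traces and transmural profiles as CSV, the passive-fit report as JSON, and
(optionally) VTK snapshots of the end-systolic deformation.

The same workflow is scriptable from the shell:

```bash
lvt patient --paper --out patient.json
lvt mesh --patient patient.json --out mesh.vtk
lvt run-all --out study/
```

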