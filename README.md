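# voxdose

Internal radiation dosimetry for preclinical PET radiopharmaceutical
studies, implemented two ways and compared head to head:

* **voxel-level**: a Monte Carlo dose engine simulates the radionuclide's
  decays from the voxelized PET activity distribution against the voxelized
  CT-derived material phantom, scoring per-voxel dose rate and statistical
  uncertainty; organ dose-rate curves are integrated over time (trapezoid
  plus physical-decay tail) and normalised to the injected activity
  (Gy/MBq).
* **organ-level (MIRD schema)**: per-organ time–activity curves in %ID/g
  give cumulated activities Ã (MBq·s), which are folded with S values,
  D(r_t) = Σ_s Ã_s · S(r_t ← r_s), for a fixed-mass animal model.

The target use case is a tumor-bearing mouse imaged with a
positron-emitting, renally excreted tracer (the defaults model ⁶⁸Ga:
T½ = 67.71 min, β⁺ branching 0.889, E_max = 1.899 MeV).  Because voxel-level
dosimetry needs no tumor S value, it yields tumor absorbed doses and
dose-volume histograms that the phantom-based route cannot provide.

The package is a library for Python users: everything is importable, and
`examples/` contains one short narrative script per capability.  A
synthetic-data module generates the whole study — a ~25 g voxelized mouse
with a 0.18 cc flank tumor, nine PET frames over 300 min with known
ground-truth kinetics, Poisson counting noise and physical decay — so every
stage can be tested against a known truth.

## What is in the box

| module | contents |
| --- | --- |
| `voxdose.phantom` | voxelized mouse (materials, organ VOIs, HU volume), ground-truth kinetics, PET frame rendering |
| `voxdose.kinetics` | %ID/g TAC extraction, organ mass estimation, association/dissociation fits, AUC with decay tail, cumulated activity |
| `voxdose.mc` | Monte Carlo dose engine: ⁶⁸Ga decay sampling, positron tracks, delta-tracking photon transport (photoelectric + Klein–Nishina Compton), batch uncertainties, dose-rate integration |
| `voxdose.mird` | S-value tables (CSV schema + MC-generated), MIRD dose, residence times, mouse→human scaling, effective dose over a fixture human model, uniform-sphere tumor dose |
| `voxdose.report` | voxel-vs-organ comparison tables with t-tests, group statistics, dose-volume histograms |

## Worked example

```python
import numpy as np
import voxdose as vd

mat, voi, hu = vd.build_mouse_phantom()          # ~25 g mouse, 0.18 cc tumor
truth = vd.default_kinetic_truth(voi)            # renal-tracer kinetics
times, durs = vd.default_frame_schedule()        # 2 ... 300 min, 9 frames
_, activity = vd.simulate_tacs(truth, times, 3.10, durs)
frames = vd.render_pet_frames(voi, activity, times, durs)

frame = frames[4]                                # 60 min post injection
dm = vd.simulate_frame(frame, mat, frame.frame_duration,
                       time_fraction=1e-3, seed=1, voi=voi)
for organ, (rate, se) in vd.organ_dose_rate(dm, voi, mat).items():
    print(f"{organ:16s} {rate:.3e} Gy/s  ({se/rate:.1%})")
```

prints (run `examples/03_voxel_dose.py` for the full script):

```
tumor            4.582e-06 Gy/s  (4.9%)
heart            1.012e-05 Gy/s  (3.1%)
lung             7.452e-06 Gy/s  (2.2%)
liver            9.440e-06 Gy/s  (1.3%)
kidneys          2.588e-05 Gy/s  (1.8%)
intestine        2.626e-06 Gy/s  (2.9%)
urinary_bladder  1.250e-05 Gy/s  (4.2%)
remainder        1.942e-06 Gy/s  (0.5%)
```

i.e. the organ-mean dose rates of the 60 min frame with their Monte Carlo
standard errors — the kidneys, the excretion route of the tracer, receive
the highest dose rate.  Repeating this for every frame and integrating each
organ's curve (`integrate_dose_rate`) gives absorbed dose per injected
activity; `examples/04_organ_vs_voxel.py` carries the same study through
both dosimetry routes and prints the comparison table, a human
effective-dose extrapolation and the sphere-model tumor dose.

## Scope and caveats

The phantom is analytic (ellipsoids on a 0.6 mm grid), not an anatomical
mouse atlas; the Monte Carlo physics is deliberately reduced (straight
positron tracks of CSDA range, no Rayleigh scattering or bremsstrahlung
transport, kerma approximation for photon interactions); the human model
behind the effective-dose estimate is a synthetic fixture, not a validated
reference phantom.  `docs/methods.md` documents the models, defaults and
error budget in detail.
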