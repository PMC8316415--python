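# Methods

This note documents the models, numerical choices and limitations of
`voxdose`, in the order data flows through the pipeline.

## Synthetic study generator

**Geometry.** The phantom is a 64 × 64 × 128 grid of 0.6 mm isotropic
voxels.  The trunk is an ellipsoid (semi-axes 13 × 13 × 34 mm) of soft
tissue (1.04 g/cm³) containing ellipsoidal organs — heart, two lungs,
liver, two kidneys, intestine, urinary bladder — a bone cylinder along the
spine (1.92 g/cm³) and a spherical subcutaneous flank tumor that may bulge
out of the trunk, as flank xenografts do.  The tumor mask is the k voxels
nearest its centre with k = round(target volume / voxel volume), so the
digitized volume matches the configured 0.18 cc within one voxel; the
whole-body mass comes out at ≈25 g.  Organ specifications are validated
pairwise after voxelization; an overlap is rejected naming the colliding
pair, so VOIs are disjoint by construction.  Analytic shapes were chosen
over an anatomical atlas because every derived quantity (volumes, masses,
overlaps) is then exactly known.

**HU synthesis and materials.** Voxels carry Hounsfield values of −1000
(air), −400 (a one-voxel air–body interface shell), 0 (soft tissue) and
+700 (bone).  The dose engine's segmentation thresholds (−700, −150, +300)
are chosen so segmentation of the synthetic CT reproduces the generator's
material labels exactly; with real CT data the thresholds are configurable
and should be treated as conventional defaults, not validated values.

**Kinetics.** Each organ follows a one-phase model in decay-corrected
%ID/g: association `y = P(1 − e^(−kt))` or dissociation
`y = (y0 − P)e^(−kt) + P`.  The defaults emulate a renally excreted
PSMA-type ligand: fast washout of blood-pool organs (heart from
~31 %ID/g with T½ ≈ 30 min; lung and liver slower; intestine fastest),
monotone accumulation in kidneys (plateau 58 %ID/g, k = 0.0085/min) and
bladder, and tumor uptake rising to ~4.6 %ID/g with a ~2 h approach to
plateau.  A whole-body remainder compartment is a bi-exponential fraction
of the injected activity (rates 0.12 and 0.008 /min, 65% fast) whose
amplitude is set so the whole-body total equals the injected activity at
t = 0; the constructor verifies numerically that the summed decay-corrected
activity never exceeds the injected activity.  Decay-uncorrected activity
is the corrected curve times `e^(−λt)` with λ from the decay scheme.

**Frame schedule and noise.** Nine frames at midpoints 2, 5, 10, 30, 60,
90 min (60 s dynamic frames) and 180, 240, 300 min (1200 s statics).
Counting noise is Poisson on expected counts per voxel
(concentration × voxel volume × duration × sensitivity, default
0.01 counts/Bq·s), optionally followed by a Gaussian point-spread blur
(default σ = 0.8 mm).  The generator does not model scanner effects the
reconstruction chain would introduce (attenuation/scatter residuals,
partial-volume bias, reconstruction correlations), so passing tests
demonstrate correctness of the quantification chain, not robustness to
real-scanner systematics.

**Calibration conventions.** `render_pet_frames` applies its calibration
factor as a scanner gain (stored values are multiplied by it);
`extract_tac` applies its factor as the correction from stored to true
concentration.  The two are reciprocal: a study rendered with gain g is
quantified exactly by extracting with factor 1/g.

## TAC quantification and pharmacokinetics

%ID/g is `mean VOI concentration × CF / (A_inj × 10⁶) × 100 / ρ` with
ρ = 1.04 g/ml for soft-tissue organs (1.0 for bladder contents).  Organ
mass is voxel count × voxel volume × density, averaging voxel counts first
when per-time-point masks differ.  Fits use `scipy.optimize.curve_fit`
with non-negative bounds; `auto` fits both model forms and keeps the lower
residual sum of squares.  Two details deserve note:

* The dissociation form with y0 < P is the association family plus a free
  intercept, so on noisy data `auto` tends to select it for accumulating
  organs.  The "accumulated" half-life flag therefore keys on the fitted
  shape, not the model label: it is set when the fitted curve rises
  throughout the window and either the raw data never decreases or the
  fitted curve is still below 95% of its plateau at the last observation.
  C_max/T_max are then reported at the last observation.  A strict
  raw-data-monotonicity rule would fail on noisy accumulating organs
  (any downward wiggle breaks it), which is why the shape-based criterion
  is used.
* A fitted rate constant of zero is flagged degenerate (infinite T½)
  rather than an error.

**AUC.** Trapezoid over the observations, a linear leading segment from
(0, 0) to the first observation (the curve is zero at injection), and a
closed-form tail `y(t_last)/λ` that assumes the tissue only decays
physically after the last frame — a conservative, standard choice for a
short-lived nuclide.  Cumulated activity Ã = AUC/100 × O_m × A_inj × 60
(MBq·s) integrates the decay-*uncorrected* curve, since Ã counts physical
decays; `cumulated_activity` converts decay-corrected TACs internally.
The printed residence-time formula with an explicit organ-mass factor is
read with Ã as cumulated activity *concentration*; this package keeps Ã as
total organ cumulated activity (the mass enters once, in the %ID/g → MBq
conversion), giving the dimensionally unambiguous `R = Ã / A_inj`.

## Monte Carlo dose engine

**Decay scheme.** ⁶⁸Ga defaults: T½ 67.71 min, β⁺ branching 0.889,
endpoint 1.899 MeV, optional 1.077 MeV prompt gamma at 3.22% (off by
default; the dose is annihilation-dominated and the two modes are both
available).  The β⁺ spectrum is the allowed shape `p·W·(Q−E)²` sampled by
tabulated inverse CDF; the Fermi Coulomb correction is omitted, which
shifts the spectrum mean from the evaluated 0.836 MeV to 0.804 MeV (≈4%);
all spectrum checks in the test suite are against the configured shape by
numeric integration.

**Positrons.** Kinetic energy is deposited uniformly along a straight
track of density-scaled CSDA range (Katz–Penfold fit,
`0.412·E^(1.265−0.0954 ln E)` g/cm², density taken at the emission voxel),
discretised into 8 equal sub-deposits; `positron_mode="local"` deposits at
the emission voxel instead.  Annihilation occurs at the track end into two
antiparallel 511 keV photons with an isotropic axis; pairs whose track end
leaves the grid are counted as escaped energy.  Photon non-collinearity is
ignored.

**Photons.** Delta (Woodcock) tracking with an energy-dependent majorant
(max of the per-material linear attenuations).  Total attenuation comes
from a shipped log-energy table (10 keV–2 MeV, soft tissue / bone / air,
log-log interpolated); the Compton component is computed from the
Klein–Nishina total cross-section and the material electron density, and
the residual (photoelectric-dominated; the small coherent-scattering
contribution is folded in) absorbs locally.  Compton scattering samples ε
from Klein–Nishina by the standard composition/rejection method; the
recoil electron is absorbed locally (kerma approximation).  Photons below
20 keV deposit locally.  Rayleigh transport and bremsstrahlung are
omitted — sub-percent effects for an annihilation-photon problem at these
geometries — and every run's energy ledger (deposited + escaped = emitted,
enforced to 10⁻⁹ relative) makes the accounting auditable.

**Histories and dose rate.** For a PET frame the simulated decay count is
`N = Σ_k conc_k × voxel volume × duration × time_fraction`, with emission
voxels sampled proportionally and positions uniform within the voxel.
`time_fraction` (default 1/10) is the acquisition-time reduction: the
scored energy is rescaled by its inverse, so the dose rate
`D_k/(mass_k · fraction · duration)` is unbiased on the frame's own clock.
Decays are split into 100 equal batches; the per-voxel standard error is
the batch-mean spread, and when a VOI set is passed the engine also records
per-batch organ totals so organ-level errors keep voxel-to-voxel
correlations.  The estimator is validated against replicate runs in the
test suite (empirical SD within 30% of the reported SE).

**Operating point.** At 4 × 10⁷ decays in a 20 mm uniformly active
soft-tissue cube (8000 voxels of 1 mm), the median per-voxel relative SE is
≈0.8%, comfortably below the 2% reporting convention for production maps;
`scripts/acceptance.py` recomputes this number.

**Dose-rate integration.** Organ curves are integrated in seconds by
trapezoid with the same leading-segment and `r(t_last)/λ` tail conventions
as the TAC AUC — deliberately identical quadrature, so the voxel-level and
organ-level routes differ only in physics, not in time handling.

## Organ-level dosimetry and extrapolation

`mird_dose` is the plain double sum over sources and targets; missing
cross-terms warn and contribute zero, and a `self_only` mode exists because
external S-value tables do not always ship cross terms.  No published
S-value database is redistributed: tables load from a small documented CSV
schema, and `svalue_table_from_mc` generates a table for the synthetic
phantom with the package's own engine (S = mean target dose per decay ×
10⁶).  That generated table powers the pipeline's strongest internal check:
the MIRD route and the voxel-level route, run end to end on the same
phantom, agree within Monte Carlo error (see
`tests/test_acceptance.py::test_voxel_and_organ_level_doses_agree_on_self_calibrated_phantom`).

Mouse→human residence-time scaling multiplies by relative organ mass,
`(B_r/O_r)·(O_h/B_h)`.  The effective-dose calculator runs over a fixture
human model — six organs with reference-adult-style masses, tissue weights
summing to 1, and a synthetic S table built from a two-component closed
form (non-penetrating energy absorbed in the source; annihilation-photon
energy shared via a sphere-equivalent absorbed fraction and a whole-body
bath) — adequate for magnitudes and unit checks, explicitly not a
validated reference-phantom calculation.

The uniform-sphere tumor model interpolates self-dose S log-log in mass
(the standard practice for mass interpolation of S values), with nodes
computed by the MC engine on voxelized unit-density spheres; extrapolation
beyond the node range is refused.

## Statistics and reporting

Method and group comparisons default to the two-sided unpaired Student
t-test with pooled variance (df = n₁+n₂−2), matching the reporting
convention of small-cohort preclinical studies; Welch and paired variants
are available.  Summaries are mean ± SEM.  No multiple-testing correction
is applied.  DVHs are cumulative volume fractions on a configurable dose
grid, starting at 1 at zero dose.

## Problem sizes used in the tests

The test suite runs the full default phantom but scales Monte Carlo decay
counts to the statistical question at hand: transport oracles at 10⁵–3×10⁵
histories, the self-calibration at `time_fraction = 3×10⁻⁴` per frame
(~5×10⁴ decays each) with 6×10⁴ decays per S-table source, and one run at
the full 4×10⁷-history operating point for the uncertainty check.  The
"within 10% at 5% noise" parameter-recovery statement is assessed as the
median absolute error over 100 seeded replicates of 9-point curves.

## Known limitations

* No condensed-history electron transport; positron lateral scattering and
  range straggling are not modeled, so sub-voxel dose gradients near
  sources are sharper than reality.
* Kerma approximation: photon-interaction secondaries deposit at the
  interaction voxel, an approximation that degrades near material
  interfaces and for the optional 1.077 MeV gamma.
* The attenuation fixture carries standard-table values at ~17 grid
  energies; log-log interpolation error is well under 1% but the table is
  not a substitute for a full cross-section library.
* The mouse-to-human chain (mass scaling + fixture human model) propagates
  all the usual caveats of preclinical extrapolation and adds a synthetic
  S table; its output is a plausibility-scale estimate only.
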