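# Methods

This note documents the models behind `v4drt`, the defaults and why they
were chosen, the numerical conventions, and what the synthetic setup does
and does not capture about real treatments.

## Problem setting

Liver tumors move with breathing, predominantly superior–inferior (SI), by
up to ~24 mm.  Conventional planning absorbs this motion geometrically (ITV
or a fixed PTV expansion), which irradiates normal liver unnecessarily.
The framework implemented here asks the dosimetric question instead: *how
much motion can a given prescription strategy tolerate before tumor
coverage fails?*  That tolerance (the Dosimetric Coverage Amplitude, DCA)
is then used to rescale the margin to the patient's actual displacement.

## Phantom and plans

The digital phantom is deliberately simple: a spherical GTV (diameter
10 mm, CTV margin 0 mm, isotropic PTV expansion 10 mm) centered in an
ellipsoidal liver (default semi-axes 80 × 60 × 70 mm) inside an
elliptic-cylinder body (140 × 90 mm, length 200 mm).  Water-equivalent
density is implicit; no heterogeneity is modelled.  The grid is 2 mm
isotropic — matching the CT slice spacing typical for this treatment site —
with 26 mm of SI padding beyond the body so that shifts up to the largest
studied amplitude (24 mm) never consume information the grid does not
hold.  A 1-mm grid is available for convergence checks; structure volumes
converge to the analytic sphere volumes within a few percent there.

Static doses come from an analytic radial profile rather than a dose
engine:

    D(r) = Dmax · S(r),  S(r) = 1 / (1 + ((r − r_GTV)₊ / s)^p)

* `p` (penumbra exponent, default 3) sets how sharply dose falls beyond the
  target; p = 3 gives a falloff of ~5–7% of Dmax per mm at the PTV surface
  for the 80% plan, in the range of clinical SBRT gradients.
* `s` is fixed in closed form by the prescription-isodose constraint
  S(r_PTV) = f.
* `Dmax` is solved (four fixed-point iterations, linear in Dmax so the
  iteration is exact to well below the 0.01-Gy DVH bin) so that D95% of the
  *voxelized* PTV equals the prescription (40 Gy).  Normalization uses the
  same DVH machinery as every later metric, so the plan constraints and the
  analysis metrics are mutually consistent.

Two properties follow structurally rather than by tuning: Dmax ≈ 40/f, so
lower prescription fractions give hotter tumor centers; and the gradient
magnitude at the PTV surface scales like (1 − f), so they also give steeper
peripheral falloff.  These are the two mechanisms that make lower-isodose
prescriptions more motion-tolerant, and the profile family guarantees them
by construction.  The calibration residuals (D95 error, surface-fraction
error, surface gradient) are recorded in each plan and in
`calibration.json`.

## Motion and accumulation

Breathing follows z(t) = z₀ − b·cos²ⁿ(πt/τ): `b` is the **peak-to-peak
span** in mm (1–24 studied), `τ` the period (default 4 s), `n = 1` a
symmetric cycle, `z₀ = 0` the exhale reference.  One cycle is discretized
into 10 phases at t = 0.1τ … 1.0τ.  Phase weights are uniform (1/10):
phases are defined at uniform time steps, so each has equal temporal
occupancy, and the position non-uniformity of the trajectory (dwelling near
the turning points) is carried by the displacement values.  A
position-PDF weighting could be substituted by constructing a `PhaseSet`
directly.

The accumulated (v4DRT) dose is Σᵢ wᵢ·shift(D_static, −zᵢ): when the
patient moves by +zᵢ the dose seen in the tumor frame shifts by −zᵢ.
Shifts are rigid SI translations with tri-linear interpolation and
edge-value padding.  **This rigid surrogate is the principal fidelity
limitation**: real liver motion deforms tissue (the tumor-frame dose is not
exactly a translate of the static dose), and real accumulation uses
deformable registration.  The endpoint studied here — tumor-frame coverage
versus relative tumor–dose displacement — is preserved by the surrogate;
absolute organ-at-risk doses are not, and are therefore only compared
*between* plans, never against clinical values.

Interplay with a dynamic delivery is modelled by splitting beam-on time
(default 120 s, 90 segments, both config-exposed since no delivery duration
is implied by the model itself) into segments that each deposit a fraction
of the *full* static distribution at the instantaneous breathing position,
offset by an initial phase (−π/2 / +π/2 for the standard comparison).
Aperture-resolved (MLC) interplay is out of scope; the surrogate exercises
initial-phase sensitivity and converges to the accumulated dose as
segmentation becomes dense or as the initial phase is averaged out.

## Metrics

* DVHs: cumulative, exact voxel counting, 0.01-Gy bins (metrics agree with
  0.001-Gy bins within 0.02 Gy).  D_v is the largest dose with cumulative
  volume ≥ v, interpolated linearly between bins; D100% is therefore the
  structure minimum up to one bin.
* Shell doses: mean dose in a shell of half-width one voxel centered at
  0.5/1/2 cm from the PTV surface (Euclidean distance transform).  The mean
  was chosen over the max for noise robustness and monotonic behaviour
  under blurring; `statistic="max"` is available.
* Gamma: global criterion, Dnorm = reference maximum, default 3%/3 mm,
  low-dose threshold 10% of Dnorm (a conventional choice; not dictated by
  the model), search radius 3×DTA, sub-voxel search at 1/10-voxel steps by
  tri-linear interpolation on the evaluated grid.  Candidates are visited
  in order of increasing distance with an exact early-termination bound, so
  the result equals the exhaustive search (verified against a brute-force
  oracle).  γ ≤ 1 + 1e−9 counts as a pass so exact-boundary cases (e.g. a
  uniform 3% offset on a flat field) pass.

## DCA, plan selection, OM

`dca_search` sweeps amplitudes 1–24 mm (1-mm grid), accumulating the dose
and evaluating D100% (or D99%) of the GTV against the critical dose, which
defaults to the prescription.  The DCA is the largest amplitude such that
the criterion holds at **every** smaller grid amplitude (prefix rule): on
monotone curves this equals the unrestricted maximum, and it is robust to
numerical non-monotonicity.  Since motion is purely SI, the sweep crops the
dose to the GTV's transverse bounding box first; this is exact, not an
approximation.

Plan selection follows three conditions: coverage maintained up to the DCA;
mean GTV dose under motion at or above the 80%-plan *static* mean; and
normal-tissue metrics (shells, liver-minus-GTV V5Gy/V20Gy) at the plan's
qualifying amplitude not exceeding the 80% plan's static values.  The
qualifying amplitude is min(reference plan's DCA, own DCA, average-dose
tolerance) snapped down to the amplitude grid; the lowest qualifying
isodose fraction wins, and "no qualifying plan" is a reported outcome, not
an exception.

The Optimal Margin is pure arithmetic: OM = PTV_margin / DCA_opt × Δresp,
with Δresp the patient's observed respiratory displacement (default 10 mm;
in clinical use it is a required input, estimated from cine imaging,
fluoroscopy or surface surrogates).  Values are stored exactly and rounded
only for reporting (0.1 mm / 1%).

## Numerical conventions

* Axes: arrays are (x, y, z) = (LR, AP, SI); positive z = superior.
* Alignment: two grids interoperate only if shape, spacing and origin
  match; no resampling is performed.
* Shifts: `scipy.ndimage.shift`, order 1, edge-value padding
  (`mode="nearest"`); a declared per-grid padding budget makes oversized
  shifts a hard error naming the required pad.
* Zero motion short-circuits to an exact copy, so the b = 0 accumulation is
  bitwise identical to the static dose rather than differing in the last
  ulp through weight summation.
* Everything is deterministic; the pipeline uses no random numbers.

## Problem sizes

The default phantom grid is 145 × 95 × 127 voxels (2 mm); the full pipeline
(3 plans × 24 amplitudes × 10 phases, all metrics, interplay gamma) runs in
about a minute on one core.  The test suite uses the same default phantom
for plan-level properties, a reduced phantom (smaller body/liver, same
structure) for pipeline-level tests, and small synthetic grids (≤ 64³) for
oracle comparisons.

## What the synthetic setup does not show

* No dose engine: absolute falloff beyond the isodose surfaces, scatter
  and beam geometry are not modelled, so absolute shell/liver values and
  absolute DCA values are model-specific; only orderings and trends
  transfer to real plans.
* Rigid translation instead of liver deformation (see above).
* Symmetric sinusoidal breathing only at the default n = 1: hysteresis,
  irregular cycles, baseline drift and LR/AP motion components are not
  modelled.
* Interplay ignores aperture shapes and fraction-to-fraction variation.
* A setup margin (van Herk-style) is outside the OM; the OM replaces only
  the motion component of the margin.
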