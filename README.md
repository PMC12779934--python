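# v4drt — virtual-4D margin optimization for liver SBRT

`v4drt` is a desk-scale simulator for optimizing the planning target volume
(PTV) margin in liver stereotactic body radiotherapy (SBRT) under
respiratory motion.  Instead of constructing a geometric internal target
volume (ITV) from the motion range, it evaluates how much motion each
prescription strategy can *dosimetrically* tolerate, and scales the margin
accordingly.

It is aimed at medical physicists and method developers who want a
self-contained, fully scriptable environment to study motion-robustness
trade-offs between prescription isodose levels — no treatment planning
system, patient data or measurement hardware required.

## The model

**Plans.** A digital phantom holds a 1-cm spherical GTV (CTV margin 0 mm,
isotropic 10-mm PTV expansion) inside an ellipsoidal liver and an
elliptic-cylinder body on a 2-mm grid.  For each prescription isodose
fraction *f* ∈ {60%, 70%, 80%} a static dose distribution is synthesized
from a monotone radial profile (flat core over the GTV, Hill-type falloff),
calibrated so that D95% of the PTV equals the prescription (40 Gy in 4
fractions) and the prescription isodose surface sits at *f*·Dmax.  Lower
*f* therefore means a hotter tumor center and a steeper peripheral
gradient.

**Motion.** Breathing follows the Lujan-type trajectory
z(t) = z₀ − b·cos²ⁿ(πt/τ) (n = 1: symmetric cycle of peak-to-peak
amplitude *b*), discretized into 10 uniform-time phases of weight 1/10.

**Accumulation.** The virtual-4D (v4DRT) dose is the phase-weighted sum of
the static dose rigidly shifted into the tumor frame,
D_acc = Σᵢ wᵢ·shift(D, −zᵢ).

**DCA and OM.** The Dosimetric Coverage Amplitude is the largest amplitude
at which GTV coverage survives,

    DCA = max { b : D100%(GTV; b) ≥ D_crit },    D_crit = prescription,

searched over b = 1…24 mm.  The optimal plan is the lowest isodose fraction
that (1) keeps coverage up to its DCA, (2) keeps the mean GTV dose under
motion at or above the 80%-plan static reference, and (3) does not exceed
the 80% plan's static normal-tissue metrics (0.5/1/2-cm shell doses, liver
V5Gy/V20Gy) at its qualifying amplitude.  The Optimal Margin then rescales
the conventional margin by the patient's observed displacement Δresp:

    OM = PTV_margin / DCA_opt × Δresp

e.g. OM(10 mm, 18 mm, 10 mm) = 5.6 mm — a 44% reduction versus the
conventional 10-mm margin.  Interplay between breathing and a dynamic
delivery is checked by simulating phase-resolved deliveries at initial
phases −π/2 and +π/2 and comparing them to the accumulated dose with a
3%/3 mm global gamma criterion.

## Worked example

```bash
v4drt run --out results/
```

runs the full pipeline on the default phantom (≈1 minute) and prints:

```
selected isodose fraction: 0.6
OM = 6.7 mm (33% reduction, DCA_opt = 15 mm)
```

What the numbers mean, from the written reports (`dca.json`, `om.json`,
`metrics_f{60,70,80}.csv`, `gamma.json`):

* Plan maxima are 61.6 / 53.9 / 48.1 Gy for the 60/70/80% plans — all
  normalized to D95%(PTV) = 40 Gy, so lower prescription fractions
  concentrate dose centrally.
* DCA under the D100% criterion: 18 / 17 / 15 mm — every plan tolerates
  motion well beyond the 10-mm margin, and tolerance grows as the
  prescription isodose drops.
* Mean-GTV-dose tolerances versus the 80%-static reference (48.1 Gy):
  18 mm (60% plan), 15 mm (70%), 0 mm (80%) — the 80% plan cannot preserve
  its own static mean under any motion.
* Qualifying amplitudes (capped by the 80% plan's DCA): 15 mm for both the
  60% and 70% plans; the 60% plan also has the lower shell and liver doses
  there, so it is selected.  With Δresp = 10 mm the margin becomes
  OM = 10/15 × 10 = 6.7 mm, a 33% reduction.
* The interplay check on the selected plan passes gamma 3%/3 mm at 100%
  for both initial phases (a 120-s, 90-segment delivery averages the cycle
  almost perfectly; coarse few-segment deliveries do show initial-phase
  sensitivity).

Library use mirrors the CLI:

```python
from v4drt import PlanSpec, build_phantom, compute_om, dca_search, synth_plan_dose

phantom = build_phantom()
plan = synth_plan_dose(PlanSpec(isodose_fraction=0.6), phantom)
dca = dca_search(plan, phantom.masks["gtv"], criterion="D100")
om = compute_om(ptv_margin_mm=10, dca_opt_mm=dca.dca_mm, delta_resp_mm=10)
print(dca.dca_mm, om.om_mm_reported, om.reduction_pct_reported)
# 18.0 5.6 44
```

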