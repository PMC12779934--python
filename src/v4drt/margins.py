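"""DCA search, optimal-plan selection and Optimal Margin computation.

The Dosimetric Coverage Amplitude (DCA) of a plan is the maximum
respiratory amplitude at which the accumulated GTV dose still satisfies a
coverage criterion (D100% or D99% >= the critical dose, here the
prescription).  The search uses a *prefix rule*: the DCA is the largest
grid amplitude such that the criterion also holds at every smaller grid
amplitude.  On monotone metric-vs-amplitude curves this coincides with the
unrestricted maximum; on noisy curves it guards against spurious
re-crossings.

The optimal prescription isodose plan is the lowest isodose fraction that
(1) maintains GTV coverage up to the DCA, (2) preserves the mean GTV dose
under motion at or above the 80%-plan static reference, and (3) does not
exceed the 80% plan's static normal-tissue metrics at its qualifying
amplitude.  The Optimal Margin then rescales the conventional PTV margin by
the observed respiratory displacement over the qualifying amplitude:

    OM = PTV_margin / DCA_opt * Delta_resp
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core import StructureMask, VolumeError, crop_xy
from .accumulate import accumulate_v4drt
from .metrics import cumulative_dvh, dose_at_volume
from .motion import MotionModel, sample_phases
from .phantom import SyntheticPlan

#: Supported GTV coverage / dose criteria.
CRITERIA = ("D100", "D99", "Dmean")


@dataclass
class DCAResult:
    """Metric-vs-amplitude curve and the resulting coverage amplitude."""

    isodose_fraction: float
    criterion: str                 # "D100", "D99" or "Dmean"
    d_crit_gy: float
    amplitudes_mm: np.ndarray
    metric_gy: np.ndarray
    dca_mm: float
    clamped: bool                  # criterion still satisfied at the grid max


@dataclass
class OARMetrics:
    """Normal-tissue metrics at one amplitude."""

    shell_gy: dict[float, float]   # distance_cm -> Gy
    liver_v5_pct: float
    liver_v20_pct: float

    def as_vector(self) -> np.ndarray:
        shells = [self.shell_gy[k] for k in sorted(self.shell_gy)]
        return np.asarray(shells + [self.liver_v5_pct, self.liver_v20_pct])


@dataclass
class PlanComparison:
    """Three-condition comparison across the prescription isodose plans."""

    dca_by_plan: dict[float, DCAResult]
    avg_tolerance_by_plan: dict[float, float]
    qualifying_amplitude_by_plan: dict[float, float]
    qualifies_by_plan: dict[float, bool]
    reference_fraction: float
    reference_mean_gtv_gy: float
    selected_fraction: float | None   # None = "no qualifying plan"

    @property
    def dca_opt_mm(self) -> float | None:
        if self.selected_fraction is None:
            return None
        return self.qualifying_amplitude_by_plan[self.selected_fraction]


@dataclass
class OMResult:
    """Optimal Margin derived from the DCA-optimal plan."""

    ptv_margin_mm: float
    dca_opt_mm: float
    delta_resp_mm: float
    om_mm: float
    reduction_pct: float

    @property
    def om_mm_reported(self) -> float:
        """OM rounded for reporting (one decimal, mm)."""
        return round(self.om_mm, 1)

    @property
    def reduction_pct_reported(self) -> int:
        """Margin reduction rounded for reporting (integer percent)."""
        return int(round(self.reduction_pct))


def default_amplitudes() -> np.ndarray:
    """The studied amplitude grid: 1..24 mm in 1-mm steps."""
    return np.arange(1.0, 25.0)


def _criterion_value(dose, gtv_mask, criterion: str, bin_gy: float) -> float:
    if criterion == "Dmean":
        return float(dose.values[gtv_mask.mask].mean())
    dvh = cumulative_dvh(dose, gtv_mask, bin_gy)
    return dose_at_volume(dvh, 100.0 if criterion == "D100" else 99.0)


def gtv_metric_curve(
    plan,
    gtv: StructureMask,
    amplitudes_mm,
    criterion: str = "D100",
    phase_count: int = 10,
    period_s: float = 4.0,
    bin_gy: float = 0.01,
) -> np.ndarray:
    """Accumulated-GTV metric at each amplitude.

    ``plan`` may be a SyntheticPlan or a bare static dose VoxelGrid.  The
    dose and mask are cropped to the GTV's x-y bounding box first: motion is
    purely along z, so accumulation commutes with the crop and the sweep
    runs on a thin column instead of the full grid.
    """
    if criterion not in CRITERIA:
        raise VolumeError(f"unknown criterion {criterion!r}; expected one of {CRITERIA}")
    amplitudes = np.asarray(amplitudes_mm, dtype=float)
    if amplitudes.size == 0:
        raise VolumeError("amplitude list must be non-empty")
    static = plan.dose if isinstance(plan, SyntheticPlan) else plan
    dose, mask = crop_xy(static, gtv)
    out = np.empty(amplitudes.size)
    for i, a in enumerate(amplitudes):
        phases = sample_phases(MotionModel(a, period_s=period_s), phase_count)
        acc = accumulate_v4drt(dose, phases)
        out[i] = _criterion_value(acc, mask, criterion, bin_gy)
    return out


def dca_from_curve(amplitudes_mm, metric_gy, d_crit_gy: float) -> tuple[float, bool]:
    """Prefix-rule DCA: largest amplitude such that the criterion holds at
    every grid amplitude up to and including it; 0 if it fails at the
    smallest amplitude.  Returns ``(dca, clamped)``."""
    amplitudes = np.asarray(amplitudes_mm, dtype=float)
    metric = np.asarray(metric_gy, dtype=float)
    if amplitudes.size == 0:
        raise VolumeError("amplitude list must be non-empty")
    if np.any(np.diff(amplitudes) <= 0):
        raise VolumeError("amplitudes must be sorted ascending")
    passing = metric >= d_crit_gy - 1e-9
    if passing.all():
        return float(amplitudes[-1]), True
    n_prefix = int(np.argmin(passing))  # first failure index
    return (float(amplitudes[n_prefix - 1]) if n_prefix > 0 else 0.0), False


def dca_search(
    plan,
    gtv: StructureMask,
    criterion: str = "D100",
    d_crit_gy: float | None = None,
    amplitudes_mm=None,
    phase_count: int = 10,
    period_s: float = 4.0,
    bin_gy: float = 0.01,
) -> DCAResult:
    """Search the maximum amplitude preserving GTV coverage for one plan.

    ``plan`` may be a SyntheticPlan (whose prescription supplies the default
    critical dose, per the coverage condition D100%/D99% >= prescribed
    dose) or a bare static dose VoxelGrid with an explicit ``d_crit_gy``.
    """
    if d_crit_gy is None:
        if not isinstance(plan, SyntheticPlan):
            raise VolumeError("d_crit_gy is required when plan is a bare dose grid")
        d_crit_gy = plan.plan.prescription_gy
    if d_crit_gy <= 0:
        raise VolumeError("critical dose must be > 0")
    amplitudes = default_amplitudes() if amplitudes_mm is None else np.asarray(
        amplitudes_mm, dtype=float
    )
    metric = gtv_metric_curve(
        plan, gtv, amplitudes, criterion, phase_count, period_s, bin_gy
    )
    dca, clamped = dca_from_curve(amplitudes, metric, d_crit_gy)
    fraction = plan.plan.isodose_fraction if isinstance(plan, SyntheticPlan) else float("nan")
    return DCAResult(
        fraction, criterion, float(d_crit_gy), amplitudes, metric, dca, clamped,
    )


def average_dose_tolerance(
    plan: SyntheticPlan,
    gtv: StructureMask,
    reference_gy: float,
    amplitudes_mm=None,
    phase_count: int = 10,
    period_s: float = 4.0,
) -> float:
    """Largest amplitude (prefix rule) at which the mean accumulated GTV
    dose stays at or above the reference (the 80% plan's static mean)."""
    if reference_gy <= 0:
        raise VolumeError("reference dose must be > 0")
    amplitudes = default_amplitudes() if amplitudes_mm is None else np.asarray(
        amplitudes_mm, dtype=float
    )
    metric = gtv_metric_curve(plan, gtv, amplitudes, "Dmean", phase_count, period_s)
    tol, _ = dca_from_curve(amplitudes, metric, reference_gy)
    return tol


def select_optimal_plan(
    dca_by_plan: Mapping[float, DCAResult],
    avg_tolerance_by_plan: Mapping[float, float],
    oar_by_plan: Mapping[float, Mapping[float, OARMetrics]],
    reference_mean_gtv_gy: float,
    reference_fraction: float = 0.8,
) -> PlanComparison:
    """Apply the three-condition rule and pick the lowest qualifying plan.

    For each plan the *qualifying amplitude* is the largest grid amplitude
    not exceeding min(reference plan's DCA, the plan's own DCA, the plan's
    average-dose tolerance).  A plan qualifies when that amplitude is
    positive and none of its normal-tissue metrics there exceeds the
    reference plan's static (amplitude 0) values.  Ties resolve to the
    lowest isodose fraction; if no plan qualifies the comparison reports
    ``selected_fraction = None`` rather than raising.
    """
    if reference_fraction not in dca_by_plan:
        raise VolumeError("reference plan missing from the DCA results")
    dca_ref = dca_by_plan[reference_fraction].dca_mm
    ref_oar = oar_by_plan[reference_fraction].get(0.0)
    if ref_oar is None:
        raise VolumeError("reference plan static (amplitude 0) OAR metrics required")

    qualifying: dict[float, float] = {}
    qualifies: dict[float, bool] = {}
    for f in sorted(dca_by_plan):
        cap = min(dca_ref, dca_by_plan[f].dca_mm, avg_tolerance_by_plan[f])
        grid = np.asarray(sorted(oar_by_plan[f]), dtype=float)
        feasible = grid[grid <= cap + 1e-9]
        q = float(feasible[-1]) if feasible.size else 0.0
        qualifying[f] = q
        if q <= 0:
            qualifies[f] = False
            continue
        oar = oar_by_plan[f][q]
        qualifies[f] = bool(np.all(oar.as_vector() <= ref_oar.as_vector() + 1e-9))

    selected = next((f for f in sorted(qualifies) if qualifies[f]), None)
    return PlanComparison(
        dict(dca_by_plan), dict(avg_tolerance_by_plan), qualifying, qualifies,
        reference_fraction, float(reference_mean_gtv_gy), selected,
    )


def compute_om(
    ptv_margin_mm: float, dca_opt_mm: float, delta_resp_mm: float
) -> OMResult:
    """Optimal Margin: OM = PTV_margin / DCA_opt * Delta_resp.

    ``delta_resp_mm`` is the patient's observed respiratory displacement.
    Values are stored exactly; rounding (one decimal for mm, integer for
    the percentage) happens only in the reporting properties.
    """
    for name, v in (
        ("ptv_margin_mm", ptv_margin_mm),
        ("dca_opt_mm", dca_opt_mm),
        ("delta_resp_mm", delta_resp_mm),
    ):
        if v <= 0:
            raise VolumeError(f"{name} must be > 0, got {v}")
    om = ptv_margin_mm / dca_opt_mm * delta_resp_mm
    reduction = (1.0 - om / ptv_margin_mm) * 100.0
    return OMResult(ptv_margin_mm, dca_opt_mm, delta_resp_mm, om, reduction)


def dca_margin_ratio(dca_mm: float, ptv_margin_mm: float) -> float:
    """How many times larger than the planning margin the tolerated motion
    amplitude is (e.g. a 22-mm DCA against a 10-mm margin gives 2.2)."""
    if ptv_margin_mm <= 0 or dca_mm < 0:
        raise VolumeError("margin must be > 0 and DCA >= 0")
    return dca_mm / ptv_margin_mm
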