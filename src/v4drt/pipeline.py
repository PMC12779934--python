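"""End-to-end margin-optimization pipeline.

Builds the digital phantom, synthesizes the 60/70/80% isodose plans, sweeps
the respiratory amplitude grid accumulating the v4DRT dose for each plan,
derives the DCA (D100% and D99%), the average-dose tolerances, the optimal
prescription isodose plan and the Optimal Margin, and finally verifies the
selected plan's interplay sensitivity with a gamma comparison between
phase-resolved deliveries and the accumulated dose.

Everything is deterministic given the configuration; no randomness is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .accumulate import DeliverySpec, accumulate_v4drt, simulate_interplay
from .core import StructureMask, VoxelGrid
from .io import write_json_report, write_nrrd
from .margins import (
    DCAResult, OARMetrics, OMResult, PlanComparison,
    compute_om, dca_from_curve, select_optimal_plan,
)
from .metrics import (
    GammaParams, cumulative_dvh, dose_at_volume, gamma_evaluate,
    shell_distance_map, shell_metrics, volume_at_dose,
)
from .motion import MotionModel, sample_phases
from .phantom import Phantom, PhantomSpec, PlanSpec, SyntheticPlan, build_phantom, synth_plan_dose


class ConfigError(ValueError):
    """Aggregated configuration schema violations."""


@dataclass
class PipelineConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    prescription_gy: float = 40.0
    fractions: int = 4
    isodose_fractions: tuple[float, ...] = (0.6, 0.7, 0.8)
    penumbra_exponent: float = 3.0
    reference_fraction: float = 0.8
    amplitudes_mm: tuple[float, ...] = tuple(np.arange(1.0, 25.0))
    period_s: float = 4.0
    phase_count: int = 10
    coverage_criterion: str = "D100"
    delta_resp_mm: float = 10.0
    shell_distances_cm: tuple[float, ...] = (0.5, 1.0, 2.0)
    shell_statistic: str = "mean"
    interplay: DeliverySpec = field(default_factory=DeliverySpec)
    interplay_phase_offsets_rad: tuple[float, ...] = (-math.pi / 2, math.pi / 2)
    gamma: GammaParams = field(default_factory=GammaParams)
    dvh_bin_gy: float = 0.01
    write_dose_grids: bool = False


_SECTION_TYPES = {
    "phantom": PhantomSpec,
    "interplay": DeliverySpec,
    "gamma": GammaParams,
}


def config_from_dict(raw: dict) -> PipelineConfig:
    """Build a config from a (possibly partial) nested dict, aggregating
    all schema violations into a single error."""
    errors: list[str] = []
    kwargs: dict = {}
    valid = set(PipelineConfig.__dataclass_fields__)
    for key, value in dict(raw).items():
        if key not in valid:
            errors.append(f"unknown config key: {key!r}")
            continue
        if key in _SECTION_TYPES and isinstance(value, dict):
            try:
                value = _SECTION_TYPES[key](**value)
            except (TypeError, ValueError) as exc:
                errors.append(f"{key}: {exc}")
                continue
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    if errors:
        raise ConfigError("; ".join(errors))
    try:
        return PipelineConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    return config_from_dict(raw)


@dataclass
class InterplayReport:
    amplitude_mm: float
    phase_offsets_rad: tuple[float, ...]
    gamma_pass_rate_pct: dict[float, float]
    max_offset_difference_gy: float


@dataclass
class PipelineReport:
    config: PipelineConfig
    phantom_volumes_mm3: dict[str, float]
    calibration: dict[float, dict]
    metrics_by_plan: dict[float, pd.DataFrame]
    dca_d100: dict[float, DCAResult]
    dca_d99: dict[float, DCAResult]
    avg_tolerance: dict[float, float]
    reference_mean_gtv_gy: float
    comparison: PlanComparison
    om: OMResult | None
    interplay: InterplayReport | None


def _plan_metrics(
    dose: VoxelGrid,
    gtv: StructureMask,
    liver_minus_gtv: StructureMask,
    ptv_dist: np.ndarray,
    ptv: StructureMask,
    cfg: PipelineConfig,
    amplitude: float,
) -> dict:
    gtv_dvh = cumulative_dvh(dose, gtv, cfg.dvh_bin_gy)
    liver_dvh = cumulative_dvh(dose, liver_minus_gtv, cfg.dvh_bin_gy)
    shells = shell_metrics(
        dose, ptv, cfg.shell_distances_cm, cfg.shell_statistic, distance_map=ptv_dist
    )
    row = {
        "amplitude_mm": amplitude,
        "gtv_d100_gy": dose_at_volume(gtv_dvh, 100.0),
        "gtv_d99_gy": dose_at_volume(gtv_dvh, 99.0),
        "gtv_mean_gy": float(dose.values[gtv.mask].mean()),
        "liver_v5gy_pct": volume_at_dose(liver_dvh, 5.0),
        "liver_v20gy_pct": volume_at_dose(liver_dvh, 20.0),
    }
    for d_cm, val in shells.items():
        row[f"shell_d{d_cm:g}cm_gy"] = val
    return row


def _crop_box(dose: VoxelGrid, center_xy: tuple[float, float], half_mm: float) -> VoxelGrid:
    """Crop in x-y around a physical center (motion is z-only, so GTV-frame
    dose along z is unaffected); used to keep the interplay gamma cheap."""
    xs = dose.axis_coords("x")
    ys = dose.axis_coords("y")
    ix = np.nonzero(np.abs(xs - center_xy[0]) <= half_mm)[0]
    iy = np.nonzero(np.abs(ys - center_xy[1]) <= half_mm)[0]
    origin = (float(xs[ix[0]]), float(ys[iy[0]]), dose.origin[2])
    return VoxelGrid(
        dose.values[ix[0]:ix[-1] + 1, iy[0]:iy[-1] + 1, :].copy(),
        dose.spacing, origin, pad_mm=dose.pad_mm,
    )


def run_pipeline(config: PipelineConfig | dict | None = None, out_dir=None) -> PipelineReport:
    """Run the full amplitude sweep, plan selection and OM derivation."""
    if config is None:
        config = PipelineConfig()
    elif isinstance(config, dict):
        config = config_from_dict(config)
    cfg = config

    phantom = build_phantom(cfg.phantom)
    gtv = phantom.masks["gtv"]
    ptv = phantom.masks["ptv"]
    liver_minus_gtv = phantom.masks["liver_minus_gtv"]
    ptv_dist = shell_distance_map(ptv)

    plans: dict[float, SyntheticPlan] = {}
    calibration: dict[float, dict] = {}
    for f in cfg.isodose_fractions:
        spec = PlanSpec(cfg.prescription_gy, cfg.fractions, f, cfg.penumbra_exponent)
        plan = synth_plan_dose(spec, phantom)
        plans[f] = plan
        calibration[f] = {
            "dmax_gy": plan.theta.dmax_gy,
            "falloff_mm": plan.theta.falloff_mm,
            "exponent": plan.theta.exponent,
            **plan.residuals,
        }

    amplitudes = tuple(float(a) for a in cfg.amplitudes_mm)
    metrics_by_plan: dict[float, pd.DataFrame] = {}
    oar_by_plan: dict[float, dict[float, OARMetrics]] = {}
    for f, plan in plans.items():
        rows = []
        if 0.0 not in amplitudes:  # static row; an explicit amplitude 0 is identical
            rows.append(
                _plan_metrics(plan.dose, gtv, liver_minus_gtv, ptv_dist, ptv, cfg, 0.0)
            )
        for a in amplitudes:
            phases = sample_phases(MotionModel(a, period_s=cfg.period_s), cfg.phase_count)
            acc = accumulate_v4drt(plan.dose, phases)
            rows.append(
                _plan_metrics(acc, gtv, liver_minus_gtv, ptv_dist, ptv, cfg, a)
            )
        df = pd.DataFrame(rows).set_index("amplitude_mm")
        metrics_by_plan[f] = df
        oar_by_plan[f] = {
            float(a): OARMetrics(
                {d: df.loc[a, f"shell_d{d:g}cm_gy"] for d in cfg.shell_distances_cm},
                float(df.loc[a, "liver_v5gy_pct"]),
                float(df.loc[a, "liver_v20gy_pct"]),
            )
            for a in df.index
        }

    amp_arr = np.asarray(amplitudes)
    dca_d100: dict[float, DCAResult] = {}
    dca_d99: dict[float, DCAResult] = {}
    for f, df in metrics_by_plan.items():
        for crit, col, store in (
            ("D100", "gtv_d100_gy", dca_d100),
            ("D99", "gtv_d99_gy", dca_d99),
        ):
            curve = df.loc[list(amplitudes), col].to_numpy()
            dca, clamped = dca_from_curve(amp_arr, curve, cfg.prescription_gy)
            store[f] = DCAResult(
                f, crit, cfg.prescription_gy, amp_arr, curve, dca, clamped
            )

    reference_mean = float(
        metrics_by_plan[cfg.reference_fraction].loc[0.0, "gtv_mean_gy"]
    )
    avg_tolerance: dict[float, float] = {}
    for f, df in metrics_by_plan.items():
        curve = df.loc[list(amplitudes), "gtv_mean_gy"].to_numpy()
        tol, _ = dca_from_curve(amp_arr, curve, reference_mean)
        avg_tolerance[f] = tol

    dca_by_crit = dca_d100 if cfg.coverage_criterion == "D100" else dca_d99
    comparison = select_optimal_plan(
        dca_by_crit, avg_tolerance, oar_by_plan, reference_mean, cfg.reference_fraction
    )

    om = None
    interplay_report = None
    if comparison.selected_fraction is not None and comparison.dca_opt_mm > 0:
        om = compute_om(
            cfg.phantom.ptv_margin_mm, comparison.dca_opt_mm, cfg.delta_resp_mm
        )
        interplay_report = _interplay_check(
            plans[comparison.selected_fraction], phantom, comparison.dca_opt_mm, cfg
        )

    report = PipelineReport(
        cfg,
        {name: m.volume_mm3 for name, m in phantom.masks.items()},
        calibration, metrics_by_plan, dca_d100, dca_d99, avg_tolerance,
        reference_mean, comparison, om, interplay_report,
    )
    if out_dir is not None:
        _write_outputs(report, plans, Path(out_dir))
    return report


def _interplay_check(
    plan: SyntheticPlan, phantom: Phantom, amplitude_mm: float, cfg: PipelineConfig
) -> InterplayReport:
    center = phantom.spec.gtv_center_mm
    half = phantom.spec.ptv_radius_mm + 3.0 * cfg.gamma.dta_mm + 10.0
    dose = _crop_box(plan.dose, (center[0], center[1]), half)
    motion = MotionModel(amplitude_mm, period_s=cfg.period_s)
    reference = accumulate_v4drt(dose, sample_phases(motion, cfg.phase_count))
    pass_rates: dict[float, float] = {}
    delivered: list[np.ndarray] = []
    for phi0 in cfg.interplay_phase_offsets_rad:
        spec = DeliverySpec(
            cfg.interplay.beam_on_time_s, cfg.interplay.segment_count, phi0,
            cfg.interplay.fractions,
        )
        dlv = simulate_interplay(dose, spec, motion)
        delivered.append(dlv.values)
        pass_rates[float(phi0)] = gamma_evaluate(reference, dlv, cfg.gamma).pass_rate_pct
    max_diff = 0.0
    for i in range(len(delivered)):
        for j in range(i + 1, len(delivered)):
            max_diff = max(max_diff, float(np.abs(delivered[i] - delivered[j]).max()))
    return InterplayReport(
        amplitude_mm, tuple(cfg.interplay_phase_offsets_rad), pass_rates, max_diff
    )


def _write_outputs(report: PipelineReport, plans, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for f, df in report.metrics_by_plan.items():
        df.to_csv(out_dir / f"metrics_f{int(round(100 * f))}.csv")
    write_json_report(
        out_dir / "dca.json",
        {
            "D100": {f: r for f, r in report.dca_d100.items()},
            "D99": {f: r for f, r in report.dca_d99.items()},
            "avg_tolerance_mm": report.avg_tolerance,
            "reference_mean_gtv_gy": report.reference_mean_gtv_gy,
            "qualifying_amplitude_mm": report.comparison.qualifying_amplitude_by_plan,
            "selected_fraction": report.comparison.selected_fraction,
        },
    )
    if report.om is not None:
        write_json_report(
            out_dir / "om.json",
            {
                **asdict(report.om),
                "om_mm_reported": report.om.om_mm_reported,
                "reduction_pct_reported": report.om.reduction_pct_reported,
            },
        )
    if report.interplay is not None:
        write_json_report(out_dir / "gamma.json", report.interplay)
    write_json_report(out_dir / "calibration.json", report.calibration)
    if report.config.write_dose_grids:
        for f, plan in plans.items():
            write_nrrd(out_dir / f"dose_f{int(round(100 * f))}.nrrd", plan.dose)
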