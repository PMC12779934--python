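"""DVH construction, dose/volume metrics and gamma-index comparison.

DVHs are cumulative, built by exact voxel counting on a fixed dose-bin
width (default 0.01 Gy, no smoothing).  Dx% / VxGy queries interpolate
linearly on the curve.  Shell metrics report the mean (or max) dose in a
one-voxel-thick shell at a stated distance from a structure surface.

The gamma index compares an evaluated dose grid against a reference with a
global dose-difference / distance-to-agreement criterion (default 3%/3 mm):
for every reference point above a low-dose threshold,

    gamma = min over |dr| <= R of sqrt( (dD / (dd * Dnorm))^2 + (|dr| / dta)^2 )

with Dnorm the global reference maximum, the search radius R a multiple of
the DTA (default 3x) and sub-voxel refinement by tri-linear interpolation of
the evaluated grid at 1/10-voxel displacement steps.  A point passes when
gamma <= 1 (boundary counted as a pass, up to a 1e-9 numerical guard).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import StructureMask, VoxelGrid, VolumeError, require_aligned


class EmptyStructureError(VolumeError):
    """Metric requested on an empty structure or shell."""


# --------------------------------------------------------------------------
# DVH

@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram.

    ``volume_pct[i]`` is the percentage of the structure receiving at least
    ``dose_gy[i]`` (bin left edges, ascending from 0).  The curve starts at
    100% and falls to 0 beyond the structure maximum dose.
    """

    dose_gy: np.ndarray
    volume_pct: np.ndarray
    structure: str
    total_volume_mm3: float
    bin_gy: float


def cumulative_dvh(dose: VoxelGrid, mask: StructureMask, bin_gy: float = 0.01) -> DVHCurve:
    """Exact-counting cumulative DVH of ``dose`` over ``mask``."""
    require_aligned(dose, mask)
    if bin_gy <= 0:
        raise VolumeError("bin width must be > 0")
    if not mask.mask.any():
        raise EmptyStructureError(f"structure '{mask.name}' is empty")
    vals = np.sort(dose.values[mask.mask])
    n_bins = int(np.floor(vals[-1] / bin_gy)) + 2  # final edge beyond max dose
    edges = bin_gy * np.arange(n_bins + 1)
    below = np.searchsorted(vals, edges, side="left")
    volume_pct = 100.0 * (vals.size - below) / vals.size
    return DVHCurve(edges, volume_pct, mask.name, mask.volume_mm3, bin_gy)


def dose_at_volume(dvh: DVHCurve, volume_pct: float) -> float:
    """D_v: the maximum dose received by at least ``volume_pct`` of the
    structure (linear interpolation between bins)."""
    v = float(volume_pct)
    if not (0.0 < v <= 100.0):
        raise VolumeError(f"volume percentage must lie in (0, 100], got {v}")
    cum = dvh.volume_pct
    idx = np.nonzero(cum >= v)[0]
    if idx.size == 0:
        return 0.0
    j = int(idx[-1])  # cum is non-increasing, so the prefix ends at j
    if j + 1 >= cum.size or cum[j] == cum[j + 1]:
        return float(dvh.dose_gy[j])
    frac = (cum[j] - v) / (cum[j] - cum[j + 1])
    return float(dvh.dose_gy[j] + frac * (dvh.dose_gy[j + 1] - dvh.dose_gy[j]))


def volume_at_dose(dvh: DVHCurve, dose_gy: float) -> float:
    """V_d: percentage of the structure receiving at least ``dose_gy``."""
    d = float(dose_gy)
    if d < 0:
        raise VolumeError(f"dose must be >= 0, got {d}")
    return float(np.interp(d, dvh.dose_gy, dvh.volume_pct, right=0.0))


@dataclass
class MetricReport:
    """Standard dose metrics for one structure (and optional OAR extras)."""

    structure: str
    d100_gy: float
    d99_gy: float
    d95_gy: float
    mean_gy: float
    v5gy_pct: float | None = None
    v20gy_pct: float | None = None
    shell_gy: dict[float, float] = field(default_factory=dict)  # distance_cm -> Gy
    amplitude_mm: float | None = None


def metric_report(
    dose: VoxelGrid,
    mask: StructureMask,
    bin_gy: float = 0.01,
    vx_gy: tuple[float, ...] = (),
    amplitude_mm: float | None = None,
) -> MetricReport:
    dvh = cumulative_dvh(dose, mask, bin_gy)
    vx = {x: volume_at_dose(dvh, x) for x in vx_gy}
    return MetricReport(
        structure=mask.name,
        d100_gy=dose_at_volume(dvh, 100.0),
        d99_gy=dose_at_volume(dvh, 99.0),
        d95_gy=dose_at_volume(dvh, 95.0),
        mean_gy=float(dose.values[mask.mask].mean()),
        v5gy_pct=vx.get(5.0),
        v20gy_pct=vx.get(20.0),
        amplitude_mm=amplitude_mm,
    )


# --------------------------------------------------------------------------
# Shell metrics

def shell_distance_map(mask: StructureMask) -> np.ndarray:
    """Distance (mm) of each voxel center from the structure (0 inside)."""
    return ndimage.distance_transform_edt(~mask.mask, sampling=mask.spacing)


def shell_metrics(
    dose: VoxelGrid,
    structure: StructureMask,
    distances_cm: tuple[float, ...] = (0.5, 1.0, 2.0),
    statistic: str = "mean",
    distance_map: np.ndarray | None = None,
) -> dict[float, float]:
    """Dose at stated distances from a structure surface.

    For each distance ``d`` (cm) the metric is the mean (or, configurably,
    max) dose over the voxels whose Euclidean distance from the structure
    lies within one voxel of ``d``.  ``distance_map`` may be supplied to
    reuse a precomputed transform across amplitudes.
    """
    require_aligned(dose, structure)
    if statistic not in ("mean", "max"):
        raise VolumeError(f"unknown shell statistic: {statistic!r}")
    dist = shell_distance_map(structure) if distance_map is None else distance_map
    half = max(dose.spacing)
    out: dict[float, float] = {}
    for d_cm in distances_cm:
        d_mm = 10.0 * float(d_cm)
        sel = np.abs(dist - d_mm) <= half
        if not sel.any():
            raise EmptyStructureError(
                f"shell at {d_cm} cm from '{structure.name}' covers no voxels"
            )
        vals = dose.values[sel]
        out[float(d_cm)] = float(vals.mean() if statistic == "mean" else vals.max())
    return out


# --------------------------------------------------------------------------
# Gamma index

#: Numerical guard so an exactly-on-criterion point counts as a pass.
GAMMA_PASS_TOL = 1e-9


@dataclass(frozen=True)
class GammaParams:
    """Global gamma criterion (defaults: 3%/3 mm, 10% low-dose threshold)."""

    dose_criterion: float = 0.03       # fraction of the global reference max
    dta_mm: float = 3.0                # distance-to-agreement
    low_dose_threshold: float = 0.10   # exclude reference points below this
    search_factor: float = 3.0         # search radius = factor * dta
    step_divisor: int = 10             # sub-voxel step = voxel / divisor

    def __post_init__(self) -> None:
        if min(self.dose_criterion, self.dta_mm, self.search_factor) <= 0:
            raise ValueError("gamma criteria must be positive")
        if not (0.0 <= self.low_dose_threshold < 1.0):
            raise ValueError("low-dose threshold must lie in [0, 1)")
        if self.step_divisor < 1:
            raise ValueError("step divisor must be >= 1")


@dataclass
class GammaResult:
    """Gamma map (NaN outside evaluated points), pass rate and point count."""

    gamma: np.ndarray
    pass_rate_pct: float
    evaluated_points: int
    params: GammaParams


def candidate_offsets(spacing, params: GammaParams) -> tuple[np.ndarray, np.ndarray]:
    """Displacement candidates in index units, sorted by physical distance.

    Candidates are integer multiples of ``voxel / step_divisor`` per axis
    whose Euclidean length is within the search radius.
    """
    spacing = np.asarray(spacing, dtype=float)
    radius = params.search_factor * params.dta_mm
    steps = spacing / params.step_divisor
    kmax = np.floor(radius / steps).astype(int)
    axes = [steps[a] * np.arange(-kmax[a], kmax[a] + 1) for a in range(3)]
    offs = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    dist = np.sqrt((offs ** 2).sum(axis=1))
    keep = dist <= radius + 1e-9
    offs, dist = offs[keep], dist[keep]
    order = np.argsort(dist, kind="stable")
    return offs[order] / spacing, dist[order]  # (index units, mm)


def _finish_points(values, pts, refv, gamma2, active_idx, offs_idx, dist2, dd):
    """Exhaustive per-point search over the remaining candidates (used once
    only a handful of points are still improvable)."""
    for i in active_idx:
        coords = (pts[i][None, :] + offs_idx).T
        vals = ndimage.map_coordinates(values, coords, order=1, mode="nearest")
        g2 = ((vals - refv[i]) / dd) ** 2 + dist2
        gamma2[i] = min(gamma2[i], float(g2.min()))


def gamma_evaluate(
    reference: VoxelGrid, evaluated: VoxelGrid, params: GammaParams = GammaParams()
) -> GammaResult:
    """Gamma map of ``evaluated`` against ``reference`` (global criterion).

    Candidates are visited in order of increasing spatial distance so the
    search terminates as soon as the distance term alone exceeds every
    remaining gamma value.
    """
    require_aligned(reference, evaluated)
    dnorm = float(reference.values.max())
    if dnorm <= 0:
        raise VolumeError("reference maximum dose must be > 0")
    dd = params.dose_criterion * dnorm
    sel = reference.values >= params.low_dose_threshold * dnorm
    if not sel.any():
        raise VolumeError("no reference points above the low-dose threshold")
    pts = np.argwhere(sel).astype(float)
    refv = reference.values[sel]
    offs_idx, dist_mm = candidate_offsets(reference.spacing, params)
    dist_term = (dist_mm / params.dta_mm) ** 2

    gamma2 = np.full(refv.size, np.inf)
    i = 0
    n_cand = offs_idx.shape[0]
    while i < n_cand:
        s = dist_term[i]
        active = gamma2 > s
        n_active = int(active.sum())
        if n_active == 0:
            break
        if n_active <= 32:
            _finish_points(
                evaluated.values, pts, refv, gamma2,
                np.nonzero(active)[0], offs_idx[i:], dist_term[i:], dd,
            )
            break
        coords = (pts[active] + offs_idx[i][None, :]).T
        vals = ndimage.map_coordinates(evaluated.values, coords, order=1, mode="nearest")
        g2 = ((vals - refv[active]) / dd) ** 2 + s
        gamma2[active] = np.minimum(gamma2[active], g2)
        i += 1

    gamma = np.sqrt(gamma2)
    gmap = np.full(reference.shape, np.nan)
    gmap[sel] = gamma
    pass_rate = 100.0 * float(np.mean(gamma <= 1.0 + GAMMA_PASS_TOL))
    return GammaResult(gmap, pass_rate, int(refv.size), params)
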