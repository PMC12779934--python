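"""Digital phantom and analytic isodose-prescription dose synthesis.

The phantom emulates a liver SBRT planning geometry: a 1-cm spherical GTV
inside an ellipsoidal liver inside an elliptic-cylinder body, with a 0-mm
CTV margin and a fixed isotropic 10-mm PTV expansion.  The grid carries a
mandatory superior-inferior padding budget (>= 24 mm, the largest
respiratory amplitude studied) so rigid dose shifts never read beyond a
physically meaningful region.

Instead of a treatment planning system, each prescription plan's static
dose is synthesized from a monotone radial profile

    D(r) = Dmax * S(r),   S(r) = 1 / (1 + ((r - r_GTV)+ / s)^p)

a flat core over the GTV followed by a Hill-type (generalized-logistic)
falloff.  The two free parameters are matched to the planning constraints:

* the isodose constraint ``S(r_PTV) = f`` fixes the falloff scale ``s`` in
  closed form (``f`` = prescription isodose fraction of Dmax), and
* ``Dmax`` is solved so that D95% of the voxelized PTV — computed with the
  same DVH machinery used for every later metric — equals the prescription.

Because ``Dmax ~ Rx / f``, the dose gradient magnitude at the PTV surface
scales like ``(1 - f)``: prescribing to a lower isodose level structurally
yields a hotter tumor center and a steeper peripheral gradient, which is
the mechanism the margin analysis exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import StructureMask, VoxelGrid, VolumeError, dilate_mask

PRESCRIPTION_VOLUME_PCT = 95.0  # normalization: D95%(PTV) = prescription


class PhantomError(VolumeError):
    """Invalid phantom geometry."""


class CalibrationError(RuntimeError):
    """Profile calibration failed to satisfy the planning constraints."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the digital phantom (all lengths in mm).

    The liver is an ellipsoid (semi-axes, center), the body an elliptic
    cylinder (semi-axes in x/y, half-length in z).  The grid covers the body
    plus ``pad_mm`` of superior/inferior padding (must exceed the largest
    motion amplitude, 24 mm).
    """

    gtv_diameter_mm: float = 10.0
    ctv_margin_mm: float = 0.0
    ptv_margin_mm: float = 10.0
    gtv_center_mm: tuple[float, float, float] = (45.0, 0.0, 0.0)
    liver_semiaxes_mm: tuple[float, float, float] = (80.0, 60.0, 70.0)
    liver_center_mm: tuple[float, float, float] = (45.0, 0.0, 0.0)
    body_semiaxes_mm: tuple[float, float] = (140.0, 90.0)
    body_half_length_mm: float = 100.0
    spacing_mm: float = 2.0
    pad_mm: float = 26.0
    min_liver_clearance_mm: float = 24.0

    @property
    def gtv_radius_mm(self) -> float:
        return self.gtv_diameter_mm / 2.0

    @property
    def ptv_radius_mm(self) -> float:
        return self.gtv_radius_mm + self.ctv_margin_mm + self.ptv_margin_mm


@dataclass(frozen=True)
class PlanSpec:
    """Prescription and normalization rule for one synthetic plan."""

    prescription_gy: float = 40.0
    fractions: int = 4
    isodose_fraction: float = 0.8
    penumbra_exponent: float = 3.0  # Hill exponent p of the radial falloff

    def __post_init__(self) -> None:
        if self.prescription_gy <= 0:
            raise ValueError("prescription must be > 0")
        if not (0.0 < self.isodose_fraction < 1.0):
            raise ValueError(
                f"isodose fraction must lie in (0, 1), got {self.isodose_fraction}"
            )
        if self.penumbra_exponent <= 0:
            raise ValueError("penumbra exponent must be > 0")


@dataclass(frozen=True)
class ProfileParams:
    """Calibrated radial-profile parameters theta."""

    dmax_gy: float
    falloff_mm: float       # Hill scale s
    exponent: float         # Hill exponent p
    core_radius_mm: float   # GTV radius (flat-core extent)


@dataclass
class Phantom:
    """Grid geometry plus the standard structure set."""

    spec: PhantomSpec
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    masks: dict[str, StructureMask]
    radius_mm: np.ndarray = field(repr=False)  # distance of voxel centers from GTV center

    def grid(self, values: np.ndarray) -> VoxelGrid:
        return VoxelGrid(values, self.spacing, self.origin, pad_mm=self.spec.pad_mm)


@dataclass
class SyntheticPlan:
    """A calibrated static dose distribution for one isodose prescription."""

    plan: PlanSpec
    theta: ProfileParams
    dose: VoxelGrid
    phantom: Phantom
    residuals: dict[str, float]


def _axis(extent: float, spacing: float) -> np.ndarray:
    n = int(np.floor(extent / spacing))
    return spacing * np.arange(-n, n + 1)


def build_phantom(spec: PhantomSpec = PhantomSpec()) -> Phantom:
    """Voxelize the phantom structures on a centered regular grid.

    Masks: ``gtv``, ``ctv``, ``ptv`` (produced by Euclidean dilation of the
    GTV), ``liver``, ``liver_minus_gtv`` and ``body``.
    """
    if spec.ctv_margin_mm < 0 or spec.ptv_margin_mm < 0:
        raise PhantomError("margins must be >= 0")
    if spec.pad_mm < spec.min_liver_clearance_mm:
        raise PhantomError(
            f"grid padding {spec.pad_mm} mm must cover the maximum motion "
            f"amplitude ({spec.min_liver_clearance_mm} mm)"
        )
    cx, cy, cz = spec.gtv_center_mm
    lx, ly, lz = spec.liver_center_mm
    ax, ay, az = spec.liver_semiaxes_mm

    # GTV must sit inside the liver with clearance along z for motion.
    need = spec.gtv_radius_mm + spec.min_liver_clearance_mm
    for z_probe in (cz - need, cz + need):
        inside = ((cx - lx) / ax) ** 2 + ((cy - ly) / ay) ** 2 + ((z_probe - lz) / az) ** 2
        if inside > 1.0:
            raise PhantomError(
                "GTV is not contained in the liver with the required "
                f"{spec.min_liver_clearance_mm} mm superior/inferior clearance"
            )

    h = spec.spacing_mm
    xs = _axis(spec.body_semiaxes_mm[0] + 2 * h, h)
    ys = _axis(spec.body_semiaxes_mm[1] + 2 * h, h)
    zs = _axis(spec.body_half_length_mm + spec.pad_mm, h)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    spacing = (h, h, h)
    origin = (float(xs[0]), float(ys[0]), float(zs[0]))

    r = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2)
    gtv = StructureMask("gtv", r <= spec.gtv_radius_mm, spacing, origin)
    if not gtv.mask.any():
        raise PhantomError("GTV does not cover any voxel center; refine the grid")
    ctv = dilate_mask(gtv, spec.ctv_margin_mm)
    ctv.name = "ctv"
    ptv = dilate_mask(gtv, spec.ctv_margin_mm + spec.ptv_margin_mm)
    ptv.name = "ptv"
    liver = StructureMask(
        "liver",
        ((X - lx) / ax) ** 2 + ((Y - ly) / ay) ** 2 + ((Z - lz) / az) ** 2 <= 1.0,
        spacing,
        origin,
    )
    body = StructureMask(
        "body",
        ((X / spec.body_semiaxes_mm[0]) ** 2 + (Y / spec.body_semiaxes_mm[1]) ** 2 <= 1.0)
        & (np.abs(Z) <= spec.body_half_length_mm),
        spacing,
        origin,
    )
    if np.any(gtv.mask & ~liver.mask):
        raise PhantomError("GTV mask extends outside the liver mask")
    liver_minus_gtv = StructureMask(
        "liver_minus_gtv", liver.mask & ~gtv.mask, spacing, origin
    )
    masks = {m.name: m for m in (gtv, ctv, ptv, liver, liver_minus_gtv, body)}
    return Phantom(spec, gtv.shape, spacing, origin, masks, r)


def radial_profile(r, theta: ProfileParams) -> np.ndarray:
    """Dose (Gy) at radius r (mm) from the GTV center."""
    d = np.maximum(np.asarray(r, dtype=float) - theta.core_radius_mm, 0.0)
    return theta.dmax_gy / (1.0 + (d / theta.falloff_mm) ** theta.exponent)


def profile_gradient(r, theta: ProfileParams) -> np.ndarray:
    """Radial dose derivative dD/dr (Gy/mm); <= 0 everywhere."""
    d = np.maximum(np.asarray(r, dtype=float) - theta.core_radius_mm, 0.0)
    x = (d / theta.falloff_mm) ** theta.exponent
    with np.errstate(divide="ignore", invalid="ignore"):
        g = -theta.dmax_gy * theta.exponent * x / (np.where(d > 0, d, np.inf) * (1.0 + x) ** 2)
    return np.where(d > 0, g, 0.0)


def calibrate_profile(plan: PlanSpec, phantom: Phantom) -> tuple[ProfileParams, dict]:
    """Solve the profile parameters for one isodose prescription.

    Returns ``(theta, residuals)`` where the residuals record how well the
    two planning constraints are met: ``d95_gy`` (DVH-based D95% of the PTV,
    target = prescription +- 0.1 Gy) and ``surface_fraction`` (profile value
    at the PTV radius over Dmax, target = isodose fraction +- 2 %).
    """
    from .metrics import cumulative_dvh, dose_at_volume

    spec = phantom.spec
    f = plan.isodose_fraction
    p = plan.penumbra_exponent
    margin = spec.ptv_radius_mm - spec.gtv_radius_mm
    if margin <= 0:
        raise CalibrationError("PTV radius must exceed the GTV radius")
    # Isodose constraint S(r_PTV) = f  =>  (margin / s)^p = 1/f - 1.
    s = margin / (1.0 / f - 1.0) ** (1.0 / p)

    ptv = phantom.masks["ptv"]
    dmax = plan.prescription_gy / f  # continuous-geometry first guess
    for _ in range(4):  # fixed-point refinement against the voxelized DVH
        theta = ProfileParams(dmax, s, p, spec.gtv_radius_mm)
        dose = phantom.grid(radial_profile(phantom.radius_mm, theta))
        d95 = dose_at_volume(cumulative_dvh(dose, ptv), PRESCRIPTION_VOLUME_PCT)
        dmax *= plan.prescription_gy / d95
    theta = ProfileParams(dmax, s, p, spec.gtv_radius_mm)
    dose = phantom.grid(radial_profile(phantom.radius_mm, theta))
    d95 = dose_at_volume(cumulative_dvh(dose, ptv), PRESCRIPTION_VOLUME_PCT)
    surface = float(radial_profile(spec.ptv_radius_mm, theta) / dmax)
    residuals = {
        "d95_gy": float(d95),
        "d95_error_gy": float(d95 - plan.prescription_gy),
        "surface_fraction": surface,
        "surface_error_rel": float(surface / f - 1.0),
        "gradient_at_ptv_gy_per_mm": float(profile_gradient(spec.ptv_radius_mm, theta)),
    }
    if abs(residuals["d95_error_gy"]) > 0.1 or abs(residuals["surface_error_rel"]) > 0.02:
        raise CalibrationError(
            f"no profile in the family satisfies the constraints for "
            f"f={f}: residuals {residuals}"
        )
    return theta, residuals


def synth_plan_dose(plan: PlanSpec, phantom: Phantom) -> SyntheticPlan:
    """Synthesize the calibrated static dose grid for one prescription."""
    theta, residuals = calibrate_profile(plan, phantom)
    dose = phantom.grid(radial_profile(phantom.radius_mm, theta))
    return SyntheticPlan(plan, theta, dose, phantom, residuals)
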