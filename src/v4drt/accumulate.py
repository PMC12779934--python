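"""Virtual-4D dose accumulation and phase-resolved interplay simulation.

The accumulated (v4DRT) dose is the phase-probability-weighted sum of the
static dose rigidly shifted into the tumor frame: when the patient moves by
``+z_i`` the dose seen by the tumor shifts by ``-z_i``, so

    D_acc = sum_i w_i * shift(D_static, -z_i, z-axis)

Rigid superior-inferior translation stands in for deformable dose warping;
the endpoint of the analysis (tumor-frame dose coverage) depends only on
the relative tumor-dose displacement, which the translation captures.  This
is the package's principal fidelity limitation and is documented as such.

Interplay is modelled by partitioning a delivery into time segments, each
depositing a fraction of the full static distribution at the instantaneous
breathing displacement — enough to exercise initial-phase sensitivity and
the gamma pipeline without aperture-resolved delivery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import VoxelGrid, VolumeError, shift_volume
from .motion import MotionModel, PhaseSet, displacement_at


@dataclass(frozen=True)
class DeliverySpec:
    """Time structure of one dynamic delivery.

    ``initial_phase_offset_rad`` shifts the breathing cycle relative to
    beam-on (the interplay comparison uses -pi/2 vs +pi/2); ``fractions``
    are per-segment dose fractions (uniform when omitted).
    """

    beam_on_time_s: float = 120.0
    segment_count: int = 90
    initial_phase_offset_rad: float = 0.0
    fractions: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.beam_on_time_s <= 0:
            raise ValueError("beam-on time must be > 0")
        if self.segment_count < 1:
            raise ValueError("segment count must be >= 1")
        if self.fractions is not None:
            fr = np.asarray(self.fractions, dtype=float)
            if fr.size != self.segment_count:
                raise ValueError("fractions length must equal segment count")
            if np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
                raise ValueError("fractions must be >= 0 and sum to 1")


def _weighted_shift_sum(static_dose: VoxelGrid, displacements, weights) -> VoxelGrid:
    z = np.asarray(displacements, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.all(z == 0.0):
        # Zero motion is an exact identity; skip the interpolation entirely
        # so the result is bitwise equal to the static dose.
        return static_dose.copy()
    acc = np.zeros_like(static_dose.values)
    for zi, wi in zip(z, w):
        acc += wi * shift_volume(static_dose, -zi, "z").values
    out = static_dose.copy()
    out.values = acc
    return out


def accumulate_v4drt(static_dose: VoxelGrid, phases: PhaseSet) -> VoxelGrid:
    """Phase-weighted accumulated dose on the static grid geometry.

    Equivalent to a discrete convolution of the static dose with the kernel
    ``{(-z_i, w_i)}`` along z, using the same tri-linear interpolation as
    ``shift_volume``.
    """
    if abs(float(np.sum(phases.weights)) - 1.0) > 1e-9:
        raise VolumeError("phase weights must sum to 1")
    return _weighted_shift_sum(static_dose, phases.displacements_mm, phases.weights)


def simulate_interplay(
    static_dose: VoxelGrid, delivery: DeliverySpec, motion: MotionModel
) -> VoxelGrid:
    """Phase-resolved delivery: per-segment deposition at the instantaneous
    breathing displacement.

    Segment ``k`` (k = 1..K) fires at ``t_k = (k / K) * beam_on_time`` with
    the breathing cycle advanced by the initial phase offset
    ``t0 = phi0 * tau / (2 pi)``; it deposits ``fraction_k`` of the full
    static distribution shifted by ``-z(t_k + t0)``.  With zero amplitude
    the result equals the static dose.
    """
    k = np.arange(1, delivery.segment_count + 1, dtype=float)
    t = k / delivery.segment_count * delivery.beam_on_time_s
    t0 = delivery.initial_phase_offset_rad * motion.period_s / (2.0 * np.pi)
    z = np.atleast_1d(displacement_at(motion, t + t0))
    if delivery.fractions is None:
        w = np.full(delivery.segment_count, 1.0 / delivery.segment_count)
    else:
        w = np.asarray(delivery.fractions, dtype=float)
    return _weighted_shift_sum(static_dose, z, w)
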