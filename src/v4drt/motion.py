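"""Parametric respiratory motion (Lujan-type trajectory) and its phase set.

The superior-inferior tumor trajectory is modelled as

    z(t) = z0 - b * cos^{2n}(pi * t / tau)

where ``z0`` is the exhale coordinate (mm), ``b`` the respiratory amplitude
(mm, the full peak-to-peak displacement span), ``tau`` the respiratory
period (s) and ``n >= 1`` an integer asymmetry parameter; larger ``n`` makes
the cycle dwell longer near exhale.  With ``n = 1`` the cycle is symmetric
and spans exactly ``[z0 - b, z0]``.

A breathing cycle is discretized into ``count`` phases at uniform time steps
``t_i = (i / count) * tau``.  Because the phases are defined at uniform time
steps, each phase has equal temporal occupancy and carries weight
``1 / count``; the non-uniform *positional* density of the trajectory
(concentrated near the end-exhale/end-inhale turning points) is carried by
the displacement values themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class MotionModel:
    """Respiratory trajectory parameters.

    amplitude_mm : peak-to-peak displacement span b (mm), >= 0
    period_s     : respiratory period tau (s), > 0
    exhale_mm    : exhale reference coordinate z0 (mm)
    n            : integer asymmetry exponent, >= 1 (1 = symmetric cycle)
    """

    amplitude_mm: float
    period_s: float = 4.0
    exhale_mm: float = 0.0
    n: int = 1

    def __post_init__(self) -> None:
        if self.amplitude_mm < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude_mm}")
        if self.period_s <= 0:
            raise ValueError(f"period must be > 0, got {self.period_s}")
        if int(self.n) != self.n or self.n < 1:
            raise ValueError(f"n must be an integer >= 1, got {self.n}")


def displacement_at(model: MotionModel, t) -> np.ndarray | float:
    """Trajectory position z(t) in mm; periodic with period tau.

    At ``t = 0`` the tumor sits at end-inhale ``z0 - b``; at ``t = tau/2``
    it returns to the exhale coordinate ``z0``.
    """
    t = np.asarray(t, dtype=float)
    c = np.cos(np.pi * t / model.period_s)
    z = model.exhale_mm - model.amplitude_mm * c ** (2 * int(model.n))
    return float(z) if z.ndim == 0 else z


@dataclass(frozen=True)
class PhaseSet:
    """Discrete respiratory phases: (time, displacement, weight) triples."""

    times_s: np.ndarray
    displacements_mm: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        z = np.asarray(self.displacements_mm, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if not (t.shape == z.shape == w.shape) or t.ndim != 1 or t.size < 1:
            raise ValueError("phases must be non-empty 1D arrays of equal length")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("phase weights must be non-negative and sum to 1")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "displacements_mm", z)
        object.__setattr__(self, "weights", w)

    @property
    def count(self) -> int:
        return self.times_s.size


def sample_phases(model: MotionModel, count: int = 10) -> PhaseSet:
    """Discretize one breathing cycle into ``count`` uniform-time phases.

    Phase times are ``t_i = (i / count) * tau`` for ``i = 1..count`` (the
    last phase closes the cycle at ``t = tau``), each with weight
    ``1 / count``.
    """
    if count < 1:
        raise ValueError(f"phase count must be >= 1, got {count}")
    i = np.arange(1, count + 1, dtype=float)
    times = i / count * model.period_s
    z = displacement_at(model, times)
    weights = np.full(count, 1.0 / count)
    return PhaseSet(times, np.atleast_1d(z), weights)
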