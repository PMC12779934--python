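from __future__ import annotations

import numpy as np
import pytest

from v4drt import PhantomSpec, PlanSpec, VoxelGrid, build_phantom, synth_plan_dose

ISODOSE_FRACTIONS = (0.6, 0.7, 0.8)


@pytest.fixture(scope="session")
def phantom():
    """Default digital phantom at the standard 2-mm grid."""
    return build_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def plans(phantom):
    """The three calibrated prescription isodose plans on the default phantom."""
    return {
        f: synth_plan_dose(PlanSpec(isodose_fraction=f), phantom)
        for f in ISODOSE_FRACTIONS
    }


@pytest.fixture(scope="session")
def small_phantom_spec():
    """A reduced phantom (same structure, smaller body/liver) for tests that
    sweep the full pipeline."""
    return PhantomSpec(
        gtv_center_mm=(0.0, 0.0, 0.0),
        liver_semiaxes_mm=(45.0, 40.0, 50.0),
        liver_center_mm=(0.0, 0.0, 0.0),
        body_semiaxes_mm=(60.0, 50.0),
        body_half_length_mm=60.0,
    )


def make_smooth_grid(shape=(64, 64, 64), spacing=(2.0, 2.0, 2.0), seed=0, pad_mm=None):
    """A smooth positive random dose field (sum of Gaussian blobs)."""
    rng = np.random.default_rng(seed)
    coords = [spacing[a] * (np.arange(shape[a]) - shape[a] / 2) for a in range(3)]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    values = np.full(shape, 0.5)
    for _ in range(4):
        cx, cy, cz = rng.uniform(-30, 30, size=3)
        amp = rng.uniform(10, 50)
        sig = rng.uniform(10, 30)
        values += amp * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2) / (2 * sig**2))
    origin = tuple(float(c[0]) for c in coords)
    return VoxelGrid(values, spacing, origin, pad_mm=pad_mm)
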