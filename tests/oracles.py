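"""Independent oracles used by the test suite.

Everything here is implemented from first principles (index arithmetic,
manual tri-linear interpolation, exhaustive search) and deliberately shares
no code with the package under test.
"""

from __future__ import annotations

import numpy as np


def shift_z_linear(values: np.ndarray, displacement_mm: float, spacing_z: float) -> np.ndarray:
    """Shift a field by +d mm along z: out[j] = in[j - d/h], linear
    interpolation with edge clamping, via explicit index arithmetic."""
    s = displacement_mm / spacing_z
    k = int(np.floor(s))
    frac = s - k
    nz = values.shape[2]
    j = np.arange(nz)
    j0 = np.clip(j - k, 0, nz - 1)
    j1 = np.clip(j - k - 1, 0, nz - 1)
    return (1.0 - frac) * values[..., j0] + frac * values[..., j1]


def convolve_phases(values: np.ndarray, spacing_z: float, displacements_mm, weights) -> np.ndarray:
    """Discrete convolution of a static field with the shift kernel
    {(-z_i, w_i)} along z (the accumulated-dose definition)."""
    out = np.zeros_like(values, dtype=float)
    for z, w in zip(displacements_mm, weights):
        out += w * shift_z_linear(values, -z, spacing_z)
    return out


def trilinear(values: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Clamped tri-linear interpolation at fractional index coordinates.

    ``coords``: (n, 3) array of (ix, iy, iz) index positions.
    """
    shape = np.asarray(values.shape)
    c = np.asarray(coords, dtype=float)
    lo = np.floor(c).astype(int)
    frac = c - lo
    out = np.zeros(c.shape[0])
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                corner = lo + np.array([dx, dy, dz])
                clamped = np.clip(corner, 0, shape - 1)
                w = (
                    np.where(dx, frac[:, 0], 1 - frac[:, 0])
                    * np.where(dy, frac[:, 1], 1 - frac[:, 1])
                    * np.where(dz, frac[:, 2], 1 - frac[:, 2])
                )
                out += w * values[clamped[:, 0], clamped[:, 1], clamped[:, 2]]
    return out


def gamma_brute_force(
    ref: np.ndarray,
    ev: np.ndarray,
    spacing,
    dose_criterion: float = 0.03,
    dta_mm: float = 3.0,
    low_dose_threshold: float = 0.10,
    search_factor: float = 3.0,
    step_divisor: int = 10,
    chunk: int = 20000,
) -> np.ndarray:
    """Exhaustive gamma search over every displacement candidate.

    Returns the gamma map (NaN below the dose threshold).  Candidates are
    integer multiples of voxel/step_divisor per axis within the search
    radius, identical to the convention the package documents.
    """
    spacing = np.asarray(spacing, dtype=float)
    dnorm = ref.max()
    dd = dose_criterion * dnorm
    radius = search_factor * dta_mm
    steps = spacing / step_divisor
    axes = [steps[a] * np.arange(-int(np.floor(radius / steps[a])),
                                 int(np.floor(radius / steps[a])) + 1)
            for a in range(3)]
    offs = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    dist = np.sqrt((offs ** 2).sum(axis=1))
    keep = dist <= radius + 1e-9
    offs, dist = offs[keep], dist[keep]
    dist_term = (dist / dta_mm) ** 2
    offs_idx = offs / spacing

    sel = ref >= low_dose_threshold * dnorm
    pts = np.argwhere(sel).astype(float)
    refv = ref[sel]
    gamma2 = np.full(refv.size, np.inf)
    for start in range(0, offs_idx.shape[0], chunk):
        block = offs_idx[start:start + chunk]
        dterm = dist_term[start:start + chunk]
        for i in range(pts.shape[0]):
            vals = trilinear(ev, pts[i][None, :] + block)
            g2 = ((vals - refv[i]) / dd) ** 2 + dterm
            gamma2[i] = min(gamma2[i], g2.min())
    gmap = np.full(ref.shape, np.nan)
    gmap[sel] = np.sqrt(gamma2)
    return gmap


def lujan_z(t, amplitude, period, n=1, z0=0.0):
    """Breathing trajectory written out independently."""
    return z0 - amplitude * np.cos(np.pi * np.asarray(t, float) / period) ** (2 * n)


def accumulated_profile_min(
    z_coords: np.ndarray,
    g: np.ndarray,
    gtv_z_centers: np.ndarray,
    amplitude: float,
    period: float = 4.0,
    phase_count: int = 10,
) -> float:
    """Exact accumulated minimum over a 1D-separable plan.

    The accumulated value at a point z is sum_i w_i * g_hat(z + z_i) with
    g_hat the edge-clamped linear interpolant of the dose samples; the
    minimum is taken over the GTV voxel centers.
    """
    t = np.arange(1, phase_count + 1) / phase_count * period
    zi = lujan_z(t, amplitude, period)
    acc = np.zeros_like(gtv_z_centers, dtype=float)
    for z in zi:
        q = np.clip(gtv_z_centers + z, z_coords[0], z_coords[-1])
        acc += np.interp(q, z_coords, g) / phase_count
    return float(acc.min())


def dca_fine_grid(
    z_coords, g, gtv_z_centers, d_crit, coarse_amplitudes,
    fine_step=0.1, period=4.0, phase_count=10,
) -> float:
    """Brute-force DCA: scan amplitudes at ``fine_step`` resolution, find the
    largest prefix that satisfies the criterion, round down to the coarse
    grid the module searches on."""
    coarse = np.asarray(coarse_amplitudes, dtype=float)
    fine = np.arange(fine_step, coarse[-1] + fine_step / 2, fine_step)
    passing = np.array([
        accumulated_profile_min(z_coords, g, gtv_z_centers, a, period, phase_count)
        >= d_crit - 1e-9
        for a in fine
    ])
    if passing.all():
        return float(coarse[-1])
    n_prefix = int(np.argmin(passing))
    if n_prefix == 0:
        return 0.0
    a_fine = fine[n_prefix - 1]
    feasible = coarse[coarse <= a_fine + 1e-9]
    return float(feasible[-1]) if feasible.size else 0.0
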