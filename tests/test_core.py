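"""Grid/mask primitives: shifts, dilations, shells and NRRD round trips."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from v4drt import (
    PaddingError, StructureMask, VolumeError, VolumeIOError, VoxelGrid,
    dilate_mask, read_mask, read_nrrd, shell_mask, shift_volume, write_nrrd,
)
from conftest import make_smooth_grid


def sphere_mask(radius_mm, spacing_mm, extent_mm, name="s"):
    xs = spacing_mm * np.arange(-int(extent_mm / spacing_mm), int(extent_mm / spacing_mm) + 1)
    X, Y, Z = np.meshgrid(xs, xs, xs, indexing="ij")
    mask = X**2 + Y**2 + Z**2 <= radius_mm**2
    return StructureMask(name, mask, (spacing_mm,) * 3, (xs[0],) * 3)


class TestShiftVolume:
    def test_zero_shift_is_identity(self):
        g = make_smooth_grid((16, 16, 16))
        out = shift_volume(g, 0.0, "z")
        assert np.array_equal(out.values, g.values)

    def test_one_voxel_shift_matches_index_arithmetic(self):
        g = make_smooth_grid((12, 12, 20), spacing=(2.0, 2.0, 2.0))
        out = shift_volume(g, 2.0, "z")
        # interior: out[..., j] must equal in[..., j-1] exactly
        np.testing.assert_allclose(out.values[..., 1:], g.values[..., :-1], atol=1e-12)

    def test_linear_field_shifts_by_closed_form(self):
        nz = 40
        zs = 2.0 * np.arange(nz)
        vals = np.broadcast_to(zs, (4, 4, nz)).copy()
        g = VoxelGrid(vals, (2.0, 2.0, 2.0))
        delta = 3.1
        out = shift_volume(g, delta, "z")
        interior = slice(4, nz - 4)
        expect = zs[interior] - delta  # out(p) = in(p - delta) = (z - delta)
        np.testing.assert_allclose(out.values[2, 2, interior], expect, atol=1e-9)

    def test_round_trip_inverts_on_interior(self):
        g = make_smooth_grid((16, 16, 32), seed=3)
        pad = 5
        # integer-voxel shifts invert exactly on the interior
        back = shift_volume(shift_volume(g, 6.0, "z"), -6.0, "z")
        np.testing.assert_allclose(
            back.values[..., pad:-pad], g.values[..., pad:-pad], atol=1e-12
        )
        # fractional shifts invert to within the tri-linear smoothing error,
        # bounded by the field's largest second difference along z
        back = shift_volume(shift_volume(g, 3.1, "z"), -3.1, "z")
        tol = float(np.abs(np.diff(g.values, 2, axis=2)).max()) / 2.0
        np.testing.assert_allclose(
            back.values[..., pad:-pad], g.values[..., pad:-pad], atol=tol
        )

    def test_padding_budget_enforced(self):
        g = make_smooth_grid((8, 8, 8), pad_mm=10.0)
        with pytest.raises(PaddingError, match="12"):
            shift_volume(g, 12.0, "z")
        shift_volume(g, 9.9, "z")  # within budget

    def test_invalid_axis_rejected(self):
        g = make_smooth_grid((4, 4, 4))
        with pytest.raises(VolumeError):
            shift_volume(g, 1.0, "q")


class TestDilation:
    def test_zero_distance_identity_and_negative_rejected(self):
        m = sphere_mask(5.0, 1.0, 10.0)
        assert np.array_equal(dilate_mask(m, 0.0).mask, m.mask)
        with pytest.raises(VolumeError):
            dilate_mask(m, -1.0)

    def test_empty_mask_stays_empty(self):
        m = StructureMask("e", np.zeros((5, 5, 5), bool), (1.0, 1.0, 1.0))
        assert dilate_mask(m, 10.0).voxel_count == 0

    def test_sphere_dilation_volume_analytic(self):
        m = sphere_mask(5.0, 1.0, 20.0)
        d = dilate_mask(m, 10.0)
        expected = 4.0 / 3.0 * np.pi * 15.0**3
        assert d.volume_mm3 == pytest.approx(expected, rel=0.05)

    @given(st.floats(0.0, 6.0), st.floats(0.0, 6.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_dilation_monotone_in_distance(self, d1, d2):
        m = sphere_mask(3.0, 1.5, 12.0)
        lo, hi = sorted((d1, d2))
        assert not np.any(dilate_mask(m, lo).mask & ~dilate_mask(m, hi).mask)


class TestShellMask:
    def test_analytic_shell_volume(self):
        m = sphere_mask(15.0, 1.0, 30.0)
        sh = shell_mask(m, 5.0, 10.0)
        expected = 4.0 / 3.0 * np.pi * (25.0**3 - 20.0**3)
        assert sh.volume_mm3 == pytest.approx(expected, rel=0.05)

    def test_shells_partition_and_disjoint_from_source(self):
        m = sphere_mask(6.0, 2.0, 20.0)
        a = shell_mask(m, 0.0, 5.0)
        b = shell_mask(m, 5.0, 10.0)
        full = shell_mask(m, 0.0, 10.0)
        assert not np.any(a.mask & b.mask)
        assert np.array_equal(a.mask | b.mask, full.mask)
        assert not np.any(full.mask & m.mask)

    def test_degenerate_width_may_be_empty_without_error(self):
        m = sphere_mask(4.0, 2.0, 12.0)
        sh = shell_mask(m, 4.9, 5.0)  # thinner than the voxel on a coarse grid
        assert sh.voxel_count >= 0  # returned, no exception

    def test_invalid_bounds_rejected(self):
        m = sphere_mask(4.0, 2.0, 12.0)
        with pytest.raises(VolumeError):
            shell_mask(m, 5.0, 5.0)


class TestVolumeIO:
    def test_grid_round_trip_bitwise(self, tmp_path):
        g = make_smooth_grid((9, 7, 11), spacing=(1.5, 2.0, 2.5), seed=5)
        path = write_nrrd(tmp_path / "g.nrrd", g)
        back = read_nrrd(path)
        assert np.array_equal(back.values, g.values)
        assert back.spacing == pytest.approx(g.spacing)
        assert back.origin == pytest.approx(g.origin)

    def test_mask_round_trip_preserves_invariants(self, tmp_path):
        m = sphere_mask(4.0, 2.0, 10.0, name="gtv")
        path = write_nrrd(tmp_path / "m.nrrd", m)
        back = read_mask(path, "gtv")
        assert np.array_equal(back.mask, m.mask)
        assert back.volume_mm3 == m.volume_mm3

    def test_wrong_dimension_count_raises_typed_error(self, tmp_path):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.zeros((6, 6)))  # 2D volume
        sitk.WriteImage(img, str(tmp_path / "flat.nrrd"))
        with pytest.raises(VolumeIOError, match="3D"):
            read_nrrd(tmp_path / "flat.nrrd")

    def test_nan_values_rejected_on_write(self, tmp_path):
        vals = np.ones((4, 4, 4))
        vals[0, 0, 0] = np.nan
        g = VoxelGrid.__new__(VoxelGrid)  # bypass constructor finiteness check
        g.values, g.spacing, g.origin, g.pad_mm = vals, (1.0, 1.0, 1.0), (0.0, 0.0, 0.0), None
        with pytest.raises(VolumeIOError, match="finite"):
            write_nrrd(tmp_path / "bad.nrrd", g)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(VolumeIOError):
            read_nrrd(tmp_path / "nope.nrrd")


def test_structure_volume_is_exact_count_times_voxel_volume():
    m = sphere_mask(5.0, 2.0, 10.0)
    assert m.volume_mm3 == m.voxel_count * 8.0
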