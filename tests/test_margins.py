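"""DCA search, plan selection and Optimal Margin arithmetic."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from v4drt import (
    DCAResult, OARMetrics, StructureMask, VolumeError, VoxelGrid,
    average_dose_tolerance, compute_om, dca_from_curve, dca_margin_ratio,
    dca_search, select_optimal_plan,
)


def separable_plan(dmax=50.0, scale=15.0, spacing=2.0, nz=101, pad=None):
    """A 1D-separable dose grid D(x,y,z) = g(z) plus a box GTV."""
    zs = spacing * (np.arange(nz) - nz // 2)
    g = dmax / (1.0 + (np.abs(zs) / scale) ** 3)
    vals = np.broadcast_to(g, (5, 5, nz)).copy()
    grid = VoxelGrid(vals, (spacing, spacing, spacing), (0.0, 0.0, float(zs[0])), pad_mm=pad)
    mask = np.zeros((5, 5, nz), bool)
    mask[1:4, 1:4, np.abs(zs) <= 4.0] = True
    return grid, StructureMask("gtv", mask, grid.spacing, grid.origin), zs, g


class TestDCASearch:
    def test_flat_plan_never_fails_and_clamps(self):
        grid, gtv, _, _ = separable_plan(dmax=50.0, scale=500.0)
        res = dca_search(grid, gtv, "D100", d_crit_gy=40.0)
        assert res.dca_mm == 24.0
        assert res.clamped

    def test_d_crit_above_static_coverage_gives_zero(self):
        grid, gtv, _, _ = separable_plan()
        res = dca_search(grid, gtv, "D100", d_crit_gy=60.0)
        assert res.dca_mm == 0.0
        assert not res.clamped

    @pytest.mark.parametrize("d_crit", [20.0, 25.0, 30.0, 35.0, 40.0])
    def test_matches_fine_grid_brute_force(self, d_crit):
        grid, gtv, zs, g = separable_plan()
        res = dca_search(grid, gtv, "D100", d_crit_gy=d_crit)
        gtv_z = zs[np.abs(zs) <= 4.0]
        expected = oracles.dca_fine_grid(zs, g, gtv_z, d_crit, res.amplitudes_mm)
        assert res.dca_mm == expected

    def test_empty_amplitude_list_rejected(self):
        grid, gtv, _, _ = separable_plan()
        with pytest.raises(VolumeError):
            dca_search(grid, gtv, "D100", d_crit_gy=40.0, amplitudes_mm=[])

    def test_prefix_rule_recovers_max_on_monotone_curves(self):
        amps = np.arange(1.0, 11.0)
        metric = np.linspace(50, 30, 10)  # strictly decreasing
        d_crit = 41.0
        dca, clamped = dca_from_curve(amps, metric, d_crit)
        unrestricted = amps[metric >= d_crit].max()
        assert dca == unrestricted and not clamped


class TestAverageDoseTolerance:
    def test_zero_amplitude_trivially_satisfies_own_reference(self):
        grid, gtv, _, _ = separable_plan()
        static_mean = grid.values[gtv.mask].mean()
        tol = average_dose_tolerance(grid, gtv, static_mean, amplitudes_mm=[0.0])
        assert tol == 0.0  # satisfied at rest; no positive amplitude demanded

    def test_lower_isodose_plan_tolerates_more_motion(self, plans, phantom):
        gtv = phantom.masks["gtv"]
        ref = float(plans[0.8].dose.values[gtv.mask].mean())
        tol = {
            f: average_dose_tolerance(plans[f], gtv, ref) for f in (0.6, 0.7)
        }
        assert tol[0.6] > tol[0.7]

    def test_reference_above_dmax_gives_zero(self):
        grid, gtv, _, _ = separable_plan(dmax=50.0)
        assert average_dose_tolerance(grid, gtv, 60.0) == 0.0


def _mock_inputs(dca, tol, oar_tables, ref_mean=48.0):
    amps = np.arange(1.0, 25.0)
    dca_by_plan = {
        f: DCAResult(f, "D100", 40.0, amps, np.full(24, 50.0), d, d >= 24.0)
        for f, d in dca.items()
    }
    return dca_by_plan, tol, oar_tables, ref_mean


def _oar(shells, v5, v20):
    return OARMetrics(dict(zip((0.5, 1.0, 2.0), shells)), v5, v20)


class TestSelectOptimalPlan:
    def test_dominant_low_isodose_plan_selected(self):
        oar = {
            0.6: {0.0: _oar((30, 20, 10), 1.0, 8.0), 15.0: _oar((28, 18, 9), 1.2, 8.5)},
            0.7: {0.0: _oar((35, 25, 15), 1.5, 9.0), 15.0: _oar((33, 23, 13), 1.6, 9.2)},
            0.8: {0.0: _oar((40, 30, 20), 2.0, 9.5), 15.0: _oar((38, 28, 18), 2.1, 9.6)},
        }
        args = _mock_inputs({0.6: 20.0, 0.7: 18.0, 0.8: 15.0},
                            {0.6: 19.0, 0.7: 16.0, 0.8: 15.0}, oar)
        cmp = select_optimal_plan(*args)
        assert cmp.selected_fraction == 0.6
        assert cmp.qualifying_amplitude_by_plan[0.6] == 15.0  # capped by DCA80

    def test_only_reference_plan_qualifies(self):
        # lower plans blow the OAR budget at their qualifying amplitudes
        hot = _oar((99, 99, 99), 50.0, 50.0)
        oar = {
            0.6: {0.0: hot, 10.0: hot},
            0.7: {0.0: hot, 10.0: hot},
            0.8: {0.0: _oar((40, 30, 20), 2.0, 9.5), 10.0: _oar((40, 30, 20), 2.0, 9.5)},
        }
        args = _mock_inputs({0.6: 12.0, 0.7: 12.0, 0.8: 10.0},
                            {0.6: 12.0, 0.7: 12.0, 0.8: 10.0}, oar)
        cmp = select_optimal_plan(*args)
        assert cmp.selected_fraction == 0.8

    def test_no_qualifying_plan_reported_not_raised(self):
        hot = _oar((99, 99, 99), 50.0, 50.0)
        oar = {f: {0.0: _oar((1, 1, 1), 0.1, 0.1) if f == 0.8 else hot, 10.0: hot}
               for f in (0.6, 0.7, 0.8)}
        args = _mock_inputs({0.6: 12.0, 0.7: 12.0, 0.8: 10.0},
                            {0.6: 12.0, 0.7: 12.0, 0.8: 10.0}, oar)
        cmp = select_optimal_plan(*args)
        assert cmp.selected_fraction is None
        assert cmp.dca_opt_mm is None


class TestComputeOM:
    def test_worked_example_values(self):
        res = compute_om(10.0, 18.0, 10.0)
        assert res.om_mm == pytest.approx(10.0 / 18.0 * 10.0)
        assert res.om_mm_reported == 5.6
        assert res.reduction_pct_reported == 44

    def test_equal_margin_and_dca_returns_displacement(self):
        for m in (5.0, 10.0, 17.0):
            assert compute_om(m, m, 12.5).om_mm == pytest.approx(12.5)

    def test_simple_arithmetic_case(self):
        assert compute_om(10.0, 20.0, 12.0).om_mm == pytest.approx(6.0)

    @given(st.floats(1.0, 30.0), st.floats(1.0, 30.0), st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_homogeneity_in_displacement_and_dca(self, margin, dca, k):
        base = compute_om(margin, dca, 8.0).om_mm
        assert compute_om(margin, dca, 8.0 * k).om_mm == pytest.approx(k * base)
        assert compute_om(margin, dca * k, 8.0).om_mm == pytest.approx(base / k)

    def test_non_positive_inputs_rejected(self):
        for bad in ((0.0, 18.0, 10.0), (10.0, 0.0, 10.0), (10.0, 18.0, -1.0)):
            with pytest.raises(VolumeError):
                compute_om(*bad)


def test_dca_margin_ratio_reports_motion_tolerance_factor():
    assert round(dca_margin_ratio(22.0, 10.0), 1) == 2.2
    assert round(dca_margin_ratio(19.0, 10.0), 1) == 1.9
    with pytest.raises(VolumeError):
        dca_margin_ratio(18.0, 0.0)
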