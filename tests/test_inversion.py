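"""Lookup-table construction, absorption scaling, IRF handling, fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phantomqc.datatypes import C0_CM_PER_PS, DTOF, IRF, RandomStream, SlabGeometry
from phantomqc.inversion import (
    FitConfig,
    apply_absorption,
    build_lut,
    convolve_irf,
    fit_dtof,
    select_fit_range,
)


def _as_measured(dtof, total=1e6):
    return dtof.replace_values(dtof.values * total / dtof.values.sum(), kind="measured")


class TestBuildLut:
    def test_default_grid_has_200_entries(self, diffusion_lut):
        assert len(diffusion_lut.mu_sp_grid) == 200
        assert diffusion_lut.mu_sp_grid[0] == pytest.approx(0.1)
        assert diffusion_lut.mu_sp_grid[-1] == pytest.approx(20.0)

    def test_degenerate_single_entry_grid_is_usable(self, slab_geom, irf35):
        lut = build_lut(10.0, 10.0, 0.1, slab_geom, engine="diffusion")
        assert len(lut.mu_sp_grid) == 1
        measured = _as_measured(convolve_irf(apply_absorption(lut.dtofs[0], 0.05), irf35))
        fit = fit_dtof(measured, lut, irf35)
        assert fit.mu_sp == pytest.approx(10.0)
        assert fit.mu_a == pytest.approx(0.05, abs=1e-3)
        assert not fit.converged  # boundary of a 1-node grid

    def test_mc_lut_rebuild_is_deterministic(self, slab_geom):
        kwargs = dict(
            geom=slab_geom, n_photons=5000, bin_width_ps=20.0, t_max_ps=4000.0,
            stream=RandomStream(11), engine="mc",
        )
        a = build_lut(9.0, 9.2, 0.1, **kwargs)
        b = build_lut(9.0, 9.2, 0.1, **kwargs)
        for da, db in zip(a.dtofs, b.dtofs):
            assert np.array_equal(da.values, db.values)

    def test_invalid_grid_rejected(self, slab_geom):
        with pytest.raises(ValueError):
            build_lut(0.0, 20.0, 0.1, slab_geom, engine="diffusion")
        with pytest.raises(ValueError):
            build_lut(5.0, 20.0, -0.1, slab_geom, engine="diffusion")


class TestApplyAbsorption:
    def test_zero_absorption_is_identity(self, diffusion_lut):
        white = diffusion_lut.dtofs[50]
        out = apply_absorption(white, 0.0)
        np.testing.assert_array_equal(out.values, white.values)
        assert out.kind == "absorbing"

    def test_single_bin_multiplier_closed_form(self):
        # bin centred at 1000 ps, mu_a = 0.1 1/cm, n = 1.54
        edges = np.array([995.0, 1005.0])
        white = DTOF(bin_edges_ps=edges, values=np.array([1.0]), kind="white")
        out = apply_absorption(white, 0.1, n_in=1.54)
        expected = math.exp(-0.1 * (C0_CM_PER_PS / 1.54) * 1000.0)
        assert out.values[0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.1428, abs=2e-4)

    def test_exponential_semigroup(self, diffusion_lut):
        white = diffusion_lut.dtofs[90]
        once = apply_absorption(white, 0.2)
        half = apply_absorption(white, 0.1)
        c_m = C0_CM_PER_PS / 1.54
        twice = half.values * np.exp(-0.1 * c_m * white.bin_centers_ps)
        np.testing.assert_allclose(once.values, twice, rtol=1e-12)

    def test_double_attenuation_rejected(self, diffusion_lut):
        absorbed = apply_absorption(diffusion_lut.dtofs[0], 0.1)
        with pytest.raises(ValueError):
            apply_absorption(absorbed, 0.1)

    def test_log_integral_affine_in_mu_a(self, diffusion_lut):
        # slope of ln(integral) vs mu_a equals -cM * <t> of the white DTOF
        white = diffusion_lut.dtofs[94]
        c_m = C0_CM_PER_PS / 1.54
        t_mean = np.sum(white.bin_centers_ps * white.values) / white.total
        h = 1e-5
        lo = math.log(apply_absorption(white, 0.1 - h).total)
        hi = math.log(apply_absorption(white, 0.1 + h).total)
        slope = (hi - lo) / (2 * h)
        # <t> of the absorbed curve at mu_a = 0.1, not of the white curve
        absorbed = apply_absorption(white, 0.1)
        t_mean_abs = np.sum(absorbed.bin_centers_ps * absorbed.values) / absorbed.total
        assert slope == pytest.approx(-c_m * t_mean_abs, rel=1e-6)
        assert -c_m * t_mean < slope < 0  # absorption shortens <t>


class TestConvolveIRF:
    def test_delta_irf_is_identity(self, diffusion_lut):
        d = diffusion_lut.dtofs[100]
        out = convolve_irf(d, IRF.delta())
        np.testing.assert_array_equal(out.values, d.values)

    def test_single_bin_becomes_gaussian_of_irf_width(self):
        edges = np.arange(0.0, 2001.0, 10.0)
        values = np.zeros(len(edges) - 1)
        values[100] = 1.0
        d = DTOF(bin_edges_ps=edges, values=values, kind="white")
        out = convolve_irf(d, IRF.gaussian(35.0))
        assert int(np.argmax(out.values)) == 100
        # FWHM of the result ~ 35 ps
        half = out.values.max() / 2
        above = np.nonzero(out.values >= half)[0]
        fwhm = (above[-1] - above[0] + 1) * 10.0
        assert abs(fwhm - 35.0) <= 10.0  # one bin width of slack

    def test_total_weight_conserved(self, diffusion_lut, irf35):
        # weight leaving the time axis is accounted for in meta
        d = diffusion_lut.dtofs[80]
        out = convolve_irf(d, irf35)
        lost = out.meta.get("edge_loss", 0.0)
        assert out.total + lost == pytest.approx(d.total, rel=1e-9)

    def test_contained_pulse_conserves_exactly(self):
        edges = np.arange(0.0, 2001.0, 10.0)
        values = np.zeros(len(edges) - 1)
        values[80:120] = np.hanning(40)
        d = DTOF(bin_edges_ps=edges, values=values, kind="white")
        out = convolve_irf(d, IRF.gaussian(35.0))
        assert out.total == pytest.approx(d.total, rel=1e-9)
        assert "edge_loss" not in out.meta


class TestSelectFitRange:
    def test_window_matches_brute_force_threshold_scan(self):
        # triangular pulse: oracle = exhaustive scan over bins
        edges = np.arange(0.0, 1010.0, 10.0)
        values = np.concatenate([np.arange(1, 51), np.arange(50, 0, -1)]).astype(float)
        d = DTOF(bin_edges_ps=edges, values=values, kind="measured")
        cfg = FitConfig(rise_fraction=0.8, tail_fraction=0.01)
        start, stop = select_fit_range(d, cfg)
        peak_idx = int(np.argmax(values))
        peak = values.max()
        brute_start = max(
            i for i in range(peak_idx + 1) if values[i] <= 0.8 * peak
        )
        brute_stop = min(
            (j for j in range(peak_idx, len(values)) if values[j] <= 0.01 * peak),
            default=len(values) - 1,
        ) + 1
        assert (start, stop) == (brute_start, brute_stop)
        assert start < peak_idx < stop

    def test_full_window_limits(self):
        edges = np.arange(0.0, 110.0, 10.0)
        values = np.array([0, 1, 5, 10, 6, 3, 1, 0.5, 0, 0], dtype=float)
        d = DTOF(bin_edges_ps=edges, values=values, kind="measured")
        start, stop = select_fit_range(d, FitConfig(rise_fraction=1.0, tail_fraction=1e-9))
        assert start == 3  # peak bin
        assert stop >= 9  # through the last nonzero bin

    def test_all_zero_dtof_rejected(self):
        edges = np.arange(0.0, 110.0, 10.0)
        d = DTOF(bin_edges_ps=edges, values=np.zeros(10), kind="measured")
        with pytest.raises(ValueError):
            select_fit_range(d)


class TestFitDtof:
    def test_noise_free_self_consistency(self, diffusion_lut, irf35):
        k = int(np.argmin(np.abs(diffusion_lut.mu_sp_grid - 9.5)))
        model = convolve_irf(apply_absorption(diffusion_lut.dtofs[k], 0.08), irf35)
        fit = fit_dtof(_as_measured(model), diffusion_lut, irf35)
        assert fit.converged
        assert fit.mu_sp == pytest.approx(9.5, abs=0.05)
        assert fit.mu_a == pytest.approx(0.08, abs=0.001)

    def test_white_entry_recovers_zero_absorption(self, diffusion_lut):
        k = int(np.argmin(np.abs(diffusion_lut.mu_sp_grid - 9.5)))
        fit = fit_dtof(_as_measured(diffusion_lut.dtofs[k]), diffusion_lut, IRF.delta())
        assert fit.mu_a == pytest.approx(0.0, abs=0.001)

    def test_scale_equivariance(self, narrow_lut, irf35):
        k = 10
        model = convolve_irf(apply_absorption(narrow_lut.dtofs[k], 0.07), irf35)
        m1 = _as_measured(model, 1e6)
        m2 = m1.replace_values(m1.values * 3.0)
        f1 = fit_dtof(m1, narrow_lut, irf35)
        f2 = fit_dtof(m2, narrow_lut, irf35)
        assert f2.mu_sp == pytest.approx(f1.mu_sp, abs=1e-9)
        assert f2.mu_a == pytest.approx(f1.mu_a, abs=1e-9)
        assert f2.amplitude == pytest.approx(3.0 * f1.amplitude, rel=1e-6)

    def test_chi2_profile_locally_convex_at_optimum(self, narrow_lut, irf35):
        from phantomqc.inversion import _chi2_at_node

        k = 15
        model = convolve_irf(apply_absorption(narrow_lut.dtofs[k], 0.08), irf35)
        measured = _as_measured(model)
        data = measured.values
        weights = 1.0 / np.maximum(data, 1.0)
        window = select_fit_range(measured, FitConfig())
        chi2 = [
            _chi2_at_node(data, weights, narrow_lut.dtofs[j], irf35, FitConfig(), window, 1.54)[0]
            for j in (k - 1, k, k + 1)
        ]
        assert chi2[1] < chi2[0] and chi2[1] < chi2[2]

    def test_coarser_lut_changes_little(self, narrow_lut, irf35):
        k = 15
        model = convolve_irf(apply_absorption(narrow_lut.dtofs[k], 0.08), irf35)
        measured = _as_measured(model)
        fine = fit_dtof(measured, narrow_lut, irf35)
        coarse = fit_dtof(measured, narrow_lut.rebin(2), irf35)
        assert abs(coarse.mu_sp - fine.mu_sp) < 0.1
        assert abs(coarse.mu_a - fine.mu_a) < 0.0025

    def test_low_count_warning(self, narrow_lut, irf35):
        model = convolve_irf(apply_absorption(narrow_lut.dtofs[5], 0.08), irf35)
        fit = fit_dtof(_as_measured(model, total=500), narrow_lut, irf35)
        assert fit.low_counts

    def test_boundary_optimum_not_converged(self, slab_geom, irf35):
        lut = build_lut(12.0, 14.0, 0.5, slab_geom, engine="diffusion")
        # truth far below the grid: optimum pinned at the boundary
        from phantomqc.transport import diffusion_slab_dtof
        from phantomqc.datatypes import OpticalProperties

        truth = diffusion_slab_dtof(OpticalProperties(mu_a=0.08, mu_sp=9.0), slab_geom)
        measured = _as_measured(convolve_irf(truth.replace_values(truth.values, kind="white"), irf35))
        fit = fit_dtof(measured, lut, irf35)
        assert not fit.converged

    @settings(max_examples=12, deadline=None)
    @given(st.floats(8.3, 10.7))
    def test_off_grid_truth_recovered_by_interpolation(self, mu_sp_true):
        # built fresh: hypothesis may not reuse session fixtures safely
        geom = SlabGeometry(thickness_cm=2.0, detector_radius_cm=np.inf)
        lut = _cached_lut(geom)
        from phantomqc.transport import diffusion_slab_dtof
        from phantomqc.datatypes import OpticalProperties

        truth = diffusion_slab_dtof(
            OpticalProperties(mu_a=0.08, mu_sp=mu_sp_true, n_in=1.54), geom
        )
        irf = IRF.gaussian(35.0)
        measured = _as_measured(
            convolve_irf(truth.replace_values(truth.values, kind="white"), irf)
        )
        fit = fit_dtof(measured, lut, irf)
        assert fit.mu_sp == pytest.approx(mu_sp_true, abs=0.05)
        assert fit.mu_a == pytest.approx(0.08, abs=0.002)


_LUT_CACHE = {}


def _cached_lut(geom):
    if "lut" not in _LUT_CACHE:
        _LUT_CACHE["lut"] = build_lut(8.0, 11.0, 0.1, geom, engine="diffusion")
    return _LUT_CACHE["lut"]
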