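"""Generators: truth round trips and programmed realism features."""

import numpy as np
import pytest

from phantomqc.datatypes import C0_CM_PER_PS, RandomStream
from phantomqc.imaging_qc import ROISpec, normalize_series, series_intensity
from phantomqc.inversion import FitConfig, fit_dtof
from phantomqc.spectra import linearity_onset, peak_wavelength
from phantomqc.synthetic import (
    ImagerModel,
    default_truth,
    gen_dtof,
    gen_dye_spectra,
    gen_image_series,
    gen_scan,
    icg,
    lumogen,
)


class TestGenDtof:
    def test_truth_recovered_by_fit(self, narrow_lut, irf35):
        truth = default_truth(mu_sp=9.5, mu_a=0.08)
        dtof, record = gen_dtof(truth, 800.0, irf35, 1e6, RandomStream(21))
        fit = fit_dtof(dtof, narrow_lut, irf35)
        assert fit.mu_sp == pytest.approx(record["mu_sp"], abs=0.2)
        assert fit.mu_a == pytest.approx(record["mu_a"], abs=0.005)

    def test_infinite_count_mode_is_deterministic(self, irf35):
        truth = default_truth()
        a, _ = gen_dtof(truth, 800.0, irf35, 1e6, RandomStream(1), poisson=False)
        b, _ = gen_dtof(truth, 800.0, irf35, 1e6, RandomStream(999), poisson=False)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.values.sum() == pytest.approx(1e6, rel=1e-12)

    def test_different_seeds_give_different_noise(self, irf35):
        truth = default_truth()
        a, _ = gen_dtof(truth, 800.0, irf35, 1e5, RandomStream(1))
        b, _ = gen_dtof(truth, 800.0, irf35, 1e5, RandomStream(2))
        assert not np.array_equal(a.values, b.values)

    def test_absorption_factorizes_up_to_normalization(self, irf35):
        # before IRF blur and renormalization, changing mu_a only
        # rescales by exp(-mu_a * c_medium * t); after per-curve count
        # normalization the two infinite-count curves must therefore be
        # proportional to a known time-dependent factor
        t_lo = default_truth(mu_a=0.05)
        t_hi = default_truth(mu_a=0.10)
        lo, _ = gen_dtof(t_lo, 800.0, irf35.delta(), 1e6, RandomStream(0), poisson=False)
        hi, _ = gen_dtof(t_hi, 800.0, irf35.delta(), 1e6, RandomStream(0), poisson=False)
        c_m = C0_CM_PER_PS / 1.54
        factor = np.exp(-0.05 * c_m * lo.bin_centers_ps)
        scaled = lo.values * factor
        scaled *= hi.values.sum() / scaled.sum()
        nz = hi.values > 1e-9 * hi.values.max()
        np.testing.assert_allclose(hi.values[nz], scaled[nz], rtol=1e-9)

    def test_unknown_wavelength_rejected(self, irf35):
        with pytest.raises(KeyError):
            gen_dtof(default_truth(), 632.8, irf35)


class TestGenScan:
    def test_anomaly_outside_outline_rejected(self):
        with pytest.raises(ValueError):
            gen_scan(
                default_truth(),
                outline_radius_mm=40.0,
                anomalies=[((50.0, 0.0), 0.07)],
            )

    def test_truth_field_marks_anomaly_cells(self):
        scan, record = gen_scan(
            default_truth(),
            step_mm=5.0,
            anomalies=[((10.0, 10.0), 0.07)],
            noise_rel=0.0,
            stream=RandomStream(3),
        )
        field = record["truth_field"]
        assert field[(10.0, 10.0)] == pytest.approx(1.07)
        assert field[(0.0, 0.0)] == pytest.approx(1.0)

    def test_noise_free_uniform_scan_has_equal_central_cells(self):
        scan, _ = gen_scan(
            default_truth(), noise_rel=0.0, stream=RandomStream(5)
        )
        central = [
            d["excitation"].values.sum()
            for (x, y), d in scan.data.items()
            if np.hypot(x, y) <= 20.0
        ]
        assert np.ptp(central) / np.mean(central) < 1e-12

    def test_edge_rolloff_attenuates_rim(self):
        scan, _ = gen_scan(
            default_truth(), noise_rel=0.0, edge_rolloff_mm=10.0,
            stream=RandomStream(5),
        )
        centre = scan.data[(0.0, 0.0)]["excitation"].values.sum()
        rim = scan.data[(40.0, 0.0)]["excitation"].values.sum()
        assert rim < 0.5 * centre

    def test_invalid_modulation_target_rejected(self):
        with pytest.raises(ValueError):
            gen_scan(default_truth(), modulate="mu_a")


class TestGenImageSeries:
    def test_overlapping_regions_rejected(self):
        t = default_truth()
        with pytest.raises(ValueError):
            gen_image_series(
                [(t, (10, 10, 30, 30)), (t, (25, 25, 30, 30))], n_frames=5
            )

    def test_region_outside_frame_rejected(self):
        with pytest.raises(ValueError):
            gen_image_series([(default_truth(), (110, 10, 30, 30))], n_frames=5)

    def test_quiet_imager_and_stable_dye_give_constant_roi(self):
        imager = ImagerModel(frame_noise_rel=0.0, warmup_amplitude=0.0, noise_floor=0.0)
        series, _ = gen_image_series(
            [(default_truth(), (50, 30, 30, 30))],
            imager=imager,
            n_frames=20,
            stream=RandomStream(8),
        )
        roi = ROISpec(x0=50, y0=30, width=30, height=30)
        norm = normalize_series(series_intensity(series, roi))
        assert np.ptp(norm) < 1e-9

    def test_icg_series_decays_lumogen_does_not(self):
        imager = ImagerModel(frame_noise_rel=0.0, warmup_amplitude=0.0, noise_floor=0.0)
        t_icg = default_truth()
        t_icg = type(t_icg)(props=t_icg.props, dye=icg(), concentration=1.5)
        series, truth = gen_image_series(
            [(t_icg, (50, 30, 30, 30)), (default_truth(), (10, 30, 30, 30))],
            imager=imager,
            n_frames=100,
            stream=RandomStream(8),
        )
        icg_roi = series_intensity(series, ROISpec(50, 30, 30, 30))
        lum_roi = series_intensity(series, ROISpec(10, 30, 30, 30))
        drop = 1.0 - icg_roi[-1] / icg_roi[0]
        # dark storage decay also runs over the ~80 s acquisition (~3e-6)
        assert drop == pytest.approx(
            truth["phantoms"][0]["programmed_drop_percent"] / 100.0, abs=1e-4
        )
        assert abs(1.0 - lum_roi[-1] / lum_roi[0]) < 1e-9

    def test_daylight_storage_decays_faster_than_dark(self):
        imager = ImagerModel(frame_noise_rel=0.0, warmup_amplitude=0.0, noise_floor=0.0)
        t_icg = default_truth()
        t_icg = type(t_icg)(props=t_icg.props, dye=icg(), concentration=1.5)
        month_s = 30.0 * 86400.0
        ts = np.array([0.0, month_s])
        roi = ROISpec(50, 30, 30, 30)

        def end_ratio(storage):
            series, _ = gen_image_series(
                [(t_icg, (50, 30, 30, 30))],
                imager=imager,
                n_frames=2,
                timestamps_s=ts,
                stream=RandomStream(8),
                storage=storage,
            )
            vals = series_intensity(series, roi)
            return vals[1] / vals[0]

        dark, light = end_ratio("dark"), end_ratio("daylight")
        # one bleaching frame elapses in both; divide it out
        bleach = np.exp(-icg().bleach_rate_per_frame)
        assert dark / bleach == pytest.approx(0.90, rel=1e-9)
        assert light / bleach == pytest.approx(0.70, rel=1e-9)


class TestGenDyeSpectra:
    def test_red_shift_nondecreasing_with_concentration(self):
        series, _ = gen_dye_spectra(lumogen(), noise_rel=0.0)
        peaks = [peak_wavelength(s).wavelength_nm for s in series.spectra]
        assert all(b >= a for a, b in zip(peaks, peaks[1:]))
        assert peaks[-1] - peaks[0] > 5.0

    def test_low_concentration_limit_is_linear(self):
        series, _ = gen_dye_spectra(
            lumogen(), concentrations=(0.01, 0.02), noise_rel=0.0
        )
        ratio = series.intensities[1] / series.intensities[0]
        assert ratio == pytest.approx(2.0, rel=0.01)

    def test_linearity_onset_at_design_concentration(self):
        series, _ = gen_dye_spectra(lumogen(), noise_rel=0.0)
        result = linearity_onset(series)
        assert result.onset == pytest.approx(1.5)

    def test_sublinear_at_high_concentration(self):
        series, _ = gen_dye_spectra(lumogen(), noise_rel=0.0)
        c, y = series.concentrations, series.intensities
        assert y[-1] / y[0] < c[-1] / c[0]

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            gen_dye_spectra(lumogen(), concentrations=(0.0, 1.0))
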