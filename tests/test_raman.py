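"""Background subtraction, peak-ratio measurement, and the two calibrations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phasorquant import raman as rq
from phasorquant import synthetic as syn


def _gaussian_spec(center, height, sigma=10.0, extra=None):
    wn = syn.default_fingerprint_wavenumbers()
    y = height * np.exp(-((wn - center) ** 2) / (2 * sigma**2))
    if extra is not None:
        y = y + extra(wn)
    return rq.RamanSpectrum(wavenumbers=wn, intensity=y)


class TestSubtractBackground:
    def test_construct_and_invert(self):
        wn = syn.default_fingerprint_wavenumbers()
        signal = np.exp(-((wn - 1654.0) ** 2) / 200.0)
        glass = 0.5 + wn / 3000.0  # smooth substrate profile
        spec = rq.RamanSpectrum(wn, signal + 0.7 * glass)
        ref = rq.RamanSpectrum(wn, glass)
        out = rq.subtract_background(spec, ref)
        region = (wn >= 600) & (wn <= 650) | (wn >= 1750) & (wn <= 1800)
        assert np.allclose(out.intensity[region], signal[region], atol=1e-8)
        assert out.meta["background_scale"] == pytest.approx(0.7, abs=1e-6)

    def test_zero_reference_leaves_spectrum_unchanged(self):
        spec = _gaussian_spec(1445, 1.0)
        ref = rq.RamanSpectrum(spec.wavenumbers, np.zeros_like(spec.intensity))
        out = rq.subtract_background(spec, ref)
        np.testing.assert_array_equal(out.intensity, spec.intensity)

    def test_fit_region_outside_axis_rejected(self):
        spec = _gaussian_spec(1445, 1.0)
        ref = rq.RamanSpectrum(spec.wavenumbers, np.ones_like(spec.intensity))
        with pytest.raises(ValueError):
            rq.subtract_background(spec, ref, fit_region=(2000.0, 2100.0))


class TestMeasurePeak:
    def test_lone_gaussian_height(self):
        spec = _gaussian_spec(1654, 2.0)
        h = rq.measure_peak(spec, rq.BAND_CC_STRETCH)
        # endpoint baseline removes the in-window tail of the band itself
        expected = 2.0 * (1 - np.exp(-(12.0**2) / 200.0))
        assert h == pytest.approx(expected, abs=1e-6)

    def test_linear_ramp_removed_by_endpoint_baseline(self):
        ramp = lambda wn: 0.3 + 0.002 * wn
        with_ramp = rq.measure_peak(_gaussian_spec(1654, 2.0, extra=ramp), rq.BAND_CC_STRETCH)
        without = rq.measure_peak(_gaussian_spec(1654, 2.0), rq.BAND_CC_STRETCH)
        assert with_ramp == pytest.approx(without, abs=1e-3)

    def test_flat_zero_spectrum_measures_zero(self):
        wn = syn.default_fingerprint_wavenumbers()
        spec = rq.RamanSpectrum(wn, np.zeros_like(wn))
        assert rq.measure_peak(spec, rq.BAND_CH2_BEND) == 0.0

    @given(offset=st.floats(-5, 5))
    @settings(deadline=None, derandomize=True, max_examples=20)
    def test_invariant_to_global_offset(self, offset):
        base = rq.measure_peak(_gaussian_spec(1445, 1.5), rq.BAND_CH2_BEND)
        shifted = rq.measure_peak(
            _gaussian_spec(1445, 1.5, extra=lambda wn: np.full_like(wn, offset)),
            rq.BAND_CH2_BEND,
        )
        assert shifted == pytest.approx(base, abs=1e-9)

    def test_window_outside_range_rejected(self):
        spec = _gaussian_spec(1445, 1.0)
        with pytest.raises(ValueError):
            rq.measure_peak(spec, rq.BandDefinition("cd", 2127.0, 10.0))

    def test_area_mode_scales_with_height(self):
        a1 = rq.measure_peak(_gaussian_spec(1445, 1.0), rq.BAND_CH2_BEND, mode="area")
        a2 = rq.measure_peak(_gaussian_spec(1445, 2.0), rq.BAND_CH2_BEND, mode="area")
        assert a2 == pytest.approx(2 * a1, rel=1e-9)


class TestBandRatio:
    def test_simple_ratio(self):
        wn = syn.default_fingerprint_wavenumbers()
        y = 0.6 * np.exp(-((wn - 1654.0) ** 2) / 200.0) + 1.2 * np.exp(-((wn - 1445.0) ** 2) / 200.0)
        spec = rq.RamanSpectrum(wn, y)
        r = rq.band_ratio(spec, rq.BAND_CC_STRETCH, rq.BAND_CH2_BEND)
        assert r == pytest.approx(0.5, abs=1e-6)

    def test_zero_analyte_gives_zero(self):
        r = rq.band_ratio(_gaussian_spec(1445, 1.2), rq.BAND_CC_STRETCH, rq.BAND_CH2_BEND)
        assert r == pytest.approx(0.0, abs=1e-9)

    def test_zero_normalizer_unnormalizable(self):
        with pytest.raises(rq.UnnormalizableError):
            rq.band_ratio(_gaussian_spec(1654, 0.6), rq.BAND_CC_STRETCH, rq.BAND_CH2_BEND)


class TestFitCalibration:
    def test_exact_points_recovered(self):
        m = rq.fit_calibration([(0, 0.1), (1, 0.5), (2, 0.9)], "unsaturation")
        assert m.slope == pytest.approx(0.4)
        assert m.intercept == pytest.approx(0.1)
        assert m.r_squared == pytest.approx(1.0)
        assert m.warning is None

    def test_standard_x_designs(self):
        assert syn.UNSATURATION_STANDARD_X == (0.0, 1.0, 2.0)
        assert len(syn.make_calibration_standards("unsaturation")) == 3
        assert len(syn.make_calibration_standards("ce_percent")) == 6

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            rq.fit_calibration([(1, 0.4)], "unsaturation")

    def test_non_increasing_slope_flagged(self):
        with pytest.warns(UserWarning):
            m = rq.fit_calibration([(0, 0.9), (1, 0.5), (2, 0.1)], "ce_percent")
        assert m.warning == "non-increasing calibration"
        with pytest.raises(ValueError):
            m.invert(0.5)

    def test_matches_analytic_generator_line(self, unsat_model, ce_model):
        s, b = syn.analytic_calibration("unsaturation")
        assert unsat_model.slope == pytest.approx(s, abs=1e-10)
        assert unsat_model.intercept == pytest.approx(b, abs=1e-10)
        s, b = syn.analytic_calibration("ce_percent")
        assert ce_model.slope == pytest.approx(s, abs=1e-10)
        assert ce_model.intercept == pytest.approx(b, abs=1e-10)


class TestComposition:
    def test_oleate_like_standard_round_trips_to_one(self, unsat_model):
        spec = syn.synth_raman_spectrum(syn.SpectrumTruth(n_cc=1.0))
        est = rq.estimate_unsaturation(spec, unsat_model)
        assert est.unsaturation_raw == pytest.approx(1.0, abs=1e-6)

    def test_palmitate_like_standard_is_saturated(self, unsat_model):
        spec = syn.synth_raman_spectrum(syn.SpectrumTruth(n_cc=0.0))
        est = rq.estimate_unsaturation(spec, unsat_model)
        assert est.unsaturation_raw == pytest.approx(0.0, abs=1e-6)
        assert est.unsaturation >= 0.0

    def test_half_oleate_half_linoleate_mixture(self, unsat_model):
        # 50/50 oleate-linoleate: mean 1.5 C=C per chain
        spec = syn.synth_raman_spectrum(syn.SpectrumTruth(n_cc=1.5))
        est = rq.estimate_unsaturation(spec, unsat_model)
        assert est.unsaturation_raw == pytest.approx(1.5, abs=0.05)

    def test_pure_tag_emulsion_is_zero_ce(self, ce_model):
        spec = syn.synth_raman_spectrum(syn.SpectrumTruth(ce_fraction=0.0))
        est = rq.estimate_ce_percent(spec, ce_model)
        assert est.ce_percent_raw == pytest.approx(0.0, abs=0.5)

    def test_pure_ce_is_hundred_percent(self, ce_model):
        spec = syn.synth_raman_spectrum(syn.SpectrumTruth(ce_fraction=1.0))
        est = rq.estimate_ce_percent(spec, ce_model)
        assert est.ce_percent_raw == pytest.approx(100.0, abs=0.5)

    def test_forty_molpct_emulsion(self, ce_model):
        spec = syn.synth_raman_spectrum(syn.SpectrumTruth(ce_fraction=0.4))
        est = rq.estimate_ce_percent(spec, ce_model)
        assert est.ce_percent_raw == pytest.approx(40.0, abs=3.0)

    def test_estimates_strictly_increase_with_truth(self, unsat_model, ce_model):
        unsat = [
            rq.estimate_unsaturation(
                syn.synth_raman_spectrum(syn.SpectrumTruth(n_cc=x)), unsat_model
            ).unsaturation_raw
            for x in (0.0, 0.5, 1.0, 1.5, 2.0, 3.0)
        ]
        assert np.all(np.diff(unsat) > 0)
        ce = [
            rq.estimate_ce_percent(
                syn.synth_raman_spectrum(syn.SpectrumTruth(ce_fraction=f)), ce_model
            ).ce_percent_raw
            for f in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert np.all(np.diff(ce) > 0)

    def test_wrong_model_kind_rejected(self, unsat_model, ce_model):
        spec = syn.synth_raman_spectrum(syn.SpectrumTruth(n_cc=1.0))
        with pytest.raises(ValueError):
            rq.estimate_unsaturation(spec, ce_model)
        with pytest.raises(ValueError):
            rq.estimate_ce_percent(spec, unsat_model)

    def test_round_trip_with_baseline_and_gain(self, unsat_model):
        # quadratic baseline + 2% gain: endpoint correction and the ratio
        # normalisation absorb both
        truth = syn.SpectrumTruth(n_cc=1.2, baseline_coeffs=(0.05, -0.02, 0.1),
                                  gain_sigma=0.02, seed=9)
        est = rq.estimate_unsaturation(syn.synth_raman_spectrum(truth), unsat_model)
        assert est.unsaturation_raw == pytest.approx(1.2, abs=0.05)
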