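"""AC/DC extraction, modulation ratio and the ratio calibration."""

import numpy as np
import pytest

import wristox as wx
from wristox import dsp

FS = 25.0


def _sine(freq, duration=60.0, amp=1.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestEstimateDC:
    def test_constant_is_identity(self):
        x = np.full(500, 3.7)
        np.testing.assert_allclose(dsp.estimate_dc(x, FS, 2.0), x)

    def test_periodic_component_cancels(self):
        x = _sine(1.0)  # window of 2 s = 2 full periods
        dc = dsp.estimate_dc(x, FS, 2.0)
        assert np.abs(dc[100:-100]).max() < 0.02

    def test_superposition_recovers_offset(self):
        x = 5.0 + _sine(1.0)
        dc = dsp.estimate_dc(x, FS, 2.0)
        np.testing.assert_allclose(dc[100:-100], 5.0, atol=0.02)

    def test_rejects_nonpositive_window(self):
        with pytest.raises(ValueError):
            dsp.estimate_dc(np.ones(100), FS, 0.0)

    def test_preserves_length(self):
        x = np.random.default_rng(0).normal(size=333)
        assert len(dsp.estimate_dc(x, FS, 2.0)) == 333


class TestEstimateAC:
    def test_inband_sinusoid_gives_rms(self):
        ac = dsp.estimate_ac(_sine(1.0, amp=1.0), FS)
        assert np.median(ac[100:-100]) == pytest.approx(1.0 / np.sqrt(2), rel=0.03)

    def test_constant_gives_zero(self):
        ac = dsp.estimate_ac(np.full(1000, 2.0), FS)
        assert np.nanmax(ac) < 1e-6

    def test_respiratory_drift_strongly_attenuated(self):
        in_band = np.median(dsp.estimate_ac(_sine(1.0), FS)[200:-200])
        out_band = np.median(dsp.estimate_ac(_sine(0.05, duration=120.0), FS)[800:-800])
        assert in_band / out_band >= 20.0

    def test_rejects_band_outside_nyquist(self):
        with pytest.raises(ValueError):
            dsp.estimate_ac(_sine(1.0), FS, band=(0.5, 20.0))


class TestModulationRatio:
    def test_identity_and_arithmetic(self):
        r, valid = dsp.modulation_ratio(np.array([0.02, 0.01]), np.array([0.02, 0.02]))
        assert valid.all()
        np.testing.assert_allclose(r, [1.0, 0.5])

    def test_near_zero_infrared_marks_invalid_not_raises(self):
        r, valid = dsp.modulation_ratio(np.array([0.01, 0.01]), np.array([0.02, 0.0]))
        assert valid.tolist() == [True, False]
        assert np.isnan(r[1])

    def test_scale_invariance_of_perfusion(self, clean_record):
        """Multiplying a raw channel by a constant leaves AC/DC and R unchanged."""
        base = dsp.compute_features(clean_record)
        scaled = wx.PPGRecord(
            fs=clean_record.fs, t0=clean_record.t0,
            red=clean_record.red * 3.7, infrared=clean_record.infrared,
            green=clean_record.green, acc_x=clean_record.acc_x,
            acc_y=clean_record.acc_y, acc_z=clean_record.acc_z,
        )
        other = dsp.compute_features(scaled)
        sel = base.r_valid & other.r_valid
        np.testing.assert_allclose(other.r[sel], base.r[sel], rtol=1e-9)


class TestRatioCalibration:
    def test_exact_linear_recovery(self):
        r = np.linspace(0.4, 1.6, 12)
        sao2 = 110.0 - 25.0 * r
        cal = dsp.fit_ratio_calibration(r, sao2)
        assert cal.intercept == pytest.approx(110.0, abs=1e-8)
        assert cal.slope == pytest.approx(-25.0, abs=1e-8)
        assert cal.residual_sd == pytest.approx(0.0, abs=1e-8)

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            dsp.fit_ratio_calibration(np.ones(12), np.linspace(70, 100, 12))
        with pytest.raises(ValueError):
            dsp.fit_ratio_calibration(np.linspace(0.4, 1.6, 5), np.linspace(70, 100, 5))

    def test_noiseless_simulator_grid_fits_tightly(self, constants):
        from conftest import plateau_record

        grid = np.linspace(0.70, 1.00, 16)
        r_values, sao2 = [], []
        for i, s in enumerate(grid):
            rec = plateau_record(float(s), seed=300 + i, duration=30.0)
            feats = dsp.compute_features(rec)
            edge = int(5 * rec.fs)
            r_values.append(np.nanmedian(feats.r[edge:-edge]))
            sao2.append(100.0 * s)
        cal = dsp.fit_ratio_calibration(r_values, sao2)
        assert cal.slope < 0
        assert cal.residual_sd < 1.0

    def test_prediction_centroid_and_clipping(self):
        r = np.linspace(0.4, 1.6, 20)
        sao2 = 110.0 - 25.0 * r
        cal = dsp.fit_ratio_calibration(r, sao2)
        assert dsp.spo2_from_ratio(float(r.mean()), cal) == pytest.approx(sao2.mean())
        assert dsp.spo2_from_ratio(0.0, cal) == 100.0  # 110 pre-clip
        assert np.isnan(dsp.spo2_from_ratio(np.nan, cal))


def test_feature_lengths_align_with_record(clean_record):
    feats = dsp.compute_features(clean_record)
    n = len(clean_record)
    assert len(feats.t) == n
    for name in ("red", "infrared", "green"):
        assert len(feats.dc[name]) == n
        assert len(feats.ac[name]) == n
    assert len(feats.r) == n


def test_calibration_round_trip_noiseless_plateaus(constants):
    """Fit on a noiseless grid, predict held-out plateaus: MAE < 1%."""
    from conftest import plateau_record

    fit_grid = np.linspace(0.70, 1.00, 13)
    r_fit, y_fit = [], []
    for i, s in enumerate(fit_grid):
        rec = plateau_record(float(s), seed=400 + i, duration=30.0)
        feats = dsp.compute_features(rec)
        edge = int(5 * rec.fs)
        r_fit.append(np.nanmedian(feats.r[edge:-edge]))
        y_fit.append(100.0 * s)
    cal = dsp.fit_ratio_calibration(r_fit, y_fit)

    held_out = [0.72, 0.82, 0.93, 0.99]
    errors = []
    for i, s in enumerate(held_out):
        rec = plateau_record(s, seed=500 + i, duration=30.0)
        feats = dsp.compute_features(rec)
        edge = int(5 * rec.fs)
        est = dsp.spo2_from_ratio(float(np.nanmedian(feats.r[edge:-edge])), cal)
        errors.append(abs(est - 100.0 * s))
    assert float(np.mean(errors)) < 1.0
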