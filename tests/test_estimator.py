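"""Windowing, the direct regressor, the quality classifier and fusion."""

import numpy as np
import pytest

import wristox as wx
from wristox import estimator
from wristox.pipeline import extract_record_windows

from conftest import plateau_record


class TestMakeWindows:
    def test_window_counts(self):
        rec = plateau_record(0.9, seed=1, duration=60.0)
        assert len(estimator.make_windows(rec, stride=1.0)) == 53
        rec8 = plateau_record(0.9, seed=1, duration=8.0)
        assert len(estimator.make_windows(rec8, stride=1.0)) == 1

    def test_too_short_record_rejected(self):
        rec = plateau_record(0.9, seed=1, duration=8.0)
        short = wx.PPGRecord(
            fs=rec.fs, t0=0.0, red=rec.red[:100], infrared=rec.infrared[:100],
            green=rec.green[:100], acc_x=rec.acc_x[:100], acc_y=rec.acc_y[:100],
            acc_z=rec.acc_z[:100],
        )
        with pytest.raises(ValueError):
            estimator.make_windows(short)

    def test_constant_channels_normalize_to_zero(self):
        rec = plateau_record(0.9, seed=1, duration=20.0)
        const = wx.PPGRecord(
            fs=rec.fs, t0=0.0, red=np.full(len(rec), 500.0),
            infrared=np.full(len(rec), 600.0), green=np.full(len(rec), 700.0),
            acc_x=rec.acc_x, acc_y=rec.acc_y, acc_z=rec.acc_z,
        )
        win = estimator.make_windows(const, stride=2.0)
        np.testing.assert_allclose(win.values, 0.0)

    def test_mask_flags_overlapping_windows(self):
        rec = plateau_record(0.9, seed=1, duration=30.0)
        mask = np.zeros(len(rec), dtype=bool)
        mask[0:10] = True  # first 0.4 s invalid
        win = estimator.make_windows(rec, stride=2.0, mask=mask)
        assert win.flagged[0]
        assert not win.flagged[-1]


def _training_windows(seed=0, n_plateaus=6, duration=40.0):
    """Labeled clean windows across a saturation spread."""
    xs, ys = [], []
    sats = np.linspace(0.72, 0.99, n_plateaus)
    for i, s in enumerate(sats):
        rec = plateau_record(float(s), seed=seed + i, duration=duration, noise_sd=0.005)
        win = estimator.make_windows(rec, stride=2.0)
        xs.append(win.values)
        ys.append(np.full(len(win), 100.0 * s))
    return np.concatenate(xs), np.concatenate(ys)


class TestRegressor:
    spec = estimator.NetworkSpec()

    def test_parameter_budget(self):
        net = self.spec.build(seed=0)
        assert net.param_count() < 50_000

    def test_training_beats_untrained_baseline(self):
        x, y = _training_windows(seed=0)
        x_val, y_val = _training_windows(seed=50)
        untrained = estimator.SpO2Regressor(self.spec, self.spec.build(seed=3))
        base_rmse = np.sqrt(np.mean((untrained.predict(x_val) - y_val) ** 2))
        model = estimator.train_regressor(self.spec, x, y, x_val=x_val, y_val=y_val,
                                          epochs=15, seed=3)
        rmse = np.sqrt(np.mean((model.predict(x_val) - y_val) ** 2))
        assert rmse < base_rmse

    def test_constant_training_collapses_predictions(self):
        rec = plateau_record(0.88, seed=9, duration=120.0, noise_sd=0.005)
        win = estimator.make_windows(rec, stride=2.0)
        y = np.full(len(win), 88.0)
        model = estimator.train_regressor(self.spec, win.values, y, epochs=15, seed=4)
        preds = model.predict(win)
        assert np.std(preds) < 1.0
        assert abs(np.mean(preds) - 88.0) < 1.5

    def test_determinism_same_seed_same_weights(self):
        x, y = _training_windows(seed=0, n_plateaus=3, duration=20.0)
        a = estimator.train_regressor(self.spec, x, y, epochs=3, seed=11)
        b = estimator.train_regressor(self.spec, x, y, epochs=3, seed=11)
        for pa, pb in zip(a.net.params(), b.net.params(), strict=True):
            np.testing.assert_array_equal(pa, pb)

    def test_noise_window_returns_bounded_value(self, trained_models):
        rng = np.random.default_rng(0)
        window = rng.normal(size=(3, 200))
        value = estimator.predict_window(trained_models.regressor, window)
        assert 50.0 <= value <= 100.0

    def test_identical_windows_identical_outputs(self, trained_models):
        rng = np.random.default_rng(1)
        window = rng.normal(size=(3, 200)) * 0.01
        batch = np.repeat(window[None], 5, axis=0)
        preds = trained_models.regressor.predict(batch)
        assert np.ptp(preds) == 0.0

    def test_clean_plateau_estimate_within_tolerance(self, trained_models, small_config):
        from wristox.pipeline import estimate_record

        rec = plateau_record(0.85, seed=77, duration=60.0)
        df = estimate_record(rec, trained_models, small_config)
        assert abs(df["spo2_net"].mean() - 85.0) <= 3.0

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            estimator.train_regressor(self.spec, np.empty((0, 3, 200)), np.empty(0))


class TestQualityClassifier:
    def test_rejects_single_class(self):
        x = np.zeros((10, 3, 200))
        with pytest.raises(ValueError):
            estimator.train_quality_classifier(estimator.NetworkSpec(), x, np.zeros(10))

    def test_balanced_holdout_accuracy(self, trained_models, small_config):
        study = wx.simulate_study(n_subjects=2, seed=8181)
        xs, poors = [], []
        for subj in study.subjects:
            for rec in subj.records.values():
                rw = extract_record_windows(rec, small_config)
                xs.append(rw.windows.values)
                poors.append(rw.poor)
        x = np.concatenate(xs)
        poor = np.concatenate(poors)
        rng = np.random.default_rng(0)
        n = min(int(poor.sum()), int((~poor).sum()))
        idx = np.concatenate([
            rng.choice(np.flatnonzero(poor), n, replace=False),
            rng.choice(np.flatnonzero(~poor), n, replace=False),
        ])
        pred = trained_models.classifier.predict(x[idx])
        assert (pred == poor[idx]).mean() > 0.9

    def test_low_poor_rate_on_clean_windows(self, trained_models):
        rec = plateau_record(0.92, seed=55, duration=120.0)
        win = estimator.make_windows(rec, stride=2.0)
        assert trained_models.classifier.predict(win).mean() < 0.05


class TestFusion:
    def test_perfect_network_predictor_dominates(self):
        rng = np.random.default_rng(0)
        ref = rng.uniform(70, 100, size=200)
        ratio_est = ref + rng.normal(0, 2.0, size=200)
        model = estimator.fit_fusion(ratio_est, ref, ref)
        assert model.w_net >= 0.9
        assert abs(model.w_ratio) < 0.1

    def test_collinear_inputs_trigger_ratio_fallback(self):
        rng = np.random.default_rng(1)
        e = rng.uniform(70, 100, size=100)
        ref = 0.9 * e + 5.0
        with pytest.warns(UserWarning):
            model = estimator.fit_fusion(e, e, ref)
        assert model.fallback
        fused = estimator.apply_fusion(model, e, e)
        slope, intercept = np.polyfit(e, ref, 1)
        np.testing.assert_allclose(fused, np.clip(intercept + slope * e, 50, 100), atol=1e-8)

    def test_fused_not_worse_than_either_path_out_of_sample(self):
        rng = np.random.default_rng(2)
        ref = rng.uniform(70, 100, size=600)
        ratio_est = ref + rng.normal(0, 2.0, size=600)
        net_est = ref + rng.normal(0, 1.5, size=600)
        model = estimator.fit_fusion(ratio_est[:300], net_est[:300], ref[:300])
        fused = estimator.apply_fusion(model, ratio_est[300:], net_est[300:])

        def rmse(est):
            return np.sqrt(np.mean((est - ref[300:]) ** 2))

        assert rmse(fused) <= min(rmse(ratio_est[300:]), rmse(net_est[300:])) + 0.1


def test_checkpoint_roundtrip(tmp_path, trained_models):
    path = tmp_path / "models.json"
    estimator.save_checkpoint(
        path,
        regressor=trained_models.regressor,
        classifier=trained_models.classifier,
        fusion=trained_models.fusion,
        calibration=trained_models.calibration,
        config_hash="abc",
    )
    regressor, classifier, fusion, calibration = estimator.load_checkpoint(path)
    rng = np.random.default_rng(5)
    batch = rng.normal(size=(4, 3, 200)) * 0.01
    np.testing.assert_allclose(regressor.predict(batch), trained_models.regressor.predict(batch))
    np.testing.assert_allclose(
        classifier.predict_proba(batch), trained_models.classifier.predict_proba(batch)
    )
    assert fusion == trained_models.fusion
    assert calibration.slope == pytest.approx(trained_models.calibration.slope)
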