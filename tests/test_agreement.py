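"""Lag estimation, plateau matching and agreement statistics."""

import numpy as np
import pytest

from wristox import agreement
from wristox.protocol import BloodSample


def _pairs(spo2, sao2, wrist="right"):
    return [
        agreement.PairedMeasurement(t_ref=float(i), sao2=float(a), spo2=float(p),
                                    wrist=wrist, subject_id=0)
        for i, (p, a) in enumerate(zip(spo2, sao2))
    ]


class TestEstimateLag:
    def _trace(self, n=600, fs=1.0):
        t = np.arange(n) / fs
        return 85.0 + 10.0 * np.sin(2 * np.pi * t / 200.0) + 3.0 * np.sin(2 * np.pi * t / 47.0)

    def test_identical_series_zero_lag(self):
        x = self._trace()
        assert agreement.estimate_lag(x, x, fs=1.0, max_lag=30.0) == 0.0

    def test_recovers_injected_shift_within_one_sample(self):
        fs = 2.0
        t = np.arange(0, 600, 1 / fs)
        ref = 85.0 + 10.0 * np.sin(2 * np.pi * t / 200.0) + 3.0 * np.sin(2 * np.pi * t / 47.0)
        lag = -4.5
        device = np.interp(t + lag, t, ref)  # device(t) = ref(t + lag)
        est = agreement.estimate_lag(device, ref, fs=fs, max_lag=30.0)
        assert abs(est - lag) <= 1.0 / fs

    def test_flat_series_rejected(self):
        with pytest.raises(ValueError):
            agreement.estimate_lag(np.ones(600), self._trace(), fs=1.0)


class TestPairing:
    def _setup(self, conclusive_value=True):
        times = np.arange(0.0, 300.0, 2.0)
        spo2 = np.full_like(times, 90.0)
        conclusive = np.full(len(times), conclusive_value, dtype=bool)
        samples = [BloodSample(t=50.0, sao2=91.0, run_index=0, plateau_index=0),
                   BloodSample(t=150.0, sao2=89.0, run_index=0, plateau_index=1)]
        return times, spo2, conclusive, samples

    def test_full_coverage_one_pair_per_sample(self):
        times, spo2, conclusive, samples = self._setup()
        pairs, dropped = agreement.pair_measurements(times, spo2, conclusive, samples, lag=0.0)
        assert len(pairs) == 2 and dropped == 0

    def test_all_inconclusive_drops_everything(self):
        times, spo2, conclusive, samples = self._setup(conclusive_value=False)
        pairs, dropped = agreement.pair_measurements(times, spo2, conclusive, samples, lag=0.0)
        assert pairs == [] and dropped == len(samples)

    def test_lag_correction_moves_the_pairing_window(self):
        times = np.arange(0.0, 300.0, 1.0)
        spo2 = np.where(times < 100, 90.0, 70.0)
        conclusive = np.ones(len(times), dtype=bool)
        samples = [BloodSample(t=90.0, sao2=90.0, run_index=0, plateau_index=0)]
        # device lags by 20 s: the reading for t_ref=90 sits at t=110
        pairs, _ = agreement.pair_measurements(times, spo2, conclusive, samples,
                                               lag=-20.0, pairing_halfwidth=5.0)
        assert pairs[0].spo2 == pytest.approx(70.0)


class TestBiasRmse:
    def test_identical_pairs_zero(self):
        stats = agreement.bias_rmse(_pairs([90, 85, 80], [90, 85, 80]))
        assert stats["bias"] == 0.0 and stats["rmse"] == 0.0

    def test_symmetric_errors(self):
        stats = agreement.bias_rmse(_pairs([91, 84], [90, 85]))
        assert stats["bias"] == pytest.approx(0.0)
        assert stats["rmse"] == pytest.approx(1.0)

    def test_identity_rmse_bias_sd(self):
        rng = np.random.default_rng(0)
        spo2 = rng.uniform(70, 100, 50)
        sao2 = spo2 + rng.normal(1.0, 2.0, 50)
        stats = agreement.bias_rmse(_pairs(spo2, sao2))
        errors = spo2 - sao2
        sd_pop = np.std(errors)
        assert stats["rmse"] ** 2 == pytest.approx(stats["bias"] ** 2 + sd_pop**2)

    def test_ci_reconstruction_from_printed_summary(self):
        lo, hi = agreement.bias_ci_from_summary(0.98, 3.00, 275)
        assert round(hi, 2) == 1.32

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            agreement.bias_rmse(_pairs([90], [89]))


class TestStratify:
    @pytest.mark.parametrize("spo2, stratum", [(80.0, "<=80"), (90.0, "80-90"),
                                               (80.1, "80-90"), (90.1, ">90"), (75.0, "<=80")])
    def test_boundary_convention(self, spo2, stratum):
        assert agreement.assign_stratum(spo2) == stratum

    def test_three_pairs_one_per_stratum(self):
        strata = agreement.stratify(_pairs([75, 85, 95], [74, 86, 95]))
        assert [strata[s]["n"] for s in agreement.STRATA] == [1, 1, 1]


class TestBlandAltman:
    def test_perfect_agreement(self):
        ba = agreement.bland_altman(_pairs([90, 85, 80], [90, 85, 80]))
        assert ba["mean_diff"] == 0.0
        assert ba["loa_lower"] == 0.0 and ba["loa_upper"] == 0.0

    def test_loa_symmetric_about_mean(self):
        rng = np.random.default_rng(1)
        spo2 = rng.uniform(70, 100, 40)
        sao2 = spo2 + rng.normal(0.5, 1.5, 40)
        ba = agreement.bland_altman(_pairs(spo2, sao2))
        mid = 0.5 * (ba["loa_lower"] + ba["loa_upper"])
        assert mid == pytest.approx(ba["mean_diff"])

    def test_two_point_antisymmetric_differences(self):
        ba = agreement.bland_altman(_pairs([81, 89, 85], [79, 91, 85]))
        assert ba["mean_diff"] == pytest.approx(0.0)
        assert abs(ba["r"]) == pytest.approx(1.0)

    def test_needs_three_pairs(self):
        with pytest.raises(ValueError):
            agreement.bland_altman(_pairs([90, 85], [89, 84]))


class TestPearson:
    def test_exact_linear_relations(self):
        x = np.linspace(70, 100, 20)
        r, _ = agreement.pearson_agreement(_pairs(x, 0.5 * x + 10))
        assert r == pytest.approx(1.0)
        r, _ = agreement.pearson_agreement(_pairs(x, -0.5 * x + 130))
        assert r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            agreement.pearson_agreement(_pairs([90] * 5, [89, 88, 90, 91, 92]))

    def test_p_value_from_t_transform(self):
        assert agreement.pearson_p_from_r(0.083, 275) == pytest.approx(0.17, abs=0.01)


class TestCompliance:
    def test_passing_study(self):
        flags = agreement.compliance_check(rmse=3.00, n_pairs=275, n_subjects=14)
        assert all(flags.values())

    def test_fda_fail_iso_pass(self):
        flags = agreement.compliance_check(rmse=3.8, n_pairs=275, n_subjects=14)
        assert not flags["arms_fda"] and flags["arms_iso"]

    def test_pairs_boundary(self):
        assert not agreement.compliance_check(3.0, 199, 14)["enough_pairs"]


def test_statistics_invariant_to_pair_order():
    rng = np.random.default_rng(3)
    spo2 = rng.uniform(70, 100, 60)
    sao2 = spo2 + rng.normal(1, 2, 60)
    pairs = _pairs(spo2, sao2)
    shuffled = list(pairs)
    rng.shuffle(shuffled)
    a, b = agreement.bias_rmse(pairs), agreement.bias_rmse(shuffled)
    assert a["bias"] == pytest.approx(b["bias"]) and a["rmse"] == pytest.approx(b["rmse"])
    assert agreement.bland_altman(pairs)["loa_upper"] == pytest.approx(
        agreement.bland_altman(shuffled)["loa_upper"]
    )
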