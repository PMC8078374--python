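"""End-to-end orchestration: train on one synthetic study, estimate
saturation series with gating, validate against reference draws.

The training study plays the role of the dedicated calibration studies
used to fit a device's machine-learning components: the ratio-path
calibration, the window regressor, the quality classifier, and the final
fusion weights (fitted on a held-out subject split, never on training
windows).  Validation then runs the full estimation pipeline on a fresh
study and produces per-wrist accuracy reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import agreement, dsp, estimator, gating
from .config import RunConfig, seed_stream
from .protocol import HypoxiaStudy, simulate_study
from .synth import PPGRecord


@dataclass
class Models:
    """All trained components of the estimation pipeline."""

    calibration: dsp.RatioCalibration
    regressor: estimator.SpO2Regressor
    classifier: estimator.QualityClassifier
    fusion: estimator.FusionModel
    config_hash: str = ""


def _window_truth(record: PPGRecord, t_centers: np.ndarray) -> np.ndarray:
    """Ground-truth saturation (%) at window centers, device time base."""
    return 100.0 * np.interp(t_centers, record.meta["truth_t"], record.meta["truth_s"])


def _window_overlaps_bursts(windows: estimator.Windows, bursts, min_overlap: float = 0.5) -> np.ndarray:
    """True where a window overlaps a motion burst by at least
    ``min_overlap`` seconds (sub-taper grazes look clean and would only
    blur the quality labels)."""
    out = np.zeros(len(windows), dtype=bool)
    w_end = windows.t_start + estimator.WINDOW_SECONDS
    for start, end in bursts:
        overlap = np.minimum(w_end, end) - np.maximum(windows.t_start, start)
        out |= overlap >= min_overlap
    return out


def _window_mean(series: np.ndarray, valid: np.ndarray, windows: estimator.Windows, fs: float) -> np.ndarray:
    """Mean of the valid points of a per-sample series in each window."""
    n_win = int(round(estimator.WINDOW_SECONDS * fs))
    out = np.full(len(windows), np.nan)
    starts = np.round((windows.t_start - windows.t_start[0]) * fs).astype(int)
    for i, s in enumerate(starts):
        seg = series[s : s + n_win]
        ok = valid[s : s + n_win] & np.isfinite(seg)
        if ok.any():
            out[i] = seg[ok].mean()
    return out


@dataclass
class RecordWindows:
    """Per-record window features shared by training and estimation."""

    windows: estimator.Windows
    r_mean: np.ndarray  # per-window mean modulation ratio (NaN if invalid)
    ir_perfusion: np.ndarray  # per-window mean infrared perfusion
    truth: np.ndarray  # % at window centers
    poor: np.ndarray  # overlaps a motion burst


def extract_record_windows(record: PPGRecord, config: RunConfig) -> RecordWindows:
    features = dsp.compute_features(record, band=config.band, window=config.dc_window)
    windows = estimator.make_windows(record, stride=config.window_stride, dc_window=config.dc_window)
    r_mean = _window_mean(features.r, features.r_valid, windows, record.fs)
    ir_perf = _window_mean(
        features.perfusion["infrared"],
        np.isfinite(features.perfusion["infrared"]),
        windows,
        record.fs,
    )
    return RecordWindows(
        windows=windows,
        r_mean=r_mean,
        ir_perfusion=ir_perf,
        truth=_window_truth(record, windows.t_center),
        poor=_window_overlaps_bursts(windows, record.meta.get("motion_bursts", [])),
    )


def train_models(train_study: HypoxiaStudy, config: RunConfig, seed: int) -> Models:
    """Fit calibration, both networks and the fusion on a training study.

    Subjects are split ~2:1 into fit and held-out groups; the regressor
    and classifier train on the fit group (regressor on artifact-free
    windows only), and the ratio calibration and fusion weights are
    estimated on windows the networks never saw.
    """
    per_subject: dict[int, list[RecordWindows]] = {}
    for subj in train_study.subjects:
        per_subject[subj.subject_id] = [
            extract_record_windows(rec, config) for rec in subj.records.values()
        ]
    ids = sorted(per_subject)
    n_val = max(1, len(ids) // 3)
    val_ids = set(ids[-n_val:])

    def stack(ids_, only_good=False):
        xs, truths, poors, rs = [], [], [], []
        for sid in ids_:
            for rw in per_subject[sid]:
                keep = ~rw.poor if only_good else np.ones(len(rw.windows), dtype=bool)
                xs.append(rw.windows.values[keep])
                truths.append(rw.truth[keep])
                poors.append(rw.poor[keep])
                rs.append(rw.r_mean[keep])
        return (
            np.concatenate(xs),
            np.concatenate(truths),
            np.concatenate(poors),
            np.concatenate(rs),
        )

    fit_ids = [i for i in ids if i not in val_ids]
    x_fit, y_fit, poor_fit, r_fit = stack(fit_ids)
    x_val, y_val, poor_val, r_val = stack(sorted(val_ids))

    spec = estimator.NetworkSpec(kernel=config.kernel, channels=config.channels, stride=config.conv_stride)
    good_fit = ~poor_fit
    good_val = ~poor_val
    regressor = estimator.train_regressor(
        spec,
        x_fit[good_fit],
        y_fit[good_fit],
        x_val=x_val[good_val],
        y_val=y_val[good_val],
        epochs=config.epochs,
        batch_size=config.batch_size,
        lr=config.learning_rate,
        seed=seed_stream(seed, "regressor"),
    )
    classifier = estimator.train_quality_classifier(
        spec,
        x_fit,
        poor_fit,
        x_val=x_val,
        poor_val=poor_val,
        epochs=config.epochs,
        batch_size=config.batch_size,
        lr=config.learning_rate,
        seed=seed_stream(seed, "classifier"),
    )

    # Ratio calibration on artifact-free fit windows with valid R.
    cal_keep = good_fit & np.isfinite(r_fit)
    calibration = dsp.fit_ratio_calibration(r_fit[cal_keep], y_fit[cal_keep])

    # Fusion on the held-out split, artifact-free windows only.
    fus_keep = good_val & np.isfinite(r_val)
    ratio_est = dsp.spo2_from_ratio(r_val[fus_keep], calibration)
    net_est = regressor.predict(x_val[fus_keep])
    fusion = estimator.fit_fusion(ratio_est, net_est, y_val[fus_keep])
    return Models(
        calibration=calibration,
        regressor=regressor,
        classifier=classifier,
        fusion=fusion,
        config_hash=config.hash(),
    )


def estimate_record(record: PPGRecord, models: Models, config: RunConfig) -> pd.DataFrame:
    """Run the full per-window estimation + gating on one record.

    Returns a frame with one row per window: center time, ratio-path,
    network and fused saturation estimates, the gate status and its
    diagnostics.
    """
    rw = extract_record_windows(record, config)
    windows = rw.windows
    ratio_est = dsp.spo2_from_ratio(rw.r_mean, models.calibration)
    net_est = models.regressor.predict(windows)
    fused = estimator.apply_fusion(models.fusion, ratio_est, net_est)
    # Where the ratio path is invalid, fall back to the network estimate
    # so gating (not arithmetic) decides whether to report.
    fused = np.where(np.isfinite(fused), fused, net_est)
    quality = models.classifier.predict_proba(windows)

    thresholds = gating.GateThresholds(
        perfusion_floor=config.perfusion_floor,
        peak_ratio_min=config.peak_ratio_min,
        acc_sd_max=config.acc_sd_max,
        cardiac_band=config.band,
    )
    acc = record.acc()
    n_win = int(round(estimator.WINDOW_SECONDS * record.fs))
    starts = np.round((windows.t_start - record.t0) * record.fs).astype(int)
    labels = []
    for i, s in enumerate(starts):
        labels.append(
            gating.gate(
                infrared_window=record.infrared[s : s + n_win],
                acc_window=acc[:, s : s + n_win],
                fs=record.fs,
                mean_ir_perfusion=rw.ir_perfusion[i],
                quality_prob=quality[i],
                poor_quality_threshold=models.classifier.threshold,
                thresholds=thresholds,
            )
        )
    return pd.DataFrame(
        {
            "t_s": windows.t_center,
            "spo2_ratio": ratio_est,
            "spo2_net": net_est,
            "spo2_fused": fused,
            "status": [lab.status for lab in labels],
            "perfusion_ir": rw.ir_perfusion,
            "acc_sd": [lab.acc_sd for lab in labels],
            "quality_prob": quality,
            "truth": rw.truth,
        }
    )


@dataclass
class WristValidation:
    report: agreement.AccuracyReport
    pairs: list = field(default_factory=list)
    conclusiveness: dict = field(default_factory=dict)
    estimated_lags: list = field(default_factory=list)
    true_lags: list = field(default_factory=list)
    n_dropped: int = 0


@dataclass
class ValidationResult:
    wrists: dict[str, WristValidation]
    n_subjects: int

    def compliance(self) -> dict:
        worst_rmse = max(w.report.rmse for w in self.wrists.values())
        min_pairs = min(w.report.n_pairs for w in self.wrists.values())
        return agreement.compliance_check(worst_rmse, min_pairs, self.n_subjects)


def validate_study(study: HypoxiaStudy, models: Models, config: RunConfig) -> ValidationResult:
    """Full validation: estimate, gate, align, pair and score per wrist."""
    per_wrist: dict[str, dict] = {}
    for subj in study.subjects:
        for wrist, record in subj.records.items():
            df = estimate_record(record, models, config)
            conclusive = (df["status"] == gating.CONCLUSIVE).to_numpy()
            ref = subj.trajectory.interp(df["t_s"].to_numpy())
            series_fs = 1.0 / config.window_stride
            try:
                lag = agreement.estimate_lag(
                    df["spo2_fused"].to_numpy(), ref, fs=series_fs, max_lag=config.max_lag
                )
            except ValueError:
                lag = 0.0
            pairs, dropped = agreement.pair_measurements(
                df["t_s"].to_numpy(),
                df["spo2_fused"].to_numpy(),
                conclusive,
                subj.samples,
                lag,
                config.pairing_halfwidth,
                wrist=wrist,
                subject_id=subj.subject_id,
            )
            bucket = per_wrist.setdefault(
                wrist, {"pairs": [], "lags": [], "true_lags": [], "statuses": [], "dropped": 0}
            )
            bucket["pairs"].extend(pairs)
            bucket["lags"].append(lag)
            bucket["true_lags"].append(subj.lags[wrist])
            bucket["statuses"].extend(df["status"].tolist())
            bucket["dropped"] += dropped

    wrists = {}
    for wrist, bucket in per_wrist.items():
        report = agreement.build_report(bucket["pairs"], bucket["lags"], wrist, bucket["dropped"])
        wrists[wrist] = WristValidation(
            report=report,
            pairs=bucket["pairs"],
            conclusiveness=gating.summarize_conclusiveness(bucket["statuses"]),
            estimated_lags=bucket["lags"],
            true_lags=bucket["true_lags"],
            n_dropped=bucket["dropped"],
        )
    return ValidationResult(wrists=wrists, n_subjects=len(study.subjects))


def run_experiment(
    seed: int,
    config: RunConfig | None = None,
) -> tuple[ValidationResult, Models, HypoxiaStudy]:
    """Simulate training + validation studies, train, and validate.

    The single entry point behind the CLI's end-to-end mode and the
    reproduction script: the training study and the validation study use
    disjoint named seed streams derived from ``seed``.
    """
    if config is None:
        config = RunConfig()
    train_study = simulate_study(
        n_subjects=config.n_train_subjects,
        lag_mean=config.lag_mean,
        lag_sd=config.lag_sd,
        seed=seed_stream(seed, "train-study"),
        fs=config.fs,
        coox_noise_sd=config.coox_noise_sd,
        skip_probability=config.skip_probability,
        motion_rate_right=config.motion_rate_right,
        motion_rate_left=config.motion_rate_left,
        noise_sd=config.noise_sd,
        transition_tau=config.transition_tau,
    )
    models = train_models(train_study, config, seed_stream(seed, "training"))
    study = simulate_study(
        n_subjects=config.n_subjects,
        lag_mean=config.lag_mean,
        lag_sd=config.lag_sd,
        seed=seed_stream(seed, "validation-study"),
        fs=config.fs,
        coox_noise_sd=config.coox_noise_sd,
        skip_probability=config.skip_probability,
        motion_rate_right=config.motion_rate_right,
        motion_rate_left=config.motion_rate_left,
        noise_sd=config.noise_sd,
        transition_tau=config.transition_tau,
    )
    result = validate_study(study, models, config)
    return result, models, study
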