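"""Classical ratio-of-ratios SpO2 path.

The baseline (DC) of each optical channel is a centered moving average;
the pulsatile amplitude (AC) is the centered moving standard deviation of
the bandpass-filtered channel (passband around the cardiac fundamental).
Perfusion is AC/DC per channel, and the modulation ratio R is red
perfusion over infrared perfusion.  R is calibrated to saturation by
ordinary least squares against co-oximeter references, giving the linear
map SpO2 = a + b·R (b < 0 for physically sensible optics).

Filtering is zero-phase (forward-backward Butterworth) so this path adds
no lag of its own; real device-vs-reference lag is modeled and estimated
separately.  Invalid points (vanishing infrared perfusion) are tracked
with a boolean mask rather than sentinel values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .synth import PPGRecord

DEFAULT_BAND = (0.5, 2.5)  # Hz; passes heart rates 40-150 bpm, rejects respiration
DEFAULT_WINDOW = 2.0  # s, for both the DC average and the AC moving SD


def estimate_dc(x: np.ndarray, fs: float, window: float = DEFAULT_WINDOW) -> np.ndarray:
    """Centered moving-average baseline; edges use a shrinking window."""
    if window <= 0:
        raise ValueError("window must be positive")
    w = int(round(window * fs))
    if w < 3:
        raise ValueError("window too short: needs at least 3 samples")
    return (
        pd.Series(np.asarray(x, dtype=float))
        .rolling(w, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def bandpass(x: np.ndarray, fs: float, band: tuple[float, float] = DEFAULT_BAND, order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth bandpass."""
    lo, hi = band
    if not 0.0 < lo < hi < fs / 2.0:
        raise ValueError(f"band {band} must lie inside (0, fs/2)")
    sos = sps.butter(order, band, btype="band", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def estimate_ac(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float] = DEFAULT_BAND,
    window: float = DEFAULT_WINDOW,
    order: int = 3,
) -> np.ndarray:
    """Pulsatile amplitude: bandpass then centered moving SD.

    For an in-band sinusoid of peak amplitude A the output approaches its
    RMS, A/√2.
    """
    filtered = bandpass(x, fs, band, order)
    w = int(round(window * fs))
    return (
        pd.Series(filtered)
        .rolling(w, center=True, min_periods=max(2, w // 4))
        .std(ddof=0)
        .to_numpy()
    )


@dataclass
class PerfusionFeatures:
    """Per-channel baseline, amplitude and perfusion plus modulation ratio.

    Arrays are aligned 1:1 with the record's sample times.  ``r`` is
    red-over-infrared perfusion; ``r_valid`` marks points where the
    infrared perfusion was large enough for the ratio to be meaningful.
    """

    t: np.ndarray
    dc: dict[str, np.ndarray]
    ac: dict[str, np.ndarray]
    perfusion: dict[str, np.ndarray]
    r: np.ndarray
    r_valid: np.ndarray


def modulation_ratio(
    perfusion_red: np.ndarray,
    perfusion_infrared: np.ndarray,
    floor: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise R = perfusion_red / perfusion_infrared with a validity
    mask; near-zero infrared perfusion marks the point invalid instead of
    raising."""
    pir = np.asarray(perfusion_infrared, dtype=float)
    pred = np.asarray(perfusion_red, dtype=float)
    valid = np.isfinite(pir) & np.isfinite(pred) & (pir > floor)
    r = np.full(pir.shape, np.nan)
    np.divide(pred, pir, out=r, where=valid)
    return r, valid


def compute_features(
    record: PPGRecord,
    band: tuple[float, float] = DEFAULT_BAND,
    window: float = DEFAULT_WINDOW,
) -> PerfusionFeatures:
    """Run the full AC/DC/perfusion/R extraction on a record."""
    dc: dict[str, np.ndarray] = {}
    ac: dict[str, np.ndarray] = {}
    perf: dict[str, np.ndarray] = {}
    for name in ("red", "infrared", "green"):
        x = getattr(record, name)
        dc[name] = estimate_dc(x, record.fs, window)
        ac[name] = estimate_ac(x, record.fs, band, window)
        perf[name] = ac[name] / dc[name]
    r, valid = modulation_ratio(perf["red"], perf["infrared"])
    return PerfusionFeatures(t=record.t, dc=dc, ac=ac, perfusion=perf, r=r, r_valid=valid)


@dataclass(frozen=True)
class RatioCalibration:
    """Linear map SpO2 = intercept + slope·R with fit diagnostics."""

    intercept: float  # %
    slope: float  # % per unit R
    residual_sd: float  # %
    n: int

    def __call__(self, r):
        return spo2_from_ratio(r, self)


def fit_ratio_calibration(r_values, reference_sao2) -> RatioCalibration:
    """OLS of reference saturation (%) on modulation ratio.

    Requires at least 10 finite pairs spanning 15 or more saturation
    points so the fitted line is identified over the clinical range.
    """
    r = np.asarray(r_values, dtype=float)
    y = np.asarray(reference_sao2, dtype=float)
    keep = np.isfinite(r) & np.isfinite(y)
    r, y = r[keep], y[keep]
    if len(r) < 10:
        raise ValueError("calibration needs at least 10 valid (R, SaO2) pairs")
    if y.max() - y.min() < 15.0:
        raise ValueError("calibration references must span at least 15 saturation points")
    if np.ptp(r) == 0:
        raise ValueError("degenerate calibration: constant modulation ratio")
    slope, intercept = np.polyfit(r, y, 1)
    resid = y - (intercept + slope * r)
    return RatioCalibration(
        intercept=float(intercept),
        slope=float(slope),
        residual_sd=float(np.std(resid, ddof=2)) if len(r) > 2 else 0.0,
        n=int(len(r)),
    )


def spo2_from_ratio(r, calibration: RatioCalibration):
    """Apply the calibration; output clipped to [50, 100]%, NaN-in NaN-out."""
    r_arr = np.asarray(r, dtype=float)
    out = calibration.intercept + calibration.slope * r_arr
    out = np.where(np.isfinite(r_arr), np.clip(out, 50.0, 100.0), np.nan)
    return float(out) if out.ndim == 0 else out
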