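"""Conclusiveness gating: worn, stillness and signal-quality checks.

A saturation reading is only reported when three gates pass, mirroring
how wrist devices reject measurements: (1) the watch is worn — there is
a pulse on the PPG (adequate infrared perfusion plus a dominant cardiac
spectral peak); (2) the user is still — the accelerometer shows no
variation; (3) the window is not classified as poor signal quality by
the learned classifier.  Failures are reported with a fixed precedence
(not worn > motion > poor signal) so each window carries exactly one
status.

Thresholds are package defaults calibrated once on synthetic fixtures;
all are plumbed through :class:`GateThresholds`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

CONCLUSIVE = "conclusive"
POOR_SIGNAL = "poor_signal"
MOTION = "motion"
NOT_WORN = "not_worn"

STATUSES = (CONCLUSIVE, POOR_SIGNAL, MOTION, NOT_WORN)


@dataclass(frozen=True)
class GateThresholds:
    """Default gate parameters.

    perfusion_floor : minimum mean infrared AC/DC for a wearable pulse
        (wrist perfusion is ~1-2%; 0.2% means effectively no pulse).
    peak_ratio_min : required ratio of the cardiac-band spectral peak to
        the median in-band power.
    acc_sd_max : maximum per-axis accelerometer SD (g) for stillness.
    cardiac_band : Hz range searched for the pulse peak.
    """

    perfusion_floor: float = 0.002
    peak_ratio_min: float = 6.0
    acc_sd_max: float = 0.04
    cardiac_band: tuple[float, float] = (0.5, 2.5)


@dataclass(frozen=True)
class QualityLabel:
    """Gating outcome for one window with its diagnostics."""

    status: str
    perfusion: float
    acc_sd: float
    quality_prob: float

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")

    @property
    def conclusive(self) -> bool:
        return self.status == CONCLUSIVE


def detect_worn(
    infrared_window: np.ndarray,
    fs: float,
    mean_ir_perfusion: float,
    thresholds: GateThresholds = GateThresholds(),
) -> bool:
    """Pulse-presence check on the raw infrared window.

    Worn iff the mean infrared perfusion clears the floor AND the
    Welch spectrum shows a dominant peak in the cardiac band (peak power
    at least ``peak_ratio_min`` times the in-band median).  Welch
    averaging over ~4-s segments tightens the broadband-noise null so a
    single threshold separates a pulse from sensor noise.
    """
    if not np.isfinite(mean_ir_perfusion) or mean_ir_perfusion < thresholds.perfusion_floor:
        return False
    x = np.asarray(infrared_window, dtype=float)
    x = x - x.mean()
    if np.allclose(x, 0.0):
        return False
    nperseg = min(len(x), int(round(4.0 * fs)))
    freqs, power = sps.welch(x, fs=fs, nperseg=nperseg, detrend="linear")
    lo, hi = thresholds.cardiac_band
    band = (freqs >= lo) & (freqs <= hi)
    if not band.any():
        return False
    in_band = power[band]
    med = np.median(in_band)
    if med <= 0:
        return in_band.max() > 0
    return bool(in_band.max() / med >= thresholds.peak_ratio_min)


def detect_still(acc_window: np.ndarray, threshold: float = GateThresholds().acc_sd_max) -> bool:
    """Stillness check: every axis SD below the threshold (in g)."""
    acc = np.atleast_2d(np.asarray(acc_window, dtype=float))
    return bool(np.max(np.std(acc, axis=-1)) < threshold)


def gate(
    *,
    infrared_window: np.ndarray,
    acc_window: np.ndarray,
    fs: float,
    mean_ir_perfusion: float,
    quality_prob: float,
    poor_quality_threshold: float = 0.5,
    thresholds: GateThresholds = GateThresholds(),
) -> QualityLabel:
    """Combine the three checks under not_worn > motion > poor_signal."""
    acc_sd = float(np.max(np.std(np.atleast_2d(acc_window), axis=-1)))
    diag = dict(perfusion=float(mean_ir_perfusion), acc_sd=acc_sd, quality_prob=float(quality_prob))
    if not detect_worn(infrared_window, fs, mean_ir_perfusion, thresholds):
        return QualityLabel(status=NOT_WORN, **diag)
    if not detect_still(acc_window, thresholds.acc_sd_max):
        return QualityLabel(status=MOTION, **diag)
    if quality_prob >= poor_quality_threshold:
        return QualityLabel(status=POOR_SIGNAL, **diag)
    return QualityLabel(status=CONCLUSIVE, **diag)


def summarize_conclusiveness(labels: list[QualityLabel] | list[str]) -> dict:
    """Counts and one-decimal percentages per status.

    Accepts QualityLabel objects or bare status strings; raises on an
    empty list (no denominator).
    """
    if not labels:
        raise ValueError("no labels to summarize")
    statuses = [lab.status if isinstance(lab, QualityLabel) else lab for lab in labels]
    counts = Counter(statuses)
    total = len(statuses)
    return {
        "total": total,
        "counts": {s: counts.get(s, 0) for s in STATUSES},
        "percent": {s: round(100.0 * counts.get(s, 0) / total, 1) for s in STATUSES},
    }
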