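"""Direct SpO2 regression from 8-second PPG windows, signal-quality
classification with the same topology, and linear fusion with the
ratio-of-ratios path.

Windows are the three LED channels, each standardized by its own moving
baseline (subtract DC, divide by DC) so the network sees relative
pulsatile waveforms regardless of skin attenuation or LED drive level.
The regressor maps a window to a saturation estimate; the classifier
maps it to a probability that the window is of poor signal quality
(labels come from the simulator's artifact ground truth).  A final
ordinary-least-squares fusion merges the ratio-path estimate and the
network estimate into one output.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nnet
from .dsp import estimate_dc
from .synth import PPGRecord

WINDOW_SECONDS = 8.0
SPO2_CENTER = 85.0  # regression target normalization: y' = (y - 85) / 15
SPO2_SCALE = 15.0


@dataclass
class Windows:
    """A batch of standardized 8-s windows cut from one record.

    values : (n, 3, L) float array, channel order red/infrared/green.
    t_start : window start times (s) in the record's time base.
    flagged : True where the window overlaps a masked/invalid region.
    fs : sampling rate the windows were cut at.
    """

    values: np.ndarray
    t_start: np.ndarray
    flagged: np.ndarray
    fs: float

    def __len__(self) -> int:
        return len(self.values)

    @property
    def t_center(self) -> np.ndarray:
        return self.t_start + WINDOW_SECONDS / 2.0


def make_windows(
    record: PPGRecord,
    stride: float = 2.0,
    *,
    mask: np.ndarray | None = None,
    dc_window: float = 2.0,
) -> Windows:
    """Cut overlapping standardized windows from a record.

    ``mask`` (optional, per-sample boolean, True = invalid) flags any
    window that overlaps an invalid sample.  Raises if the record is
    shorter than one window.
    """
    n_win = int(round(WINDOW_SECONDS * record.fs))
    n = len(record)
    if n < n_win:
        raise ValueError("record shorter than one 8-second window")
    step = max(1, int(round(stride * record.fs)))
    starts = np.arange(0, n - n_win + 1, step)

    channels = []
    for name in ("red", "infrared", "green"):
        x = getattr(record, name)
        dc = estimate_dc(x, record.fs, dc_window)
        channels.append((x - dc) / dc)
    norm = np.stack(channels)  # (3, n)

    values = np.stack([norm[:, s : s + n_win] for s in starts])
    flagged = np.zeros(len(starts), dtype=bool)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        flagged = np.array([mask[s : s + n_win].any() for s in starts])
    return Windows(
        values=values,
        t_start=record.t0 + starts / record.fs,
        flagged=flagged,
        fs=record.fs,
    )


@dataclass(frozen=True)
class NetworkSpec:
    """Topology of the small 1D conv net (shared by both heads)."""

    kernel: int = 5
    channels: tuple[int, ...] = (8, 16, 32)
    stride: int = 2
    head: str = "regression"  # or "classification"

    def build(self, in_channels: int = 3, seed: int = 0) -> nnet.Sequential:
        rng = np.random.default_rng(seed)
        layers: list[nnet.Layer] = []
        prev = in_channels
        for ch in self.channels:
            layers.append(nnet.Conv1d(prev, ch, self.kernel, self.stride, rng))
            layers.append(nnet.ReLU())
            prev = ch
        layers.append(nnet.GlobalAvgPool())
        layers.append(nnet.Dense(prev, 1, rng))
        net = nnet.Sequential(layers)
        if net.param_count() >= 50_000:
            raise ValueError("network exceeds the 50k-parameter budget")
        return net


@dataclass
class SpO2Regressor:
    spec: NetworkSpec
    net: nnet.Sequential
    history: dict = field(default_factory=dict)

    def predict(self, windows: Windows | np.ndarray) -> np.ndarray:
        x = windows.values if isinstance(windows, Windows) else np.asarray(windows)
        if x.ndim == 2:
            x = x[None]
        raw = self.net.forward(x)[:, 0]
        return np.clip(SPO2_CENTER + SPO2_SCALE * raw, 50.0, 100.0)


@dataclass
class QualityClassifier:
    spec: NetworkSpec
    net: nnet.Sequential
    threshold: float = 0.5
    history: dict = field(default_factory=dict)

    def predict_proba(self, windows: Windows | np.ndarray) -> np.ndarray:
        x = windows.values if isinstance(windows, Windows) else np.asarray(windows)
        if x.ndim == 2:
            x = x[None]
        return nnet.sigmoid(self.net.forward(x)[:, 0])

    def predict(self, windows) -> np.ndarray:
        """True where the window is classified poor-quality."""
        return self.predict_proba(windows) >= self.threshold


def train_regressor(
    spec: NetworkSpec,
    x: np.ndarray,
    y_spo2: np.ndarray,
    *,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    epochs: int = 30,
    batch_size: int = 128,
    lr: float = 2e-3,
    seed: int = 0,
) -> SpO2Regressor:
    """Fit the direct SpO2 regressor on labeled windows.

    ``y_spo2`` are reference saturations in percent (ground-truth
    trajectory interpolated at window centers).  Deterministic under a
    fixed seed.
    """
    if len(x) == 0:
        raise ValueError("empty training set")
    net = spec.build(in_channels=x.shape[1], seed=seed)
    yn = (np.asarray(y_spo2, dtype=float)[:, None] - SPO2_CENTER) / SPO2_SCALE
    yv = None if y_val is None else (np.asarray(y_val, dtype=float)[:, None] - SPO2_CENTER) / SPO2_SCALE
    history = nnet.fit(
        net, x, yn, loss="mse", x_val=x_val, y_val=yv,
        epochs=epochs, batch_size=batch_size, lr=lr, seed=seed + 1,
    )
    return SpO2Regressor(spec=spec, net=net, history=history)


def predict_window(regressor: SpO2Regressor, window: np.ndarray) -> float:
    """Saturation estimate (%) for a single standardized window."""
    return float(regressor.predict(window)[0])


def train_quality_classifier(
    spec: NetworkSpec,
    x: np.ndarray,
    poor: np.ndarray,
    *,
    x_val: np.ndarray | None = None,
    poor_val: np.ndarray | None = None,
    epochs: int = 30,
    batch_size: int = 128,
    lr: float = 2e-3,
    seed: int = 0,
) -> QualityClassifier:
    """Fit the poor-signal classifier; labels True = poor quality.

    The decision threshold is chosen on the validation set (maximum
    Youden index over a probability grid); with no validation set it
    stays at 0.5.
    """
    poor = np.asarray(poor, dtype=float)
    if len(np.unique(poor)) < 2:
        raise ValueError("quality training set must contain both classes")
    cls_spec = NetworkSpec(kernel=spec.kernel, channels=spec.channels, stride=spec.stride,
                           head="classification")
    net = cls_spec.build(in_channels=x.shape[1], seed=seed)
    yv = None if poor_val is None else np.asarray(poor_val, dtype=float)[:, None]
    history = nnet.fit(
        net, x, poor[:, None], loss="bce", x_val=x_val, y_val=yv,
        epochs=epochs, batch_size=batch_size, lr=lr, seed=seed + 1,
    )
    clf = QualityClassifier(spec=cls_spec, net=net, history=history)
    if x_val is not None and len(x_val) and len(np.unique(poor_val)) == 2:
        proba = clf.predict_proba(x_val)
        pv = np.asarray(poor_val, dtype=bool)
        best_thr, best_j = 0.5, -np.inf
        for thr in np.linspace(0.05, 0.95, 19):
            pred = proba >= thr
            sens = (pred & pv).sum() / max(pv.sum(), 1)
            spec_ = (~pred & ~pv).sum() / max((~pv).sum(), 1)
            j = sens + spec_ - 1.0
            if j > best_j:
                best_j, best_thr = j, float(thr)
        clf.threshold = best_thr
    return clf


@dataclass(frozen=True)
class FusionModel:
    """Linear merge of the ratio-path and network estimates."""

    intercept: float
    w_ratio: float
    w_net: float
    fallback: bool = False  # True when collinearity forced a ratio-only fit


def fit_fusion(ratio_estimates, network_estimates, reference) -> FusionModel:
    """OLS of reference saturation on the two estimates (held-out data).

    If the two estimate series are collinear the two-predictor fit is
    unidentifiable; the model falls back to regressing on the ratio-path
    estimate alone and warns.
    """
    r = np.asarray(ratio_estimates, dtype=float)
    m = np.asarray(network_estimates, dtype=float)
    y = np.asarray(reference, dtype=float)
    keep = np.isfinite(r) & np.isfinite(m) & np.isfinite(y)
    r, m, y = r[keep], m[keep], y[keep]
    if len(y) < 3:
        raise ValueError("fusion needs at least 3 aligned calibration triples")
    X = np.column_stack([np.ones_like(r), r, m])
    collinear = np.ptp(r) == 0 or np.ptp(m) == 0
    if not collinear:
        rc = (r - r.mean()) / (r.std() or 1.0)
        mc = (m - m.mean()) / (m.std() or 1.0)
        collinear = abs(float(np.mean(rc * mc))) > 0.9999
    if collinear:
        warnings.warn("fusion inputs collinear; falling back to ratio path", stacklevel=2)
        slope, intercept = np.polyfit(r, y, 1)
        return FusionModel(intercept=float(intercept), w_ratio=float(slope), w_net=0.0, fallback=True)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return FusionModel(intercept=float(beta[0]), w_ratio=float(beta[1]), w_net=float(beta[2]))


def apply_fusion(model: FusionModel, ratio_estimate, network_estimate):
    """Pointwise fused estimate, clipped to [50, 100]%.

    A non-finite ratio estimate (invalid R) defers entirely to the
    network channel via the fallback-free linear form only when the
    model's ratio weight is zero; otherwise the point is NaN.
    """
    r = np.asarray(ratio_estimate, dtype=float)
    m = np.asarray(network_estimate, dtype=float)
    out = model.intercept + model.w_ratio * r + model.w_net * m
    out = np.where(np.isfinite(out), np.clip(out, 50.0, 100.0), np.nan)
    return float(out) if out.ndim == 0 else out


# --- portable checkpoints (JSON, no pickles) -------------------------------

def save_checkpoint(path: str | Path, *, regressor: SpO2Regressor,
                    classifier: QualityClassifier, fusion: FusionModel,
                    calibration, config_hash: str = "") -> None:
    """Write all trained components to one documented JSON container."""
    payload = {
        "format": "wristox-checkpoint-v1",
        "config_hash": config_hash,
        "normalization": {"spo2_center": SPO2_CENTER, "spo2_scale": SPO2_SCALE},
        "regressor": {
            "spec": {"kernel": regressor.spec.kernel, "channels": list(regressor.spec.channels),
                      "stride": regressor.spec.stride},
            "weights": [w.tolist() for w in regressor.net.state()],
        },
        "classifier": {
            "spec": {"kernel": classifier.spec.kernel, "channels": list(classifier.spec.channels),
                      "stride": classifier.spec.stride},
            "threshold": classifier.threshold,
            "weights": [w.tolist() for w in classifier.net.state()],
        },
        "fusion": {"intercept": fusion.intercept, "w_ratio": fusion.w_ratio,
                    "w_net": fusion.w_net, "fallback": fusion.fallback},
        "ratio_calibration": {"intercept": calibration.intercept, "slope": calibration.slope,
                               "residual_sd": calibration.residual_sd, "n": calibration.n},
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path: str | Path):
    """Load a checkpoint; returns (regressor, classifier, fusion, calibration)."""
    from .dsp import RatioCalibration

    raw = json.loads(Path(path).read_text())
    if raw.get("format") != "wristox-checkpoint-v1":
        raise ValueError("unrecognized checkpoint format")

    def revive(section, head):
        spec = NetworkSpec(kernel=section["spec"]["kernel"],
                           channels=tuple(section["spec"]["channels"]),
                           stride=section["spec"]["stride"], head=head)
        net = spec.build(in_channels=3, seed=0)
        net.load_state([np.asarray(w) for w in section["weights"]])
        return spec, net

    rspec, rnet = revive(raw["regressor"], "regression")
    cspec, cnet = revive(raw["classifier"], "classification")
    regressor = SpO2Regressor(spec=rspec, net=rnet)
    classifier = QualityClassifier(spec=cspec, net=cnet, threshold=raw["classifier"]["threshold"])
    fusion = FusionModel(**raw["fusion"])
    calibration = RatioCalibration(**raw["ratio_calibration"])
    return regressor, classifier, fusion, calibration
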