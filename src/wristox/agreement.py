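"""Device-vs-reference agreement statistics for oximeter validation.

Implements the validation pipeline used in controlled hypoxia studies:
cross-correlation lag estimation between the device saturation series
and the co-oximeter references, plateau matching (pairing each blood
draw with the average of conclusive device readings in a window around
the lag-corrected draw time), bias and Arms (RMS error) with a 95% CI on
the bias, stratified accuracy over the standard saturation ranges (≤80,
80-90, >90%), Bland-Altman limits of agreement, Pearson association,
and the arithmetic accuracy gates used for regulatory review (Arms
≤ 3.5% / ≤ 4.0%, at least 200 pairs from at least 10 subjects).

Sign convention throughout: a negative lag means the device lags behind
the co-oximeter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

STRATA = ("<=80", "80-90", ">90")


@dataclass(frozen=True)
class PairedMeasurement:
    """One blood draw matched to lag-corrected conclusive device output."""

    t_ref: float
    sao2: float
    spo2: float
    wrist: str
    subject_id: int
    stratum: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "stratum", assign_stratum(self.spo2))


def assign_stratum(spo2: float) -> str:
    """Boundary convention: inclusive upper bounds (80 → first stratum,
    90 → middle stratum)."""
    if spo2 <= 80.0:
        return STRATA[0]
    if spo2 <= 90.0:
        return STRATA[1]
    return STRATA[2]


def estimate_lag(
    device: np.ndarray,
    reference: np.ndarray,
    fs: float,
    max_lag: float = 30.0,
) -> float:
    """Cross-correlation lag between two series on a common uniform grid.

    Returns the shift (s) in [-max_lag, max_lag] maximizing the
    normalized cross-correlation of ``device(t)`` against
    ``reference(t + lag)``; negative = device lags the reference.
    Raises on flat input (correlation undefined).
    """
    d = np.asarray(device, dtype=float)
    r = np.asarray(reference, dtype=float)
    if np.ptp(d[np.isfinite(d)]) == 0 or np.ptp(r[np.isfinite(r)]) == 0:
        raise ValueError("flat series: lag undefined")
    n = min(len(d), len(r))
    if n < 4 * int(max_lag * fs):
        raise ValueError("overlap too short for the requested max_lag")
    d, r = d[:n].copy(), r[:n].copy()
    for x in (d, r):
        bad = ~np.isfinite(x)
        if bad.any():
            x[bad] = np.interp(np.flatnonzero(bad), np.flatnonzero(~bad), x[~bad])
    max_shift = int(round(max_lag * fs))
    best_lag, best_c = 0.0, -np.inf
    for k in range(-max_shift, max_shift + 1):
        # device(t) vs reference(t + lag), lag = k / fs
        if k >= 0:
            a, b = d[: n - k], r[k:]
        else:
            a, b = d[-k:], r[: n + k]
        if len(a) < 8 or np.ptp(a) == 0 or np.ptp(b) == 0:
            continue
        c = np.corrcoef(a, b)[0, 1]
        if c > best_c:
            best_c, best_lag = c, k / fs
    return float(best_lag)


def pair_measurements(
    times: np.ndarray,
    spo2: np.ndarray,
    conclusive: np.ndarray,
    samples,
    lag: float,
    pairing_halfwidth: float = 15.0,
    *,
    wrist: str = "",
    subject_id: int = -1,
) -> tuple[list[PairedMeasurement], int]:
    """Plateau matching: average conclusive readings around each draw.

    For a blood draw at reference time t, the matching device interval
    is centered at t - lag (negative lag = device later), halfwidth
    ``pairing_halfwidth`` seconds.  Draws with no conclusive reading in
    their window are dropped; returns (pairs, dropped_count).
    """
    times = np.asarray(times, dtype=float)
    spo2 = np.asarray(spo2, dtype=float)
    conclusive = np.asarray(conclusive, dtype=bool)
    pairs: list[PairedMeasurement] = []
    dropped = 0
    for sample in samples:
        center = sample.t - lag
        sel = (
            conclusive
            & np.isfinite(spo2)
            & (np.abs(times - center) <= pairing_halfwidth)
        )
        if not sel.any():
            dropped += 1
            continue
        pairs.append(
            PairedMeasurement(
                t_ref=float(sample.t),
                sao2=float(sample.sao2),
                spo2=float(np.mean(spo2[sel])),
                wrist=wrist,
                subject_id=subject_id,
            )
        )
    return pairs, dropped


def bias_rmse(pairs, *, use_t: bool = False) -> dict:
    """Bias, Arms and the 95% CI of the bias for a pair list.

    error = spo2 - sao2; bias = mean error; Arms = sqrt(mean error²);
    CI = bias ± 1.96·SD/√n with SD = sqrt(Arms² - bias²) (population SD,
    the identity form used when reconstructing CIs from printed
    summaries).  ``use_t`` swaps 1.96 for the t critical value.
    """
    errors = np.array([p.spo2 - p.sao2 for p in pairs], dtype=float)
    n = len(errors)
    if n < 2:
        raise ValueError("bias CI needs at least 2 pairs")
    bias = float(np.mean(errors))
    rmse = float(np.sqrt(np.mean(errors**2)))
    sd = float(np.sqrt(max(rmse**2 - bias**2, 0.0)))
    crit = float(sstats.t.ppf(0.975, n - 1)) if use_t else 1.96
    half = crit * sd / np.sqrt(n)
    return {
        "n": n,
        "bias": bias,
        "rmse": rmse,
        "bias_ci": (bias - half, bias + half),
    }


def bias_ci_from_summary(bias: float, rmse: float, n: int) -> tuple[float, float]:
    """Reconstruct the 95% bias CI from printed (bias, Arms, n)."""
    sd = np.sqrt(max(rmse**2 - bias**2, 0.0))
    half = 1.96 * sd / np.sqrt(n)
    return (bias - half, bias + half)


def stratify(pairs) -> dict:
    """Per-stratum n/bias/rmse, stratified on the device value."""
    out: dict = {}
    for stratum in STRATA:
        sub = [p for p in pairs if p.stratum == stratum]
        if len(sub) >= 2:
            out[stratum] = bias_rmse(sub)
        else:
            errors = [p.spo2 - p.sao2 for p in sub]
            out[stratum] = {
                "n": len(sub),
                "bias": float(np.mean(errors)) if sub else float("nan"),
                "rmse": float(np.sqrt(np.mean(np.square(errors)))) if sub else float("nan"),
                "bias_ci": (float("nan"), float("nan")),
            }
    return out


def bland_altman(pairs) -> dict:
    """Mean difference, 95% limits of agreement and proportional-bias r.

    Differences d = spo2 - sao2 plotted against pair means; limits of
    agreement are mean(d) ± 1.96·SD(d) with the n-1 sample SD; the
    difference-vs-mean Pearson r (with two-sided p) quantifies whether
    the error grows with the measured level.
    """
    if len(pairs) < 3:
        raise ValueError("Bland-Altman needs at least 3 pairs")
    d = np.array([p.spo2 - p.sao2 for p in pairs], dtype=float)
    m = np.array([(p.spo2 + p.sao2) / 2.0 for p in pairs], dtype=float)
    mean_d = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    if np.ptp(d) == 0 or np.ptp(m) == 0:
        r_val, p_val = float("nan"), float("nan")
    else:
        r_val, p_val = (float(v) for v in sstats.pearsonr(d, m))
    return {
        "mean_diff": mean_d,
        "loa_lower": mean_d - 1.96 * sd_d,
        "loa_upper": mean_d + 1.96 * sd_d,
        "r": r_val,
        "p": p_val,
    }


def pearson_agreement(pairs) -> tuple[float, float]:
    """Pearson r (and two-sided p) of device vs reference saturation."""
    x = np.array([p.spo2 for p in pairs], dtype=float)
    y = np.array([p.sao2 for p in pairs], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r_val, p_val = sstats.pearsonr(x, y)
    return float(r_val), float(p_val)


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a correlation via the t transform,
    t = r·√(n-2)/√(1-r²) on n-2 degrees of freedom."""
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    return float(2.0 * sstats.t.sf(abs(t), n - 2))


@dataclass
class AccuracyReport:
    """Full validation summary for one wrist."""

    wrist: str
    n_pairs: int
    n_dropped: int
    bias: float
    bias_ci: tuple[float, float]
    rmse: float
    strata: dict
    pearson_r: float
    pearson_p: float
    bland_altman: dict
    lag_mean: float
    lag_median: float
    lag_sd: float

    def to_dict(self) -> dict:
        return {
            "wrist": self.wrist,
            "n_pairs": self.n_pairs,
            "n_dropped": self.n_dropped,
            "bias": round(self.bias, 2),
            "bias_ci": [round(v, 2) for v in self.bias_ci],
            "rmse": round(self.rmse, 2),
            "strata": {
                k: {
                    "n": v["n"],
                    "bias": round(v["bias"], 2),
                    "rmse": round(v["rmse"], 2),
                }
                for k, v in self.strata.items()
            },
            "pearson_r": round(self.pearson_r, 3),
            "pearson_p": round(self.pearson_p, 4),
            "bland_altman": {k: round(v, 3) for k, v in self.bland_altman.items()},
            "lag_mean": round(self.lag_mean, 2),
            "lag_median": round(self.lag_median, 2),
            "lag_sd": round(self.lag_sd, 2),
        }


def build_report(pairs, lags, wrist: str, n_dropped: int = 0) -> AccuracyReport:
    """Assemble the per-wrist accuracy report from pairs and lags."""
    overall = bias_rmse(pairs)
    r_val, p_val = pearson_agreement(pairs)
    lags = np.asarray(list(lags), dtype=float)
    return AccuracyReport(
        wrist=wrist,
        n_pairs=overall["n"],
        n_dropped=n_dropped,
        bias=overall["bias"],
        bias_ci=overall["bias_ci"],
        rmse=overall["rmse"],
        strata=stratify(pairs),
        pearson_r=r_val,
        pearson_p=p_val,
        bland_altman=bland_altman(pairs),
        lag_mean=float(np.mean(lags)),
        lag_median=float(np.median(lags)),
        lag_sd=float(np.std(lags, ddof=1)) if len(lags) > 1 else 0.0,
    )


def compliance_check(rmse: float, n_pairs: int, n_subjects: int) -> dict:
    """Arithmetic accuracy gates cited for reflectance oximeters.

    arms_fda: Arms ≤ 3.5%; arms_iso: Arms ≤ 4.0%; plus the minimum
    evidence base of 200 pairs from 10 subjects.  These are threshold
    checks only, not a regulatory claim.
    """
    return {
        "arms_fda": bool(rmse <= 3.5),
        "arms_iso": bool(rmse <= 4.0),
        "enough_pairs": bool(n_pairs >= 200),
        "enough_subjects": bool(n_subjects >= 10),
    }


def plot_agreement(pairs, path, title: str = "") -> None:
    """Correlation and Bland-Altman panels with best-fit lines (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.array([p.sao2 for p in pairs])
    y = np.array([p.spo2 for p in pairs])
    d = y - x
    m = (x + y) / 2.0
    ba = bland_altman(pairs)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ax1.scatter(x, y, s=8, alpha=0.6)
    lims = [min(x.min(), y.min()) - 2, max(x.max(), y.max()) + 2]
    ax1.plot(lims, lims, "k--", lw=1)
    b, a = np.polyfit(x, y, 1)
    ax1.plot(lims, a + b * np.asarray(lims), "r-", lw=1, label="best fit")
    ax1.set_xlabel("reference SaO2 (%)")
    ax1.set_ylabel("device SpO2 (%)")
    ax1.legend()
    ax2.scatter(m, d, s=8, alpha=0.6)
    for level, style in ((ba["mean_diff"], "-"), (ba["loa_lower"], "--"), (ba["loa_upper"], "--")):
        ax2.axhline(level, color="r", ls=style, lw=1)
    ax2.set_xlabel("mean of methods (%)")
    ax2.set_ylabel("difference SpO2 - SaO2 (%)")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
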