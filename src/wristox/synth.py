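"""Synthesis of realistic multichannel wrist PPG with accelerometer.

Each optical channel is modeled as a large DC level (scaled by a skin
attenuation factor standing in for pigmentation and coupling) modulated by
a small cardiac pulsatile term, a weaker respiratory term, additive sensor
noise, and occasional high-amplitude motion bursts shared with the
accelerometer.  The cardiac modulation depth of the red and infrared
channels follows the Beer-Lambert mixture extinction at the instantaneous
arterial saturation, normalized so that the infrared perfusion equals the
subject's ``perfusion_scale``; the green channel pulses with a fixed,
saturation-independent depth (it carries no oximetric information and is
used downstream only as a denoising reference).

Wrist reflectance perfusion is low (AC/DC on the order of 1-2%), which is
what makes the estimation problem interesting; defaults reflect that.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .optics import GREEN, INFRARED, RED, OpticalConstants, analytic_modulation_ratio


@dataclass
class SubjectParams:
    """Per-subject physiology and artifact parameters.

    heart_rate : bpm, must lie in [40, 180].
    respiratory_rate : breaths/min.
    perfusion_scale : baseline infrared AC/DC (dimensionless), > 0.
    skin_attenuation : DC multiplier in (0, 1]; lower = darker skin or
        poorer optical coupling.
    motion_rate : expected motion bursts per minute.
    noise_sd : additive sensor noise SD as a fraction of channel DC.
    """

    heart_rate: float = 75.0
    respiratory_rate: float = 15.0
    perfusion_scale: float = 0.02
    skin_attenuation: float = 0.8
    motion_rate: float = 0.5
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if not 40.0 <= self.heart_rate <= 180.0:
            raise ValueError("heart_rate must lie in [40, 180] bpm")
        if self.perfusion_scale <= 0:
            raise ValueError("perfusion_scale must be positive")
        if not 0.0 < self.skin_attenuation <= 1.0:
            raise ValueError("skin_attenuation must lie in (0, 1]")
        if self.motion_rate < 0 or self.noise_sd < 0:
            raise ValueError("motion_rate and noise_sd must be non-negative")


@dataclass
class PPGRecord:
    """Uniformly sampled optical and accelerometer traces.

    Optical channels are light intensities in arbitrary units (strictly
    positive); accelerometer axes are in g.  All channels share the same
    length and sampling rate.  ``meta`` carries ground truth needed by
    tests and training: the saturation trajectory (device time base),
    motion-burst intervals, the seed, and subject parameters.
    """

    fs: float
    t0: float
    red: np.ndarray
    infrared: np.ndarray
    green: np.ndarray
    acc_x: np.ndarray
    acc_y: np.ndarray
    acc_z: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        n = len(self.red)
        for ch in (self.infrared, self.green, self.acc_x, self.acc_y, self.acc_z):
            if len(ch) != n:
                raise ValueError("all channels must have equal length")

    def __len__(self) -> int:
        return len(self.red)

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.fs

    @property
    def duration(self) -> float:
        return len(self) / self.fs

    def optical(self) -> np.ndarray:
        """(3, n) array in package channel order red/infrared/green."""
        return np.stack([self.red, self.infrared, self.green])

    def acc(self) -> np.ndarray:
        return np.stack([self.acc_x, self.acc_y, self.acc_z])


def cardiac_waveform(t: np.ndarray, heart_rate: float, phase: float = 0.0) -> np.ndarray:
    """Asymmetric periodic pulse (fundamental + one harmonic), unit SD.

    The harmonic makes systolic upstroke steeper than the decay, so that
    bandpass + moving-SD amplitude estimation is exercised on a non-pure
    tone.  Normalized to unit continuous-time standard deviation so a
    modulation depth m yields a measured perfusion (AC/DC) of m.
    """
    w = 2.0 * np.pi * heart_rate / 60.0
    raw = np.sin(w * t + phase) + 0.35 * np.sin(2.0 * w * t + 2.0 * phase + 1.0)
    return raw / np.sqrt(0.5 * (1.0 + 0.35**2))


def _draw_motion_bursts(
    rng: np.random.Generator,
    duration: float,
    rate_per_min: float,
    length_range: tuple[float, float],
) -> list[tuple[float, float]]:
    """Poisson burst arrivals; returns sorted (start, end) intervals."""
    if rate_per_min <= 0:
        return []
    n = rng.poisson(rate_per_min * duration / 60.0)
    starts = np.sort(rng.uniform(0.0, duration, size=n))
    lengths = rng.uniform(*length_range, size=n)
    return [(float(s), float(min(s + L, duration))) for s, L in zip(starts, lengths)]


def _burst_envelope(t: np.ndarray, bursts: list[tuple[float, float]]) -> np.ndarray:
    """Raised-cosine envelope, 1 inside bursts with 0.25 s tapers."""
    env = np.zeros_like(t)
    taper = 0.25
    for start, end in bursts:
        seg = np.clip((t - start) / taper, 0, 1) * np.clip((end - t) / taper, 0, 1)
        env = np.maximum(env, np.clip(seg, 0, 1))
    return env


def synthesize_ppg(
    subject: SubjectParams,
    sao2_t: np.ndarray,
    sao2_s: np.ndarray,
    constants: OpticalConstants | None = None,
    fs: float = 25.0,
    duration: float | None = None,
    seed: int = 0,
    *,
    dc_level: float = 1000.0,
    resp_amplitude: float = 0.005,
    green_pulse_ratio: float = 1.2,
    burst_length_range: tuple[float, float] = (1.0, 5.0),
    burst_optical_gain: float = 10.0,
    acc_noise_sd: float = 0.01,
    acc_burst_sd: float = 0.5,
) -> PPGRecord:
    """Render a PPG record for a saturation trajectory.

    Parameters
    ----------
    sao2_t, sao2_s
        Ground-truth saturation trajectory: times in seconds and values
        as fractions in [0, 1].  Linearly interpolated to the sample grid
        and clamped at the edges; must be finite.
    duration
        Record length in seconds; defaults to the trajectory span.
    seed
        Seeds every random draw; identical seeds give bit-identical
        records.

    Notes
    -----
    Motion bursts are Poisson-arriving 1-5 s disturbances injected into
    both the accelerometer and the optical channels; their intervals are
    recorded in ``meta['motion_bursts']`` as ground truth for gating.
    """
    if constants is None:
        constants = OpticalConstants.default()
    if fs < 10.0:
        raise ValueError("fs must be at least 10 Hz")
    sao2_t = np.asarray(sao2_t, dtype=float)
    sao2_s = np.asarray(sao2_s, dtype=float)
    if not np.all(np.isfinite(sao2_s)) or not np.all(np.isfinite(sao2_t)):
        raise ValueError("saturation trajectory must be finite")
    if duration is None:
        duration = float(sao2_t[-1] - sao2_t[0])
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)

    s = np.interp(t, sao2_t - sao2_t[0], sao2_s)
    s = np.clip(s, 0.0, 1.0)

    # Modulation depths: infrared pinned at perfusion_scale; red follows
    # the closed-form extinction ratio so the measured R is R(s).
    m_ir = subject.perfusion_scale
    m_red = m_ir * analytic_modulation_ratio(s, constants)
    m_green = m_ir * green_pulse_ratio

    phase = rng.uniform(0.0, 2.0 * np.pi)
    pulse = cardiac_waveform(t, subject.heart_rate, phase)
    resp_phase = rng.uniform(0.0, 2.0 * np.pi)
    resp = resp_amplitude * np.sin(2.0 * np.pi * subject.respiratory_rate / 60.0 * t + resp_phase)

    bursts = _draw_motion_bursts(rng, duration, subject.motion_rate, burst_length_range)
    env = _burst_envelope(t, bursts)

    # Shared low-frequency motion disturbance (tendon/coupling artifact).
    if bursts:
        raw_noise = rng.standard_normal(n)
        sos = sps.butter(2, min(5.0, 0.45 * fs), btype="low", fs=fs, output="sos")
        motion = sps.sosfilt(sos, raw_noise) * env
    else:
        motion = np.zeros(n)

    dc = dc_level * subject.skin_attenuation
    channels = {}
    for name, m in (("red", m_red), ("infrared", m_ir), ("green", m_green)):
        noise = subject.noise_sd * rng.standard_normal(n) if subject.noise_sd > 0 else 0.0
        x = dc * (1.0 + m * pulse + resp + burst_optical_gain * m_ir * motion + noise)
        # Intensities are physical light counts: floor at 1% of DC so
        # extreme burst excursions cannot drive them non-positive.
        channels[name] = np.maximum(x, 0.01 * dc)

    acc = np.zeros((3, n))
    acc[2] = 1.0  # gravity on z at rest
    if acc_noise_sd > 0:
        acc += acc_noise_sd * rng.standard_normal((3, n))
    if bursts:
        acc += acc_burst_sd * env * rng.standard_normal((3, n))

    meta = {
        "seed": int(seed),
        "fs": float(fs),
        "subject": subject,
        "motion_bursts": bursts,
        "truth_t": t.copy(),
        "truth_s": s.copy(),
    }
    return PPGRecord(
        fs=fs,
        t0=0.0,
        red=channels["red"],
        infrared=channels["infrared"],
        green=channels["green"],
        acc_x=acc[0],
        acc_y=acc[1],
        acc_z=acc[2],
        meta=meta,
    )
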