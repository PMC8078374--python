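"""Synthetic hypoxia-study generation.

A controlled desaturation study steps healthy volunteers through a series
of stable arterial-saturation plateaus (typically 92, 87, 82, 77 and 70%)
by adjusting inspired oxygen, drawing two arterial blood samples 30 s
apart on each plateau (and at room air at the start of each run) for
co-oximeter reference analysis.  Wrist devices on both arms record
optical and accelerometer traces throughout, with a device-vs-reference
time lag.  This module generates complete such studies: saturation
trajectories, blood-sample schedules with occasional skipped second
draws, per-subject device records on both wrists, and ground-truth lags —
plus standalone apnea/hypopnea-style desaturation traces.

Saturation values at this level are percentages (70-100); the optical
synthesizer works in fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .synth import PPGRecord, SubjectParams, synthesize_ppg
from .optics import OpticalConstants

#: plateau_index used for room-air baseline draws in BloodSample records.
BASELINE_PLATEAU = -1


@dataclass(frozen=True)
class HypoxiaProtocol:
    """Desaturation-plateau protocol parameters (times in seconds)."""

    plateau_targets: tuple[float, ...] = (92.0, 87.0, 82.0, 77.0, 70.0)
    plateau_duration: float = 75.0
    sample_separation: float = 30.0
    runs: int = 2
    recovery_duration: float = 120.0
    baseline_samples: int = 2
    baseline_duration: float = 75.0
    transition_duration: float = 45.0
    first_sample_offset: float = 10.0

    def __post_init__(self) -> None:
        if any(not 70.0 <= x <= 100.0 for x in self.plateau_targets):
            raise ValueError("plateau targets must lie in [70, 100] %")
        margin = self.first_sample_offset
        if self.plateau_duration < self.sample_separation + margin:
            raise ValueError("plateau too short for two draws plus margin")

    def max_samples_per_subject(self) -> int:
        stages = 1 + len(self.plateau_targets)  # baseline + plateaus, per run
        return self.runs * stages * 2


def default_protocol() -> HypoxiaProtocol:
    """Standard two-run, five-plateau protocol (targets 92…70%, 75 s
    plateaus, draws 30 s apart, room-air draws at the start of each run)."""
    return HypoxiaProtocol()


@dataclass(frozen=True)
class BloodSample:
    """One co-oximeter reference draw."""

    t: float
    sao2: float  # %, includes co-oximeter measurement noise
    run_index: int
    plateau_index: int  # BASELINE_PLATEAU for room-air draws

    def __post_init__(self) -> None:
        if not 50.0 <= self.sao2 <= 100.0:
            raise ValueError("sao2 out of plausible range [50, 100]")


@dataclass
class Stage:
    """A constant-target segment of the trajectory eligible for draws."""

    run_index: int
    plateau_index: int
    t_start: float
    t_end: float
    target: float


@dataclass
class Trajectory:
    t: np.ndarray
    sao2: np.ndarray  # %
    stages: list[Stage]

    def interp(self, times) -> np.ndarray:
        return np.interp(times, self.t, self.sao2)


def simulate_sao2_trajectory(
    protocol: HypoxiaProtocol,
    transition_tau: float = 20.0,
    seed: int = 0,
    *,
    dt: float = 0.5,
    baseline_sao2: float = 98.0,
    recovery_sao2: float = 99.0,
    jitter_amp_range: tuple[float, float] = (0.1, 0.3),
) -> Trajectory:
    """Piecewise plateau/transition saturation trajectory in percent.

    Transitions follow a normalized exponential with time constant
    ``transition_tau`` that reaches the target exactly at the end of the
    transition window (inspired gas changes abruptly; saturation follows
    physiologically).  Plateaus hold the target plus a slow sinusoidal
    jitter with amplitude well under the 1% stability criterion.
    """
    if transition_tau <= 0:
        raise ValueError("transition_tau must be positive")
    rng = np.random.default_rng(seed)
    pieces_t: list[np.ndarray] = []
    pieces_s: list[np.ndarray] = []
    stages: list[Stage] = []
    cursor = 0.0
    current = baseline_sao2

    def plateau(level: float, length: float, run: int, idx: int) -> None:
        nonlocal cursor, current
        tt = np.arange(0.0, length, dt)
        amp = rng.uniform(*jitter_amp_range)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        period = rng.uniform(30.0, 60.0)
        # keep the jitter inside the protocol's 70-100% range at the
        # extreme targets by recentering it against the nearer bound
        center = min(max(level, 70.0 + amp), 100.0 - amp)
        s = center + amp * np.sin(2.0 * np.pi * tt / period + phase)
        pieces_t.append(cursor + tt)
        pieces_s.append(s)
        stages.append(Stage(run, idx, cursor, cursor + length, level))
        cursor += length
        current = level

    def transition(target: float, length: float) -> None:
        nonlocal cursor, current
        tt = np.arange(0.0, length, dt)
        # normalized exponential: hits target exactly at t = length
        frac = (1.0 - np.exp(-tt / transition_tau)) / (1.0 - np.exp(-length / transition_tau))
        s = current + (target - current) * frac
        pieces_t.append(cursor + tt)
        pieces_s.append(s)
        cursor += length
        current = target

    for run in range(protocol.runs):
        if run == 0:
            plateau(baseline_sao2, protocol.baseline_duration, run, BASELINE_PLATEAU)
        else:
            transition(baseline_sao2, protocol.recovery_duration)
            plateau(baseline_sao2, protocol.baseline_duration, run, BASELINE_PLATEAU)
        for idx, target in enumerate(protocol.plateau_targets):
            transition(target, protocol.transition_duration)
            plateau(target, protocol.plateau_duration, run, idx)
    transition(recovery_sao2, protocol.recovery_duration)

    t = np.concatenate(pieces_t)
    s = np.concatenate(pieces_s)
    return Trajectory(t=t, sao2=np.clip(s, 50.0, 100.0), stages=stages)


def draw_blood_samples(
    trajectory: Trajectory,
    protocol: HypoxiaProtocol,
    coox_noise_sd: float = 0.3,
    seed: int = 0,
    *,
    skip_probability: float = 0.08,
) -> list[BloodSample]:
    """Schedule and value the reference draws for one subject.

    Two draws per stage (room-air baseline of each run, then each
    plateau), 30 s apart; the second draw is skipped with probability
    ``skip_probability``, standing in for plateaus destabilizing between
    draws.  Sample values are the true saturation at the draw time plus
    Gaussian co-oximeter noise.
    """
    if trajectory.stages and trajectory.t[-1] < trajectory.stages[-1].t_end - 1e-9:
        raise ValueError("trajectory does not cover its stage schedule")
    rng = np.random.default_rng(seed)
    samples: list[BloodSample] = []
    for stage in trajectory.stages:
        times = [stage.t_start + protocol.first_sample_offset]
        t2 = times[0] + protocol.sample_separation
        if t2 <= stage.t_end and rng.uniform() >= skip_probability:
            times.append(t2)
        for ts in times:
            value = trajectory.interp(ts)
            if coox_noise_sd > 0:
                value += coox_noise_sd * rng.standard_normal()
            samples.append(
                BloodSample(
                    t=float(ts),
                    sao2=float(np.clip(value, 50.0, 100.0)),
                    run_index=stage.run_index,
                    plateau_index=stage.plateau_index,
                )
            )
    return samples


@dataclass
class SubjectStudy:
    """One participant: params, both wrist records, truth, references."""

    subject_id: int
    params: SubjectParams
    trajectory: Trajectory
    samples: list[BloodSample]
    records: dict[str, PPGRecord]  # keys "right", "left"
    lags: dict[str, float]  # s; negative = device lags the co-oximeter


@dataclass
class HypoxiaStudy:
    protocol: HypoxiaProtocol
    subjects: list[SubjectStudy]
    seed: int

    def all_samples(self) -> list[BloodSample]:
        return [s for subj in self.subjects for s in subj.samples]


def _draw_subject_params(rng: np.random.Generator, motion_rate: float, noise_sd: float) -> SubjectParams:
    return SubjectParams(
        heart_rate=float(rng.uniform(55.0, 95.0)),
        respiratory_rate=float(rng.uniform(12.0, 18.0)),
        perfusion_scale=float(np.exp(rng.normal(np.log(0.02), 0.25))),
        skin_attenuation=float(rng.uniform(0.4, 1.0)),
        motion_rate=motion_rate,
        noise_sd=noise_sd,
    )


def simulate_study(
    n_subjects: int = 14,
    protocol: HypoxiaProtocol | None = None,
    lag_mean: float = -4.5,
    lag_sd: float = 9.5,
    seed: int = 0,
    *,
    fs: float = 25.0,
    constants: OpticalConstants | None = None,
    coox_noise_sd: float = 0.3,
    skip_probability: float = 0.08,
    motion_rate_right: float = 0.5,
    motion_rate_left: float = 1.2,
    noise_sd: float = 0.01,
    transition_tau: float = 20.0,
    max_lag: float = 30.0,
) -> HypoxiaStudy:
    """Generate a full two-wrist hypoxia validation study.

    Each wrist's device trace is synthesized from the subject's
    trajectory shifted by a lag drawn from Normal(lag_mean, lag_sd),
    truncated to ±``max_lag``; negative lag means the device lags the
    co-oximeter (the device at time t reflects the arterial state of
    time t + lag).  The left wrist gets a higher motion rate by default,
    reproducing the artifact asymmetry caused by blood draws from the
    left arm.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    if protocol is None:
        protocol = default_protocol()
    if constants is None:
        constants = OpticalConstants.default()
    root = np.random.SeedSequence(seed)
    subjects: list[SubjectStudy] = []
    for sid, ss in enumerate(root.spawn(n_subjects)):
        traj_seed, sample_seed, param_seed, lag_seed, right_seed, left_seed = [
            int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(6)
        ]
        trajectory = simulate_sao2_trajectory(protocol, transition_tau, traj_seed)
        samples = draw_blood_samples(
            trajectory, protocol, coox_noise_sd, sample_seed, skip_probability=skip_probability
        )
        prng = np.random.default_rng(param_seed)
        lrng = np.random.default_rng(lag_seed)
        records: dict[str, PPGRecord] = {}
        lags: dict[str, float] = {}
        base_params = _draw_subject_params(prng, motion_rate_right, noise_sd)
        for wrist, wseed, mrate in (
            ("right", right_seed, motion_rate_right),
            ("left", left_seed, motion_rate_left),
        ):
            lag = float(np.clip(lrng.normal(lag_mean, lag_sd), -max_lag, max_lag)) if lag_sd > 0 else float(
                np.clip(lag_mean, -max_lag, max_lag)
            )
            params = replace(base_params, motion_rate=mrate)
            t_dev = trajectory.t - trajectory.t[0]
            # device(t) = reference(t + lag): shift the truth fed to the synth
            s_dev = trajectory.interp(trajectory.t[0] + t_dev + lag) / 100.0
            rec = synthesize_ppg(
                params,
                t_dev,
                s_dev,
                constants=constants,
                fs=fs,
                duration=float(t_dev[-1]),
                seed=wseed,
            )
            rec.meta["wrist"] = wrist
            rec.meta["true_lag_s"] = lag
            rec.meta["subject_id"] = sid
            records[wrist] = rec
            lags[wrist] = lag
        subjects.append(
            SubjectStudy(
                subject_id=sid,
                params=base_params,
                trajectory=trajectory,
                samples=samples,
                records=records,
                lags=lags,
            )
        )
    return HypoxiaStudy(protocol=protocol, subjects=subjects, seed=seed)


def simulate_desaturation_events(
    base_sao2: float = 96.0,
    event_rate: float = 30.0,
    event_depth: float = 4.0,
    event_duration: float = 30.0,
    duration: float = 3600.0,
    seed: int = 0,
    *,
    dt: float = 1.0,
    jitter_sd: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, list[tuple[float, float]]]:
    """Apnea/hypopnea-style trace: V-shaped dips on a stable baseline.

    Events arrive as a Poisson process at ``event_rate`` per hour, each a
    symmetric linear descent/ascent of the stated depth and duration.
    Returns (t, sao2, events) with events as (start, end) ground truth.
    """
    if event_rate > 0 and event_duration >= 3600.0 / event_rate:
        raise ValueError("event_duration must be below the mean inter-event time")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, dt)
    s = np.full_like(t, base_sao2)
    events: list[tuple[float, float]] = []
    if event_rate > 0:
        n = rng.poisson(event_rate * duration / 3600.0)
        starts = np.sort(rng.uniform(0.0, max(duration - event_duration, 0.0), size=n))
        # enforce non-overlap so each dip is an unambiguous event
        last_end = -np.inf
        for start in starts:
            if start < last_end:
                continue
            end = start + event_duration
            mid = start + event_duration / 2.0
            mask = (t >= start) & (t <= end)
            shape = 1.0 - np.abs(t[mask] - mid) / (event_duration / 2.0)
            s[mask] -= event_depth * shape
            events.append((float(start), float(end)))
            last_end = end
    if jitter_sd > 0:
        s = s + jitter_sd * rng.standard_normal(len(t))
    return t, np.clip(s, 50.0, 100.0), events
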