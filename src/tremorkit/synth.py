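"""Synthetic free-living IMU sessions with clinician-style tremor scores.

The clinical recordings this pipeline was designed for are not publicly
deposited, so this module generates labelled sessions with the same
statistical structure the analysis assumes: a 50 Hz six-channel IMU stream
per limb, rest tremor as an amplitude-modulated 4-7 Hz oscillation,
voluntary movement as band-limited 0.5-3 Hz motion, sensor noise, a
gravity offset on one accelerometer axis, and a clinician score
(0 = no tremor, 1 = mild, 2 = strong, or NO_DATA) every three minutes
with a heavily imbalanced marginal (~91.5% / 7.5% / 1%).

Severity evolves as a sequence of bouts: bout durations have a 5-minute
mean and each bout's severity is drawn from the target stationary
distribution (a Markov chain whose transition rows all equal the
stationary vector), so the long-run label marginal matches the target
exactly while states persist across neighbouring scoring intervals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import signal

#: Sentinel label for intervals where no clinical observation was possible.
NO_DATA: int = -1

#: Standard gravity added as a constant offset on one accelerometer axis.
GRAVITY_MS2: float = 9.81

LIMBS = ("left_wrist", "right_wrist", "left_ankle", "right_ankle")


@dataclass(frozen=True)
class SessionConfig:
    """Parameters of one simulated monitoring session.

    Defaults mirror the free-living protocol the analysis targets:
    ~2 h 48 min sessions sampled at 50 Hz, scores every 180 s, severity
    marginal (0.915, 0.075, 0.01), tremor carrier in 4-7 Hz.

    Parameters
    ----------
    duration_s : float
        Session length in seconds.
    fs : float
        Sampling rate in Hz; must exceed twice the upper tremor frequency.
    score_interval_s : float
        Clinician scoring cadence in seconds.
    severity_stationary : tuple of 3 floats
        Long-run probability of severity 0/1/2; must sum to 1.
    tremor_freq_range : (low, high) in Hz
        Carrier frequency band for the tremor oscillation.
    tremor_amp : tuple of 3 floats, m/s^2
        RMS tremor amplitude per severity; amp[0] must be 0 and
        amp[1] < amp[2].
    voluntary_band : (low, high) in Hz
        Band of the voluntary-movement component.
    voluntary_amp : float, m/s^2
        RMS amplitude of voluntary movement on the accelerometer.
    noise_sd : float, m/s^2
        White sensor-noise standard deviation on each accel channel.
    gyro_scale : float, (deg/s) per (m/s^2)
        Converts the dimensionless tremor/voluntary waveforms to
        gyroscope units (rotational tremor amplitude per unit of
        translational amplitude).
    mean_bout_s : float
        Mean duration of one constant-severity bout.
    nodata_prob : float
        Probability that a score entry is NO_DATA (observation gap).
    seed : int
        Seed for all randomness in ``simulate_session``.
    """

    duration_s: float = 10080.0
    fs: float = 50.0
    score_interval_s: float = 180.0
    severity_stationary: tuple[float, float, float] = (0.915, 0.075, 0.01)
    tremor_freq_range: tuple[float, float] = (4.0, 7.0)
    tremor_amp: tuple[float, float, float] = (0.0, 0.5, 2.0)
    voluntary_band: tuple[float, float] = (0.5, 3.0)
    voluntary_amp: float = 0.6
    noise_sd: float = 0.05
    gyro_scale: float = 25.0
    mean_bout_s: float = 300.0
    nodata_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.severity_stationary, dtype=float)
        if p.shape != (3,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(
                "severity_stationary must be 3 nonnegative probabilities summing to 1, "
                f"got {self.severity_stationary}"
            )
        amp = self.tremor_amp
        if amp[0] != 0.0:
            raise ValueError("tremor_amp[0] must be 0 (severity 0 = no tremor)")
        if not (0.0 < amp[1] < amp[2]):
            raise ValueError("tremor_amp must be strictly increasing for severities 1 and 2")
        if self.fs <= 2.0 * self.tremor_freq_range[1]:
            raise ValueError(
                f"fs={self.fs} must exceed twice the upper tremor frequency "
                f"{self.tremor_freq_range[1]} Hz"
            )
        if self.duration_s <= 0 or self.score_interval_s <= 0:
            raise ValueError("duration_s and score_interval_s must be positive")

    def replace(self, **kw) -> "SessionConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class ImuRecording:
    """One limb's six-channel 50 Hz sensor stream.

    ``acc`` is (n, 3) in m/s^2, ``gyr`` is (n, 3) in deg/s, ``t`` holds
    uniform timestamps in seconds.
    """

    subject_id: str
    limb: str
    t: np.ndarray
    acc: np.ndarray
    gyr: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        n = len(self.t)
        if self.acc.shape != (n, 3) or self.gyr.shape != (n, 3):
            raise ValueError("acc and gyr must be (n, 3) arrays matching t")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if np.max(np.abs(dt - 1.0 / self.fs)) > 1e-9:
                raise ValueError("timestamps must be uniform at 1/fs (within 1e-9 s)")

    @property
    def duration_s(self) -> float:
        return len(self.t) / self.fs


@dataclass(frozen=True)
class ScoreEvent:
    """A timestamped clinician label; ``time_s`` marks the end of the scored interval."""

    time_s: float
    label: int  # 0, 1, 2 or NO_DATA
    limb: str

    def __post_init__(self) -> None:
        if self.label not in (0, 1, 2, NO_DATA):
            raise ValueError(f"label must be 0, 1, 2 or NO_DATA, got {self.label}")


def severity_schedule(
    config: SessionConfig, seed: int | None = None
) -> list[tuple[tuple[float, float], int]]:
    """Piecewise-constant severity over [0, duration_s].

    Returns a list of ``((t_start, t_end), severity)`` bouts. Bout lengths
    are uniform on [0.5, 1.5] x ``config.mean_bout_s`` (5-minute mean
    dwell); severities are drawn from ``config.severity_stationary``, so
    empirical occupancy converges to that vector.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    p = np.asarray(config.severity_stationary, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("invalid stationary vector")
    bouts: list[tuple[tuple[float, float], int]] = []
    t = 0.0
    while t < config.duration_s:
        dur = rng.uniform(0.5, 1.5) * config.mean_bout_s
        dur = max(dur, 1.0 / config.fs)  # avoid zero-length bouts
        sev = int(rng.choice(3, p=p))
        t1 = min(t + dur, config.duration_s)
        bouts.append(((t, t1), sev))
        t = t1
    return bouts


def _am_envelope(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Slow (<= 0.5 Hz) positive amplitude envelope, unit RMS."""
    if n == 0:
        return np.zeros(0)
    raw = rng.standard_normal(max(n, 64))
    sos = signal.butter(2, 0.25, btype="low", fs=fs, output="sos")
    env = signal.sosfiltfilt(sos, raw)[:n]
    env = np.abs(env) + 0.1 * np.max(np.abs(env) + 1e-30)  # strictly positive
    rms = np.sqrt(np.mean(env**2))
    return env / rms if rms > 0 else env


def tremor_component(
    severity: int,
    duration_s: float,
    fs: float,
    freq_range: tuple[float, float] = (4.0, 7.0),
    amp: tuple[float, float, float] = (0.0, 0.5, 2.0),
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Amplitude-modulated tremor oscillation for one bout.

    The carrier frequency is drawn once per call, uniformly in
    ``freq_range``; the envelope is low-pass-filtered positive noise.
    Severity 0 returns zeros. Output RMS equals ``amp[severity]``.
    """
    if severity not in (0, 1, 2):
        raise ValueError(f"severity must be 0, 1 or 2, got {severity}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    # Keep the generator stream identical across severities so that equal
    # seeds give equal carrier/envelope and RMS ordering follows amp.
    f0 = rng.uniform(*freq_range)
    phase = rng.uniform(0, 2 * np.pi)
    env = _am_envelope(n, fs, rng)
    if severity == 0 or n == 0:
        return np.zeros(n)
    t = np.arange(n) / fs
    carrier = np.sqrt(2.0) * np.sin(2 * np.pi * f0 * t + phase)
    return amp[severity] * env * carrier


def voluntary_component(
    duration_s: float,
    fs: float,
    band: tuple[float, float] = (0.5, 3.0),
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Band-limited voluntary-movement waveform, standardized to unit variance."""
    if not (0.0 < band[0] < band[1] < fs / 2):
        raise ValueError(f"band {band} must lie inside (0, fs/2)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    if n == 0:
        return np.zeros(0)
    pad = int(4 * fs / band[0])  # settle room for the narrow low edge
    raw = rng.standard_normal(n + 2 * pad)
    sos = signal.butter(4, band, btype="band", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, raw)[pad : pad + n]
    sd = np.std(x)
    return x / sd if sd > 0 else x


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def simulate_session(
    config: SessionConfig,
    subject_id: str = "S00",
    limb: str = "right_wrist",
    return_schedule: bool = False,
):
    """Generate one labelled session: a 6-channel recording plus score events.

    Accelerometer channels are voluntary movement + tremor (projected on a
    random fixed unit direction per bout) + white noise + gravity on the
    z axis; gyroscope channels are analogous (scaled by ``gyro_scale``)
    without gravity. One ScoreEvent is emitted per ``score_interval_s``
    (at t = 0, interval, 2*interval, ...), labelled with the modal severity
    of the preceding 30 s, replaced by NO_DATA with ``nodata_prob``.
    """
    if limb not in LIMBS:
        raise ValueError(f"limb must be one of {LIMBS}")
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs

    schedule = severity_schedule(config, seed=int(rng.integers(2**31)))

    acc = np.zeros((n, 3))
    gyr = np.zeros((n, 3))

    vol = voluntary_component(
        config.duration_s, config.fs, config.voluntary_band, seed=rng
    )
    vol_dir_acc = _random_unit_vector(rng)
    vol_dir_gyr = _random_unit_vector(rng)
    acc += config.voluntary_amp * np.outer(vol, vol_dir_acc)
    gyr += config.voluntary_amp * config.gyro_scale * np.outer(vol, vol_dir_gyr)

    for (t0, t1), sev in schedule:
        i0, i1 = int(round(t0 * config.fs)), int(round(t1 * config.fs))
        i1 = min(i1, n)
        if i1 <= i0:
            continue
        trem = tremor_component(
            sev,
            (i1 - i0) / config.fs,
            config.fs,
            config.tremor_freq_range,
            config.tremor_amp,
            seed=rng,
        )
        dir_acc = _random_unit_vector(rng)
        dir_gyr = _random_unit_vector(rng)
        acc[i0:i1] += np.outer(trem, dir_acc)
        gyr[i0:i1] += config.gyro_scale * np.outer(trem, dir_gyr)

    acc += config.noise_sd * rng.standard_normal((n, 3))
    gyr += config.gyro_scale * config.noise_sd * rng.standard_normal((n, 3))
    acc[:, 2] += GRAVITY_MS2

    events: list[ScoreEvent] = []
    n_scores = int(np.floor(config.duration_s / config.score_interval_s))
    for k in range(n_scores):
        te = k * config.score_interval_s
        label = modal_severity(schedule, max(te - 30.0, 0.0), te) if te > 0 else modal_severity(
            schedule, 0.0, max(te, 1.0 / config.fs)
        )
        if rng.uniform() < config.nodata_prob:
            label = NO_DATA
        events.append(ScoreEvent(time_s=te, label=label, limb=limb))

    rec = ImuRecording(subject_id=subject_id, limb=limb, t=t, acc=acc, gyr=gyr, fs=config.fs)
    if return_schedule:
        return rec, events, schedule
    return rec, events


def modal_severity(
    schedule: list[tuple[tuple[float, float], int]], t0: float, t1: float
) -> int:
    """Severity occupying the most time in [t0, t1] under the bout schedule."""
    occ = np.zeros(3)
    for (a, b), sev in schedule:
        occ[sev] += max(0.0, min(b, t1) - max(a, t0))
    return int(np.argmax(occ))
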