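"""Seeded synthetic bimodal EOG/EEG recordings with ground-truth SEM intervals.

The generator emulates the signal structure seen at the two outer-canthus
electrodes (Hl, Hr) and the occipital O2 electrode during drowsy simulated
driving:

* slow eye movements (SEMs): slow sinusoidal excursions appearing with
  opposite phase on Hl and Hr (0.2-0.6 Hz, 20-200 uV, > 2 s, small
  inter-channel onset lag),
* saccades: fast step-like opposite-phase deflections during alert periods,
* a common-mode EEG component: band-limited 1/f background plus bursty
  alpha (8-13 Hz) activity that attenuates while a SEM is in progress,
* slow baseline drift and independent broadband electrode noise.

O2 shares the alpha-burst envelope of the common-mode component (this is
what makes HSUM = Hl + Hr a usable stand-in for occipital EEG) but carries
its own background noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal.windows import tukey

from .io import EventInterval, Recording

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SEMEvent",
    "generate_sem_event",
    "generate_saccade",
    "generate_recording",
]

# Labeling-criteria bounds that simulator parameters must respect
SEM_FREQ_BOUNDS = (0.2, 0.6)
SEM_AMP_BOUNDS = (20.0, 200.0)
SEM_MIN_DURATION_S = 2.0
SEM_MAX_ONSET_DIFF_MS = 300.0


def _check_range(name, pair, bounds=None):
    lo, hi = pair
    if lo > hi:
        raise ValueError(f"{name} must be ordered (low <= high), got {pair}")
    if bounds is not None and not (bounds[0] <= lo and hi <= bounds[1]):
        raise ValueError(f"{name}={pair} must lie inside {bounds}")


@dataclass
class SimConfig:
    """Simulation parameters.  Defaults are the study conditions used
    throughout the test-suite and the reproduction script."""

    duration_s: float = 360.0
    fs: float = 500.0
    n_sem_events: int = 12
    sem_freq_range: tuple = (0.25, 0.5)
    sem_amp_range: tuple = (30.0, 150.0)
    sem_duration_range: tuple = (4.0, 7.0)
    onset_diff_max_ms: float = 100.0
    n_saccades: int = 30
    saccade_amp_range: tuple = (50.0, 200.0)
    saccade_rise_ms: float = 20.0
    saccade_duration_s: float = 0.8
    alpha_freq_range: tuple = (8.0, 13.0)
    alpha_amp_uv: float = 10.0
    alpha_attenuation_factor: float = 0.3
    eeg_background_sd_uv: float = 5.0
    drift_amp_uv: float = 30.0
    drift_freq_hz: float = 0.05
    noise_sd_uv: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        _check_range("sem_freq_range", self.sem_freq_range, SEM_FREQ_BOUNDS)
        _check_range("sem_amp_range", self.sem_amp_range, SEM_AMP_BOUNDS)
        _check_range("sem_duration_range", self.sem_duration_range)
        if self.sem_duration_range[0] <= SEM_MIN_DURATION_S:
            raise ValueError(
                f"sem_duration_range lower bound must exceed {SEM_MIN_DURATION_S} s"
            )
        if not (0 <= self.onset_diff_max_ms <= SEM_MAX_ONSET_DIFF_MS):
            raise ValueError(
                f"onset_diff_max_ms must be in [0, {SEM_MAX_ONSET_DIFF_MS}]"
            )
        _check_range("saccade_amp_range", self.saccade_amp_range)
        _check_range("alpha_freq_range", self.alpha_freq_range)
        if not (0 <= self.alpha_attenuation_factor <= 1):
            raise ValueError("alpha_attenuation_factor must be in [0, 1]")
        if self.drift_freq_hz >= 0.1:
            raise ValueError("drift_freq_hz must be below 0.1 Hz")


@dataclass(frozen=True)
class SEMEvent:
    """Ground-truth parameters of one generated SEM event."""

    start_s: float
    end_s: float
    freq_hz: float
    amp_uv: float
    onset_diff_ms: float

    @property
    def interval(self) -> EventInterval:
        return EventInterval(self.start_s, self.end_s, "SEM")


@dataclass
class GroundTruth:
    """Ground-truth SEM intervals plus per-event parameters."""

    events: list
    duration_s: float

    @property
    def intervals(self) -> list:
        return [e.interval for e in self.events]


def generate_sem_event(
    freq: float, amp: float, duration: float, onset_diff_ms: float, fs: float
) -> tuple:
    """Opposite-phase sinusoidal excursion pair for one SEM.

    Returns ``(hl, hr)``: the Hl component is an amplitude-``amp`` sinusoid
    under a raised-cosine (Tukey) taper over the first/last 10% of the
    event; the Hr component is its negation delayed by ``onset_diff_ms``.
    Both arrays have the same length (event duration plus the lag) and are
    zero outside their support.
    """
    if not (SEM_FREQ_BOUNDS[0] <= freq <= SEM_FREQ_BOUNDS[1]):
        raise ValueError(
            f"frequency criterion violated: {freq} Hz outside {SEM_FREQ_BOUNDS}"
        )
    if not (SEM_AMP_BOUNDS[0] <= amp <= SEM_AMP_BOUNDS[1]):
        raise ValueError(
            f"amplitude criterion violated: {amp} uV outside {SEM_AMP_BOUNDS}"
        )
    if duration <= SEM_MIN_DURATION_S:
        raise ValueError(
            f"duration criterion violated: {duration} s not > {SEM_MIN_DURATION_S} s"
        )
    if not (0 <= onset_diff_ms <= SEM_MAX_ONSET_DIFF_MS):
        raise ValueError(
            "onset-difference criterion violated: "
            f"{onset_diff_ms} ms outside [0, {SEM_MAX_ONSET_DIFF_MS}]"
        )
    n = int(round(duration * fs))
    lag = int(round(onset_diff_ms / 1000.0 * fs))
    t = np.arange(n) / fs
    base = amp * np.sin(2 * np.pi * freq * t) * tukey(n, alpha=0.2)
    hl = np.zeros(n + lag)
    hr = np.zeros(n + lag)
    hl[:n] = base
    hr[lag : lag + n] = -base
    return hl, hr


def generate_saccade(
    amp: float, rise_ms: float = 20.0, fs: float = 500.0, duration_s: float = 0.8
) -> tuple:
    """Step-like opposite-phase deflection: linear rise then sustained plateau.

    A linear ramp of ``rise_ms`` gives a 10-90% rise time of 0.8*rise_ms.
    Zero amplitude returns all-zero traces; negative amplitude is rejected.
    """
    if amp < 0:
        raise ValueError(f"saccade amplitude must be non-negative, got {amp}")
    n = int(round(duration_s * fs))
    n_rise = max(int(round(rise_ms / 1000.0 * fs)), 1)
    if n_rise >= n:
        raise ValueError("rise time must be shorter than the saccade duration")
    profile = np.ones(n) * amp
    profile[:n_rise] = amp * np.arange(n_rise) / n_rise
    return profile, -profile


def _place_intervals(
    rng: np.random.Generator,
    durations: Sequence[float],
    total_s: float,
    occupied: Sequence[tuple],
    guard_s: float = 1.0,
    max_attempts: int = 1000,
) -> list:
    """Uniform random non-overlapping placement with guard gaps."""
    placed = list(occupied)
    starts = []
    for k, dur in enumerate(durations):
        ok = False
        for _ in range(max_attempts):
            s = rng.uniform(guard_s, total_s - dur - guard_s)
            if all(
                s + dur + guard_s <= a or s >= b + guard_s for a, b in placed
            ):
                placed.append((s, s + dur))
                starts.append(s)
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could only place {k} of {len(durations)} events of total "
                f"duration {sum(durations):.1f} s in {total_s:.1f} s "
                "without overlap; reduce the event count or durations"
            )
    return starts


def _pink_noise(rng: np.random.Generator, n: int, fs: float, band=(0.1, 30.0)) -> np.ndarray:
    """Unit-variance 1/f noise band-limited to ``band`` (Hz)."""
    freqs = np.fft.rfftfreq(n, d=1 / fs)
    spectrum = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    shape = np.zeros(len(freqs))
    inside = (freqs >= band[0]) & (freqs <= band[1])
    shape[inside] = 1.0 / np.sqrt(freqs[inside])
    x = np.fft.irfft(spectrum * shape, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _alpha_envelope(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Slowly varying non-negative burst envelope with mean one."""
    # smooth squared Gaussian noise (~0.3 Hz bandwidth) -> bursty envelope
    raw = rng.standard_normal(n)
    freqs = np.fft.rfftfreq(n, d=1 / fs)
    lowpass = np.exp(-((freqs / 0.3) ** 2))
    smooth = np.fft.irfft(np.fft.rfft(raw) * lowpass, n=n)
    env = smooth**2
    mean = env.mean()
    return env / mean if mean > 0 else env


def _attenuation_profile(
    n: int, fs: float, events: Sequence[SEMEvent], factor: float, ramp_s: float = 0.2
) -> np.ndarray:
    """Multiplicative alpha gain: ``factor`` inside SEM events, 1 elsewhere,
    with cosine ramps at event edges."""
    gain = np.ones(n)
    n_ramp = int(round(ramp_s * fs))
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp)) if n_ramp else None
    for ev in events:
        i0, i1 = int(round(ev.start_s * fs)), int(round(ev.end_s * fs))
        gain[i0:i1] = factor
        if n_ramp and i0 - n_ramp >= 0:
            gain[i0 - n_ramp : i0] = 1 + (factor - 1) * ramp
        if n_ramp and i1 + n_ramp <= n:
            gain[i1 : i1 + n_ramp] = factor + (1 - factor) * ramp
    return gain


def generate_recording(config: SimConfig) -> tuple:
    """Generate a seeded recording (Hl, Hr, O2) and its ground truth.

    Construction: ``Hl = +eye + eeg + drift + noise_l``,
    ``Hr = -eye + eeg + drift + noise_r`` (the eye-movement component flips
    sign between the canthi, the EEG-like component is common mode), and
    ``O2`` shares the alpha-burst envelope of ``eeg`` but has independent
    background noise.  Alpha amplitude is multiplied by
    ``alpha_attenuation_factor`` inside SEM intervals.  Identical config and
    seed give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n = int(round(config.duration_s * fs))

    # --- SEM events -------------------------------------------------------
    durations = rng.uniform(*config.sem_duration_range, size=config.n_sem_events)
    starts = _place_intervals(rng, durations, config.duration_s, occupied=[])
    events = []
    for s, dur in zip(starts, durations):
        events.append(
            SEMEvent(
                start_s=round(s, 3),
                end_s=round(s + dur, 3),
                freq_hz=float(rng.uniform(*config.sem_freq_range)),
                amp_uv=float(rng.uniform(*config.sem_amp_range)),
                onset_diff_ms=float(rng.uniform(0, config.onset_diff_max_ms)),
            )
        )
    events.sort(key=lambda e: e.start_s)

    eye_l = np.zeros(n)
    eye_r = np.zeros(n)
    for ev in events:
        hl, hr = generate_sem_event(
            ev.freq_hz, ev.amp_uv, ev.end_s - ev.start_s, ev.onset_diff_ms, fs
        )
        i0 = int(round(ev.start_s * fs))
        seg = slice(i0, min(i0 + len(hl), n))
        eye_l[seg] += hl[: seg.stop - i0]
        eye_r[seg] += hr[: seg.stop - i0]

    # --- saccades in alert (non-SEM) periods ------------------------------
    if config.n_saccades:
        occupied = [(ev.start_s, ev.end_s) for ev in events]
        sac_durs = [config.saccade_duration_s] * config.n_saccades
        sac_starts = _place_intervals(rng, sac_durs, config.duration_s, occupied)
        for s in sac_starts:
            amp = float(rng.uniform(*config.saccade_amp_range))
            sign = rng.choice([-1.0, 1.0])
            hl, hr = generate_saccade(
                amp, config.saccade_rise_ms, fs, config.saccade_duration_s
            )
            i0 = int(round(s * fs))
            seg = slice(i0, min(i0 + len(hl), n))
            eye_l[seg] += sign * hl[: seg.stop - i0]
            eye_r[seg] += sign * hr[: seg.stop - i0]

    # --- common-mode EEG: band-limited 1/f background + bursty alpha ------
    envelope = _alpha_envelope(rng, n, fs)
    envelope = envelope * _attenuation_profile(
        n, fs, events, config.alpha_attenuation_factor
    )
    f_alpha = float(rng.uniform(*config.alpha_freq_range))
    phase = rng.uniform(0, 2 * np.pi)
    t = np.arange(n) / fs
    alpha = config.alpha_amp_uv * envelope * np.sin(2 * np.pi * f_alpha * t + phase)
    eeg = config.eeg_background_sd_uv * _pink_noise(rng, n, fs) + alpha

    # --- drift and noise --------------------------------------------------
    drift = config.drift_amp_uv * np.sin(
        2 * np.pi * config.drift_freq_hz * t + rng.uniform(0, 2 * np.pi)
    )
    noise_l = config.noise_sd_uv * rng.standard_normal(n)
    noise_r = config.noise_sd_uv * rng.standard_normal(n)
    noise_o = config.noise_sd_uv * rng.standard_normal(n)

    hl_sig = eye_l + eeg + drift + noise_l
    hr_sig = eye_r + eeg + drift + noise_r
    o2 = (
        alpha
        + config.eeg_background_sd_uv * _pink_noise(rng, n, fs)
        + drift
        + noise_o
    )

    recording = Recording(
        {"Hl": hl_sig, "Hr": hr_sig, "O2": o2}, fs=fs, subject_id=f"sim{config.seed}"
    )
    return recording, GroundTruth(events=events, duration_s=config.duration_s)
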