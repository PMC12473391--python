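"""Executable SEM labeling criteria and windowed dataset construction.

A SEM epoch must simultaneously show (1) opposite-phase excursions on the
two canthus channels, (2) a dominant frequency of 0.2-0.6 Hz sustained for
more than 2 s, (3) an excursion amplitude of 20-200 uV, (4) an
inter-channel onset lag of at most 300 ms, and (5) no gross artifacts.
``check_sem_criteria`` turns these visual-marking rules into measurements;
``extract_windows`` and ``chronological_split`` build the two-class window
dataset the classifier consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import EventInterval, Recording, WindowDataset, validate_intervals
from .preprocess import downsample_window

__all__ = [
    "CriteriaConfig",
    "CriteriaReport",
    "DatasetSplit",
    "check_sem_criteria",
    "extract_windows",
    "chronological_split",
    "complement_intervals",
]


@dataclass(frozen=True)
class CriteriaConfig:
    """Thresholds operationalizing the visual SEM-marking rules.

    The frequency/amplitude/duration/onset bounds come from the published
    criteria; the phase-correlation threshold and artifact ceiling make the
    qualitative rules ("opposite phases", "no obvious artifacts")
    executable.  Phase, frequency, amplitude and onset are measured on a
    0.1-1.5 Hz zero-phase band-passed copy of the epoch — the slow
    component a human marker attends to — while the artifact ceiling is
    checked on the raw samples.
    """

    freq_band_hz: tuple = (0.2, 0.6)
    amp_range_uv: tuple = (20.0, 200.0)
    min_duration_s: float = 2.0
    max_onset_diff_ms: float = 300.0
    phase_corr_max: float = -0.8
    artifact_ceiling_uv: float = 500.0
    measurement_band_hz: tuple = (0.1, 1.5)
    # A genuine 0.2-0.6 Hz excursion has essentially no energy above the
    # SEM band, so the 1.5-15 Hz component of HEOG stays at the noise
    # floor; a saccadic step necessarily drives a large fast transient.
    # The first/last quarter second is excluded from the peak search to
    # keep zero-phase filter edge transients out of the measurement.
    fast_band_hz: tuple = (1.5, 15.0)
    fast_transient_max_uv: float = 38.0
    fast_band_trim_s: float = 0.25
    onset_max_lag_s: float = 0.6


@dataclass
class CriteriaReport:
    """Per-criterion verdicts with the measured values behind them."""

    passed: bool
    verdicts: dict
    dominant_freq_hz: float
    amplitude_uv: float
    onset_diff_ms: float
    phase_correlation: float
    max_abs_uv: float
    duration_s: float


def _slow_component(x: np.ndarray, fs: float, band: tuple) -> np.ndarray:
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def check_sem_criteria(
    hl_epoch: np.ndarray,
    hr_epoch: np.ndarray,
    fs: float,
    config: CriteriaConfig = CriteriaConfig(),
) -> CriteriaReport:
    """Evaluate all five SEM criteria on one Hl/Hr epoch.

    An epoch shorter than the minimum duration fails the duration verdict
    (no exception).  ``passed`` is true iff every verdict is true.
    """
    hl = np.asarray(hl_epoch, dtype=float)
    hr = np.asarray(hr_epoch, dtype=float)
    if hl.shape != hr.shape:
        raise ValueError("Hl and Hr epochs must have equal length")
    n = len(hl)
    if n < fs:
        raise ValueError("epoch must be at least 1 s long")
    duration = n / fs

    hl_f = _slow_component(hl, fs, config.measurement_band_hz)
    hr_f = _slow_component(hr, fs, config.measurement_band_hz)
    heog = hl_f - hr_f

    # dominant frequency: zero-padded periodogram peak of the HEOG trace
    nfft = int(2 ** math.ceil(math.log2(max(16 * n, 4096))))
    freqs, power = signal.periodogram(heog, fs=fs, nfft=nfft, detrend="constant")
    dominant = float(freqs[1:][np.argmax(power[1:])])  # skip the DC bin

    # phase opposition: Pearson correlation of the two channels in a
    # narrow band around the dominant frequency, i.e. opposition of the
    # oscillation itself rather than of whatever broadband background
    # happens to share the wide measurement band
    lo = max(dominant / 1.6, 0.05)
    hi = max(min(dominant * 1.6, fs / 2 * 0.9), lo * 1.5)
    sos_nb = signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    hl_nb = signal.sosfiltfilt(sos_nb, hl)
    hr_nb = signal.sosfiltfilt(sos_nb, hr)
    with np.errstate(invalid="ignore"):
        denom = hl_nb.std() * hr_nb.std()
        corr = (
            float((hl_nb - hl_nb.mean()) @ (hr_nb - hr_nb.mean()) / (n * denom))
            if denom > 0
            else 0.0
        )

    # fast-transient bound (saccade rejector)
    sos_fast = signal.butter(4, config.fast_band_hz, btype="bandpass", fs=fs, output="sos")
    fast = signal.sosfiltfilt(sos_fast, hl - hr)
    trim = int(config.fast_band_trim_s * fs)
    fast_peak = float(np.max(np.abs(fast[trim : n - trim] if n > 2 * trim else fast)))

    # excursion amplitude recovered from the difference trace: HEOG doubles
    # the single-channel excursion, so half its peak-to-peak swing is the
    # per-channel amplitude the 20-200 uV rule refers to
    amplitude = float(np.ptp(heog) / 4.0)

    # onset lag between the channels: cross-correlation peak of the slow
    # components (Hr negated), restricted to lags below half a SEM period
    max_lag = int(config.onset_max_lag_s * fs)
    a = hl_f - hl_f.mean()
    b = -(hr_f - hr_f.mean())
    full = signal.correlate(a, b, mode="full", method="fft")
    lags = signal.correlation_lags(n, n, mode="full")
    keep = np.abs(lags) <= max_lag
    onset_ms = abs(int(lags[keep][np.argmax(full[keep])])) / fs * 1000.0

    max_abs = float(max(np.max(np.abs(hl)), np.max(np.abs(hr))))

    verdicts = {
        "phase_opposition": corr <= config.phase_corr_max,
        "frequency_band": (
            config.freq_band_hz[0] <= dominant <= config.freq_band_hz[1]
            and fast_peak <= config.fast_transient_max_uv
        ),
        "duration": duration > config.min_duration_s,
        "amplitude": config.amp_range_uv[0] <= amplitude <= config.amp_range_uv[1],
        "onset_difference": onset_ms <= config.max_onset_diff_ms,
        "artifact_free": max_abs <= config.artifact_ceiling_uv,
    }
    return CriteriaReport(
        passed=all(verdicts.values()),
        verdicts=verdicts,
        dominant_freq_hz=dominant,
        amplitude_uv=amplitude,
        onset_diff_ms=onset_ms,
        phase_correlation=corr,
        max_abs_uv=max_abs,
        duration_s=duration,
    )


def complement_intervals(
    intervals, duration_s: float, guard_s: float = 0.5, label: str = "NONSEM"
):
    """Label the gaps between (sorted, non-overlapping) intervals.

    A ``guard_s`` margin is kept on each side of every existing interval so
    complement epochs never touch event boundaries.
    """
    ordered = validate_intervals(intervals)
    gaps = []
    cursor = 0.0
    for iv in ordered:
        lo, hi = cursor, iv.start_s - guard_s
        if hi - lo > 1e-9:
            gaps.append(EventInterval(lo, hi, label))
        cursor = iv.end_s + guard_s
    if duration_s - cursor > 1e-9:
        gaps.append(EventInterval(cursor, duration_s, label))
    return gaps


def extract_windows(
    recording: Recording,
    intervals,
    win_s: float = 3.0,
    step_s: float = 0.1,
    modalities: tuple = ("HEOG", "HSUM"),
    downsample_factor: int = 3,
) -> WindowDataset:
    """Cut labeled sliding windows from a preprocessed recording.

    Windows fully contained in a labeled epoch inherit its label (SEM = 1);
    windows straddling an epoch boundary or an unlabeled gap are never
    produced.  Each raw window of ``win_s * fs`` samples is decimated by
    ``downsample_factor``.
    """
    recording.require(*modalities)
    ordered = validate_intervals(intervals)
    fs = recording.fs
    win_n = int(round(win_s * fs))

    xs, ys, starts = [], [], []
    for iv in ordered:
        n_fit = math.floor((iv.duration_s - win_s) / step_s + 1e-9) + 1
        label = 1 if iv.label == "SEM" else 0
        for k in range(max(n_fit, 0)):
            t0 = iv.start_s + k * step_s
            i0 = int(round(t0 * fs))
            if i0 + win_n > recording.n_samples:
                break
            pair = np.stack(
                [
                    downsample_window(recording[m][i0 : i0 + win_n], downsample_factor)
                    for m in modalities
                ]
            )
            xs.append(pair)
            ys.append(label)
            starts.append(t0)
    if not xs:
        raise ValueError("no labeled epochs produced any windows")
    order = np.argsort(starts, kind="stable")
    return WindowDataset(
        X=np.stack(xs)[order],
        y=np.asarray(ys)[order],
        t_start=np.asarray(starts)[order],
        fs=fs / downsample_factor,
        modalities=tuple(modalities),
        subject_id=recording.subject_id,
    )


@dataclass
class DatasetSplit:
    """Chronological train/test split with contiguous CV folds over train."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    folds: list

    @property
    def n_train(self) -> int:
        return len(self.train_idx)

    @property
    def n_test(self) -> int:
        return len(self.test_idx)


def chronological_split(
    dataset: WindowDataset, train_frac: float = 0.7, n_folds: int = 5
) -> DatasetSplit:
    """First ``ceil(train_frac * n)`` windows train, the rest test, with
    ``n_folds`` contiguous folds partitioning the training block."""
    n = len(dataset)
    n_train = math.ceil(train_frac * n)
    if n_train == 0 or n_train == n:
        raise ValueError(f"split leaves an empty side (n={n}, train={n_train})")
    train_idx = np.arange(n_train)
    test_idx = np.arange(n_train, n)
    classes = np.unique(dataset.y[train_idx])
    if len(classes) < 2:
        raise ValueError(
            "training portion contains a single class; the chronological "
            "split needs both SEM and non-SEM windows before the cut"
        )
    folds = [f for f in np.array_split(train_idx, n_folds)]
    return DatasetSplit(train_idx=train_idx, test_idx=test_idx, folds=folds)
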