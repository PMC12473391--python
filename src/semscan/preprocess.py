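"""Channel derivation and the per-modality cleaning chain.

Modality 1 (eye movement): HEOG = Hl - Hr, smoothed with a 10-sample
sliding median.  Modality 2 (EEG-like): O2 or HSUM = Hl + Hr, with the
baseline drift removed by subtracting the level-10 Daubechies-2 DWT
approximation.  The chain is applied to the continuous recording before
windowing; windows are decimated 1500 -> 500 afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .io import Recording

__all__ = [
    "DerivedSignals",
    "derive_channels",
    "median_smooth",
    "remove_baseline_dwt",
    "downsample_window",
    "preprocess_recording",
]

MODALITY_PAIRS = {
    "heog+hsum": ("HEOG", "HSUM"),
    "heog+o2": ("HEOG", "O2"),
}


@dataclass
class DerivedSignals:
    """HEOG (difference) and HSUM (sum) traces derived from Hl and Hr."""

    heog: np.ndarray
    hsum: np.ndarray
    fs: float


def derive_channels(hl: np.ndarray, hr: np.ndarray, fs: float = 500.0) -> DerivedSignals:
    """Elementwise difference (HEOG) and sum (HSUM) of the two canthus traces."""
    hl = np.asarray(hl, dtype=float)
    hr = np.asarray(hr, dtype=float)
    if hl.shape != hr.shape:
        raise ValueError(f"Hl and Hr lengths differ: {hl.shape} vs {hr.shape}")
    return DerivedSignals(heog=hl - hr, hsum=hl + hr, fs=fs)


def median_smooth(x: np.ndarray, window: int = 10) -> np.ndarray:
    """Sliding median with reflect padding; output length equals input length.

    For an even window the median is the mean of the two central order
    statistics (the numpy convention).
    """
    x = np.asarray(x, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(x) < window:
        raise ValueError(f"signal length {len(x)} shorter than window {window}")
    left = (window - 1) // 2
    right = window - 1 - left
    padded = np.pad(x, (left, right), mode="reflect")
    views = np.lib.stride_tricks.sliding_window_view(padded, window)
    return np.median(views, axis=1)


def remove_baseline_dwt(
    x: np.ndarray, wavelet: str = "db2", level: int = 10
) -> np.ndarray:
    """Subtract the level-``level`` DWT approximation (the baseline drift).

    All detail bands are kept: the output is ``x`` minus the reconstruction
    of the approximation coefficients alone, using symmetric signal
    extension.  With fs = 500 Hz and level 10 the approximation band ends
    near fs / 2**11 = 0.24 Hz, so drift is removed while alpha-band content
    is untouched.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2**level:
        raise ValueError(
            f"signal of length {len(x)} is too short for a level-{level} "
            f"decomposition (needs >= {2**level} samples); use a lower level"
        )
    coeffs = pywt.wavedec(x, wavelet, level=level, mode="symmetric")
    approx_only = [coeffs[0]] + [np.zeros_like(c) for c in coeffs[1:]]
    baseline = pywt.waverec(approx_only, wavelet, mode="symmetric")[: len(x)]
    return x - baseline


def downsample_window(x: np.ndarray, factor: int = 3) -> np.ndarray:
    """Decimate by keeping every ``factor``-th sample starting at index 0.

    The signals are band-limited to 30 Hz at acquisition, far below the
    new Nyquist frequency, so no anti-alias filter is applied.
    """
    x = np.asarray(x)
    if len(x) % factor != 0:
        raise ValueError(f"length {len(x)} not divisible by factor {factor}")
    return x[::factor]


def preprocess_recording(
    recording: Recording,
    modalities: str | tuple = "heog+hsum",
    median_window: int = 10,
    dwt_wavelet: str = "db2",
    dwt_level: int = 10,
) -> Recording:
    """Apply the full cleaning chain and return a recording holding the
    requested modality channels (plus the originals).

    HEOG is median-smoothed; the EEG-like modality (HSUM or O2) is
    baseline-corrected by DWT approximation subtraction.
    """
    if isinstance(modalities, str):
        try:
            modalities = MODALITY_PAIRS[modalities.lower()]
        except KeyError:
            raise ValueError(
                f"unknown modality pair {modalities!r}; expected one of "
                f"{sorted(MODALITY_PAIRS)}"
            ) from None
    recording.require("Hl", "Hr")
    derived = derive_channels(recording["Hl"], recording["Hr"], recording.fs)
    channels = dict(recording.channels)
    channels["HEOG"] = median_smooth(derived.heog, median_window)
    if "HSUM" in modalities:
        channels["HSUM"] = remove_baseline_dwt(derived.hsum, dwt_wavelet, dwt_level)
    if "O2" in modalities:
        recording.require("O2")
        channels["O2"] = remove_baseline_dwt(recording["O2"], dwt_wavelet, dwt_level)
    return Recording(channels, fs=recording.fs, subject_id=recording.subject_id)
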