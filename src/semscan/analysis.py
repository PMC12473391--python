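"""Alpha-band wavelet-energy correlation and attention interpretability.

Two analyses accompany the classifier:

* the alpha-band (default 6-14 Hz) complex-Morlet CWT energy of HSUM
  tracks that of O2 — the empirical basis for substituting the two-
  electrode HSUM signal for occipital EEG — quantified by per-window
  Pearson correlations of the time-varying energy curves;
* the encoder's self-attention maps, captured per layer/head/branch and
  averaged per class, show which temporal relations the trained model
  attends to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .architectures import ParallelNet
from .io import Recording, WindowDataset

__all__ = [
    "EnergyCurve",
    "AttentionMaps",
    "cwt_alpha_energy",
    "energy_correlation",
    "extract_attention",
    "class_average_attention",
]

DEFAULT_WAVELET = "cmor1.5-1.0"


@dataclass
class EnergyCurve:
    """Time-varying mean alpha-band wavelet-coefficient magnitude."""

    values: np.ndarray
    band_hz: tuple
    fs: float


@dataclass
class AttentionMaps:
    """Attention weight matrices: ``maps[branch][layer]`` has shape
    (heads, l, l) with row-stochastic rows."""

    maps: list
    probabilities: np.ndarray


def cwt_alpha_energy(
    x: np.ndarray,
    fs: float,
    band: tuple = (6.0, 14.0),
    freq_step: float = 0.25,
    wavelet: str = DEFAULT_WAVELET,
) -> EnergyCurve:
    """Mean complex-Morlet CWT coefficient magnitude over the alpha band.

    Frequencies are sampled every ``freq_step`` Hz across ``band``; the
    curve is the mean over the frequency axis of |coefficients| at each
    time point, so it is linear in the signal amplitude.
    """
    x = np.asarray(x, dtype=float)
    if not (0 < band[0] < band[1] < fs / 2):
        raise ValueError(f"band {band} must lie inside (0, {fs / 2})")
    if len(x) < fs:
        raise ValueError("need at least 1 s of samples")
    freqs = np.arange(band[0], band[1] + 1e-9, freq_step)
    scales = pywt.frequency2scale(wavelet, freqs / fs)
    coeffs, _ = pywt.cwt(x, scales, wavelet, sampling_period=1 / fs)
    return EnergyCurve(values=np.abs(coeffs).mean(axis=0), band_hz=tuple(band), fs=fs)


def energy_correlation(
    recording: Recording,
    win_s: float = 3.0,
    band: tuple = (6.0, 14.0),
    channels: tuple = ("O2", "HSUM"),
    outlier_sd: float = 2.0,
):
    """Per-window Pearson r between the two channels' alpha-energy curves.

    The recording is cut into non-overlapping ``win_s`` windows; windows
    whose r deviates from the mean by more than ``outlier_sd`` standard
    deviations are removed (single pass).  Returns ``(kept_r, summary)``
    with the median, mean and counts in ``summary``.
    """
    recording.require(*channels)
    fs = recording.fs
    win_n = int(round(win_s * fs))
    n_win = recording.n_samples // win_n
    if n_win < 3:
        raise ValueError(f"need at least 3 windows, recording yields {n_win}")
    a_curve = cwt_alpha_energy(recording[channels[0]], fs, band).values
    b_curve = cwt_alpha_energy(recording[channels[1]], fs, band).values
    rs = np.empty(n_win)
    for k in range(n_win):
        sl = slice(k * win_n, (k + 1) * win_n)
        rs[k] = np.corrcoef(a_curve[sl], b_curve[sl])[0, 1]
    keep = np.abs(rs - rs.mean()) <= outlier_sd * rs.std()
    kept = rs[keep]
    summary = {
        "median_r": float(np.median(kept)),
        "mean_r": float(np.mean(kept)),
        "n_windows": int(n_win),
        "n_removed": int(n_win - keep.sum()),
    }
    return kept, summary


def extract_attention(net: ParallelNet, x1: np.ndarray, x2: np.ndarray) -> AttentionMaps:
    """Capture the self-attention weights of every encoder layer and head
    in both branches during one forward pass.

    The instrumentation does not alter the forward computation: returned
    probabilities equal a plain forward pass.
    """
    x1 = np.atleast_2d(np.asarray(x1, dtype=np.float32))
    x2 = np.atleast_2d(np.asarray(x2, dtype=np.float32))
    net.set_attention_capture(True)
    try:
        probs = net.predict_proba(x1, x2)
        maps = [
            [mha.last_attention.mean(axis=0) for mha in net.attention_layers(branch)]
            for branch in (0, 1)
        ]
    finally:
        net.set_attention_capture(False)
    return AttentionMaps(maps=maps, probabilities=probs)


def class_average_attention(
    net: ParallelNet, dataset: WindowDataset, layer: int = -1, batch_size: int = 256
):
    """Per-class elementwise mean of one encoder layer's attention maps.

    Returns ``{0: [branch1_map, branch2_map], 1: [...]}`` where each map
    has shape (heads, l, l); averaging preserves row-stochasticity.
    """
    y = dataset.y
    if len(np.unique(y)) < 2:
        raise ValueError("dataset must contain both classes")
    sums = {c: [None, None] for c in (0, 1)}
    counts = {0: 0, 1: 0}
    net.set_attention_capture(True)
    try:
        for i in range(0, len(dataset), batch_size):
            xb = dataset.X[i : i + batch_size]
            yb = y[i : i + batch_size]
            net.predict_proba(xb[:, 0], xb[:, 1])
            per_branch = [
                net.attention_layers(branch)[layer].last_attention for branch in (0, 1)
            ]
            for c in (0, 1):
                mask = yb == c
                if not mask.any():
                    continue
                counts[c] += int(mask.sum())
                for b in (0, 1):
                    part = per_branch[b][mask].sum(axis=0)
                    sums[c][b] = part if sums[c][b] is None else sums[c][b] + part
    finally:
        net.set_attention_capture(False)
    return {c: [s / counts[c] for s in sums[c]] for c in (0, 1)}
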