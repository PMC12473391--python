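"""Reading and writing recordings, interval labels, and window datasets.

Recordings travel as plain CSV (``time_s,Hl,Hr[,O2]``) or EDF; interval
labels as CSV (``start_s,end_s,label``); window datasets as HDF5.  All
sample values are microvolts, all times are seconds from recording start,
and intervals are half-open ``[start_s, end_s)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "EventInterval",
    "WindowDataset",
    "read_recording",
    "write_recording",
    "read_labels",
    "write_labels",
    "read_edf",
    "write_edf",
    "save_window_dataset",
    "load_window_dataset",
]

VALID_LABELS = ("SEM", "NONSEM")


@dataclass
class Recording:
    """Multi-channel recording in microvolts at a fixed sampling rate.

    ``Hl`` and ``Hr`` (the two outer-canthus horizontal EOG electrodes) are
    required; other channels (``O2``, or derived ``HEOG``/``HSUM``) are
    optional.
    """

    channels: dict
    fs: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channels:
            raise ValueError("recording has no channels")
        lengths = {name: len(v) for name, v in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"channel lengths differ: {lengths}")
        for name, v in self.channels.items():
            arr = np.asarray(v, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains NaN/Inf samples")
            self.channels[name] = arr

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.channels]
        if missing:
            raise KeyError(f"recording is missing required channel(s): {missing}")


@dataclass(frozen=True)
class EventInterval:
    """A labeled time span, half-open ``[start_s, end_s)``."""

    start_s: float
    end_s: float
    label: str

    def __post_init__(self) -> None:
        if not (0 <= self.start_s < self.end_s):
            raise ValueError(
                f"invalid interval [{self.start_s}, {self.end_s}): "
                "need 0 <= start_s < end_s"
            )
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {VALID_LABELS}, got {self.label!r}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def validate_intervals(intervals: Sequence[EventInterval]) -> list:
    """Sort intervals by start time and reject overlaps."""
    ordered = sorted(intervals, key=lambda iv: (iv.start_s, iv.end_s))
    offenders = [
        (a, b)
        for a, b in zip(ordered, ordered[1:])
        if b.start_s < a.end_s - 1e-9
    ]
    if offenders:
        lines = "; ".join(
            f"[{a.start_s:.3f},{a.end_s:.3f}) overlaps [{b.start_s:.3f},{b.end_s:.3f})"
            for a, b in offenders
        )
        raise ValueError(f"overlapping intervals: {lines}")
    return ordered


# ---------------------------------------------------------------------------
# Recording CSV


def write_recording(recording: Recording, path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        t = np.arange(recording.n_samples) / recording.fs
        df = pd.DataFrame({"time_s": t})
        for name, v in recording.channels.items():
            df[name] = v
        df.to_csv(path, index=False)
    elif fmt == "edf":
        write_edf(recording, path)
    else:
        raise ValueError(f"unsupported recording format {fmt!r}")


def read_recording(path, fmt: str | None = None, fs: float | None = None) -> Recording:
    """Read a recording from CSV (``fs`` from argument or time column) or EDF."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "edf":
        return read_edf(path)
    if fmt != "csv":
        raise ValueError(f"unsupported recording format {fmt!r}")
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c != "time_s"]
    for required in ("Hl", "Hr"):
        if required not in cols:
            raise KeyError(f"CSV recording is missing channel {required!r}")
    if fs is None:
        if "time_s" not in df.columns or len(df) < 2:
            raise ValueError("fs not given and no time_s column to infer it from")
        fs = 1.0 / float(np.median(np.diff(df["time_s"].to_numpy())))
    return Recording({c: df[c].to_numpy(float) for c in cols}, fs=float(fs))


# ---------------------------------------------------------------------------
# EDF (European Data Format): fixed-layout ASCII header + 16-bit samples.

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _ascii(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path) -> None:
    """Write an EDF file with 1-second data records and physical unit uV.

    The recording length must be a whole number of seconds and the sampling
    rate an integer (both hold for simulator output).
    """
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n = recording.n_samples
    if n % fs != 0:
        raise ValueError("EDF writer requires a whole number of seconds of data")
    n_records = n // fs
    names = list(recording.channels)
    ns = len(names)

    phys_min, phys_max = [], []
    digital = {}
    for name in names:
        x = recording.channels[name]
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi - lo < 1e-6:
            hi = lo + 1.0
        # integer physical bounds survive the 8-char ASCII header exactly,
        # so the reader reconstructs the same gain we digitize with
        lo, hi = float(np.floor(lo)), float(np.ceil(hi))
        phys_min.append(lo)
        phys_max.append(hi)
        gain = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (hi - lo)
        digital[name] = np.round((x - lo) * gain + _EDF_DIG_MIN).astype("<i2")

    header_bytes = 256 * (1 + ns)
    with open(path, "wb") as f:
        f.write(_ascii("0", 8))
        f.write(_ascii(recording.subject_id or "X", 80))
        f.write(_ascii("Startdate 01-JAN-2000", 80))
        f.write(_ascii("01.01.00", 8))
        f.write(_ascii("00.00.00", 8))
        f.write(_ascii(header_bytes, 8))
        f.write(_ascii("", 44))
        f.write(_ascii(n_records, 8))
        f.write(_ascii(1, 8))  # record duration, seconds
        f.write(_ascii(ns, 4))
        for name in names:
            f.write(_ascii(name, 16))
        for _ in names:
            f.write(_ascii("", 80))  # transducer
        for _ in names:
            f.write(_ascii("uV", 8))
        for lo in phys_min:
            f.write(_ascii(int(lo), 8))
        for hi in phys_max:
            f.write(_ascii(int(hi), 8))
        f.write(_ascii(_EDF_DIG_MIN, 8) * ns)
        f.write(_ascii(_EDF_DIG_MAX, 8) * ns)
        for _ in names:
            f.write(_ascii("", 80))  # prefiltering
        f.write(_ascii(fs, 8) * ns)  # samples per record
        f.write(_ascii("", 32) * ns)
        for rec in range(n_records):
            sl = slice(rec * fs, (rec + 1) * fs)
            for name in names:
                f.write(digital[name][sl].tobytes())


def read_edf(path) -> Recording:
    """Read an EDF file written by :func:`write_edf` (or any plain EDF)."""
    with open(path, "rb") as f:
        head = f.read(256)
        subject_id = head[8:88].decode("ascii").strip()
        n_records = int(head[236:244])
        record_dur = float(head[244:252])
        ns = int(head[252:256])
        sig = f.read(256 * ns)

        def fields(offset: int, width: int) -> list:
            base = offset * ns
            return [
                sig[base + i * width : base + (i + 1) * width].decode("ascii").strip()
                for i in range(ns)
            ]

        labels = fields(0, 16)
        phys_min = [float(v) for v in fields(16 + 80 + 8, 8)]
        phys_max = [float(v) for v in fields(16 + 80 + 8 + 8, 8)]
        dig_min = [int(v) for v in fields(16 + 80 + 8 + 16, 8)]
        dig_max = [int(v) for v in fields(16 + 80 + 8 + 24, 8)]
        nspr = [int(v) for v in fields(16 + 80 + 8 + 32 + 80, 8)]

        data = {name: [] for name in labels}
        for _ in range(n_records):
            for i, name in enumerate(labels):
                raw = np.frombuffer(f.read(2 * nspr[i]), dtype="<i2")
                data[name].append(raw)

    channels = {}
    fs = None
    for i, name in enumerate(labels):
        dig = np.concatenate(data[name]).astype(float)
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        channels[name] = (dig - dig_min[i]) * gain + phys_min[i]
        fs = nspr[i] / record_dur
    return Recording(channels, fs=fs, subject_id=subject_id)


# ---------------------------------------------------------------------------
# Interval label CSV


def write_labels(intervals: Sequence[EventInterval], path) -> None:
    ordered = validate_intervals(intervals)
    df = pd.DataFrame(
        {
            "start_s": [iv.start_s for iv in ordered],
            "end_s": [iv.end_s for iv in ordered],
            "label": [iv.label for iv in ordered],
        }
    )
    df.to_csv(path, index=False)


def read_labels(path) -> list:
    df = pd.read_csv(path)
    expected = ["start_s", "end_s", "label"]
    if list(df.columns)[:3] != expected:
        raise ValueError(f"label CSV must have header {expected}, got {list(df.columns)}")
    intervals = [
        EventInterval(float(r.start_s), float(r.end_s), str(r.label))
        for r in df.itertuples()
    ]
    return validate_intervals(intervals)


# ---------------------------------------------------------------------------
# Window dataset container (HDF5)


@dataclass
class WindowDataset:
    """Paired bimodal window samples ready for the classifier.

    ``X`` has shape ``(n, 2, win)`` (modality 1 then modality 2), ``y`` is
    0/1 (1 = SEM), ``t_start`` the window start time in seconds.
    """

    X: np.ndarray
    y: np.ndarray
    t_start: np.ndarray
    fs: float
    modalities: tuple
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float32)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.t_start = np.asarray(self.t_start, dtype=float)
        if self.X.ndim != 3 or self.X.shape[1] != 2:
            raise ValueError(f"X must have shape (n, 2, win), got {self.X.shape}")
        if not (len(self.X) == len(self.y) == len(self.t_start)):
            raise ValueError("X, y, t_start must have equal length")

    def __len__(self) -> int:
        return len(self.y)


def save_window_dataset(dataset: WindowDataset, path) -> None:
    if len(dataset) == 0:
        raise ValueError("refusing to save an empty window dataset")
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=dataset.X)
        f.create_dataset("y", data=dataset.y)
        f.create_dataset("t_start", data=dataset.t_start)
        f.attrs["fs"] = dataset.fs
        f.attrs["modalities"] = ",".join(dataset.modalities)
        f.attrs["subject_id"] = dataset.subject_id


def load_window_dataset(path) -> WindowDataset:
    try:
        with h5py.File(path, "r") as f:
            return WindowDataset(
                X=f["X"][...],
                y=f["y"][...],
                t_start=f["t_start"][...],
                fs=float(f.attrs["fs"]),
                modalities=tuple(str(f.attrs["modalities"]).split(",")),
                subject_id=str(f.attrs["subject_id"]),
            )
    except OSError as exc:
        raise OSError(f"could not load window dataset from {path}: {exc}") from exc
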