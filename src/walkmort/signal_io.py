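"""Reading, writing and epoch segmentation of raw tri-axial recordings.

Two on-disk formats are supported:

* plain CSV with mandatory header ``t,x,y,z`` (time in seconds, acceleration
  in g) — convenient for tests and small excerpts;
* a chunk-free columnar binary container (magic ``WMB1``, JSON header with
  sampling rate / start time / sample count, then float64 little-endian
  ``(n, 3)`` data) — practical for week-long files.

Units are g throughout (1 g = 9.81 m/s^2); inputs recorded in m/s^2 can be
converted at read time.  The original CWA device format is out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

G_IN_MS2 = 9.81
_MAGIC = b"WMB1"

WALKING = "walking"
OTHER = "other"

__all__ = [
    "RawRecording",
    "Epoch",
    "read_recording",
    "write_recording",
    "segment_epochs",
    "read_labels",
    "write_labels",
    "WALKING",
    "OTHER",
]


@dataclass
class RawRecording:
    """A fixed-rate tri-axial acceleration stream in g."""

    samples: np.ndarray  # (n, 3) float
    sampling_rate_hz: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError(f"samples must be (n, 3); got {self.samples.shape}")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate_hz


@dataclass
class Epoch:
    """One non-overlapping fixed-length window with a single activity label."""

    index: int
    samples: np.ndarray  # (rate * duration_s, 3)
    label: str = OTHER
    duration_s: float = 30.0


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "binary" if path.suffix in {".wmb", ".bin"} else "csv"


def read_recording(path, fmt: str | None = None, unit: str = "g") -> RawRecording:
    """Read a recording; ``unit='ms2'`` converts m/s^2 input to g.

    CSV requires the exact header columns ``t, x, y, z``; malformed rows,
    non-monotone timestamps and NaNs raise a parse error naming the row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        rec = _read_csv(path)
    elif fmt == "binary":
        rec = _read_binary(path)
    else:
        raise ValueError(f"unknown recording format {fmt!r}")
    if unit == "ms2":
        rec.samples = rec.samples / G_IN_MS2
    elif unit != "g":
        raise ValueError(f"unknown unit {unit!r}; expected 'g' or 'ms2'")
    return rec


def _read_csv(path: Path) -> RawRecording:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty recording file") from None
    required = ["t", "x", "y", "z"]
    if list(df.columns[:4]) != required:
        raise ValueError(f"{path}: CSV header must start with {required}, got {list(df.columns)}")
    if len(df) == 0:
        raise ValueError(f"{path}: recording has no samples")
    arr = df[required].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(arr).all(axis=1))
    if bad.size:
        raise ValueError(f"{path}: non-finite value at data row {bad[0]}")
    t = arr[:, 0]
    if len(t) > 1:
        dt = np.diff(t)
        nonmono = np.flatnonzero(dt <= 0)
        if nonmono.size:
            raise ValueError(f"{path}: non-monotone timestamp at data row {nonmono[0] + 1}")
        rate = 1.0 / float(np.median(dt))
    else:
        rate = 1.0
    return RawRecording(samples=arr[:, 1:], sampling_rate_hz=rate, start_time=float(t[0]))


def _read_binary(path: Path) -> RawRecording:
    with open(path, "rb") as fh:
        magic = fh.read(4)
        if magic != _MAGIC:
            raise ValueError(f"{path}: not a WMB recording (bad magic {magic!r})")
        (hlen,) = np.frombuffer(fh.read(4), dtype="<u4")
        header = json.loads(fh.read(int(hlen)).decode("utf-8"))
        n = int(header["n_samples"])
        data = np.frombuffer(fh.read(n * 3 * 8), dtype="<f8")
        if data.size != n * 3:
            raise ValueError(f"{path}: truncated data block ({data.size} of {n * 3} values)")
    return RawRecording(
        samples=data.reshape(n, 3).copy(),
        sampling_rate_hz=float(header["sampling_rate_hz"]),
        start_time=float(header.get("start_time", 0.0)),
    )


def write_recording(recording: RawRecording, path, fmt: str | None = None) -> Path:
    """Write a recording as CSV (t,x,y,z) or the WMB binary container."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        df = pd.DataFrame(
            {
                "t": recording.times(),
                "x": recording.samples[:, 0],
                "y": recording.samples[:, 1],
                "z": recording.samples[:, 2],
            }
        )
        df.to_csv(path, index=False, float_format="%.17g")
    elif fmt == "binary":
        header = json.dumps(
            {
                "sampling_rate_hz": recording.sampling_rate_hz,
                "start_time": recording.start_time,
                "n_samples": recording.n_samples,
            }
        ).encode("utf-8")
        with open(path, "wb") as fh:
            fh.write(_MAGIC)
            fh.write(np.uint32(len(header)).tobytes())
            fh.write(header)
            fh.write(np.ascontiguousarray(recording.samples, dtype="<f8").tobytes())
    else:
        raise ValueError(f"unknown recording format {fmt!r}")
    return path


def segment_epochs(recording: RawRecording, labels, epoch_s: float = 30.0) -> list[Epoch]:
    """Cut the stream into contiguous non-overlapping labeled epochs.

    The trailing partial window is dropped; ``labels`` must supply exactly one
    label per complete epoch.
    """
    if epoch_s <= 0:
        raise ValueError("epoch_s must be positive")
    spe = int(round(recording.sampling_rate_hz * epoch_s))
    n_epochs = recording.n_samples // spe
    labels = list(labels)
    if len(labels) != n_epochs:
        raise ValueError(f"label count {len(labels)} != complete epoch count {n_epochs}")
    return [
        Epoch(
            index=i,
            samples=recording.samples[i * spe : (i + 1) * spe],
            label=labels[i],
            duration_s=epoch_s,
        )
        for i in range(n_epochs)
    ]


def read_labels(path) -> list[str]:
    """Read an epoch-label file: CSV with columns (epoch_index, label)."""
    df = pd.read_csv(path)
    required = {"epoch_index", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: labels file needs columns {sorted(required)}")
    df = df.sort_values("epoch_index")
    idx = df["epoch_index"].to_numpy()
    if not np.array_equal(idx, np.arange(len(idx))):
        raise ValueError(f"{path}: epoch_index must be 0..n-1 without gaps")
    return df["label"].astype(str).tolist()


def write_labels(labels, path) -> Path:
    path = Path(path)
    pd.DataFrame({"epoch_index": np.arange(len(labels)), "label": list(labels)}).to_csv(
        path, index=False
    )
    return path
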