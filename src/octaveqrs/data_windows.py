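"""Recordings, windowing, frame labels, record splits, noise injection, IO.

A recording is a 4-channel abdominal ECG sampled at 1000 Hz (microvolts)
with fetal-QRS annotations as strictly increasing 0-based sample indices.
Training operates on one-second 4 x 1000 windows, each carrying ten binary
frame labels: frame j is positive iff an annotation falls in the half-open
interval ``[start + 100 j, start + 100 (j + 1))``.

IO covers a plain CSV dialect plus text annotation lists for synthetic
data, a minimal reader/writer for WFDB format-16 records (.hea/.dat), and
an HDF5 container packing all windows of a dataset for training.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "SignalWindow",
    "extract_windows",
    "windows_to_arrays",
    "standardize_windows",
    "split_records",
    "PHYSIONET_EXCLUDED",
    "add_gaussian_noise",
    "add_motion_artifact",
    "read_csv_recording",
    "read_wfdb_record",
    "write_recording",
    "windows_to_hdf5",
    "windows_from_hdf5",
]

REQUIRED_CHANNELS = 4
REQUIRED_FS = 1000

#: Set-A records with inaccurate reference annotations, excluded everywhere.
PHYSIONET_EXCLUDED = frozenset({"a33", "a38", "a47", "a52", "a54", "a71", "a74"})


@dataclass
class Recording:
    """One multi-channel recording with fetal R-peak ground truth."""

    signals: np.ndarray  # (channels, samples), microvolts
    fqrs_annotations: np.ndarray  # strictly increasing sample indices
    record_id: str
    sampling_rate: int = REQUIRED_FS
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.fqrs_annotations = np.asarray(self.fqrs_annotations, dtype=np.int64)
        if self.signals.ndim != 2:
            raise ValueError("signals must be (channels, samples)")
        ann = self.fqrs_annotations
        if ann.size:
            if np.any(np.diff(ann) <= 0):
                raise ValueError("annotations must be strictly increasing")
            if ann[0] < 0 or ann[-1] >= self.num_samples:
                raise ValueError("annotations must lie within [0, num_samples)")

    @property
    def num_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def num_channels(self) -> int:
        return self.signals.shape[0]


@dataclass
class SignalWindow:
    """One 4 x 1000 excerpt with per-frame fQRS labels."""

    samples: np.ndarray  # (channels, window_length)
    frame_labels: np.ndarray  # (frames,), binary
    record_id: str = ""
    start: int = 0


def frame_labels_for_window(
    annotations: np.ndarray, start: int, window_length: int, n_frames: int
) -> np.ndarray:
    frame_length = window_length // n_frames
    labels = np.zeros(n_frames, dtype=np.int64)
    in_win = annotations[(annotations >= start) & (annotations < start + window_length)]
    if in_win.size:
        labels[np.unique((in_win - start) // frame_length)] = 1
    return labels


def extract_windows(
    rec: Recording,
    stride: int = 1000,
    window_length: int = 1000,
    n_frames: int = 10,
) -> list[SignalWindow]:
    """Cut a recording into labeled windows starting at 0, stride, 2*stride...

    Trailing samples that do not fill a whole window are dropped.  Each
    annotation inside a retained window labels exactly one frame.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if rec.num_samples < window_length:
        warnings.warn(
            f"recording {rec.record_id!r} shorter than one window; no windows extracted",
            stacklevel=2,
        )
        return []
    out = []
    for start in range(0, rec.num_samples - window_length + 1, stride):
        out.append(
            SignalWindow(
                samples=rec.signals[:, start : start + window_length],
                frame_labels=frame_labels_for_window(
                    rec.fqrs_annotations, start, window_length, n_frames
                ),
                record_id=rec.record_id,
                start=start,
            )
        )
    return out


def windows_to_arrays(windows: list[SignalWindow]) -> tuple[np.ndarray, np.ndarray]:
    """Stack windows into (N, C, L) samples and (N, frames) labels."""
    x = np.stack([w.samples for w in windows])
    y = np.stack([w.frame_labels for w in windows])
    return x, y


def standardize_windows(x: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Per-window, per-channel standardization to zero mean, unit variance."""
    mu = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    return (x - mu) / (sd + eps)


_SETA_ID = re.compile(r"^a(\d\d)$")


def split_records(record_ids: list[str]) -> tuple[list[str], list[str], list[str]]:
    """Partition set-A record ids into (train, val, test).

    Test is a01-a07, validation a08-a13, training the remainder minus the
    records with inaccurate reference annotations.  With the full a01-a75
    this yields 55/6/7 records.
    """
    train, val, test = [], [], []
    for rid in record_ids:
        m = _SETA_ID.match(rid)
        if not m or not 1 <= int(m.group(1)) <= 75:
            raise ValueError(f"unknown record id {rid!r}: expected a01..a75")
        if rid in PHYSIONET_EXCLUDED:
            continue
        num = int(m.group(1))
        (test if num <= 7 else val if num <= 13 else train).append(rid)
    return train, val, test


def add_gaussian_noise(rec: Recording, level: float, seed) -> Recording:
    """Add scaled Gaussian noise, emulating sensor noise at graded levels.

    The base noise is zero-mean Gaussian rescaled so its maximum absolute
    value over the recording is 4 microvolts, then multiplied by ``level``
    (typical levels: 3, 6, 9).  Annotations are untouched.
    """
    if level <= 0:
        raise ValueError("level must be positive")
    rng = np.random.default_rng(seed)
    base = rng.standard_normal(rec.signals.shape)
    base *= 4.0 / np.max(np.abs(base))
    return Recording(
        signals=rec.signals + level * base,
        fqrs_annotations=rec.fqrs_annotations.copy(),
        record_id=rec.record_id,
        sampling_rate=rec.sampling_rate,
        meta={**rec.meta, "gaussian_noise_level": level},
    )


def motion_artifact_trace(
    num_samples: int,
    severity: float,
    rng: np.random.Generator,
    sampling_rate: int = REQUIRED_FS,
    n_sinusoids: int = 8,
    step_rate_hz: float = 0.05,
) -> np.ndarray:
    """Synthetic motion-like artifact: random-phase 0.1-1 Hz sinusoids plus
    sparse smoothed step transients, scaled by ``severity``."""
    t = np.arange(num_samples) / sampling_rate
    freqs = rng.uniform(0.1, 1.0, n_sinusoids)
    phases = rng.uniform(0, 2 * np.pi, n_sinusoids)
    amps = rng.uniform(0.2, 1.0, n_sinusoids)
    artifact = (amps[:, None] * np.sin(2 * np.pi * freqs[:, None] * t + phases[:, None])).sum(0)
    artifact /= n_sinusoids
    n_steps = rng.poisson(step_rate_hz * num_samples / sampling_rate)
    ramp_len = sampling_rate // 2
    for _ in range(n_steps):
        pos = rng.integers(0, num_samples)
        height = rng.uniform(-1.0, 1.0)
        ramp = np.clip((np.arange(num_samples) - pos) / ramp_len, 0.0, 1.0)
        artifact += height * ramp
    return severity * artifact


def add_motion_artifact(rec: Recording, severity: float, seed) -> Recording:
    """Min-max normalize each channel to [-1, 1], then add a motion-like
    baseline artifact.  Annotations are untouched."""
    if severity < 0:
        raise ValueError("severity must be >= 0")
    rng = np.random.default_rng(seed)
    signals = np.empty_like(rec.signals)
    for i, ch in enumerate(rec.signals):
        lo, hi = ch.min(), ch.max()
        if hi - lo == 0:
            raise ValueError(f"channel {i} is constant; [-1, 1] normalization undefined")
        signals[i] = 2.0 * (ch - lo) / (hi - lo) - 1.0
        signals[i] += motion_artifact_trace(rec.num_samples, severity, rng, rec.sampling_rate)
    return Recording(
        signals=signals,
        fqrs_annotations=rec.fqrs_annotations.copy(),
        record_id=rec.record_id,
        sampling_rate=rec.sampling_rate,
        meta={**rec.meta, "motion_severity": severity},
    )


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

_CSV_HEADER = ["ch1", "ch2", "ch3", "ch4"]


def _annotation_path(base: Path) -> Path:
    return base.with_suffix(".fqrs.txt")


def _read_annotations(path: Path) -> np.ndarray:
    if not path.exists():
        return np.empty(0, dtype=np.int64)
    values = [int(line) for line in path.read_text().split()]
    return np.asarray(values, dtype=np.int64)


def read_csv_recording(path) -> Recording:
    """Read the CSV dialect: header ``ch1,ch2,ch3,ch4``, one sample per
    line, with annotations in ``<stem>.fqrs.txt`` beside it."""
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != _CSV_HEADER:
        raise ValueError(f"CSV must have columns {_CSV_HEADER}, got {list(df.columns)}")
    return Recording(
        signals=df.to_numpy().T,
        fqrs_annotations=_read_annotations(_annotation_path(path)),
        record_id=path.stem,
    )


def read_wfdb_record(path) -> Recording:
    """Read a WFDB format-16 record (``<record>.hea`` + ``<record>.dat``).

    Supports the subset this package writes: 4 channels, 1000 Hz, 16-bit
    two's-complement samples with per-channel gain (adu per microvolt) and
    baseline.  Fetal QRS annotations are read from ``<record>.fqrs.txt``.
    """
    path = Path(path)
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"missing header file {hea}")
    lines = [
        ln
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    record_name, n_sig = head[0], int(head[1])
    fs = int(float(head[2])) if len(head) > 2 else 250
    n_samples = int(head[3]) if len(head) > 3 else None
    if n_sig != REQUIRED_CHANNELS:
        raise ValueError(
            f"record {record_name!r} has {n_sig} channels; this detector requires "
            f"{REQUIRED_CHANNELS} abdominal channels"
        )
    if fs != REQUIRED_FS:
        raise ValueError(f"record {record_name!r} sampled at {fs} Hz; {REQUIRED_FS} Hz required")
    gains, baselines = [], []
    dat_name = None
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        dat_name = tok[0]
        if len(tok) < 2 or tok[1].split("x")[0] != "16":
            raise ValueError(f"unsupported WFDB signal format in line: {ln!r} (format 16 only)")
        gain_field = tok[2] if len(tok) > 2 else "200"
        m = re.match(r"([-+0-9.eE]+)(?:\(([-+0-9]+)\))?(?:/(\S+))?", gain_field)
        gains.append(float(m.group(1)) if m else 200.0)
        baselines.append(int(m.group(2)) if m and m.group(2) else 0)
    dat = path.parent / dat_name
    if not dat.exists():
        raise FileNotFoundError(f"missing signal file {dat}")
    raw = np.fromfile(dat, dtype="<i2")
    if n_samples is None:
        n_samples = raw.size // n_sig
    digital = raw[: n_samples * n_sig].reshape(n_samples, n_sig).T.astype(float)
    physical = (digital - np.asarray(baselines)[:, None]) / np.asarray(gains)[:, None]
    return Recording(
        signals=physical,
        fqrs_annotations=_read_annotations(_annotation_path(path)),
        record_id=record_name,
        sampling_rate=fs,
    )


def write_recording(rec: Recording, path, fmt: str = "csv", gain: float = 100.0) -> Path:
    """Write a recording as CSV or WFDB format 16, plus the annotation list.

    Returns the primary file written (.csv or .hea).  WFDB digitization
    uses ``gain`` adu per microvolt with baseline 0; values are clipped to
    the int16 range.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if rec.num_channels != REQUIRED_CHANNELS:
        raise ValueError(f"recordings must have {REQUIRED_CHANNELS} channels")
    if fmt == "csv":
        out = path.with_suffix(".csv")
        pd.DataFrame(rec.signals.T, columns=_CSV_HEADER).to_csv(out, index=False)
    elif fmt == "wfdb":
        out = path.with_suffix(".hea")
        digital = np.clip(np.round(rec.signals * gain), -32768, 32767).astype("<i2")
        dat = path.with_suffix(".dat")
        digital.T.reshape(-1).tofile(dat)  # sample-interleaved
        lines = [f"{path.stem} {rec.num_channels} {rec.sampling_rate} {rec.num_samples}"]
        for i in range(rec.num_channels):
            first = int(digital[i, 0]) if rec.num_samples else 0
            lines.append(f"{dat.name} 16 {gain:g}(0)/uV 16 0 {first} 0 0 ch{i + 1}")
        out.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}: use 'csv' or 'wfdb'")
    ann_path = _annotation_path(path)
    ann_path.write_text("\n".join(str(int(a)) for a in rec.fqrs_annotations) + "\n")
    return out


def windows_to_hdf5(windows: list[SignalWindow], path) -> None:
    """Pack a window list into one HDF5 file (samples, labels, sources)."""
    x, y = windows_to_arrays(windows)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("samples", data=x)
        fh.create_dataset("frame_labels", data=y)
        fh.create_dataset(
            "source", data=np.array([f"{w.record_id}:{w.start}" for w in windows], dtype="S")
        )


def windows_from_hdf5(path) -> list[SignalWindow]:
    with h5py.File(path, "r") as fh:
        x = fh["samples"][...]
        y = fh["frame_labels"][...]
        src = [s.decode() for s in fh["source"][...]]
    out = []
    for xi, yi, si in zip(x, y, src):
        rid, _, start = si.rpartition(":")
        out.append(SignalWindow(samples=xi, frame_labels=yi, record_id=rid, start=int(start)))
    return out
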