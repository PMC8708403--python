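"""Domain types for uniformly sampled waveforms plus CSV / WFDB record I/O.

Everything downstream operates on :class:`TimedSignal` — a 1-D real waveform
with a sampling rate — and on 10-second :class:`SegmentPair` windows that pair
an ECG segment with its time-aligned, resampled 3-axis accelerometer segment.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .errors import ContractError, FormatError, ParseError

__all__ = [
    "TimedSignal",
    "AccelTriplet",
    "SegmentPair",
    "read_csv_record",
    "write_csv_record",
    "read_wfdb_record",
    "write_wfdb_record",
    "segment_recording",
]


@dataclass
class TimedSignal:
    """A uniformly sampled real-valued waveform.

    Parameters
    ----------
    samples : array-like of float
        Sample values (normalized voltage or acceleration; unitless after
        normalization). Must be finite and non-empty.
    fs : float
        Sampling rate in Hz, strictly positive.
    label : str
        Free-text channel name.
    allow_gaps : bool
        Permit NaN samples; used only for assembled pipeline output where
        rejected segments are explicit gaps.
    """

    samples: np.ndarray
    fs: float
    label: str = ""
    allow_gaps: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ContractError("samples must be a non-empty 1-D sequence")
        if not self.allow_gaps and not np.all(np.isfinite(self.samples)):
            raise ContractError("samples must all be finite")
        if not (self.fs > 0):
            raise ContractError(f"fs must be > 0, got {self.fs}")
        self.fs = float(self.fs)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        """Duration in seconds (length / fs)."""
        return self.samples.size / self.fs

    def with_samples(self, samples: np.ndarray, label: str | None = None) -> "TimedSignal":
        """A copy of this signal carrying new samples (same fs)."""
        return TimedSignal(samples, self.fs, self.label if label is None else label)


@dataclass
class AccelTriplet:
    """Three accelerometer channels sharing one sampling rate and length."""

    ax: TimedSignal
    ay: TimedSignal
    az: TimedSignal

    def __post_init__(self) -> None:
        fs = {self.ax.fs, self.ay.fs, self.az.fs}
        n = {len(self.ax), len(self.ay), len(self.az)}
        if len(fs) != 1 or len(n) != 1:
            raise ContractError("accelerometer channels must share fs and length")

    @property
    def fs(self) -> float:
        return self.ax.fs

    def __len__(self) -> int:
        return len(self.ax)

    def channels(self) -> tuple[TimedSignal, TimedSignal, TimedSignal]:
        return (self.ax, self.ay, self.az)

    def map(self, fn) -> "AccelTriplet":
        """Apply ``fn(TimedSignal) -> TimedSignal`` to all three channels."""
        return AccelTriplet(fn(self.ax), fn(self.ay), fn(self.az))


@dataclass
class SegmentPair:
    """One analysis window: ECG segment + time-aligned accelerometer segment."""

    ecg: TimedSignal
    accel: AccelTriplet
    index: int

    def __post_init__(self) -> None:
        if self.ecg.fs != self.accel.fs:
            raise ContractError("ECG and accelerometer fs must match within a segment")
        if len(self.ecg) != len(self.accel):
            raise ContractError("ECG and accelerometer length must match within a segment")


def read_csv_record(
    path: Union[str, Path],
    fs: float,
    columns: Union[str, Sequence[str]],
    allow_gaps: bool = False,
) -> Union[TimedSignal, AccelTriplet]:
    """Read one channel (str) or three channels (sequence of 3 names) from a CSV.

    The file is expected to be comma-separated with one header row and one
    sample per row; row order is preserved and no resampling happens here.
    With ``allow_gaps`` NaN cells are kept (pipeline output marks rejected
    segments that way); otherwise any non-numeric cell is an error.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except FileNotFoundError:
        raise
    wanted = [columns] if isinstance(columns, str) else list(columns)
    missing = [c for c in wanted if c not in frame.columns]
    if missing:
        raise FormatError(
            f"{path.name}: missing column(s) {missing}; present: {list(frame.columns)}"
        )
    signals = []
    for name in wanted:
        col = frame[name]
        values = pd.to_numeric(col, errors="coerce").to_numpy(dtype=np.float64)
        bad = np.flatnonzero(~np.isfinite(values))
        if bad.size and not allow_gaps:
            raise ParseError(
                f"{path.name}: non-numeric cell in column {name!r} at row {int(bad[0])}",
                row=int(bad[0]),
            )
        signals.append(TimedSignal(values, fs, label=name, allow_gaps=allow_gaps))
    if isinstance(columns, str):
        return signals[0]
    if len(signals) != 3:
        raise ContractError("expect exactly 1 or 3 column names")
    return AccelTriplet(*signals)


def write_csv_record(path: Union[str, Path], signal: Union[TimedSignal, AccelTriplet]) -> None:
    """Write a signal (or triplet) as CSV, full precision, one sample per row."""
    path = Path(path)
    if isinstance(signal, AccelTriplet):
        frame = pd.DataFrame(
            {
                (signal.ax.label or "ax"): signal.ax.samples,
                (signal.ay.label or "ay"): signal.ay.samples,
                (signal.az.label or "az"): signal.az.samples,
            }
        )
    else:
        frame = pd.DataFrame({(signal.label or "signal"): signal.samples})
    frame.to_csv(path, index=False, float_format="%.17g")


# --- Minimal WFDB (format 16, single segment) support ----------------------
#
# Header:  "<record> <nsig> <fs> <nsamp>" then one line per signal:
#          "<file> 16 <gain>(<baseline>)/<units> 16 0 <first> <checksum> 0 <label>"
# Signal file: interleaved little-endian int16; physical = (adc - baseline)/gain.

_WFDB_GAIN = 2000.0  # ADC units per physical unit; LSB = 0.5e-3


def write_wfdb_record(
    record_base: Union[str, Path],
    signals: Sequence[TimedSignal],
    units: str = "mV",
) -> None:
    """Write a format-16 WFDB record (``<base>.hea`` + ``<base>.dat``)."""
    record_base = Path(record_base)
    if not signals:
        raise ContractError("need at least one signal")
    fs = signals[0].fs
    n = len(signals[0])
    if any(s.fs != fs or len(s) != n for s in signals):
        raise ContractError("all channels must share fs and length")
    adc = np.empty((n, len(signals)), dtype=np.int16)
    for j, s in enumerate(signals):
        q = np.clip(np.rint(s.samples * _WFDB_GAIN), -32768, 32767)
        adc[:, j] = q.astype(np.int16)
    dat_name = record_base.name + ".dat"
    lines = [f"{record_base.name} {len(signals)} {fs:.17g} {n}"]
    for j, s in enumerate(signals):
        checksum = int(np.sum(adc[:, j], dtype=np.int64) % 65536)
        lines.append(
            f"{dat_name} 16 {_WFDB_GAIN:g}(0)/{units} 16 0 "
            f"{int(adc[0, j])} {checksum} 0 {s.label or f'ch{j}'}"
        )
    record_base.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    record_base.with_suffix(".dat").write_bytes(adc.tobytes())


def read_wfdb_record(record_base: Union[str, Path], channel: Union[int, str] = 0) -> TimedSignal:
    """Read one channel of a format-16 WFDB record, converted to physical units."""
    record_base = Path(record_base)
    header = record_base.with_suffix(".hea")
    if not header.exists():
        raise FileNotFoundError(header)
    lines = [ln for ln in header.read_text().splitlines() if ln.strip() and not ln.startswith("#")]
    rec_fields = lines[0].split()
    nsig = int(rec_fields[1])
    fs = float(rec_fields[2])
    nsamp = int(rec_fields[3])
    sig_lines = lines[1 : 1 + nsig]
    labels = []
    gains = []
    baselines = []
    for ln in sig_lines:
        parts = ln.split()
        if parts[1] != "16":
            raise FormatError(f"only format 16 supported, got {parts[1]}")
        gain_spec = parts[2]
        gain_part = gain_spec.split("/")[0]
        if "(" in gain_part:
            g, b = gain_part.split("(")
            gains.append(float(g))
            baselines.append(int(b.rstrip(")")))
        else:
            gains.append(float(gain_part))
            baselines.append(0)
        labels.append(parts[-1])
    if isinstance(channel, str):
        if channel not in labels:
            raise LookupError(f"channel {channel!r} not in {labels}")
        idx = labels.index(channel)
    else:
        if not (0 <= channel < nsig):
            raise LookupError(f"channel index {channel} out of range (nsig={nsig})")
        idx = channel
    raw = record_base.with_suffix(".dat").read_bytes()
    adc = np.frombuffer(raw, dtype="<i2").reshape(nsamp, nsig)
    physical = (adc[:, idx].astype(np.float64) - baselines[idx]) / gains[idx]
    return TimedSignal(physical, fs, label=labels[idx])


def segment_recording(
    ecg: TimedSignal,
    accel: AccelTriplet,
    window_s: float = 10.0,
) -> list[SegmentPair]:
    """Cut an aligned recording into consecutive non-overlapping windows.

    The accelerometer must already be resampled to ``ecg.fs`` and carry the
    same number of samples. The trailing partial window (if any) is dropped,
    because downstream stages assume a fixed expected beat count per window.
    """
    if accel.fs != ecg.fs:
        raise ContractError("accelerometer must be resampled to the ECG rate first")
    if len(accel) != len(ecg):
        raise ContractError(
            f"length mismatch: ecg {len(ecg)} vs accel {len(accel)} samples"
        )
    win = int(round(window_s * ecg.fs))
    if win < 1:
        raise ContractError("window too short")
    n_seg = len(ecg) // win
    pairs = []
    for i in range(n_seg):
        sl = slice(i * win, (i + 1) * win)
        pairs.append(
            SegmentPair(
                ecg=TimedSignal(ecg.samples[sl], ecg.fs, ecg.label),
                accel=AccelTriplet(
                    TimedSignal(accel.ax.samples[sl], ecg.fs, accel.ax.label),
                    TimedSignal(accel.ay.samples[sl], ecg.fs, accel.ay.label),
                    TimedSignal(accel.az.samples[sl], ecg.fs, accel.az.label),
                ),
                index=i,
            )
        )
    return pairs
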