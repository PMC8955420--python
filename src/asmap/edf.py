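"""Minimal European Data Format (EDF) reader and writer.

Implements the plain EDF subset this package needs: identical sampling
rate on every signal, 16-bit samples, physical range defaulting to
+/-500 microvolts (typical scalp-EEG headroom). Values outside the
physical range are clipped on write; round trips are exact to one
quantization step ``(phys_max - phys_min) / (dig_max - dig_min)``.

Layout per the EDF specification: a 256-byte fixed header, 256 bytes of
signal header per signal, then data records of little-endian int16,
channel-sequential within each record.
"""

from __future__ import annotations

import math
from datetime import datetime
from pathlib import Path

import numpy as np

from asmap.errors import FormatError, ValidationError
from asmap.recording import EEGRecording

__all__ = ["read_edf", "write_edf", "quantization_step"]

_DIG_MIN = -32768
_DIG_MAX = 32767
DEFAULT_PHYSICAL_RANGE = (-500.0, 500.0)


def quantization_step(phys_min: float, phys_max: float) -> float:
    """Amplitude resolution of one digital count for the given physical range."""
    return (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValidationError(f"EDF header field {s!r} exceeds {width} ASCII bytes")
    return s.ljust(width).encode("ascii")


def write_edf(
    rec: EEGRecording,
    path: str | Path,
    physical_range: tuple[float, float] = DEFAULT_PHYSICAL_RANGE,
) -> None:
    """Write ``rec`` as a single-header EDF file.

    Uses 1-second data records when the sample count divides evenly,
    otherwise one record spanning the whole signal (duration is an ASCII
    field, so any rational length fits).
    """
    path = Path(path)
    phys_min, phys_max = physical_range
    if not phys_min < phys_max:
        raise ValidationError(f"physical range must be increasing, got {physical_range}")
    n_channels, n_samples = rec.data.shape

    fs_int = int(rec.fs)
    if float(rec.fs).is_integer() and n_samples % fs_int == 0:
        n_records = n_samples // fs_int
        samples_per_record = fs_int
        record_duration = 1.0
    else:
        n_records = 1
        samples_per_record = n_samples
        record_duration = n_samples / rec.fs

    dur_str = _ascii_number(record_duration, 8)
    header_bytes = 256 * (1 + n_channels)

    scale = (_DIG_MAX - _DIG_MIN) / (phys_max - phys_min)
    digital = np.clip(rec.data, phys_min, phys_max)
    digital = np.round((digital - phys_min) * scale + _DIG_MIN).astype("<i2")

    patient = rec.subject_id or "X"
    recording_id = rec.trial_id or "X"
    now = datetime(2000, 1, 1)  # fixed stamp: byte-identical reruns

    with open(path, "wb") as f:
        f.write(_field("0", 8))
        f.write(_field(patient, 80))
        f.write(_field(recording_id, 80))
        f.write(_field(now.strftime("%d.%m.%y"), 8))
        f.write(_field(now.strftime("%H.%M.%S"), 8))
        f.write(_field(str(header_bytes), 8))
        f.write(_field("", 44))
        f.write(_field(str(n_records), 8))
        f.write(_field(dur_str, 8))
        f.write(_field(str(n_channels), 4))
        for name in rec.channel_names:
            f.write(_field(name, 16))
        for _ in rec.channel_names:
            f.write(_field("", 80))  # transducer
        for _ in rec.channel_names:
            f.write(_field("uV", 8))
        for _ in rec.channel_names:
            f.write(_field(_ascii_number(phys_min, 8), 8))
        for _ in rec.channel_names:
            f.write(_field(_ascii_number(phys_max, 8), 8))
        for _ in rec.channel_names:
            f.write(_field(str(_DIG_MIN), 8))
        for _ in rec.channel_names:
            f.write(_field(str(_DIG_MAX), 8))
        for _ in rec.channel_names:
            f.write(_field("", 80))  # prefiltering
        for _ in rec.channel_names:
            f.write(_field(str(samples_per_record), 8))
        for _ in rec.channel_names:
            f.write(_field("", 32))
        # data records: channel-sequential chunks
        for r in range(n_records):
            sl = slice(r * samples_per_record, (r + 1) * samples_per_record)
            f.write(digital[:, sl].tobytes())


def _ascii_number(x: float, width: int) -> str:
    """Shortest decimal representation of ``x`` fitting in ``width`` chars."""
    if float(x).is_integer():
        s = str(int(x))
    else:
        s = repr(round(float(x), 6))
        if len(s) > width:
            s = f"{x:.{max(width - 7, 1)}g}"
    if len(s) > width:
        raise ValidationError(f"number {x} does not fit an EDF {width}-char field")
    return s


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF file written under the conventions of :func:`write_edf`.

    Requires all signals to share one sampling rate; rejects files whose
    header arithmetic is inconsistent.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise FormatError(f"{path}: truncated EDF header ({len(raw)} bytes)")

    def ascii_at(offset: int, width: int) -> str:
        return raw[offset : offset + width].decode("ascii", errors="replace").strip()

    version = ascii_at(0, 8)
    if version != "0":
        raise FormatError(f"{path}: unsupported EDF version field {version!r}")
    patient = ascii_at(8, 80)
    recording_id = ascii_at(88, 80)
    try:
        header_bytes = int(ascii_at(184, 8))
        n_records = int(ascii_at(236, 8))
        record_duration = float(ascii_at(244, 8))
        n_signals = int(ascii_at(252, 4))
    except ValueError as exc:
        raise FormatError(f"{path}: malformed numeric header field ({exc})") from None
    if n_signals < 1:
        raise FormatError(f"{path}: header reports {n_signals} signals")
    if header_bytes != 256 * (1 + n_signals):
        raise FormatError(
            f"{path}: header size field {header_bytes} inconsistent with {n_signals} signals"
        )
    if len(raw) < header_bytes:
        raise FormatError(f"{path}: file shorter than declared header")

    base = 256
    labels = [ascii_at(base + i * 16, 16) for i in range(n_signals)]
    offset = 16 * n_signals
    offset += 80 * n_signals  # transducer
    offset += 8 * n_signals  # physical dimension
    phys_min = [float(ascii_at(base + offset + i * 8, 8)) for i in range(n_signals)]
    offset += 8 * n_signals
    phys_max = [float(ascii_at(base + offset + i * 8, 8)) for i in range(n_signals)]
    offset += 8 * n_signals
    dig_min = [int(ascii_at(base + offset + i * 8, 8)) for i in range(n_signals)]
    offset += 8 * n_signals
    dig_max = [int(ascii_at(base + offset + i * 8, 8)) for i in range(n_signals)]
    offset += 8 * n_signals
    offset += 80 * n_signals  # prefiltering
    spr = [int(ascii_at(base + offset + i * 8, 8)) for i in range(n_signals)]

    if len(set(spr)) != 1:
        raise FormatError(f"{path}: signals with differing samples-per-record {sorted(set(spr))}")
    samples_per_record = spr[0]
    if record_duration <= 0:
        raise FormatError(f"{path}: non-positive record duration {record_duration}")
    fs = samples_per_record / record_duration
    if math.isclose(fs, round(fs), rel_tol=0, abs_tol=1e-6):
        fs = float(round(fs))

    expected = header_bytes + n_records * n_signals * samples_per_record * 2
    if len(raw) < expected:
        raise FormatError(
            f"{path}: expected {expected} bytes for {n_records} records, file has {len(raw)}"
        )
    body = np.frombuffer(raw[header_bytes:expected], dtype="<i2")
    body = body.reshape(n_records, n_signals, samples_per_record)
    digital = np.concatenate([body[r] for r in range(n_records)], axis=1).astype(np.float64)

    data = np.empty_like(digital)
    for i in range(n_signals):
        span_d = dig_max[i] - dig_min[i]
        if span_d == 0:
            raise FormatError(f"{path}: signal {labels[i]!r} has zero digital range")
        gain = (phys_max[i] - phys_min[i]) / span_d
        data[i] = (digital[i] - dig_min[i]) * gain + phys_min[i]

    return EEGRecording(
        data=data,
        fs=fs,
        channel_names=labels,
        subject_id=patient if patient not in ("", "X") else None,
        trial_id=recording_id if recording_id not in ("", "X") else None,
    )
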