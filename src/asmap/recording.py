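"""Recording and band-set containers plus EDF/CSV/HDF5 readers and writers.

The CSV dialect is deliberately trivial so fixtures stay human-inspectable:
a ``# fs=<Hz>`` comment line, a header row of channel names, then one
sample per row. HDF5 files carry datasets ``data`` (channels x samples,
float64), ``fs`` and ``channel_names``. EDF I/O lives in :mod:`asmap.edf`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np

from asmap.errors import FormatError, ValidationError

__all__ = [
    "EEGRecording",
    "BandSet",
    "DEFAULT_BANDS",
    "read_recording",
    "write_recording",
]


@dataclass
class EEGRecording:
    """A channels x samples EEG matrix in microvolts with its metadata.

    Parameters
    ----------
    data
        Real matrix of shape ``(n_channels, n_samples)``, microvolts.
    fs
        Sampling rate in Hz, strictly positive.
    channel_names
        Ordered, unique 10-20 style channel labels, one per row of ``data``.
    subject_id, trial_id
        Optional provenance strings.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    subject_id: str | None = None
    trial_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValidationError(f"data must be 2-D (channels x samples), got ndim={self.data.ndim}")
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got fs={self.fs}")
        n_channels, n_samples = self.data.shape
        if n_channels < 2:
            raise ValidationError(f"need at least 2 channels, got {n_channels}")
        if n_samples < 1:
            raise ValidationError("recording contains no samples")
        self.channel_names = [str(c) for c in self.channel_names]
        if len(self.channel_names) != n_channels:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for {n_channels} data rows"
            )
        dupes = _duplicates(self.channel_names)
        if dupes:
            raise ValidationError(f"duplicate channel names: {sorted(dupes)}")
        if not np.isfinite(self.data).all():
            raise ValidationError("data contains non-finite samples (NaN or Inf)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ValidationError(f"unknown channel {name!r}") from None

    def reorder(self, channel_order: Sequence[str]) -> "EEGRecording":
        """Return a copy with rows rearranged to ``channel_order``.

        The montage's channel order is authoritative for AsMap row/column
        semantics; files may store channels in any order.
        """
        idx = [self.channel_index(name) for name in channel_order]
        return EEGRecording(
            data=self.data[idx],
            fs=self.fs,
            channel_names=list(channel_order),
            subject_id=self.subject_id,
            trial_id=self.trial_id,
        )


def _duplicates(names: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for n in names:
        if n in seen:
            dupes.add(n)
        seen.add(n)
    return dupes


@dataclass(frozen=True)
class BandSet:
    """Ordered named frequency bands ``(name, low_hz, high_hz)``, inclusive edges."""

    bands: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        names = [b[0] for b in self.bands]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate band names: {sorted(_duplicates(names))}")
        for name, low, high in self.bands:
            if not (0 < low < high):
                raise ValidationError(f"band {name!r} needs 0 < low < high, got ({low}, {high})")

    @property
    def names(self) -> list[str]:
        return [b[0] for b in self.bands]

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)

    def subset(self, names: Sequence[str]) -> "BandSet":
        known = self.names
        for n in names:
            if n not in known:
                raise ValidationError(f"unknown band {n!r}; available: {known}")
        return BandSet(tuple(b for b in self.bands if b[0] in names))

    def check_nyquist(self, fs: float) -> None:
        for name, low, high in self.bands:
            if high > fs / 2 + 1e-9:
                raise ValidationError(
                    f"band {name!r} upper edge {high} Hz exceeds Nyquist {fs / 2} Hz"
                )


#: The five conventional EEG rhythms with the edges used throughout.
DEFAULT_BANDS = BandSet(
    (
        ("delta", 1.0, 3.0),
        ("theta", 4.0, 7.0),
        ("alpha", 8.0, 13.0),
        ("beta", 14.0, 30.0),
        ("gamma", 31.0, 50.0),
    )
)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_FORMATS = ("edf", "csv", "hdf5")


def read_recording(path: str | Path, format: str | None = None) -> EEGRecording:
    """Read a recording from ``path`` in one of the supported formats.

    ``format`` defaults to a guess from the file suffix (.edf/.csv/.h5/.hdf5).
    """
    path = Path(path)
    fmt = format or _guess_format(path)
    if fmt == "hdf5":
        return _read_hdf5(path)
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "edf":
        from asmap.edf import read_edf

        return read_edf(path)
    raise ValidationError(f"unknown format {fmt!r}; expected one of {_FORMATS}")


def write_recording(rec: EEGRecording, path: str | Path, format: str | None = None) -> None:
    """Write ``rec`` so that :func:`read_recording` reproduces it.

    HDF5 and CSV round-trip exactly (CSV at the text precision below); EDF
    quantizes to 16-bit over the physical range.
    """
    path = Path(path)
    fmt = format or _guess_format(path)
    if fmt == "hdf5":
        _write_hdf5(rec, path)
    elif fmt == "csv":
        _write_csv(rec, path)
    elif fmt == "edf":
        from asmap.edf import write_edf

        write_edf(rec, path)
    else:
        raise ValidationError(f"unknown format {fmt!r}; expected one of {_FORMATS}")


def _guess_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix == ".csv":
        return "csv"
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    raise ValidationError(f"cannot guess format from suffix {suffix!r}; pass format=")


def _read_hdf5(path: Path) -> EEGRecording:
    with h5py.File(path, "r") as f:
        for key in ("data", "fs", "channel_names"):
            if key not in f:
                raise FormatError(f"HDF5 file {path} is missing dataset {key!r}")
        data = np.asarray(f["data"], dtype=np.float64)
        fs = float(np.asarray(f["fs"]))
        names = [
            n.decode() if isinstance(n, bytes) else str(n) for n in np.asarray(f["channel_names"])
        ]
        subject = f.attrs.get("subject_id")
        trial = f.attrs.get("trial_id")
    return EEGRecording(
        data=data,
        fs=fs,
        channel_names=names,
        subject_id=None if subject is None else str(subject),
        trial_id=None if trial is None else str(trial),
    )


def _write_hdf5(rec: EEGRecording, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.create_dataset("fs", data=float(rec.fs))
        f.create_dataset(
            "channel_names", data=np.array(rec.channel_names, dtype=h5py.string_dtype())
        )
        if rec.subject_id is not None:
            f.attrs["subject_id"] = rec.subject_id
        if rec.trial_id is not None:
            f.attrs["trial_id"] = rec.trial_id


def _read_csv(path: Path) -> EEGRecording:
    with open(path, "r") as f:
        meta = f.readline().strip()
        if not meta.startswith("#"):
            raise FormatError(f"{path}: first line must be '# fs=<Hz>', got {meta!r}")
        try:
            fs = float(meta.lstrip("#").strip().split("=", 1)[1])
        except (IndexError, ValueError):
            raise FormatError(f"{path}: cannot parse sampling rate from {meta!r}") from None
        header = f.readline().strip()
        if not header:
            raise FormatError(f"{path}: missing channel-name header row")
        names = [h.strip() for h in header.split(",")]
        try:
            body = np.loadtxt(io.StringIO(f.read()), delimiter=",", ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{path}: malformed sample rows ({exc})") from None
    if body.size == 0:
        raise FormatError(f"{path}: no sample rows")
    if body.shape[1] != len(names):
        raise FormatError(
            f"{path}: {body.shape[1]} columns but {len(names)} channel names in header"
        )
    return EEGRecording(data=body.T, fs=fs, channel_names=names)


def _write_csv(rec: EEGRecording, path: Path) -> None:
    fs = rec.fs
    fs_repr = repr(int(fs)) if float(fs).is_integer() else repr(fs)
    with open(path, "w") as f:
        f.write(f"# fs={fs_repr}\n")
        f.write(",".join(rec.channel_names) + "\n")
        np.savetxt(f, rec.data.T, delimiter=",", fmt="%.9g")
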