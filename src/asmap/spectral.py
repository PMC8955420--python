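"""Epoching, short-time Fourier band power, and differential entropy.

The recording is cut into non-overlapping epochs (1 s by default); each
epoch is Hann-windowed, zero-padded to ``n_fft`` points and turned into a
one-sided periodogram normalised so that the sum of bin powers estimates
the signal variance (Parseval-consistent). Band power is the sum over the
bins whose frequency falls inside the band's inclusive edges. Under a
Gaussian signal model the differential entropy of a band then has the
closed form ``0.5 * ln(2*pi*e*P)`` — a log band-power feature up to an
additive constant, which is what every downstream difference feature
consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import h5py
import numpy as np
from scipy.signal.windows import hann

from asmap.errors import ValidationError
from asmap.recording import BandSet, DEFAULT_BANDS, EEGRecording

__all__ = [
    "EpochGrid",
    "DEFeatureArray",
    "segment_epochs",
    "epoch_band_power",
    "differential_entropy",
    "compute_de_features",
    "smooth_moving_average",
    "save_de_features",
    "load_de_features",
    "POWER_FLOOR",
]

#: Band power (in microvolts squared) is clamped to at least this before the
#: log, so silent fixtures produce a large negative DE instead of -inf.
POWER_FLOOR = 1e-12

#: 0.5 * ln(2*pi*e), the differential entropy of a unit-variance Gaussian.
GAUSSIAN_DE_CONST = 0.5 * np.log(2 * np.pi * np.e)


@dataclass(frozen=True)
class EpochGrid:
    """Bookkeeping for contiguous, non-overlapping fixed-length epochs."""

    epoch_len_s: float
    n_epochs: int
    samples_per_epoch: int


def segment_epochs(rec: EEGRecording, epoch_len_s: float = 1.0) -> EpochGrid:
    """Divide ``rec`` into non-overlapping epochs, discarding the partial tail."""
    if epoch_len_s <= 0:
        raise ValidationError(f"epoch_len_s must be positive, got {epoch_len_s}")
    samples_per_epoch = int(round(rec.fs * epoch_len_s))
    if samples_per_epoch < 2:
        raise ValidationError(
            f"epoch of {epoch_len_s} s at fs={rec.fs} holds {samples_per_epoch} samples; need >= 2"
        )
    n_epochs = rec.n_samples // samples_per_epoch
    if n_epochs < 1:
        raise ValidationError(
            f"recording of {rec.n_samples} samples shorter than one "
            f"{samples_per_epoch}-sample epoch"
        )
    return EpochGrid(
        epoch_len_s=float(epoch_len_s), n_epochs=n_epochs, samples_per_epoch=samples_per_epoch
    )


def _periodogram_bins(frames: np.ndarray, n_fft: int) -> np.ndarray:
    """One-sided bin powers of Hann-windowed frames, summing to variance.

    frames: (..., n) with n <= n_fft; returns (..., n_fft//2 + 1).
    """
    n = frames.shape[-1]
    w = hann(n, sym=False)
    spec = np.fft.rfft(frames * w, n=n_fft, axis=-1)
    p = np.abs(spec) ** 2
    # one-sided doubling; DC and (for even n_fft) Nyquist appear once
    p *= 2.0
    p[..., 0] /= 2.0
    if n_fft % 2 == 0:
        p[..., -1] /= 2.0
    return p / (n_fft * np.sum(w**2))


def epoch_band_power(
    rec: EEGRecording,
    grid: EpochGrid,
    bands: BandSet = DEFAULT_BANDS,
    n_fft: int = 256,
) -> np.ndarray:
    """Per-epoch, per-band power, shape ``(n_channels, n_bands, n_epochs)``.

    Epochs longer than ``n_fft`` samples are split into ``n_fft``-sample
    frames whose periodograms are averaged; shorter epochs are
    zero-padded. A frequency bin belongs to band ``(low, high)`` iff
    ``low <= f <= high`` (inclusive edges; bins in gaps between bands
    belong to no band).
    """
    bands.check_nyquist(rec.fs)
    spe = grid.samples_per_epoch
    x = rec.data[:, : grid.n_epochs * spe].reshape(rec.n_channels, grid.n_epochs, spe)

    if spe <= n_fft:
        bins = _periodogram_bins(x, n_fft)
    else:
        n_frames = spe // n_fft
        frames = x[:, :, : n_frames * n_fft].reshape(rec.n_channels, grid.n_epochs, n_frames, n_fft)
        bins = _periodogram_bins(frames, n_fft).mean(axis=2)

    freqs = np.fft.rfftfreq(n_fft, d=1.0 / rec.fs)
    out = np.empty((rec.n_channels, len(bands), grid.n_epochs))
    for k, (name, low, high) in enumerate(bands):
        member = (freqs >= low) & (freqs <= high)
        if not member.any():
            raise ValidationError(
                f"band {name!r} ({low}-{high} Hz) contains no FFT bins at fs={rec.fs}, n_fft={n_fft}"
            )
        out[:, k, :] = bins[..., member].sum(axis=-1)
    return out


def differential_entropy(power: np.ndarray | float, floor: float = POWER_FLOOR) -> np.ndarray:
    """Gaussian closed-form DE in nats: ``0.5 * ln(2*pi*e*P)``.

    ``P`` below ``floor`` is clamped; negative power is a contract
    violation upstream and raises.
    """
    p = np.asarray(power, dtype=np.float64)
    if (p < 0).any():
        raise ValidationError("negative band power passed to differential_entropy")
    return 0.5 * np.log(2 * np.pi * np.e * np.maximum(p, floor))


@dataclass
class DEFeatureArray:
    """Per-channel, per-band, per-epoch DE values (nats) with provenance."""

    values: np.ndarray  # (n_channels, n_bands, n_epochs)
    band_set: BandSet
    channel_names: list[str]
    epoch_len_s: float
    smoothed: bool = False
    span: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValidationError("DE values must be 3-D (channels x bands x epochs)")
        c, k, _ = self.values.shape
        if c != len(self.channel_names):
            raise ValidationError(f"{len(self.channel_names)} names for {c} channel rows")
        if k != len(self.band_set):
            raise ValidationError(f"{len(self.band_set)} bands for {k} band rows")
        if not np.isfinite(self.values).all():
            raise ValidationError("DE values contain non-finite entries")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[2]


def compute_de_features(
    rec: EEGRecording,
    bands: BandSet = DEFAULT_BANDS,
    epoch_len_s: float = 1.0,
    n_fft: int = 256,
) -> DEFeatureArray:
    """Epoch ``rec`` and compute raw (unsmoothed) DE features."""
    grid = segment_epochs(rec, epoch_len_s)
    power = epoch_band_power(rec, grid, bands, n_fft)
    return DEFeatureArray(
        values=differential_entropy(power),
        band_set=bands,
        channel_names=list(rec.channel_names),
        epoch_len_s=epoch_len_s,
    )


def smooth_moving_average(features: DEFeatureArray, span: int = 5) -> DEFeatureArray:
    """Centered moving average along the epoch axis, shrinking at the edges.

    At position ``t`` the window is ``[t - h, t + h]`` with ``h = span // 2``
    clipped to the series, so the first and last epochs average over fewer
    points rather than being padded. Span 1 is the identity.
    """
    if span < 1 or span % 2 == 0:
        raise ValidationError(f"span must be a positive odd integer, got {span}")
    if span == 1:
        return replace(features, values=features.values.copy(), smoothed=True, span=1)
    v = features.values
    n = v.shape[2]
    h = span // 2
    csum = np.concatenate([np.zeros(v.shape[:2] + (1,)), np.cumsum(v, axis=2)], axis=2)
    lo = np.maximum(np.arange(n) - h, 0)
    hi = np.minimum(np.arange(n) + h, n - 1) + 1
    out = (csum[:, :, hi] - csum[:, :, lo]) / (hi - lo)
    return DEFeatureArray(
        values=out,
        band_set=features.band_set,
        channel_names=list(features.channel_names),
        epoch_len_s=features.epoch_len_s,
        smoothed=True,
        span=span,
    )


def save_de_features(features: DEFeatureArray, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=features.values)
        f.create_dataset(
            "band_names", data=np.array(features.band_set.names, dtype=h5py.string_dtype())
        )
        f.create_dataset(
            "band_edges", data=np.array([(b[1], b[2]) for b in features.band_set])
        )
        f.create_dataset(
            "channel_names", data=np.array(features.channel_names, dtype=h5py.string_dtype())
        )
        f.attrs["epoch_len_s"] = features.epoch_len_s
        f.attrs["smoothed"] = features.smoothed
        f.attrs["span"] = features.span


def load_de_features(path: str | Path) -> DEFeatureArray:
    with h5py.File(path, "r") as f:
        names = [n.decode() for n in f["band_names"][()]]
        edges = f["band_edges"][()]
        band_set = BandSet(tuple((n, float(lo), float(hi)) for n, (lo, hi) in zip(names, edges)))
        return DEFeatureArray(
            values=f["values"][()],
            band_set=band_set,
            channel_names=[c.decode() for c in f["channel_names"][()]],
            epoch_len_s=float(f.attrs["epoch_len_s"]),
            smoothed=bool(f.attrs["smoothed"]),
            span=int(f.attrs["span"]),
        )
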