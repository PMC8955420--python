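"""Windowed DE averaging, asymmetry-map construction, and baseline vectors.

The asymmetry map of one analysis window is the C x C x K tensor of all
pairwise channel differences ``map[i, j, k] = DE(i, k) - DE(j, k)``; it is
antisymmetric with a zero diagonal by construction. For CNN input each
band slice is min-max scaled to [0, 1] independently (a constant slice
maps to 0.5), which turns antisymmetry into ``v[i,j] + v[j,i] = 1``. The
classic DASM and DCAU vectors are exact sub-samples of the raw map at the
montage's pair indices; RASM is the ratio variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from asmap.errors import ValidationError
from asmap.montage import Montage
from asmap.recording import BandSet
from asmap.spectral import DEFeatureArray

__all__ = [
    "WindowedDE",
    "AsMapTensor",
    "BaselineFeatureVector",
    "window_average",
    "build_asmap",
    "normalize_asmap",
    "baseline_features",
    "BASELINE_METHODS",
    "RASM_DIVISOR_EPS",
    "RASM_CAP",
]

BASELINE_METHODS = ("DE", "DASM", "RASM", "DCAU")

RASM_DIVISOR_EPS = 1e-9
RASM_CAP = 1e9


@dataclass
class WindowedDE:
    """DE features averaged over fixed non-overlapping windows of epochs."""

    values: np.ndarray  # (n_channels, n_bands, n_windows)
    band_set: BandSet
    channel_names: list[str]
    window_len_s: float
    epoch_len_s: float
    smoothed: bool = False
    span: int = 0

    @property
    def n_windows(self) -> int:
        return self.values.shape[2]

    def band_indices(self, band_subset: Sequence[str] | None) -> list[int]:
        if band_subset is None:
            return list(range(len(self.band_set)))
        names = self.band_set.names
        idx = []
        for b in band_subset:
            if b not in names:
                raise ValidationError(f"unknown band {b!r}; available: {names}")
            idx.append(names.index(b))
        if not idx:
            raise ValidationError("band subset is empty")
        return idx


def window_average(features: DEFeatureArray, window_len_s: float) -> WindowedDE:
    """Average DE over consecutive non-overlapping windows of epochs.

    ``window_len_s`` must be a positive integer multiple of the epoch
    length; a trailing partial window is discarded.
    """
    ratio = window_len_s / features.epoch_len_s
    epochs_per_window = int(round(ratio))
    if epochs_per_window < 1 or abs(ratio - epochs_per_window) > 1e-9:
        raise ValidationError(
            f"window of {window_len_s} s is not a positive integer multiple of "
            f"the {features.epoch_len_s} s epoch"
        )
    n_windows = features.n_epochs // epochs_per_window
    if n_windows < 1:
        raise ValidationError(
            f"{features.n_epochs} epochs hold no complete {window_len_s} s window"
        )
    v = features.values[:, :, : n_windows * epochs_per_window]
    v = v.reshape(v.shape[0], v.shape[1], n_windows, epochs_per_window).mean(axis=3)
    return WindowedDE(
        values=v,
        band_set=features.band_set,
        channel_names=list(features.channel_names),
        window_len_s=float(window_len_s),
        epoch_len_s=features.epoch_len_s,
        smoothed=features.smoothed,
        span=features.span,
    )


@dataclass
class AsMapTensor:
    """C x C x K pairwise DE-difference tensor for one analysis window."""

    values: np.ndarray
    band_names: list[str]
    channel_names: list[str]
    window_index: int
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.shape[0] != self.values.shape[1]:
            raise ValidationError(
                f"asymmetry tensor must be square C x C x K, got shape {self.values.shape}"
            )
        if self.values.shape[2] != len(self.band_names):
            raise ValidationError("band axis length does not match band_names")
        if self.values.shape[0] != len(self.channel_names):
            raise ValidationError("channel axes do not match channel_names")


def build_asmap(
    windowed: WindowedDE,
    window_index: int,
    band_subset: Sequence[str] | None = None,
) -> AsMapTensor:
    """Raw pairwise-difference tensor for one window: ``v[i,j,k] = DE_i - DE_j``."""
    if not 0 <= window_index < windowed.n_windows:
        raise ValidationError(
            f"window_index {window_index} out of range [0, {windowed.n_windows})"
        )
    k_idx = windowed.band_indices(band_subset)
    de = windowed.values[:, k_idx, window_index]  # (C, K)
    values = de[:, None, :] - de[None, :, :]
    return AsMapTensor(
        values=values,
        band_names=[windowed.band_set.names[k] for k in k_idx],
        channel_names=list(windowed.channel_names),
        window_index=window_index,
        normalized=False,
    )


def normalize_asmap(asmap: AsMapTensor) -> AsMapTensor:
    """Min-max scale each band slice to [0, 1]; a constant slice maps to 0.5."""
    if asmap.normalized:
        raise ValidationError("tensor is already normalized")
    v = asmap.values
    lo = v.min(axis=(0, 1), keepdims=True)
    hi = v.max(axis=(0, 1), keepdims=True)
    rng = hi - lo
    flat = rng == 0
    rng = np.where(flat, 1.0, rng)
    out = (v - lo) / rng
    out = np.where(flat, 0.5, out)
    return AsMapTensor(
        values=out,
        band_names=list(asmap.band_names),
        channel_names=list(asmap.channel_names),
        window_index=asmap.window_index,
        normalized=True,
    )


@dataclass
class BaselineFeatureVector:
    """Flat feature vector for one window under a classic DE-derived method."""

    method: str
    values: np.ndarray
    band_names: list[str]
    window_index: int
    capped: bool = False  # RASM divisor guard fired somewhere

    def __len__(self) -> int:
        return len(self.values)


def baseline_features(
    windowed: WindowedDE,
    window_index: int,
    method: str,
    montage: Montage,
    band_subset: Sequence[str] | None = None,
) -> BaselineFeatureVector:
    """DE / DASM / RASM / DCAU vector for one window.

    Element order is pair-major, band-minor (channel-major for DE),
    following montage order. With a 62-channel montage of 27 hemispheric
    and 23 frontal-posterior pairs and five bands the lengths are 310,
    135, 135 and 115.
    """
    if method not in BASELINE_METHODS:
        raise ValidationError(f"unknown method {method!r}; choose from {BASELINE_METHODS}")
    if not 0 <= window_index < windowed.n_windows:
        raise ValidationError(
            f"window_index {window_index} out of range [0, {windowed.n_windows})"
        )
    if list(windowed.channel_names) != list(montage.channel_order):
        raise ValidationError("windowed DE channel order does not match montage order")
    k_idx = windowed.band_indices(band_subset)
    band_names = [windowed.band_set.names[k] for k in k_idx]
    de = windowed.values[:, k_idx, window_index]  # (C, K)

    capped = False
    if method == "DE":
        values = de.reshape(-1)  # channel-major, band-minor
    elif method in ("DASM", "RASM"):
        pairs = montage.pair_indices("hemispheric")
        left = de[[i for i, _ in pairs]]
        right = de[[j for _, j in pairs]]
        if method == "DASM":
            values = (left - right).reshape(-1)
        else:
            right_g = right.copy()
            small = np.abs(right_g) < RASM_DIVISOR_EPS
            if small.any():
                capped = True
                right_g = np.where(small, RASM_DIVISOR_EPS * np.where(right_g < 0, -1, 1), right_g)
            values = (left / right_g).reshape(-1)
            values = np.clip(values, -RASM_CAP, RASM_CAP)
    else:  # DCAU
        pairs = montage.pair_indices("frontal_posterior")
        front = de[[i for i, _ in pairs]]
        back = de[[j for _, j in pairs]]
        values = (front - back).reshape(-1)

    return BaselineFeatureVector(
        method=method,
        values=values,
        band_names=band_names,
        window_index=window_index,
        capped=capped,
    )


def save_asmaps(
    asmaps: Sequence[AsMapTensor],
    path: str | Path,
    provenance: dict | None = None,
) -> None:
    """Stack a sequence of same-shape tensors into one HDF5 file."""
    if not asmaps:
        raise ValidationError("no tensors to save")
    first = asmaps[0]
    stack = np.stack([a.values for a in asmaps])
    with h5py.File(path, "w") as f:
        f.create_dataset("asmaps", data=stack)
        f.create_dataset("window_index", data=np.array([a.window_index for a in asmaps]))
        f.create_dataset(
            "band_names", data=np.array(first.band_names, dtype=h5py.string_dtype())
        )
        f.create_dataset(
            "channel_names", data=np.array(first.channel_names, dtype=h5py.string_dtype())
        )
        f.attrs["normalized"] = first.normalized
        for key, val in (provenance or {}).items():
            f.attrs[key] = val


def load_asmaps(path: str | Path) -> list[AsMapTensor]:
    with h5py.File(path, "r") as f:
        stack = f["asmaps"][()]
        idx = f["window_index"][()]
        band_names = [b.decode() for b in f["band_names"][()]]
        channel_names = [c.decode() for c in f["channel_names"][()]]
        normalized = bool(f.attrs["normalized"])
    return [
        AsMapTensor(
            values=stack[i],
            band_names=band_names,
            channel_names=channel_names,
            window_index=int(idx[i]),
            normalized=normalized,
        )
        for i in range(stack.shape[0])
    ]


def asmap_to_image(asmap: AsMapTensor, band: str, path: str | Path) -> None:
    """Export one band slice as an 8-bit grayscale PNG via matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if band not in asmap.band_names:
        raise ValidationError(f"band {band!r} not in tensor bands {asmap.band_names}")
    k = asmap.band_names.index(band)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(asmap.values[:, :, k], cmap="gray", interpolation="nearest")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", pad_inches=0)
    plt.close(fig)
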