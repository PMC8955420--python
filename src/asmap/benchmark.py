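"""End-to-end pipeline: recordings -> features -> model -> accuracy table.

`prepare_examples` turns labeled recordings into one example per analysis
window (a normalized asymmetry tensor for the CNN route, or a flat
DE/DASM/RASM/DCAU vector for the dense-head route). `run_benchmark`
sweeps method x band x window-size combinations and reports held-out
accuracy per cell, with the split and all initialisation driven by one
seed. Band option "ALL" means all bands of the band set stacked on the
third axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from asmap.errors import ValidationError
from asmap.features import (
    BASELINE_METHODS,
    baseline_features,
    build_asmap,
    normalize_asmap,
    window_average,
)
from asmap.labels import EmotionLabel
from asmap.montage import Montage
from asmap.nn import (
    CNNConfig,
    HeadConfig,
    TrainConfig,
    build_mlp,
    build_model,
    evaluate,
    group_split,
    stratified_split,
    train,
)
from asmap.recording import BandSet, DEFAULT_BANDS, EEGRecording
from asmap.spectral import compute_de_features, smooth_moving_average

__all__ = [
    "PipelineConfig",
    "prepare_examples",
    "run_benchmark",
    "train_eval_single",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = ["method", "band", "window_s", "seed", "accuracy", "n_test"]

ALL_BANDS = "ALL"


@dataclass(frozen=True)
class PipelineConfig:
    """Feature-side knobs shared by every benchmark cell."""

    epoch_len_s: float = 1.0
    n_fft: int = 256
    smooth_span: int = 5  # 1 disables smoothing
    bands: BandSet = DEFAULT_BANDS


def _resolve_bands(band: str | Sequence[str], band_set: BandSet) -> list[str]:
    if isinstance(band, str):
        if band.upper() == ALL_BANDS:
            return band_set.names
        return [band]
    return list(band)


def prepare_examples(
    dataset: Sequence[tuple[EEGRecording, EmotionLabel]],
    montage: Montage,
    method: str,
    band: str | Sequence[str],
    window_s: float,
    pipeline: PipelineConfig = PipelineConfig(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-window examples from labeled recordings.

    Returns ``(x, y, groups)`` where ``x`` is ``(n, C, C, K)`` for method
    'asmap' or ``(n, d)`` for a baseline method, ``y`` are class indices
    (the trial label repeated for every window of that trial), and
    ``groups`` is the trial index of each window. Smoothing and windowing
    never cross trial boundaries.
    """
    if not dataset:
        raise ValidationError("empty dataset")
    method_u = method.upper() if method.upper() in BASELINE_METHODS else method.lower()
    if method_u not in BASELINE_METHODS and method_u != "asmap":
        raise ValidationError(
            f"unknown method {method!r}; choose 'asmap' or one of {BASELINE_METHODS}"
        )
    band_names = _resolve_bands(band, pipeline.bands)
    pipeline.bands.subset(band_names)  # validates names

    xs: list[np.ndarray] = []
    ys: list[int] = []
    groups: list[int] = []
    for trial_idx, (rec, label) in enumerate(dataset):
        rec = rec.reorder(montage.channel_order)
        de = compute_de_features(rec, pipeline.bands, pipeline.epoch_len_s, pipeline.n_fft)
        if pipeline.smooth_span > 1:
            de = smooth_moving_average(de, pipeline.smooth_span)
        windowed = window_average(de, window_s)
        for w in range(windowed.n_windows):
            if method_u == "asmap":
                xs.append(normalize_asmap(build_asmap(windowed, w, band_names)).values)
            else:
                xs.append(
                    baseline_features(windowed, w, method_u, montage, band_names).values
                )
            ys.append(label.class_index)
            groups.append(trial_idx)
    return np.stack(xs), np.asarray(ys, dtype=np.int64), np.asarray(groups, dtype=np.int64)


def train_eval_single(
    x: np.ndarray,
    y: np.ndarray,
    method: str,
    seed: int,
    test_fraction: float = 0.2,
    groups: np.ndarray | None = None,
    train_cfg: TrainConfig | None = None,
    n_classes: int | None = None,
):
    """Split, fit, and score one feature set.

    Baselines are z-scored with statistics from the training portion only.
    ``groups`` switches the outer split from window-stratified to
    group-aware (held-out trials). Returns ``(report, model, history)``.
    """
    rng = np.random.default_rng(seed)
    if groups is not None:
        pool_idx, test_idx = group_split(groups, test_fraction, rng)
    else:
        pool_idx, test_idx = stratified_split(y, test_fraction, rng)
    n_classes = n_classes or int(y.max()) + 1
    cfg = train_cfg or TrainConfig(seed=seed)

    if x.ndim == 4:
        model = build_model(CNNConfig(input_shape=x.shape[1:]), HeadConfig(n_classes))
        x_in = x
    else:
        mu = x[pool_idx].mean(axis=0)
        sd = x[pool_idx].std(axis=0)
        sd[sd == 0] = 1.0
        x_in = (x - mu) / sd
        model = build_mlp(x.shape[1], HeadConfig(n_classes))
    history = train(model, x_in[pool_idx], y[pool_idx], cfg)
    report = evaluate(model, x_in[test_idx], y[test_idx])
    return report, model, history


def run_benchmark(
    dataset: Sequence[tuple[EEGRecording, EmotionLabel]],
    montage: Montage,
    methods: Sequence[str],
    bands: Sequence[str],
    window_sizes: Sequence[float],
    seed: int = 0,
    pipeline: PipelineConfig = PipelineConfig(),
    test_fraction: float = 0.2,
    group_aware: bool = False,
    train_cfg: TrainConfig | None = None,
) -> pd.DataFrame:
    """One accuracy cell per (method, band, window size)."""
    rows = []
    n_classes = max(label.class_index for _, label in dataset) + 1
    for window_s in window_sizes:
        for band in bands:
            for method in methods:
                x, y, groups = prepare_examples(
                    dataset, montage, method, band, window_s, pipeline
                )
                report, _, _ = train_eval_single(
                    x,
                    y,
                    method,
                    seed=seed,
                    test_fraction=test_fraction,
                    groups=groups if group_aware else None,
                    train_cfg=train_cfg,
                    n_classes=n_classes,
                )
                rows.append(
                    {
                        "method": method,
                        "band": band,
                        "window_s": window_s,
                        "seed": seed,
                        "accuracy": report.accuracy,
                        "n_test": report.n_test,
                    }
                )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def save_results(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def load_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
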