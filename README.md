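# asmap-eeg

Feature-engineering pipeline for EEG emotion classification built around
pairwise-channel asymmetry maps ("AsMaps"). The pipeline:

1. cut a multichannel recording into non-overlapping 1-s epochs;
2. estimate per-band power with a Hann-windowed 256-point short-time
   Fourier transform (delta/theta/alpha/beta/gamma by default);
3. convert band power to differential entropy (DE), `0.5·ln(2πe·P)` nats,
   optionally smoothed with a centered moving average;
4. average DE over fixed windows (3/6/12/30 s) and build, per window, a
   `C×C×K` tensor of all pairwise DE differences, min–max normalized per
   band slice to [0, 1];
5. feed the tensor to a small CNN (conv 3×3×32 → pool → dropout →
   conv 3×3×16 → pool → dropout → flatten) with a 512–512 dense softmax
   head — or feed the classic DE / DASM / RASM / DCAU vectors to the dense
   head directly as baselines.

Because the public emotional-EEG datasets this design targets are
access-restricted, the package ships a synthetic-EEG generator
(`asmap.synth`) producing band-limited Gaussian noise with
class-conditioned hemispheric band-power gains; the expected asymmetry of
an affected channel pair is analytically `0.5·ln(gain)`, which makes the
whole pipeline testable end to end.

The CNN/MLP stack is implemented directly on numpy (im2col convolutions,
Adam, inverted dropout) so the package runs on a bare scientific-Python
stack with no deep-learning framework. A minimal EDF codec is included for
the same reason.

## Library quick start

```python
import numpy as np
from asmap import (
    EEGRecording, compute_de_features, smooth_moving_average,
    window_average, build_asmap, normalize_asmap, packaged_montage,
)

montage = packaged_montage("seed62")          # 62 ch, 27 + 23 pairs
rec = EEGRecording(np.random.randn(62, 200 * 60), fs=200.0,
                   channel_names=list(montage.channel_order))
de = smooth_moving_average(compute_de_features(rec), span=5)
windowed = window_average(de, window_len_s=3.0)
asmap = normalize_asmap(build_asmap(windowed, window_index=0, band_subset=["gamma"]))
asmap.values.shape                             # (62, 62, 1), values in [0, 1]
```

`asmap.benchmark.run_benchmark` sweeps method × band × window-size grids
and returns a tidy accuracy table; `asmap.nn` exposes `build_model`,
`train`, `extract_features`, `evaluate`.

## CLI

```sh
asmap simulate --config configs/synth_default.yaml --out runs/trials --seed 1
asmap extract  --recordings runs/trials --montage seed62 \
               --bands gamma --window-s 3 --method asmap --out runs/features
asmap train    --features runs/features/features.h5 --seed 1 --out runs/model
asmap evaluate --model runs/model --features runs/features/features.h5 --out runs/eval
asmap report   --results runs
```

Recordings are read/written as HDF5, CSV (`# fs=…` header line) or EDF;
every command writes a `manifest.json` with config snapshot, input hashes
and seeds, and reruns with the same seed reproduce identical outputs.

Montages are YAML data files (channel order plus hemispheric and
frontal–posterior pair lists). Two defaults are packaged: `seed62`
(62 channels — with five bands the baseline feature lengths are DE 310,
DASM 135, RASM 135, DCAU 115) and `deap32` (32 channels). The 62-channel
ordering follows the common reference-cap distribution order; it is
configuration, not code, and any montage file with the same keys works.

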