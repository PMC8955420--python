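import numpy as np
import pytest

from asmap.montage import Montage, packaged_montage
from asmap.recording import BandSet, EEGRecording
from asmap.spectral import DEFeatureArray


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def seed62():
    return packaged_montage("seed62")


@pytest.fixture(scope="session")
def deap32():
    return packaged_montage("deap32")


@pytest.fixture
def toy_montage():
    """Four channels, two hemispheric pairs, one frontal-posterior pair."""
    return Montage(
        channel_order=("F3", "F4", "P3", "P4"),
        hemispheric_pairs=(("F3", "F4"), ("P3", "P4")),
        frontal_posterior_pairs=(("F3", "P3"),),
        name="toy4",
    )


@pytest.fixture
def white_recording(rng):
    """Two channels of unit-variance white noise, 200 Hz, 10 s."""
    return EEGRecording(
        data=rng.standard_normal((2, 2000)), fs=200.0, channel_names=["C3", "C4"]
    )


def make_de_array(values, band_names=None, epoch_len_s=1.0):
    """DEFeatureArray from a raw (C, K, E) array with generated names."""
    values = np.asarray(values, dtype=float)
    c, k, _ = values.shape
    band_names = band_names or [f"b{i}" for i in range(k)]
    band_set = BandSet(tuple((n, 1.0 + 2 * i, 2.0 + 2 * i) for i, n in enumerate(band_names)))
    return DEFeatureArray(
        values=values,
        band_set=band_set,
        channel_names=[f"ch{i}" for i in range(c)],
        epoch_len_s=epoch_len_s,
    )
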