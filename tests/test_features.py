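import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from asmap.errors import ValidationError
from asmap.features import (
    RASM_CAP,
    baseline_features,
    build_asmap,
    load_asmaps,
    normalize_asmap,
    save_asmaps,
    window_average,
)
from asmap.montage import Montage
from tests.conftest import make_de_array


def windowed_from(values, window_len_s=1.0, **kwargs):
    de = make_de_array(values, **kwargs)
    return window_average(de, window_len_s)


class TestWindowAverage:
    def test_window_counts(self, rng):
        de = make_de_array(rng.standard_normal((2, 1, 60)))
        assert window_average(de, 3.0).n_windows == 20
        assert window_average(de, 7.0).n_windows == 8

    def test_mean_within_window(self):
        de = make_de_array(np.array([1.0, 2.0, 3.0]).reshape(1, 1, 3))
        w = window_average(de, 3.0)
        assert w.values[0, 0, 0] == pytest.approx(2.0)

    def test_non_multiple_window_rejected(self, rng):
        de = make_de_array(rng.standard_normal((2, 1, 60)))
        with pytest.raises(ValidationError, match="multiple"):
            window_average(de, 2.5)

    def test_zero_complete_windows_rejected(self, rng):
        de = make_de_array(rng.standard_normal((2, 1, 5)))
        with pytest.raises(ValidationError, match="window"):
            window_average(de, 10.0)


class TestBuildAsmap:
    def test_three_channel_example(self):
        w = windowed_from(np.array([2.0, 1.0, 0.0]).reshape(3, 1, 1))
        a = build_asmap(w, 0)
        expected = np.array([[0.0, 1.0, 2.0], [-1.0, 0.0, 1.0], [-2.0, -1.0, 0.0]])
        np.testing.assert_array_equal(a.values[:, :, 0], expected)

    def test_identical_channels_zero_map(self):
        w = windowed_from(np.full((4, 2, 1), 1.7))
        a = build_asmap(w, 0)
        np.testing.assert_array_equal(a.values, 0.0)

    def test_constant_shift_invariance(self, rng):
        v = rng.standard_normal((5, 2, 1))
        a1 = build_asmap(windowed_from(v), 0)
        a2 = build_asmap(windowed_from(v + 3.3), 0)
        np.testing.assert_allclose(a1.values, a2.values, atol=1e-12)

    def test_brute_force_all_pairs_oracle(self, rng):
        de = rng.standard_normal((4, 3, 2))
        w = windowed_from(de)
        a = build_asmap(w, 1)
        for i in range(4):
            for j in range(4):
                for k in range(3):
                    assert a.values[i, j, k] == de[i, k, 1] - de[j, k, 1]

    def test_antisymmetry_and_zero_diagonal_exact(self, rng):
        w = windowed_from(rng.standard_normal((6, 5, 3)))
        a = build_asmap(w, 2)
        np.testing.assert_array_equal(a.values, -a.values.transpose(1, 0, 2))
        for k in range(5):
            np.testing.assert_array_equal(np.diagonal(a.values[:, :, k]), 0.0)

    def test_band_subset_selection(self, rng):
        w = windowed_from(rng.standard_normal((3, 2, 1)), band_names=["alpha", "gamma"])
        a = build_asmap(w, 0, ["gamma"])
        assert a.band_names == ["gamma"]
        assert a.values.shape == (3, 3, 1)

    def test_unknown_band_rejected(self, rng):
        w = windowed_from(rng.standard_normal((3, 2, 1)))
        with pytest.raises(ValidationError, match="nope"):
            build_asmap(w, 0, ["nope"])

    def test_window_index_out_of_range(self, rng):
        w = windowed_from(rng.standard_normal((3, 2, 4)))
        with pytest.raises(ValidationError, match="out of range"):
            build_asmap(w, 4)


class TestNormalizeAsmap:
    def test_worked_example(self):
        w = windowed_from(np.array([2.0, 1.0, 0.0]).reshape(3, 1, 1))
        n = normalize_asmap(build_asmap(w, 0))
        expected = np.array([[0.5, 0.75, 1.0], [0.25, 0.5, 0.75], [0.0, 0.25, 0.5]])
        np.testing.assert_allclose(n.values[:, :, 0], expected)

    def test_constant_slice_maps_to_half(self):
        w = windowed_from(np.full((3, 1, 1), 2.0))
        n = normalize_asmap(build_asmap(w, 0))
        np.testing.assert_array_equal(n.values, 0.5)

    def test_gain_invariance(self, rng):
        v = rng.standard_normal((4, 2, 1))
        n1 = normalize_asmap(build_asmap(windowed_from(v), 0))
        n2 = normalize_asmap(build_asmap(windowed_from(v * 4.0), 0))
        np.testing.assert_allclose(n1.values, n2.values, atol=1e-12)

    def test_range_and_complement(self, rng):
        w = windowed_from(rng.standard_normal((5, 3, 1)))
        n = normalize_asmap(build_asmap(w, 0))
        assert n.values.min() >= 0.0 and n.values.max() <= 1.0
        np.testing.assert_allclose(n.values + n.values.transpose(1, 0, 2), 1.0, atol=1e-12)
        for k in range(3):
            assert n.values[:, :, k].min() == 0.0
            assert n.values[:, :, k].max() == 1.0

    def test_double_normalize_rejected(self, rng):
        n = normalize_asmap(build_asmap(windowed_from(rng.standard_normal((3, 1, 1))), 0))
        with pytest.raises(ValidationError, match="already"):
            normalize_asmap(n)


@settings(max_examples=50, deadline=None)
@given(
    de=arrays(
        np.float64,
        (5, 2, 1),
        elements=st.floats(min_value=-10, max_value=10, allow_nan=False),
    )
)
def test_property_antisymmetry_and_normalized_range(de):
    w = windowed_from(de)
    raw = build_asmap(w, 0)
    assert np.array_equal(raw.values, -raw.values.transpose(1, 0, 2))
    n = normalize_asmap(raw)
    assert (n.values >= 0).all() and (n.values <= 1).all()
    np.testing.assert_allclose(n.values + n.values.transpose(1, 0, 2), 1.0, atol=1e-9)


class TestBaselineFeatures:
    def two_pair_windowed(self, toy_montage, left=2.0, right=0.5):
        de = np.zeros((4, 1, 1))
        de[0, 0, 0] = left  # F3
        de[1, 0, 0] = right  # F4
        de[2, 0, 0] = left  # P3
        de[3, 0, 0] = right  # P4
        w = windowed_from(de)
        w.channel_names = list(toy_montage.channel_order)
        return w

    def test_dasm_rasm_definitions(self, toy_montage):
        w = self.two_pair_windowed(toy_montage)
        dasm = baseline_features(w, 0, "DASM", toy_montage)
        rasm = baseline_features(w, 0, "RASM", toy_montage)
        np.testing.assert_allclose(dasm.values, [1.5, 1.5])
        np.testing.assert_allclose(rasm.values, [4.0, 4.0])

    def test_symmetric_de(self, toy_montage):
        w = self.two_pair_windowed(toy_montage, left=1.3, right=1.3)
        assert np.allclose(baseline_features(w, 0, "DASM", toy_montage).values, 0.0)
        assert np.allclose(baseline_features(w, 0, "RASM", toy_montage).values, 1.0)

    def test_rasm_divisor_guard(self, toy_montage):
        w = self.two_pair_windowed(toy_montage, left=1.0, right=0.0)
        rasm = baseline_features(w, 0, "RASM", toy_montage)
        assert rasm.capped
        np.testing.assert_allclose(rasm.values, RASM_CAP)

    def test_dimensions_62ch_5band(self, rng, seed62):
        de = make_de_array(rng.standard_normal((62, 5, 3)))
        de.channel_names = list(seed62.channel_order)
        w = window_average(de, 1.0)
        lengths = {
            m: len(baseline_features(w, 0, m, seed62)) for m in ("DE", "DASM", "RASM", "DCAU")
        }
        assert lengths == {"DE": 310, "DASM": 135, "RASM": 135, "DCAU": 115}

    def test_dasm_dcau_are_asmap_subsamples(self, rng, seed62):
        de = make_de_array(rng.standard_normal((62, 5, 1)))
        de.channel_names = list(seed62.channel_order)
        w = window_average(de, 1.0)
        raw = build_asmap(w, 0)
        dasm = baseline_features(w, 0, "DASM", seed62).values.reshape(27, 5)
        for p, (i, j) in enumerate(seed62.pair_indices("hemispheric")):
            np.testing.assert_array_equal(dasm[p], raw.values[i, j, :])
        dcau = baseline_features(w, 0, "DCAU", seed62).values.reshape(23, 5)
        for p, (i, j) in enumerate(seed62.pair_indices("frontal_posterior")):
            np.testing.assert_array_equal(dcau[p], raw.values[i, j, :])

    def test_channel_order_mismatch_rejected(self, rng, toy_montage):
        w = windowed_from(rng.standard_normal((4, 1, 1)))
        with pytest.raises(ValidationError, match="order"):
            baseline_features(w, 0, "DE", toy_montage)

    def test_unknown_method(self, rng, toy_montage):
        w = self.two_pair_windowed(toy_montage)
        with pytest.raises(ValidationError, match="method"):
            baseline_features(w, 0, "PSD", toy_montage)


def test_asmap_hdf5_round_trip(tmp_path, rng):
    w = windowed_from(rng.standard_normal((4, 2, 3)))
    maps = [normalize_asmap(build_asmap(w, i)) for i in range(3)]
    save_asmaps(maps, tmp_path / "maps.h5", provenance={"window_s": 1.0})
    back = load_asmaps(tmp_path / "maps.h5")
    assert len(back) == 3
    for a, b in zip(maps, back):
        np.testing.assert_array_equal(a.values, b.values)
        assert b.normalized


def test_asmap_png_export(tmp_path, rng):
    w = windowed_from(rng.standard_normal((4, 1, 1)), band_names=["gamma"])
    n = normalize_asmap(build_asmap(w, 0))
    from asmap.features import asmap_to_image

    asmap_to_image(n, "gamma", tmp_path / "map.png")
    assert (tmp_path / "map.png").stat().st_size > 0
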