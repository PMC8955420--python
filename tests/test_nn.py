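import numpy as np
import pytest

from asmap.errors import ValidationError
from asmap.nn import (
    CNNConfig,
    HeadConfig,
    TrainConfig,
    build_mlp,
    build_model,
    cnn_flatten_length,
    evaluate,
    extract_features,
    group_split,
    load_model,
    save_model,
    stratified_split,
    train,
)


class TestShapes:
    @pytest.mark.parametrize("side, expected", [(62, 3136), (32, 576), (12, 16), (10, 16)])
    def test_closed_form(self, side, expected):
        assert cnn_flatten_length(side) == expected

    @pytest.mark.parametrize("side, k", [(62, 5), (32, 5), (62, 1), (12, 1)])
    def test_model_flatten_matches_closed_form(self, side, k):
        model = build_model(CNNConfig((side, side, k)), HeadConfig(3))
        x = np.full((2, side, side, k), 0.5)
        feats = extract_features(model, x)
        assert feats.shape == (2, cnn_flatten_length(side))
        assert model.meta["flatten_length"] == cnn_flatten_length(side)

    def test_too_small_input_rejected(self):
        with pytest.raises(ValidationError, match="small"):
            build_model(CNNConfig((7, 7, 1)), HeadConfig(2))

    def test_eight_collapses_under_second_pool(self):
        with pytest.raises(ValidationError):
            build_model(CNNConfig((8, 8, 1)), HeadConfig(2))

    def test_non_square_rejected(self):
        with pytest.raises(ValidationError, match="square"):
            CNNConfig((10, 12, 1))


class TestExtractFeatures:
    def test_rows_preserved_and_deterministic(self, rng):
        model = build_model(CNNConfig((12, 12, 2)), HeadConfig(2))
        x = np.repeat(rng.random((1, 12, 12, 2)), 10, axis=0)
        feats = extract_features(model, x)
        assert feats.shape[0] == 10
        for row in feats[1:]:
            np.testing.assert_array_equal(row, feats[0])

    def test_constant_input_finite(self):
        model = build_model(CNNConfig((12, 12, 1)), HeadConfig(2))
        feats = extract_features(model, np.full((3, 12, 12, 1), 0.5))
        assert np.isfinite(feats).all()

    def test_mlp_has_no_flatten_stage(self):
        model = build_mlp(10, HeadConfig(2))
        with pytest.raises(ValidationError, match="flatten"):
            extract_features(model, np.zeros((2, 10)))

    def test_shape_mismatch_rejected(self):
        model = build_model(CNNConfig((12, 12, 1)), HeadConfig(2))
        with pytest.raises(ValidationError, match="shape"):
            extract_features(model, np.zeros((2, 10, 10, 1)))


class TestSplits:
    def test_disjoint_and_stratified(self, rng):
        y = np.repeat([0, 1, 2], [30, 20, 10])
        main, held = stratified_split(y, 0.2, rng)
        assert set(main) & set(held) == set()
        assert len(main) + len(held) == 60
        for cls, expected in [(0, 6), (1, 4), (2, 2)]:
            assert abs((y[held] == cls).sum() - expected) <= 1

    def test_same_seed_identical(self):
        y = np.repeat([0, 1], 20)
        a = stratified_split(y, 0.25, np.random.default_rng(7))
        b = stratified_split(y, 0.25, np.random.default_rng(7))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_group_split_keeps_groups_whole(self, rng):
        groups = np.repeat(np.arange(10), 6)
        main, held = group_split(groups, 0.3, rng)
        assert set(groups[main]) & set(groups[held]) == set()


def _separable_maps(n_per_class, side=12, seed=0):
    """Two classes distinguished by which half of the map is bright."""
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for cls in (0, 1):
        base = np.full((side, side, 1), 0.3)
        if cls:
            base[:, side // 2 :, :] = 0.7
        else:
            base[:, : side // 2, :] = 0.7
        for _ in range(n_per_class):
            xs.append(base + 0.05 * rng.standard_normal(base.shape))
            ys.append(cls)
    return np.stack(xs), np.array(ys)


class TestTraining:
    def test_separable_data_learned(self):
        x, y = _separable_maps(30, seed=5)
        model = build_model(CNNConfig((12, 12, 1)), HeadConfig(2))
        cfg = TrainConfig(seed=1234, max_epochs=20, batch_size=16)
        history = train(model, x, y, cfg)
        assert max(history["train_accuracy"]) >= 0.95
        assert model.trained

    def test_same_seed_same_split_indices(self):
        x, y = _separable_maps(15)
        cfg = TrainConfig(seed=99, max_epochs=2)
        m1 = build_model(CNNConfig((12, 12, 1)), HeadConfig(2))
        h1 = train(m1, x, y, cfg)
        m2 = build_model(CNNConfig((12, 12, 1)), HeadConfig(2))
        h2 = train(m2, x, y, cfg)
        assert h1["train_indices"] == h2["train_indices"]
        assert h1["val_indices"] == h2["val_indices"]
        np.testing.assert_array_equal(m1.parameters[0], m2.parameters[0])

    def test_shuffled_labels_at_chance(self):
        rng = np.random.default_rng(11)
        x = rng.random((120, 20))
        y = rng.integers(0, 2, size=120)
        model = build_mlp(20, HeadConfig(2, hidden_units=(32,)))
        history = train(model, x, y, TrainConfig(seed=3, max_epochs=15))
        # 95% binomial interval around 0.5 for the 24-example validation split
        acc = history["val_accuracy"][-1]
        half_width = 1.96 * np.sqrt(0.25 / 24)
        assert abs(acc - 0.5) <= half_width + 1e-9

    def test_singleton_class_rejected(self):
        x, y = _separable_maps(5)
        y = y.copy()
        y[y == 1] = 0
        y[0] = 1
        model = build_model(CNNConfig((12, 12, 1)), HeadConfig(2))
        with pytest.raises(ValidationError, match="fewer than 2"):
            train(model, x, y, TrainConfig(seed=0, max_epochs=1))

    def test_label_shape_mismatch(self):
        x, y = _separable_maps(5)
        model = build_model(CNNConfig((12, 12, 1)), HeadConfig(2))
        with pytest.raises(ValidationError, match="labels"):
            train(model, x, y[:-2], TrainConfig(seed=0))


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        model = build_model(CNNConfig((10, 10, 1)), HeadConfig(2, hidden_units=(8,)))
        model.initialize(seed=3)
        x = rng.random((4, 10, 10, 1))
        y = np.array([0, 1, 0, 1])

        def loss():
            logits = model.forward(x, training=False)
            z = logits - logits.max(axis=1, keepdims=True)
            p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
            return -np.mean(np.log(p[np.arange(4), y] + 1e-12))

        logits = model.forward(x, training=False)
        z = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        d = p.copy()
        d[np.arange(4), y] -= 1
        model.backward(d / 4)

        eps = 1e-6
        for p_idx in (0, len(model.parameters) - 2):
            param = model.parameters[p_idx]
            grad = model.gradients[p_idx]
            flat = param.reshape(-1)
            for j in rng.choice(flat.size, size=3, replace=False):
                orig = flat[j]
                flat[j] = orig + eps
                lp = loss()
                flat[j] = orig - eps
                lm = loss()
                flat[j] = orig
                numeric = (lp - lm) / (2 * eps)
                assert numeric == pytest.approx(grad.reshape(-1)[j], abs=1e-4, rel=1e-3)


class TestEvaluate:
    def test_perfect_predictions(self):
        x, y = _separable_maps(15, seed=2)
        model = build_model(CNNConfig((12, 12, 1)), HeadConfig(2))
        train(model, x, y, TrainConfig(seed=1234, max_epochs=20, batch_size=16))
        report = evaluate(model, x, y)
        assert report.confusion.sum() == report.n_test == 30
        assert report.confusion.sum(axis=1).tolist() == [15, 15]
        assert report.accuracy == pytest.approx(np.trace(report.confusion) / 30)

    def test_empty_test_set_rejected(self):
        model = build_mlp(4, HeadConfig(2))
        with pytest.raises(ValidationError, match="empty"):
            evaluate(model, np.zeros((0, 4)), np.zeros(0, dtype=int))

    def test_constant_predictor_on_balanced_classes(self):
        model = build_mlp(4, HeadConfig(3, hidden_units=(4,)))
        for p in model.parameters:
            p[...] = 0.0
        model.parameters[-1][0] = 5.0  # bias toward class 0
        y = np.repeat([0, 1, 2], 10)
        report = evaluate(model, np.ones((30, 4)), y)
        assert report.accuracy == pytest.approx(1 / 3)
        assert report.confusion[:, 0].sum() == 30


def test_save_load_round_trip(tmp_path):
    x, y = _separable_maps(10)
    model = build_model(CNNConfig((12, 12, 1)), HeadConfig(2))
    train(model, x, y, TrainConfig(seed=0, max_epochs=3))
    save_model(model, tmp_path / "model")
    back = load_model(tmp_path / "model")
    np.testing.assert_array_equal(model.predict_proba(x), back.predict_proba(x))
    assert back.trained
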