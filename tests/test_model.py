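import numpy as np
import pytest

from eegcorrcam import nn
from eegcorrcam.model import (CorrelationCNNClassifier, LayerSpec, ModelSpec,
                              build_model, class_weights, cross_validate,
                              default_layers, restore_checkpoint, train)

#: layer-by-layer output sizes of the default architecture on a 360x360x1
#: input
FULL_TRACE = [
    (360, 360, 8), (180, 180, 8),
    (180, 180, 16), (90, 90, 16),
    (90, 90, 32), (45, 45, 32),
    (45, 45, 64), (22, 22, 64),
    (22, 22, 128), (11, 11, 128),
    (128,), (128,), (32,), (32,), (3,),
]


class TestArchitecture:
    def test_default_shape_trace_row_for_row(self):
        net = build_model(ModelSpec())
        assert net.shape_trace() == FULL_TRACE

    def test_pooled_feature_vector_has_length_128(self):
        net = build_model(ModelSpec())
        gmp_shape = net.shape_trace()[10]
        assert gmp_shape == (128,)

    def test_same_stack_on_96_input(self):
        # same-padded convs keep spatial size; 2x2 pools floor-divide
        spec = ModelSpec(input_shape=(96, 96, 1))
        sizes = [s[0] for s in build_model(spec).shape_trace()[:10]]
        assert sizes == [96, 48, 48, 24, 24, 12, 12, 6, 6, 3]
        assert build_model(spec).shape_trace()[10] == (128,)

    def test_untrained_model_outputs_probabilities(self, rng):
        spec = ModelSpec.scaled(input_side=24, conv_filters=(2, 3))
        net = build_model(spec)
        probs = net.forward(rng.standard_normal((5, 24, 24, 1)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_final_layer_must_be_softmax(self):
        with pytest.raises(ValueError, match="softmax"):
            ModelSpec(layers=(LayerSpec("dense", units=3),), n_classes=3)

    def test_layer_spec_validates_required_fields(self):
        with pytest.raises(ValueError, match="filters"):
            LayerSpec("conv2d", kernel=3)


class TestClassWeights:
    def test_inverse_frequency_formula(self):
        labels = [0] * 128 + [1] * 360 + [2] * 496
        w = class_weights(labels)
        assert w[0] == pytest.approx(2.5625, abs=1e-12)  # 984 / (3*128) exactly
        assert w[1] == pytest.approx(984 / (3 * 360))
        assert w[2] == pytest.approx(984 / (3 * 496))

    def test_total_loss_mass_is_preserved(self):
        labels = [0] * 7 + [1] * 2 + [2] * 21
        w = class_weights(labels)
        counts = {0: 7, 1: 2, 2: 21}
        assert sum(counts[c] * w[c] for c in w) == pytest.approx(len(labels))

    def test_balanced_classes_get_unit_weights(self):
        w = class_weights([0, 0, 1, 1, 2, 2])
        assert all(v == pytest.approx(1.0) for v in w.values())

    def test_absent_class_is_an_error(self):
        with pytest.raises(ValueError, match="class 2"):
            class_weights([0, 0, 1], n_classes=3)


def test_unit_sample_weights_reproduce_unweighted_loss(rng):
    probs = nn.softmax(rng.standard_normal((10, 3)).astype(np.float32))
    y = rng.integers(0, 3, 10)
    loss_none, grad_none = nn.weighted_sparse_crossentropy(probs, y)
    loss_ones, grad_ones = nn.weighted_sparse_crossentropy(probs, y, np.ones(10))
    assert loss_none == loss_ones
    np.testing.assert_array_equal(grad_none, grad_ones)


def _toy_blocks(rng, n_per_class=12, side=16):
    """Separable two-class images: class 1 contains a bright block (the
    network's global max pooling makes feature *presence* the natural
    separable signal)."""
    X, y = [], []
    for label in (0, 1):
        for _ in range(n_per_class):
            img = rng.normal(0, 0.05, (side, side))
            if label == 1:
                r, c = rng.integers(0, side // 2, 2)
                img[r : r + side // 2, c : c + side // 2] += 1.0
            X.append(img)
            y.append(label)
    return np.array(X, dtype=np.float32), np.array(y)


class TestTraining:
    @pytest.fixture
    def toy(self, rng):
        X, y = _toy_blocks(rng)
        spec = ModelSpec.scaled(input_side=16, n_classes=2, conv_filters=(4,),
                                dense_units=8, epochs=30, batch_size=8,
                                learning_rate=0.01)
        return X, y, spec

    def test_separable_toy_reaches_full_training_accuracy(self, toy):
        X, y, spec = toy
        net = build_model(spec, seed=0)
        hist = train(net, X[2:], y[2:], X[:2], y[:2], spec, seed=0)
        assert max(hist.accuracy) == 1.0

    def test_same_seed_gives_identical_loss_curve(self, toy):
        X, y, spec = toy
        losses = []
        for _ in range(2):
            net = build_model(spec, seed=7)
            hist = train(net, X[2:], y[2:], X[:2], y[:2], spec, seed=7)
            losses.append(hist.loss)
        assert losses[0] == losses[1]

    def test_checkpoint_restores_best_validation_metric(self, toy):
        X, y, spec = toy
        net = build_model(spec, seed=1)
        hist = train(net, X[4:], y[4:], X[:4], y[:4], spec, seed=1)
        restore_checkpoint(net)
        probs = net.predict_proba(X[:4])
        acc = float(np.mean(probs.argmax(axis=1) == y[:4]))
        assert acc == pytest.approx(net.best_val_accuracy)
        assert net.best_val_accuracy == max(hist.val_accuracy)

    def test_empty_validation_set_rejected(self, toy):
        X, y, spec = toy
        net = build_model(spec)
        with pytest.raises(ValueError, match="non-empty"):
            train(net, X, y, X[:0], y[:0], spec)


def _cv_data(rng, n=100, side=8):
    X = rng.normal(0, 1, (n, side, side)).astype(np.float32)
    y = np.array([0] * 60 + [1] * 40)
    return X, y


TINY_SPEC = ModelSpec.scaled(input_side=8, n_classes=2, conv_filters=(2,),
                             dense_units=4, epochs=1, batch_size=32)


class TestCrossValidation:
    def test_folds_partition_samples_exactly_and_stratified(self, rng):
        X, y = _cv_data(rng)
        results = cross_validate(X, y, TINY_SPEC, k=10, seed=0)
        all_test = np.concatenate([r.test_indices for r in results])
        assert sorted(all_test) == list(range(100))  # exact disjoint cover
        for r in results:
            counts = np.bincount(y[r.test_indices], minlength=2)
            assert abs(counts[0] - 6) <= 1 and abs(counts[1] - 4) <= 1

    def test_subject_grouping_never_splits_a_subject(self, rng):
        X, y = _cv_data(rng)
        subjects = np.repeat([f"s{i}" for i in range(20)], 5)
        results = cross_validate(X, y, TINY_SPEC, k=5, grouping="subject",
                                 groups=subjects, seed=0)
        seen = {}
        for fold, r in enumerate(results):
            for s in set(subjects[r.test_indices]):
                assert s not in seen, f"subject {s} tested in two folds"
                seen[s] = fold
        assert len(seen) == 20

    def test_too_few_samples_for_k_rejected(self, rng):
        X, y = _cv_data(rng, n=100)
        with pytest.raises(ValueError, match="at least"):
            cross_validate(X[:5], y[:5], TINY_SPEC, k=10)

    def test_subject_grouping_requires_groups(self, rng):
        X, y = _cv_data(rng)
        with pytest.raises(ValueError, match="groups"):
            cross_validate(X, y, TINY_SPEC, k=5, grouping="subject")


class TestSklearnEstimator:
    def test_fit_predict_roundtrip_with_string_labels(self, rng):
        X, y_int = _toy_blocks(rng, n_per_class=10)
        y = np.array(["ctrl", "case"])[y_int]
        spec = ModelSpec.scaled(input_side=16, n_classes=2, conv_filters=(4,),
                                dense_units=8, epochs=20, batch_size=8,
                                learning_rate=0.01)
        clf = CorrelationCNNClassifier(spec=spec, seed=0).fit(X, y)
        assert set(clf.classes_) == {"case", "ctrl"}
        preds = clf.predict(X)
        assert (preds == y).mean() >= 0.9
        probs = clf.predict_proba(X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_get_set_params_clone_compatible(self):
        from sklearn.base import clone
        clf = CorrelationCNNClassifier(seed=5)
        cloned = clone(clf)
        assert cloned.get_params()["seed"] == 5
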