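"""Architectures, initialisation, freezing and the CNN estimator."""

import numpy as np
import pytest

from speclearn.nn import (
    CNNClassifier,
    ModelState,
    Network,
    build_architecture,
    class_weights,
    init_parameters,
    replace_decision_head,
    set_representation_mode,
)
from speclearn.nn.architectures import layer_output_shapes
from speclearn.nn.classifier import TrainConfig, train_network
from speclearn.nn.network import REPRESENTATION_MODES


class TestBuildArchitecture:
    @pytest.mark.parametrize(
        "name,n_weight",
        [("variant_lecun", 4), ("variant_lenet", 5), ("variant_vgg9", 9)],
    )
    def test_weight_layer_counts(self, name, n_weight):
        arch = build_architecture(name, 2000, 2)
        assert arch.n_weight_layers == n_weight

    def test_binary_head_is_single_sigmoid_unit(self):
        arch = build_architecture("variant_lecun", 2000, 2)
        assert arch.head_activation == "sigmoid"
        assert arch.layers[-1].units == 1

    def test_multiclass_head_is_softmax_with_class_units(self):
        arch = build_architecture("variant_lenet", 2000, 12)
        assert arch.head_activation == "softmax"
        assert arch.layers[-1].units == 12

    @pytest.mark.parametrize("length", [1500, 7084, 15000, 19000])
    @pytest.mark.parametrize("name", ["variant_lecun", "variant_lenet", "variant_vgg9"])
    def test_builds_at_all_feature_dimensionalities(self, name, length):
        arch = build_architecture(name, length, 3)
        shapes = layer_output_shapes(arch)
        assert shapes[-1] == 3

    def test_representation_portion_is_conv_pool_only(self):
        arch = build_architecture("variant_vgg9", 7084, 2)
        kinds = {l.kind for l in arch.layers[: arch.representation_end]}
        assert kinds <= {"conv1d", "maxpool1d", "activation"}
        assert arch.layers[arch.representation_end].kind == "flatten"

    def test_unknown_name_and_short_input_rejected(self):
        with pytest.raises(ValueError, match="unknown architecture"):
            build_architecture("alexnet", 2000, 2)
        with pytest.raises(ValueError):
            build_architecture("variant_lecun", 32, 2)


class TestInit:
    def test_seed_reproducibility(self):
        arch = build_architecture("variant_lecun", 500, 2)
        a = init_parameters(arch, seed=3)
        b = init_parameters(arch, seed=3)
        for pa, pb in zip(a.parameters, b.parameters):
            if pa is not None:
                assert np.array_equal(pa["W"], pb["W"])

    def test_he_variance_on_large_tensor(self):
        """Empirical variance of a ~10^6-element He tensor within 5% of 2/fan_in."""
        arch = build_architecture("variant_lecun", 15000, 2)
        state = init_parameters(arch, seed=0)
        dense = [p for p in state.parameters if p is not None][2]
        W = dense["W"]
        assert W.size > 2e5
        fan_in = W.shape[0]
        assert np.var(W) == pytest.approx(2.0 / fan_in, rel=0.05)

    def test_biases_start_at_zero(self):
        arch = build_architecture("variant_lenet", 600, 3)
        state = init_parameters(arch, seed=1)
        for p in state.parameters:
            if p is not None:
                assert np.all(p["b"] == 0)

    def test_n_classes_changes_only_output_layer(self):
        arch2 = build_architecture("variant_lecun", 800, 2)
        arch5 = build_architecture("variant_lecun", 800, 5)
        s2 = init_parameters(arch2, seed=0)
        s5 = init_parameters(arch5, seed=0)
        shapes2 = [None if p is None else p["W"].shape for p in s2.parameters]
        shapes5 = [None if p is None else p["W"].shape for p in s5.parameters]
        assert shapes2[:-1] == shapes5[:-1]
        assert shapes2[-1][1] == 1 and shapes5[-1][1] == 5


class TestClassWeights:
    def test_balanced_classes_get_unit_weight(self):
        assert class_weights([0, 0, 1, 1]) == {0: 1.0, 1: 1.0}

    def test_inverse_frequency_formula(self):
        w = class_weights([0, 0, 0, 1])
        assert w[0] == pytest.approx(2 / 3)
        assert w[1] == pytest.approx(2.0)

    def test_sample_weighted_mean_is_one(self, rng):
        labels = rng.integers(0, 3, 60)
        w = class_weights(labels)
        per_sample = np.array([w[int(c)] for c in labels])
        assert per_sample.mean() == pytest.approx(1.0)


class TestForward:
    def test_softmax_scores_sum_to_one(self, rng):
        arch = build_architecture("variant_lecun", 400, 4)
        net = Network(init_parameters(arch, 0))
        proba = net.predict_proba(rng.uniform(0, 1, (8, 400)))
        assert proba.shape == (8, 4)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_sigmoid_scores_are_probability_pairs(self, rng):
        arch = build_architecture("variant_lecun", 400, 2)
        net = Network(init_parameters(arch, 0))
        proba = net.predict_proba(rng.uniform(0, 1, (5, 400)))
        assert proba.shape == (5, 2)
        assert np.all((proba > 0) & (proba < 1))
        assert np.allclose(proba.sum(axis=1), 1.0)


class TestRepresentationModes:
    def test_mode_trainable_flags(self):
        arch = build_architecture("variant_lenet", 600, 3)
        state = init_parameters(arch, 0)
        convs = state.architecture.conv_layer_indices
        st = set_representation_mode(state, "train_all")
        assert all(l.trainable for l in st.architecture.layers if l.has_weights)
        st = set_representation_mode(state, "freeze_all_conv")
        assert all(not st.architecture.layers[i].trainable for i in convs)
        st = set_representation_mode(state, "freeze_all_conv_but_last")
        flags = [st.architecture.layers[i].trainable for i in convs]
        assert flags == [False, False, True]  # exactly the last of 3 conv layers

    def test_unknown_mode_rejected(self):
        state = init_parameters(build_architecture("variant_lecun", 400, 2), 0)
        with pytest.raises(ValueError):
            set_representation_mode(state, "freeze_everything")


class TestReplaceHead:
    def test_conv_preserved_bitwise_and_head_resized(self):
        state = init_parameters(build_architecture("variant_lecun", 400, 2), 0)
        new = replace_decision_head(state, 12, seed=9)
        end = state.architecture.representation_end
        for i in range(end):
            if state.parameters[i] is not None:
                assert np.array_equal(new.parameters[i]["W"], state.parameters[i]["W"])
        assert new.architecture.layers[-1].units == 12
        assert new.architecture.head_activation == "softmax"

    def test_same_shape_new_seed_changes_dense_only(self):
        state = init_parameters(build_architecture("variant_lecun", 400, 2), 0)
        new = replace_decision_head(state, 2, seed=1)
        end = state.architecture.representation_end
        dense_old = [p for p in state.parameters[end:] if p is not None]
        dense_new = [p for p in new.parameters[end:] if p is not None]
        assert not any(np.array_equal(a["W"], b["W"])
                       for a, b in zip(dense_old, dense_new))
        assert new.architecture.head_activation == "sigmoid"
        three = replace_decision_head(state, 3, seed=1)
        assert three.architecture.head_activation == "softmax"

    def test_too_few_classes_rejected(self):
        state = init_parameters(build_architecture("variant_lecun", 400, 2), 0)
        with pytest.raises(ValueError):
            replace_decision_head(state, 1)


def _toy_problem(n=60, length=256, n_classes=2, seed=0):
    """Linearly separable toy spectra: one bump whose position encodes class."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 0.05, (n, length))
    y = np.arange(n) % n_classes
    grid = np.arange(length)
    for i in range(n):
        center = 40 + 120 * y[i] / max(1, n_classes - 1) + rng.normal(0, 2)
        X[i] += np.exp(-0.5 * ((grid - center) / 4) ** 2)
    return X, y


class TestTraining:
    def test_all_frozen_returns_identical_parameters(self):
        X, y = _toy_problem()
        arch = build_architecture("variant_lecun", 256, 2)
        state = init_parameters(arch, 0)
        for spec in state.architecture.layers:
            spec.trainable = False
        out, _ = train_network(state, X, y, X, y, TrainConfig(max_epochs=2, seed=0))
        for a, b in zip(state.parameters, out.parameters):
            if a is not None:
                assert np.array_equal(a["W"], b["W"]) and np.array_equal(a["b"], b["b"])

    def test_frozen_layers_bitwise_unchanged_in_every_mode(self):
        """Freezing contract across all architectures and modes."""
        X, y = _toy_problem(n=40, length=512)
        for name in ("variant_lecun", "variant_lenet", "variant_vgg9"):
            base = init_parameters(build_architecture(name, 512, 2), 0)
            for mode in REPRESENTATION_MODES:
                state = set_representation_mode(base, mode)
                out, _ = train_network(state, X, y, X, y,
                                       TrainConfig(max_epochs=2, seed=1))
                for i, spec in enumerate(state.architecture.layers):
                    if spec.has_weights and not spec.trainable:
                        assert np.array_equal(state.parameters[i]["W"],
                                              out.parameters[i]["W"]), (name, mode, i)
                        assert np.array_equal(state.parameters[i]["b"],
                                              out.parameters[i]["b"])

    def test_separable_task_reaches_high_accuracy(self):
        X, y = _toy_problem(n=200, seed=3)
        clf = CNNClassifier("variant_lecun", max_epochs=30, patience=30,
                            learning_rate=1e-3, random_state=0)
        clf.fit(X, y)
        assert max(clf.history_["val_accuracy"]) >= 0.95

    def test_training_is_deterministic(self):
        X, y = _toy_problem(n=40)
        cfg = dict(max_epochs=3, learning_rate=1e-3, random_state=5)
        a = CNNClassifier("variant_lecun", **cfg).fit(X, y)
        b = CNNClassifier("variant_lecun", **cfg).fit(X, y)
        assert a.history_ == b.history_
        for pa, pb in zip(a.model_state_.parameters, b.model_state_.parameters):
            if pa is not None:
                assert np.array_equal(pa["W"], pb["W"])

    def test_shape_mismatch_reported(self):
        X, y = _toy_problem(n=20)
        state = init_parameters(build_architecture("variant_lecun", 512, 2), 0)
        with pytest.raises(ValueError, match="512"):
            train_network(state, X, y, X, y, TrainConfig(max_epochs=1))

    def test_freeze_modes_require_init_state(self):
        X, y = _toy_problem(n=20)
        clf = CNNClassifier(representation_mode="freeze_all_conv")
        with pytest.raises(ValueError, match="init_state"):
            clf.fit(X, y)
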