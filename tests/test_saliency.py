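"""Attribution methods: closed forms, completeness axioms, post-processing."""

import numpy as np
import pytest

from ppgxai._nn import ReLU, ResNet1d
from ppgxai.saliency import (
    AttentionExtractor,
    UnsupportedModelError,
    attention_map,
    default_background,
    guided_backprop,
    integrated_gradients,
    reduce_columns,
    reference_attribution,
    to_attention,
)


class LinearModel:
    """F(x) = w . x + b with exact gradients — the closed-form oracle."""

    activation = "relu"  # ReLU-free, so guided backprop reduces to the gradient

    def __init__(self, w, b=0.0):
        self.w = np.asarray(w, dtype=float)
        self.b = b

    def predict_proba(self, X):
        return np.atleast_2d(X) @ self.w + self.b

    def input_gradient(self, X, guided=False):
        return np.tile(self.w, (np.atleast_2d(X).shape[0], 1))


def small_relu_net(n=64, seed=0):
    return ResNet1d(n_input=n, depth=1, kernel_size=8, channels=4, seed=seed)


class TestIntegratedGradients:
    def test_linear_model_closed_form_for_any_steps(self, rng):
        w = rng.standard_normal(6)
        x = rng.standard_normal(6)
        for steps in (1, 3, 64):
            attr = integrated_gradients(LinearModel(w, 0.5), x, steps=steps)
            assert np.allclose(attr.values, w * x, atol=1e-12)

    def test_constant_model_gives_zero_attribution(self, rng):
        attr = integrated_gradients(LinearModel(np.zeros(5), 0.3), rng.standard_normal(5))
        assert not attr.values.any()

    def test_completeness_on_small_relu_nets(self, rng):
        for seed in range(5):
            net = small_relu_net(seed=seed)
            x = rng.standard_normal(64)
            attr = integrated_gradients(net, x, steps=512)
            delta = net.predict_proba(x)[0] - net.predict_proba(np.zeros(64))[0]
            assert abs(attr.values.sum() - delta) <= 1e-3 * max(abs(delta), 1e-12)

    def test_completeness_error_shrinks_with_steps(self, rng):
        net = small_relu_net(seed=7)
        x = 3.0 * rng.standard_normal(64)
        delta = net.predict_proba(x)[0] - net.predict_proba(np.zeros(64))[0]
        errs = [
            abs(integrated_gradients(net, x, steps=s).values.sum() - delta)
            for s in (4, 512)
        ]
        assert errs[1] <= errs[0] + 1e-12

    def test_steps_below_one_rejected(self, rng):
        with pytest.raises(ValueError):
            integrated_gradients(small_relu_net(), rng.standard_normal(64), steps=0)

    def test_baseline_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            integrated_gradients(
                small_relu_net(), rng.standard_normal(64), baseline=np.zeros(10)
            )


class TestGuidedBackprop:
    def test_relu_free_linear_model_with_nonnegative_weights_is_plain_gradient(self):
        w = np.array([0.5, 0.0, 2.0])
        attr = guided_backprop(LinearModel(w), np.array([1.0, 1.0, 1.0]))
        assert np.array_equal(attr.values, w)

    def test_relu_layer_masks_negative_preactivation_and_negative_signal(self):
        # hand computation of the two masking rules on one ReLU
        layer = ReLU()
        layer.forward(np.array([[1.0, -1.0, 2.0, -2.0]]))
        g = layer.backward(np.array([[1.0, 1.0, -1.0, -1.0]]), guided=True)
        # negative pre-activation (cols 1, 3) and negative incoming signal
        # (cols 2, 3) are both zeroed
        assert np.array_equal(g, [[1.0, 0.0, 0.0, 0.0]])

    def test_maps_are_nonnegative_for_random_nets(self, rng):
        for seed in range(5):
            net = small_relu_net(seed=seed)
            attr = guided_backprop(net, rng.standard_normal(64))
            assert attr.values.min() >= 0.0

    def test_saturating_nonlinearity_rejected(self, rng):
        net = ResNet1d(n_input=64, depth=1, kernel_size=8, channels=4, seed=0,
                       activation="tanh")
        with pytest.raises(UnsupportedModelError):
            guided_backprop(net, rng.standard_normal(64))


class TestReferenceAttribution:
    def test_background_equal_to_input_gives_zero_attribution(self, rng):
        net = small_relu_net(seed=1)
        x = rng.standard_normal(64)
        attr = reference_attribution(net, x, background=x[None, :])
        assert np.allclose(attr.values, 0.0, atol=1e-12)

    def test_linear_model_with_zero_background_is_w_times_x(self, rng):
        w, x = rng.standard_normal(6), rng.standard_normal(6)
        attr = reference_attribution(LinearModel(w), x, background=np.zeros((1, 6)))
        assert np.allclose(attr.values, w * x, atol=1e-12)

    def test_summation_to_delta_with_jittered_background(self, rng):
        for seed in range(3):
            net = small_relu_net(seed=seed)
            x = rng.standard_normal(64)
            bg = default_background(64, n_references=8, seed=seed)
            attr = reference_attribution(net, x, background=bg, steps=64)
            delta = net.predict_proba(x)[0] - net.predict_proba(bg).mean()
            assert abs(attr.values.sum() - delta) <= 1e-2 * max(abs(delta), 1e-12)

    def test_empty_background_rejected(self, rng):
        with pytest.raises(ValueError):
            reference_attribution(
                small_relu_net(), rng.standard_normal(64), background=np.empty((0, 64))
            )


class TestPostProcessing:
    def test_absolute_value_and_idempotence(self):
        assert np.array_equal(to_attention(np.array([-1.0, 2.0, 0.0])), [1, 2, 0])
        att = to_attention(np.array([-1.0, 2.0, 0.0]))
        assert np.array_equal(to_attention(att), att)

    def test_2d_attribution_requires_column_reduction(self):
        with pytest.raises(ValueError):
            to_attention(np.ones((2, 3)))

    def test_column_max_hand_example(self):
        profile = reduce_columns(np.array([[1.0, 0, 2], [0, 3, 1]]), n=3)
        assert np.array_equal(profile, [1, 3, 2])

    def test_single_row_passes_through_as_absolute_values(self):
        assert np.array_equal(reduce_columns(np.array([[-2.0, -1.0]])), [2, 1])

    def test_nearest_neighbor_rescaling_to_n(self):
        profile = reduce_columns(np.array([[1.0, 2.0]]), n=4)
        assert profile.shape == (4,)
        assert set(profile) <= {1.0, 2.0}

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            reduce_columns(np.empty((0, 0)))


class TestAttentionExtractor:
    def test_constant_model_yields_zero_maps_for_all_methods(self, rng):
        net = small_relu_net(seed=2)
        for p, _ in net.params:
            p[...] = 0.0
        net.Wd[...] = 0.0
        X = rng.standard_normal((2, 64))
        for method in ("integrated_gradients", "guided", "expected_gradients"):
            maps = AttentionExtractor(model=net, method=method, steps=8).transform(X)
            assert maps.shape == (2, 64) and np.allclose(maps, 0.0, atol=1e-12)

    def test_deepshap_alias_and_map_shape(self, trained_clf, easy_test_set):
        X = easy_test_set.X[:2]
        maps = AttentionExtractor(
            model=trained_clf, method="deepshap", steps=8, n_references=4
        ).transform(X)
        assert maps.shape == X.shape and maps.min() >= 0.0

    def test_unknown_method_rejected(self, trained_clf):
        with pytest.raises(ValueError):
            attention_map(trained_clf, np.zeros(trained_clf.n_features_in_), "gradcam")
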