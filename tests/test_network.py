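"""The numpy training engine: determinism, composition, gradients, decoder."""

import numpy as np
import pytest

from melcaps import capsule_core as cc
from melcaps.architecture import (
    ArchitectureSpec,
    DecoderSpec,
    LayerSpec,
    ShapeError,
    default_melcap_spec,
    reduced_melcap_spec,
)
from melcaps.network import Model, build_model, forward_capsules, reconstruction_loss


class TestBuildDeterminism:
    def test_same_seed_bit_identical_weights(self, tiny_spec):
        p1 = build_model(tiny_spec, seed=7).parameters()
        p2 = build_model(tiny_spec, seed=7).parameters()
        assert p1.keys() == p2.keys()
        for k in p1:
            assert np.array_equal(p1[k], p2[k])

    def test_different_seeds_differ(self, tiny_spec):
        p1 = build_model(tiny_spec, seed=1).parameters()
        p2 = build_model(tiny_spec, seed=2).parameters()
        assert any(not np.array_equal(p1[k], p2[k]) for k in p1)

    def test_underflowing_input_raises_at_build(self):
        with pytest.raises(ShapeError):
            build_model(default_melcap_spec(15), seed=0)


class TestForward:
    def test_output_lengths_in_unit_interval(self, tiny_spec, rng):
        model = build_model(tiny_spec, seed=0)
        out = model.forward(rng.random((4, 12, 12, 3)))
        assert out.shape == (4, 2)
        assert np.all((out >= 0) & (out < 1))

    def test_duplicated_images_give_identical_rows(self, tiny_spec, rng):
        model = build_model(tiny_spec, seed=0)
        img = rng.random((1, 12, 12, 3))
        out = model.forward(np.concatenate([img, img, img]))
        assert np.allclose(out[0], out[1]) and np.allclose(out[1], out[2])

    def test_wrong_input_shape_raises(self, tiny_spec, rng):
        model = build_model(tiny_spec, seed=0)
        with pytest.raises(ValueError, match="input shape"):
            model.forward(rng.random((2, 10, 10, 3)))

    def test_composes_capsule_core_operations(self, rng):
        """A 1x1-conv model must equal the manual composition of the
        pointwise conv with the reference squash / votes / routing ops."""
        spec = ArchitectureSpec(
            layers=[
                LayerSpec("conv2d_1", "conv", (1, 1), 1, "valid", 8),
                LayerSpec("primary_capsule_reshape", "reshape", width=4),
                LayerSpec("primary_capsule_squash", "caps_squash"),
                LayerSpec(
                    "digit_capsule",
                    "capsule_layer",
                    width=6,
                    params={"num_classes": 2, "routing_iterations": 1},
                ),
                LayerSpec("output_capsule", "length"),
            ],
            primary_caps_dim=4,
            class_caps_features=6,
            input_shape=(4, 4, 3),
        )
        model = build_model(spec, seed=3)
        x = rng.random((2, 4, 4, 3))
        lengths, caps = forward_capsules(model, x)

        Wc = model.layers[0].params["W"][0, 0]  # (3, 8) pointwise weights
        bc = model.layers[0].params["b"]
        Wcaps = model.layers[3].params["W"]
        for n in range(2):
            feat = x[n] @ Wc + bc  # (4, 4, 8)
            u = cc.squash(feat.reshape(-1, 4))
            votes = cc.compute_votes(u, Wcaps)
            v, _ = cc.dynamic_routing(votes, 1)
            assert np.allclose(caps[n], v, atol=1e-9)
            assert np.allclose(lengths[n], cc.capsule_lengths(v), atol=1e-9)


class TestGradients:
    def test_matches_finite_differences(self, tiny_spec, rng):
        model = build_model(tiny_spec, seed=1)
        x = rng.random((3, 12, 12, 3))
        T = np.array([[1, 0], [0, 1], [1, 0]], dtype=float)

        def loss():
            return model.loss_and_grad(model.forward(x, train=True), T, "margin")[0]

        _, g = model.loss_and_grad(model.forward(x, train=True), T, "margin")
        model.backward(g)
        grads = {k: v.copy() for k, v in model.gradients().items()}
        params = model.parameters()
        pick = np.random.default_rng(0)
        eps = 1e-6
        for key, grad in grads.items():
            flat = params[key].reshape(-1)
            for i in pick.choice(flat.size, size=min(4, flat.size), replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp = loss()
                flat[i] = old - eps
                lm = loss()
                flat[i] = old
                fd = (lp - lm) / (2 * eps)
                an = grad.reshape(-1)[i]
                assert abs(fd - an) <= 1e-4 + 1e-3 * (abs(fd) + abs(an)), key

    def test_gradient_step_reduces_margin_loss(self, tiny_spec, rng):
        """End-to-end differentiability: a plain SGD step on one batch
        changes (here: lowers) the in-sample loss with finite gradients."""
        model = build_model(tiny_spec, seed=2)
        x = rng.random((4, 12, 12, 3))
        T = np.array([[1, 0], [0, 1], [1, 0], [0, 1]], dtype=float)
        l0, g = model.loss_and_grad(model.forward(x, train=True), T, "margin")
        model.backward(g)
        grads = model.gradients()
        assert all(np.all(np.isfinite(v)) for v in grads.values())
        for k, p in model.parameters().items():
            if k in grads:
                p -= 0.5 * grads[k]
        l1, _ = model.loss_and_grad(model.forward(x, train=True), T, "margin")
        assert np.isfinite(l1) and l1 < l0

    def test_bce_mode_gradients_finite(self, tiny_spec, rng):
        model = build_model(tiny_spec, seed=2)
        x = rng.random((2, 12, 12, 3))
        T = np.array([[1, 0], [0, 1]], dtype=float)
        loss, g = model.loss_and_grad(model.forward(x, train=True), T, "bce")
        assert np.isfinite(loss)
        model.backward(g)
        assert all(np.all(np.isfinite(v)) for v in model.gradients().values())


class TestPersistence:
    def test_save_load_round_trip(self, tiny_spec, rng, tmp_path):
        model = build_model(tiny_spec, seed=5)
        x = rng.random((2, 12, 12, 3))
        model.forward(x, train=True)  # move BN running stats off init
        path = tmp_path / "model.pkl"
        model.save(path)
        clone = Model.load(path)
        assert np.allclose(model.forward(x), clone.forward(x), atol=1e-12)


class TestDecoder:
    def _decoder_model(self, tiny_spec):
        spec = ArchitectureSpec(
            layers=tiny_spec.layers,
            primary_caps_dim=4,
            class_caps_features=6,
            input_shape=(12, 12, 3),
            decoder=DecoderSpec(
                hidden_widths=(16,),
                reconstruction_target_size=(6, 6, 3),
                reconstruction_loss_weight=0.5,
            ),
        )
        return build_model(spec, seed=0)

    def test_perfect_reconstruction_is_zero(self):
        spec = DecoderSpec(reconstruction_target_size=(6, 6, 3), reconstruction_loss_weight=0.5)
        img = np.random.default_rng(0).random((6, 6, 3))
        assert reconstruction_loss(img.copy(), img, spec) == 0.0

    def test_zero_weight_is_zero(self):
        spec = DecoderSpec(reconstruction_target_size=(6, 6, 3), reconstruction_loss_weight=0.0)
        rng = np.random.default_rng(0)
        assert reconstruction_loss(rng.random((6, 6, 3)), rng.random((6, 6, 3)), spec) == 0.0

    def test_closed_form_sse(self):
        spec = DecoderSpec(
            reconstruction_target_size=(56, 56, 3), reconstruction_loss_weight=0.0005
        )
        out = np.full((56, 56, 3), 0.5)
        assert reconstruction_loss(out, np.full((56, 56, 3), 0.5), spec) == 0.0
        expected = 0.0005 * 0.25 * 56 * 56 * 3
        assert reconstruction_loss(out, np.zeros((56, 56, 3)), spec) == pytest.approx(expected)

    def test_masked_decode_shape_and_class_dependence(self, tiny_spec, rng):
        model = self._decoder_model(tiny_spec)
        x = rng.random((2, 12, 12, 3))
        _, caps = model.forward_capsules(x)
        rec0 = model.decode(caps, np.array([0, 0]))
        rec1 = model.decode(caps, np.array([1, 1]))
        assert rec0.shape == (2, 6, 6, 3)
        assert not np.allclose(rec0, rec1)  # masking selects different capsules
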