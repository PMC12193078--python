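"""Window/shift bijections, attention masking, dense-block MLP, training."""

from dataclasses import replace

import numpy as np
import pytest

from cxrtriad.imstrans import (
    DenseMLP,
    SwinConfig,
    SwinModel,
    WindowAttention,
    build_attention_mask,
    conv2d,
    cyclic_shift,
    cyclic_unshift,
    dense_mlp,
    features_to_grids,
    global_average_pool,
    imstrans_forward,
    load_swin,
    save_swin,
    train_classifier,
    window_attention,
    window_partition,
    window_reverse,
)
from cxrtriad.nn import Tensor

TINY = SwinConfig(input_side=16, patch_size=2, embed_dim=16, window_P=4, num_heads=2,
                  n_classes=3, epochs=3, learning_rate=1e-3, seed=0)


class TestStructuralOps:
    def test_single_window_equals_grid(self, rng):
        g = rng.random((4, 4, 3))
        wins = window_partition(g, 4)
        assert wins.shape == (1, 4, 4, 3)
        assert np.array_equal(wins[0], g)

    def test_row_major_window_order(self):
        g = np.arange(16).reshape(4, 4)
        wins = window_partition(g, 2)
        assert np.array_equal(wins[0], [[0, 1], [4, 5]])
        assert np.array_equal(wins[1], [[2, 3], [6, 7]])
        assert np.array_equal(wins[2], [[8, 9], [12, 13]])
        assert np.array_equal(wins[3], [[10, 11], [14, 15]])

    def test_partition_reverse_bijection(self, rng):
        for _ in range(20):
            P = int(rng.choice([2, 4]))
            h = P * int(rng.integers(1, 4))
            w = P * int(rng.integers(1, 4))
            g = rng.standard_normal((h, w, int(rng.integers(1, 5))))
            assert np.array_equal(window_reverse(window_partition(g, P), h, w), g)

    def test_partition_divisibility_enforced(self):
        with pytest.raises(ValueError):
            window_partition(np.zeros((5, 5, 1)), 2)

    def test_cyclic_shift_examples_and_inverse(self, rng):
        assert np.array_equal(cyclic_shift(np.array([[1, 2], [3, 4]]), 1), [[4, 3], [2, 1]])
        g = rng.standard_normal((6, 6, 2))
        assert np.array_equal(cyclic_shift(g, 0), g)
        for s in (1, 2, 5):
            assert np.array_equal(cyclic_unshift(cyclic_shift(g, s), s), g)
        with pytest.raises(ValueError):
            cyclic_shift(g, 6)


class TestConvAndPooling:
    def test_identity_kernel(self, rng):
        img = rng.random((6, 6))
        k = np.zeros((3, 3))
        k[1, 1] = 1.0
        assert np.allclose(conv2d(img, k), img)

    def test_ones_kernel_on_impulse_gives_plateau(self):
        img = np.zeros((7, 7))
        img[3, 3] = 1.0
        out = conv2d(img, np.ones((3, 3)))
        assert np.array_equal(out[2:5, 2:5], np.ones((3, 3)))
        assert out.sum() == pytest.approx(9.0)

    def test_zero_kernel_and_even_kernel(self, rng):
        assert np.array_equal(conv2d(rng.random((4, 4)), np.zeros((3, 3))), np.zeros((4, 4)))
        with pytest.raises(ValueError):
            conv2d(np.ones((4, 4)), np.ones((2, 2)))

    def test_global_average_pool(self):
        assert global_average_pool(np.full((3, 5), 2.5)) == pytest.approx(2.5)
        assert global_average_pool(np.array([[1.0, 2.0], [3.0, 6.0]])) == pytest.approx(3.0)
        assert global_average_pool(np.array([[7.0]])) == pytest.approx(7.0)
        assert np.allclose(global_average_pool(np.arange(8.0).reshape(2, 2, 2)), [1.5, 5.5])


class TestWindowAttentionOp:
    def test_identity_value_path_single_token(self, rng):
        """One token per window with identity V and output projections."""
        wa = WindowAttention(3, 1, 1, rng)
        wa.qkv.weight.data = np.zeros((3, 9))
        wa.qkv.weight.data[:, 6:] = np.eye(3)  # value block = identity
        wa.qkv.bias.data = np.zeros(9)
        wa.proj.weight.data = np.eye(3)
        wa.proj.bias.data = np.zeros(3)
        x = rng.standard_normal((5, 1, 3))
        assert np.allclose(wa.forward_np(x), x)

    def test_two_token_window_matches_manual_softmax(self, rng):
        """Hand-set projections reproduce softmax(QK^T/sqrt(d)) V exactly."""
        wa = WindowAttention(2, 2, 1, rng)
        W = rng.standard_normal((2, 6))
        wa.qkv.weight.data = W
        wa.qkv.bias.data = np.zeros(6)
        wa.proj.weight.data = np.eye(2)
        wa.proj.bias.data = np.zeros(2)
        x = rng.standard_normal((1, 2, 2))
        q, k, v = x[0] @ W[:, :2], x[0] @ W[:, 2:4], x[0] @ W[:, 4:6]
        scores = q @ k.T / np.sqrt(2)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        weights = e / e.sum(axis=1, keepdims=True)
        assert np.allclose(window_attention(x, wa), (weights @ v)[None], atol=1e-12)

    def test_masked_pairs_have_exactly_zero_weight(self, rng):
        mask = np.array([[[0.0, -np.inf], [-np.inf, 0.0]]])
        x = Tensor(rng.standard_normal((1, 2, 4)))
        wa = WindowAttention(4, 2, 2, rng)
        qkv = wa.qkv(x).reshape(1, 2, 3, 2, 2).transpose(2, 0, 3, 1, 4)
        attn = (qkv[0] @ qkv[1].transpose(0, 1, 3, 2)) * (1 / np.sqrt(2)) + Tensor(mask[:, None])
        weights = attn.softmax(axis=-1).data
        assert np.all(weights[..., 0, 1] == 0.0) and np.all(weights[..., 1, 0] == 0.0)
        assert np.allclose(weights.sum(axis=-1), 1.0)

    def test_head_divisibility_enforced(self):
        with pytest.raises(ValueError):
            SwinConfig(embed_dim=10, num_heads=3)


class TestAttentionMask:
    def test_unmasked_when_no_shift_no_padding(self):
        assert build_attention_mask(8, 8, 4, 0) is None

    def test_shifted_mask_blocks_cross_region_pairs(self):
        mask = build_attention_mask(8, 8, 4, 2)
        assert mask.shape == (4, 16, 16)
        assert np.isneginf(mask).any()
        # the top-left window is interior: fully unmasked
        assert np.all(mask[0] == 0.0)
        # diagonal never masked
        assert np.all(~np.isneginf(np.diagonal(mask, axis1=1, axis2=2)))


class TestDenseMLP:
    def test_width_bookkeeping(self, rng):
        for C, L, g in [(16, 3, 8), (8, 1, 4), (12, 4, 2)]:
            block = DenseMLP(C, L, g, rng)
            assert block.pre_transition_width() == C + L * g
            out = block(Tensor(rng.standard_normal((2, 5, C))))
            assert out.shape == (2, 5, C)
        assert DenseMLP(16, 3, 8, rng).pre_transition_width() == 40

    def test_single_sublayer_matches_manual_arithmetic(self, rng):
        """Replicate Linear -> LayerNorm -> ReLU -> concat -> transition by hand."""
        C, g = 3, 2
        block = DenseMLP(C, 1, g, rng)
        x = rng.standard_normal((1, 4, C))
        w0, b0 = block.sublayers[0].weight.data, block.sublayers[0].bias.data
        h = x @ w0 + b0
        mu = h.mean(axis=-1, keepdims=True)
        var = ((h - mu) ** 2).mean(axis=-1, keepdims=True)
        normed = (h - mu) / np.sqrt(var + 1e-5)
        sub = np.maximum(normed, 0.0)
        cat = np.concatenate([x, sub], axis=-1)
        expected = cat @ block.transition.weight.data + block.transition.bias.data
        assert np.allclose(block(Tensor(x)).data, expected, atol=1e-12)

    def test_functional_wrapper_shapes(self, rng):
        tokens = rng.standard_normal((7, 5))
        assert dense_mlp(tokens, L=2, g=3, seed=1).shape == (7, 5)


class TestForwardAndTraining:
    def test_softmax_probabilities_contract(self, rng):
        model = SwinModel(TINY)
        probs = imstrans_forward(model, rng.random((4, 16, 16)))
        assert probs.shape == (4, 3)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        single = imstrans_forward(model, rng.random((16, 16)))
        assert single.shape == (3,)

    def test_sigmoid_head_bounds(self, rng):
        model = SwinModel(replace(TINY, head_mode="sigmoid", n_classes=4))
        probs = imstrans_forward(model, rng.random((2, 16, 16)))
        assert probs.shape == (2, 4)
        assert np.all((probs > 0) & (probs < 1))

    def test_fresh_model_has_no_positional_information(self, rng):
        """Swapping window contents leaves pooled logits unchanged (no shift)."""
        model = SwinModel(TINY)
        model.masks = {"plain": None, "shifted": None, "shift": 0}
        x = rng.random((1, 16, 16))
        swapped = x.copy()
        # windows are 8x8 pixel regions (window 4 x patch 2); swap two of them
        swapped[0, :8, :8], swapped[0, :8, 8:] = x[0, :8, 8:].copy(), x[0, :8, :8].copy()
        a = model.logits(x).data
        b = model.logits(swapped).data
        assert np.allclose(a, b, atol=1e-10)

    def test_swapping_identical_regions_is_exactly_neutral(self, rng):
        model = SwinModel(TINY)
        x = rng.random((1, 16, 16))
        x[0, :8, 8:] = x[0, :8, :8]
        swapped = x.copy()
        swapped[0, :8, :8], swapped[0, :8, 8:] = x[0, :8, 8:].copy(), x[0, :8, :8].copy()
        assert np.allclose(model.logits(x).data, model.logits(swapped).data)

    def test_zero_epochs_keeps_initialization(self, small_pixel_matrix):
        X = small_pixel_matrix[:30].reshape(-1, 16, 16)
        y = np.arange(30) % 3
        cfg = replace(TINY, epochs=0)
        trained = train_classifier(X, y, cfg)
        fresh = SwinModel(cfg)
        for a, b in zip(trained.parameters(), fresh.parameters()):
            assert np.array_equal(a.data, b.data)

    def test_training_is_deterministic_and_loss_decreases(self, small_dataset, small_pixel_matrix):
        X = small_pixel_matrix.reshape(-1, 16, 16)
        y = small_dataset.primary_labels()
        m1 = train_classifier(X, y, TINY)
        m2 = train_classifier(X, y, TINY)
        assert m1.history["train_loss"] == m2.history["train_loss"]
        assert m1.history["train_loss"][-1] < m1.history["train_loss"][0]

    def test_feature_row_input_mode(self, rng):
        F = rng.standard_normal((40, 10))  # pads to 4x4 grids
        y = (F[:, 0] > 0).astype(int)
        cfg = SwinConfig(patch_size=1, embed_dim=8, window_P=2, num_heads=2,
                         n_classes=2, epochs=2, learning_rate=1e-3, seed=0)
        model = train_classifier(F, y, cfg)
        assert model.cfg.input_side == 4
        grids = features_to_grids(F)
        assert grids.shape == (40, 4, 4)
        assert np.allclose(grids[0].ravel()[:10], F[0])
        assert np.all(grids[0].ravel()[10:] == 0)

    def test_single_class_training_rejected(self, rng):
        with pytest.raises(ValueError, match="2 classes"):
            train_classifier(rng.random((10, 16, 16)), np.zeros(10, dtype=int), TINY)

    def test_gradient_reaches_every_dense_sublayer(self, rng):
        """Dense connectivity keeps a live gradient path into each sub-layer."""
        from cxrtriad.nn import cross_entropy

        model = SwinModel(TINY)
        loss = cross_entropy(model.logits(rng.random((4, 16, 16))), np.eye(3)[[0, 1, 2, 0]])
        loss.backward()
        for block in model.blocks:
            for mlp in (block.mlp1, block.mlp2):
                for sub in mlp.sublayers:
                    norm = np.linalg.norm(sub.weight.grad)
                    assert np.isfinite(norm) and norm > 0

    def test_conv_stem_trains_with_finite_gradients(self, rng):
        from cxrtriad.nn import cross_entropy

        cfg = replace(TINY, conv_stem=True, stem_channels=3, patch_size=2, window_P=2)
        model = SwinModel(cfg)
        loss = cross_entropy(model.logits(rng.random((3, 16, 16))), np.eye(3)[[0, 1, 2]])
        loss.backward()
        for w in model.stem.convs + [model.stem.transition]:
            norm = np.linalg.norm(w.grad)
            assert np.isfinite(norm) and norm > 0

    def test_relative_position_bias_flag(self, rng):
        model = SwinModel(replace(TINY, relative_position_bias=True))
        probs = imstrans_forward(model, rng.random((2, 16, 16)))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_checkpoint_round_trip(self, rng, tmp_path):
        X = rng.random((12, 16, 16))
        y = np.arange(12) % 3
        model = train_classifier(X, y, replace(TINY, epochs=1))
        save_swin(model, tmp_path / "swin")
        back = load_swin(tmp_path / "swin")
        assert np.allclose(imstrans_forward(back, X), imstrans_forward(model, X))
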