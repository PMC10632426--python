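"""The MIL head against independent scalar-loop oracles, its invariants
(attention normalisation, permutation invariance), and gradient checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pathomil import model
from pathomil.model import (
    AttMILParams,
    attention_scores,
    classify,
    embed,
    forward,
    init_params,
    load_checkpoint,
    loss_and_grads,
    mil_pool,
    save_checkpoint,
)

# ---------------------------------------------------------------------------
# scalar-loop oracle: a deliberately naive re-implementation used as the
# independent reference for the vectorised forward pass


def oracle_forward(X, params):
    """Triple-loop forward pass (evaluation mode); returns (probs, attention)."""
    K, d = X.shape
    H = np.zeros((K, 256))
    for k in range(K):
        z = np.zeros(256)
        for i in range(256):
            acc = params.b_embed[i]
            for j in range(d):
                acc += params.W_embed[i, j] * X[k, j]
            z[i] = max(acc, 0.0)
        for i in range(256):
            acc = params.b_proj[i]
            for j in range(256):
                acc += params.W_proj[i, j] * z[j]
            H[k, i] = acc
    e = np.zeros(K)
    for k in range(K):
        t = np.tanh(params.V @ H[k])
        e[k] = float(params.w @ t)
    a = np.exp(e - e.max())
    a = a / a.sum()
    h_sum = np.zeros(256)
    for k in range(K):
        h_sum += a[k] * H[k]
    y = params.bn_gamma * (h_sum - params.bn_mean) / np.sqrt(params.bn_var + model.BN_EPS) \
        + params.bn_beta
    logits = params.W_cls @ y + params.b_cls
    p = np.exp(logits - logits.max())
    return p / p.sum(), a


def tiny_params(d, seed=0):
    rng = np.random.default_rng(seed)
    p = init_params(d, seed=seed)
    # non-trivial running stats so evaluation-mode batch norm is exercised
    p.bn_mean = rng.standard_normal(256) * 0.1
    p.bn_var = rng.uniform(0.5, 2.0, 256)
    return p


class TestForwardOracle:
    @pytest.mark.parametrize("K,d,seed", [(1, 2, 0), (3, 4, 1), (5, 8, 2), (4, 3, 3)])
    def test_forward_matches_scalar_oracle(self, K, d, seed):
        rng = np.random.default_rng(seed)
        params = tiny_params(d, seed)
        X = rng.standard_normal((K, d))
        pred = forward(X, params)
        probs_o, a_o = oracle_forward(X, params)
        np.testing.assert_allclose(pred.probs, probs_o, atol=1e-6)
        np.testing.assert_allclose(pred.attention, a_o, atol=1e-6)

    def test_embed_zero_weights_gives_zero(self):
        params = tiny_params(4)
        for k in ("W_embed", "b_embed", "W_proj", "b_proj"):
            getattr(params, k)[:] = 0.0
        h = embed(np.random.default_rng(0).standard_normal((3, 4)), params)
        np.testing.assert_array_equal(h, np.zeros((3, 256)))

    def test_dimension_mismatch_reports_expected_and_got(self):
        params = tiny_params(4)
        with pytest.raises(ValueError, match="expected 4, got 7"):
            embed(np.zeros((2, 7)), params)


class TestAttention:
    def test_singleton_bag_attention_is_one(self):
        params = tiny_params(3)
        h = embed(np.random.default_rng(0).standard_normal((1, 3)), params)
        np.testing.assert_allclose(attention_scores(h, params), [1.0])

    def test_identical_rows_share_attention(self):
        params = tiny_params(3)
        h = embed(np.tile(np.random.default_rng(1).standard_normal(3), (2, 1)), params)
        np.testing.assert_allclose(attention_scores(h, params), [0.5, 0.5], atol=1e-12)

    def test_matches_direct_formula_small_dims(self):
        # 2x3 attention on 3 distinct embeddings, computed entry by entry
        rng = np.random.default_rng(5)
        V = rng.standard_normal((2, 3))
        w = rng.standard_normal(2)
        h = rng.standard_normal((3, 3))
        e = np.array([w @ np.tanh(V @ h[k]) for k in range(3)])
        expected = np.exp(e) / np.exp(e).sum()
        params = tiny_params(3)
        got = np.exp(np.tanh(h @ V.T) @ w)
        got = got / got.sum()
        np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_empty_bag_rejected(self):
        params = tiny_params(3)
        with pytest.raises(ValueError, match="empty bag"):
            attention_scores(np.zeros((0, 256)), params)


class TestPooling:
    def test_single_weight_returns_embedding(self, rng):
        h = rng.standard_normal((1, 256))
        np.testing.assert_array_equal(mil_pool(h, np.array([1.0])), h[0])

    def test_cancellation(self, rng):
        h1 = rng.standard_normal(256)
        h = np.stack([h1, -h1])
        np.testing.assert_allclose(mil_pool(h, np.array([0.5, 0.5])), np.zeros(256),
                                   atol=1e-12)

    def test_matches_scalar_loop(self, rng):
        h = rng.standard_normal((4, 256))
        a = rng.dirichlet(np.ones(4))
        expected = sum(a[i] * h[i] for i in range(4))
        np.testing.assert_allclose(mil_pool(h, a), expected, atol=1e-8)

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            mil_pool(rng.standard_normal((3, 256)), np.ones(2) / 2)


class TestClassifier:
    def test_zero_final_weights_uniform(self):
        params = tiny_params(4)
        params.W_cls[:] = 0.0
        params.b_cls[:] = 0.0
        probs = classify(np.random.default_rng(0).standard_normal(256), params)
        np.testing.assert_allclose(probs, [[0.5, 0.5]])

    def test_eval_mode_deterministic(self, rng):
        params = tiny_params(4)
        x = rng.standard_normal(256)
        np.testing.assert_array_equal(classify(x, params), classify(x, params))

    def test_training_dropout_reproducible_from_seed(self, rng):
        params = tiny_params(4)
        x = rng.standard_normal((3, 256))
        a = classify(x, params, training=True, rng=np.random.default_rng(9))
        b = classify(x, params, training=True, rng=np.random.default_rng(9))
        c = classify(x, params, training=True, rng=np.random.default_rng(10))
        np.testing.assert_array_equal(a, b)
        assert not np.allclose(a, c)


class TestBagForward:
    def test_permutation_invariance(self, rng):
        params = tiny_params(6)
        X = rng.standard_normal((7, 6))
        perm = rng.permutation(7)
        p1 = forward(X, params)
        p2 = forward(X[perm], params)
        np.testing.assert_allclose(p1.probs, p2.probs, atol=1e-6)
        np.testing.assert_allclose(p1.attention[perm], p2.attention, atol=1e-6)

    def test_identical_tiles_match_singleton_score(self, rng):
        params = tiny_params(5)
        x = rng.standard_normal(5)
        bag = np.tile(x, (6, 1))
        p_bag = forward(bag, params)
        p_one = forward(x[None, :], params)
        np.testing.assert_allclose(p_bag.attention, np.full(6, 1 / 6), atol=1e-9)
        np.testing.assert_allclose(p_bag.probs, p_one.probs, atol=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_attention_always_normalised(self, seed):
        rng = np.random.default_rng(seed)
        params = tiny_params(4, seed % 17)
        X = rng.standard_normal((int(rng.integers(1, 12)), 4)) * rng.uniform(0.1, 10)
        pred = forward(X, params)
        assert abs(pred.attention.sum() - 1.0) < 1e-6
        assert np.all(pred.attention > 0)
        assert abs(pred.probs.sum() - 1.0) < 1e-6


class TestGradients:
    def test_finite_difference_attention_params(self):
        rng = np.random.default_rng(3)
        d = 5
        params = tiny_params(d, 1)
        bags = [rng.standard_normal((4, d)), rng.standard_normal((2, d))]
        labels = np.array([1, 0])

        def loss_fn():
            return loss_and_grads(bags, labels, params, np.random.default_rng(99))[0]

        _, grads, _ = loss_and_grads(bags, labels, params, np.random.default_rng(99))
        eps = 1e-6
        for name in ("V", "w"):
            arr = getattr(params, name)
            flat_idx = rng.choice(arr.size, size=8, replace=False)
            for fi in flat_idx:
                idx = np.unravel_index(fi, arr.shape)
                orig = arr[idx]
                arr[idx] = orig + eps
                lp = loss_fn()
                arr[idx] = orig - eps
                lm = loss_fn()
                arr[idx] = orig
                fd = (lp - lm) / (2 * eps)
                g = grads[name][idx]
                assert abs(fd - g) / max(abs(fd), abs(g), 1e-8) < 1e-4


class TestCheckpoint:
    def test_roundtrip_preserves_everything(self, tmp_path, rng):
        params = tiny_params(6, 2)
        params.extractor_name = "builtin-rp6"
        path = save_checkpoint(params, tmp_path / "m.ckpt.npz", train_config={"K": 64})
        loaded = load_checkpoint(path)
        for k, v in params.weights().items():
            np.testing.assert_array_equal(v, getattr(loaded, k))
        np.testing.assert_array_equal(params.bn_mean, loaded.bn_mean)
        assert loaded.extractor_name == "builtin-rp6"
        X = rng.standard_normal((3, 6))
        np.testing.assert_array_equal(forward(X, params).probs, forward(X, loaded).probs)
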