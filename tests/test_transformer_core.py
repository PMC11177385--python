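"""Attention layer stages vs independently coded dense-algebra oracles."""

import numpy as np
import pytest

from neurostitch import (
    AttentionParams,
    FeedForwardParams,
    attention_mix,
    feed_forward,
    init_layer_params,
    qkv_project,
    residual_fuse,
)
from neurostitch.transformer_core import layer_backward, layer_forward


def softmax_oracle(row):
    """Plain exp/sum softmax of one score row."""
    e = [np.exp(v) for v in row]
    s = sum(e)
    return [v / s for v in e]


def attention_oracle(q, k, v):
    """Element-by-element softmax(QK^T)V, no vectorised shortcuts."""
    t, t2 = q.shape[0], k.shape[0]
    scores = [[sum(q[i, a] * k[j, a] for a in range(q.shape[1])) for j in range(t2)]
              for i in range(t)]
    weights = [softmax_oracle(r) for r in scores]
    out = np.zeros((t, v.shape[1]))
    for i in range(t):
        for c in range(v.shape[1]):
            out[i, c] = sum(weights[i][j] * v[j, c] for j in range(t2))
    return out


def rand_params(n, rng):
    p = init_layer_params(n, rng)
    for k in p:  # non-zero biases so the oracle also checks the bias path
        p[k] = p[k] + 0.1 * rng.standard_normal(p[k].shape)
    return p


def test_qkv_shapes_and_zero_params(rng):
    n = 6
    p = AttentionParams(
        Wq=np.zeros((n, 3)), bq=np.zeros(3),
        Wk=np.zeros((n, 3)), bk=np.zeros(3),
        Wv=np.zeros((n, n)), bv=np.zeros(n),
    )
    f = rng.standard_normal((4, n))
    q, k, v = qkv_project(f, p)
    assert q.shape == (4, 3) and k.shape == (4, 3) and v.shape == (4, n)
    assert not q.any() and not k.any() and not v.any()


def test_identity_value_projection(rng):
    n = 5
    p = AttentionParams(
        Wq=np.zeros((n, 2)), bq=np.zeros(2),
        Wk=np.zeros((n, 2)), bk=np.zeros(2),
        Wv=np.eye(n), bv=np.zeros(n),
    )
    f = rng.standard_normal((7, n))
    _, _, v = qkv_project(f, p)
    assert np.array_equal(v, f)


def test_qkv_matches_affine_oracle(rng):
    for _ in range(20):
        n = int(rng.integers(2, 9))
        t = int(rng.integers(1, 7))
        pdict = rand_params(n, rng)
        p = AttentionParams(pdict["Wq"], pdict["bq"], pdict["Wk"], pdict["bk"],
                            pdict["Wv"], pdict["bv"])
        f = rng.standard_normal((t, n))
        q, k, v = qkv_project(f, p)
        for out, w, b in ((q, p.Wq, p.bq), (k, p.Wk, p.bk), (v, p.Wv, p.bv)):
            expected = np.array(
                [[sum(f[i, a] * w[a, j] for a in range(n)) + b[j]
                  for j in range(w.shape[1])] for i in range(t)]
            )
            assert np.allclose(out, expected, atol=1e-6)


def test_attention_singleton_time_returns_value(rng):
    q = rng.standard_normal((1, 3))
    k = rng.standard_normal((1, 3))
    v = rng.standard_normal((1, 5))
    out = attention_mix(q, k, v)
    assert np.allclose(out, v)


def test_attention_zero_query_averages_values(rng):
    t = 6
    k = rng.standard_normal((t, 3))
    v = rng.standard_normal((t, 4))
    out = attention_mix(np.zeros((t, 3)), k, v)
    assert np.allclose(out, np.tile(v.mean(axis=0), (t, 1)))


def test_attention_matches_oracle_many_instances(rng):
    for _ in range(120):
        t = int(rng.integers(1, 7))
        h = int(rng.integers(1, 5))
        n = int(rng.integers(1, 6))
        q = rng.standard_normal((t, h))
        k = rng.standard_normal((t, h))
        v = rng.standard_normal((t, n))
        assert np.allclose(attention_mix(q, k, v), attention_oracle(q, k, v), atol=1e-6)


def test_attention_rows_of_scores_sum_to_one(rng):
    # verified through the mix: attending to all-ones values returns ones
    q = rng.standard_normal((8, 3)) * 5
    k = rng.standard_normal((8, 3)) * 5
    out = attention_mix(q, k, np.ones((8, 2)))
    assert np.allclose(out, 1.0, atol=1e-6)


def test_scaled_attention_flag_changes_mixing(rng):
    q = rng.standard_normal((5, 4)) * 3
    k = rng.standard_normal((5, 4)) * 3
    v = rng.standard_normal((5, 4))
    plain = attention_mix(q, k, v)
    scaled = attention_mix(q, k, v, scaled=True)
    assert not np.allclose(plain, scaled)
    assert np.allclose(scaled, attention_oracle(q / 4 ** 0.25, k / 4 ** 0.25, v), atol=1e-6)


def test_time_permutation_equivariance(rng):
    t = 7
    q = rng.standard_normal((t, 3))
    k = rng.standard_normal((t, 3))
    v = rng.standard_normal((t, 5))
    pi = rng.permutation(t)
    out = attention_mix(q, k, v)
    out_pi = attention_mix(q[pi], k[pi], v[pi])
    assert np.allclose(out_pi, out[pi], atol=1e-10)


def test_residual_fuse_definition(rng):
    f_hat = rng.standard_normal((4, 3))
    f = rng.standard_normal((4, 3))
    fused = residual_fuse(f_hat, f)
    assert np.allclose(fused - f, f_hat, rtol=0, atol=1e-14)
    assert np.array_equal(residual_fuse(np.zeros_like(f), f), f)
    assert np.array_equal(residual_fuse(f_hat, np.zeros_like(f_hat)), f_hat)
    with pytest.raises(ValueError):
        residual_fuse(f_hat, f[:2])


def test_feed_forward_identity_and_clamp(rng):
    n = 4
    p = FeedForwardParams(Wf=np.eye(n), bf=np.zeros(n))
    nonneg = np.abs(rng.standard_normal((3, n)))
    assert np.array_equal(feed_forward(nonneg, p), nonneg)
    p_neg = FeedForwardParams(Wf=np.eye(n), bf=np.full(n, -100.0))
    assert not feed_forward(nonneg, p_neg).any()


def test_feed_forward_matches_affine_clamp_oracle(rng):
    for _ in range(100):
        n = int(rng.integers(2, 7))
        t = int(rng.integers(1, 6))
        w = rng.standard_normal((n, n))
        b = rng.standard_normal(n)
        f = rng.standard_normal((t, n))
        got = feed_forward(f, FeedForwardParams(Wf=w, bf=b))
        expected = np.array(
            [[max(0.0, sum(f[i, a] * w[a, j] for a in range(n)) + b[j])
              for j in range(n)] for i in range(t)]
        )
        assert np.allclose(got, expected, atol=1e-6)
        assert got.min() >= 0.0


def test_layer_preserves_shape_and_matches_stagewise_composition(rng):
    n, t = 6, 5
    p = rand_params(n, rng)
    f = rng.standard_normal((t, n))
    out, _ = layer_forward(f, p)
    assert out.shape == (t, n)
    q, k, v = f @ p["Wq"] + p["bq"], f @ p["Wk"] + p["bk"], f @ p["Wv"] + p["bv"]
    staged = feed_forward(
        residual_fuse(attention_mix(q, k, v), f),
        FeedForwardParams(p["Wf"], p["bf"]),
    )
    assert np.allclose(out, staged, atol=1e-12)


def test_layer_backward_matches_finite_differences(rng):
    n, t = 4, 3
    p = rand_params(n, rng)
    f = rng.standard_normal((t, n))
    w_out = rng.standard_normal((t, n))  # random linear functional as the loss

    def loss(f_in):
        out, _ = layer_forward(f_in, p)
        return float((out * w_out).sum())

    out, cache = layer_forward(f, p)
    dinp, grads = layer_backward(w_out, cache, p)
    eps = 1e-6
    for i in range(t):
        for j in range(n):
            fp = f.copy(); fp[i, j] += eps
            fm = f.copy(); fm[i, j] -= eps
            fd = (loss(fp) - loss(fm)) / (2 * eps)
            assert dinp[i, j] == pytest.approx(fd, rel=1e-4, abs=1e-7)
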