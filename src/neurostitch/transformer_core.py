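"""One layer of a per-task transformer column.

Each layer maps a T x N feature matrix to a T x N feature matrix through
four stages:

1. Q/K/V projections: row-wise affine maps of the input features. Q and K
   project the region axis N -> floor(N/2) (halving the inner-product
   dimension to cut compute), V keeps the full width N so the residual sum
   is well-typed.
2. Softmax attention: scores = softmax(Q K^T) row-normalised over the T x T
   time-node correlation matrix; the attended features are scores @ V.
   There is no 1/sqrt(d) temperature by default; ``scaled=True`` enables it.
3. Residual fusion: attended features + layer input, compensating for
   information lost by the attention mixing.
4. Position-wise feed-forward: ReLU(affine) applied to each time-node row,
   preserving the T x N shape.

All functions accept a single matrix (T, N) or a batch (B, T, N).
Handwritten reverse-mode gradients live in :func:`layer_backward`; they are
validated against finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class AttentionParams:
    """Q/K/V projection weights: Wq, Wk are N x floor(N/2); Wv is N x N."""

    Wq: np.ndarray
    bq: np.ndarray
    Wk: np.ndarray
    bk: np.ndarray
    Wv: np.ndarray
    bv: np.ndarray

    def __post_init__(self) -> None:
        n = self.Wv.shape[0]
        if self.Wv.shape != (n, n):
            raise ValueError(f"Wv must be square N x N, got {self.Wv.shape}")
        if self.Wq.shape[0] != n or self.Wk.shape[0] != n:
            raise ValueError("Wq/Wk input dim must match Wv's N")
        if self.Wq.shape[1] != self.Wk.shape[1]:
            raise ValueError("Wq and Wk must share their output dim")


@dataclass
class FeedForwardParams:
    """Position-wise feed-forward weights: Wf is N x N, bf length N."""

    Wf: np.ndarray
    bf: np.ndarray

    def __post_init__(self) -> None:
        n = self.Wf.shape[0]
        if self.Wf.shape != (n, n) or self.bf.shape != (n,):
            raise ValueError(
                f"feed-forward must preserve width: Wf {self.Wf.shape}, bf {self.bf.shape}"
            )


def _fan_in_uniform(rng: np.random.Generator, fan_in: int, shape: tuple) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


def init_layer_params(N: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Fan-in uniform weights, zero biases, for one attention + FF layer."""
    if N < 2:
        raise ValueError(f"need at least 2 brain regions, got N={N}")
    h = N // 2
    return {
        "Wq": _fan_in_uniform(rng, N, (N, h)),
        "bq": np.zeros(h),
        "Wk": _fan_in_uniform(rng, N, (N, h)),
        "bk": np.zeros(h),
        "Wv": _fan_in_uniform(rng, N, (N, N)),
        "bv": np.zeros(N),
        "Wf": _fan_in_uniform(rng, N, (N, N)),
        "bf": np.zeros(N),
    }


def qkv_project(
    f: np.ndarray, p: AttentionParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project features into query, key and value spaces (row-wise affine).

    Returns (Q, K, V) with Q, K of trailing shape (T, floor(N/2)) and V of
    trailing shape (T, N).
    """
    f = np.asarray(f, dtype=float)
    if f.shape[-1] != p.Wv.shape[0]:
        raise ValueError(
            f"feature width {f.shape[-1]} does not match params N={p.Wv.shape[0]}"
        )
    q = f @ p.Wq + p.bq
    k = f @ p.Wk + p.bk
    v = f @ p.Wv + p.bv
    return q, k, v


def _softmax_rows(s: np.ndarray) -> np.ndarray:
    shifted = s - s.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def attention_mix(
    wq: np.ndarray, wk: np.ndarray, wv: np.ndarray, scaled: bool = False
) -> np.ndarray:
    """Softmax attention over time nodes: softmax(Q K^T) V.

    Each row of the T x T score matrix is softmax-normalised (sums to 1);
    no temperature unless ``scaled`` (then 1/sqrt(key dim)).
    """
    wq = np.asarray(wq, dtype=float)
    wk = np.asarray(wk, dtype=float)
    wv = np.asarray(wv, dtype=float)
    if wq.shape[-1] != wk.shape[-1]:
        raise ValueError(f"Q/K inner dims differ: {wq.shape[-1]} vs {wk.shape[-1]}")
    if wq.shape[-2] != wk.shape[-2] or wq.shape[-2] != wv.shape[-2]:
        raise ValueError("Q, K, V must share the time-node row count T")
    s = wq @ np.swapaxes(wk, -1, -2)
    if scaled:
        s = s / np.sqrt(wq.shape[-1])
    if not np.all(np.isfinite(s)):
        raise FloatingPointError("non-finite attention scores")
    return _softmax_rows(s) @ wv


def residual_fuse(f_hat: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Add the layer input back onto the attended features."""
    f_hat = np.asarray(f_hat, dtype=float)
    f = np.asarray(f, dtype=float)
    if f_hat.shape != f.shape:
        raise ValueError(f"shape mismatch: {f_hat.shape} vs {f.shape}")
    return f_hat + f


def feed_forward(f_bar: np.ndarray, p: FeedForwardParams) -> np.ndarray:
    """Row-wise ReLU(f_bar Wf + bf); preserves the T x N shape."""
    f_bar = np.asarray(f_bar, dtype=float)
    if f_bar.shape[-1] != p.Wf.shape[0]:
        raise ValueError(
            f"feature width {f_bar.shape[-1]} does not match Wf N={p.Wf.shape[0]}"
        )
    return np.maximum(f_bar @ p.Wf + p.bf, 0.0)


# --- fused layer forward/backward used by the multi-task model ---


def layer_forward(
    f: np.ndarray, p: dict[str, np.ndarray], scaled: bool = False
) -> tuple[np.ndarray, dict]:
    """Full layer pass on (..., T, N) features; returns (output, cache)."""
    q = f @ p["Wq"] + p["bq"]
    k = f @ p["Wk"] + p["bk"]
    v = f @ p["Wv"] + p["bv"]
    s = q @ np.swapaxes(k, -1, -2)
    if scaled:
        s = s / np.sqrt(q.shape[-1])
    a = _softmax_rows(s)
    f_hat = a @ v
    f_bar = f_hat + f
    z = f_bar @ p["Wf"] + p["bf"]
    out = np.maximum(z, 0.0)
    cache = {"f": f, "q": q, "k": k, "v": v, "a": a, "f_bar": f_bar, "z": z}
    return out, cache


def layer_backward(
    dout: np.ndarray, cache: dict, p: dict[str, np.ndarray], scaled: bool = False
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Gradients of a scalar loss through one layer.

    Given d(loss)/d(output), returns (d(loss)/d(input), grads-by-name).
    Bias gradients sum over all leading/time axes; weight gradients sum over
    any batch axes.
    """
    f, q, k, v, a, f_bar, z = (
        cache["f"], cache["q"], cache["k"], cache["v"],
        cache["a"], cache["f_bar"], cache["z"],
    )
    fT = np.swapaxes(f, -1, -2)

    dz = dout * (z > 0)
    g_Wf = _collapse(np.swapaxes(f_bar, -1, -2) @ dz)
    g_bf = dz.reshape(-1, dz.shape[-1]).sum(axis=0)
    df_bar = dz @ p["Wf"].T

    df_hat = df_bar
    df = df_bar.copy()  # residual branch

    da = df_hat @ np.swapaxes(v, -1, -2)
    dv = np.swapaxes(a, -1, -2) @ df_hat
    # softmax rows: ds = a * (da - sum(da * a))
    ds = a * (da - (da * a).sum(axis=-1, keepdims=True))
    if scaled:
        ds = ds / np.sqrt(q.shape[-1])
    dq = ds @ k
    dk = np.swapaxes(ds, -1, -2) @ q

    g_Wq = _collapse(fT @ dq)
    g_bq = dq.reshape(-1, dq.shape[-1]).sum(axis=0)
    g_Wk = _collapse(fT @ dk)
    g_bk = dk.reshape(-1, dk.shape[-1]).sum(axis=0)
    g_Wv = _collapse(fT @ dv)
    g_bv = dv.reshape(-1, dv.shape[-1]).sum(axis=0)

    df += dq @ p["Wq"].T + dk @ p["Wk"].T + dv @ p["Wv"].T
    grads = {
        "Wq": g_Wq, "bq": g_bq, "Wk": g_Wk, "bk": g_bk,
        "Wv": g_Wv, "bv": g_bv, "Wf": g_Wf, "bf": g_bf,
    }
    return df, grads


def _collapse(g: np.ndarray) -> np.ndarray:
    """Sum any leading batch axes of a per-sample weight gradient."""
    if g.ndim == 2:
        return g
    return g.reshape(-1, g.shape[-2], g.shape[-1]).sum(axis=0)
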