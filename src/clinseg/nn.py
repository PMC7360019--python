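"""Compact numpy neural-network kit: the primitives behind the tagger.

Implements exactly the pieces the architecture needs — embedding lookup,
1-D convolution with global max pooling, batch normalization, an LSTM with
input and recurrent dropout, a dense sigmoid layer, weighted binary
cross-entropy and the Adam optimizer — as forward/backward function pairs
over plain ndarrays.  Gradients are hand-derived and verified against
finite differences in the test suite.  Everything is deterministic given a
``numpy.random.Generator``.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np

Array = np.ndarray

# ---------------------------------------------------------------------------
# Initializers


def glorot_uniform(rng: np.random.Generator, shape: Tuple[int, ...]) -> Array:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def orthogonal(rng: np.random.Generator, shape: Tuple[int, int]) -> Array:
    a = rng.standard_normal(shape)
    q, r = np.linalg.qr(a if shape[0] >= shape[1] else a.T)
    q = q * np.sign(np.diag(r))
    return q if shape[0] >= shape[1] else q.T


# ---------------------------------------------------------------------------
# Elementwise


def sigmoid(x: Array) -> Array:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# Embedding


def embedding_forward(table: Array, ids: Array) -> Array:
    return table[ids]


def embedding_backward(d_out: Array, ids: Array, vocab_size: int) -> Array:
    grad = np.zeros((vocab_size, d_out.shape[-1]), dtype=np.float64)
    np.add.at(grad, ids.reshape(-1), d_out.reshape(-1, d_out.shape[-1]))
    grad[0] = 0.0  # PAD embedding is pinned at zero
    return grad


# ---------------------------------------------------------------------------
# 1-D convolution over character embeddings + global max pooling


def conv1d_maxpool_forward(
    x: Array, kernel: Array, bias: Array
) -> Tuple[Array, dict]:
    """``x``: (N, L, d) char embeddings; ``kernel``: (width*d, F).

    Valid convolution over the length axis followed by a max over
    positions.  Requires L >= width (pad the id sequence with PAD first).
    """
    n, length, d = x.shape
    width = kernel.shape[0] // d
    p = length - width + 1
    if p < 1:
        raise ValueError(f"char sequence of length {length} shorter than kernel width {width}")
    windows = np.stack([x[:, k : p + k, :] for k in range(width)], axis=2)
    windows = windows.reshape(n, p, width * d)
    z = windows @ kernel + bias  # (N, P, F)
    argmax = z.argmax(axis=1)  # (N, F)
    pooled = np.take_along_axis(z, argmax[:, None, :], axis=1)[:, 0, :]
    cache = {"windows": windows, "argmax": argmax, "shape": (n, length, d, width, p)}
    return pooled, cache


def conv1d_maxpool_backward(
    d_pooled: Array, kernel: Array, cache: dict
) -> Tuple[Array, Array, Array]:
    windows, argmax = cache["windows"], cache["argmax"]
    n, length, d, width, p = cache["shape"]
    f = kernel.shape[1]
    dz = np.zeros((n, p, f), dtype=np.float64)
    np.put_along_axis(dz, argmax[:, None, :], d_pooled[:, None, :], axis=1)
    d_bias = dz.sum(axis=(0, 1))
    d_kernel = windows.reshape(n * p, -1).T @ dz.reshape(n * p, f)
    d_windows = (dz @ kernel.T).reshape(n, p, width, d)
    dx = np.zeros((n, length, d), dtype=np.float64)
    for k in range(width):
        dx[:, k : p + k, :] += d_windows[:, :, k, :]
    return dx, d_kernel, d_bias


# ---------------------------------------------------------------------------
# Batch normalization (over the row axis of a 2-D matrix)


def batchnorm_forward(
    x: Array,
    gamma: Array,
    beta: Array,
    running: Dict[str, Array],
    training: bool,
    momentum: float = 0.9,
    eps: float = 1e-5,
) -> Tuple[Array, Optional[dict]]:
    if training:
        mu = x.mean(axis=0)
        var = x.var(axis=0)
        running["mean"] = momentum * running["mean"] + (1 - momentum) * mu
        running["var"] = momentum * running["var"] + (1 - momentum) * var
    else:
        mu, var = running["mean"], running["var"]
    ivar = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * ivar
    out = gamma * xhat + beta
    cache = {"xhat": xhat, "ivar": ivar, "gamma": gamma, "m": x.shape[0]} if training else None
    return out, cache


def batchnorm_backward(d_out: Array, cache: dict) -> Tuple[Array, Array, Array]:
    xhat, ivar, gamma, m = cache["xhat"], cache["ivar"], cache["gamma"], cache["m"]
    d_gamma = (d_out * xhat).sum(axis=0)
    d_beta = d_out.sum(axis=0)
    dxhat = d_out * gamma
    dx = (ivar / m) * (m * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))
    return dx, d_gamma, d_beta


def batchnorm_inference(x: Array, gamma: Array, beta: Array, running, eps: float = 1e-5) -> Array:
    return gamma * (x - running["mean"]) / np.sqrt(running["var"] + eps) + beta


# ---------------------------------------------------------------------------
# LSTM (single direction) with variational input/recurrent dropout masks
#
# Gate order in the fused weight matrices: input, forget, cell, output.


def lstm_forward(
    x: Array,
    w_x: Array,
    w_h: Array,
    bias: Array,
    recurrent_mask: Optional[Array] = None,
) -> Tuple[Array, list]:
    """``x``: (B, T, D) inputs (input dropout already applied).

    ``recurrent_mask``: optional (B, H) inverted-dropout mask applied to
    the previous hidden state inside each gate computation, fixed across
    time (variational recurrent dropout).
    """
    b, t, _ = x.shape
    h_units = w_h.shape[0]
    h_out = np.zeros((b, t, h_units), dtype=np.float64)
    h_prev = np.zeros((b, h_units), dtype=np.float64)
    c_prev = np.zeros((b, h_units), dtype=np.float64)
    caches = []
    for step in range(t):
        xt = x[:, step, :]
        hd = h_prev if recurrent_mask is None else h_prev * recurrent_mask
        a = xt @ w_x + hd @ w_h + bias
        i = sigmoid(a[:, :h_units])
        f = sigmoid(a[:, h_units : 2 * h_units])
        g = np.tanh(a[:, 2 * h_units : 3 * h_units])
        o = sigmoid(a[:, 3 * h_units :])
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h = o * tc
        caches.append((xt, hd, i, f, g, o, c_prev, tc))
        h_out[:, step, :] = h
        h_prev, c_prev = h, c
    return h_out, caches


def lstm_backward(
    d_h_out: Array,
    caches: list,
    w_x: Array,
    w_h: Array,
    recurrent_mask: Optional[Array] = None,
) -> Tuple[Array, Array, Array, Array]:
    b, h_units = caches[0][2].shape
    t = len(caches)
    d_in = w_x.shape[0]
    dx = np.zeros((b, t, d_in), dtype=np.float64)
    d_wx = np.zeros_like(w_x)
    d_wh = np.zeros_like(w_h)
    d_b = np.zeros(4 * h_units, dtype=np.float64)
    dh_next = np.zeros((b, h_units), dtype=np.float64)
    dc_next = np.zeros((b, h_units), dtype=np.float64)
    for step in reversed(range(t)):
        xt, hd, i, f, g, o, c_prev, tc = caches[step]
        dh = d_h_out[:, step, :] + dh_next
        do = dh * tc
        dc = dh * o * (1.0 - tc * tc) + dc_next
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dc_next = dc * f
        da = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        d_wx += xt.T @ da
        d_wh += hd.T @ da
        d_b += da.sum(axis=0)
        dx[:, step, :] = da @ w_x.T
        dh_prev = da @ w_h.T
        if recurrent_mask is not None:
            dh_prev = dh_prev * recurrent_mask
        dh_next = dh_prev
    return dx, d_wx, d_wh, d_b


# ---------------------------------------------------------------------------
# Loss


def weighted_bce(
    prob: Array, target: Array, weights: Array, mask: Array
) -> Tuple[float, Array]:
    """Class-weighted binary cross-entropy over unmasked positions.

    Returns (loss, d_logit): the gradient is with respect to the
    pre-sigmoid logit, already divided by the unmasked count.
    """
    count = mask.sum()
    if count == 0:
        return 0.0, np.zeros_like(prob)
    p = np.clip(prob, 1e-9, 1.0 - 1e-9)
    per = -(target * np.log(p) + (1.0 - target) * np.log(1.0 - p))
    loss = float((weights * mask * per).sum() / count)
    d_logit = weights * mask * (p - target) / count
    return loss, d_logit


# ---------------------------------------------------------------------------
# Optimizer


class Adam:
    """Adam over a dict of named parameter arrays (updated in place)."""

    def __init__(
        self,
        params: Dict[str, Array],
        learning_rate: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
    ):
        self.params = params
        self.lr = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: Dict[str, Array]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1.0 - self.beta2**self.t) / (1.0 - self.beta1**self.t)
        for name, g in grads.items():
            p = self.params[name]
            m = self.m[name]
            v = self.v[name]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * np.square(g)
            p -= lr_t * m / (np.sqrt(v) + self.eps)


def dropout_mask(
    rng: np.random.Generator, shape: Tuple[int, ...], rate: float
) -> Optional[Array]:
    """Inverted-dropout mask, or None when the rate is 0."""
    if rate <= 0.0:
        return None
    keep = 1.0 - rate
    return (rng.random(shape) < keep).astype(np.float64) / keep
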