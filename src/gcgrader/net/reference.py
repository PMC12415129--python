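"""Hand-written forward pass of the hybrid classifier, one equation at a time.

This module re-implements inference with explicit Python loops following the
layer equations directly:

* convolution:      y_t = sum_i w_i * x_{t+i-1} + b
* batch norm:       y = gamma * (z - mu) / sqrt(sigma^2 + eps) + beta
* max pooling:      a_p = max(a_t, a_{t+1}, ..., a_{t+p-1})
* dropout:          a' = a . m   (inference: m = 1 everywhere)
* GRU gates:        z_t = sigma(W_z h_{t-1} + U_z x_t + b_z)
                    r_t = sigma(W_r h_{t-1} + U_r x_t + b_r)
                    h~_t = tanh(W_h (r_t . h_{t-1}) + U_h x_t + b_h)
                    h_t = (1 - z_t) . h_{t-1} + z_t . h~_t
* layer norm:       y = gamma * (a - mu) / sqrt(sigma^2 + eps) + beta
* dense:            y = W a + b   (ReLU / sigmoid as configured)

It shares nothing with the vectorized engine except the exported weights,
and exists as an independent check that the engine computes exactly these
equations (agreement to well below 1e-4 on the same weights and input).
"""

from __future__ import annotations

import math

import numpy as np

from ..errors import SchemaError
from .config import ModelConfig

_BN_EPS = 1e-3
_LN_EPS = 1e-3


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def reference_forward(
    weights: dict[str, np.ndarray], config: ModelConfig, profile
) -> np.ndarray:
    """Class scores for a single scaled expression profile (length L).

    ``weights`` is a :meth:`HybridNet.state_dict` export; dropout is
    disabled and batch normalization uses the exported moving statistics.
    """
    x = [float(v) for v in np.asarray(profile).ravel()]
    L = len(x)
    k, F = config.kernel_size, config.conv_filters
    W_conv, b_conv = weights["conv_W"], weights["conv_b"]
    if W_conv.shape != (F, k):
        raise SchemaError(f"conv weights {W_conv.shape} do not match config ({F}, {k})")
    if L < k:
        raise SchemaError(f"profile of length {L} shorter than kernel {k}")

    # --- convolution + ReLU:  y[t][f] = sum_i w[f][i] x[t+i-1] + b[f]
    T1 = L - k + 1
    conv = [[0.0] * F for _ in range(T1)]
    for t in range(T1):
        for f in range(F):
            s = b_conv[f]
            for i in range(k):
                s += W_conv[f, i] * x[t + i]
            conv[t][f] = max(s, 0.0)

    # --- batch normalization (inference: moving mean/variance)
    gamma, beta = weights["bn_gamma"], weights["bn_beta"]
    mu, var = weights["bn_moving_mean"], weights["bn_moving_var"]
    for t in range(T1):
        for f in range(F):
            conv[t][f] = gamma[f] * (conv[t][f] - mu[f]) / math.sqrt(var[f] + _BN_EPS) + beta[f]

    # --- max pooling, window p, stride p (window clamped to the sequence)
    p = min(config.pool_size, T1)
    T2 = T1 // p
    pooled = [[0.0] * F for _ in range(T2)]
    for t in range(T2):
        for f in range(F):
            pooled[t][f] = max(conv[t * p + j][f] for j in range(p))

    # --- dropout: identity at inference (mask of ones)

    # --- GRU recursion over the pooled sequence
    H = config.gru_units
    Uz, Ur, Uh = weights["gru_Uz"], weights["gru_Ur"], weights["gru_Uh"]
    Wz, Wr, Wh = weights["gru_Wz"], weights["gru_Wr"], weights["gru_Wh"]
    bz, br, bh = weights["gru_bz"], weights["gru_br"], weights["gru_bh"]
    if Uz.shape != (F, H):
        raise SchemaError(f"GRU input weights {Uz.shape} do not match ({F}, {H})")
    h = [0.0] * H
    for t in range(T2):
        xt = pooled[t]
        z = [0.0] * H
        r = [0.0] * H
        hc = [0.0] * H
        for u in range(H):
            az = bz[u]
            ar = br[u]
            for c in range(F):
                az += Uz[c, u] * xt[c]
                ar += Ur[c, u] * xt[c]
            for v in range(H):
                az += Wz[v, u] * h[v]
                ar += Wr[v, u] * h[v]
            z[u] = _sigmoid(az)
            r[u] = _sigmoid(ar)
        for u in range(H):
            ah = bh[u]
            for c in range(F):
                ah += Uh[c, u] * xt[c]
            for v in range(H):
                ah += Wh[v, u] * (r[v] * h[v])
            hc[u] = math.tanh(ah)
        h = [(1.0 - z[u]) * h[u] + z[u] * hc[u] for u in range(H)]

    # --- layer normalization over the H features of the final state
    lg, lb = weights["ln_gamma"], weights["ln_beta"]
    mean_h = sum(h) / H
    var_h = sum((v - mean_h) ** 2 for v in h) / H
    h = [
        lg[u] * (h[u] - mean_h) / math.sqrt(var_h + _LN_EPS) + lb[u]
        for u in range(H)
    ]

    # --- flatten (already a vector) -> dense ReLU -> dense head
    D = config.dense_units
    W1, b1 = weights["d1_W"], weights["d1_b"]
    a1 = [0.0] * D
    for d in range(D):
        s = b1[d]
        for u in range(H):
            s += W1[u, d] * h[u]
        a1[d] = max(s, 0.0)

    C = config.n_classes
    W2, b2 = weights["d2_W"], weights["d2_b"]
    out = [0.0] * C
    for c in range(C):
        s = b2[c]
        for d in range(D):
            s += W2[d, c] * a1[d]
        out[c] = s
    if config.output_activation == "sigmoid":
        out = [_sigmoid(v) for v in out]
    else:
        mx = max(out)
        exps = [math.exp(v - mx) for v in out]
        tot = sum(exps)
        out = [e / tot for e in exps]
    return np.asarray(out)
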