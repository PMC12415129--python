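"""Vectorized numpy training engine for the hybrid 1D-CNN/GRU classifier.

The layer stack (fixed, matching the published architecture)::

    input (N, L, 1 channel)
    -> Conv1D(filters F, kernel k, ReLU)      (N, L-k+1, F)
    -> BatchNormalization (per channel)
    -> MaxPooling1D(pool p, stride p)         (N, (L-k+1)//p, F)
    -> Dropout(conv_dropout)
    -> GRU(H units, input dropout)            (N, H)   last state only
    -> LayerNormalization (per feature row)
    -> Flatten
    -> Dense(D, ReLU) -> Dropout
    -> Dense(n_classes, sigmoid)              (N, 2)

Loss is categorical cross-entropy on one-hot targets; optimization is Adam.
All forward/backward passes are float64 and fully deterministic given the
seeded generators passed in (numpy only, no threading-dependent ops).

GRU conventions: standard gate equations

    z_t = sigmoid(x_t U_z + h_{t-1} W_z + b_z)
    r_t = sigmoid(x_t U_r + h_{t-1} W_r + b_r)
    h~_t = tanh((r_t . h_{t-1}) W_h + x_t U_h + b_h)
    h_t = (1 - z_t) . h_{t-1} + z_t . h~_t

so a saturated update gate (z_t -> 1) hands the state entirely to the
candidate.  The GRU dropout acts on the input transformation only (one mask
per sample, shared across time steps); there is no recurrent dropout.
"""

from __future__ import annotations

import numpy as np

from ..errors import ParameterError
from .config import ModelConfig

_BN_EPS = 1e-3
_LN_EPS = 1e-3
_P_CLIP = 1e-12


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.normal(size=(n, n))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


class HybridNet:
    """The trainable network: parameters, forward, backward, Adam step."""

    def __init__(
        self,
        config: ModelConfig,
        input_length: int,
        rng: np.random.Generator | None = None,
    ):
        config.validate(input_length)
        self.config = config
        self.input_length = int(input_length)
        k, F = config.kernel_size, config.conv_filters
        p, H, D = config.pool_size, config.gru_units, config.dense_units
        C = config.n_classes
        self.t1 = input_length - k + 1
        # short signatures: clamp the pool window to the conv output length
        self.pool = min(p, self.t1)
        self.t2 = self.t1 // self.pool
        rng = rng or np.random.default_rng(config.seed)

        P: dict[str, np.ndarray] = {}
        P["conv_W"] = _glorot(rng, (F, k), k, F)
        P["conv_b"] = np.zeros(F)
        P["bn_gamma"] = np.ones(F)
        P["bn_beta"] = np.zeros(F)
        for gate in ("z", "r", "h"):
            P[f"gru_U{gate}"] = _glorot(rng, (F, H), F, H)
            P[f"gru_W{gate}"] = _orthogonal(rng, H)
            P[f"gru_b{gate}"] = np.zeros(H)
        P["ln_gamma"] = np.ones(H)
        P["ln_beta"] = np.zeros(H)
        P["d1_W"] = _glorot(rng, (H, D), H, D)
        P["d1_b"] = np.zeros(D)
        P["d2_W"] = _glorot(rng, (D, C), D, C)
        P["d2_b"] = np.zeros(C)
        self.params = P
        self.bn_moving_mean = np.zeros(F)
        self.bn_moving_var = np.ones(F)
        self._cache: dict | None = None

    # ------------------------------------------------------------------ #
    @property
    def shapes(self) -> dict[str, tuple]:
        cfg = self.config
        return {
            "input": (self.input_length, 1),
            "conv": (self.t1, cfg.conv_filters),
            "pool": (self.t2, cfg.conv_filters),
            "gru": (cfg.gru_units,),
            "dense": (cfg.dense_units,),
            "output": (cfg.n_classes,),
        }

    # ------------------------------------------------------------------ #
    def forward(
        self,
        X: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Class probability activations for rows of X (N, L).

        With the sigmoid head these are the raw per-unit sigmoids (each in
        [0, 1], not necessarily summing to 1); see :meth:`predict_proba`
        for the normalized probabilities used in thresholding.
        """
        cfg = self.config
        P = self.params
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.input_length:
            raise ParameterError(
                f"expected input (N, {self.input_length}), got {X.shape}"
            )
        if training and rng is None:
            rng = np.random.default_rng(cfg.seed)
        N = X.shape[0]
        cache: dict = {"training": training}

        # Conv1D + ReLU
        k = cfg.kernel_size
        Xw = np.lib.stride_tricks.sliding_window_view(X, k, axis=1)  # (N,T1,k)
        Z1 = Xw @ P["conv_W"].T + P["conv_b"]  # (N,T1,F)
        A1 = np.maximum(Z1, 0.0)
        cache.update(X=X, Xw=Xw, Z1=Z1)

        # BatchNorm per channel over (N, T1)
        if training:
            mu = A1.mean(axis=(0, 1))
            var = A1.var(axis=(0, 1))
            mom = cfg.bn_momentum
            self.bn_moving_mean = mom * self.bn_moving_mean + (1 - mom) * mu
            self.bn_moving_var = mom * self.bn_moving_var + (1 - mom) * var
        else:
            mu, var = self.bn_moving_mean, self.bn_moving_var
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (A1 - mu) * inv_std
        B = P["bn_gamma"] * xhat + P["bn_beta"]
        cache.update(A1=A1, bn_mu=mu, bn_var=var, bn_inv_std=inv_std, bn_xhat=xhat)

        # MaxPool (pool = stride)
        p = self.pool
        trimmed = B[:, : self.t2 * p, :].reshape(N, self.t2, p, -1)
        arg = trimmed.argmax(axis=2)
        M = np.take_along_axis(trimmed, arg[:, :, None, :], axis=2)[:, :, 0, :]
        cache.update(pool_in_shape=B.shape, pool_arg=arg, pool_p=p)

        # Dropout after pooling
        if training and cfg.conv_dropout > 0:
            mask1 = (rng.random(M.shape) >= cfg.conv_dropout) / (1 - cfg.conv_dropout)
            M = M * mask1
        else:
            mask1 = None
        cache["mask1"] = mask1

        # GRU over T2 steps, input dropout mask shared across time
        H = cfg.gru_units
        if training and cfg.gru_dropout > 0:
            gmask = (rng.random((N, M.shape[2])) >= cfg.gru_dropout) / (
                1 - cfg.gru_dropout
            )
        else:
            gmask = None
        h = np.zeros((N, H))
        steps = []
        for t in range(self.t2):
            x_t = M[:, t, :] if gmask is None else M[:, t, :] * gmask
            z = sigmoid(x_t @ P["gru_Uz"] + h @ P["gru_Wz"] + P["gru_bz"])
            r = sigmoid(x_t @ P["gru_Ur"] + h @ P["gru_Wr"] + P["gru_br"])
            hc = np.tanh((r * h) @ P["gru_Wh"] + x_t @ P["gru_Uh"] + P["gru_bh"])
            h_new = (1.0 - z) * h + z * hc
            steps.append((x_t, h, z, r, hc))
            h = h_new
        cache.update(gru_steps=steps, gmask=gmask, M_shape=M.shape)

        # LayerNorm over features
        lmu = h.mean(axis=1, keepdims=True)
        lvar = h.var(axis=1, keepdims=True)
        linv = 1.0 / np.sqrt(lvar + _LN_EPS)
        lhat = (h - lmu) * linv
        LN = P["ln_gamma"] * lhat + P["ln_beta"]
        cache.update(h_last=h, ln_inv=linv, ln_hat=lhat)

        # Dense(ReLU) -> Dropout -> Dense(head)
        Zd = LN @ P["d1_W"] + P["d1_b"]
        Ad = np.maximum(Zd, 0.0)
        if training and cfg.dense_dropout > 0:
            mask2 = (rng.random(Ad.shape) >= cfg.dense_dropout) / (
                1 - cfg.dense_dropout
            )
            Ad2 = Ad * mask2
        else:
            mask2, Ad2 = None, Ad
        logits = Ad2 @ P["d2_W"] + P["d2_b"]
        probs = sigmoid(logits) if cfg.output_activation == "sigmoid" else softmax(logits)
        cache.update(LN=LN, Zd=Zd, Ad=Ad, mask2=mask2, Ad2=Ad2, logits=logits, probs=probs)
        self._cache = cache
        return probs

    # ------------------------------------------------------------------ #
    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Normalized class probabilities (rows sum to 1)."""
        p = self.forward(X, training=False)
        if self.config.output_activation == "sigmoid":
            s = p.sum(axis=1, keepdims=True)
            p = np.where(s > 0, p / np.maximum(s, _P_CLIP), 1.0 / p.shape[1])
        return p

    # ------------------------------------------------------------------ #
    def loss(self, probs: np.ndarray, Y: np.ndarray) -> float:
        """Categorical cross-entropy on one-hot targets.

        With the sigmoid head the per-unit activations are first
        renormalized to sum to 1 across classes (the categorical loss is
        defined on a probability distribution), so the loss drives the
        *normalized* class probability toward 1 — the quantity the
        confidence threshold acts on.
        """
        if self.config.output_activation == "sigmoid":
            probs = probs / np.maximum(probs.sum(axis=1, keepdims=True), _P_CLIP)
        p = np.clip(probs, _P_CLIP, 1.0)
        return float(-(Y * np.log(p)).sum(axis=1).mean())

    def backward_from_targets(self, Y: np.ndarray) -> np.ndarray:
        """Gradient step entry: d(loss)/d(logits) for the cached forward."""
        cache = self._cache
        probs = cache["probs"]
        N = probs.shape[0]
        if self.config.output_activation == "sigmoid":
            # loss = -sum y log(p / s), s = sum p  =>  dL/dp = 1/s - y/p
            p = np.clip(probs, _P_CLIP, 1.0)
            s = np.maximum(p.sum(axis=1, keepdims=True), _P_CLIP)
            dlogits = (p / s - Y) * (1.0 - probs) / N
        else:
            dlogits = (probs - Y) / N
        return self.backward(dlogits)

    # ------------------------------------------------------------------ #
    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        """Backprop from d(objective)/d(logits); fills ``self.grads`` and
        returns the gradient with respect to the input (N, L)."""
        cfg = self.config
        P = self.params
        cache = self._cache
        if cache is None:
            raise ParameterError("backward called before forward")
        training = cache["training"]
        G = {k: np.zeros_like(v) for k, v in P.items()}

        # Dense head
        G["d2_W"] = cache["Ad2"].T @ dlogits
        G["d2_b"] = dlogits.sum(axis=0)
        dAd2 = dlogits @ P["d2_W"].T
        if cache["mask2"] is not None:
            dAd = dAd2 * cache["mask2"]
        else:
            dAd = dAd2
        dZd = dAd * (cache["Zd"] > 0)
        G["d1_W"] = cache["LN"].T @ dZd
        G["d1_b"] = dZd.sum(axis=0)
        dLN = dZd @ P["d1_W"].T

        # LayerNorm backward (per row, m = H features)
        lhat, linv = cache["ln_hat"], cache["ln_inv"]
        G["ln_gamma"] = (dLN * lhat).sum(axis=0)
        G["ln_beta"] = dLN.sum(axis=0)
        dlhat = dLN * P["ln_gamma"]
        m = lhat.shape[1]
        dh = linv * (
            dlhat
            - dlhat.mean(axis=1, keepdims=True)
            - lhat * (dlhat * lhat).mean(axis=1, keepdims=True)
        )

        # GRU BPTT
        N, T2, C = cache["M_shape"]
        gmask = cache["gmask"]
        dM = np.zeros((N, T2, C))
        for t in range(T2 - 1, -1, -1):
            x_t, h_prev, z, r, hc = cache["gru_steps"][t]
            dz = dh * (hc - h_prev)
            dhc = dh * z
            dh_prev = dh * (1.0 - z)

            dahc = dhc * (1.0 - hc**2)
            G["gru_Wh"] += (r * h_prev).T @ dahc
            G["gru_Uh"] += x_t.T @ dahc
            G["gru_bh"] += dahc.sum(axis=0)
            drh = dahc @ P["gru_Wh"].T
            dr = drh * h_prev
            dh_prev += drh * r

            daz = dz * z * (1.0 - z)
            dar = dr * r * (1.0 - r)
            G["gru_Wz"] += h_prev.T @ daz
            G["gru_Uz"] += x_t.T @ daz
            G["gru_bz"] += daz.sum(axis=0)
            G["gru_Wr"] += h_prev.T @ dar
            G["gru_Ur"] += x_t.T @ dar
            G["gru_br"] += dar.sum(axis=0)
            dh_prev += daz @ P["gru_Wz"].T + dar @ P["gru_Wr"].T

            dx = dahc @ P["gru_Uh"].T + daz @ P["gru_Uz"].T + dar @ P["gru_Ur"].T
            dM[:, t, :] = dx if gmask is None else dx * gmask
            dh = dh_prev

        # Dropout after pooling
        if cache["mask1"] is not None:
            dM = dM * cache["mask1"]

        # MaxPool backward (positions beyond t2*p were discarded -> zero grad)
        p = cache["pool_p"]
        dB = np.zeros(cache["pool_in_shape"])
        F = dB.shape[2]
        dtrim = np.zeros((N, self.t2, p, F))
        np.put_along_axis(dtrim, cache["pool_arg"][:, :, None, :], dM[:, :, None, :], axis=2)
        dB[:, : self.t2 * p, :] = dtrim.reshape(N, self.t2 * p, F)

        # BatchNorm backward
        xhat, inv_std = cache["bn_xhat"], cache["bn_inv_std"]
        G["bn_gamma"] = (dB * xhat).sum(axis=(0, 1))
        G["bn_beta"] = dB.sum(axis=(0, 1))
        dxhat = dB * P["bn_gamma"]
        if training:
            dA1 = inv_std * (
                dxhat
                - dxhat.mean(axis=(0, 1))
                - xhat * (dxhat * xhat).mean(axis=(0, 1))
            )
        else:
            dA1 = dxhat * inv_std

        # Conv backward
        dZ1 = dA1 * (cache["Z1"] > 0)
        G["conv_W"] = np.einsum("ntf,ntk->fk", dZ1, cache["Xw"])
        G["conv_b"] = dZ1.sum(axis=(0, 1))
        dX = np.zeros_like(cache["X"])
        W = P["conv_W"]
        for i in range(cfg.kernel_size):
            dX[:, i : i + self.t1] += dZ1 @ W[:, i]
        self.grads = G
        return dX

    # ------------------------------------------------------------------ #
    def input_gradient(self, X: np.ndarray, class_idx: np.ndarray) -> np.ndarray:
        """d(predicted-class probability)/d(input), dropout off."""
        probs = self.forward(X, training=False)
        N = probs.shape[0]
        d = np.zeros_like(probs)
        rows = np.arange(N)
        if self.config.output_activation == "sigmoid":
            pc = probs[rows, class_idx]
            d[rows, class_idx] = pc * (1.0 - pc)
        else:
            pc = probs[rows, class_idx]
            d = -probs * pc[:, None]
            d[rows, class_idx] += pc
        return self.backward(d)

    # ------------------------------------------------------------------ #
    def state_dict(self) -> dict[str, np.ndarray]:
        d = {k: v.copy() for k, v in self.params.items()}
        d["bn_moving_mean"] = self.bn_moving_mean.copy()
        d["bn_moving_var"] = self.bn_moving_var.copy()
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(d[k], dtype=np.float64).copy()
        self.bn_moving_mean = np.asarray(d["bn_moving_mean"], dtype=np.float64).copy()
        self.bn_moving_var = np.asarray(d["bn_moving_var"], dtype=np.float64).copy()


class Adam:
    """Adam optimizer (beta1 = 0.9, beta2 = 0.999, eps = 1e-7)."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
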