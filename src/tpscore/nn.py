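"""Minimal NumPy recurrent networks for binary sequence classification.

Implements the three classic recurrent cells (tanh RNN, GRU, LSTM) with a
sigmoid read-out on the final hidden state, exact backpropagation through
time, and an Adam optimizer. The networks here are deliberately small —
one recurrent layer over a 10-step binary sequence — so a hand-rolled
implementation is both fast (a handful of matrix products per step) and
fully deterministic given a seed, which matters because every downstream
pattern score is defined through the trained predictor.

Gate layouts follow the common convention:

* GRU: ``h_t = (1 - z_t) * n_t + z_t * h_{t-1}`` with update gate ``z``,
  reset gate ``r`` and candidate ``n = tanh(x W_xn + r * (h W_hn) + b_n)``.
* LSTM: input/forget/cell/output gates, forget bias initialized to +1.

Gradients are verified against central finite differences in the test
suite, which is the contract that keeps this module honest.
"""

from __future__ import annotations

import numpy as np

_N_GATES = {"rnn": 1, "gru": 3, "lstm": 4}


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class RecurrentNet:
    """Single-layer recurrent classifier p(y=1 | x_{1..T})."""

    def __init__(self, kind: str, n_features: int, hidden: int, seed: int = 0):
        if kind not in _N_GATES:
            raise ValueError(f"kind must be one of {sorted(_N_GATES)}, got {kind!r}")
        self.kind = kind
        self.n_features = n_features
        self.hidden = hidden
        k = _N_GATES[kind]
        rng = np.random.default_rng(seed)
        s = 1.0 / np.sqrt(hidden)
        self.params = {
            "Wx": rng.uniform(-s, s, (n_features, k * hidden)),
            "Wh": rng.uniform(-s, s, (hidden, k * hidden)),
            "b": np.zeros(k * hidden),
            "w_out": rng.uniform(-s, s, hidden),
            "b_out": np.zeros(1),
        }
        if kind == "lstm":  # forget-gate bias trick: start remembering
            self.params["b"][hidden : 2 * hidden] = 1.0

    # ------------------------------------------------------------ forward

    def _step(self, x, h, c):
        """One cell step; returns (h_new, c_new, cache)."""
        p = self.params
        H = self.hidden
        ax = x @ p["Wx"]
        hh = h @ p["Wh"]
        if self.kind == "rnn":
            h_new = np.tanh(ax + hh + p["b"])
            return h_new, None, (x, h, h_new)
        if self.kind == "gru":
            z = _sigmoid(ax[:, :H] + hh[:, :H] + p["b"][:H])
            r = _sigmoid(ax[:, H : 2 * H] + hh[:, H : 2 * H] + p["b"][H : 2 * H])
            hh_n = hh[:, 2 * H :]
            n = np.tanh(ax[:, 2 * H :] + r * hh_n + p["b"][2 * H :])
            h_new = (1.0 - z) * n + z * h
            return h_new, None, (x, h, z, r, n, hh_n)
        # lstm
        pre = ax + hh + p["b"]
        i = _sigmoid(pre[:, :H])
        f = _sigmoid(pre[:, H : 2 * H])
        g = np.tanh(pre[:, 2 * H : 3 * H])
        o = _sigmoid(pre[:, 3 * H :])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        return h_new, c_new, (x, h, c, i, f, g, o, tc)

    def forward(self, X: np.ndarray, return_cache: bool = False):
        """Probabilities for a (B, T, F) float batch."""
        B = X.shape[0]
        h = np.zeros((B, self.hidden))
        c = np.zeros((B, self.hidden)) if self.kind == "lstm" else None
        caches = []
        for t in range(X.shape[1]):
            h, c, cache = self._step(X[:, t, :], h, c)
            if return_cache:
                caches.append(cache)
        logits = h @ self.params["w_out"] + self.params["b_out"][0]
        probs = _sigmoid(logits)
        if return_cache:
            return probs, (h, caches)
        return probs

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forward(np.asarray(X, dtype=float))

    # ----------------------------------------------------------- backward

    def backward(self, probs, cache, y: np.ndarray):
        """Gradients of mean binary cross-entropy w.r.t. every parameter."""
        p = self.params
        H = self.hidden
        h_last, caches = cache
        B = y.shape[0]
        dlogit = (probs - y) / B  # d BCE / d logit
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        grads["w_out"] = h_last.T @ dlogit
        grads["b_out"][0] = dlogit.sum()
        dh = dlogit[:, None] * p["w_out"][None, :]
        dc = np.zeros((B, H)) if self.kind == "lstm" else None

        for t in range(len(caches) - 1, -1, -1):
            if self.kind == "rnn":
                x, h_prev, h_new = caches[t]
                da = dh * (1.0 - h_new**2)
                grads["Wx"] += x.T @ da
                grads["Wh"] += h_prev.T @ da
                grads["b"] += da.sum(axis=0)
                dh = da @ p["Wh"].T
            elif self.kind == "gru":
                x, h_prev, z, r, n, hh_n = caches[t]
                dz = dh * (h_prev - n)
                dn = dh * (1.0 - z)
                dh_prev = dh * z
                dnpre = dn * (1.0 - n**2)
                dr = dnpre * hh_n
                dhh_n = dnpre * r
                daz = dz * z * (1.0 - z)
                dar = dr * r * (1.0 - r)
                dax = np.concatenate([daz, dar, dnpre], axis=1)
                dhh = np.concatenate([daz, dar, dhh_n], axis=1)
                grads["Wx"] += x.T @ dax
                grads["Wh"] += h_prev.T @ dhh
                grads["b"] += dax.sum(axis=0)
                dh = dh_prev + dhh @ p["Wh"].T
            else:  # lstm
                x, h_prev, c_prev, i, f, g, o, tc = caches[t]
                do = dh * tc
                dc = dc + dh * o * (1.0 - tc**2)
                df = dc * c_prev
                di = dc * g
                dg = dc * i
                dc_prev = dc * f
                dpre = np.concatenate(
                    [
                        di * i * (1.0 - i),
                        df * f * (1.0 - f),
                        dg * (1.0 - g**2),
                        do * o * (1.0 - o),
                    ],
                    axis=1,
                )
                grads["Wx"] += x.T @ dpre
                grads["Wh"] += h_prev.T @ dpre
                grads["b"] += dpre.sum(axis=0)
                dh = dpre @ p["Wh"].T
                dc = dc_prev
        return grads

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        probs = self.forward(np.asarray(X, dtype=float))
        return float(bce(probs, y))

    def get_weights(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict) -> None:
        for k in self.params:
            self.params[k] = np.asarray(weights[k], dtype=float).reshape(self.params[k].shape)


def bce(probs: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    """Mean binary cross-entropy."""
    p = np.clip(probs, eps, 1.0 - eps)
    return float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).mean())


class Adam:
    """Adam optimizer over a parameter dict, with decoupled weight decay.

    Weight decay is applied to the weight matrices only (not biases), the
    AdamW convention. Decay keeps the network close to the smallest model
    consistent with the data, which matters downstream: counterfactual
    probes read the model off the data manifold, and an interpolating
    (overfitted) network shows spurious sensitivity there.
    """

    def __init__(
        self,
        params: dict,
        lr: float = 1e-3,
        beta1=0.9,
        beta2=0.999,
        eps=1e-8,
        weight_decay: float = 0.0,
    ):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)
            if self.weight_decay and k.startswith("W"):
                params[k] -= self.lr * self.weight_decay * params[k]
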