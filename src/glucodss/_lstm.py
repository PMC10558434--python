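"""Compact numpy LSTM regressor (single layer + linear read-out).

Forward pass, truncated-nothing BPTT and Adam updates are written directly
in numpy: the networks used here are small (a single layer of 64 units on
12-step windows of 3 channels), so explicit matrix code is fast enough and
keeps training bit-reproducible from a seed.  Gate layout follows the
classic formulation (input, forget, candidate, output) with forget-gate
bias initialized to 1.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


class LSTMRegressor:
    """Many-to-one LSTM: window (L, F) -> scalar (standardized glucose)."""

    def __init__(self, n_features: int, hidden: int, seed: int = 0):
        self.F = n_features
        self.H = hidden
        rng = np.random.default_rng(seed)
        H, F = hidden, n_features

        def glorot(fan_in, fan_out, shape):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=shape)

        self.params = {
            "Wx": glorot(F, 4 * H, (F, 4 * H)),
            "Wh": glorot(H, 4 * H, (H, 4 * H)),
            "b": np.zeros(4 * H),
            "wo": glorot(H, 1, (H,)),
            "bo": np.zeros(1),
        }
        self.params["b"][H:2 * H] = 1.0  # forget-gate bias
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- forward ----------------------------------------------------------

    def forward(self, X: np.ndarray, cache: bool = False):
        """X: (B, L, F) -> predictions (B,); optionally keep the BPTT cache."""
        B, L, F = X.shape
        H = self.H
        p = self.params
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        steps = []
        for t in range(L):
            x_t = X[:, t, :]
            z = x_t @ p["Wx"] + h @ p["Wh"] + p["b"]
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            if cache:
                steps.append((x_t, h, c, i, f, g, o, tc))
            h, c = h_new, c_new
        y = h @ p["wo"] + p["bo"][0]
        if cache:
            return y, (X.shape, steps, h)
        return y

    # -- backward ---------------------------------------------------------

    def backward(self, cache, dy: np.ndarray) -> dict:
        """Gradients of sum(dy * y) w.r.t. parameters."""
        (B, L, F), steps, h_last = cache
        H = self.H
        p = self.params
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        grads["wo"] = h_last.T @ dy
        grads["bo"] = np.array([dy.sum()])
        dh = dy[:, None] * p["wo"][None, :]
        dc = np.zeros((B, H))
        for t in range(L - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tc = steps[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ], axis=1)
            grads["Wx"] += x_t.T @ dz
            grads["Wh"] += h_prev.T @ dz
            grads["b"] += dz.sum(axis=0)
            dh = dz @ p["Wh"].T
            dc = dc * f
        return grads

    # -- optimization -----------------------------------------------------

    def adam_step(self, grads: dict, lr: float,
                  beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self._adam_t += 1
        t = self._adam_t
        for k, p in self.params.items():
            gk = grads[k]
            self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * gk
            self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * gk * gk
            m_hat = self._adam_m[k] / (1 - beta1 ** t)
            v_hat = self._adam_v[k] / (1 - beta2 ** t)
            p -= lr * m_hat / (np.sqrt(v_hat) + eps)

    def mse(self, X: np.ndarray, y: np.ndarray, batch: int = 4096) -> float:
        err = 0.0
        n = len(y)
        for a in range(0, n, batch):
            pred = self.forward(X[a:a + batch])
            err += float(np.sum((pred - y[a:a + batch]) ** 2))
        return err / n

    def fit(self, X: np.ndarray, y: np.ndarray,
            X_val: np.ndarray, y_val: np.ndarray,
            epochs: int, batch_size: int, lr: float, patience: int,
            seed: int = 0) -> dict:
        """Minimize MSE with Adam + early stopping on validation loss.

        Returns a history dict; parameters are restored to the best
        validation epoch.  Fully deterministic given the seed.
        """
        rng = np.random.default_rng(seed)
        n = len(y)
        best_val = np.inf
        best_params = {k: v.copy() for k, v in self.params.items()}
        bad_epochs = 0
        history = {"train": [], "val": []}
        for _ in range(epochs):
            order = rng.permutation(n)
            for a in range(0, n, batch_size):
                idx = order[a:a + batch_size]
                pred, cache = self.forward(X[idx], cache=True)
                dy = 2.0 * (pred - y[idx]) / len(idx)
                self.adam_step(self.backward(cache, dy), lr)
            val = self.mse(X_val, y_val) if len(y_val) else self.mse(X, y)
            history["train"].append(self.mse(X, y))
            history["val"].append(val)
            if val < best_val:
                best_val = val
                best_params = {k: v.copy() for k, v in self.params.items()}
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= patience:
                    break
        self.params = best_params
        history["best_val"] = float(best_val)
        return history

    # -- (de)serialization ------------------------------------------------

    def state_dict(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=float).reshape(self.params[k].shape)
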