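"""Heteroscedastic fully connected regression network.

A small ReLU MLP with two output heads — a linear mean head and a
positive variance head (softplus plus a floor) — trained by minimizing
the Gaussian negative log-likelihood

    GNLL = mean( 0.5 * (log s2 + (y - mu)^2 / s2) )

with the Adam optimizer.  The network is deliberately tiny (default
hidden sizes 10-20-10) and is implemented directly in numpy with explicit
backpropagation, which keeps training bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import json

import numpy as np

__all__ = ["HeteroscedasticMLP", "gnll_loss"]


def _softplus(x):
    return np.logaddexp(0.0, x)


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def gnll_loss(mu, sigma2, y, variance_floor: float = 1e-6) -> float:
    """Gaussian negative log-likelihood, constant term dropped.

    ``0.5 * (log s2 + (y - mu)^2 / s2)`` averaged over the batch;
    variances below the floor are clamped.  Zero when mu = y and s2 = 1.
    """
    mu = np.asarray(mu, dtype=float)
    s2 = np.maximum(np.asarray(sigma2, dtype=float), variance_floor)
    y = np.asarray(y, dtype=float)
    return float(np.mean(0.5 * (np.log(s2) + (y - mu) ** 2 / s2)))


class HeteroscedasticMLP:
    """ReLU MLP with mean and variance heads, trained with GNLL + Adam."""

    def __init__(self, n_features: int, hidden_sizes=(10, 20, 10),
                 variance_floor: float = 1e-6, seed: int = 0):
        self.n_features = int(n_features)
        self.hidden_sizes = tuple(int(h) for h in hidden_sizes)
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        self.variance_floor = float(variance_floor)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        sizes = [self.n_features, *self.hidden_sizes]
        self.W, self.b = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            # He initialization, appropriate for ReLU
            self.W.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        last = sizes[-1]
        self.Wm = rng.normal(0.0, np.sqrt(1.0 / last), (last, 1))
        self.bm = np.zeros(1)
        self.Ws = rng.normal(0.0, np.sqrt(1.0 / last), (last, 1))
        self.bs = np.zeros(1)
        self._adam_state = None

    # -- forward / backward -------------------------------------------------

    def _forward(self, X):
        acts = [X]
        h = X
        for W, b in zip(self.W, self.b):
            h = np.maximum(h @ W + b, 0.0)
            acts.append(h)
        s_raw = h @ self.Ws + self.bs
        mu = (h @ self.Wm + self.bm)[:, 0]
        sigma2 = _softplus(s_raw)[:, 0] + self.variance_floor
        return mu, sigma2, s_raw[:, 0], acts

    def predict(self, X):
        """Standardized-space prediction: ``(mu, sigma2)`` per row."""
        mu, sigma2, _, _ = self._forward(np.asarray(X, dtype=float))
        return mu, sigma2

    def _params(self):
        return [*self.W, *self.b, self.Wm, self.bm, self.Ws, self.bs]

    def _grads(self, X, y):
        n = X.shape[0]
        mu, sigma2, s_raw, acts = self._forward(X)
        resid = mu - y
        dmu = resid / sigma2 / n
        ds2 = 0.5 * (1.0 / sigma2 - resid ** 2 / sigma2 ** 2) / n
        dsr = ds2 * _sigmoid(s_raw)
        h = acts[-1]
        gWm = h.T @ dmu[:, None]
        gbm = np.array([dmu.sum()])
        gWs = h.T @ dsr[:, None]
        gbs = np.array([dsr.sum()])
        dh = dmu[:, None] @ self.Wm.T + dsr[:, None] @ self.Ws.T
        gW, gb = [None] * len(self.W), [None] * len(self.b)
        for layer in range(len(self.W) - 1, -1, -1):
            da = dh * (acts[layer + 1] > 0)
            gW[layer] = acts[layer].T @ da
            gb[layer] = da.sum(axis=0)
            dh = da @ self.W[layer].T
        loss = float(np.mean(0.5 * (np.log(sigma2) + resid ** 2 / sigma2)))
        return loss, [*gW, *gb, gWm, gbm, gWs, gbs]

    # -- optimization -------------------------------------------------------

    def adam_step(self, X, y, lr: float = 1e-3, beta1: float = 0.9,
                  beta2: float = 0.999, eps: float = 1e-8) -> float:
        params = self._params()
        if self._adam_state is None:
            self._adam_state = {
                "t": 0,
                "m": [np.zeros_like(p) for p in params],
                "v": [np.zeros_like(p) for p in params],
            }
        loss, grads = self._grads(X, y)
        if not np.isfinite(loss):
            raise FloatingPointError("training diverged: non-finite GNLL")
        st = self._adam_state
        st["t"] += 1
        t = st["t"]
        for p, g, m, v in zip(params, grads, st["m"], st["v"]):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1 ** t)
            vhat = v / (1 - beta2 ** t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)
        return loss

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_features": self.n_features,
            "hidden_sizes": list(self.hidden_sizes),
            "variance_floor": self.variance_floor,
            "seed": self.seed,
            "W": [w.tolist() for w in self.W],
            "b": [b.tolist() for b in self.b],
            "Wm": self.Wm.tolist(), "bm": self.bm.tolist(),
            "Ws": self.Ws.tolist(), "bs": self.bs.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HeteroscedasticMLP":
        net = cls(d["n_features"], d["hidden_sizes"], d["variance_floor"],
                  d.get("seed", 0))
        net.W = [np.asarray(w, dtype=float) for w in d["W"]]
        net.b = [np.asarray(b, dtype=float) for b in d["b"]]
        net.Wm = np.asarray(d["Wm"], dtype=float)
        net.bm = np.asarray(d["bm"], dtype=float)
        net.Ws = np.asarray(d["Ws"], dtype=float)
        net.bs = np.asarray(d["bs"], dtype=float)
        return net

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "HeteroscedasticMLP":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
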