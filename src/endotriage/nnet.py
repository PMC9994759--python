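"""A small, fully deterministic neural network trained with SGD.

Single-hidden-layer perceptron with ReLU hidden units, softmax output and
cross-entropy loss, optimised by minibatch stochastic gradient descent with
momentum.  Written on numpy so that seeding gives bit-reproducible training
and the learning-rate schedule, early stopping and checkpointing semantics
are fully under the caller's control.
"""

from __future__ import annotations

import numpy as np


class TinyNet:
    def __init__(self, n_in: int, n_hidden: int, n_out: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        # He initialisation for the ReLU layer
        self.w1 = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_hidden))
        self.b1 = np.zeros(n_hidden)
        self.w2 = rng.normal(0.0, np.sqrt(2.0 / n_hidden), size=(n_hidden, n_out))
        self.b2 = np.zeros(n_out)
        self._vel = [np.zeros_like(p) for p in (self.w1, self.b1, self.w2, self.b2)]
        self.n_in, self.n_hidden, self.n_out = n_in, n_hidden, n_out

    # -- inference ---------------------------------------------------------
    def _forward(self, X: np.ndarray):
        h = np.maximum(X @ self.w1 + self.b1, 0.0)
        z = h @ self.w2 + self.b2
        z -= z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return h, e / e.sum(axis=1, keepdims=True)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._forward(np.atleast_2d(np.asarray(X, dtype=np.float64)))[1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    # -- training ----------------------------------------------------------
    def train_epoch(
        self,
        X: np.ndarray,
        y: np.ndarray,
        lr: float,
        rng: np.random.Generator,
        batch_size: int = 32,
        momentum: float = 0.9,
    ) -> float:
        """One pass over shuffled minibatches; returns mean training loss."""
        n = X.shape[0]
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = X[idx], y[idx]
            h, p = self._forward(xb)
            losses.append(-np.log(p[np.arange(len(idx)), yb] + 1e-12).mean())
            # gradients of mean cross-entropy
            dz = p.copy()
            dz[np.arange(len(idx)), yb] -= 1.0
            dz /= len(idx)
            gw2 = h.T @ dz
            gb2 = dz.sum(axis=0)
            dh = dz @ self.w2.T
            dh[h <= 0.0] = 0.0
            gw1 = xb.T @ dh
            gb1 = dh.sum(axis=0)
            params = (self.w1, self.b1, self.w2, self.b2)
            grads = (gw1, gb1, gw2, gb2)
            for i, (p_, g) in enumerate(zip(params, grads)):
                self._vel[i] = momentum * self._vel[i] - lr * g
                p_ += self._vel[i]
        return float(np.mean(losses))

    def accuracy(self, X: np.ndarray, y: np.ndarray) -> float:
        return float((self.predict(X) == y).mean())

    # -- checkpointing -----------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in (self.w1, self.b1, self.w2, self.b2)]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        self.w1, self.b1, self.w2, self.b2 = [w.copy() for w in weights]
        self._vel = [np.zeros_like(p) for p in (self.w1, self.b1, self.w2, self.b2)]
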