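"""Small configurable MLP classifier trained by mini-batch gradient descent.

Features -> ReLU hidden layers -> C logits, cross-entropy loss against
hard (one-hot) or soft simplex targets.  Plain numpy with explicit
backprop; deliberately small since the federated experiments run many
such models.
"""

from __future__ import annotations

import numpy as np
from scipy.special import softmax

__all__ = ["MLPClassifier"]


class MLPClassifier:
    """Fully connected network ``d -> hidden ... -> C``.

    Parameters
    ----------
    dim : input feature dimension.
    C : number of classes (output logits).
    hidden : tuple of hidden-layer widths; default one layer of 32.
    seed : controls weight initialization and batch shuffling.
    """

    def __init__(self, dim: int, C: int, hidden: tuple[int, ...] = (32,), seed: int = 0):
        if dim < 1 or C < 1:
            raise ValueError("dim and C must be positive")
        self.dim, self.C, self.hidden = dim, C, tuple(hidden)
        self._rng = np.random.default_rng(seed)
        widths = [dim, *self.hidden, C]
        self.W = [
            self._rng.normal(scale=np.sqrt(2.0 / widths[i]), size=(widths[i], widths[i + 1]))
            for i in range(len(widths) - 1)
        ]
        # zero output layer: with ReLU hidden units this makes a model
        # trained on a single class a provably constant predictor of that
        # class (off-class logits only accumulate non-positive terms)
        self.W[-1][:] = 0.0
        self.b = [np.zeros(widths[i + 1]) for i in range(len(widths) - 1)]
        # input standardization, frozen at the first fit; keeps gradient
        # descent well conditioned regardless of the feature scale
        self._mu: np.ndarray | None = None
        self._sigma: np.ndarray | None = None

    # --- inference ---------------------------------------------------
    def logits(self, X: np.ndarray) -> np.ndarray:
        a = np.atleast_2d(np.asarray(X, dtype=float))
        if self._mu is not None:
            a = (a - self._mu) / self._sigma
        for W, b in zip(self.W[:-1], self.b[:-1]):
            a = np.maximum(a @ W + b, 0.0)
        return a @ self.W[-1] + self.b[-1]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return softmax(self.logits(X), axis=1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.logits(X), axis=1)

    # --- training ----------------------------------------------------
    def fit(
        self,
        X: np.ndarray,
        targets: np.ndarray,
        epochs: int,
        lr: float = 0.05,
        batch_size: int = 32,
    ) -> float:
        """Mini-batch gradient descent on cross-entropy; returns final mean loss.

        ``targets`` may be integer class labels or simplex rows (soft
        targets for distillation).  Deterministic given the construction
        seed and call order.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = X.shape[0]
        if n == 0 or epochs == 0:
            return float("nan")
        if self._mu is None:
            self._mu = X.mean(axis=0)
            self._sigma = np.maximum(X.std(axis=0), 1e-8)
        X = (X - self._mu) / self._sigma
        T = np.asarray(targets)
        if T.ndim == 1:
            T = np.eye(self.C)[T.astype(int)]
        T = T.astype(float)
        loss = float("nan")
        for _ in range(epochs):
            order = self._rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                losses.append(self._step(X[idx], T[idx], lr))
            loss = float(np.mean(losses))
            if not np.isfinite(loss):
                raise FloatingPointError("NaN/Inf training loss; reduce the learning rate")
        return loss

    def _step(self, Xb: np.ndarray, Tb: np.ndarray, lr: float) -> float:
        acts = [Xb]
        a = Xb
        for W, b in zip(self.W[:-1], self.b[:-1]):
            a = np.maximum(a @ W + b, 0.0)
            acts.append(a)
        z = a @ self.W[-1] + self.b[-1]
        p = softmax(z, axis=1)
        m = Xb.shape[0]
        loss = float(-np.mean(np.sum(Tb * np.log(np.clip(p, 1e-12, None)), axis=1)))
        delta = (p - Tb) / m
        for layer in range(len(self.W) - 1, -1, -1):
            gW = acts[layer].T @ delta
            gb = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ self.W[layer].T) * (acts[layer] > 0)
            self.W[layer] -= lr * gW
            self.b[layer] -= lr * gb
        return loss

    # --- parameter vector (FedAvg / reproducibility digests) ---------
    @property
    def n_parameters(self) -> int:
        return sum(W.size for W in self.W) + sum(b.size for b in self.b)

    def get_parameters(self) -> np.ndarray:
        return np.concatenate([a.ravel() for a in (*self.W, *self.b)])

    def set_parameters(self, flat: np.ndarray) -> None:
        flat = np.asarray(flat, dtype=float)
        if flat.size != self.n_parameters:
            raise ValueError("parameter vector size mismatch")
        pos = 0
        for coll in (self.W, self.b):
            for i, a in enumerate(coll):
                coll[i] = flat[pos : pos + a.size].reshape(a.shape).copy()
                pos += a.size
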