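"""Feed-forward regression network with dropout, in pure numpy.

A deliberately small implementation covering exactly what the ensemble
framework needs from a neural adapter: ReLU hidden layers, a linear
output, inverted dropout in every hidden layer during training, and —
crucially for Monte Carlo dropout — the ability to run stochastic
forward passes with freshly sampled dropout masks after fitting.
Training uses mini-batch Adam on the mean-squared error.

Two reference architectures are used by the adapter layer: a shallow
network with one 128-unit hidden layer and a deeper one with hidden
layers of 256, 128 and 16 units.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["DropoutMLPRegressor"]


class DropoutMLPRegressor(RegressorMixin, BaseEstimator):
    """Multi-layer perceptron regressor with dropout in every hidden layer.

    Parameters
    ----------
    hidden_layer_sizes : tuple of int
        Units per hidden layer, in forward-propagation order.
    dropout_rate : float in [0, 1)
        Fraction of hidden units dropped (inverted dropout) during
        training and during stochastic MC-dropout passes.
    epochs : int
        Full passes over the training data.
    batch_size, learning_rate : Adam mini-batch settings.
    random_state : seed for weight initialization, batch shuffling and
        training-time dropout masks.
    """

    def __init__(
        self,
        hidden_layer_sizes=(128,),
        dropout_rate=0.2,
        epochs=1000,
        batch_size=32,
        learning_rate=1e-3,
        random_state=None,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.dropout_rate = dropout_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    # -- internals -----------------------------------------------------------

    def _init_params(self, n_features, rng):
        sizes = [n_features, *self.hidden_layer_sizes, 1]
        W, b = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            # He initialization, suited to ReLU hidden layers
            W.append(rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in))
            b.append(np.zeros(fan_out))
        return W, b

    def _forward(self, X, rng=None, rate=None):
        """Forward pass; with ``rng`` given, applies inverted dropout masks.

        Returns (output, caches) where caches hold pre-activations,
        activations and masks for backpropagation.
        """
        rate = self.dropout_rate if rate is None else rate
        a = X
        caches = []
        n_hidden = len(self.W_) - 1
        for layer in range(n_hidden):
            z = a @ self.W_[layer] + self.b_[layer]
            h = np.maximum(z, 0.0)
            mask = None
            if rng is not None and rate > 0.0:
                mask = (rng.random(h.shape) >= rate) / (1.0 - rate)
                h = h * mask
            caches.append((a, z, mask))
            a = h
        out = a @ self.W_[-1] + self.b_[-1]
        caches.append((a, None, None))
        return out[:, 0], caches

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one row per target")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training samples")
        if not np.all(np.isfinite(y)):
            raise ValueError("targets must be finite")
        rng = np.random.default_rng(self.random_state)
        self.n_features_in_ = X.shape[1]
        self.W_, self.b_ = self._init_params(X.shape[1], rng)

        mW = [np.zeros_like(w) for w in self.W_]
        vW = [np.zeros_like(w) for w in self.W_]
        mb = [np.zeros_like(b) for b in self.b_]
        vb = [np.zeros_like(b) for b in self.b_]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        n = X.shape[0]
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = X[idx], y[idx]
                pred, caches = self._forward(xb, rng=rng)
                # MSE gradient, backpropagated through ReLU + dropout
                delta = (2.0 / len(idx)) * (pred - yb)[:, None]
                gW = [None] * len(self.W_)
                gb = [None] * len(self.b_)
                a_last = caches[-1][0]
                gW[-1] = a_last.T @ delta
                gb[-1] = delta.sum(axis=0)
                grad_a = delta @ self.W_[-1].T
                for layer in range(len(self.W_) - 2, -1, -1):
                    a_in, z, mask = caches[layer]
                    if mask is not None:
                        grad_a = grad_a * mask
                    grad_z = grad_a * (z > 0.0)
                    gW[layer] = a_in.T @ grad_z
                    gb[layer] = grad_z.sum(axis=0)
                    if layer > 0:
                        grad_a = grad_z @ self.W_[layer].T
                t += 1
                lr_t = self.learning_rate * np.sqrt(1 - beta2**t) / (1 - beta1**t)
                for layer in range(len(self.W_)):
                    mW[layer] = beta1 * mW[layer] + (1 - beta1) * gW[layer]
                    vW[layer] = beta2 * vW[layer] + (1 - beta2) * gW[layer] ** 2
                    self.W_[layer] -= lr_t * mW[layer] / (np.sqrt(vW[layer]) + eps)
                    mb[layer] = beta1 * mb[layer] + (1 - beta1) * gb[layer]
                    vb[layer] = beta2 * vb[layer] + (1 - beta2) * gb[layer] ** 2
                    self.b_[layer] -= lr_t * mb[layer] / (np.sqrt(vb[layer]) + eps)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            return np.empty(0)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        out, _ = self._forward(X, rng=None)
        return out

    def predict_stochastic(self, X, n_passes: int, rng, dropout_rate: float | None = None):
        """(n_passes, n) matrix of forward passes with dropout active."""
        X = np.asarray(X, dtype=float)
        rate = self.dropout_rate if dropout_rate is None else dropout_rate
        return np.stack(
            [self._forward(X, rng=rng, rate=rate)[0] for _ in range(n_passes)]
        )
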