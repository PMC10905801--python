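"""Compact feed-forward regression network in numpy.

All arithmetic runs in float32 for speed; outputs are returned as float64.

Implements exactly the architecture family the synergy model searches over:
an input layer, three (in general, any number of) fully-connected hidden
layers each followed by inverted dropout, and a single linear output node.
Training minimises mean-squared error with the Adam optimizer, optionally
early-stopping on a held-out validation split.  Everything — weight
initialisation, minibatch order, dropout masks — is driven by explicit
seeds, so a fit is bit-reproducible on a single thread.
"""

from __future__ import annotations

import numpy as np

__all__ = ["FeedForwardRegressor"]


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def _relu_grad(z: np.ndarray) -> np.ndarray:
    return (z > 0.0).astype(z.dtype)


def _tanh(z: np.ndarray) -> np.ndarray:
    return np.tanh(z)


def _tanh_grad(z: np.ndarray) -> np.ndarray:
    t = np.tanh(z)
    return 1.0 - t * t


_ACTIVATIONS = {"relu": (_relu, _relu_grad), "tanh": (_tanh, _tanh_grad)}


class FeedForwardRegressor:
    """Dense regression network with per-layer activations and dropout.

    Parameters
    ----------
    input_width : int
        Number of input features.
    hidden_sizes : sequence of int
        Width of each hidden layer.
    activations : sequence of str
        Activation per hidden layer, each ``"relu"`` or ``"tanh"``.
    dropout_rate : float
        Inverted-dropout rate applied after every hidden activation during
        training only; inference is deterministic.
    seed : int
        Seed for weight initialisation (He for relu layers, Glorot for tanh
        and the linear output).
    """

    def __init__(
        self,
        input_width: int,
        hidden_sizes,
        activations,
        dropout_rate: float = 0.5,
        seed: int = 0,
    ) -> None:
        if input_width < 1:
            raise ValueError("input_width must be >= 1")
        hidden_sizes = tuple(int(h) for h in hidden_sizes)
        activations = tuple(str(a) for a in activations)
        if len(hidden_sizes) != len(activations):
            raise ValueError("hidden_sizes and activations must have equal length")
        for a in activations:
            if a not in _ACTIVATIONS:
                raise ValueError(f"unknown activation {a!r}; choose from {sorted(_ACTIVATIONS)}")
        if not 0.0 <= dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

        self.input_width = int(input_width)
        self.hidden_sizes = hidden_sizes
        self.activations = activations
        self.dropout_rate = float(dropout_rate)
        self.seed = int(seed)
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}

        rng = np.random.default_rng(seed)
        sizes = (self.input_width, *hidden_sizes, 1)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for i in range(len(sizes) - 1):
            fan_in, fan_out = sizes[i], sizes[i + 1]
            act = activations[i] if i < len(hidden_sizes) else "linear"
            if act == "relu":
                w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
            else:  # Glorot uniform for tanh and the linear head
                limit = np.sqrt(6.0 / (fan_in + fan_out))
                w = rng.uniform(-limit, limit, size=(fan_in, fan_out))
            self.weights.append(w.astype(np.float32))
            self.biases.append(np.zeros(fan_out, dtype=np.float32))

    # ------------------------------------------------------------------ #
    # inference
    # ------------------------------------------------------------------ #

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Deterministic forward pass (dropout inert). Returns shape (n,)."""
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.input_width:
            raise ValueError(
                f"input width mismatch: got {X.shape[1]}, model expects {self.input_width}"
            )
        h = X
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ w + b
            if i < len(self.hidden_sizes):
                h = _ACTIVATIONS[self.activations[i]][0](z)
            else:
                h = z
        return h[:, 0].astype(np.float64)

    # ------------------------------------------------------------------ #
    # training
    # ------------------------------------------------------------------ #

    def _forward_train(self, X, rng):
        """Forward pass with dropout masks; returns output and caches."""
        pre, post = [], []
        h = X
        keep = 1.0 - self.dropout_rate
        masks = []
        for i in range(len(self.hidden_sizes)):
            z = h @ self.weights[i] + self.biases[i]
            a = _ACTIVATIONS[self.activations[i]][0](z)
            if self.dropout_rate > 0.0:
                m = (rng.random(a.shape) < keep).astype(a.dtype) / keep
                a = a * m
            else:
                m = None
            pre.append(z)
            post.append(h)
            masks.append(m)
            h = a
        out = h @ self.weights[-1] + self.biases[-1]
        post.append(h)
        return out[:, 0], pre, post, masks

    def _backward(self, out, y, pre, post, masks):
        n = y.shape[0]
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        d = (2.0 / n) * (out - y)[:, None]  # dL/d(out), column
        grads_w[-1] = post[-1].T @ d
        grads_b[-1] = d.sum(axis=0)
        d = d @ self.weights[-1].T
        for i in range(len(self.hidden_sizes) - 1, -1, -1):
            if masks[i] is not None:
                d = d * masks[i]
            d = d * _ACTIVATIONS[self.activations[i]][1](pre[i])
            grads_w[i] = post[i].T @ d
            grads_b[i] = d.sum(axis=0)
            d = d @ self.weights[i].T
        return grads_w, grads_b

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        learning_rate: float = 1e-5,
        max_epochs: int = 500,
        batch_size: int = 128,
        patience: int = 20,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        seed: int = 0,
        min_delta: float = 0.0,
    ) -> "FeedForwardRegressor":
        """Minimise MSE with Adam.

        When a validation set is supplied, training stops after ``patience``
        epochs without improvement in validation loss and the best weights
        are restored.  Raises ``FloatingPointError`` with diagnostics if the
        loss goes non-finite.
        """
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("feature rows and target count differ")
        if X.shape[1] != self.input_width:
            raise ValueError("input width mismatch")
        has_val = X_val is not None and y_val is not None and len(np.ravel(y_val)) > 0
        if has_val:
            X_val = np.asarray(X_val, dtype=np.float32)
            y_val = np.asarray(y_val, dtype=np.float32).ravel()

        rng = np.random.default_rng(seed)
        params = self.weights + self.biases
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0

        best_val = np.inf
        best_params = None
        stall = 0
        n = X.shape[0]
        self.history = {"train_loss": [], "val_loss": []}

        for epoch in range(max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb, yb = X[idx], y[idx]
                out, pre, post, masks = self._forward_train(xb, rng)
                loss = float(np.mean((out - yb) ** 2))
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        "non-finite training loss at epoch "
                        f"{epoch}; learning_rate={learning_rate}, seed={self.seed}; "
                        "try a smaller learning rate or re-initialise"
                    )
                epoch_loss += loss * len(idx)
                gw, gb = self._backward(out, yb, pre, post, masks)
                t += 1
                for j, (p, g) in enumerate(zip(params, gw + gb)):
                    m[j] = beta1 * m[j] + (1 - beta1) * g
                    v[j] = beta2 * v[j] + (1 - beta2) * g * g
                    mhat = m[j] / (1 - beta1**t)
                    vhat = v[j] / (1 - beta2**t)
                    p -= learning_rate * mhat / (np.sqrt(vhat) + eps)
            self.history["train_loss"].append(epoch_loss / n)

            if has_val:
                val_loss = float(np.mean((self.predict(X_val) - y_val) ** 2))
                self.history["val_loss"].append(val_loss)
                if val_loss < best_val - min_delta:
                    best_val = val_loss
                    best_params = [p.copy() for p in params]
                    stall = 0
                else:
                    stall += 1
                    if stall >= patience:
                        break

        if has_val and best_params is not None:
            k = len(self.weights)
            self.weights = best_params[:k]
            self.biases = best_params[k:]
        return self
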