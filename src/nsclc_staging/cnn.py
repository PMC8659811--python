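"""Binary staging classifier: multi-scale convolution over a document matrix.

Architecture: a bank of convolution kernels with window sizes {3, 4, 5}
(one or more kernels per size) slides over the token axis of the document
matrix; each kernel yields a feature map ``a_i = f(<K, V_{i:i+m-1}> + b)``;
1-max pooling reduces every map to its single maximum, giving a feature
vector whose length equals the number of kernels; a fully connected layer
with dropout and a 2-way softmax produces the positive-class probability
``eta``. Training is plain minibatch SGD on cross-entropy, implemented in
numpy with hand-written backpropagation (a finite-difference gradient
check in the test suite guards it).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, ClassifierMixin

from ._rng import stream

__all__ = ["TextCNNClassifier", "conv_feature", "max_pool"]


def _relu(x):
    return np.maximum(x, 0.0)


def _relu_grad(pre):
    return (pre > 0).astype(float)


def _tanh_grad(pre):
    t = np.tanh(pre)
    return 1.0 - t * t


_ACTIVATIONS = {
    "relu": (_relu, _relu_grad),
    "tanh": (np.tanh, _tanh_grad),
    "identity": (lambda x: x, lambda pre: np.ones_like(pre)),
}


def conv_feature(matrix: np.ndarray, weights: np.ndarray, bias: float,
                 activation: str = "relu") -> np.ndarray:
    """Feature map of one kernel over one document matrix.

    ``matrix`` is (num, n); ``weights`` is (m, n). Entry i of the output is
    ``f(<weights, matrix[i:i+m]> + bias)`` (elementwise-product sum); the
    output has length num - m + 1.
    """
    matrix = np.asarray(matrix, dtype=float)
    weights = np.asarray(weights, dtype=float)
    m, n = weights.shape
    if matrix.ndim != 2 or matrix.shape[1] != n:
        raise ValueError(f"matrix width {matrix.shape} does not match kernel {weights.shape}")
    if matrix.shape[0] < m:
        raise ValueError(f"document of {matrix.shape[0]} rows is too short for window {m}")
    f, _ = _ACTIVATIONS[activation]
    windows = sliding_window_view(matrix, m, axis=0)       # (L, n, m)
    return f(np.einsum("lnm,mn->l", windows, weights) + bias)


def max_pool(feature: np.ndarray) -> float:
    """1-max pooling: the single maximum of a non-empty feature map."""
    feature = np.asarray(feature)
    if feature.size == 0:
        raise ValueError("cannot max-pool an empty feature map")
    return float(feature.max())


class TextCNNClassifier(BaseEstimator, ClassifierMixin):
    """Multi-scale-kernel text CNN for one binary (one-vs-rest) stage label.

    Parameters
    ----------
    kernel_sizes : token windows of the convolution kernels.
    kernels_per_size : number of kernels at each window size.
    activation : "relu" (default) or "tanh".
    dropout : dropout rate on the pooled feature vector during training.
    lr : SGD learning rate (constant).
    batch_size : minibatch size.
    epochs : SGD epochs run by :meth:`fit`.
    init_weights : optional parameter snapshot (as returned by
        :meth:`get_weights`) used as the starting point instead of random
        initialization — this is how transfer initialization from a
        source-stage model is expressed.
    seed : master seed; init, dropout and shuffling use independent streams.

    Attributes
    ----------
    kernels_ : list of (weights (m, n), bias) pairs.
    fc_weights_, fc_bias_ : fully connected layer, shape (2, K) and (2,).
    classes_ : always [0, 1] (eta = probability of class 1).
    """

    def __init__(
        self,
        kernel_sizes: Sequence[int] = (3, 4, 5),
        kernels_per_size: int = 1,
        activation: str = "relu",
        dropout: float = 0.5,
        lr: float = 0.05,
        batch_size: int = 32,
        epochs: int = 256,
        init_weights: dict | None = None,
        seed: int = 0,
    ):
        self.kernel_sizes = kernel_sizes
        self.kernels_per_size = kernels_per_size
        self.activation = activation
        self.dropout = dropout
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.init_weights = init_weights
        self.seed = seed

    # -- parameter handling -----------------------------------------------

    def _window_list(self) -> list[int]:
        return [int(m) for m in self.kernel_sizes for _ in range(self.kernels_per_size)]

    def initialize(self, n_dim: int) -> "TextCNNClassifier":
        """Set up parameters for embeddings of width ``n_dim`` (no training)."""
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.init_weights is not None:
            self.set_weights(self.init_weights)
            return self
        rng = stream(self.seed, "cnn-init")
        windows = self._window_list()
        self.kernels_ = [
            (rng.standard_normal((m, n_dim)) * np.sqrt(2.0 / (m * n_dim)), 0.0)
            for m in windows
        ]
        K = len(windows)
        self.fc_weights_ = rng.standard_normal((2, K)) * np.sqrt(1.0 / K)
        self.fc_bias_ = np.zeros(2)
        self.classes_ = np.array([0, 1])
        self.n_dim_ = n_dim
        self._dropout_rng = stream(self.seed, "cnn-dropout")
        self._shuffle_rng = stream(self.seed, "cnn-shuffle")
        return self

    def get_weights(self) -> dict:
        """Deep-copied parameter snapshot (usable as ``init_weights``)."""
        self._check_fitted()
        return {
            "kernels": [(w.copy(), float(b)) for w, b in self.kernels_],
            "fc_weights": self.fc_weights_.copy(),
            "fc_bias": self.fc_bias_.copy(),
            "n_dim": self.n_dim_,
        }

    def set_weights(self, weights: dict) -> None:
        self.kernels_ = [(np.array(w, dtype=float), float(b))
                         for w, b in weights["kernels"]]
        self.fc_weights_ = np.array(weights["fc_weights"], dtype=float)
        self.fc_bias_ = np.array(weights["fc_bias"], dtype=float)
        self.n_dim_ = int(weights["n_dim"])
        self.classes_ = np.array([0, 1])
        self._dropout_rng = stream(self.seed, "cnn-dropout")
        self._shuffle_rng = stream(self.seed, "cnn-shuffle")

    def _check_fitted(self):
        if not hasattr(self, "kernels_"):
            raise RuntimeError("TextCNNClassifier is not initialized/fitted")

    # -- forward ------------------------------------------------------------

    def _forward(self, X: np.ndarray, dropout_mask: np.ndarray | None = None):
        """Batched forward pass; returns (probs, cache for backprop)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        max_m = max(w.shape[0] for w, _ in self.kernels_)
        if X.shape[1] < max_m:
            raise ValueError(
                f"documents of {X.shape[1]} rows are too short for window {max_m}")
        if X.shape[2] != self.n_dim_:
            raise ValueError("document-matrix width does not match model n_dim")
        f, _ = _ACTIVATIONS[self.activation]
        B = X.shape[0]
        pooled = np.empty((B, len(self.kernels_)))
        cache_k = []
        for k, (w, b) in enumerate(self.kernels_):
            m = w.shape[0]
            windows = sliding_window_view(X, m, axis=1)      # (B, L, n, m)
            pre = np.einsum("blnm,mn->bl", windows, w) + b    # (B, L)
            act = f(pre)
            arg = act.argmax(axis=1)
            pooled[:, k] = act[np.arange(B), arg]
            cache_k.append((windows, pre, arg))
        z = pooled if dropout_mask is None else pooled * dropout_mask
        scores = z @ self.fc_weights_.T + self.fc_bias_       # (B, 2)
        scores = scores - scores.max(axis=1, keepdims=True)
        e = np.exp(scores)
        probs = e / e.sum(axis=1, keepdims=True)
        return probs, (X, cache_k, pooled, z)

    def positive_probability(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        """eta in [0, 1] per document: the positive-class probability.

        Evaluation mode (default) is deterministic; ``training=True``
        applies inverted dropout from the model's dropout stream.
        """
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        single = X.ndim == 2
        if single:
            X = X[None]
        mask = None
        if training and self.dropout > 0:
            mask = (self._dropout_rng.random((X.shape[0], len(self.kernels_)))
                    >= self.dropout) / (1.0 - self.dropout)
        probs, _ = self._forward(X, mask)
        eta = probs[:, 1]
        return float(eta[0]) if single else eta

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        self._check_fitted()
        probs, _ = self._forward(np.asarray(X, dtype=float))
        return probs

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        """Mean cross-entropy on (X, y) in evaluation mode."""
        probs = self.predict_proba(X)
        y = np.asarray(y, dtype=int)
        p = np.clip(probs[np.arange(len(y)), y], 1e-12, None)
        return float(-np.log(p).mean())

    # -- training -----------------------------------------------------------

    def _backward(self, probs, cache, y, dropout_mask):
        X, cache_k, pooled, z = cache
        B = len(y)
        _, fgrad = _ACTIVATIONS[self.activation]
        d_scores = probs.copy()
        d_scores[np.arange(B), y] -= 1.0
        d_scores /= B
        g_fc_w = d_scores.T @ z
        g_fc_b = d_scores.sum(axis=0)
        d_z = d_scores @ self.fc_weights_
        d_pooled = d_z if dropout_mask is None else d_z * dropout_mask
        g_kernels = []
        for k, (w, b) in enumerate(self.kernels_):
            windows, pre, arg = cache_k[k]
            idx = np.arange(B)
            d_pre = d_pooled[:, k] * fgrad(pre[idx, arg])     # (B,)
            win_sel = windows[idx, arg]                       # (B, n, m)
            g_w = np.einsum("b,bnm->mn", d_pre, win_sel)
            g_b = float(d_pre.sum())
            g_kernels.append((g_w, g_b))
        return g_kernels, g_fc_w, g_fc_b

    def train_epochs(self, X, y, epochs: int) -> "TextCNNClassifier":
        """Continue SGD training from the current parameters."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(X) == 0:
            raise ValueError("training set is empty")
        for _ in range(epochs):
            order = self._shuffle_rng.permutation(len(X))
            for start in range(0, len(X), self.batch_size):
                sel = order[start : start + self.batch_size]
                xb, yb = X[sel], y[sel]
                mask = None
                if self.dropout > 0:
                    mask = (self._dropout_rng.random((len(sel), len(self.kernels_)))
                            >= self.dropout) / (1.0 - self.dropout)
                probs, cache = self._forward(xb, mask)
                g_kernels, g_fc_w, g_fc_b = self._backward(probs, cache, yb, mask)
                self.kernels_ = [
                    (w - self.lr * gw, b - self.lr * gb)
                    for (w, b), (gw, gb) in zip(self.kernels_, g_kernels)
                ]
                self.fc_weights_ -= self.lr * g_fc_w
                self.fc_bias_ -= self.lr * g_fc_b
        return self

    def fit(self, X, y) -> "TextCNNClassifier":
        """Initialize (random or from ``init_weights``) and run SGD."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be (n_samples, num, n_dim)")
        if len(X) == 0:
            raise ValueError("training set is empty")
        self.initialize(X.shape[2])
        return self.train_epochs(X, y, self.epochs)
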