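"""Skip-gram word vectors and the document matrix.

The staging classifier consumes a record's text as a two-dimensional
matrix: one row per token position, each row the token's dense embedding,
zero-padded (or prefix-truncated) to a fixed length. Embeddings are
pre-trained with the skip-gram objective — maximize the log-likelihood
``sum_{gamma in G(w_c)} log p(gamma | w_c)`` of the context tokens gamma
within a symmetric window of size ``d`` around each center token ``w_c``,
with ``p`` a softmax over output vectors — so tokens that co-occur end up
with similar vectors.

For the small closed vocabularies produced by the record generator the
exact softmax gradient is used; above a configurable vocabulary size the
objective is optimized by negative sampling (unigram^0.75 noise), the
standard large-vocabulary approximation.
"""

from __future__ import annotations

from collections import Counter
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._rng import stream

__all__ = ["SkipgramEmbedding", "embed_document", "context_window"]


def context_window(tokens: Sequence[str], position: int, d: int) -> list[str]:
    """Context set G(w_c): tokens within d positions before/after `position`."""
    lo = max(0, position - d)
    return [t for i, t in enumerate(tokens[lo : position + d + 1], start=lo)
            if i != position]


class SkipgramEmbedding(BaseEstimator, TransformerMixin):
    """Skip-gram token embeddings with document-matrix transform.

    Parameters
    ----------
    n_dim : embedding dimension (rows of the document matrix have this width).
    window : context window d; context tokens are drawn from d positions on
        each side of the center token.
    epochs : SGD passes over all (center, context) pairs.
    lr : SGD learning rate (constant).
    negative : number of noise tokens per pair when negative sampling is used.
    exact_softmax_max_vocab : vocabulary size up to which the exact softmax
        gradient is used; larger vocabularies fall back to negative sampling.
    max_len : default document-matrix length (pad/truncate target).
    batch_pairs : minibatch size over (center, context) pairs.
    seed : master seed (all streams derived from it).

    Attributes
    ----------
    vocabulary_ : ordered token list (frequency-descending, ties lexical).
    vectors_ : (V, n_dim) input embedding matrix, one row per token.
    """

    def __init__(
        self,
        n_dim: int = 64,
        window: int = 2,
        epochs: int = 5,
        lr: float = 0.05,
        negative: int = 5,
        exact_softmax_max_vocab: int = 1000,
        max_len: int = 64,
        batch_pairs: int = 512,
        seed: int = 0,
    ):
        self.n_dim = n_dim
        self.window = window
        self.epochs = epochs
        self.lr = lr
        self.negative = negative
        self.exact_softmax_max_vocab = exact_softmax_max_vocab
        self.max_len = max_len
        self.batch_pairs = batch_pairs
        self.seed = seed

    # -- fitting ----------------------------------------------------------

    def fit(self, corpus: Sequence[Sequence[str]], y=None):
        if not corpus or all(len(doc) == 0 for doc in corpus):
            raise ValueError("corpus must contain at least one non-empty document")
        if min(self.n_dim, self.window, self.epochs) < 1:
            raise ValueError("n_dim, window and epochs must all be >= 1")

        counts = Counter(t for doc in corpus for t in doc)
        self.vocabulary_ = [t for t, _ in
                            sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]
        self.index_ = {t: i for i, t in enumerate(self.vocabulary_)}
        V = len(self.vocabulary_)

        centers, contexts = [], []
        for doc in corpus:
            idx = [self.index_[t] for t in doc]
            for pos, c in enumerate(idx):
                lo = max(0, pos - self.window)
                for j in range(lo, min(len(idx), pos + self.window + 1)):
                    if j != pos:
                        centers.append(c)
                        contexts.append(idx[j])
        centers = np.asarray(centers, dtype=np.intp)
        contexts = np.asarray(contexts, dtype=np.intp)

        rng = stream(self.seed, "skipgram")
        w_in = (rng.random((V, self.n_dim)) - 0.5) / self.n_dim
        w_out = np.zeros((V, self.n_dim))

        use_exact = V <= self.exact_softmax_max_vocab
        if not use_exact:
            freq = np.array([counts[t] for t in self.vocabulary_], dtype=float)
            noise = freq ** 0.75
            noise /= noise.sum()

        n_pairs = len(centers)
        for _ in range(self.epochs):
            order = rng.permutation(n_pairs)
            for start in range(0, n_pairs, self.batch_pairs):
                sel = order[start : start + self.batch_pairs]
                c, x = centers[sel], contexts[sel]
                if use_exact:
                    self._sgd_exact(w_in, w_out, c, x)
                else:
                    self._sgd_negative(w_in, w_out, c, x, noise, rng)

        self.vectors_ = w_in
        self.context_vectors_ = w_out
        return self

    def _sgd_exact(self, w_in, w_out, c, x):
        """Exact softmax gradient step on one minibatch of (center, context)."""
        vc = w_in[c]                                   # (B, n)
        scores = vc @ w_out.T                          # (B, V)
        scores -= scores.max(axis=1, keepdims=True)
        p = np.exp(scores)
        p /= p.sum(axis=1, keepdims=True)
        d = p.copy()
        d[np.arange(len(x)), x] -= 1.0                 # dL/dscores, L = -log p
        d /= len(x)
        grad_out = d.T @ vc                            # (V, n)
        grad_c = d @ w_out                             # (B, n)
        w_out -= self.lr * grad_out
        np.subtract.at(w_in, c, self.lr * grad_c)

    def _sgd_negative(self, w_in, w_out, c, x, noise, rng):
        """Negative-sampling (SGNS) gradient step on one minibatch."""
        B = len(c)
        neg = rng.choice(len(noise), size=(B, self.negative), p=noise)
        vc = w_in[c]                                   # (B, n)
        tgt = np.concatenate([x[:, None], neg], axis=1)  # (B, 1+k)
        lab = np.zeros_like(tgt, dtype=float)
        lab[:, 0] = 1.0
        u = w_out[tgt]                                 # (B, 1+k, n)
        s = 1.0 / (1.0 + np.exp(-np.einsum("bkn,bn->bk", u, vc)))
        d = (s - lab) / B                              # (B, 1+k)
        grad_c = np.einsum("bk,bkn->bn", d, u)
        grad_u = d[..., None] * vc[:, None, :]         # (B, 1+k, n)
        np.subtract.at(w_in, c, self.lr * grad_c)
        np.subtract.at(w_out, tgt.ravel(),
                       self.lr * grad_u.reshape(-1, self.n_dim))

    # -- document matrices ------------------------------------------------

    def embed(self, tokens: Sequence[str], max_len: int | None = None) -> np.ndarray:
        """Document matrix V_{1:num} for one token sequence.

        Rows 1..min(len, max_len) are the tokens' embeddings in order
        (out-of-vocabulary tokens map to the zero UNK vector); the rest is
        zero padding. Truncation keeps the prefix.
        """
        self._check_fitted()
        return embed_document(tokens, self, max_len or self.max_len)

    def transform(self, corpus: Sequence[Sequence[str]]) -> np.ndarray:
        """(n_docs, max_len, n_dim) array of document matrices."""
        self._check_fitted()
        return np.stack([self.embed(doc) for doc in corpus])

    def _check_fitted(self):
        if not hasattr(self, "vectors_"):
            raise RuntimeError("SkipgramEmbedding is not fitted")

    # -- word2vec text serialization --------------------------------------

    def save_word2vec(self, path) -> None:
        self._check_fitted()
        with open(path, "w") as fh:
            fh.write(f"{len(self.vocabulary_)} {self.n_dim}\n")
            for tok, vec in zip(self.vocabulary_, self.vectors_):
                fh.write(tok + " " + " ".join(f"{v:.17g}" for v in vec) + "\n")

    @classmethod
    def load_word2vec(cls, path, **params) -> "SkipgramEmbedding":
        """Load vectors from word2vec text format; ``params`` restores any
        non-default constructor settings (e.g. ``max_len``)."""
        with open(path) as fh:
            header = fh.readline().split()
            v_size, n_dim = int(header[0]), int(header[1])
            vocab, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                vocab.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        if len(vocab) != v_size:
            raise ValueError("vocabulary size does not match header")
        params.pop("n_dim", None)
        model = cls(n_dim=n_dim, **params)
        model.vocabulary_ = vocab
        model.index_ = {t: i for i, t in enumerate(vocab)}
        model.vectors_ = np.asarray(rows, dtype=float)
        model.context_vectors_ = np.zeros_like(model.vectors_)
        return model


def embed_document(
    tokens: Sequence[str], model: SkipgramEmbedding, max_len: int
) -> np.ndarray:
    """Pure function: token sequence -> (max_len, n_dim) document matrix."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    out = np.zeros((max_len, model.n_dim))
    for i, tok in enumerate(tokens[:max_len]):
        j = model.index_.get(tok)
        if j is not None:
            out[i] = model.vectors_[j]
    return out
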