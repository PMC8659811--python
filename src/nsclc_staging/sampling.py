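"""One-vs-Rest staging with co-occurrence transfer and dynamic sampling.

The four NSCLC stage labels {I, II, III, IV} are learned as four binary
classifiers (one-vs-rest). Two devices target the heavy class imbalance of
real staging cohorts (III/IV-majority, stage I rare):

* **Transfer by co-occurrence** — for a small-sample stage label l_i the
  source stage is the label l_j maximizing the co-occurrence count
  ``F(l_i, l_j) = #{samples whose label set contains both}``; the source
  model's trained parameters initialize the small-sample model.

* **Dynamic sampling** — each binary model is trained iteratively on a
  freshly drawn, approximately balanced block. Sampling probabilities
  start at ``M/(2 Npos)`` for positives and ``M/(2 Nneg)`` for negatives
  (each class then contributes M/2 draws in expectation). After each
  iteration the model scores every sample with its positive-class
  probability eta; probabilities are multiplied by ``exp(1 - eta)`` for
  positives and ``exp(eta)`` for negatives — boosting misclassified and
  low-confidence samples — then each class is renormalized back to sum
  M/2 and capped at 1 (a probability compared to a uniform [0,1) draw is
  operationally 1 beyond that).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from ._rng import stream, spawn_seed
from .cnn import TextCNNClassifier
from .records import STAGES

__all__ = [
    "OvRDataset",
    "SamplingState",
    "ovr_split",
    "cooccurrence",
    "select_source_label",
    "init_sampling_probs",
    "sample_balanced",
    "update_sampling_probs",
    "train_with_dynamic_sampling",
    "DynamicSamplingStager",
]

# fixed tie-break order: later (larger-sample, in practice) stages first
_STAGE_PRIORITY = {"IV": 0, "III": 1, "II": 2, "I": 3}


@dataclass
class OvRDataset:
    """One binary (one-vs-rest) view of a multi-label dataset."""

    label: str
    features: np.ndarray          # (N, ...) feature array, row-aligned
    positive: np.ndarray          # (N,) boolean mask: label in sample's set

    def __post_init__(self):
        self.positive = np.asarray(self.positive, dtype=bool)
        if len(self.features) != len(self.positive):
            raise ValueError("features and mask lengths differ")

    @property
    def n_pos(self) -> int:
        return int(self.positive.sum())

    @property
    def n_neg(self) -> int:
        return int((~self.positive).sum())

    def __len__(self) -> int:
        return len(self.positive)


@dataclass
class SamplingState:
    """Per-sample inclusion probabilities for one OvR label at iteration t."""

    probs: np.ndarray             # (N,) in [0, 1]
    positive: np.ndarray          # (N,) boolean mask
    M: int                        # target block size (M/2 per class)
    t: int = 1
    rng: np.random.Generator = field(
        default_factory=lambda: np.random.default_rng(0))


def ovr_split(
    features: Sequence, label_sets: Sequence[set], labels: Sequence[str] = STAGES
) -> dict[str, OvRDataset]:
    """Split a multi-label dataset into one binary dataset per label.

    Every sample appears in every label's dataset, positive iff the label
    is in its label set (so |pos| + |neg| = N for each label).
    """
    if len(features) == 0:
        raise ValueError("dataset is empty")
    feats = np.asarray(features, dtype=float)
    return {
        li: OvRDataset(li, feats, np.array([li in y for y in label_sets]))
        for li in labels
    }


def cooccurrence(
    label_sets: Sequence[set], labels: Sequence[str] = STAGES
) -> pd.DataFrame:
    """Label co-occurrence counts F(l_i, l_j).

    F(l_i, l_j) is the number of samples whose label set contains both l_i
    and l_j; the diagonal F(l_i, l_i) counts samples containing l_i. F is
    symmetric by construction.
    """
    labels = list(labels)
    F = np.zeros((len(labels), len(labels)), dtype=int)
    for y in label_sets:
        present = [k for k, li in enumerate(labels) if li in y]
        for a in present:
            for b in present:
                F[a, b] += 1
    return pd.DataFrame(F, index=labels, columns=labels)


def select_source_label(
    F: pd.DataFrame, li: str, sizes: Mapping[str, int]
) -> str:
    """Transfer source for label ``li``: the other label with the largest
    co-occurrence count F(li, .).

    Ties are broken by the larger positive-sample count, then by the fixed
    stage order IV > III > II > I. If every off-diagonal count is zero
    (strictly single-label data), falls back to the label with the largest
    positive-sample count.
    """
    others = [lj for lj in F.columns if lj != li]
    counts = {lj: int(F.loc[li, lj]) for lj in others}
    if max(counts.values()) > 0:
        key = lambda lj: (-counts[lj], -sizes.get(lj, 0), _STAGE_PRIORITY[lj])
    else:
        key = lambda lj: (-sizes.get(lj, 0), _STAGE_PRIORITY[lj])
    return min(others, key=key)


def init_sampling_probs(
    ds: OvRDataset, M: int, rng: np.random.Generator | None = None
) -> SamplingState:
    """Initial inclusion probabilities: M/(2 Npos) per positive and
    M/(2 Nneg) per negative, capped at 1, so each class contributes M/2
    draws in expectation (exactly M/2 when uncapped)."""
    if M < 2:
        raise ValueError("block size M must be >= 2")
    if ds.n_pos == 0 or ds.n_neg == 0:
        raise ValueError(
            f"label {ds.label}: both classes must be non-empty to balance "
            f"(Npos={ds.n_pos}, Nneg={ds.n_neg})")
    probs = np.where(ds.positive, M / (2.0 * ds.n_pos), M / (2.0 * ds.n_neg))
    return SamplingState(
        probs=np.minimum(probs, 1.0),
        positive=ds.positive.copy(),
        M=M,
        t=1,
        rng=rng if rng is not None else np.random.default_rng(0),
    )


def sample_balanced(
    ds: OvRDataset, state: SamplingState
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one training block: sample j is included iff its uniform draw
    R(x_j) <= P_t(j). Returns (selected indices, selected-positive mask)."""
    if len(state.probs) != len(ds):
        raise ValueError("sampling state does not match dataset size")
    draws = state.rng.random(len(ds))
    included = draws <= state.probs
    idx = np.flatnonzero(included)
    return idx, state.positive[idx]


def update_sampling_probs(
    state: SamplingState, eta: np.ndarray
) -> SamplingState:
    """One multiplicative update + per-class renormalization + cap.

    Positives are multiplied by exp(1 - eta), negatives by exp(eta) (low
    confidence or misclassification raises the inclusion probability);
    each class is then rescaled to sum M/2 and entries are capped at 1.
    """
    eta = np.asarray(eta, dtype=float)
    if eta.shape != state.probs.shape:
        raise ValueError("eta must have one entry per sample")
    if np.any((eta < 0) | (eta > 1)):
        raise ValueError("eta entries must lie in [0, 1]")
    pos = state.positive
    p = state.probs * np.where(pos, np.exp(1.0 - eta), np.exp(eta))
    sum_pos = p[pos].sum()
    sum_neg = p[~pos].sum()
    if sum_pos <= 0 or sum_neg <= 0:
        raise ValueError("degenerate sampling state: a class sums to zero")
    p[pos] *= state.M / (2.0 * sum_pos)
    p[~pos] *= state.M / (2.0 * sum_neg)
    return replace(state, probs=np.minimum(p, 1.0), t=state.t + 1)


def train_with_dynamic_sampling(
    ds: OvRDataset,
    model: TextCNNClassifier,
    n_iterations: int,
    M: int,
    seed: int,
    inner_epochs: int = 1,
    max_resample: int = 10,
) -> tuple[TextCNNClassifier, pd.DataFrame]:
    """Iterative dynamic-sampling training of one OvR binary model.

    Each of the ``n_iterations`` rounds draws a fresh approximately
    balanced block, runs ``inner_epochs`` SGD epochs on it (continuing
    from the current parameters — or from the transferred source
    parameters if ``model`` carries ``init_weights``), scores all N
    samples in evaluation mode, and updates the sampling probabilities.
    An empty draw is retried up to ``max_resample`` times.

    Returns the final model and a per-iteration log (iteration, block
    composition, training loss, mean eta per class, probability sums).
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    model.initialize(np.asarray(ds.features).shape[-1])
    state = init_sampling_probs(ds, M, rng=stream(seed, "dynamic-sampling"))
    y_all = ds.positive.astype(int)
    rows = []
    for it in range(1, n_iterations + 1):
        for attempt in range(max_resample + 1):
            idx, pos_sel = sample_balanced(ds, state)
            if len(idx) > 0:
                break
        else:
            raise RuntimeError(
                f"label {ds.label}: empty training block after "
                f"{max_resample} resampling attempts")
        model.train_epochs(ds.features[idx], y_all[idx], inner_epochs)
        eta = model.positive_probability(ds.features)
        rows.append({
            "iteration": it,
            "n_pos_drawn": int(pos_sel.sum()),
            "n_neg_drawn": int(len(idx) - pos_sel.sum()),
            "loss": model.loss(ds.features[idx], y_all[idx]),
            "mean_eta_pos": float(eta[ds.positive].mean()),
            "mean_eta_neg": float(eta[~ds.positive].mean()),
            "sum_p_pos": float(state.probs[ds.positive].sum()),
            "sum_p_neg": float(state.probs[~ds.positive].sum()),
        })
        if it < n_iterations:
            state = update_sampling_probs(state, eta)
    return model, pd.DataFrame(rows)


class DynamicSamplingStager(BaseEstimator, ClassifierMixin):
    """Four one-vs-rest stage classifiers trained with transfer and
    dynamic sampling over shared document-matrix features.

    ``fit(X, y)`` takes ``X`` as an (N, num, n_dim) array of document
    matrices and ``y`` as a sequence of stage label *sets* (empty set =
    non-NSCLC). Labels are trained in descending positive-count order;
    every label after the first is initialized from its co-occurrence-
    selected source model when that source is already trained.

    Parameters mirror :class:`TextCNNClassifier` plus the outer loop:
    ``n_iterations`` (E), ``block_size`` (M; ``None`` = twice the label's
    positive count), ``inner_epochs`` (SGD epochs per iteration), and
    ``dynamic``/``use_transfer`` switches (both on by default; switching
    ``dynamic`` off trains each label on its full binary set for an
    equivalent epoch budget, the plain baseline).
    """

    def __init__(
        self,
        kernel_sizes: Sequence[int] = (3, 4, 5),
        kernels_per_size: int = 1,
        activation: str = "relu",
        dropout: float = 0.5,
        lr: float = 0.05,
        batch_size: int = 32,
        n_iterations: int = 10,
        block_size: int | None = None,
        inner_epochs: int = 1,
        use_transfer: bool = True,
        dynamic: bool = True,
        labels: Sequence[str] = STAGES,
        seed: int = 0,
    ):
        self.kernel_sizes = kernel_sizes
        self.kernels_per_size = kernels_per_size
        self.activation = activation
        self.dropout = dropout
        self.lr = lr
        self.batch_size = batch_size
        self.n_iterations = n_iterations
        self.block_size = block_size
        self.inner_epochs = inner_epochs
        self.use_transfer = use_transfer
        self.dynamic = dynamic
        self.labels = labels
        self.seed = seed

    def _make_cnn(self, label: str, init_weights: dict | None) -> TextCNNClassifier:
        return TextCNNClassifier(
            kernel_sizes=self.kernel_sizes,
            kernels_per_size=self.kernels_per_size,
            activation=self.activation,
            dropout=self.dropout,
            lr=self.lr,
            batch_size=self.batch_size,
            epochs=self.n_iterations * self.inner_epochs,
            init_weights=init_weights,
            seed=spawn_seed(self.seed, f"cnn-{label}"),
        )

    def fit(self, X, y) -> "DynamicSamplingStager":
        X = np.asarray(X, dtype=float)
        label_sets = [set(s) for s in y]
        splits = ovr_split(X, label_sets, self.labels)
        self.cooccurrence_ = cooccurrence(label_sets, self.labels)
        sizes = {li: splits[li].n_pos for li in self.labels}
        order = sorted(self.labels,
                       key=lambda li: (-sizes[li], _STAGE_PRIORITY[li]))
        self.sources_: dict[str, str | None] = {}
        self.models_: dict[str, TextCNNClassifier] = {}
        self.logs_: dict[str, pd.DataFrame] = {}
        for rank, li in enumerate(order):
            init = None
            self.sources_[li] = None
            if self.use_transfer and rank > 0:
                src = select_source_label(self.cooccurrence_, li, sizes)
                if src in self.models_:
                    init = self.models_[src].get_weights()
                    self.sources_[li] = src
            model = self._make_cnn(li, init)
            ds = splits[li]
            M = self.block_size if self.block_size is not None else 2 * ds.n_pos
            if self.dynamic:
                model, log = train_with_dynamic_sampling(
                    ds, model, self.n_iterations, M,
                    seed=spawn_seed(self.seed, f"sampling-{li}"),
                    inner_epochs=self.inner_epochs,
                )
            else:
                model.initialize(X.shape[2])
                model.train_epochs(ds.features, ds.positive.astype(int),
                                   self.n_iterations * self.inner_epochs)
                log = pd.DataFrame()
            self.models_[li] = model
            self.logs_[li] = log
        return self

    def predict_confidences(self, X) -> pd.DataFrame:
        """Per-stage positive-class probabilities eta (columns = labels)."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(
            {li: self.models_[li].positive_probability(X) for li in self.labels}
        )

    def predict(self, X) -> list[str]:
        """Highest-confidence stage per document ("healthy" when every
        stage confidence is below 0.5)."""
        conf = self.predict_confidences(X)
        out = []
        for _, row in conf.iterrows():
            if row.max() < 0.5:
                out.append("healthy")
            else:
                best = min((li for li in self.labels if row[li] == row.max()),
                           key=lambda li: _STAGE_PRIORITY[li])
                out.append(best)
        return out

    def _check_fitted(self):
        if not hasattr(self, "models_"):
            raise RuntimeError("DynamicSamplingStager is not fitted")
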