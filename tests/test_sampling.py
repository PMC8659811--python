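"""One-vs-rest split, co-occurrence transfer selection, dynamic sampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nsclc_staging import (
    OvRDataset,
    TextCNNClassifier,
    cooccurrence,
    init_sampling_probs,
    ovr_split,
    sample_balanced,
    select_source_label,
    train_with_dynamic_sampling,
    update_sampling_probs,
    DynamicSamplingStager,
)

from conftest import make_separable_docs


def _features(n):
    return np.zeros((n, 4, 2))


# -- one-vs-rest split -------------------------------------------------------

def test_multilabel_sample_is_positive_in_both_sets():
    label_sets = [{"III", "IV"}, {"I"}, set()]
    splits = ovr_split(_features(3), label_sets)
    assert splits["III"].positive[0] and splits["IV"].positive[0]
    assert not splits["II"].positive[0]


def test_empty_label_set_is_negative_everywhere():
    splits = ovr_split(_features(2), [set(), {"II"}])
    assert all(not splits[li].positive[0] for li in splits)


def test_split_partitions_every_label():
    label_sets = [{"I"}, {"II", "III"}, set(), {"IV"}, {"III"}]
    splits = ovr_split(_features(5), label_sets)
    for li, ds in splits.items():
        assert ds.n_pos + ds.n_neg == 5


# -- co-occurrence -----------------------------------------------------------

def test_single_label_data_has_zero_offdiagonal():
    F = cooccurrence([{"I"}, {"II"}, {"IV"}, {"IV"}])
    off = F.values[~np.eye(4, dtype=bool)]
    assert np.all(off == 0)


def test_cooccurrence_worked_example():
    F = cooccurrence([{"III", "IV"}, {"III", "IV"}, {"IV"}])
    assert F.loc["III", "IV"] == 2
    assert F.loc["IV", "IV"] == 3
    assert F.loc["III", "III"] == 2


def _brute_force_counts(label_sets, labels):
    F = pd.DataFrame(0, index=labels, columns=labels)
    for li in labels:
        for lj in labels:
            F.loc[li, lj] = sum(1 for y in label_sets if li in y and lj in y)
    return F


def test_cooccurrence_matches_exhaustive_pair_count():
    rng = np.random.default_rng(42)
    labels = ["I", "II", "III", "IV"]
    for _ in range(100):
        n = int(rng.integers(1, 100))
        sets = [{l for l in labels if rng.random() < 0.3} for _ in range(n)]
        F = cooccurrence(sets)
        assert F.equals(_brute_force_counts(sets, labels))
        assert np.array_equal(F.values, F.values.T)


# -- source selection --------------------------------------------------------

def _F(rows):
    return pd.DataFrame(rows, index=["I", "II", "III", "IV"],
                        columns=["I", "II", "III", "IV"])


def test_source_selection_tie_broken_by_sample_count():
    F = _F([[20, 5, 9, 9], [5, 0, 0, 0], [9, 0, 0, 0], [9, 0, 0, 0]])
    sizes = {"II": 50, "III": 300, "IV": 500}
    assert select_source_label(F, "I", sizes) == "IV"


def test_source_selection_unique_argmax():
    F = _F([[20, 5, 9, 2], [5, 0, 0, 0], [9, 0, 0, 0], [2, 0, 0, 0]])
    assert select_source_label(F, "I", {"II": 1, "III": 1, "IV": 1}) == "III"


def test_source_selection_fallback_to_largest_class():
    F = _F(np.diag([10, 20, 300, 500]))
    sizes = {"I": 10, "II": 20, "III": 300, "IV": 500}
    assert select_source_label(F, "I", sizes) == "IV"


# -- sampling-probability initialization -------------------------------------

def _ovr(n_pos, n_neg, label="I"):
    mask = np.zeros(n_pos + n_neg, dtype=bool)
    mask[:n_pos] = True
    return OvRDataset(label, _features(n_pos + n_neg), mask)


def test_init_probs_direct_arithmetic():
    state = init_sampling_probs(_ovr(20, 80), M=20)
    assert np.allclose(state.probs[:20], 0.5)
    assert np.allclose(state.probs[20:], 0.125)
    assert state.t == 1


def test_init_probs_capped_at_one():
    state = init_sampling_probs(_ovr(10, 100), M=100)  # raw positives 5.0
    assert np.all(state.probs[:10] == 1.0)


def test_init_probs_boundary_all_ones():
    state = init_sampling_probs(_ovr(10, 10), M=20)
    assert np.all(state.probs == 1.0)


def test_init_probs_degenerate_classes_error():
    with pytest.raises(ValueError):
        init_sampling_probs(_ovr(0, 10), M=4)
    with pytest.raises(ValueError):
        init_sampling_probs(_ovr(10, 0), M=4)
    with pytest.raises(ValueError):
        init_sampling_probs(_ovr(5, 5), M=1)


# -- balanced block drawing --------------------------------------------------

def test_probability_one_draws_everything():
    ds = _ovr(5, 5)
    state = init_sampling_probs(ds, M=10, rng=np.random.default_rng(0))
    idx, pos_sel = sample_balanced(ds, state)
    assert len(idx) == 10 and pos_sel.sum() == 5


def test_probability_zero_draws_nothing():
    ds = _ovr(5, 5)
    state = init_sampling_probs(ds, M=10, rng=np.random.default_rng(0))
    state.probs[:] = 0.0
    idx, _ = sample_balanced(ds, state)
    assert len(idx) == 0


def test_expected_class_draws_are_half_block():
    # uncapped regime: each class contributes M/2 draws in expectation
    ds = _ovr(50, 200)
    state = init_sampling_probs(ds, M=40, rng=np.random.default_rng(1))
    reps = 2000
    pos_counts, neg_counts = [], []
    for _ in range(reps):
        idx, pos_sel = sample_balanced(ds, state)
        pos_counts.append(int(pos_sel.sum()))
        neg_counts.append(int(len(idx) - pos_sel.sum()))
    p = state.probs
    for counts, mask in ((pos_counts, state.positive), (neg_counts, ~state.positive)):
        var = float((p[mask] * (1 - p[mask])).sum())
        sigma_mean = np.sqrt(var / reps)
        assert abs(np.mean(counts) - 20.0) <= 3 * sigma_mean


# -- probability updates -----------------------------------------------------

def test_update_boundary_multipliers():
    ds = _ovr(2, 2)
    state = init_sampling_probs(ds, M=2, rng=np.random.default_rng(0))
    # positive with eta=1 -> exp(0)=1; positive with eta=0 -> e
    new = update_sampling_probs(state, np.array([1.0, 0.0, 0.5, 0.5]))
    pre_norm = state.probs[:2] * np.array([1.0, np.e])
    ratio = new.probs[0] / new.probs[1]
    assert ratio == pytest.approx(pre_norm[0] / pre_norm[1])
    assert ratio == pytest.approx(np.exp(-1.0))
    assert new.t == state.t + 1


def test_update_ratio_closed_form():
    # two positives, equal prior, eta 0.2 vs 0.8: posterior ratio exp(0.6),
    # preserved by the per-class renormalization
    ds = _ovr(4, 4)
    state = init_sampling_probs(ds, M=4, rng=np.random.default_rng(0))
    new = update_sampling_probs(
        state, np.array([0.2, 0.8, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5]))
    assert np.all(new.probs < 1.0)  # cap inactive, ratio exactly preserved
    assert new.probs[0] / new.probs[1] == pytest.approx(np.exp(0.6))


@settings(max_examples=30, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=12, max_size=12))
def test_conservation_invariant_uncapped(etas):
    # uncapped regime: after update + renormalize, each class sums to M/2
    ds = _ovr(4, 8)
    state = init_sampling_probs(ds, M=4, rng=np.random.default_rng(0))
    new = update_sampling_probs(state, np.array(etas))
    if np.all(new.probs < 1.0):  # no cap active
        assert new.probs[:4].sum() == pytest.approx(2.0, rel=1e-9)
        assert new.probs[4:].sum() == pytest.approx(2.0, rel=1e-9)


def test_monotone_attention():
    # equal priors: lower eta => strictly higher posterior for positives,
    # higher eta => strictly higher posterior for negatives
    ds = _ovr(3, 3)
    state = init_sampling_probs(ds, M=2, rng=np.random.default_rng(0))
    new = update_sampling_probs(
        state, np.array([0.1, 0.5, 0.9, 0.1, 0.5, 0.9]))
    assert new.probs[0] > new.probs[1] > new.probs[2]
    assert new.probs[3] < new.probs[4] < new.probs[5]


def test_update_rejects_bad_eta_and_degenerate_state():
    ds = _ovr(2, 2)
    state = init_sampling_probs(ds, M=2, rng=np.random.default_rng(0))
    with pytest.raises(ValueError):
        update_sampling_probs(state, np.array([0.5, 0.5, 0.5, 1.5]))
    state.probs[:] = 0.0
    with pytest.raises(ValueError):
        update_sampling_probs(state, np.full(4, 0.5))


# -- iterative training ------------------------------------------------------

def test_single_iteration_full_probability_reduces_to_plain_round():
    X, y = make_separable_docs(10, 10, seed=5)
    mask = y.astype(bool)
    ds = OvRDataset("I", X, mask)
    dyn = TextCNNClassifier(dropout=0.0, seed=7, epochs=0)
    # M = N makes every initial probability exactly 1: the drawn block is
    # the full set, so one iteration is one plain epoch on the full set
    model, log = train_with_dynamic_sampling(ds, dyn, n_iterations=1, M=20, seed=1)
    plain = TextCNNClassifier(dropout=0.0, seed=7, epochs=0)
    plain.initialize(X.shape[2])
    plain.train_epochs(X, y, 1)
    for (wa, ba), (wb, bb) in zip(model.kernels_, plain.kernels_):
        assert np.array_equal(wa, wb) and ba == bb
    assert log.iloc[0]["n_pos_drawn"] == 10 and log.iloc[0]["n_neg_drawn"] == 10


def test_dynamic_training_deterministic_and_logged():
    X, y = make_separable_docs(8, 40, seed=6)
    ds = OvRDataset("I", X, y.astype(bool))
    run = lambda: train_with_dynamic_sampling(
        ds, TextCNNClassifier(dropout=0.0, seed=2, epochs=0),
        n_iterations=5, M=16, seed=9)
    m1, log1 = run()
    m2, log2 = run()
    assert np.array_equal(m1.fc_weights_, m2.fc_weights_)
    assert log1.equals(log2)
    assert list(log1.columns) == [
        "iteration", "n_pos_drawn", "n_neg_drawn", "loss",
        "mean_eta_pos", "mean_eta_neg", "sum_p_pos", "sum_p_neg"]
    assert len(log1) == 5


def test_stager_trains_all_labels_with_transfer_chain(small_cohort):
    from nsclc_staging import SkipgramEmbedding, render_text
    corpus = [render_text(r) for r in small_cohort]
    emb = SkipgramEmbedding(n_dim=8, epochs=2, max_len=16, seed=0).fit(corpus)
    X = emb.transform(corpus)
    y = [r.stages for r in small_cohort]
    stager = DynamicSamplingStager(n_iterations=3, seed=5).fit(X, y)
    assert set(stager.models_) == {"I", "II", "III", "IV"}
    # the largest-sample label trains from scratch; the others transfer
    assert sum(src is None for src in stager.sources_.values()) == 1
    conf = stager.predict_confidences(X[:10])
    assert conf.shape == (10, 4)
    assert ((conf.values >= 0) & (conf.values <= 1)).all()
    preds = stager.predict(X[:10])
    assert all(p in ("healthy", "I", "II", "III", "IV") for p in preds)
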