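import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enosewilks.exceptions import InsufficientDataError
from enosewilks.pnn import (
    DEFAULT_SPREAD_GRID,
    ConfusionMatrix,
    evaluate,
    predict,
    split_first_k,
    spread_grid_search,
    train_pnn,
)
from enosewilks.reference import (
    RICE_CLASSES,
    RICE_CONFUSION_PC1_PC2,
    RICE_CONFUSION_PC1_PC5,
)


def test_one_pattern_neuron_per_training_sample(rng):
    X = rng.normal(size=(90, 2))
    labels = [f"c{g}" for g in range(6) for _ in range(15)]
    model = train_pnn(X, labels, spread=1e-4)
    assert model.n_patterns == 90
    model6 = train_pnn(np.eye(6), [f"c{g}" for g in range(6)], spread=0.1)
    assert model6.n_patterns == 6


def test_spread_must_be_positive(rng):
    with pytest.raises(ValueError):
        train_pnn(rng.normal(size=(4, 2)), ["a", "a", "b", "b"], spread=0.0)


def test_zero_norm_pattern_rejected_under_dot_product():
    X = np.array([[0.0, 0.0], [1.0, 1.0]])
    with pytest.raises(ValueError, match="zero-norm"):
        train_pnn(X, ["a", "b"], spread=0.1, kernel="dot_product")


@pytest.mark.parametrize("kernel", ["dot_product", "euclidean"])
def test_query_on_training_pattern_at_tiny_spread_recovers_its_class(rng, kernel):
    X = rng.normal(size=(12, 3))
    labels = ["a", "b", "c"] * 4
    model = train_pnn(X, labels, spread=1e-6, kernel=kernel)
    for i in (0, 5, 11):
        assert predict(model, X[i]).class_label == labels[i]


def test_two_pattern_hand_computed_gaussians():
    """1-D euclidean kernel: class scores match the two-term hand calculation."""
    X = np.array([[0.0], [2.0]])
    model = train_pnn(X, ["A", "B"], spread=1.0, kernel="euclidean")
    pred = predict(model, [0.5])
    expected_a = np.exp(-0.25 / 2.0)
    expected_b = np.exp(-2.25 / 2.0)
    np.testing.assert_allclose(pred.class_scores, [expected_a, expected_b], rtol=1e-12)
    assert pred.class_label == "A"
    assert not pred.tie


def test_equidistant_query_ties_to_lower_class_index():
    X = np.array([[0.0], [2.0]])
    model = train_pnn(X, ["A", "B"], spread=0.5, kernel="euclidean")
    pred = predict(model, [1.0])
    assert pred.tie
    assert pred.class_index == 0


def test_dot_product_activations_bounded_by_one(rng):
    X = rng.normal(size=(10, 4))
    labels = ["a", "b"] * 5
    model = train_pnn(X, labels, spread=0.7, kernel="dot_product")
    from enosewilks.pnn import _activations

    act = _activations(model, rng.normal(size=(5, 4)))
    assert np.all(act > 0.0) and np.all(act <= 1.0 + 1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 100_000), kernel=st.sampled_from(["dot_product", "euclidean"]))
def test_small_spread_limit_is_nearest_neighbour(seed, kernel):
    """As spread -> 0 the PNN decision matches 1-NN in the kernel's metric."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(12, 3))
    labels = ["a", "b", "c"] * 4
    model = train_pnn(X, labels, spread=1e-8, kernel=kernel)
    P = model.patterns
    for q in rng.normal(size=(6, 3)):
        pred = predict(model, q)
        if kernel == "dot_product":
            qn = q / np.linalg.norm(q)
            nn = int(np.argmax(P @ qn))
        else:
            nn = int(np.argmin(((P - q) ** 2).sum(axis=1)))
        if not pred.tie:
            assert pred.class_index == model.pattern_class[nn]


def test_large_spread_limit_gives_class_counts(rng):
    """As spread -> inf every activation tends to 1, so class scores tend to
    the per-class pattern counts."""
    X = rng.normal(size=(9, 2))
    labels = ["a"] * 2 + ["b"] * 3 + ["c"] * 4
    model = train_pnn(X, labels, spread=1e6, kernel="euclidean")
    pred = predict(model, rng.normal(size=2))
    np.testing.assert_allclose(pred.class_scores, [2.0, 3.0, 4.0], rtol=1e-6)


def test_permuting_training_samples_never_changes_predictions(rng):
    X = rng.normal(size=(15, 2))
    labels = ["a", "b", "c"] * 5
    queries = rng.normal(size=(8, 2))
    m1 = train_pnn(X, labels, spread=0.3, kernel="euclidean")
    perm = rng.permutation(15)
    m2 = train_pnn(X[perm], [labels[i] for i in perm], spread=0.3, kernel="euclidean")
    for q in queries:
        assert predict(m1, q).class_label == predict(m2, q).class_label


def test_accuracy_of_published_confusion_matrices():
    """Printed test-set matrices give 90% (PC1/PC2) and 96.67% (PC1/PC5)."""
    cm12 = ConfusionMatrix(RICE_CONFUSION_PC1_PC2, RICE_CLASSES)
    cm15 = ConfusionMatrix(RICE_CONFUSION_PC1_PC5, RICE_CLASSES)
    assert round(cm12.accuracy_pct, 2) == 90.00
    assert round(cm15.accuracy_pct, 2) == 96.67
    assert cm12.total == cm15.total == 30
    np.testing.assert_array_equal(cm12.counts.sum(axis=1), [5] * 6)


def test_perfect_prediction_gives_diagonal_matrix(rng):
    X = np.array([[0.0, 0.0], [0.1, 0.0], [5.0, 5.0], [5.1, 5.0]])
    labels = ["a", "a", "b", "b"]
    model = train_pnn(X, labels, spread=0.1, kernel="euclidean")
    cm, acc = evaluate(model, X, labels)
    assert acc == pytest.approx(100.0)
    np.testing.assert_array_equal(cm.counts, [[2, 0], [0, 2]])


def test_evaluate_rejects_unseen_labels(rng):
    X = rng.normal(size=(4, 2))
    model = train_pnn(X, ["a", "a", "b", "b"], spread=0.1, kernel="euclidean")
    with pytest.raises(ValueError, match="unseen"):
        evaluate(model, X[:1], ["zzz"])


def test_split_first_k_takes_per_class_heads():
    X = np.arange(20.0).reshape(10, 2)
    labels = ["a"] * 5 + ["b"] * 5
    X_tr, y_tr, X_te, y_te = split_first_k(X, labels, n_train_per_class=3)
    assert y_tr == ["a"] * 3 + ["b"] * 3
    assert y_te == ["a"] * 2 + ["b"] * 2
    np.testing.assert_array_equal(X_tr[0], [0.0, 1.0])
    np.testing.assert_array_equal(X_te[0], [6.0, 7.0])


def test_default_grid_is_ten_values_1e5_to_1e4():
    np.testing.assert_allclose(DEFAULT_SPREAD_GRID, np.arange(1, 11) * 1e-5)


def test_grid_search_single_value_and_tie_selection(rng):
    X = np.array([[0.0, 0.0], [0.1, 0.1], [5.0, 5.0], [5.1, 5.1]])
    labels = ["a", "a", "b", "b"]
    res = spread_grid_search(X, labels, X, labels, grid=[0.2], kernel="euclidean")
    assert res["selected_spread"] == 0.2
    # a cleanly separable set reaches 100/100 at both grid points; the rule
    # must return the smaller spread
    res2 = spread_grid_search(X, labels, X, labels, grid=[1e-5, 1e-4],
                              kernel="euclidean")
    assert all(r["train_acc"] == 100.0 and r["test_acc"] == 100.0 for r in res2["grid"])
    assert res2["selected_spread"] == 1e-5


def test_empty_test_set_rejected(rng):
    X = rng.normal(size=(4, 2))
    model = train_pnn(X, ["a", "a", "b", "b"], spread=0.1, kernel="euclidean")
    with pytest.raises(InsufficientDataError):
        evaluate(model, np.empty((0, 2)), [])
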