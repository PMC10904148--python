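import warnings

import numpy as np
import pytest

from graphannot import (
    ClassifierConfig,
    ClassifierParams,
    LabelTable,
    Split,
    cross_entropy,
    evaluate,
    forward,
    train_classifier,
)
from graphannot.classify import _backward, _forward_cached, init_params
from graphannot.errors import ValidationError


def _table(codes, n_types):
    ids = np.array([f"c{i}" for i in range(len(codes))], dtype=object)
    return LabelTable(ids, [f"t{i}" for i in range(n_types)], np.asarray(codes))


class TestForward:
    def test_zero_output_weights_give_uniform_rows(self):
        rng = np.random.default_rng(0)
        S = np.eye(5)
        X = rng.random((5, 3))
        params = ClassifierParams(W1=rng.normal(size=(3, 4)), W2=np.zeros((4, 3)))
        probs = forward(S, X, params)
        np.testing.assert_allclose(probs, 1.0 / 3.0)

    def test_rows_on_simplex_for_random_params(self):
        rng = np.random.default_rng(1)
        S = rng.random((6, 6))
        S = (S + S.T) / 2
        S /= S.sum(axis=1, keepdims=True)
        probs = forward(S, rng.random((6, 4)), init_params(4, 5, 3, seed=2))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0) and np.all(probs <= 1)

    def test_hand_instance_with_both_hops(self):
        S = np.array([[0.5, 0.5], [0.5, 0.5]])
        X = np.array([[2.0, 0.0], [0.0, 4.0]])
        W1 = np.array([[1.0, -1.0], [0.5, 1.0]])
        W2 = np.array([[1.0, 0.0], [0.0, 1.0]])
        # S X = [[1, 2], [1, 2]]; hidden pre-act = [[2, 1], [2, 1]] -> ReLU same
        # second hop: S H1 = [[2, 1], [2, 1]]; logits U = same; softmax rows
        expected_row = np.exp([2.0, 1.0]) / np.exp([2.0, 1.0]).sum()
        probs = forward(S, X, ClassifierParams(W1, W2))
        np.testing.assert_allclose(probs, np.tile(expected_row, (2, 1)), atol=1e-12)

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(3)
        m, n, h, c = 7, 5, 4, 3
        S = rng.random((m, m))
        S = (S + S.T) / 2
        S /= S.sum(axis=1, keepdims=True)
        X = rng.random((m, n))
        params = init_params(n, h, c, seed=4)
        codes = rng.integers(0, c, m)
        batch = np.array([0, 2, 5])
        probs, cache = _forward_cached(S, X, params)
        dW1, dW2 = _backward(S, X, params, cache, probs, codes, batch)

        def loss_of(W1, W2):
            p, _ = _forward_cached(S, X, ClassifierParams(W1, W2))
            return cross_entropy(p, codes, batch)

        eps = 1e-6
        for W, dW, which in ((params.W1, dW1, "W1"), (params.W2, dW2, "W2")):
            numeric = np.zeros_like(W)
            it = np.nditer(W, flags=["multi_index"])
            while not it.finished:
                idx = it.multi_index
                Wp, Wm = W.copy(), W.copy()
                Wp[idx] += eps
                Wm[idx] -= eps
                if which == "W1":
                    numeric[idx] = (loss_of(Wp, params.W2) - loss_of(Wm, params.W2)) / (2 * eps)
                else:
                    numeric[idx] = (loss_of(params.W1, Wp) - loss_of(params.W1, Wm)) / (2 * eps)
                it.iternext()
            np.testing.assert_allclose(dW, numeric, atol=1e-7)


class TestCrossEntropy:
    def test_perfect_prediction_zero_loss(self):
        probs = np.eye(3)
        assert cross_entropy(probs, np.array([0, 1, 2]), np.arange(3)) == pytest.approx(0.0)

    def test_uniform_prediction_four_classes(self):
        probs = np.full((3, 4), 0.25)
        loss = cross_entropy(probs, np.array([0, 1, 2]), np.arange(3))
        assert loss == pytest.approx(3 * np.log(4), abs=1e-12)  # ~4.15888

    def test_non_negative(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(3), size=5)
        assert cross_entropy(probs, rng.integers(0, 3, 5), np.arange(5)) >= 0.0

    def test_chance_level_loss_at_initialization(self):
        # balanced random data: initial loss within 10% of |B| log c
        rng = np.random.default_rng(5)
        m, n, c = 40, 10, 4
        S = np.eye(m)
        X = rng.random((m, n))
        params = init_params(n, 8, c, seed=6)
        params.W1 *= 0.1
        params.W2 *= 0.1
        codes = np.tile(np.arange(c), m // c)
        probs = forward(S, X, params)
        loss = cross_entropy(probs, codes, np.arange(m))
        assert abs(loss - m * np.log(c)) <= 0.1 * m * np.log(c)


class TestEvaluate:
    def test_perfect_classifier(self):
        probs = np.eye(3)
        metrics = evaluate(probs, _table([0, 1, 2], 3), np.arange(3))
        assert metrics["accuracy"] == 1.0
        assert metrics["macro_f1"] == 1.0
        assert metrics["macro_auc"] == 1.0

    def test_hand_confusion_matrix(self):
        # truth (A, A, B), predictions (A, B, B): acc 2/3, per-class F1 both 2/3
        probs = np.array([[0.9, 0.1], [0.2, 0.8], [0.3, 0.7]])
        metrics = evaluate(probs, _table([0, 0, 1], 2), np.arange(3))
        assert metrics["accuracy"] == pytest.approx(2 / 3)
        assert metrics["macro_f1"] == pytest.approx(2 / 3)

    def test_random_probabilities_near_chance_auc(self):
        rng = np.random.default_rng(7)
        m = 4000
        probs = rng.dirichlet(np.ones(3), size=m)
        codes = rng.integers(0, 3, m)
        metrics = evaluate(probs, _table(codes, 3), np.arange(m))
        assert metrics["macro_auc"] == pytest.approx(0.5, abs=0.05)

    def test_absent_class_excluded_with_warning(self):
        probs = np.array([[0.6, 0.3, 0.1], [0.2, 0.7, 0.1]])
        with pytest.warns(UserWarning, match="absent"):
            metrics = evaluate(probs, _table([0, 1, 2], 3), np.array([0, 1]))
        assert metrics["accuracy"] == 1.0


class TestTraining:
    def test_deterministic_given_seed(self, tiny_chain):
        X, truth, split = tiny_chain["X"], tiny_chain["truth"], tiny_chain["split"]
        S = tiny_chain["denoised"].values
        cfg = ClassifierConfig(epochs=10, seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, a = train_classifier(S, X.values, truth, split, cfg)
            _, b = train_classifier(S, X.values, truth, split, cfg)
        assert a.metrics == b.metrics
        np.testing.assert_array_equal(a.probabilities, b.probabilities)

    def test_block_structure_with_few_labels_recovers_types(self):
        # block-diagonal propagation aligned with types, well-separated features
        rng = np.random.default_rng(8)
        m, c = 60, 3
        codes = np.repeat(np.arange(c), m // c)
        S = np.zeros((m, m))
        for t in range(c):
            mask = codes == t
            S[np.ix_(mask, mask)] = 1.0 / mask.sum()
        X = np.zeros((m, c))
        X[np.arange(m), codes] = 5.0
        X += rng.random((m, c)) * 0.1
        truth = _table(codes, c)
        train = np.array([0, 20, 40])
        rest = np.setdiff1d(np.arange(m), train)
        split = Split(train=train, validation=rest[::2], test=rest[1::2])
        _, result = train_classifier(
            S, X, truth, split, ClassifierConfig(epochs=200, hidden_dim=10, seed=0)
        )
        assert result.metrics["accuracy"] >= 0.95

    def test_fully_labeled_separable_instance_reaches_training_accuracy_one(self):
        codes = np.repeat([0, 1], 10)
        X = np.zeros((20, 2))
        X[np.arange(20), codes] = 3.0
        split = Split(
            train=np.arange(20),
            validation=np.array([], dtype=int),
            test=np.arange(20),
        )
        _, result = train_classifier(
            np.eye(20), X, _table(codes, 2), split,
            ClassifierConfig(epochs=60, hidden_dim=4, learning_rate=0.05, seed=1),
        )
        assert result.metrics["accuracy"] == 1.0

    def test_empty_train_split_rejected(self, tiny_chain):
        split = Split(
            train=np.array([], dtype=int),
            validation=np.array([0]),
            test=np.array([1]),
        )
        with pytest.raises(ValidationError):
            train_classifier(
                tiny_chain["denoised"].values,
                tiny_chain["X"].values,
                tiny_chain["truth"],
                split,
            )

    def test_missing_class_in_train_warns_or_raises(self, tiny_chain):
        truth = tiny_chain["truth"]
        train = np.flatnonzero(truth.codes == 0)[:2]
        rest = np.setdiff1d(np.arange(truth.n_cells), train)
        split = Split(train=train, validation=rest[:5], test=rest[5:10])
        args = (tiny_chain["denoised"].values, tiny_chain["X"].values, truth, split)
        with pytest.warns(UserWarning, match="no labeled train cell"):
            train_classifier(*args, ClassifierConfig(epochs=1))
        with pytest.raises(ValidationError):
            train_classifier(*args, ClassifierConfig(epochs=1, strict_classes=True))
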