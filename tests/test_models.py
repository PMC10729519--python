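"""PLS-DA, SIMCA, LOO component selection, classification metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metabolip import (fit_plsda, predict_plsda, fit_simca, predict_simca,
                       select_components_loo, evaluate, autoscale)


def two_class_toy(n=20, p=5, sep=10.0, seed=0):
    """Two classes separated by `sep` SDs along the first variable."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2), dtype=object)
    X[y == "B", 0] += sep
    Z, mean, sd = autoscale(X)
    return Z, y


class TestPLSDA:
    def test_separated_toy_perfect_training(self):
        Z, y = two_class_toy()
        m = fit_plsda(Z, y, 1)
        pred, _ = predict_plsda(m, Z)
        assert (pred == y).all()

    def test_full_rank_equals_least_squares(self):
        """At full rank PLS2 reproduces the OLS fit on centered one-hot Y."""
        rng = np.random.default_rng(1)
        Z, _, _ = autoscale(rng.normal(size=(20, 6)))
        y = np.array(list("ABC") * 6 + ["A", "B"], dtype=object)
        m = fit_plsda(Z, y, 6)
        Y = np.column_stack([(y == c).astype(float) for c in m.classes])
        B_ols, *_ = np.linalg.lstsq(Z, Y - Y.mean(axis=0), rcond=None)
        np.testing.assert_allclose(Z @ m.coef, Z @ B_ols, atol=1e-8)

    def test_scores_orthogonal(self):
        Z, y = two_class_toy(n=30, p=8, sep=3.0, seed=2)
        m = fit_plsda(Z, y, 4)
        G = m.x_scores.T @ m.x_scores
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0, atol=1e-8)

    def test_duplicated_samples_same_coefficients(self):
        Z, y = two_class_toy(seed=3)
        m1 = fit_plsda(Z, y, 2)
        m2 = fit_plsda(np.vstack([Z, Z]), np.concatenate([y, y]), 2)
        np.testing.assert_allclose(m1.coef, m2.coef, atol=1e-8)

    def test_column_mean_input_predicts_y_mean(self):
        Z, y = two_class_toy(seed=4)
        m = fit_plsda(Z, y, 2)
        _, scores = predict_plsda(m, Z.mean(axis=0))
        np.testing.assert_allclose(scores[0], m.y_mean, atol=1e-10)

    def test_tie_goes_to_lowest_class_index(self):
        Z, y = two_class_toy(seed=5)
        m = fit_plsda(Z, y, 1)
        m.coef[:] = 0.0  # force identical class scores
        m.y_mean[:] = 0.5
        pred, _ = predict_plsda(m, Z[:3])
        assert (pred == m.classes[0]).all()

    def test_single_class_rejected(self):
        Z, _ = two_class_toy()
        with pytest.raises(ValueError):
            fit_plsda(Z, ["A"] * len(Z), 1)

    def test_ss_bookkeeping_bounded(self):
        Z, y = two_class_toy(n=30, p=8, sep=2.0, seed=6)
        m = fit_plsda(Z, y, 5)
        Y = np.column_stack([(y == c).astype(float) for c in m.classes])
        total = ((Y - Y.mean(axis=0)) ** 2).sum()
        assert m.ss_y.sum() <= total + 1e-8

    def test_against_sklearn_reference(self):
        """Cross-check predictions with an independent PLS2 implementation."""
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        Z, y = two_class_toy(n=24, p=6, sep=2.0, seed=7)
        m = fit_plsda(Z, y, 3)
        Y = np.column_stack([(y == c).astype(float) for c in m.classes])
        ref = sklearn.PLSRegression(n_components=3, scale=False).fit(Z, Y)
        np.testing.assert_allclose(Z @ m.coef + m.y_mean, ref.predict(Z),
                                   atol=1e-6)


class TestSIMCA:
    def three_class_toy(self, n_per=30, p=6, sep=8.0, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(3 * n_per, p))
        y = np.array(["A"] * n_per + ["B"] * n_per + ["C"] * n_per,
                     dtype=object)
        X[y == "B", 0] += sep
        X[y == "C", 1] += sep
        return X, y

    def test_discriminant_separated_perfect(self):
        X, y = self.three_class_toy()
        m = fit_simca(X, y, n_pcs=2)
        pred = predict_simca(m, X, "discriminant")
        assert (pred == y).all()

    def test_discriminant_emits_one_label_per_sample(self):
        X, y = self.three_class_toy(seed=1)
        m = fit_simca(X, y, 2)
        pred = predict_simca(m, X, "discriminant")
        assert pred.shape == (len(y),)
        assert set(pred) <= set(m.classes)

    def test_extreme_outlier_rejected_by_all(self):
        X, y = self.three_class_toy(seed=2)
        m = fit_simca(X, y, 2)
        far = np.full((1, X.shape[1]), 100.0)
        accepts = predict_simca(m, far, "class_modelling")
        assert not accepts.any()

    def test_identical_classes_tie_to_lowest(self):
        rng = np.random.default_rng(3)
        Xc = rng.normal(size=(20, 4))
        X = np.vstack([Xc, Xc])
        y = np.array(["A"] * 20 + ["B"] * 20, dtype=object)
        m = fit_simca(X, y, 2)
        D = m.reduced_distances(Xc)
        np.testing.assert_allclose(D[:, 0], D[:, 1], atol=1e-10)
        pred = predict_simca(m, Xc, "discriminant")
        assert (pred == "A").all()

    def test_self_acceptance_near_95pct(self):
        """Fresh draws from a class's own distribution are accepted at
        roughly 1 - alpha by the combined T2/Q distance rule."""
        rng = np.random.default_rng(4)
        A = rng.standard_normal((3, 12))
        def draw(n):
            return (rng.standard_normal((n, 3)) * [4, 2.5, 1.5]) @ A \
                + rng.standard_normal((n, 12)) * 0.4
        X = draw(150)
        y = np.array(["A"] * 150, dtype=object)
        y2 = np.concatenate([y, ["B"] * 10])
        X2 = np.vstack([X, rng.normal(50, 1, size=(10, 12))])
        m = fit_simca(X2, y2, {"A": 3, "B": 2})
        accepts = predict_simca(m, draw(2000), "class_modelling")[:, 0]
        assert 0.90 < accepts.mean() < 0.99

    def test_class_too_small_rejected(self):
        X, y = self.three_class_toy(n_per=4)
        with pytest.raises(ValueError, match="training samples"):
            fit_simca(X, y, 3)


class TestSelectComponentsLOO:
    def test_single_direction_returns_one(self):
        Z, y = two_class_toy(n=16, p=4, sep=10.0)
        k, errors = select_components_loo(Z, y, "plsda", max_components=3)
        assert k == 1
        assert errors[0] == 0

    def test_noise_ties_break_to_parsimony(self):
        rng = np.random.default_rng(1)
        Z, _, _ = autoscale(rng.normal(size=(14, 5)))
        y = np.array(["A", "B"] * 7, dtype=object)
        k, errors = select_components_loo(Z, y, "plsda", max_components=4)
        assert errors[k - 1] == errors.min()
        assert (errors[:k - 1] > errors[k - 1]).all()

    def test_chosen_error_is_minimal(self):
        Z, y = two_class_toy(n=18, p=6, sep=2.0, seed=2)
        k, errors = select_components_loo(Z, y, "plsda", max_components=4)
        assert (errors[k - 1] <= errors).all()

    def test_noise_loo_accuracy_near_chance(self):
        """Pure-noise data: LOO accuracy compatible with coin flipping."""
        rng = np.random.default_rng(3)
        Z, _, _ = autoscale(rng.normal(size=(40, 10)))
        y = np.array(["A", "B"] * 20, dtype=object)
        _, errors = select_components_loo(Z, y, "plsda", max_components=2)
        acc = 1 - errors.min() / 40
        assert acc < 0.8  # 0.8 is ~4 SD above 0.5 for n=40

    def test_simca_fitter_runs(self):
        X, y = TestSIMCA().three_class_toy(n_per=12, sep=8.0, seed=5)
        k, errors = select_components_loo(X, y, "simca", max_components=3)
        assert 1 <= k <= 3
        assert errors[k - 1] == errors.min()


class TestEvaluate:
    def test_hand_counted_example(self):
        m = evaluate(["A", "A", "B", "B"], ["A", "B", "B", "B"])
        assert m.per_class.loc["A", "sensitivity"] == pytest.approx(50.0)
        assert m.per_class.loc["A", "specificity"] == pytest.approx(100.0)
        assert m.accuracy == pytest.approx(75.0)

    def test_perfect_prediction(self):
        m = evaluate(list("ABCABC"), list("ABCABC"))
        assert (m.per_class["sensitivity"] == 100.0).all()
        assert (m.per_class["specificity"] == 100.0).all()
        assert m.accuracy == 100.0

    def test_constant_prediction(self):
        m = evaluate(["A", "A", "B", "B"], ["A", "A", "A", "A"])
        assert m.per_class.loc["A", "sensitivity"] == 100.0
        assert m.per_class.loc["A", "specificity"] == 0.0

    def test_unseen_predicted_label_flagged(self):
        m = evaluate(["A", "B"], ["A", "C"])
        assert m.unseen_predictions == ["C"]
        assert m.confusion.loc["B", "C"] == 1

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.sampled_from("ABC"), st.sampled_from("ABC")),
                    min_size=1, max_size=40))
    def test_metric_identities(self, pairs):
        """TP+FN = class size; confusion total = n; accuracy = trace/n;
        sens/spec follow from the one-vs-rest counts."""
        yt = [a for a, _ in pairs]
        yp = [b for _, b in pairs]
        m = evaluate(yt, yp)
        assert m.confusion.to_numpy().sum() == len(pairs)
        trace = sum(m.confusion.loc[c, c] for c in m.classes
                    if c in m.confusion.columns)
        assert m.accuracy == pytest.approx(100 * trace / len(pairs))
        for c in m.classes:
            row = m.per_class.loc[c]
            assert row["TP"] + row["FN"] == yt.count(c)
            assert row["TP"] + row["FP"] + row["TN"] + row["FN"] == len(pairs)
            if row["TP"] + row["FN"]:
                assert row["sensitivity"] == pytest.approx(
                    100 * row["TP"] / (row["TP"] + row["FN"]))
            if row["TN"] + row["FP"]:
                assert row["specificity"] == pytest.approx(
                    100 * row["TN"] / (row["TN"] + row["FP"]))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            evaluate(["A"], ["A", "B"])
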