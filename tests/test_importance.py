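"""VIP scores, ROC/AUROC, univariate statistics, ORA, reduced refits."""

import numpy as np
import pandas as pd
import pytest

from metabolip import (fit_plsda, vip_scores, roc_curve, univariate_anova,
                       age_correlation, over_representation, read_gmt,
                       refit_reduced, autoscale)
from test_models import two_class_toy


def brute_force_auroc(scores, labels):
    """Concordant-pair counting with half credit for ties: the oracle."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    pos, neg = s[y], s[~y]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestVIP:
    def test_squared_vips_average_to_one(self):
        Z, y = two_class_toy(n=30, p=8, sep=2.0, seed=0)
        m = fit_plsda(Z, y, 3)
        v = vip_scores(m)
        assert (v.scores ** 2).sum() == pytest.approx(8.0, abs=1e-8)

    def test_exchangeable_features_all_one(self):
        """Duplicating one informative column makes all weights equal."""
        rng = np.random.default_rng(1)
        col = rng.normal(size=(20, 1))
        y = np.array(["A"] * 10 + ["B"] * 10, dtype=object)
        col[10:] += 5.0
        Z, _, _ = autoscale(np.hstack([col, col, col]))
        m = fit_plsda(Z, y, 1)
        v = vip_scores(m)
        np.testing.assert_allclose(v.scores, 1.0, atol=1e-8)

    def test_single_feature_vip_is_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(20, 1))
        y = np.array(["A"] * 10 + ["B"] * 10, dtype=object)
        x[10:] += 3.0
        Z, _, _ = autoscale(x)
        m = fit_plsda(Z, y, 1)
        assert vip_scores(m).scores.iloc[0] == pytest.approx(1.0)

    def test_signal_feature_ranks_first(self):
        Z, y = two_class_toy(n=30, p=6, sep=8.0, seed=3)
        m = fit_plsda(Z, y, 2)
        v = vip_scores(m, feature_ids=[f"F{j}" for j in range(6)])
        assert v.ranking[0] == "F0"
        assert "F0" in v.above_one


class TestROC:
    @pytest.mark.parametrize("scores,labels,expected", [
        ([1, 2, 3, 4], [0, 0, 1, 1], 1.0),    # perfect separation
        ([5, 5, 5, 5], [0, 1, 0, 1], 0.5),    # uninformative
        ([1, 2, 3, 4], [0, 1, 0, 1], 0.75),   # 3 of 4 concordant pairs
    ])
    def test_known_values(self, scores, labels, expected):
        r = roc_curve(scores, np.array(labels) == 1, positive=True)
        assert r.auroc == pytest.approx(expected)

    def test_curve_monotone(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=60)
        y = rng.random(60) < 0.4
        r = roc_curve(s, y, positive=True)
        assert (np.diff(r.tpr) >= 0).all()
        assert (np.diff(r.fpr) >= 0).all()
        assert r.tpr[0] == 0 and r.tpr[-1] == 1
        assert r.fpr[0] == 0 and r.fpr[-1] == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_auroc_equals_pair_counting(self, seed):
        """Trapezoid AUROC = Mann-Whitney U/(n+ n-) incl. tied scores."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 51))
        s = rng.integers(0, 6, size=n).astype(float)  # heavy ties
        y = rng.random(n) < 0.5
        if y.all() or not y.any():
            y[0] = ~y[0]
        r = roc_curve(s, y, positive=True)
        assert r.auroc == pytest.approx(brute_force_auroc(s, y), abs=1e-12)

    def test_one_class_absent_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1, 2], [True, True], positive=True)


class TestUnivariateANOVA:
    def test_identical_groups_give_p_one(self):
        X = np.array([[1.0], [2.0], [3.0], [1.0], [2.0], [3.0]])
        res = univariate_anova(X, ["a"] * 3 + ["b"] * 3)
        assert res["F"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_degenerate_constant_feature(self):
        X = np.ones((6, 1))
        res = univariate_anova(X, ["a"] * 3 + ["b"] * 3)
        assert res["p"].iloc[0] == 1.0

    def test_large_shift_highly_significant(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 1))
        X[10:] += 5.0
        res = univariate_anova(X, ["a"] * 10 + ["b"] * 10)
        assert res["p"].iloc[0] < 1e-6

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            univariate_anova(np.zeros((3, 1)), ["a", "a", "b"])


class TestAgeCorrelation:
    def test_perfect_positive(self):
        ages = [50.0, 60.0, 70.0, 80.0]
        r, p = age_correlation(ages, ages)
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        r, _ = age_correlation([1, 2, 3], [6, 4, 2])
        assert r == pytest.approx(-1.0)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(1)
        r, p = age_correlation(rng.normal(size=500), rng.normal(size=500))
        assert abs(r) < 0.15

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError):
            age_correlation([1.0, 1.0, 1.0], [4.0, 5.0, 6.0])


class TestOverRepresentation:
    def test_enrichment_ratio_example(self):
        universe = [f"f{i}" for i in range(100)]
        selected = universe[:10]
        sets = {"S": universe[5:15]}  # overlap 5, expected 1
        res = over_representation(selected, sets, universe)
        assert res.loc["S", "enrichment_ratio"] == pytest.approx(5.0)
        assert res.loc["S", "p"] < 0.01

    def test_zero_overlap(self):
        universe = [f"f{i}" for i in range(50)]
        res = over_representation(universe[:5], {"S": universe[40:]}, universe)
        assert res.loc["S", "enrichment_ratio"] == 0.0
        assert res.loc["S", "p"] > 0.5

    def test_selected_equals_universe(self):
        universe = [f"f{i}" for i in range(30)]
        res = over_representation(universe, {"S": universe[:7]}, universe)
        assert res.loc["S", "enrichment_ratio"] == pytest.approx(1.0)
        assert res.loc["S", "p"] == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            over_representation([], {"S": ["x"]}, [])

    def test_gmt_reader(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("SetA\tdesc\tf1\tf2\nSetB\tdesc\tf3\n")
        sets = read_gmt(path)
        assert sets == {"SetA": ["f1", "f2"], "SetB": ["f3"]}


class TestRefitReduced:
    def frames(self, seed=0, n=40, p=12):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        y = np.array(["HCC", "HCV"] * (n // 2), dtype=object)
        X[y == "HCC", :4] += 2.0  # features F0..F3 carry the signal
        cols = [f"F{j}" for j in range(p)]
        Xtr = pd.DataFrame(X[: n - 10], columns=cols)
        Xte = pd.DataFrame(X[n - 10:], columns=cols)
        return Xtr, y[: n - 10], Xte, y[n - 10:]

    def test_full_subset_identical_to_full_fit(self):
        Xtr, ytr, Xte, yte = self.frames()
        _, m_all, roc_all = refit_reduced(Xtr, ytr, Xte, yte,
                                          Xtr.columns, n_lv=2)
        _, m_again, roc_again = refit_reduced(Xtr, ytr, Xte, yte,
                                              list(Xtr.columns), n_lv=2)
        assert m_all.accuracy == m_again.accuracy
        assert roc_all.auroc == pytest.approx(roc_again.auroc)

    def test_signal_subset_beats_noise_subset(self):
        Xtr, ytr, Xte, yte = self.frames(seed=1)
        _, _, roc_sig = refit_reduced(Xtr, ytr, Xte, yte,
                                      ["F0", "F1", "F2", "F3"], n_lv=1)
        _, _, roc_noise = refit_reduced(Xtr, ytr, Xte, yte,
                                        ["F8", "F9", "F10", "F11"], n_lv=1)
        assert roc_sig.auroc >= roc_noise.auroc

    def test_empty_subset_rejected(self):
        Xtr, ytr, Xte, yte = self.frames()
        with pytest.raises(ValueError):
            refit_reduced(Xtr, ytr, Xte, yte, [], n_lv=1)

    def test_constant_subset_rejected(self):
        Xtr, ytr, Xte, yte = self.frames()
        Xtr = Xtr.copy()
        Xtr["F0"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            refit_reduced(Xtr, ytr, Xte, yte, ["F0"], n_lv=1)
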