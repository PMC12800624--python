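"""Discriminant classification, LOOCV oracle equivalence, exact binomial
tests and the variable-contribution analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from callcontext import discriminant
from callcontext.discriminant import (
    assess_classification,
    binomial_test,
    chance_probabilities,
    classify_loocv,
    contribution_matrix,
    fit_dfa,
)


def gaussian_classes(means, n_per, sd=1.0, seed=0, p=2):
    rng = np.random.default_rng(seed)
    rows = []
    for ci, m in enumerate(means):
        m = np.atleast_1d(np.asarray(m, dtype=float))
        X = rng.normal(0, sd, (n_per, len(m))) + m
        for i, x in enumerate(X):
            row = {"call_id": f"c{ci}_{i}", "context": f"class{ci}"}
            row.update({f"x{j}": v for j, v in enumerate(x)})
            rows.append(row)
    return pd.DataFrame(rows)


class TestFitDfa:
    def test_separable_classes_axis_and_accuracy(self):
        t = gaussian_classes([(0, 0), (10, 0)], 30, sd=0.5, seed=1)
        model = fit_dfa(t, ["x0", "x1"])
        axis = model.scaling[:, 0] / np.linalg.norm(model.scaling[:, 0])
        assert abs(axis[0]) > 0.99  # discriminates along x0
        assert model.predict(t[["x0", "x1"]].to_numpy()) == list(t["context"])

    def test_permuted_labels_give_near_zero_eigenvalues(self):
        t = gaussian_classes([(0, 0), (5, 0), (0, 5)], 40, sd=1.0, seed=2)
        rng = np.random.default_rng(3)
        t["context"] = rng.permutation(t["context"].to_numpy())
        model = fit_dfa(t, ["x0", "x1"])
        strong = fit_dfa(gaussian_classes([(0, 0), (5, 0), (0, 5)], 40, sd=1.0, seed=2), ["x0", "x1"])
        assert model.eigenvalues.max() < 0.15 * strong.eigenvalues.max()
        acc = np.mean(np.array(model.predict(t[["x0", "x1"]].to_numpy())) == t["context"])
        assert abs(acc - 1 / 3) < 0.15

    def test_mahalanobis_rule_matches_sklearn_lda(self):
        """Independent cross-check: same model family, same predictions."""
        t = gaussian_classes([(0, 0, 0), (2, 1, 0), (0, 2, 1)], 25, sd=1.2, seed=4, p=3)
        feats = ["x0", "x1", "x2"]
        model = fit_dfa(t, feats)
        ours = model.predict(t[feats].to_numpy())
        sk = LinearDiscriminantAnalysis(priors=[1 / 3] * 3).fit(t[feats], t["context"])
        assert (np.asarray(ours) == sk.predict(t[feats])).mean() > 0.97

    def test_tiny_class_rejected(self):
        t = gaussian_classes([(0,), (5,)], 5, seed=5)
        t = t.drop(index=t.index[t["context"] == "class1"][1:])
        with pytest.raises(ValueError, match="<= 1 row"):
            fit_dfa(t, ["x0"])


class TestLoocv:
    def test_perfect_separation_scores_1(self):
        t = gaussian_classes([(0, 0), (20, 0), (0, 20)], 10, sd=0.3, seed=6)
        res = classify_loocv(t, ["x0", "x1"])
        assert res.total_correct == 1.0
        assert int(np.trace(res.confusion.to_numpy())) == 30

    def test_equivalent_to_per_fold_sklearn_refit(self):
        """Brute-force oracle: refit sklearn LDA on each n-1 subset."""
        t = gaussian_classes([(0, 0), (1.5, 0.5), (0.5, 1.5)], 10, sd=1.0, seed=7)
        feats = ["x0", "x1"]
        res = classify_loocv(t, feats)
        oracle = []
        for i in range(len(t)):
            train = t.drop(index=i)
            sk = LinearDiscriminantAnalysis(priors=[1 / 3] * 3).fit(train[feats], train["context"])
            oracle.append(sk.predict(t.loc[[i], feats])[0])
        assert (res.table["predicted"].to_numpy() == np.asarray(oracle)).all()

    def test_confusion_row_sums_and_total(self):
        t = gaussian_classes([(0, 0), (2, 0), (0, 2)], 12, sd=1.5, seed=8)
        res = classify_loocv(t, ["x0", "x1"])
        assert (res.confusion.sum(axis=1) == 12).all()
        assert res.total_correct == pytest.approx(np.trace(res.confusion.to_numpy()) / 36)


class TestChance:
    def test_class_proportions(self):
        labels = ["high"] * 41 + ["low"] * 26 + ["non"] * 21
        chance = chance_probabilities(labels)
        assert chance["low"] == pytest.approx(0.295, abs=5e-4)
        assert chance["pooled"] == pytest.approx(1 / 3)
        assert sum(v for k, v in chance.items() if k != "pooled") == pytest.approx(1.0)

    def test_equal_classes(self):
        chance = chance_probabilities(["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        assert chance["a"] == chance["b"] == chance["c"] == pytest.approx(1 / 3)


class TestBinomial:
    def test_closed_forms(self):
        assert binomial_test(2, 2, 0.5, "greater")["p_value"] == pytest.approx(0.25)
        assert binomial_test(0, 7, 0.3, "greater")["p_value"] == pytest.approx(1.0)

    @pytest.mark.parametrize("k,n,p0", [(42, 88, 1 / 3), (13, 15, 0.25), (3, 40, 0.3), (250, 500, 0.5)])
    def test_matches_scipy_to_1e12(self, k, n, p0):
        for alt, scipy_alt in (("greater", "greater"), ("two_sided", "two-sided")):
            ours = binomial_test(k, n, p0, alt)["p_value"]
            ref = binomtest(k, n, p0, alternative=scipy_alt).pvalue
            assert ours == pytest.approx(ref, rel=1e-12)

    def test_matches_exact_fraction_summation(self):
        """Independent oracle: exact rational tail sum via math.comb."""
        from fractions import Fraction
        from math import comb

        k, n = 9, 20
        p0 = Fraction(1, 3)
        tail = sum(comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(k, n + 1))
        assert binomial_test(k, n, 1 / 3, "greater")["p_value"] == pytest.approx(float(tail), rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binomial_test(5, 3, 0.5)
        with pytest.raises(ValueError):
            binomial_test(1, 3, 1.0)


class TestAssessment:
    def test_all_correct_gives_p0_power_n(self):
        t = gaussian_classes([(0, 0), (30, 0)], 8, sd=0.2, seed=9)
        res = classify_loocv(t, ["x0", "x1"])
        assessment = assess_classification(res).set_index("test")
        assert assessment.loc["class0", "p_value"] == pytest.approx(0.5**8, rel=1e-9)

    def test_below_expectation_p_above_half(self):
        row = binomial_test(2, 20, 0.5, "greater")
        assert row["p_value"] > 0.5

    def test_pooled_test_uses_one_over_g(self):
        t = gaussian_classes([(0, 0), (2, 0), (0, 2)], 10, sd=1.0, seed=10)
        res = classify_loocv(t, ["x0", "x1"])
        assessment = assess_classification(res).set_index("test")
        assert assessment.loc["pooled", "p0"] == pytest.approx(1 / 3)
        assert assessment.loc["pooled", "n"] == 30


class TestContributions:
    def test_feature_equal_to_scores_has_r_1(self):
        t = gaussian_classes([(0, 0), (3, 1)], 20, sd=1.0, seed=11)
        model = fit_dfa(t, ["x0", "x1"])
        scores = model.transform(t[["x0", "x1"]].to_numpy())
        t["ld_copy"] = scores[:, 0]
        contrib = contribution_matrix(t, ["ld_copy"], scores)
        assert contrib.loc[0, "r"] == pytest.approx(1.0)

    def test_orthogonalized_feature_uncorrelated(self):
        rng = np.random.default_rng(12)
        t = gaussian_classes([(0, 0), (2, 1), (1, 2)], 67, sd=1.0, seed=12)
        model = fit_dfa(t, ["x0", "x1"])
        scores = model.transform(t[["x0", "x1"]].to_numpy())
        z = rng.normal(size=len(t))
        Q, _ = np.linalg.qr(np.column_stack([scores, np.ones(len(t))]))
        z = z - Q @ (Q.T @ z)
        t["orth"] = z
        contrib = contribution_matrix(t, ["orth"], scores)
        assert (contrib["r"].abs() < 0.1).all()

    def test_r_bounded_and_long_format(self, feature_table):
        feats = ["f0_median_hz", "dur_s", "spec_centroid_hz"]
        model = fit_dfa(feature_table, feats)
        scores = model.transform(feature_table[feats].to_numpy())
        contrib = contribution_matrix(feature_table, feats, scores)
        assert len(contrib) == len(feats) * scores.shape[1]
        assert contrib["r"].abs().max() <= 1.0


def test_nested_selection_loocv_recovers_true_signal(feature_table):
    """Per-fold re-selection still finds real context structure: accuracy
    well above chance on shifted synthetic calls, and every fold records
    how many features its training data retained."""
    usable = [f for f in feature_table.columns if f in __import__("callcontext").features.FEATURE_NAMES]
    usable = [f for f in usable if feature_table[f].notna().all()]
    res = discriminant.nested_select_classify_loocv(feature_table, usable)
    assert res.total_correct > 0.5  # 45 calls, chance 1/3
    assert "n_features" in res.table.columns
    assert (res.table["n_features"] >= 0).all()
    assert (res.confusion.sum(axis=1) == 15).all()


def test_label_permutation_accuracy_matches_binomial_null():
    """Permuting labels makes LOOCV accuracy binomial(n, 1/g) on average."""
    rng = np.random.default_rng(13)
    accs = []
    for rep in range(30):
        t = gaussian_classes([(0, 0), (2, 0), (0, 2)], 10, sd=1.0, seed=100 + rep)
        t["context"] = rng.permutation(t["context"].to_numpy())
        accs.append(classify_loocv(t, ["x0", "x1"]).total_correct)
    n, p = 30, 1 / 3
    se = np.sqrt(p * (1 - p) / n / len(accs))
    assert abs(np.mean(accs) - p) < 3 * se
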