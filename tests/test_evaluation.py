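"""ROC/AUC, Youden, Pearson, ICC, kappa and concordance statistics."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

from bvbquant.evaluation import (
    concordance_table,
    icc,
    kappa,
    pearson_r,
    roc_auc,
    youden_index,
)
from bvbquant.synthetic_data import correlated_normal


def pairwise_auc_oracle(scores, labels):
    """Exhaustive case-control pair comparison (ties count 1/2)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 4], [0, 0, 1, 1])
        assert res.auc == 1.0
        assert res.youden == pytest.approx(1.0)

    def test_pure_ties(self):
        res = roc_auc([5.0] * 6, [0, 1, 0, 1, 0, 1])
        assert res.auc == pytest.approx(0.5)

    def test_matches_exhaustive_pairwise_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = rng.integers(4, 13)
            scores = rng.integers(0, 5, n).astype(float)  # heavy ties
            labels = np.zeros(n, int)
            labels[rng.choice(n, rng.integers(1, n), replace=False)] = 1
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            res = roc_auc(scores, labels)
            assert res.auc == pytest.approx(pairwise_auc_oracle(scores, labels), abs=1e-12)

    def test_score_negation_symmetry(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        labels[0], labels[1] = 0, 1
        a = roc_auc(scores, labels).auc
        b = roc_auc(-scores, labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_youden_cutoff_maximises_scan(self):
        rng = np.random.default_rng(2)
        scores = np.concatenate([rng.normal(0, 1, 30), rng.normal(1.5, 1, 20)])
        labels = np.concatenate([np.zeros(30, int), np.ones(20, int)])
        res = roc_auc(scores, labels)
        best = max(
            np.mean(scores[labels == 1] >= t) + np.mean(scores[labels == 0] < t) - 1
            for t in scores
        )
        assert res.youden == pytest.approx(best, abs=1e-12)

    def test_ci_contains_auc(self):
        rng = np.random.default_rng(3)
        scores = np.concatenate([rng.normal(0, 1, 50), rng.normal(1, 1, 50)])
        labels = np.repeat([0, 1], 50)
        res = roc_auc(scores, labels)
        lo, hi = res.ci_95
        assert 0 <= lo < res.auc < hi <= 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])


class TestYouden:
    @pytest.mark.parametrize(
        "sens,spec,expected",
        [(0.657, 0.784, 0.441), (0.843, 0.784, 0.627), (0.814, 0.898, 0.712), (1.0, 1.0, 1.0)],
    )
    def test_closed_form(self, sens, spec, expected):
        assert youden_index(sens, spec) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            youden_index(1.2, 0.5)


class TestPearson:
    def test_exact_linearity(self):
        x = np.arange(10, dtype=float)
        assert pearson_r(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_copula_target_recovered(self):
        rs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            z = rng.standard_normal(10000)
            z2 = correlated_normal(z, 0.612, rng)
            rs.append(pearson_r(z, z2)[0])
        assert np.mean(rs) == pytest.approx(0.612, abs=0.02)


class TestIcc:
    def test_perfect_agreement(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=30)
        res = icc(np.column_stack([col, col]))
        assert res.icc == pytest.approx(1.0, abs=1e-9)

    def test_null_case_near_zero(self):
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vals.append(icc(rng.normal(size=(200, 2))).icc)
        assert np.mean(vals) == pytest.approx(0.0, abs=0.05)

    def test_recovery_of_high_agreement_design_point(self):
        true_icc = 0.923
        err_sd = np.sqrt(1 / true_icc - 1)
        est = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            subject = rng.normal(size=65)
            ratings = np.column_stack(
                [subject + rng.normal(0, err_sd, 65), subject + rng.normal(0, err_sd, 65)]
            )
            est.append(icc(ratings).icc)
        assert np.mean(est) == pytest.approx(true_icc, abs=0.03)

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        arr = rng.normal(size=(40, 3))
        a = icc(arr).icc
        b = icc(2.5 * arr + 7.0).icc
        assert a == pytest.approx(b, abs=1e-9)

    def test_missing_cells_rejected(self):
        arr = np.ones((10, 2))
        arr[0, 0] = np.nan
        with pytest.raises(ValueError):
            icc(arr)


def weighted_kappa_oracle(c1, c2, weights):
    """Direct double-summation of the weighted-kappa definition."""
    cats = sorted(set(c1) | set(c2))
    k = len(cats)
    idx = {c: i for i, c in enumerate(cats)}
    if weights == "none":
        w = np.eye(k)
    else:
        diff = np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
        w = 1 - diff / (k - 1) if weights == "linear" else 1 - (diff / (k - 1)) ** 2
    n = len(c1)
    po = sum(w[idx[a], idx[b]] for a, b in zip(c1, c2)) / n
    pe = 0.0
    for a in cats:
        for b in cats:
            pe += w[idx[a], idx[b]] * (list(c1).count(a) / n) * (list(c2).count(b) / n)
    return (po - pe) / (1 - pe)


class TestKappa:
    def test_identical_ratings(self):
        c = [0, 1, 2, 1, 0, 2, 2, 1]
        for w in ("none", "linear", "quadratic"):
            assert kappa(c, c, weights=w).kappa == pytest.approx(1.0)

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(0)
        c1 = rng.integers(0, 3, 10000)
        c2 = rng.integers(0, 3, 10000)
        assert kappa(c1, c2).kappa == pytest.approx(0.0, abs=0.03)

    @pytest.mark.parametrize("weights", ["none", "linear", "quadratic"])
    def test_matches_direct_formula_oracle(self, weights):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = rng.integers(10, 31)
            c1 = rng.integers(0, 3, n)
            c2 = np.where(rng.random(n) < 0.6, c1, rng.integers(0, 3, n))
            res = kappa(c1, c2, weights=weights, categories=[0, 1, 2])
            assert res.kappa == pytest.approx(
                weighted_kappa_oracle(list(c1), list(c2), weights), abs=1e-12
            )

    def test_matches_sklearn(self):
        rng = np.random.default_rng(8)
        c1 = rng.integers(0, 4, 200)
        c2 = np.where(rng.random(200) < 0.5, c1, rng.integers(0, 4, 200))
        assert kappa(c1, c2).kappa == pytest.approx(cohen_kappa_score(c1, c2), abs=1e-12)
        assert kappa(c1, c2, weights="linear").kappa == pytest.approx(
            cohen_kappa_score(c1, c2, weights="linear"), abs=1e-12
        )
        assert kappa(c1, c2, weights="quadratic").kappa == pytest.approx(
            cohen_kappa_score(c1, c2, weights="quadratic"), abs=1e-12
        )

    def test_permutation_invariance_unweighted(self):
        rng = np.random.default_rng(9)
        c1 = rng.integers(0, 3, 100)
        c2 = rng.integers(0, 3, 100)
        perm = {0: 2, 1: 0, 2: 1}
        a = kappa(c1, c2).kappa
        b = kappa([perm[c] for c in c1], [perm[c] for c in c2]).kappa
        assert a == pytest.approx(b, abs=1e-12)

    def test_se_positive_and_plausible(self):
        rng = np.random.default_rng(10)
        c1 = rng.integers(0, 2, 100)
        c2 = np.where(rng.random(100) < 0.8, c1, 1 - c1)
        res = kappa(c1, c2)
        assert 0 < res.kappa_se < 0.2

    def test_degenerate_marginals_rejected(self):
        with pytest.raises(ValueError):
            kappa([0, 0, 0], [0, 0, 0])


class TestConcordance:
    def test_published_style_confusion_rows(self):
        true = ["I"] * 42 + ["II"] * 16 + ["III"] * 7
        called = (
            ["I"] * 38 + ["II"] * 4          # stage I row: 38, 4, 0
            + ["I"] * 3 + ["II"] * 11 + ["III"] * 2  # stage II row: 3, 11, 2
            + ["III"] * 7                     # stage III row: 0, 0, 7
        )
        res = concordance_table(true, called, categories=["I", "II", "III"])
        assert res.per_class_concordance["I"] == pytest.approx(90.48, abs=0.005)
        assert res.per_class_concordance["II"] == pytest.approx(68.75, abs=0.005)
        assert res.per_class_concordance["III"] == pytest.approx(100.0)
        np.testing.assert_array_equal(
            res.confusion, [[38, 4, 0], [3, 11, 2], [0, 0, 7]]
        )

    def test_perfect_prediction(self):
        true = ["I", "II", "III"] * 5
        res = concordance_table(true, true, categories=["I", "II", "III"])
        assert all(v == 100.0 for v in res.per_class_concordance.values())
        assert np.trace(res.confusion) == 15

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            concordance_table(["I", "IV"], ["I", "I"], categories=["I", "II", "III"])
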