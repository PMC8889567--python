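"""SMOTE, the L2 logistic solver and the ranking metrics."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score

from dosiomics_rp import (
    fit_l2_logistic,
    pr_auc,
    roc_auc,
    smote_balance,
    z_test,
)
from dosiomics_rp.modeling import predict_proba


# --- SMOTE -----------------------------------------------------------------


def test_smote_equalizes_class_counts():
    rng = np.random.default_rng(0)
    x = rng.standard_normal((100, 6))
    y = np.array([0] * 80 + [1] * 20)
    xb, yb = smote_balance(x, y, k=5, rng=rng)
    assert np.bincount(yb).tolist() == [80, 80]
    assert xb.shape == (160, 6)
    # originals retained verbatim
    np.testing.assert_array_equal(xb[:100], x)


def test_smote_synthetics_are_convex_combinations():
    rng = np.random.default_rng(1)
    # two minority points: every synthetic must lie on their segment
    x = np.vstack([rng.standard_normal((10, 2)), [[0.0, 0.0], [2.0, 2.0]]])
    y = np.array([0] * 10 + [1] * 2)
    xb, yb = smote_balance(x, y, k=5, rng=rng)
    synth = xb[12:]
    assert synth.shape[0] == 8
    # on the segment between (0,0) and (2,2): x == y and 0 <= x <= 2
    np.testing.assert_allclose(synth[:, 0], synth[:, 1], atol=1e-12)
    assert ((synth >= 0) & (synth <= 2)).all()


def test_smote_noop_when_balanced():
    rng = np.random.default_rng(2)
    x = rng.standard_normal((10, 3))
    y = np.array([0, 1] * 5)
    xb, yb = smote_balance(x, y, rng=rng)
    np.testing.assert_array_equal(xb, x)
    np.testing.assert_array_equal(yb, y)


def test_smote_minority_guardrails():
    rng = np.random.default_rng(3)
    x = rng.standard_normal((5, 2))
    with pytest.raises(ValueError):
        smote_balance(x, np.array([0, 0, 0, 0, 1]), rng=rng)
    with pytest.warns(UserWarning, match="reduced"):
        smote_balance(
            rng.standard_normal((8, 2)), np.array([0] * 5 + [1] * 3), k=5, rng=rng
        )


# --- L2 logistic regression ------------------------------------------------


def test_ridge_limit_shrinks_to_prevalence():
    rng = np.random.default_rng(4)
    x = rng.standard_normal((50, 3))
    y = (rng.uniform(size=50) < 0.3).astype(int)
    coef, icpt = fit_l2_logistic(x, y, reg_strength=1e8)
    assert np.abs(coef).max() < 1e-4
    np.testing.assert_allclose(predict_proba(x, coef, icpt), y.mean(), atol=1e-3)


def test_separable_two_points_coefficient_sign():
    x = np.array([[-1.0], [1.0]])
    y = np.array([0, 1])
    coef, _ = fit_l2_logistic(x, y, reg_strength=1.0)
    assert coef[0] > 0


def test_agreement_with_independent_optimizer():
    """Coefficients match scikit-learn's LBFGS solver to 1e-6."""
    rng = np.random.default_rng(5)
    x = rng.standard_normal((20, 5))
    y = (x @ rng.standard_normal(5) + 0.3 * rng.standard_normal(20) > 0).astype(int)
    for lam in (0.05, 1.0, 50.0):
        coef, icpt = fit_l2_logistic(x, y, reg_strength=lam)
        ref = LogisticRegression(C=1.0 / lam, solver="lbfgs", tol=1e-12,
                                 max_iter=10000).fit(x, y)
        np.testing.assert_allclose(coef, ref.coef_[0], atol=1e-6)
        np.testing.assert_allclose(icpt, ref.intercept_[0], atol=1e-6)


# --- metrics ---------------------------------------------------------------


def test_perfect_ranking_gives_unit_aucs():
    scores = np.array([0.9, 0.8, 0.2, 0.1])
    labels = np.array([1, 1, 0, 0])
    assert roc_auc(scores, labels) == 1.0
    assert pr_auc(scores, labels) == 1.0


def test_rocauc_matches_pairwise_enumeration():
    labels = np.array([1, 0, 1, 0])
    scores = np.array([0.9, 0.8, 0.7, 0.6])
    assert roc_auc(scores, labels) == 0.75
    rng = np.random.default_rng(6)
    for _ in range(10):
        s = rng.choice(np.linspace(0, 1, 15), size=40)  # many ties
        y = rng.integers(0, 2, size=40)
        if y.sum() in (0, 40):
            continue
        pos, neg = s[y == 1], s[y == 0]
        brute = np.mean([
            1.0 if a > b else (0.5 if a == b else 0.0) for a in pos for b in neg
        ])
        assert roc_auc(s, y) == pytest.approx(brute, abs=1e-12)
        assert roc_auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


def test_prauc_matches_sklearn_step_integration():
    rng = np.random.default_rng(7)
    for _ in range(10):
        s = rng.choice(np.linspace(0, 1, 12), size=50)
        y = rng.integers(0, 2, size=50)
        if y.sum() in (0, 50):
            continue
        assert pr_auc(s, y) == pytest.approx(average_precision_score(y, s), abs=1e-12)


def test_random_scores_prauc_near_prevalence():
    rng = np.random.default_rng(8)
    pi = 0.17
    vals = []
    for _ in range(1000):
        n = 100
        y = (rng.uniform(size=n) < pi).astype(int)
        if y.sum() == 0 or y.sum() == n:
            continue
        vals.append(pr_auc(rng.uniform(size=n), y))
    assert abs(np.mean(vals) - pi) < 0.05


def test_single_class_metrics_error():
    with pytest.raises(ValueError):
        roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))
    with pytest.raises(ValueError):
        pr_auc(np.array([0.1, 0.2]), np.array([0, 0]))


# --- Z-test ----------------------------------------------------------------


def test_z_identical_samples():
    v = np.full(100, 0.7)
    z, p = z_test(v, v)
    assert z == 0.0 and p == 1.0


def test_z_formula_hand_evaluation():
    """Means 0.75 vs 0.67, SDs 0.10/0.11, n=500 -> z ~ 12, p << 0.05."""
    rng = np.random.default_rng(9)
    a = rng.standard_normal(500)
    a = (a - a.mean()) / a.std(ddof=1) * 0.10 + 0.75
    b = rng.standard_normal(500)
    b = (b - b.mean()) / b.std(ddof=1) * 0.11 + 0.67
    z, p = z_test(a, b)
    expected = 0.08 / np.sqrt((0.10**2 + 0.11**2) / 500)
    assert z == pytest.approx(expected, rel=1e-9)
    assert z == pytest.approx(12.03, abs=0.01)
    assert p < 1e-10


def test_z_antisymmetry():
    rng = np.random.default_rng(10)
    a, b = rng.uniform(size=50), rng.uniform(size=50)
    z1, p1 = z_test(a, b)
    z2, p2 = z_test(b, a)
    assert z1 == pytest.approx(-z2)
    assert p1 == pytest.approx(p2)
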