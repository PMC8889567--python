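"""Statistical building blocks: SMOTE, L2-penalized logistic regression and
ROC / precision-recall AUC.

The logistic solver minimizes the negative log-likelihood plus
``0.5 * reg_strength * ||w||^2`` (intercept unpenalized) by damped Newton
iterations; it is deterministic given the data and strength, and agrees with
scikit-learn's ``LogisticRegression(C=1/reg_strength)`` to high precision.
ROCAUC is the Mann-Whitney pairwise statistic (ties count 1/2); PRAUC is the
step-wise (rectangle) integral of the precision-recall curve,
``sum_k (R_k - R_{k-1}) P_k`` over descending score thresholds.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import special, stats

__all__ = [
    "ConvergenceError",
    "smote_balance",
    "fit_l2_logistic",
    "predict_proba",
    "roc_auc",
    "pr_auc",
    "roc_pr_auc",
    "Standardizer",
    "z_test",
]

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    pass


class Standardizer:
    """Zero-mean / unit-variance scaling fitted on training data only."""

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, x: np.ndarray) -> "Standardizer":
        x = np.asarray(x, dtype=np.float64)
        self.mean_ = x.mean(axis=0)
        scale = x.std(axis=0)
        scale[scale == 0] = 1.0  # constant columns pass through centered
        self.scale_ = scale
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        assert self.mean_ is not None and self.scale_ is not None
        return (np.asarray(x, dtype=np.float64) - self.mean_) / self.scale_

    def fit_transform(self, x: np.ndarray) -> np.ndarray:
        return self.fit(x).transform(x)


def smote_balance(
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 5,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Equalize the two classes by synthetic minority oversampling.

    Each synthetic sample is ``x + u * (x_nn - x)`` with ``u ~ Uniform(0,1)``
    and ``x_nn`` one of the ``k`` nearest minority neighbours of ``x``
    (Euclidean distance).  Already-balanced input is returned unchanged.
    ``k`` is reduced to ``n_minority - 1`` with a warning when necessary.
    """
    if rng is None:
        rng = np.random.default_rng()
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("SMOTE requires exactly two classes present")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    n_new = int(n_maj - n_min)
    if n_new == 0:
        return x, y
    if n_min < 2:
        raise ValueError("SMOTE requires at least 2 minority samples")
    if k > n_min - 1:
        warnings.warn(
            f"SMOTE k={k} reduced to {n_min - 1} (minority size {n_min})",
            stacklevel=2,
        )
        k = n_min - 1
    xm = x[y == minority]
    d2 = ((xm[:, None, :] - xm[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1, kind="stable")[:, :k]

    base_idx = rng.integers(0, n_min, size=n_new)
    nb_choice = rng.integers(0, k, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    base = xm[base_idx]
    neighbour = xm[nn[base_idx, nb_choice]]
    synthetic = base + u[:, None] * (neighbour - base)
    x_out = np.vstack([x, synthetic])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return x_out, y_out


def predict_proba(x: np.ndarray, coef: np.ndarray, intercept: float) -> np.ndarray:
    return special.expit(x @ coef + intercept)


def fit_l2_logistic(
    features: np.ndarray,
    labels: np.ndarray,
    reg_strength: float = 0.0,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, float]:
    """Fit logistic regression minimizing NLL + 0.5*reg*||w||^2.

    Returns ``(coef, intercept)``.  With ``reg_strength == 0`` on separable
    data the likelihood has no finite optimum; iteration then stops at
    ``max_iter`` with near-perfect fitted probabilities (logged, not raised).
    With a positive strength, failure to converge raises
    :class:`ConvergenceError` naming the strength.
    """
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    n, d = x.shape
    if reg_strength < 0:
        raise ValueError("reg_strength must be >= 0")
    beta = np.zeros(d + 1)  # [intercept, coef]
    xa = np.hstack([np.ones((n, 1)), x])
    ridge = np.diag([0.0] + [reg_strength] * d)

    def objective(b: np.ndarray) -> float:
        z = xa @ b
        # log(1 + exp(-z*y_pm)) stable form
        nll = np.logaddexp(0.0, z).sum() - (y * z).sum()
        return nll + 0.5 * reg_strength * (b[1:] @ b[1:])

    obj = objective(beta)
    converged = False
    for _ in range(max_iter):
        p = special.expit(xa @ beta)
        g = xa.T @ (p - y) + ridge @ beta
        if np.linalg.norm(g, ord=np.inf) < tol * max(1.0, n):
            converged = True
            break
        w = np.clip(p * (1 - p), 1e-12, None)
        h = (xa * w[:, None]).T @ xa + ridge
        try:
            step = np.linalg.solve(h, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(h, g, rcond=None)[0]
        # damped Newton: halve until the objective does not increase
        t = 1.0
        for _ in range(30):
            new_beta = beta - t * step
            new_obj = objective(new_beta)
            if new_obj <= obj + 1e-12:
                break
            t *= 0.5
        beta, obj = new_beta, new_obj
    if not converged:
        if reg_strength > 0:
            raise ConvergenceError(
                f"L2 logistic fit did not converge at reg_strength={reg_strength}"
            )
        logger.debug("unregularized logistic fit stopped at max_iter (separable data?)")
    return beta[1:].copy(), float(beta[0])


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney ROCAUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROCAUC needs both classes present")
    ranks = stats.rankdata(scores)  # average ranks handle ties as 1/2
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def pr_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Step integration of the precision-recall curve over descending
    thresholds at distinct score values."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    if n_pos == 0 or n_pos == labels.size:
        raise ValueError("PRAUC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # thresholds at the last index of each tied block
    distinct = np.nonzero(np.diff(s, append=np.nan))[0]
    precision = tp[distinct] / (tp[distinct] + fp[distinct])
    recall = tp[distinct] / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(((recall - prev_recall) * precision).sum())


def roc_pr_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    return roc_auc(scores, labels), pr_auc(scores, labels)


def z_test(
    values_a: np.ndarray, values_b: np.ndarray, paired: bool = False
) -> tuple[float, float]:
    """Two-sample Z-test on per-split metric means.

    Unpaired by default (the two models' 500 test metrics treated as
    independent samples); ``paired=True`` tests the mean of per-split
    differences instead.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("z_test needs at least 2 values per sample")
    if paired:
        if a.size != b.size:
            raise ValueError("paired z_test needs equal sample sizes")
        d = a - b
        se = d.std(ddof=1) / np.sqrt(d.size)
        z = d.mean() / se if se > 0 else 0.0
    else:
        se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
        z = (a.mean() - b.mean()) / se if se > 0 else 0.0
    p = 2.0 * stats.norm.sf(abs(z)) if z != 0 else 1.0
    return float(z), float(p)
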