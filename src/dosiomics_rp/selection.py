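"""Two-stage univariate feature selection.

Stage 1 fits a univariate logistic regression per feature on the full
cohort and eliminates features with Wald p >= 0.1 (constant features are
excluded with a warning; perfectly separating features are kept with p = 0).
Stage 2 ranks the survivors by the mean held-out ROCAUC of an unregularized
univariate logistic model over 50 repetitions of stratified 5-fold
cross-validation (250 fold scores per feature) and keeps the top 10 per
feature group.  Ties are broken by smaller univariate p, then by name.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .extract import feature_group_columns
from .modeling import fit_l2_logistic, predict_proba, roc_auc

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "univariate_filter",
    "univariate_pvalues",
    "rank_by_repeated_cv",
    "select_features",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    p_threshold: float = 0.1
    n_folds: int = 5
    n_repeats: int = 50
    top_k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.n_folds < 2 or self.n_repeats < 1:
            raise ValueError("need n_folds >= 2 and n_repeats >= 1")


@dataclass(frozen=True)
class SelectionResult:
    """Ranked univariate screening outcome for one feature group."""

    group: str
    #: per surviving feature: (name, univariate p, mean CV ROCAUC), ranked
    ranking: tuple[tuple[str, float, float], ...]
    selected: tuple[str, ...]
    config: SelectionConfig = field(default_factory=SelectionConfig)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.ranking, columns=["feature", "univariate_p", "mean_cv_rocauc"])
        df["selected"] = df["feature"].isin(self.selected)
        return df


def _wald_p(x: np.ndarray, y: np.ndarray) -> float:
    """Univariate logistic Wald p-value for the slope coefficient."""
    design = sm.add_constant(x.reshape(-1, 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            return 0.0
        p = float(res.pvalues[1])
    if not np.isfinite(p):
        # complete separation drives the Wald statistic degenerate; the
        # association is as strong as it gets, so the feature is kept
        return 0.0
    return p


def univariate_pvalues(table: pd.DataFrame, labels: np.ndarray, columns) -> dict[str, float]:
    """Wald p per feature; constant features map to NaN (excluded)."""
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) != 2:
        raise ValueError("labels must contain both classes")
    out: dict[str, float] = {}
    for col in columns:
        x = table[col].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"feature {col!r} has missing values among used rows")
        if np.ptp(x) == 0:
            logger.warning("feature %s is constant; excluded from selection", col)
            out[col] = float("nan")
            continue
        out[col] = _wald_p(x, y)
    return out


def univariate_filter(
    table: pd.DataFrame,
    labels: np.ndarray,
    columns,
    cfg: SelectionConfig = SelectionConfig(),
) -> list[str]:
    """Features whose univariate Wald p is strictly below the threshold."""
    pvals = univariate_pvalues(table, labels, columns)
    return [c for c in columns if np.isfinite(pvals[c]) and pvals[c] < cfg.p_threshold]


def _stratified_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator):
    """Index folds with class proportions preserved."""
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % n_folds].append(int(j))
    return [np.array(sorted(f)) for f in folds]


def _feature_cv_auc(
    x: np.ndarray, y: np.ndarray, cfg: SelectionConfig, rng: np.random.Generator
) -> float:
    """Mean held-out ROCAUC of the unregularized univariate model."""
    scores = []
    for _ in range(cfg.n_repeats):
        folds = _stratified_folds(y, cfg.n_folds, rng)
        for k in range(cfg.n_folds):
            test = folds[k]
            train = np.concatenate([folds[j] for j in range(cfg.n_folds) if j != k])
            if len(np.unique(y[test])) < 2 or len(np.unique(y[train])) < 2:
                continue  # stratification prevents this except in tiny groups
            coef, icpt = fit_l2_logistic(x[train, None], y[train], reg_strength=0.0,
                                         max_iter=50)
            scores.append(roc_auc(predict_proba(x[test, None], coef, icpt), y[test]))
    return float(np.mean(scores))


def rank_by_repeated_cv(
    table: pd.DataFrame,
    labels: np.ndarray,
    survivors: list[str],
    cfg: SelectionConfig = SelectionConfig(),
    group: str = "",
    pvalues: dict[str, float] | None = None,
) -> SelectionResult:
    """Rank surviving features by repeated-CV ROCAUC and keep the top k."""
    if not survivors:
        raise ValueError("no surviving features to rank")
    y = np.asarray(labels, dtype=float)
    if pvalues is None:
        pvalues = univariate_pvalues(table, y, survivors)
    records = []
    for i, col in enumerate(survivors):
        rng = np.random.default_rng(
            np.random.SeedSequence((cfg.seed % (2**31), 11, i))
        )
        auc = _feature_cv_auc(table[col].to_numpy(dtype=float), y, cfg, rng)
        records.append((col, float(pvalues[col]), auc))
    records.sort(key=lambda r: (-r[2], r[1], r[0]))
    if len(records) < cfg.top_k:
        logger.warning(
            "group %s has only %d survivors (< top_k=%d); selecting all",
            group, len(records), cfg.top_k,
        )
    selected = tuple(r[0] for r in records[: cfg.top_k])
    return SelectionResult(group=group, ranking=tuple(records), selected=selected, config=cfg)


def select_features(
    table: pd.DataFrame,
    labels: np.ndarray,
    group: str,
    cfg: SelectionConfig = SelectionConfig(),
) -> SelectionResult:
    """Full two-stage selection for one feature group.

    Rows with missing values in the group's columns are dropped (with a log
    note) before selection.
    """
    columns = list(feature_group_columns(group))
    y = np.asarray(labels, dtype=float)
    sub = table[columns]
    keep = ~sub.isna().any(axis=1).to_numpy()
    if not keep.all():
        logger.info("group %s: dropping %d rows with missing features",
                    group, int((~keep).sum()))
    sub = sub.loc[keep]
    y = y[keep]
    pvals = univariate_pvalues(sub, y, columns)
    survivors = [c for c in columns if np.isfinite(pvals[c]) and pvals[c] < cfg.p_threshold]
    if not survivors:
        logger.warning("group %s: no features pass the p<%.2f filter; "
                       "falling back to the smallest-p feature",
                       group, cfg.p_threshold)
        finite = [c for c in columns if np.isfinite(pvals[c])]
        survivors = [min(finite, key=lambda c: pvals[c])]
    return rank_by_repeated_cv(sub, y, survivors, cfg, group=group, pvalues=pvals)
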