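"""Nested Monte-Carlo cross-validated evaluation of RP prediction models.

:class:`PneumonitisModel` is built from a feature table, binary labels and an
:class:`EvalConfig`; :meth:`PneumonitisModel.fit` runs the full nested
procedure and returns a :class:`PneumonitisResults` carrying the per-split
test ROCAUC / PRAUC lists, their summaries and diagnostics.

Per outer split (stratified 80/20 by default):

1. standardize features on the outer-train rows only;
2. inner loop: ``n_inner_splits`` Monte-Carlo 80/20 splits of the outer-train
   set; SMOTE-balance each inner-train; fit L2 logistic regression at every
   strength of the grid; pick the strength maximizing mean validation ROCAUC;
3. refit on the full (SMOTE-balanced) outer-train set at the chosen strength
   and record test ROCAUC and PRAUC.

Nothing computed from test rows enters training: the stored per-split
diagnostics (chosen strength, scaler statistics) allow an audit that
perturbing test rows leaves the training artifacts unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .modeling import (
    Standardizer,
    fit_l2_logistic,
    predict_proba,
    roc_auc,
    pr_auc,
    smote_balance,
    z_test,
)
from .selection import SelectionConfig, select_features

__all__ = [
    "EvalConfig",
    "PneumonitisModel",
    "PneumonitisResults",
    "evaluate_model",
    "compare_models",
    "transfer_evaluate",
]

logger = logging.getLogger(__name__)

DEFAULT_REG_GRID = tuple(np.logspace(-3, 3, 13))


@dataclass(frozen=True)
class EvalConfig:
    n_outer_splits: int = 500
    outer_test_fraction: float = 0.2
    n_inner_splits: int = 250
    inner_val_fraction: float = 0.2
    reg_strength_grid: tuple[float, ...] = DEFAULT_REG_GRID
    smote_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.outer_test_fraction < 1.0:
            raise ValueError("outer_test_fraction must be in (0, 1)")
        if not 0.0 < self.inner_val_fraction < 1.0:
            raise ValueError("inner_val_fraction must be in (0, 1)")
        grid = tuple(float(g) for g in self.reg_strength_grid)
        if not grid or any(g <= 0 for g in grid):
            raise ValueError("reg_strength_grid must be non-empty positive reals")
        object.__setattr__(self, "reg_strength_grid", grid)
        if self.n_outer_splits < 1 or self.n_inner_splits < 1:
            raise ValueError("split counts must be >= 1")


def _stratified_split(
    y: np.ndarray, test_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random train/test split preserving class proportions; guarantees at
    least one sample of each class on both sides."""
    train_idx, test_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_test = int(round(test_fraction * idx.size))
        n_test = min(max(n_test, 1), idx.size - 1)
        test_idx.append(idx[:n_test])
        train_idx.append(idx[n_test:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


@dataclass(frozen=True)
class PneumonitisResults:
    """Per-split test metrics and summaries of one fitted model."""

    name: str
    roc_aucs: np.ndarray
    pr_aucs: np.ndarray
    chosen_strengths: np.ndarray
    #: per-split sum of the training scaler means (leakage-audit artifact)
    scaler_mean_sums: np.ndarray
    test_indices: tuple[np.ndarray, ...] = field(repr=False)
    config: EvalConfig = field(default_factory=EvalConfig, repr=False)
    feature_set: tuple[str, ...] = ()

    @staticmethod
    def _summ(v: np.ndarray) -> dict[str, float]:
        return {
            "mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
            "p10": float(np.percentile(v, 10)),
            "p90": float(np.percentile(v, 90)),
        }

    def summary(self) -> pd.DataFrame:
        """Mean, SD and 10th/90th percentiles of ROCAUC and PRAUC."""
        rows = {
            "rocauc": self._summ(self.roc_aucs),
            "prauc": self._summ(self.pr_aucs),
        }
        df = pd.DataFrame(rows).T
        df.index.name = self.name
        return df

    def compare(self, other: "PneumonitisResults", metric: str = "rocauc",
                paired: bool = False) -> tuple[float, float]:
        return compare_models(self, other, metric=metric, paired=paired)

    def metric_values(self, metric: str) -> np.ndarray:
        if metric == "rocauc":
            return self.roc_aucs
        if metric == "prauc":
            return self.pr_aucs
        raise ValueError(f"unknown metric {metric!r}")


class PneumonitisModel:
    """RP prediction model evaluated by nested Monte-Carlo cross-validation.

    Parameters
    ----------
    table : DataFrame holding the feature columns (plus any metadata).
    labels : binary outcome per row (1 = RP positive).
    feature_set : columns to model; rows with missing values in these
        columns are dropped listwise (logged).
    config : :class:`EvalConfig`.
    name : label used in summaries.
    selection : optional ``(SelectionConfig, group)`` pair enabling the
        anti-leakage variant that redoes feature selection inside each outer
        training split instead of using a fixed ``feature_set``.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        labels,
        feature_set,
        config: EvalConfig = EvalConfig(),
        name: str = "model",
        selection: tuple[SelectionConfig, str] | None = None,
    ) -> None:
        feature_set = list(feature_set)
        missing = [c for c in feature_set if c not in table.columns]
        if missing:
            raise KeyError(f"feature columns not in table: {missing}")
        y = np.asarray(labels, dtype=int)
        if y.size != len(table):
            raise ValueError("labels length does not match table")
        sub = table[feature_set] if selection is None else table
        keep = ~table[feature_set].isna().any(axis=1).to_numpy()
        if not keep.all():
            logger.info("%s: excluding %d patients with missing features",
                        name, int((~keep).sum()))
        self.table = sub.loc[keep].reset_index(drop=True)
        self.endog = y[keep]
        if len(np.unique(self.endog)) < 2:
            raise ValueError("labels must contain both classes")
        self.feature_set = tuple(feature_set)
        self.config = config
        self.name = name
        self.selection = selection

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, group_columns, label_column: str = "label",
                       **kwargs) -> "PneumonitisModel":
        return cls(df, df[label_column].to_numpy(), group_columns, **kwargs)

    # -- fitting ------------------------------------------------------------

    def _inner_select_strength(
        self, x_tr: np.ndarray, y_tr: np.ndarray, rng: np.random.Generator
    ) -> float:
        cfg = self.config
        grid = cfg.reg_strength_grid
        val_scores = np.zeros(len(grid))
        val_counts = np.zeros(len(grid))
        for _ in range(cfg.n_inner_splits):
            tr, va = _stratified_split(y_tr, cfg.inner_val_fraction, rng)
            xb, yb = smote_balance(x_tr[tr], y_tr[tr], k=cfg.smote_k, rng=rng)
            for gi, lam in enumerate(grid):
                coef, icpt = fit_l2_logistic(xb, yb, reg_strength=lam)
                val_scores[gi] += roc_auc(predict_proba(x_tr[va], coef, icpt), y_tr[va])
                val_counts[gi] += 1
        return grid[int(np.argmax(val_scores / val_counts))]

    def fit(self) -> PneumonitisResults:
        cfg = self.config
        y = self.endog
        n = y.size
        rocs = np.empty(cfg.n_outer_splits)
        prs = np.empty(cfg.n_outer_splits)
        lams = np.empty(cfg.n_outer_splits)
        scaler_sums = np.empty(cfg.n_outer_splits)
        test_sets: list[np.ndarray] = []
        for s in range(cfg.n_outer_splits):
            rng = np.random.default_rng(
                np.random.SeedSequence((cfg.seed % (2**31), 23, s))
            )
            train, test = _stratified_split(y, cfg.outer_test_fraction, rng)
            features = list(self.feature_set)
            if self.selection is not None:
                sel_cfg, group = self.selection
                result = select_features(
                    self.table.iloc[train], y[train], group, sel_cfg
                )
                features = list(result.selected)
            x = self.table[features].to_numpy(dtype=float)
            scaler = Standardizer().fit(x[train])
            x_tr = scaler.transform(x[train])
            x_te = scaler.transform(x[test])
            y_tr, y_te = y[train], y[test]

            lam = self._inner_select_strength(x_tr, y_tr, rng)
            xb, yb = smote_balance(x_tr, y_tr, k=cfg.smote_k, rng=rng)
            coef, icpt = fit_l2_logistic(xb, yb, reg_strength=lam)
            scores = predict_proba(x_te, coef, icpt)
            rocs[s] = roc_auc(scores, y_te)
            prs[s] = pr_auc(scores, y_te)
            lams[s] = lam
            scaler_sums[s] = float(scaler.mean_.sum())
            test_sets.append(test)
        logger.info("%s: mean test ROCAUC %.3f, PRAUC %.3f over %d splits",
                    self.name, rocs.mean(), prs.mean(), cfg.n_outer_splits)
        return PneumonitisResults(
            name=self.name,
            roc_aucs=rocs,
            pr_aucs=prs,
            chosen_strengths=lams,
            scaler_mean_sums=scaler_sums,
            test_indices=tuple(test_sets),
            config=cfg,
            feature_set=tuple(self.feature_set),
        )


def evaluate_model(
    table: pd.DataFrame,
    labels,
    feature_set,
    cfg: EvalConfig = EvalConfig(),
    name: str = "model",
) -> PneumonitisResults:
    """Functional wrapper: build a :class:`PneumonitisModel` and fit it."""
    return PneumonitisModel(table, labels, feature_set, cfg, name=name).fit()


def compare_models(
    a: PneumonitisResults, b: PneumonitisResults, metric: str = "rocauc",
    paired: bool = False,
) -> tuple[float, float]:
    """Z-test on the mean per-split metric of two models (unpaired default)."""
    return z_test(a.metric_values(metric), b.metric_values(metric), paired=paired)


def transfer_evaluate(
    source_selected,
    target_table: pd.DataFrame,
    target_labels,
    cfg: EvalConfig = EvalConfig(),
    name: str = "transfer",
) -> PneumonitisResults:
    """Evaluate features selected on a source cohort on a target cohort.

    The source-selected feature names must all exist in the target table;
    missing columns raise ``KeyError`` naming them.
    """
    return PneumonitisModel(
        target_table, target_labels, list(source_selected), cfg, name=name
    ).fit()
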