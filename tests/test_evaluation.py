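"""Nested Monte-Carlo CV evaluation: determinism, leakage audit, bounds,
summaries and transfer."""

import numpy as np
import pandas as pd
import pytest

from dosiomics_rp import (
    EvalConfig,
    PneumonitisModel,
    compare_models,
    evaluate_model,
    transfer_evaluate,
)

FAST = dict(
    n_outer_splits=12,
    n_inner_splits=6,
    reg_strength_grid=(0.01, 1.0, 100.0),
)


def _toy(n=60, d=6, signal=1.5, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, d))
    logits = signal * x[:, 0] + rng.standard_normal(n)
    y = (logits > np.median(logits)).astype(int)
    df = pd.DataFrame(x, columns=[f"f{i}" for i in range(d)])
    return df, y


def test_determinism_under_fixed_seed():
    df, y = _toy()
    cfg = EvalConfig(seed=4, **FAST)
    a = PneumonitisModel(df, y, df.columns, cfg).fit()
    b = PneumonitisModel(df, y, df.columns, cfg).fit()
    np.testing.assert_array_equal(a.roc_aucs, b.roc_aucs)
    np.testing.assert_array_equal(a.pr_aucs, b.pr_aucs)
    np.testing.assert_array_equal(a.chosen_strengths, b.chosen_strengths)


def test_metric_bounds_and_summary_consistency():
    df, y = _toy(seed=1)
    res = evaluate_model(df, y, df.columns, EvalConfig(seed=1, **FAST))
    assert ((res.roc_aucs >= 0) & (res.roc_aucs <= 1)).all()
    assert ((res.pr_aucs >= 0) & (res.pr_aucs <= 1)).all()
    s = res.summary()
    assert s.loc["rocauc", "mean"] == pytest.approx(res.roc_aucs.mean())
    assert s.loc["rocauc", "sd"] == pytest.approx(res.roc_aucs.std(ddof=1))
    assert s.loc["prauc", "p10"] == pytest.approx(np.percentile(res.pr_aucs, 10))
    assert s.loc["prauc", "p90"] == pytest.approx(np.percentile(res.pr_aucs, 90))


def test_signal_recovered_on_separated_data():
    df, y = _toy(n=80, signal=3.0, seed=2)
    res = evaluate_model(df, y, ["f0"], EvalConfig(seed=2, **FAST))
    assert res.roc_aucs.mean() > 0.8


def test_no_leakage_audit():
    """Perturbing rows leaves training artifacts of splits where those rows
    are in the test portion unchanged."""
    df, y = _toy(seed=3)
    cfg = EvalConfig(seed=3, **FAST)
    base = PneumonitisModel(df, y, df.columns, cfg).fit()
    victim = 7
    df2 = df.copy()
    df2.iloc[victim] = df2.iloc[victim] * 10 + 5.0
    pert = PneumonitisModel(df2, y, df.columns, cfg).fit()
    audited = 0
    for s, test_idx in enumerate(base.test_indices):
        if victim in test_idx:
            audited += 1
            assert base.chosen_strengths[s] == pert.chosen_strengths[s]
            assert base.scaler_mean_sums[s] == pert.scaler_mean_sums[s]
    assert audited > 0


def test_missing_rows_dropped_listwise():
    df, y = _toy(seed=5)
    df.loc[3, "f1"] = np.nan
    model = PneumonitisModel(df, y, df.columns, EvalConfig(seed=5, **FAST))
    assert len(model.table) == len(df) - 1


def test_missing_columns_named_in_error():
    df, y = _toy(seed=6)
    with pytest.raises(KeyError, match="not_a_feature"):
        transfer_evaluate(["f0", "not_a_feature"], df, y, EvalConfig(**FAST))


def test_transfer_runs_on_matching_columns():
    df_a, y_a = _toy(seed=7)
    df_b, y_b = _toy(seed=8)
    res = transfer_evaluate(["f0", "f1"], df_b, y_b, EvalConfig(seed=8, **FAST))
    assert res.roc_aucs.size == FAST["n_outer_splits"]


def test_compare_models_symmetry_and_pairing():
    df, y = _toy(seed=9)
    a = evaluate_model(df, y, ["f0"], EvalConfig(seed=9, **FAST))
    b = evaluate_model(df, y, ["f1"], EvalConfig(seed=9, **FAST))
    z_ab, p_ab = compare_models(a, b)
    z_ba, p_ba = compare_models(b, a)
    assert z_ab == pytest.approx(-z_ba)
    assert p_ab == pytest.approx(p_ba)
    z_p, p_p = compare_models(a, b, paired=True)
    assert np.isfinite(z_p) and 0 <= p_p <= 1


def test_within_cv_selection_mode_runs(small_table):
    from dosiomics_rp import SelectionConfig

    y = small_table["label"].to_numpy()
    cfg = EvalConfig(seed=10, n_outer_splits=3, n_inner_splits=4,
                     reg_strength_grid=(0.1, 10.0))
    sel_cfg = SelectionConfig(n_repeats=1, top_k=3, seed=10)
    model = PneumonitisModel(
        small_table, y, small_table.columns[4:19], cfg, name="dvh-within-cv",
        selection=(sel_cfg, "dvh"),
    )
    res = model.fit()
    assert res.roc_aucs.size == 3
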