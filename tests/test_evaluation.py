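"""Metrics, fold bookkeeping, statistical comparisons, harness plumbing."""

import numpy as np
import pandas as pd
import pytest

from dcan.errors import DomainError
from dcan.evaluation import (
    ABLATION_CONFIGS,
    CVSpec,
    FoldResult,
    aggregate_fold_metrics,
    baseline_harness,
    bland_altman,
    kendalls_w,
    paired_t_test,
    prepare_windows,
    regression_metrics,
    repeated_patient_kfold,
    run_cv,
    summarize_folds,
)
from dcan.features import FeatureConfig
from dcan.model import ModelConfig
from dcan.training import TrainConfig


# ---------------------------------------------------------------------------
# metrics


def test_metrics_perfect_prediction():
    y = np.array([1.0, 2.0, 3.0])
    assert regression_metrics(y, y) == (0.0, 0.0, 0.0, 1.0)


def test_metrics_mean_predictor_has_zero_r2():
    y = np.array([1.0, 2.0, 3.0, 6.0])
    yhat = np.full(4, y.mean())
    mae, mse, rmse, r2 = regression_metrics(y, yhat)
    assert r2 == pytest.approx(0.0, abs=1e-12)


def test_metrics_hand_computed_four_points():
    y = np.array([1.0, 2.0, 3.0, 4.0])
    yhat = np.array([1.5, 2.0, 2.5, 5.0])
    mae, mse, rmse, r2 = regression_metrics(y, yhat)
    # errors: 0.5, 0, -0.5, 1 -> MAE 0.5, MSE (0.25+0+0.25+1)/4 = 0.375
    assert mae == pytest.approx(0.5)
    assert mse == pytest.approx(0.375)
    assert rmse == pytest.approx(np.sqrt(0.375))
    assert r2 == pytest.approx(1.0 - 1.5 / 5.0)


def test_metrics_zero_variance_targets_flagged():
    mae, mse, rmse, r2 = regression_metrics(np.ones(3), np.ones(3) * 2)
    assert np.isnan(r2)


# ---------------------------------------------------------------------------
# paired t and Kendall's W


def test_paired_t_identical_samples():
    t, p = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == 0.0 and p == 1.0


def test_paired_t_textbook_example_matches_formula():
    a = np.array([3.0, 4.0, 5.0, 6.0, 7.0])
    b = np.array([2.5, 4.5, 4.0, 5.0, 8.0])
    t, p = paired_t_test(a, b)
    d = a - b
    t_expect = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    assert t == pytest.approx(t_expect, abs=1e-12)
    from scipy.stats import t as tdist

    assert p == pytest.approx(2 * tdist.sf(abs(t_expect), len(d) - 1), abs=1e-12)


def test_paired_t_antisymmetry():
    a = [1.0, 2.0, 4.0, 3.0]
    b = [1.5, 1.0, 5.0, 2.0]
    t_ab, p_ab = paired_t_test(a, b)
    t_ba, p_ba = paired_t_test(b, a)
    assert t_ab == pytest.approx(-t_ba)
    assert p_ab == pytest.approx(p_ba)


def test_paired_t_exact_tie_flag():
    t, p = paired_t_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
    assert np.isinf(t) and p == 0.0


def test_kendalls_w_identical_rankings():
    ranks = np.tile([1.0, 2.0, 3.0, 4.0], (5, 1))
    assert kendalls_w(ranks) == pytest.approx(1.0)


def test_kendalls_w_two_reversed_rankings():
    # rank sums all equal -> S = 0 -> W = 0
    ranks = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
    assert kendalls_w(ranks) == pytest.approx(0.0)


def test_kendalls_w_matches_brute_force_oracle(rng):
    from scipy.stats import rankdata

    scores = rng.normal(size=(6, 4))
    ranks = np.apply_along_axis(rankdata, 1, scores)
    w = kendalls_w(ranks)
    m, k = ranks.shape
    rank_sums = ranks.sum(axis=0)
    s = np.sum((rank_sums - rank_sums.mean()) ** 2)
    expect = 12 * s / (m**2 * (k**3 - k))  # no ties in continuous scores
    assert w == pytest.approx(expect, abs=1e-12)
    assert 0.0 <= w <= 1.0


def test_kendalls_w_degenerate_input_rejected():
    with pytest.raises(DomainError):
        kendalls_w(np.array([[1.0, 2.0]]))


# ---------------------------------------------------------------------------
# Bland-Altman


def test_bland_altman_identity():
    y = np.array([1.0, 2.0, 3.0])
    assert bland_altman(y, y) == (0.0, 0.0, 0.0)


def test_bland_altman_constant_offset():
    y = np.array([1.0, 2.0, 3.0])
    bias, lo, hi = bland_altman(y, y + 2.0)
    assert bias == pytest.approx(2.0)
    assert lo == pytest.approx(2.0) and hi == pytest.approx(2.0)


def test_bland_altman_matches_formula(rng):
    y = rng.normal(size=30)
    yhat = y + rng.normal(0, 0.5, size=30)
    bias, lo, hi = bland_altman(y, yhat)
    d = yhat - y
    assert bias == pytest.approx(d.mean())
    assert lo == pytest.approx(d.mean() - 1.96 * d.std(ddof=1))
    assert hi == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))


# ---------------------------------------------------------------------------
# fold bookkeeping


def test_repeated_kfold_42_patients_fold_sizes():
    ids = [str(i) for i in range(1, 43)]
    table = repeated_patient_kfold(ids, k=5, repeats=8, seed=0)
    sizes = table.groupby(["repetition", "fold"]).size()
    assert set(sizes) <= {8, 9}
    assert len(sizes) == 40


def test_repeated_kfold_each_patient_tested_exactly_repeats_times():
    ids = [str(i) for i in range(1, 43)]
    table = repeated_patient_kfold(ids, k=5, repeats=8, seed=0)
    counts = table["subject_id"].value_counts()
    assert set(counts) == {8}


def test_repeated_kfold_partition_per_repetition():
    ids = [str(i) for i in range(1, 43)]
    table = repeated_patient_kfold(ids, k=5, repeats=3, seed=1)
    for rep, grp in table.groupby("repetition"):
        assert sorted(grp["subject_id"]) == sorted(ids)
        folds = [set(g["subject_id"]) for _, g in grp.groupby("fold")]
        for i in range(len(folds)):
            for j in range(i + 1, len(folds)):
                assert not (folds[i] & folds[j])


def test_repeated_kfold_repetitions_differ():
    ids = [str(i) for i in range(1, 21)]
    table = repeated_patient_kfold(ids, k=4, repeats=2, seed=0)
    rep1 = table[table.repetition == 1].groupby("fold")["subject_id"].apply(set)
    rep2 = table[table.repetition == 2].groupby("fold")["subject_id"].apply(set)
    assert any(rep1[f] != rep2[f] for f in rep1.index)


def test_repeated_kfold_rejects_too_many_folds():
    with pytest.raises(DomainError):
        repeated_patient_kfold(["a", "b"], k=3, repeats=1)


# ---------------------------------------------------------------------------
# aggregation


def test_aggregation_closed_form():
    agg = aggregate_fold_metrics([1.0, 2.0, 3.0])
    assert agg["mean"] == pytest.approx(2.0)
    assert agg["sd"] == pytest.approx(1.0)
    assert agg["range"] == pytest.approx(2.0)
    assert agg["min"] == 1.0 and agg["max"] == 3.0
    assert agg["cv_pct"] == pytest.approx(50.0)
    from scipy.stats import t as tdist

    half = tdist.ppf(0.975, 2) * 1.0 / np.sqrt(3)
    assert agg["ci_low"] == pytest.approx(2.0 - half)
    assert agg["ci_high"] == pytest.approx(2.0 + half)


def test_aggregation_identical_values_zero_width_ci():
    agg = aggregate_fold_metrics([0.7] * 6)
    assert agg["sd"] == pytest.approx(0.0, abs=1e-12)
    assert agg["ci_high"] - agg["ci_low"] == pytest.approx(0.0, abs=1e-12)
    assert agg["ci_low"] == pytest.approx(0.7) and agg["ci_high"] == pytest.approx(0.7)
    assert agg["range"] == 0.0


def test_aggregation_matches_independent_recomputation(rng):
    vals = rng.uniform(0.5, 1.5, size=40)
    agg = aggregate_fold_metrics(vals)
    assert agg["mean"] == pytest.approx(vals.mean())
    assert agg["sd"] == pytest.approx(vals.std(ddof=1))
    assert agg["ci_high"] - agg["ci_low"] == pytest.approx(
        2 * 2.0226909117 * vals.std(ddof=1) / np.sqrt(40), rel=1e-6)
    # CI contains the mean and is symmetric
    assert agg["ci_low"] <= agg["mean"] <= agg["ci_high"]


def test_fold_result_rmse_mse_identity():
    FoldResult(1, 1, ("a",), mae=0.5, mse=0.49, rmse=0.7, r2=0.9)
    with pytest.raises(AssertionError):
        FoldResult(1, 1, ("a",), mae=0.5, mse=0.5, rmse=0.9, r2=0.9)


def test_summarize_folds_shape():
    folds = [FoldResult(1, i, (str(i),), 0.5, 0.25, 0.5, 0.9) for i in range(1, 4)]
    frame = summarize_folds(folds)
    assert list(frame.index) == ["mae", "mse", "rmse", "r2"]
    assert "ci_low" in frame.columns


# ---------------------------------------------------------------------------
# ablation bookkeeping


def test_pct_change_formula_published_values():
    """RMSE 0.7273 -> 0.6727 is the published -7.5% full-vs-clinical change."""
    change = 100.0 * (0.6727 - 0.7273) / 0.7273
    assert change == pytest.approx(-7.5, abs=0.01)


def test_ablation_config_names_cover_published_grid():
    assert set(ABLATION_CONFIGS) == {
        "clinical_only", "text_only", "clinical_text", "clinical_meta",
        "clinical_voice_meta", "full"}
    assert ABLATION_CONFIGS["full"] == ("voice", "clinical", "meta", "text")


# ---------------------------------------------------------------------------
# harness smoke tests (tiny budgets; correctness of plumbing, not accuracy)


@pytest.fixture(scope="module")
def tiny_cv_setup(small_cohort):
    spec = CVSpec(k=2, repeats=1, seed=0, window_stride=6)
    fcfg = FeatureConfig()
    windows = prepare_windows(small_cohort, fcfg, spec)
    return spec, fcfg, windows


def test_run_cv_patient_disjointness_and_schema(small_cohort, tiny_cv_setup):
    spec, fcfg, windows = tiny_cv_setup
    mcfg = ModelConfig(seed=0).ablation_preset(modalities=("clinical",))
    tcfg = TrainConfig(rng_seed=0, max_epochs=2, early_stop_patience=2)
    report = run_cv(small_cohort, mcfg, tcfg, spec, feature_config=fcfg,
                    windows=windows, collect_predictions=True)
    assert len(report.folds) == 2
    tested = [pid for f in report.folds for pid in f.test_patients]
    assert sorted(tested) == sorted(windows)  # partition
    for f in report.folds:
        assert f.rmse**2 == pytest.approx(f.mse, abs=1e-9)
    assert report.predictions is not None
    assert {"repetition", "fold", "y", "y_hat"} <= set(report.predictions.columns)


def test_baseline_harness_shares_folds_and_schema(small_cohort, tiny_cv_setup):
    spec, fcfg, windows = tiny_cv_setup
    table = baseline_harness(small_cohort, spec, feature_config=fcfg,
                             models=("ridge", "random_forest"), windows=windows,
                             rf_estimators=10)
    assert set(table["model"]) == {"ridge", "random_forest"}
    assert "error" not in table.columns or table["error"].isna().all()
    assert {"mae", "rmse", "r2"} <= set(table.columns)
    assert len(table) == 2 * 2  # 2 models x 2 folds
    # same fold structure as repeated_patient_kfold would give
    folds = repeated_patient_kfold(list(windows), k=spec.k, repeats=spec.repeats,
                                   seed=spec.seed)
    assert set(table["fold"]) == set(folds["fold"])


def test_ridge_with_huge_regularization_predicts_training_mean(small_cohort, tiny_cv_setup):
    from sklearn.linear_model import Ridge

    spec, fcfg, windows = tiny_cv_setup
    pool = [s for v in windows.values() for s in v]
    from dcan.evaluation import _flatten_final
    from dcan.training import apply_scalers, fit_scalers

    scaled = apply_scalers(pool, fit_scalers(pool))
    X = _flatten_final(scaled, include_text=False)
    y = np.array([s.y for s in scaled])
    model = Ridge(alpha=1e12).fit(X, y)
    preds = model.predict(X)
    np.testing.assert_allclose(preds, y.mean(), atol=0.05)
    _, _, _, r2 = regression_metrics(y, preds)
    assert r2 == pytest.approx(0.0, abs=1e-3)
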