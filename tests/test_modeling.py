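"""Regressors, metrics, cross-validation, greedy selection and trimming."""

import math

import numpy as np
import pandas as pd
import pytest

from ligsig.curation import LigandRecord
from ligsig.modeling import (
    ALGORITHMS,
    MetricsReport,
    ModelSpec,
    cross_measure_experiment,
    cross_validate,
    evaluate,
    greedy_forward_selection,
    outlier_trimmed_metrics,
    select_best_model,
    top_feature_usage,
    train_model,
)
from ligsig.splitting import stratified_kfold


def _toy_features(n=40, p=4, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.normal(size=(n, p)), columns=[f"f{i}" for i in range(p)])


# ----------------------------------------------------------------- training

@pytest.mark.parametrize("algorithm", ALGORITHMS)
def test_train_predict_deterministic(algorithm):
    X = _toy_features()
    y = X["f0"].to_numpy() + 0.1
    a = train_model(X, y, algorithm, n_estimators=20).predict(X)
    b = train_model(X, y, algorithm, n_estimators=20).predict(X)
    assert np.isfinite(a).all()
    assert np.array_equal(a, b)


def test_constant_targets_give_constant_predictions():
    X = _toy_features()
    y = np.full(len(X), 5.5)
    preds = train_model(X, y, "random_forest", n_estimators=10).predict(X)
    assert np.allclose(preds, 5.5)


def test_train_rejects_unknown_algorithm():
    with pytest.raises(ValueError, match="unknown algorithm"):
        train_model(_toy_features(), np.zeros(40), "deep_net")


def test_train_rejects_tiny_or_missing_data():
    X = _toy_features(n=5)
    with pytest.raises(ValueError, match="at least 10"):
        train_model(X, np.zeros(5), "random_forest")
    X = _toy_features()
    X.iloc[0, 0] = np.nan
    with pytest.raises(ValueError, match="missing"):
        train_model(X, np.zeros(40), "random_forest")


# ---------------------------------------------------------------- evaluation

def test_perfect_predictions():
    rep = evaluate([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
    assert rep.pearson_r == pytest.approx(1.0)
    assert rep.mse == 0.0 and rep.rmse == 0.0


def test_reversed_ranks_give_spearman_minus_one():
    rep = evaluate([4.0, 3.0, 2.0, 1.0], [1.0, 2.0, 3.0, 4.0])
    assert rep.spearman_rho == pytest.approx(-1.0)
    assert rep.kendall_tau == pytest.approx(-1.0)


def test_closed_form_three_point_metrics():
    rep = evaluate([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
    assert rep.pearson_r == pytest.approx(1.0, abs=1e-12)
    assert rep.mse == pytest.approx((1 + 4 + 9) / 3, abs=1e-12)
    assert rep.rmse == pytest.approx(math.sqrt(rep.mse), abs=1e-12)


def test_zero_variance_reports_missing_correlations():
    rep = evaluate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    assert rep.pearson_r is None and rep.spearman_rho is None and rep.kendall_tau is None
    assert rep.mse > 0


def test_evaluate_length_mismatch():
    with pytest.raises(ValueError):
        evaluate([1.0, 2.0], [1.0, 2.0, 3.0])


# ----------------------------------------------------------- cross-validation

def test_cv_pools_every_row_exactly_once():
    X = _toy_features(n=30)
    y = X["f0"].to_numpy()
    folds = stratified_kfold(y, k=5, seed=0)
    report, per_fold, pooled = cross_validate(X, y, "extra_trees", folds, n_estimators=10)
    assert report.n == 30 and len(pooled) == 30
    assert np.isfinite(pooled).all()
    assert len(per_fold) == 5


def test_cv_leave_one_out_runs():
    X = _toy_features(n=12)
    y = X["f0"].to_numpy()
    folds = np.arange(12)
    report, _, pooled = cross_validate(X, y, "extra_trees", folds, n_estimators=5)
    assert len(pooled) == 12 and np.isfinite(pooled).all()


def test_cv_noise_free_signal_recovered():
    X = _toy_features(n=120, p=3, seed=2)
    y = 6.0 + X["f0"].to_numpy() + 0.5 * X["f1"].to_numpy()
    folds = stratified_kfold(y, k=5, seed=0)
    report, _, _ = cross_validate(X, y, "extra_trees", folds, n_estimators=50)
    assert report.pearson_r >= 0.95


# ------------------------------------------------------------ greedy selection

def test_greedy_picks_the_true_feature_first():
    X = _toy_features(n=60, p=5, seed=3)
    y = X["f2"].to_numpy() * 2.0 + 5.0
    folds = stratified_kfold(y, k=5, seed=0)
    selected, trace = greedy_forward_selection(X, y, "extra_trees", folds, n_estimators=20)
    assert selected[0] == "f2"
    assert trace[0] > 0.9


def test_greedy_never_prefers_constant_feature():
    X = _toy_features(n=60, p=3, seed=4)
    X["dead"] = 1.0
    y = X["f0"].to_numpy() + 0.1 * np.random.default_rng(0).normal(size=60)
    folds = stratified_kfold(y, k=5, seed=0)
    selected, _ = greedy_forward_selection(X, y, "extra_trees", folds, n_estimators=20)
    informative = [f for f in selected if f != "dead"]
    assert selected.index("f0") < (selected.index("dead") if "dead" in selected else len(selected))
    assert informative[0] == "f0"


def test_greedy_first_pick_equals_exhaustive_singleton():
    for seed in range(3):
        X = _toy_features(n=50, p=3, seed=10 + seed)
        rng = np.random.default_rng(seed)
        y = X["f1"].to_numpy() + 0.3 * rng.normal(size=50)
        folds = stratified_kfold(y, k=5, seed=0)

        def singleton_score(col):
            rep, _, _ = cross_validate(X[[col]], y, "extra_trees", folds, n_estimators=20)
            return rep.pearson_r

        best = max(X.columns, key=singleton_score)
        selected, _ = greedy_forward_selection(X, y, "extra_trees", folds, n_estimators=20)
        assert selected[0] == best


def test_greedy_requires_two_candidates():
    X = _toy_features(p=1)
    with pytest.raises(ValueError):
        greedy_forward_selection(X, np.zeros(40), "extra_trees", np.zeros(40, dtype=int))


# ------------------------------------------------------------ model selection

def _report(pearson, rmse):
    return MetricsReport(pearson, pearson, pearson, rmse**2, rmse, 50)


def test_select_best_single_candidate():
    alg, rep = select_best_model({"xgboost": _report(0.8, 0.5)})
    assert alg == "xgboost"


def test_select_best_pearson_then_rmse():
    reports = {
        "random_forest": _report(0.85, 0.60),
        "extra_trees": _report(0.85, 0.55),
        "gradient_boost": _report(0.80, 0.10),
    }
    alg, _ = select_best_model(reports)
    assert alg == "extra_trees"


def test_select_best_fixed_order_tiebreak():
    reports = {a: _report(0.85, 0.55) for a in ("xgboost", "random_forest")}
    alg, _ = select_best_model(reports)
    assert alg == "random_forest"  # earlier in the canonical algorithm order


# ---------------------------------------------------------- outlier trimming

def test_trim_perfect_predictions_only_changes_n():
    y = np.linspace(4, 9, 20)
    rep, dropped = outlier_trimmed_metrics(y, y)
    assert rep.n == 18 and rep.mse == 0.0
    assert len(dropped) == 2  # ceil(0.1 * 20)


def test_trim_removes_the_gross_outlier():
    y = np.linspace(5, 7, 10)
    p = y.copy()
    p[4] += 10.0
    rep, dropped = outlier_trimmed_metrics(p, y, identities=[f"m{i}" for i in range(10)])
    assert dropped == ["m4"]
    assert rep.mse == pytest.approx(0.0)


def test_trim_never_increases_mse():
    rng = np.random.default_rng(5)
    for _ in range(10):
        y = rng.normal(6, 1, 37)
        p = y + rng.normal(0, 1, 37)
        full = evaluate(p, y)
        trimmed, dropped = outlier_trimmed_metrics(p, y)
        assert trimmed.mse <= full.mse
        assert len(dropped) == math.ceil(0.1 * 37)


def test_trim_fraction_bounds():
    y = np.zeros(10)
    with pytest.raises(ValueError):
        outlier_trimmed_metrics(y, y, trim_fraction=0.0)
    with pytest.raises(ValueError):
        outlier_trimmed_metrics(y, y, trim_fraction=0.6)


# ------------------------------------------------------------- feature usage

def test_top_feature_usage_counts():
    m1 = ModelSpec("random_forest", ["a", "b"], None, selection_order=["a", "b", "c"])
    m2 = ModelSpec("extra_trees", ["a"], None, selection_order=["a", "d"])
    counts = top_feature_usage([m1, m2], top_k=2)
    assert counts["a"] == 2 and counts["b"] == 1 and counts["d"] == 1
    assert counts.sum() == min(2, 3) + min(2, 2)
    assert "c" not in counts.index


# ------------------------------------------------------- cross-measure study

def test_cross_measure_larger_group_trains(small_library):
    rng = np.random.default_rng(0)
    records = []
    for i, smi in enumerate(small_library[:40]):
        bio = rng.normal(6.5, 1.0)
        mt = "Ki" if i < 25 else "IC50"
        records.append(LigandRecord(smi, mt, 10.0 ** (-bio)))

    def featurizer(smiles):
        from ligsig.descriptors import combined_feature_matrix

        return combined_feature_matrix(smiles)

    reports = cross_measure_experiment(records, featurizer, "extra_trees", k=5, n_estimators=15)
    assert reports["train_cv"].n == 25  # Ki group is larger, so it trains
    assert reports["cross_measure_test"].n == 15


def test_cross_measure_offset_inflates_mse_not_pearson(small_records):
    records, truth = small_records
    offset = 1.5
    shifted = []
    for i, smi in enumerate(truth.index):
        bio = truth.loc[smi, "true_bioactivity"]
        if i % 3 == 0:
            shifted.append(LigandRecord(smi, "IC50", 10.0 ** (-(bio + offset))))
        else:
            shifted.append(LigandRecord(smi, "Ki", 10.0 ** (-bio)))

    def featurizer(smiles):
        from ligsig.descriptors import combined_feature_matrix

        return combined_feature_matrix(smiles)

    reports = cross_measure_experiment(shifted, featurizer, "extra_trees", k=5, n_estimators=30)
    test_rep = reports["cross_measure_test"]
    # systematic shift: correlation survives, squared error absorbs ~offset^2
    assert test_rep.pearson_r > 0.6
    assert test_rep.mse > 0.5 * offset**2


def test_cross_measure_empty_group_is_hard_error(small_library):
    records = [LigandRecord(s, "Ki", 1e-6) for s in small_library[:12]]

    def featurizer(smiles):
        from ligsig.descriptors import combined_feature_matrix

        return combined_feature_matrix(smiles)

    with pytest.raises(ValueError, match="IC50"):
        cross_measure_experiment(records, featurizer, "extra_trees")
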