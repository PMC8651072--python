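"""Tree-ensemble regression, evaluation and feature selection.

Four regressor families are supported — Random Forest, Extra Trees,
Gradient Boosting and XGBoost — trained with a fixed random seed (0)
and otherwise default hyperparameters; no hyperparameter tuning is
performed.  Evaluation reports Pearson, Spearman and Kendall (tau-b)
correlations together with MSE/RMSE; cross-validation pools
out-of-fold predictions so each training ligand is scored exactly once.
Forward-greedy feature selection adds, at each step, the single feature
that most improves pooled cross-validated Pearson correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import (
    ExtraTreesRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from xgboost import XGBRegressor

ALGORITHMS = ("random_forest", "extra_trees", "gradient_boost", "xgboost")

#: Fixed estimator seed; every ensemble is reproducible bit-for-bit.
RANDOM_STATE = 0


def _make_estimator(algorithm: str, n_estimators: int | None = None):
    kw = {} if n_estimators is None else {"n_estimators": n_estimators}
    if algorithm == "random_forest":
        return RandomForestRegressor(random_state=RANDOM_STATE, **kw)
    if algorithm == "extra_trees":
        return ExtraTreesRegressor(random_state=RANDOM_STATE, **kw)
    if algorithm == "gradient_boost":
        return GradientBoostingRegressor(random_state=RANDOM_STATE, **kw)
    if algorithm == "xgboost":
        return XGBRegressor(random_state=RANDOM_STATE, n_jobs=1, **kw)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


@dataclass
class ModelSpec:
    """A fitted regressor plus the metadata needed to reproduce it."""

    algorithm: str
    feature_names: list[str]
    estimator: object
    random_state: int = RANDOM_STATE
    selection_order: list[str] | None = None  # greedy pick order, if selected

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        X = np.asarray(features[self.feature_names], dtype=np.float64)
        return np.asarray(self.estimator.predict(X), dtype=np.float64)

    @property
    def feature_importances(self) -> pd.Series:
        """Impurity-based importances of the fitted ensemble."""
        return pd.Series(
            np.asarray(self.estimator.feature_importances_, dtype=float),
            index=self.feature_names,
        ).sort_values(ascending=False)


@dataclass
class MetricsReport:
    """Correlation and error metrics for one (model, evaluation set) pair.

    Correlations are None when either side has zero variance (they are
    undefined there, and reporting 0 would be misleading).
    """

    pearson_r: float | None
    spearman_rho: float | None
    kendall_tau: float | None
    mse: float
    rmse: float
    n: int
    set_label: str = ""

    def to_dict(self) -> dict:
        return {
            "set_label": self.set_label,
            "n": self.n,
            "pearson_r": self.pearson_r,
            "spearman_rho": self.spearman_rho,
            "kendall_tau": self.kendall_tau,
            "mse": self.mse,
            "rmse": self.rmse,
        }


def train_model(
    features: pd.DataFrame,
    targets: Sequence[float],
    algorithm: str,
    n_estimators: int | None = None,
) -> ModelSpec:
    """Fit one tree ensemble on a feature table.

    ``n_estimators`` overrides the ensemble size for quick smoke runs;
    by default every hyperparameter except the seed is the library
    default.
    """
    y = np.asarray(targets, dtype=np.float64)
    if len(features) != len(y):
        raise ValueError("features and targets differ in length")
    if len(y) < 10:
        raise ValueError(f"need at least 10 training rows, got {len(y)}")
    X = np.asarray(features, dtype=np.float64)
    if np.isnan(X).any():
        raise ValueError("feature table contains missing values; impute or drop upstream")
    est = _make_estimator(algorithm, n_estimators)
    est.fit(X, y)
    return ModelSpec(algorithm=algorithm, feature_names=list(features.columns), estimator=est)


def evaluate(predictions: Sequence[float], targets: Sequence[float], set_label: str = "") -> MetricsReport:
    """Textbook regression metrics on a prediction/target pair."""
    p = np.asarray(predictions, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    if len(p) < 3:
        raise ValueError("need at least 3 points to report correlations")
    mse = float(np.mean((p - t) ** 2))
    if (p == p[0]).all() or (t == t[0]).all():
        pear = spear = tau = None
    else:
        pear = float(stats.pearsonr(p, t).statistic)
        spear = float(stats.spearmanr(p, t).statistic)
        tau = float(stats.kendalltau(p, t).statistic)  # tau-b: tie-corrected
    return MetricsReport(
        pearson_r=pear,
        spearman_rho=spear,
        kendall_tau=tau,
        mse=mse,
        rmse=math.sqrt(mse),
        n=len(p),
        set_label=set_label,
    )


def cross_validate(
    features: pd.DataFrame,
    targets: Sequence[float],
    algorithm: str,
    folds: np.ndarray,
    n_estimators: int | None = None,
    set_label: str = "cv",
) -> tuple[MetricsReport, list[MetricsReport], np.ndarray]:
    """Out-of-fold evaluation over a precomputed fold assignment.

    Returns the pooled report (every row predicted exactly once, by the
    model that did not see it), the per-fold reports, and the pooled
    out-of-fold prediction vector.
    """
    y = np.asarray(targets, dtype=np.float64)
    folds = np.asarray(folds)
    pooled = np.full(len(y), np.nan)
    per_fold = []
    for f in np.unique(folds):
        test = folds == f
        train = ~test
        if not test.any() or not train.any():
            raise ValueError(f"fold {f} leaves an empty train or test side")
        model = train_model(features.iloc[train], y[train], algorithm, n_estimators)
        preds = model.predict(features.iloc[test])
        pooled[test] = preds
        if test.sum() >= 3:
            per_fold.append(evaluate(preds, y[test], set_label=f"{set_label}-fold{f}"))
    report = evaluate(pooled, y, set_label=set_label)
    return report, per_fold, pooled


def greedy_forward_selection(
    features: pd.DataFrame,
    targets: Sequence[float],
    algorithm: str,
    folds: np.ndarray,
    patience: int = 1,
    max_features: int | None = None,
    n_estimators: int | None = None,
) -> tuple[list[str], list[float]]:
    """Forward-greedy feature selection on pooled CV Pearson correlation.

    Starting from the empty set, each step adds the candidate feature
    whose inclusion maximizes the pooled cross-validated Pearson r of
    the model; ties go to the earlier column in the table's canonical
    order.  Selection stops after ``patience`` consecutive steps without
    improvement, or at ``max_features``.

    Returns the selected features in pick order and the CV-score trace
    (score after each accepted pick; an unaccepted trailing pick is not
    included).
    """
    if features.shape[1] < 2:
        raise ValueError("need at least 2 candidate features")
    y = np.asarray(targets, dtype=np.float64)
    candidates = list(features.columns)
    selected: list[str] = []
    trace: list[float] = []
    best_score = -np.inf
    stall = 0
    cap = max_features or features.shape[1]
    while candidates and len(selected) < cap:
        step_best: tuple[float, int, str] | None = None
        for pos, feat in enumerate(candidates):
            cols = selected + [feat]
            report, _, _ = cross_validate(features[cols], y, algorithm, folds, n_estimators)
            score = report.pearson_r if report.pearson_r is not None else -np.inf
            if step_best is None or score > step_best[0]:
                step_best = (score, pos, feat)
        score, pos, feat = step_best
        if score <= best_score:
            stall += 1
            if stall >= patience:
                break
            # accept a non-improving pick only while patience lasts
        else:
            stall = 0
            best_score = score
        selected.append(feat)
        trace.append(score)
        candidates.pop(pos)
    return selected, trace


def select_best_model(reports: dict[str, MetricsReport]) -> tuple[str, MetricsReport]:
    """Pick the winning algorithm: highest Pearson, then lowest RMSE, then
    the fixed algorithm order as the final tie-break."""
    if not reports:
        raise ValueError("no reports to select from")
    order = {alg: i for i, alg in enumerate(ALGORITHMS)}

    def key(item):
        alg, rep = item
        pear = rep.pearson_r if rep.pearson_r is not None else -np.inf
        return (-pear, rep.rmse, order.get(alg, len(order)))

    alg, rep = min(reports.items(), key=key)
    return alg, rep


def outlier_trimmed_metrics(
    predictions: Sequence[float],
    targets: Sequence[float],
    trim_fraction: float = 0.1,
    identities: Sequence[str] | None = None,
    set_label: str = "trimmed",
) -> tuple[MetricsReport, list]:
    """Re-evaluate after dropping the worst-predicted fraction of points.

    The ceil(trim_fraction * n) rows with the largest absolute residual
    are removed (ties broken by row order) and metrics recomputed on the
    remainder; the dropped identities (indices, or ``identities``
    entries when given) are returned for inspection.
    """
    if not (0 < trim_fraction <= 0.5):
        raise ValueError(f"trim_fraction must be in (0, 0.5], got {trim_fraction}")
    p = np.asarray(predictions, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    n = len(p)
    if n < 10:
        raise ValueError("need at least 10 points to trim outliers")
    n_drop = math.ceil(trim_fraction * n)
    resid = np.abs(p - t)
    drop = np.argsort(-resid, kind="stable")[:n_drop]
    keep = np.setdiff1d(np.arange(n), drop)
    report = evaluate(p[keep], t[keep], set_label=set_label)
    dropped = [identities[i] if identities is not None else int(i) for i in drop]
    return report, dropped


def top_feature_usage(models: Sequence[ModelSpec], top_k: int = 10) -> pd.Series:
    """Tally how often each feature appears among the first ``top_k``
    greedy picks across a collection of models."""
    counts: dict[str, int] = {}
    for model in models:
        order = model.selection_order or model.feature_names
        for feat in order[:top_k]:
            counts[feat] = counts.get(feat, 0) + 1
    return pd.Series(counts, dtype=int).sort_values(ascending=False)


def cross_measure_experiment(
    records,
    featurizer: Callable[[Sequence[str]], pd.DataFrame],
    algorithm: str = "random_forest",
    group_a: Sequence[str] = ("Ki", "Kd"),
    group_b: Sequence[str] = ("IC50", "EC50"),
    max_spread: float = 1.0,
    k: int = 5,
    seed: int = 0,
    n_estimators: int | None = None,
) -> dict[str, MetricsReport]:
    """Train on one activity-measure family, test on the other.

    Records are curated separately per measure-type group (binding
    constants Ki+Kd vs functional readouts IC50+EC50); the larger
    curated group becomes the training set.  The within-training CV
    report is returned alongside the cross-measure test report, so the
    performance drop attributable to mixing measure types is visible
    directly.
    """
    from .curation import CurationError, curate_dataset
    from .splitting import stratified_kfold

    try:
        data_a = curate_dataset(records, max_spread=max_spread, measure_types=group_a)
    except CurationError:
        raise ValueError(f"measure-type group {tuple(group_a)} is empty after curation")
    try:
        data_b = curate_dataset(records, max_spread=max_spread, measure_types=group_b)
    except CurationError:
        raise ValueError(f"measure-type group {tuple(group_b)} is empty after curation")

    train_set, test_set = (data_a, data_b) if len(data_a) >= len(data_b) else (data_b, data_a)
    X_train = featurizer([lig.smiles for lig in train_set])
    X_test = featurizer([lig.smiles for lig in test_set])
    y_train = np.asarray([lig.bioactivity for lig in train_set])
    y_test = np.asarray([lig.bioactivity for lig in test_set])

    folds = stratified_kfold(y_train, k=min(k, len(y_train)), seed=seed)
    cv_report, _, _ = cross_validate(X_train, y_train, algorithm, folds, n_estimators, set_label="train-cv")
    model = train_model(X_train, y_train, algorithm, n_estimators)
    test_report = evaluate(model.predict(X_test), y_test, set_label="cross-measure-test")
    return {"train_cv": cv_report, "cross_measure_test": test_report}
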