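"""Random-forest feature importance and cross-validated evaluation.

The screening model is a random forest trained on the 27-feature table.
Feature importance is the impurity (Gini) importance averaged over the
training fits of a k-fold cross-validation; the top-k features by mean
importance are then used to re-train and evaluate the classifier.

With ~74 subjects a 50-fold split leaves 1-2 subjects per test fold, so
per-fold AUC is undefined for most folds.  The default aggregation
therefore pools out-of-fold predicted probabilities across folds and
computes one ROC AUC on the pooled predictions; averaging AUC over the
folds where it is defined is available via ``auc_aggregation``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import precision_score, recall_score, roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .features import FEATURE_NAMES, MSE_FEATURE_NAMES

logger = logging.getLogger(__name__)


class ModelError(ValueError):
    """Raised for degenerate inputs to the cross-validation machinery."""


@dataclass(frozen=True)
class CvConfig:
    """Cross-validation and random-forest settings.

    n_folds defaults to 50; rf_n_trees to 500 for stable importance
    estimates.  fold_strategy "stratified_where_possible" uses stratified
    folds whenever every class has at least n_folds members, else plain
    k-fold.  auc_aggregation chooses pooled out-of-fold AUC (default) or
    the mean over folds where AUC is defined.
    """

    n_folds: int = 50
    rf_n_trees: int = 500
    rf_hyperparams: dict = field(default_factory=dict)
    seed: int = 0
    fold_strategy: str = "stratified_where_possible"
    auc_aggregation: str = "pooled_out_of_fold"
    importance_kind: str = "impurity"

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ModelError("n_folds must be >= 2")
        if self.fold_strategy not in ("stratified_where_possible", "plain"):
            raise ModelError(f"unknown fold_strategy {self.fold_strategy!r}")
        if self.auc_aggregation not in ("pooled_out_of_fold",
                                        "mean_over_valid_folds"):
            raise ModelError(
                f"unknown auc_aggregation {self.auc_aggregation!r}")
        if self.importance_kind not in ("impurity", "permutation"):
            raise ModelError(f"unknown importance_kind {self.importance_kind!r}")


@dataclass
class ImportanceReport:
    """Mean per-feature importance across CV folds, with ranking."""

    mean_importance: pd.Series        # indexed by feature name
    fold_importances: pd.DataFrame    # folds x features
    ranking: list[str]                # features, most important first


@dataclass
class EvaluationResult:
    """Pooled/aggregate metrics for one (label, feature subset) condition."""

    condition: str
    features_used: list[str]
    mean_auc: float
    precision: float
    recall: float
    per_fold_auc: list[float]
    config: CvConfig


def _make_forest(config: CvConfig) -> RandomForestClassifier:
    params = dict(n_estimators=config.rf_n_trees,
                  random_state=config.seed, n_jobs=1)
    params.update(config.rf_hyperparams)
    return RandomForestClassifier(**params)


def _fold_iterator(y: np.ndarray, config: CvConfig):
    n = y.size
    n_folds = config.n_folds
    if n_folds > n:
        raise ModelError(f"n_folds={n_folds} exceeds n_subjects={n}")
    class_counts = np.bincount(y)
    stratify = (config.fold_strategy == "stratified_where_possible"
                and class_counts.min() >= n_folds)
    if stratify:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                   random_state=config.seed)
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True,
                         random_state=config.seed)
    return splitter.split(np.zeros(n), y)


def _check_inputs(features: pd.DataFrame, labels: pd.Series | np.ndarray):
    X = features.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ModelError("feature table contains missing or undefined values")
    y = np.asarray(labels).astype(int).ravel()
    if y.size != len(features):
        raise ModelError("labels length does not match feature table")
    if len(np.unique(y)) < 2:
        raise ModelError("labels contain a single class; cannot train")
    return X, y


def cross_validated_importance(features: pd.DataFrame,
                               labels: pd.Series | np.ndarray,
                               config: CvConfig = CvConfig()) -> ImportanceReport:
    """Mean impurity importance of each feature across CV training fits.

    Folds whose training split lacks one of the classes are skipped with
    a warning; if every fold is skipped an error is raised.
    """
    X, y = _check_inputs(features, labels)
    if config.importance_kind == "permutation":
        from sklearn.inspection import permutation_importance
    fold_rows = []
    for fold, (train, _test) in enumerate(_fold_iterator(y, config)):
        if len(np.unique(y[train])) < 2:
            logger.warning("fold %d skipped: single-class training split", fold)
            continue
        forest = _make_forest(config).fit(X[train], y[train])
        if config.importance_kind == "impurity":
            imp = forest.feature_importances_
        else:
            imp = permutation_importance(
                forest, X[train], y[train], n_repeats=5,
                random_state=config.seed).importances_mean
        fold_rows.append(imp)
    if not fold_rows:
        raise ModelError("all folds skipped: no usable training split")
    fold_importances = pd.DataFrame(fold_rows, columns=features.columns)
    mean_importance = fold_importances.mean(axis=0)
    # ties broken by canonical feature order (stable sort on -importance)
    canonical = {name: i for i, name in enumerate(FEATURE_NAMES)}
    ranking = sorted(features.columns,
                     key=lambda f: (-mean_importance[f],
                                    canonical.get(f, len(canonical))))
    return ImportanceReport(mean_importance=mean_importance,
                            fold_importances=fold_importances,
                            ranking=list(ranking))


def select_top_k(report: ImportanceReport, k: int) -> list[str]:
    """The k highest-mean-importance features, most important first."""
    if not 1 <= k <= len(report.ranking):
        raise ModelError(
            f"k must be in 1..{len(report.ranking)}, got {k}")
    return report.ranking[:k]


def evaluate_subset(features: pd.DataFrame, labels: pd.Series | np.ndarray,
                    subset: Sequence[str],
                    config: CvConfig = CvConfig(),
                    condition: str = "") -> EvaluationResult:
    """Cross-validated evaluation of a random forest on a feature subset.

    AUC follows ``config.auc_aggregation``; precision and recall are
    macro-averaged over classes at a 0.5 probability threshold on the
    pooled out-of-fold predictions.
    """
    subset = list(subset)
    if not subset:
        raise ModelError("feature subset is empty")
    unknown = set(subset) - set(features.columns)
    if unknown:
        raise ModelError(f"unknown features in subset: {sorted(unknown)}")
    # fit on columns in table order so results do not depend on the
    # order in which the subset was listed
    cols = [c for c in features.columns if c in set(subset)]
    X, y = _check_inputs(features[cols], labels)
    pooled_proba = np.full(y.size, np.nan)
    per_fold_auc = []
    for fold, (train, test) in enumerate(_fold_iterator(y, config)):
        if len(np.unique(y[train])) < 2:
            logger.warning("fold %d skipped: single-class training split", fold)
            continue
        forest = _make_forest(config).fit(X[train], y[train])
        proba = forest.predict_proba(X[test])[:, list(forest.classes_).index(1)]
        pooled_proba[test] = proba
        if len(np.unique(y[test])) == 2:
            per_fold_auc.append(float(roc_auc_score(y[test], proba)))
        else:
            logger.debug("fold %d: single-class test split, no fold AUC", fold)
    seen = ~np.isnan(pooled_proba)
    if not seen.any():
        raise ModelError("no out-of-fold predictions produced")
    if config.auc_aggregation == "pooled_out_of_fold":
        mean_auc = float(roc_auc_score(y[seen], pooled_proba[seen]))
    else:
        if not per_fold_auc:
            raise ModelError("no fold had both classes; cannot average fold AUC")
        mean_auc = float(np.mean(per_fold_auc))
    pred = (pooled_proba[seen] >= 0.5).astype(int)
    precision = float(precision_score(y[seen], pred, average="macro",
                                      zero_division=0))
    recall = float(recall_score(y[seen], pred, average="macro",
                                zero_division=0))
    return EvaluationResult(condition=condition, features_used=subset,
                            mean_auc=mean_auc, precision=precision,
                            recall=recall, per_fold_auc=per_fold_auc,
                            config=config)


def rank_and_evaluate(features: pd.DataFrame, labels: pd.Series | np.ndarray,
                      k_list: Sequence[int] = (15, 10, 5),
                      config: CvConfig = CvConfig(),
                      condition: str = "") -> tuple[ImportanceReport,
                                                    dict[int, EvaluationResult]]:
    """Importance ranking followed by top-k re-training for each k."""
    report = cross_validated_importance(features, labels, config)
    results = {}
    for k in k_list:
        subset = select_top_k(report, min(k, len(report.ranking)))
        results[k] = evaluate_subset(features, labels, subset, config,
                                     condition=f"{condition} top-{k}".strip())
    return report, results


def compare_with_without_mse(features: pd.DataFrame,
                             labels: pd.Series | np.ndarray,
                             config: CvConfig = CvConfig(),
                             k_list: Sequence[int] = (15, 10, 5),
                             condition: str = "") -> dict:
    """Paired evaluation with the full table vs. the table minus MSE features.

    The 9 multiscale-entropy features (MSEM/MSTD/CI on each axis) are
    removed before importance ranking in the "without" arm, so each arm
    ranks and selects its own top-k.
    """
    missing = [f for f in FEATURE_NAMES if f not in features.columns]
    if missing:
        raise ModelError(f"feature table missing canonical features: {missing}")
    without_cols = [c for c in features.columns if c not in MSE_FEATURE_NAMES]
    report_with, with_results = rank_and_evaluate(
        features, labels, k_list, config, condition=f"{condition} with-MSE")
    report_without, without_results = rank_and_evaluate(
        features[without_cols], labels, k_list, config,
        condition=f"{condition} without-MSE")
    return {
        "with": {"importance": report_with, "results": with_results},
        "without": {"importance": report_without, "results": without_results},
        "k_list": list(k_list),
    }
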