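"""Linear-SVM base estimators, weighted-voting fusion, and LOOCV evaluation.

The fusion model trains one linear support-vector machine per correlation
metric of a duet and combines their decision scores linearly:

    fused = alpha * score_a + (1 - alpha) * score_b,   alpha in (0, 1)

with the positive class (MCI) predicted when the fused score is strictly
positive (exact ties go to the control class).  Leave-one-out
cross-validation recomputes the feature filter on every training fold so the
held-out subject never influences selection; the nested variant additionally
tunes (alpha, p-value threshold) by an inner LOOCV within each training set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.svm import SVC

from .dynamics import SlidingWindowConfig
from .errors import InputError, MuscnetError
from .features import select

logger = logging.getLogger(__name__)

#: class coding used throughout: MCI patients are the positive class
POSITIVE_LABEL = 1  # MCI
NEGATIVE_LABEL = 0  # NC

#: the fusion-weight sweep
ALPHA_GRID = tuple(round(0.1 * i, 1) for i in range(1, 10))


@dataclass(frozen=True)
class FusionSpec:
    """One fusion configuration: a metric duet plus its hyper-parameters."""

    metric_pair: tuple[str, str]
    alpha: float = 0.5
    filter_method: str = "Ttest"
    threshold: float = 0.05
    window: SlidingWindowConfig | None = None
    layout: str = "upper_triangle"
    regularization: float = 1.0

    def __post_init__(self) -> None:
        if len(self.metric_pair) != 2:
            raise InputError("metric_pair must name exactly two metrics")
        if not (0.0 < self.alpha < 1.0):
            raise InputError("alpha must lie in (0, 1)")
        if self.regularization <= 0:
            raise InputError("regularization must be positive")


@dataclass
class LinearEstimator:
    """A trained linear decision function over a selected feature subset."""

    weights: np.ndarray
    intercept: float
    feature_indices: np.ndarray
    metric: str = ""
    fallback_label: int | None = None  # set when trained on an empty selection

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.fallback_label is not None:
            s = 1.0 if self.fallback_label == POSITIVE_LABEL else -1.0
            return np.full(X.shape[0], s)
        return X[:, self.feature_indices] @ self.weights + self.intercept


def train_estimator(
    X: np.ndarray,
    y: np.ndarray,
    feature_indices: np.ndarray | Sequence[int],
    regularization: float = 1.0,
    metric: str = "",
) -> LinearEstimator:
    """Fit a linear-kernel SVM on the selected columns of ``X``.

    An empty selection cannot support a separating hyperplane; the estimator
    degrades to a constant majority-class scorer and is flagged via
    ``fallback_label``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    idx = np.asarray(feature_indices, dtype=int)
    classes = np.unique(y)
    if classes.shape[0] < 2:
        raise InputError("training labels contain a single class")
    if idx.shape[0] == 0:
        majority = POSITIVE_LABEL if (y == POSITIVE_LABEL).sum() > (y == NEGATIVE_LABEL).sum() \
            else NEGATIVE_LABEL
        logger.warning("empty feature selection for metric %s: majority-class fallback", metric)
        return LinearEstimator(
            weights=np.zeros(0), intercept=0.0, feature_indices=idx,
            metric=metric, fallback_label=majority,
        )
    svm = SVC(kernel="linear", C=regularization)
    svm.fit(X[:, idx], y)
    return LinearEstimator(
        weights=svm.coef_.ravel().copy(),
        intercept=float(svm.intercept_[0]),
        feature_indices=idx,
        metric=metric,
    )


def fuse(score_a: float, score_b: float, alpha: float) -> float:
    """Linear decision-score fusion: alpha * a + (1 - alpha) * b."""
    if not (0.0 < alpha < 1.0):
        raise InputError("alpha must lie in (0, 1)")
    return alpha * score_a + (1.0 - alpha) * score_b


def predict_from_score(score: float) -> int:
    """Positive (MCI) iff the fused score is strictly positive."""
    return POSITIVE_LABEL if score > 0.0 else NEGATIVE_LABEL


def compute_metrics(TP: int, FN: int, TN: int, FP: int) -> tuple[float, float, float]:
    """(Accuracy, Sensitivity, Specificity) from confusion counts."""
    if min(TP, FN, TN, FP) < 0:
        raise InputError("confusion counts must be non-negative")
    P = TP + FN
    N = TN + FP
    if P == 0 or N == 0:
        raise MuscnetError("Acc/Sn/Sp undefined without both positives and negatives")
    return (TP + TN) / (P + N), TP / P, TN / N


@dataclass
class EvaluationResult:
    config: FusionSpec
    per_subject_prediction: np.ndarray
    per_subject_score: np.ndarray
    TP: int
    FN: int
    TN: int
    FP: int
    Acc: float
    Sn: float
    Sp: float
    per_fold_selected: list[dict[str, np.ndarray]]
    fallback_folds: int = 0
    inner_choices: list[tuple[float, float]] | None = None  # nested-LOOCV picks

    def to_dict(self) -> dict:
        cfg = asdict(self.config)
        cfg["metric_pair"] = list(self.config.metric_pair)
        if self.config.window is not None:
            cfg["window"] = {
                "window_size": self.config.window.window_size,
                "window_step": self.config.window.window_step,
            }
        return {
            "config": cfg,
            "predictions": self.per_subject_prediction.tolist(),
            "scores": self.per_subject_score.tolist(),
            "confusion": {"TP": self.TP, "FN": self.FN, "TN": self.TN, "FP": self.FP},
            "metrics": {"Acc": self.Acc, "Sn": self.Sn, "Sp": self.Sp},
            "per_fold_selected": [
                {m: v.tolist() for m, v in fold.items()} for fold in self.per_fold_selected
            ],
            "fallback_folds": self.fallback_folds,
            "inner_choices": self.inner_choices,
        }


def _check_dataset(feature_matrices: Mapping[str, np.ndarray], y: np.ndarray,
                   pair: tuple[str, str]) -> int:
    for m in set(pair):
        if m not in feature_matrices:
            raise InputError(f"no feature matrix for metric {m!r}")
    n = np.asarray(y).shape[0]
    for m, X in feature_matrices.items():
        if np.asarray(X).shape[0] != n:
            raise InputError(f"feature matrix {m!r} row count differs from label count")
    y = np.asarray(y)
    if (y == POSITIVE_LABEL).sum() < 2 or (y == NEGATIVE_LABEL).sum() < 2:
        raise InputError("need at least 2 subjects per class")
    return n


def _fold_scores(
    feature_matrices: Mapping[str, np.ndarray],
    y: np.ndarray,
    pair: tuple[str, str],
    filter_method: str,
    threshold: float,
    regularization: float,
    subject_ids: np.ndarray,
    audit_log: list | None = None,
    audit_context: dict | None = None,
) -> tuple[np.ndarray, np.ndarray, list[dict[str, np.ndarray]], int]:
    """Raw per-metric held-out decision scores across LOOCV folds.

    Scores do not depend on the fusion weight, so one pass serves the whole
    alpha grid.  ``subject_ids`` gives the global identity of each row (used
    by the audit log and by nested evaluation on subsets).
    """
    n = y.shape[0]
    scores = {m: np.empty(n) for m in set(pair)}
    per_fold_selected: list[dict[str, np.ndarray]] = []
    fallback_folds = 0
    for i in range(n):
        train = np.r_[0:i, i + 1 : n]
        fold_sel: dict[str, np.ndarray] = {}
        fold_fallback = False
        for m in set(pair):
            X = np.asarray(feature_matrices[m], dtype=float)
            res = select(X[train], y[train], method=filter_method, threshold=threshold)
            if audit_log is not None:
                audit_log.append(
                    {"stage": "filter", "metric": m,
                     "subjects": tuple(subject_ids[train].tolist()),
                     **(audit_context or {})}
                )
            est = train_estimator(X[train], y[train], res.selected,
                                  regularization=regularization, metric=m)
            if audit_log is not None:
                audit_log.append(
                    {"stage": "train", "metric": m,
                     "subjects": tuple(subject_ids[train].tolist()),
                     **(audit_context or {})}
                )
            fold_sel[m] = res.selected
            fold_fallback = fold_fallback or est.fallback_label is not None
            scores[m][i] = est.decision_scores(X[i : i + 1])[0]
            logger.debug("fold %d metric %s: %d features selected", i, m, res.selected.size)
        per_fold_selected.append(fold_sel)
        fallback_folds += int(fold_fallback)
    a, b = pair
    return scores[a], scores[b], per_fold_selected, fallback_folds


def _assemble(config: FusionSpec, y: np.ndarray, fused_scores: np.ndarray,
              per_fold_selected, fallback_folds: int,
              inner_choices=None) -> EvaluationResult:
    preds = np.array([predict_from_score(s) for s in fused_scores])
    TP = int(np.sum((preds == POSITIVE_LABEL) & (y == POSITIVE_LABEL)))
    FN = int(np.sum((preds == NEGATIVE_LABEL) & (y == POSITIVE_LABEL)))
    TN = int(np.sum((preds == NEGATIVE_LABEL) & (y == NEGATIVE_LABEL)))
    FP = int(np.sum((preds == POSITIVE_LABEL) & (y == NEGATIVE_LABEL)))
    acc, sn, sp = compute_metrics(TP, FN, TN, FP)
    return EvaluationResult(
        config=config, per_subject_prediction=preds, per_subject_score=fused_scores,
        TP=TP, FN=FN, TN=TN, FP=FP, Acc=acc, Sn=sn, Sp=sp,
        per_fold_selected=per_fold_selected, fallback_folds=fallback_folds,
        inner_choices=inner_choices,
    )


def loocv(
    feature_matrices: Mapping[str, np.ndarray],
    y: np.ndarray,
    spec: FusionSpec,
    audit_log: list | None = None,
) -> EvaluationResult:
    """Leave-one-out evaluation of one fusion configuration.

    Feature selection and estimator training are recomputed inside every
    fold from the training subjects only.
    """
    y = np.asarray(y)
    n = _check_dataset(feature_matrices, y, spec.metric_pair)
    ids = np.arange(n)
    sa, sb, per_fold, fb = _fold_scores(
        feature_matrices, y, spec.metric_pair, spec.filter_method, spec.threshold,
        spec.regularization, ids, audit_log=audit_log, audit_context={"level": "outer"},
    )
    fused = spec.alpha * sa + (1.0 - spec.alpha) * sb
    return _assemble(spec, y, fused, per_fold, fb)


def alpha_grid(
    feature_matrices: Mapping[str, np.ndarray],
    y: np.ndarray,
    spec: FusionSpec,
    alphas: Iterable[float] = ALPHA_GRID,
) -> list[EvaluationResult]:
    """LOOCV at every fusion weight; full table, never just the argmax.

    The per-metric decision scores are alpha-free, so the folds are run once.
    """
    y = np.asarray(y)
    n = _check_dataset(feature_matrices, y, spec.metric_pair)
    sa, sb, per_fold, fb = _fold_scores(
        feature_matrices, y, spec.metric_pair, spec.filter_method, spec.threshold,
        spec.regularization, np.arange(n),
    )
    table = []
    for a in alphas:
        cfg = FusionSpec(
            metric_pair=spec.metric_pair, alpha=a, filter_method=spec.filter_method,
            threshold=spec.threshold, window=spec.window, layout=spec.layout,
            regularization=spec.regularization,
        )
        table.append(_assemble(cfg, y, a * sa + (1.0 - a) * sb, per_fold, fb))
    return table


def best_result(table: Sequence[EvaluationResult]) -> EvaluationResult:
    """Argmax accuracy; ties broken toward smaller alpha then smaller threshold."""
    return max(
        table,
        key=lambda r: (r.Acc, -r.config.alpha, -r.config.threshold),
    )


def nested_loocv(
    feature_matrices: Mapping[str, np.ndarray],
    y: np.ndarray,
    spec: FusionSpec,
    alphas: Sequence[float] = ALPHA_GRID,
    thresholds: Sequence[float] = (0.05,),
    audit_log: list | None = None,
) -> EvaluationResult:
    """Two-level LOOCV: inner folds pick (alpha, threshold), outer folds score.

    For each outer held-out subject, an inner LOOCV over the remaining
    subjects evaluates every candidate pair; the candidate with the highest
    inner accuracy wins (ties go to the smaller alpha, then the smaller
    threshold).  The outer estimators are then trained on the full outer
    training set with the winning parameters.  The outer subject is never
    visible to the inner level (verifiable through ``audit_log``).
    """
    y = np.asarray(y)
    n = _check_dataset(feature_matrices, y, spec.metric_pair)
    pair = spec.metric_pair
    fused_scores = np.empty(n)
    per_fold_selected: list[dict[str, np.ndarray]] = []
    fallback_folds = 0
    inner_choices: list[tuple[float, float]] = []
    mats = {m: np.asarray(feature_matrices[m], dtype=float) for m in set(pair)}

    for i in range(n):
        train = np.r_[0:i, i + 1 : n]
        y_tr = y[train]
        inner_mats = {m: X[train] for m, X in mats.items()}
        best_key = None
        best_choice = None
        for thr in thresholds:
            sa, sb, _, _ = _fold_scores(
                inner_mats, y_tr, pair, spec.filter_method, thr, spec.regularization,
                subject_ids=train, audit_log=audit_log,
                audit_context={"level": "inner", "outer_fold": i},
            )
            for a in alphas:
                preds = np.where(a * sa + (1.0 - a) * sb > 0, POSITIVE_LABEL, NEGATIVE_LABEL)
                acc = float(np.mean(preds == y_tr))
                key = (acc, -a, -thr)
                if best_key is None or key > best_key:
                    best_key = key
                    best_choice = (a, thr)
        a_star, thr_star = best_choice
        inner_choices.append((a_star, thr_star))
        logger.debug("outer fold %d: inner pick alpha=%.1f threshold=%.3g", i, a_star, thr_star)

        fold_sel: dict[str, np.ndarray] = {}
        fold_fallback = False
        score_by_metric = {}
        for m in set(pair):
            X = mats[m]
            res = select(X[train], y_tr, method=spec.filter_method, threshold=thr_star)
            est = train_estimator(X[train], y_tr, res.selected,
                                  regularization=spec.regularization, metric=m)
            if audit_log is not None:
                audit_log.append(
                    {"stage": "outer_train", "metric": m, "outer_fold": i,
                     "level": "outer", "subjects": tuple(train.tolist())}
                )
            fold_sel[m] = res.selected
            fold_fallback = fold_fallback or est.fallback_label is not None
            score_by_metric[m] = est.decision_scores(X[i : i + 1])[0]
        per_fold_selected.append(fold_sel)
        fallback_folds += int(fold_fallback)
        fused_scores[i] = fuse(score_by_metric[pair[0]], score_by_metric[pair[1]], a_star)

    return _assemble(spec, y, fused_scores, per_fold_selected, fallback_folds,
                     inner_choices=inner_choices)
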