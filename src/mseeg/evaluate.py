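"""Stratified cross-validation, the model-1..5 ablation ladder, and metrics.

The evaluation contract is leak-free recording-level cross-validation:
folds partition *recordings* (never segments of one recording across
folds), and every data-dependent fitting step — feature z-scoring,
m-ACO selection, GOA hyperparameter tuning — sees training-fold rows
only.  When the feature matrix has one row per segment, a recording's
label is the majority vote over its segments' predictions and its ROC
score the mean decision value.

The ablation ladder:

======  ==================  ==========  =========
model   feature domains     selection   tuning
======  ==================  ==========  =========
1       time                none        none
2       frequency           none        none
3       time + frequency    none        none
4       time + frequency    m-ACO       none
5       time + frequency    m-ACO       GOA
======  ==================  ==========  =========

Reported metrics: accuracy, sensitivity, specificity, G-mean (MS is the
positive class), ROC/AUC from pooled decision scores, and per-fold
accuracies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .classify import GoaConfig, SvmSpec, gmean, train_svm, tune_svm_goa
from .features import FeatureConfig, FeatureMatrix, build_feature_matrix
from .preprocess import Recording, segment_recording
from .selection import MacoConfig, run_maco

__all__ = [
    "EvaluationError",
    "CvPlan",
    "ConfusionMatrix",
    "RocResult",
    "FitQuality",
    "MetricsReport",
    "ModelVariant",
    "kfold_split",
    "confusion",
    "roc_auc",
    "r_squared",
    "extract_dataset_features",
    "cross_validate_matrix",
    "run_variant",
]

POSITIVE_LABEL = "MS"
NEGATIVE_LABEL = "healthy"


class EvaluationError(ValueError):
    """Invalid evaluation request."""


# ---------------------------------------------------------------------------
# Cross-validation plan
# ---------------------------------------------------------------------------


@dataclass
class CvPlan:
    """Recording-level stratified fold assignment."""

    K: int
    assignments: np.ndarray  # fold index per recording
    seed: int
    stratified: bool = True

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


def kfold_split(recording_labels, K: int = 10, seed: int = 0) -> CvPlan:
    """Stratified K-fold partition of recordings.

    Raises
    ------
    EvaluationError
        If any class has fewer than ``K`` members.
    """
    y = np.asarray(recording_labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < K:
        raise EvaluationError(
            f"smallest class has {counts.min()} recordings, fewer than K={K} folds"
        )
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    assignments = np.empty(y.size, dtype=int)
    for fold, (_, test) in enumerate(skf.split(np.zeros((y.size, 1)), y)):
        assignments[test] = fold
    return CvPlan(K=K, assignments=assignments, seed=seed)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass
class ConfusionMatrix:
    """2x2 counts with MS as the positive class."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @property
    def accuracy(self) -> float:
        return (self.TP + self.TN) / self.total

    @property
    def sensitivity(self) -> float:
        return self.TP / (self.TP + self.FN)

    @property
    def specificity(self) -> float:
        return self.TN / (self.TN + self.FP)


def confusion(y_true, y_pred, positive: str = POSITIVE_LABEL) -> ConfusionMatrix:
    """Count the 2x2 confusion matrix.

    Raises
    ------
    EvaluationError
        On length mismatch or labels outside the binary set.
    """
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.size != p.size:
        raise EvaluationError("y_true and y_pred lengths differ")
    valid = {positive, NEGATIVE_LABEL if positive == POSITIVE_LABEL else POSITIVE_LABEL}
    seen = set(np.unique(t).tolist()) | set(np.unique(p).tolist())
    if not seen <= valid:
        raise EvaluationError(f"labels {seen - valid} outside the binary set {valid}")
    tp = int(((p == positive) & (t == positive)).sum())
    tn = int(((p != positive) & (t != positive)).sum())
    fp = int(((p == positive) & (t != positive)).sum())
    fn = int(((p != positive) & (t == positive)).sum())
    return ConfusionMatrix(TP=tp, TN=tn, FP=fp, FN=fn)


@dataclass
class RocResult:
    """ROC curve by threshold sweep and its trapezoid-rule area."""

    points: np.ndarray  # (n, 2) of (FPR, TPR), from (0,0) to (1,1)
    auc: float


def roc_auc(scores, y_true, positive: str = POSITIVE_LABEL) -> RocResult:
    """ROC points and AUC from real-valued decision scores.

    Constant scores yield a degenerate diagonal curve and AUC 0.5, with
    a warning.
    """
    scores = np.asarray(scores, dtype=float)
    t = np.asarray(y_true)
    if np.unique(t).size < 2:
        raise EvaluationError("ROC requires both classes present")
    if np.ptp(scores) == 0:
        warnings.warn("constant scores: degenerate ROC, AUC = 0.5", stacklevel=2)
        return RocResult(points=np.array([[0.0, 0.0], [1.0, 1.0]]), auc=0.5)
    fpr, tpr, _ = roc_curve(t, scores, pos_label=positive)
    points = np.column_stack([fpr, tpr])
    return RocResult(points=points, auc=float(np.trapezoid(tpr, fpr)))


@dataclass
class FitQuality:
    """Mean squared error and coefficient of determination."""

    mse: float
    r2: float
    n: int


def r_squared(y, y_hat) -> FitQuality:
    """``MSE = mean (y - y_hat)^2`` and ``R^2 = 1 - SSE / SST``.

    Raises
    ------
    EvaluationError
        On length mismatch, fewer than 2 points, or constant ``y``.
    """
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size != y_hat.size:
        raise EvaluationError("y and y_hat lengths differ")
    if y.size < 2:
        raise EvaluationError("need at least two observations")
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise EvaluationError("R^2 undefined for constant y")
    sse = float(((y - y_hat) ** 2).sum())
    return FitQuality(mse=sse / y.size, r2=1.0 - sse / sst, n=y.size)


@dataclass
class MetricsReport:
    """Pooled cross-validated performance of one model variant."""

    accuracy: float
    sensitivity: float
    specificity: float
    g_mean: float
    auc: float
    roc_points: np.ndarray
    confusion_matrix: ConfusionMatrix
    fold_accuracies: list[float]
    variant_id: int | None = None

    def to_dict(self) -> dict:
        return {
            "variant": self.variant_id,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "g_mean": self.g_mean,
            "auc": self.auc,
            "confusion": {
                "TP": self.confusion_matrix.TP,
                "TN": self.confusion_matrix.TN,
                "FP": self.confusion_matrix.FP,
                "FN": self.confusion_matrix.FN,
            },
            "fold_accuracies": self.fold_accuracies,
        }


# ---------------------------------------------------------------------------
# Model variants
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelVariant:
    """One rung of the ablation ladder."""

    id: int
    feature_domains: tuple[str, ...]
    use_selection: str  # "none" | "maco"
    use_tuning: str  # "none" | "goa"

    @classmethod
    def from_id(cls, variant_id: int) -> "ModelVariant":
        table = {
            1: (("time",), "none", "none"),
            2: (("frequency",), "none", "none"),
            3: (("time", "frequency"), "none", "none"),
            4: (("time", "frequency"), "maco", "none"),
            5: (("time", "frequency"), "maco", "goa"),
        }
        if variant_id not in table:
            raise EvaluationError(f"variant id must be 1..5, got {variant_id}")
        domains, sel, tune = table[variant_id]
        return cls(id=variant_id, feature_domains=domains, use_selection=sel, use_tuning=tune)


@dataclass
class EvalConfig:
    """Everything one cross-validated run depends on."""

    K: int = 10
    frame_ms: float = 400.0
    frame_overlap: float = 0.35
    wavelet: str = "db8"
    levels: int = 5
    features: FeatureConfig = field(default_factory=FeatureConfig)
    maco: MacoConfig = field(default_factory=MacoConfig)
    goa: GoaConfig = field(default_factory=GoaConfig)
    svm_c: float = 1.0
    svm_gamma: float | str = "scale"


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def extract_dataset_features(
    recordings: list[Recording], config: EvalConfig | None = None
) -> FeatureMatrix:
    """Decompose, window and featurize a whole dataset."""
    config = config or EvalConfig()
    segments = []
    for rec in recordings:
        frame_len = int(round(config.frame_ms / 1000.0 * rec.fs))
        segments.extend(
            segment_recording(
                rec,
                frame_len=frame_len,
                overlap=config.frame_overlap,
                wavelet=config.wavelet,
                levels=config.levels,
            )
        )
    return build_feature_matrix(segments, config.features)


def _majority_vote(pred: np.ndarray) -> str:
    values, counts = np.unique(pred, return_counts=True)
    # ties break toward the alphabetically later label (MS before healthy
    # never ties at odd segment counts; recording-level rows never tie)
    return str(values[np.argmax(counts)])


def cross_validate_matrix(
    fm: FeatureMatrix,
    variant: ModelVariant,
    config: EvalConfig | None = None,
    rng: np.random.Generator | None = None,
) -> MetricsReport:
    """Leak-free stratified CV of one variant over a feature matrix.

    Standardization, selection and tuning are fitted inside each fold on
    training rows only; folds are cut at recording level.
    """
    config = config or EvalConfig()
    rng = rng or np.random.default_rng()
    if fm.labels is None or fm.recording_ids is None:
        raise EvaluationError("feature matrix lacks labels or recording ids")

    rec_ids = np.asarray(fm.recording_ids)
    row_labels = np.asarray(fm.labels)
    unique_recs, first_pos = np.unique(rec_ids, return_index=True)
    rec_labels = row_labels[first_pos]

    cv_seed = int(rng.integers(0, 2**31 - 1))
    plan = kfold_split(rec_labels, K=config.K, seed=cv_seed)

    columns = fm.columns_in_domains(variant.feature_domains)
    if not columns:
        raise EvaluationError(f"no features in domains {variant.feature_domains}")

    rec_pred: dict[str, str] = {}
    rec_score: dict[str, float] = {}
    fold_accuracies: list[float] = []

    for fold in range(plan.K):
        train_recs = set(unique_recs[plan.train_indices(fold)])
        test_recs = set(unique_recs[plan.test_indices(fold)])
        train_rows = np.flatnonzero(np.isin(rec_ids, list(train_recs)))
        test_rows = np.flatnonzero(np.isin(rec_ids, list(test_recs)))

        fm.fit_standardize(train_rows)
        z = fm.transform()
        x_train = z.iloc[train_rows][columns].to_numpy()
        x_test = z.iloc[test_rows][columns].to_numpy()
        y_train = row_labels[train_rows]
        y_test = row_labels[test_rows]

        kept = list(range(len(columns)))
        if variant.use_selection == "maco":
            sel = run_maco(x_train, y_train, config.maco, rng)
            kept = sel.selected
        x_train_sel = x_train[:, kept]
        x_test_sel = x_test[:, kept]

        if variant.use_tuning == "goa":
            spec, _ = tune_svm_goa(x_train_sel, y_train, config.goa, rng)
        else:
            spec = train_svm(
                x_train_sel, y_train, SvmSpec(C=config.svm_c, gamma=config.svm_gamma)
            )
        pred = spec.predict(x_test_sel)
        scores = spec.decision_scores(x_test_sel)
        if spec.model.classes_[-1] != POSITIVE_LABEL:
            scores = -scores  # orient scores so larger means more MS-like

        fold_correct = []
        for rec in sorted(test_recs):
            rows = np.flatnonzero(rec_ids[test_rows] == rec)
            rec_pred[rec] = _majority_vote(pred[rows])
            rec_score[rec] = float(scores[rows].mean())
            fold_correct.append(rec_pred[rec] == y_test[rows[0]])
        fold_accuracies.append(float(np.mean(fold_correct)))

    order = list(unique_recs)
    y_true = np.array([rec_labels[list(unique_recs).index(r)] for r in order])
    y_pred = np.array([rec_pred[r] for r in order])
    y_score = np.array([rec_score[r] for r in order])

    cm = confusion(y_true, y_pred)
    roc = roc_auc(y_score, y_true)
    return MetricsReport(
        accuracy=cm.accuracy,
        sensitivity=cm.sensitivity,
        specificity=cm.specificity,
        g_mean=gmean(cm),
        auc=roc.auc,
        roc_points=roc.points,
        confusion_matrix=cm,
        fold_accuracies=fold_accuracies,
        variant_id=variant.id,
    )


def run_variant(
    recordings: list[Recording],
    variant: ModelVariant | int,
    config: EvalConfig | None = None,
    rng: np.random.Generator | None = None,
    feature_matrix: FeatureMatrix | None = None,
) -> MetricsReport:
    """End-to-end evaluation of one model variant on labeled recordings.

    ``feature_matrix`` may be passed to reuse an extraction across
    variants (features are raw until standardization, which is fitted
    per fold, so sharing the matrix leaks nothing).
    """
    if isinstance(variant, int):
        variant = ModelVariant.from_id(variant)
    config = config or EvalConfig()
    fm = feature_matrix or extract_dataset_features(recordings, config)
    return cross_validate_matrix(fm, variant, config, rng)
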