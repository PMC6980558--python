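"""SVM classification with leave-one-out cross-validation.

Mirrors the evaluation design used for small DAT-SPECT cohorts: features
are standardized, a (default linear) support-vector machine is trained,
and every subject is scored by a model trained on the remaining n - 1
subjects.  Standardization is refit inside each fold on the training rows
only, so no information about the held-out subject leaks into its score.
The pooled continuous decision scores feed ROC analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .stats_roc import FeatureTable

__all__ = ["SvmConfig", "CvResult", "standardize_fit", "standardize_apply",
           "svm_train", "svm_score", "loocv"]


@dataclass(frozen=True)
class SvmConfig:
    """Kernel and regularization of the SVM, plus the positive class."""

    kernel: str = "linear"
    C: float = 1.0
    positive: str = "PD"
    gamma: str | float = "scale"
    per_fold_standardization: bool = True

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("regularization strength C must be positive")


@dataclass(frozen=True)
class CvResult:
    """Pooled leave-one-out decision scores and predictions."""

    scores: np.ndarray
    predicted: np.ndarray
    labels: np.ndarray
    feature_set: tuple[str, ...]
    model_config: SvmConfig


def standardize_fit(train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fit a column-wise standardizer (mean, sd) on training rows only."""
    train = np.asarray(train, dtype=float)
    if train.ndim != 2 or train.shape[0] < 2:
        raise ValueError("need a 2D matrix with at least 2 training rows")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"zero-variance training column(s): {bad.tolist()}")
    return mean, sd


def standardize_apply(scaler: tuple[np.ndarray, np.ndarray],
                      features: np.ndarray) -> np.ndarray:
    """Apply a fitted (mean, sd) map to new rows."""
    mean, sd = scaler
    return (np.asarray(features, dtype=float) - mean) / sd


def _encode(labels, positive: str) -> np.ndarray:
    labels = np.asarray(labels)
    y = (labels == positive).astype(int)
    if y.all() or not y.any():
        raise ValueError("training data must contain both classes")
    return y


def svm_train(features: np.ndarray, labels, config: SvmConfig = SvmConfig()) -> SVC:
    """Train an SVM; decision scores are positive toward ``config.positive``."""
    X = np.asarray(features, dtype=float)
    y = _encode(labels, config.positive)
    model = SVC(kernel=config.kernel, C=config.C, gamma=config.gamma)
    model.fit(X, y)
    return model


def svm_score(model: SVC, features: np.ndarray) -> np.ndarray:
    """Continuous decision-function scores (positive => positive class)."""
    return np.asarray(model.decision_function(np.asarray(features, dtype=float)))


def loocv(table: FeatureTable, feature_set, config: SvmConfig = SvmConfig()) -> CvResult:
    """Leave-one-out cross-validated SVM decision scores.

    For each subject, the scaler and SVM are fit on the other n - 1 rows
    and the held-out row is scored.  Fully deterministic; fold failures
    are reported with the offending subject.
    """
    feature_set = tuple(feature_set)
    X = table.feature_matrix(feature_set)
    labels = table.labels
    n = X.shape[0]
    if n < 4:
        raise ValueError("leave-one-out needs at least 4 subjects")

    if not config.per_fold_standardization:
        # global-standardization variant, for sensitivity analysis only
        X = standardize_apply(standardize_fit(X), X)

    scores = np.empty(n)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        try:
            Xtr, Xte = X[keep], X[~keep]
            if config.per_fold_standardization:
                scaler = standardize_fit(Xtr)
                Xtr = standardize_apply(scaler, Xtr)
                Xte = standardize_apply(scaler, Xte)
            model = svm_train(Xtr, labels[keep], config)
            scores[i] = svm_score(model, Xte)[0]
        except ValueError as err:
            sid = table.data["subject_id"].iloc[i]
            raise ValueError(f"LOOCV fold for subject {sid!r} failed: {err}") from err

    predicted = np.where(scores > 0, config.positive,
                         next(l for l in np.unique(labels) if l != config.positive))
    return CvResult(scores=scores, predicted=predicted, labels=labels,
                    feature_set=feature_set, model_config=config)
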