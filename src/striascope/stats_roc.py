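"""Feature ranking, ROC analysis and the DeLong test for paired AUCs.

Features are ranked by two-sided Welch t-test p-values.  ROC analysis uses
the trapezoidal AUC (equal to the tie-corrected Mann-Whitney proportion),
an optimal cutoff by Youden's J, and 95% confidence intervals from the
DeLong structural-component variance.  Differences between AUCs measured on
the same subjects are tested with the DeLong test, implemented with
midranks in O(n log n).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "RocResult",
    "DeLongResult",
    "welch_t",
    "rank_features",
    "roc",
    "delong_paired",
    "FEATURE_COLUMNS",
]

#: feature columns of the per-subject table, in canonical order
FEATURE_COLUMNS = (
    "area",
    "equivalent_diameter",
    "major_axis_length",
    "minor_axis_length",
    "perimeter",
    "circularity",
    "max_count",
    "min_count",
    "mean_count",
    "sbr_caudate",
    "sbr_putamen",
)


@dataclass
class FeatureTable:
    """Per-subject feature table with group labels.

    ``data`` holds one row per subject with at least ``subject_id`` and
    ``group`` (in {NC, PD}) columns plus named numeric feature columns.
    ``provenance`` records the config/seeds the table was produced from.
    """

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data
        for col in ("subject_id", "group"):
            if col not in df.columns:
                raise ValueError(f"feature table lacks required column {col!r}")
        groups = set(df["group"].unique())
        if not groups <= {"NC", "PD"}:
            raise ValueError(f"unknown group labels: {groups - {'NC', 'PD'}}")
        if groups != {"NC", "PD"}:
            raise ValueError("both NC and PD groups must be represented")

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("subject_id", "group")]

    def feature_matrix(self, names: list[str] | tuple[str, ...]) -> np.ndarray:
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise ValueError(f"unknown features: {missing}")
        X = self.data[list(names)].to_numpy(dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("feature table contains missing/non-finite values")
        return X

    @property
    def labels(self) -> np.ndarray:
        return self.data["group"].to_numpy()


@dataclass(frozen=True)
class RocResult:
    """AUC with 95% CI, the full curve, and Youden-cutoff metrics."""

    auc: float
    ci95: tuple[float, float]
    curve: np.ndarray  # (k, 2) array of (fpr, tpr)
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    positive_higher: bool


@dataclass(frozen=True)
class DeLongResult:
    """DeLong test of the difference between two correlated AUCs."""

    auc_a: float
    auc_b: float
    delta: float
    variance_of_delta: float
    z: float
    p: float


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test with Satterthwaite df.

    Returns ``(t, df, p)`` with a two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, float(x.size + y.size - 2), 1.0
        raise ValueError("degenerate samples: both have zero variance")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def rank_features(table: FeatureTable) -> list[tuple[str, float]]:
    """Rank features by ascending Welch p-value (NC vs PD).

    Ties are broken by feature name so the ordering is deterministic.
    """
    is_pd = table.labels == "PD"
    out = []
    for name in table.feature_names:
        vals = table.feature_matrix([name])[:, 0]
        _, _, p = welch_t(vals[~is_pd], vals[is_pd])
        out.append((name, p))
    return sorted(out, key=lambda fp: (fp[1], fp[0]))


def _check_binary(labels, positive: str) -> np.ndarray:
    labels = np.asarray(labels)
    pos = labels == positive
    if pos.all() or not pos.any():
        raise ValueError("ROC requires both classes to be present")
    return pos


def _delong_components(scores: np.ndarray, is_pos: np.ndarray):
    """AUC and DeLong structural components via midranks.

    Returns ``(auc, v10, v01)`` where ``v10`` are the per-positive and
    ``v01`` the per-negative placement components; the AUC is their common
    mean (the tie-corrected Mann-Whitney proportion).
    """
    pos = scores[is_pos]
    neg = scores[~is_pos]
    m, n = pos.size, neg.size
    r_all = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    return float(auc), v10, v01


def auc_mann_whitney(scores, labels, positive: str = "PD") -> float:
    """AUC as the tie-corrected probability of correct pair ordering."""
    scores = np.asarray(scores, dtype=float)
    is_pos = _check_binary(labels, positive)
    auc, _, _ = _delong_components(scores, is_pos)
    return auc


def roc(scores, labels, positive: str = "PD",
        positive_higher: bool | None = None,
        ci_method: str = "normal") -> RocResult:
    """ROC analysis of one score against binary group labels.

    The AUC is the trapezoidal area (ties handled by midranks); the cutoff
    maximizes Youden's J = sensitivity + specificity - 1, with ties broken
    toward higher specificity; sensitivity/specificity/PPV/NPV are
    evaluated at that cutoff (predict positive when score >= cutoff).  The
    95% CI uses the DeLong variance: ``ci_method="normal"`` gives a normal
    interval clipped to [0, 1]; ``"logit"`` builds the interval on the
    logit scale and back-transforms (never leaves (0, 1)).

    If ``positive_higher`` is None the orientation is auto-detected (the
    direction giving AUC >= 0.5) and logged.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    is_pos = _check_binary(labels, positive)

    auc_raw, _, _ = _delong_components(scores, is_pos)
    if positive_higher is None:
        positive_higher = auc_raw >= 0.5
        logger.info("ROC orientation auto-detected: higher scores are %s",
                    "positive" if positive_higher else "negative")
    oriented = scores if positive_higher else -scores

    auc, v10, v01 = _delong_components(oriented, is_pos)
    m, n = v10.size, v01.size
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    se = float(np.sqrt(var))
    if ci_method == "normal":
        ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))
    elif ci_method == "logit":
        if auc <= 0.0 or auc >= 1.0 or se == 0.0:
            ci = (auc, auc)
        else:
            logit = np.log(auc / (1 - auc))
            se_logit = se / (auc * (1 - auc))
            lo, hi = logit - 1.96 * se_logit, logit + 1.96 * se_logit
            ci = (float(1 / (1 + np.exp(-lo))), float(1 / (1 + np.exp(-hi))))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    # full curve over the distinct score values, descending
    thresholds = np.unique(oriented)[::-1]
    pos_total = int(is_pos.sum())
    neg_total = int((~is_pos).sum())
    tpr = np.empty(thresholds.size + 1)
    fpr = np.empty(thresholds.size + 1)
    tpr[0] = fpr[0] = 0.0
    for i, t in enumerate(thresholds, start=1):
        pred = oriented >= t
        tpr[i] = (pred & is_pos).sum() / pos_total
        fpr[i] = (pred & ~is_pos).sum() / neg_total
    curve = np.column_stack([fpr, tpr])

    j = tpr - fpr
    # ties toward higher specificity = lower fpr = earlier index
    best = int(np.argmax(j[1:])) + 1
    cutoff_oriented = float(thresholds[best - 1])
    pred = oriented >= cutoff_oriented
    tp = int((pred & is_pos).sum())
    fp = int((pred & ~is_pos).sum())
    fn = pos_total - tp
    tn = neg_total - fp
    sens = tp / pos_total
    spec = tn / neg_total
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    cutoff = cutoff_oriented if positive_higher else -cutoff_oriented

    return RocResult(
        auc=auc, ci95=ci, curve=curve, cutoff=cutoff,
        sensitivity=float(sens), specificity=float(spec),
        ppv=float(ppv), npv=float(npv), positive_higher=bool(positive_higher),
    )


def delong_paired(scores_a, scores_b, labels, positive: str = "PD") -> DeLongResult:
    """DeLong test for the difference of two AUCs on the same subjects.

    The covariance of the two AUC estimates is computed from the paired
    structural components; ``z = delta / sqrt(var)`` with a two-sided
    normal p-value.  Identical score vectors give ``p = 1``.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score vectors must cover the same subjects")
    is_pos = _check_binary(labels, positive)
    if is_pos.size != a.size:
        raise ValueError("labels and scores differ in length")

    auc_a, v10_a, v01_a = _delong_components(a, is_pos)
    auc_b, v10_b, v01_b = _delong_components(b, is_pos)
    delta = auc_a - auc_b

    if np.array_equal(a, b):
        return DeLongResult(auc_a=auc_a, auc_b=auc_b, delta=0.0,
                            variance_of_delta=0.0, z=0.0, p=1.0)

    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    var = float(max(var, 0.0))

    if var == 0.0:
        if delta == 0.0:
            return DeLongResult(auc_a=auc_a, auc_b=auc_b, delta=0.0,
                                variance_of_delta=0.0, z=0.0, p=1.0)
        raise ValueError("degenerate DeLong variance with nonzero AUC difference")

    z = delta / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return DeLongResult(auc_a=auc_a, auc_b=auc_b, delta=float(delta),
                        variance_of_delta=var, z=float(z), p=float(p))
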