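"""Prediction-performance evaluation: ROC/AUC threshold sweep, group
statistics, clinically integrated random-forest cross-validation, and
cross-dataset comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

STAGE_CODES = {"I": 1, "II": 2, "III": 3, "IV": 4}
GRADE_CODES = {"I": 1, "II": 2, "III": 3}


@dataclass(frozen=True)
class RocResult:
    """Threshold sweep over observed score values plus the AUC."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


@dataclass(frozen=True)
class CvReport:
    """Summary of repeated stratified k-fold random-forest evaluation."""

    mean_auc: float
    sd_auc: float
    per_repeat_auc: np.ndarray  # length = repeats
    feature_importances: pd.DataFrame  # repeats × features
    folds: int
    repeats: int
    seed: int


def roc_curve(scores, labels) -> RocResult:
    """Sweep a pCR-if-score-above-threshold rule over every observed score.

    The AUC (trapezoidal over the sweep, ties counting half) equals the
    Mann–Whitney concordance probability.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("labels must contain both classes, coded 1 (pCR)/0 (RD)")
    thresholds = np.unique(scores)
    pos = scores[y == 1]
    neg = scores[y == 0]
    sens = np.array([(pos > t).mean() for t in thresholds])
    spec = np.array([(neg <= t).mean() for t in thresholds])
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=float(roc_auc_score(y, scores)),
    )


def rank_sum_test(scores_pcr, scores_rd) -> float:
    """Two-sided Wilcoxon rank-sum p-value comparing the two groups.

    Exact for combined n ≤ 20 without ties; otherwise the tie-corrected
    normal approximation.
    """
    a = np.asarray(scores_pcr, dtype=float)
    b = np.asarray(scores_rd, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:  # every value tied: no evidence of a shift
        return 1.0
    exact = len(pooled) <= 20 and len(np.unique(pooled)) == len(pooled)
    method = "exact" if exact else "asymptotic"
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def tertile_enrichment(scores, labels):
    """Chi-square test of response enrichment across score tertiles.

    Samples are split at the 1/3 and 2/3 score quantiles (boundary ties go
    to the lower tertile); a Pearson chi-square without continuity
    correction is computed on the 2 × 3 response-by-tertile table.
    Returns ``(counts, chi2, p)`` with counts as a 2 × 3 frame
    (rows pCR/RD, columns low/mid/high).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if len(scores) < 6:
        raise ValueError("need at least 6 samples")
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("both classes must be present")
    q1, q2 = np.quantile(scores, [1 / 3, 2 / 3])
    tertile = np.where(scores <= q1, 0, np.where(scores <= q2, 1, 2))
    counts = np.zeros((2, 3))
    for row, cls in enumerate((1.0, 0.0)):  # pCR first
        for col in range(3):
            counts[row, col] = np.sum((y == cls) & (tertile == col))
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("an empty tertile after tie handling")
    chi2, p, _, _ = stats.chi2_contingency(counts, correction=False)
    frame = pd.DataFrame(
        counts, index=["pCR", "RD"], columns=["low", "mid", "high"], dtype=int
    )
    return frame, float(chi2), float(p)


def chi_square_statistic(counts) -> float:
    """Pearson Σ(O−E)²/E on an arbitrary contingency table (no correction)."""
    chi2, _, _, _ = stats.chi2_contingency(np.asarray(counts), correction=False)
    return float(chi2)


def encode_clinical_features(annotations: pd.DataFrame) -> pd.DataFrame:
    """Encode age/stage/grade numerically for the classifier.

    Stage and grade become ordered integers; samples with unknown values
    are excluded (their count is logged), never imputed.
    """
    out = pd.DataFrame(index=annotations.index)
    out["age"] = pd.to_numeric(annotations["age"], errors="coerce")
    out["stage"] = annotations["stage"].map(STAGE_CODES)
    out["grade"] = annotations["grade"].map(GRADE_CODES)
    complete = out.dropna()
    n_dropped = len(out) - len(complete)
    if n_dropped:
        logger.info("excluded %d sample(s) with unknown clinical values", n_dropped)
    return complete


def combined_classifier_cv(
    features: pd.DataFrame,
    labels,
    folds: int = 10,
    repeats: int = 100,
    seed: int | None = None,
    n_estimators: int = 500,
    pooling: str = "pooled",
) -> CvReport:
    """Repeated stratified k-fold random-forest evaluation with balanced
    class sampling.

    Per repeat, samples are randomly assigned to stratified folds; in each
    training split the majority class is randomly subsampled to the
    minority class size before fitting a random forest (``n_estimators``
    trees, √p features per split). Held-out class-1 probabilities are
    pooled across folds into one AUC per repeat (``pooling='fold_mean'``
    averages per-fold AUCs instead). Mean-decrease-in-impurity feature
    importances are averaged across the folds of each repeat.
    """
    if pooling not in ("pooled", "fold_mean"):
        raise ValueError(f"unknown pooling {pooling!r}")
    X = features.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=float)
    if len(y) != len(X):
        raise ValueError("features and labels disagree on sample count")
    if len(X) < 30:
        raise ValueError("need at least 30 samples")
    class_counts = pd.Series(y).value_counts()
    if len(class_counts) < 2 or class_counts.min() < folds:
        raise ValueError("each class needs at least as many samples as folds")

    rng = np.random.default_rng(seed)
    per_repeat_auc = np.empty(repeats)
    importances = np.empty((repeats, X.shape[1]))
    for r in range(repeats):
        fold_seed = int(rng.integers(2**31))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=fold_seed)
        pooled_prob = np.empty(len(y))
        fold_aucs = []
        fold_imps = []
        for train_idx, test_idx in skf.split(X, y):
            bal_idx = _balance_classes(train_idx, y, rng)
            clf = RandomForestClassifier(
                n_estimators=n_estimators,
                max_features="sqrt",
                random_state=int(rng.integers(2**31)),
            )
            clf.fit(X[bal_idx], y[bal_idx])
            prob = clf.predict_proba(X[test_idx])[:, list(clf.classes_).index(1.0)]
            pooled_prob[test_idx] = prob
            fold_imps.append(clf.feature_importances_)
            if pooling == "fold_mean" and len(np.unique(y[test_idx])) == 2:
                fold_aucs.append(roc_auc_score(y[test_idx], prob))
        if pooling == "pooled":
            per_repeat_auc[r] = roc_auc_score(y, pooled_prob)
        else:
            per_repeat_auc[r] = float(np.mean(fold_aucs))
        importances[r] = np.mean(fold_imps, axis=0)
    return CvReport(
        mean_auc=float(per_repeat_auc.mean()),
        sd_auc=float(per_repeat_auc.std(ddof=1)) if repeats > 1 else 0.0,
        per_repeat_auc=per_repeat_auc,
        feature_importances=pd.DataFrame(importances, columns=features.columns),
        folds=folds,
        repeats=repeats,
        seed=int(seed) if seed is not None else -1,
    )


def _balance_classes(train_idx, y, rng) -> np.ndarray:
    """Subsample the majority class to the minority class size."""
    idx0 = train_idx[y[train_idx] == 0]
    idx1 = train_idx[y[train_idx] == 1]
    m = min(len(idx0), len(idx1))
    keep0 = rng.choice(idx0, size=m, replace=False)
    keep1 = rng.choice(idx1, size=m, replace=False)
    out = np.concatenate([keep0, keep1])
    out.sort()
    return out


def importance_comparison(report: CvReport):
    """Per-feature mean importance plus a one-way ANOVA across features.

    Returns ``(mean_importance: Series, anova_p: float)``; the F statistic
    is available from the returned Series' ``.attrs['F']``.
    """
    imps = report.feature_importances
    if imps.shape[1] < 2:
        raise ValueError("need at least 2 features")
    if imps.shape[0] < 2:
        raise ValueError("need at least 2 repeats")
    groups = [imps[c].to_numpy() for c in imps.columns]
    f_stat, p = stats.f_oneway(*groups)
    if np.isnan(f_stat):  # identical values in every group
        f_stat, p = 0.0, 1.0
    mean_imp = imps.mean(axis=0)
    mean_imp.attrs["F"] = float(f_stat)
    return mean_imp, float(p)


def paired_auc_comparison(auc_a, auc_b):
    """Paired two-sided t-test on per-dataset AUC differences.

    Returns ``(t, p)``; positive t means the first signature's AUCs are
    higher on average.
    """
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need paired vectors of equal length >= 3")
    diff = a - b
    if np.var(diff, ddof=1) == 0:
        raise ValueError("zero variance of AUC differences")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
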