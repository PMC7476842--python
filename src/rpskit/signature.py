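"""Weight-profile construction from a labelled training cohort.

Each gene is fit with a univariate logistic regression of response
(pCR = 1, RD = 0) on its log2 expression. Genes up-regulated in responders
(β₁ > 0) receive weight −log(p) in the up profile w⁺, down-regulated genes
receive it in w⁻; the opposite side is exactly zero. Raw weights are capped
at ``trim`` and min-max rescaled into [0, 1] on a scale shared by both
profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationWarning

# a univariate logistic slope on log2 expression beyond this magnitude is a
# numerical-divergence signature, not a biological effect size
_MAX_FINITE_SLOPE = 50.0


@dataclass(frozen=True)
class GeneStats:
    """Per-gene logistic-fit summary."""

    gene_id: str
    beta0: float
    beta1: float
    p_value: float
    converged: bool


def fit_gene_logistic(expr, labels, gene_id: str = "") -> GeneStats:
    """Maximum-likelihood fit of logit P(pCR) = β₀ + β₁·expr for one gene.

    Returns Wald two-sided p-value for β₁. Quasi-separated data (no finite
    MLE) and optimizer failures are reported with ``converged=False``; such
    genes are excluded from the weight profiles because their p-values are
    unreliable.
    """
    expr = np.asarray(expr, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if expr.shape != labels.shape:
        raise ValueError("expr and labels must have equal length")
    if len(expr) < 4:
        raise ValueError("need at least 4 samples")
    if not (set(np.unique(labels)) <= {0.0, 1.0}):
        raise ValueError("labels must be coded pCR=1, RD=0")
    if len(np.unique(labels)) < 2:
        raise ValueError("both response classes must be present")

    if np.ptp(expr) == 0:
        # constant predictor: slope is identically 0, no evidence either way
        p1 = labels.mean()
        beta0 = float(np.log(p1 / (1 - p1))) if 0 < p1 < 1 else 0.0
        return GeneStats(gene_id, beta0, 0.0, 1.0, True)

    X = sm.add_constant(expr)
    separated = False
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = sm.Logit(labels, X).fit(disp=0, maxiter=100)
        separated = any(
            issubclass(w.category, PerfectSeparationWarning) for w in caught
        )
        failed = any(issubclass(w.category, ConvergenceWarning) for w in caught)
    except Exception:  # singular Hessian, optimizer failure
        return GeneStats(gene_id, np.nan, np.nan, np.nan, False)

    beta0, beta1 = float(res.params[0]), float(res.params[1])
    p_value = float(res.pvalues[1])
    ok = (
        not separated
        and not failed
        and bool(res.mle_retvals.get("converged", False))
        and np.isfinite(beta1)
        and np.isfinite(p_value)
        and abs(beta1) <= _MAX_FINITE_SLOPE
    )
    if not ok:
        return GeneStats(gene_id, beta0, beta1, p_value, False)
    return GeneStats(gene_id, beta0, beta1, min(max(p_value, 1e-300), 1.0), True)


def fit_logistic_weights(m: pd.DataFrame, labels) -> list[GeneStats]:
    """Fit :func:`fit_gene_logistic` for every gene of a genes × samples matrix.

    ``labels`` may be a 0/1 vector aligned to columns or a pCR/RD string
    Series indexed by sample id.
    """
    y = response_to_binary(labels, m.columns)
    return [
        fit_gene_logistic(m.loc[g].to_numpy(), y, gene_id=str(g)) for g in m.index
    ]


def response_to_binary(labels, sample_ids=None) -> np.ndarray:
    """Map pCR/RD labels (or an already-binary vector) to 1/0 floats."""
    if isinstance(labels, pd.Series) and sample_ids is not None:
        missing = [s for s in sample_ids if s not in labels.index]
        if missing:
            raise ValueError(f"samples without response label: {missing[:5]}")
        labels = labels.reindex(sample_ids)
    arr = np.asarray(labels)
    if arr.dtype.kind in "OUS":
        bad = set(np.unique(arr)) - {"pCR", "RD"}
        if bad:
            raise ValueError(f"invalid response label(s) {sorted(bad)}")
        return (arr == "pCR").astype(float)
    return arr.astype(float)


def build_weight_profiles(
    stats: list[GeneStats], trim: float = 10.0, log_base: float = 10.0
) -> pd.DataFrame:
    """Turn per-gene fits into the paired weight profiles (w⁺, w⁻).

    Raw weight −log(p) goes to w⁺ when β₁ > 0 and to w⁻ when β₁ < 0 (the
    other side is zero; β₁ = 0 leaves both sides zero). Raw weights are
    capped at ``trim`` and min-max rescaled jointly over both profiles so
    that exact zeros stay zero and the largest weight becomes 1.
    """
    if log_base not in (10.0, 10, np.e) and not np.isclose(log_base, np.e):
        raise ValueError("log_base must be 10 or e")
    usable = [s for s in stats if s.converged]
    if not usable:
        raise ValueError("no gene produced a converged logistic fit")
    gene_ids = [s.gene_id for s in stats]
    w_plus = np.zeros(len(stats))
    w_minus = np.zeros(len(stats))
    log_den = np.log(log_base)
    for i, s in enumerate(stats):
        if not s.converged or s.beta1 == 0:
            continue
        raw = min(-np.log(s.p_value) / log_den, trim)
        if s.beta1 > 0:
            w_plus[i] = raw
        else:
            w_minus[i] = raw
    pooled = np.concatenate([w_plus, w_minus])
    lo, hi = pooled.min(), pooled.max()
    if hi > lo:
        w_plus = (w_plus - lo) / (hi - lo)
        w_minus = (w_minus - lo) / (hi - lo)
    profiles = pd.DataFrame(
        {"w_plus": w_plus, "w_minus": w_minus},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return profiles


def tnbc_mask(annotations: pd.DataFrame) -> pd.Series:
    """Boolean mask for triple-negative samples (ER−, PR−, Her2−)."""
    return (
        (annotations["er_status"] == "negative")
        & (annotations["pr_status"] == "negative")
        & (annotations["her2_status"] == "negative")
    )


def subset_samples(annotations: pd.DataFrame, criteria: dict) -> pd.Series:
    """Mask of samples matching ``{column: value}`` equality criteria."""
    mask = pd.Series(True, index=annotations.index)
    for col, value in criteria.items():
        if col not in annotations.columns:
            raise ValueError(f"unknown annotation column {col!r}")
        mask &= annotations[col] == value
    return mask
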