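"""Expression-matrix preprocessing: probe collapse, quantile normalization,
and empirical-Bayes batch adjustment.

All functions take genes × samples :class:`pandas.DataFrame` matrices of
log2-scale intensities (values are assumed already log-transformed; nothing
here re-logs). Thin scikit-learn transformer wrappers operating on the
conventional samples × features orientation live at the bottom.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


def collapse_probes(pm: pd.DataFrame, probe_to_gene: pd.Series) -> pd.DataFrame:
    """Collapse a probe-level matrix to gene level.

    For a gene measured by several probesets the probeset with the largest
    mean intensity across samples represents the gene, and its row is kept
    verbatim. Ties on the mean break toward the lexicographically smaller
    probe id so the collapse is deterministic. Probes without a gene mapping
    are dropped.
    """
    if len(probe_to_gene) == 0:
        raise ValueError("probe_to_gene map is empty")
    mapped = pm.index.intersection(probe_to_gene.index)
    if len(mapped) == 0:
        raise ValueError("no probe in the matrix has a gene mapping")
    sub = pm.loc[mapped]
    info = pd.DataFrame(
        {
            "gene_id": probe_to_gene.loc[mapped].to_numpy(),
            "mean": sub.mean(axis=1).to_numpy(),
            "probe_id": mapped.astype(str),
        }
    )
    info = info.sort_values(
        ["gene_id", "mean", "probe_id"], ascending=[True, False, True]
    )
    chosen = info.drop_duplicates("gene_id", keep="first")
    out = sub.loc[chosen["probe_id"].to_numpy()].copy()
    out.index = pd.Index(chosen["gene_id"].to_numpy(), name="gene_id")
    return out


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize samples (columns) to a common distribution.

    The reference distribution is the across-sample mean of the per-sample
    sorted value vectors; each sample's values are replaced by the reference
    values at their within-sample ranks. Tied values within a sample receive
    the mean of the reference values over the tied rank positions (the
    limma convention), keeping the map deterministic.
    """
    if m.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    values = m.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("missing values are not allowed")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        out[:, j] = _map_to_reference(values[:, j], reference)
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def _map_to_reference(col: np.ndarray, reference: np.ndarray) -> np.ndarray:
    order = np.argsort(col, kind="stable")
    sorted_vals = col[order]
    result = np.empty_like(col)
    i = 0
    n = len(col)
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        result[order[i : j + 1]] = reference[i : j + 1].mean()
        i = j + 1
    return result


def adjust_batches(
    m: pd.DataFrame,
    batch,
    method: str = "eb",
) -> pd.DataFrame:
    """Remove per-gene batch location/scale differences.

    Parameters
    ----------
    m : genes × samples matrix.
    batch : per-sample batch labels — a Series/array aligned to ``m``'s
        columns, or an annotation frame carrying a ``batch`` column indexed
        by sample id.
    method : {'eb', 'center_scale', 'none'}
        ``'eb'`` applies a parametric empirical-Bayes location-scale
        adjustment (ComBat-style: batch effects are shrunk toward common
        priors estimated across genes). ``'center_scale'`` applies the
        direct per-gene location-scale formula without shrinkage and
        preserves each gene's grand mean exactly. ``'none'`` returns a copy.
    """
    if method == "none":
        return m.copy()
    if method not in ("eb", "center_scale"):
        raise ValueError(f"unknown batch method {method!r}")
    labels = _batch_labels(m, batch)
    groups = labels.groupby(labels).size()
    if len(groups) < 2:
        raise ValueError(
            "batch adjustment needs >= 2 batches; with a single batch, pass "
            "method='none' or skip adjustment"
        )
    singletons = groups[groups < 2].index.tolist()
    if singletons:
        raise ValueError(
            f"batch(es) {singletons} contain a single sample; merge them with "
            "another batch or exclude those samples before adjustment"
        )
    x = m.to_numpy(dtype=float)
    codes, uniques = pd.factorize(labels)
    n_i = np.bincount(codes).astype(float)  # samples per batch
    n_total = x.shape[1]

    batch_mean = np.stack(
        [x[:, codes == b].mean(axis=1) for b in range(len(uniques))], axis=0
    )  # batches × genes
    grand_mean = (n_i[:, None] / n_total * batch_mean).sum(axis=0)
    resid = x - batch_mean[codes].T
    var_pooled = (resid**2).sum(axis=1) / n_total
    var_pooled = np.where(var_pooled <= 0, 1e-12, var_pooled)
    sd_pooled = np.sqrt(var_pooled)

    if method == "center_scale":
        out = np.empty_like(x)
        for b in range(len(uniques)):
            idx = codes == b
            mu_b = batch_mean[b]
            sd_b = x[:, idx].std(axis=1, ddof=1)
            scale = np.where(sd_b > 0, sd_pooled / np.where(sd_b > 0, sd_b, 1.0), 1.0)
            out[:, idx] = (x[:, idx] - mu_b[:, None]) * scale[:, None] + grand_mean[
                :, None
            ]
        return pd.DataFrame(out, index=m.index, columns=m.columns)

    # parametric empirical-Bayes (ComBat) path
    z = (x - grand_mean[:, None]) / sd_pooled[:, None]
    gamma_hat = np.stack(
        [z[:, codes == b].mean(axis=1) for b in range(len(uniques))], axis=0
    )
    delta_hat = np.stack(
        [z[:, codes == b].var(axis=1, ddof=1) for b in range(len(uniques))], axis=0
    )
    delta_hat = np.where(delta_hat <= 0, 1e-12, delta_hat)

    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    a_prior = _aprior(delta_hat)
    b_prior = _bprior(delta_hat)

    z_adj = np.empty_like(z)
    for b in range(len(uniques)):
        idx = codes == b
        g_star, d_star = _eb_posterior(
            z[:, idx],
            gamma_hat[b],
            delta_hat[b],
            gamma_bar[b],
            tau2[b],
            a_prior[b],
            b_prior[b],
        )
        z_adj[:, idx] = (z[:, idx] - g_star[:, None]) / np.sqrt(d_star)[:, None]
    out = z_adj * sd_pooled[:, None] + grand_mean[:, None]
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def _batch_labels(m: pd.DataFrame, batch) -> pd.Series:
    if isinstance(batch, pd.DataFrame):
        if "batch" not in batch.columns:
            raise ValueError("annotation frame lacks a 'batch' column")
        batch = batch["batch"]
    if isinstance(batch, pd.Series):
        missing = [s for s in m.columns if s not in batch.index]
        if missing:
            raise ValueError(f"samples without a batch label: {missing[:5]}")
        return batch.reindex(m.columns)
    batch = pd.Series(np.asarray(batch), index=m.columns)
    return batch


def _aprior(delta_hat: np.ndarray) -> np.ndarray:
    mean = delta_hat.mean(axis=1)
    s2 = delta_hat.var(axis=1, ddof=1)
    s2 = np.where(s2 <= 0, 1e-12, s2)
    return (2 * s2 + mean**2) / s2


def _bprior(delta_hat: np.ndarray) -> np.ndarray:
    mean = delta_hat.mean(axis=1)
    s2 = delta_hat.var(axis=1, ddof=1)
    s2 = np.where(s2 <= 0, 1e-12, s2)
    return (mean * s2 + mean**3) / s2


def _eb_posterior(
    z_b: np.ndarray,
    gamma_hat: np.ndarray,
    delta_hat: np.ndarray,
    gamma_bar: float,
    tau2: float,
    a: float,
    b: float,
    tol: float = 1e-4,
    max_iter: int = 200,
):
    """Iterative posterior-mean solution for one batch's EB parameters."""
    n = z_b.shape[1]
    g_old = gamma_hat.copy()
    d_old = delta_hat.copy()
    for _ in range(max_iter):
        g_new = (tau2 * n * gamma_hat + d_old * gamma_bar) / (tau2 * n + d_old)
        sum2 = ((z_b - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2 + a - 1)
        change = max(
            np.abs(g_new - g_old).max() / max(np.abs(g_old).max(), 1e-12),
            np.abs(d_new - d_old).max() / max(np.abs(d_old).max(), 1e-12),
        )
        g_old, d_old = g_new, d_new
        if change < tol:
            break
    return g_old, d_old


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Map each sample's values onto a stored reference distribution.

    Operates on samples × genes arrays (scikit-learn orientation). ``fit``
    learns the reference as the mean of the per-sample sorted vectors;
    ``transform`` maps any cohort with the same gene set onto it, so a
    normalization learned on a training cohort can be applied to validation
    samples one at a time.
    """

    def fit(self, X, y=None):
        X = self._validate_data(X, dtype=float, ensure_min_samples=2)
        self.reference_distribution_ = np.sort(X, axis=1).mean(axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_distribution_")
        X = self._validate_data(X, dtype=float, reset=False)
        out = np.empty_like(X)
        for i in range(X.shape[0]):
            out[i] = _map_to_reference(X[i], self.reference_distribution_)
        return out

    def _validate_data(self, X, **kwargs):  # sklearn >=1.6 moved validate_data
        try:
            from sklearn.utils.validation import validate_data

            return validate_data(self, X, **kwargs)
        except ImportError:  # pragma: no cover - older sklearn
            return super()._validate_data(X, **kwargs)


class BatchAdjuster(BaseEstimator, TransformerMixin):
    """Transformer facade over :func:`adjust_batches`.

    Because the adjustment needs every batch jointly, this estimator is
    fit-transform shaped: call ``fit_transform(X, batch=labels)`` with
    samples × genes input.
    """

    def __init__(self, method: str = "eb"):
        self.method = method

    def fit_transform(self, X, y=None, *, batch):
        X = np.asarray(X, dtype=float)
        m = pd.DataFrame(X.T)
        adjusted = adjust_batches(m, np.asarray(batch), method=self.method)
        self.n_features_in_ = X.shape[1]
        return adjusted.to_numpy().T

    def fit(self, X, y=None, *, batch):
        self.fit_transform(X, batch=batch)
        return self
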