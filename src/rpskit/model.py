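"""Scikit-learn estimator facade for the response-probability framework.

``ResponseProbabilityScorer.fit`` learns the paired weight profiles from a
labelled training cohort (per-gene logistic regressions); ``transform`` /
``decision_function`` score new cohorts with the permutation-normalized
BASE statistic. The estimator composes with sklearn pipelines and model
selection; the functional API in :mod:`rpskit.signature` and
:mod:`rpskit.scoring` does the actual work.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import scoring, signature


class ResponseProbabilityScorer(BaseEstimator, TransformerMixin):
    """Whole-transcriptome response scoring (RPS / TNBC-RPS).

    Parameters
    ----------
    trim : float, default 10.0
        Cap on the raw −log(p) weights before rescaling into [0, 1].
    log_base : float, default 10.0
        Base of the −log(p) transform (10 or e).
    n_permutations : int, default 1000
        Permutations per sample for the scoring null.
    deviation : {'max_abs_signed', 'max_signed'}
        Convention for the maximum foreground/background deviation.
    random_state : int or None
        Master seed for the per-sample permutation streams.

    Attributes
    ----------
    weight_profiles_ : DataFrame with columns ``w_plus``/``w_minus`` per gene.
    gene_stats_ : list of per-gene logistic-fit summaries.
    feature_names_in_ : gene identifiers seen at fit time.

    Examples
    --------
    >>> scorer = ResponseProbabilityScorer(n_permutations=200, random_state=0)
    >>> scorer.fit(X_train, y_train)              # doctest: +SKIP
    >>> rps = scorer.decision_function(X_test)    # doctest: +SKIP
    """

    def __init__(
        self,
        trim: float = 10.0,
        log_base: float = 10.0,
        n_permutations: int = 1000,
        deviation: str = "max_abs_signed",
        random_state: int | None = None,
    ):
        self.trim = trim
        self.log_base = log_base
        self.n_permutations = n_permutations
        self.deviation = deviation
        self.random_state = random_state

    def fit(self, X, y):
        """Fit per-gene logistic weights on a samples × genes cohort.

        ``y`` holds pCR/RD strings or a 1/0 vector (pCR = 1).
        """
        matrix = self._as_gene_matrix(X, reset=True)
        labels = signature.response_to_binary(
            y, matrix.columns if isinstance(y, pd.Series) else None
        )
        if len(labels) != matrix.shape[1]:
            raise ValueError("X and y disagree on sample count")
        self.gene_stats_ = signature.fit_logistic_weights(matrix, labels)
        self.weight_profiles_ = signature.build_weight_profiles(
            self.gene_stats_, trim=self.trim, log_base=self.log_base
        )
        self.classes_ = np.array([0.0, 1.0])
        return self

    def transform(self, X) -> np.ndarray:
        """Score a cohort; returns columns [rps_plus, rps_minus, rps]."""
        return self.score_frame(X)[["rps_plus", "rps_minus", "rps"]].to_numpy()

    def decision_function(self, X) -> np.ndarray:
        """Final RPS per sample (higher = more pCR-like)."""
        return self.score_frame(X)["rps"].to_numpy()

    def score_frame(self, X) -> pd.DataFrame:
        """Full per-sample score table, including null summaries."""
        check_is_fitted(self, "weight_profiles_")
        matrix = self._as_gene_matrix(X, reset=False)
        scores = scoring.score_cohort(
            matrix,
            self.weight_profiles_,
            n_perm=self.n_permutations,
            seed=self.random_state,
            mode=self.deviation,
        )
        return scoring.scores_to_frame(scores)

    def get_feature_names_out(self, input_features=None):
        return np.array(["rps_plus", "rps_minus", "rps"])

    def _as_gene_matrix(self, X, reset: bool) -> pd.DataFrame:
        """Validate samples × genes input and return a genes × samples frame."""
        if isinstance(X, pd.DataFrame):
            genes = X.columns.astype(str)
            values = X.to_numpy(dtype=float)
            samples = X.index.astype(str)
        else:
            values = np.asarray(X, dtype=float)
            if values.ndim != 2:
                raise ValueError("X must be 2-dimensional (samples × genes)")
            genes = pd.Index([f"g{i}" for i in range(values.shape[1])])
            samples = pd.Index([str(i) for i in range(values.shape[0])])
        if np.isnan(values).any():
            raise ValueError("X contains missing values")
        if genes.duplicated().any():
            raise ValueError("duplicated gene identifiers in X")
        if reset:
            self.feature_names_in_ = np.asarray(genes)
            self.n_features_in_ = len(genes)
        else:
            check_is_fitted(self, "n_features_in_")
        return pd.DataFrame(values.T, index=genes, columns=samples)
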