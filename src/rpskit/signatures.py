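"""Published comparator signatures: the generic weighted Module score and
the formulaic composite scores built from it.

Gene lists are user-supplied (TSV: ``name,gene_id,weight``); nothing is
hard-coded. Commercial assay algorithms (Oncotype DX, MammaPrint, ...) are
out of scope — only scores expressible through the Module-score machinery
are computed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COMBINATORS = ("module", "mean", "consensus", "desmedt", "metagene_diff")


@dataclass(frozen=True)
class SignatureDefinition:
    """A named gene signature with signed per-gene weights."""

    name: str
    entries: tuple  # of (gene_id, weight)
    combinator: str = "module"

    def __post_init__(self):
        if len(self.entries) == 0:
            raise ValueError(f"signature {self.name!r} has no entries")
        if self.combinator not in COMBINATORS:
            raise ValueError(f"unknown combinator {self.combinator!r}")
        weights = np.array([w for _, w in self.entries], dtype=float)
        if not np.isfinite(weights).all():
            raise ValueError(f"signature {self.name!r} has non-finite weights")

    @classmethod
    def from_table(cls, table: pd.DataFrame, name: str, combinator: str = "module"):
        sub = table[table["name"] == name]
        entries = tuple(zip(sub["gene_id"].astype(str), sub["weight"].astype(float)))
        return cls(name=name, entries=entries, combinator=combinator)

    @property
    def gene_ids(self):
        return [g for g, _ in self.entries]


def module_score(
    sample_expr: pd.Series, sig: SignatureDefinition, abs_denominator: bool = False
) -> float:
    """Weighted average Σwᵢeᵢ / Σwᵢ over the signature genes present.

    Missing genes are dropped (their count is logged). For signed-weight
    modules whose literal weight sum vanishes, ``abs_denominator`` divides
    by Σ|wᵢ| instead.
    """
    present = [(g, w) for g, w in sig.entries if g in sample_expr.index]
    if not present:
        raise ValueError(f"no gene of signature {sig.name!r} present in profile")
    dropped = len(sig.entries) - len(present)
    if dropped:
        logger.info("signature %s: %d gene(s) missing, dropped", sig.name, dropped)
    weights = np.array([w for _, w in present], dtype=float)
    expr = sample_expr.loc[[g for g, _ in present]].to_numpy(dtype=float)
    denom = np.abs(weights).sum() if abs_denominator else weights.sum()
    if denom == 0:
        raise ValueError(
            f"signature {sig.name!r}: weight sum is zero; pass "
            "abs_denominator=True for signed-weight modules"
        )
    return float((weights * expr).sum() / denom)


def mean_expression_score(sample_expr: pd.Series, gene_list) -> float:
    """Arithmetic mean expression of the listed genes that are present."""
    present = [g for g in gene_list if g in sample_expr.index]
    if not present:
        raise ValueError("no listed gene present in profile")
    dropped = len(list(gene_list)) - len(present)
    if dropped:
        logger.warning("%d listed gene(s) missing, dropped from mean", dropped)
    return float(sample_expr.loc[present].mean())


def rescale_median_iqr(values) -> np.ndarray:
    """Rescale a cohort vector to median 0 and inter-quartile range 1.

    Quartiles use the midpoint convention so that e.g. (1,2,3,4) maps to
    (−0.75, −0.25, 0.25, 0.75).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 4:
        raise ValueError("IQR rescaling needs at least 4 samples")
    q25, q75 = np.percentile(x, [25, 75], method="midpoint")
    iqr = q75 - q25
    if iqr == 0:
        raise ValueError("zero inter-quartile range")
    return (x - np.median(x)) / iqr


def consensus_score(cohort_module, top2a, laptm4b) -> np.ndarray:
    """Consensus signature: sum of three median-0/IQR-1 rescaled components
    (an immune module score, TOP2A, and LAPTM4B expression), per sample."""
    parts = [np.asarray(v, dtype=float) for v in (cohort_module, top2a, laptm4b)]
    n = len(parts[0])
    if any(len(p) != n for p in parts):
        raise ValueError("component vectors must have equal length")
    return sum(rescale_median_iqr(p) for p in parts)


def desmedt_score(
    sample_expr: pd.Series,
    her2_status: str,
    immune_sig: SignatureDefinition,
    stroma_sig: SignatureDefinition,
    top2a_sig: SignatureDefinition,
) -> float:
    """Her2-dependent microenvironment combination: immune + stroma modules,
    plus the TOP2A proliferation module for Her2-positive tumors."""
    if her2_status not in ("positive", "negative"):
        raise ValueError(f"Her2 status must be positive/negative, got {her2_status!r}")
    total = module_score(sample_expr, immune_sig) + module_score(
        sample_expr, stroma_sig
    )
    if her2_status == "positive":
        total += module_score(sample_expr, top2a_sig)
    return float(total)


def metagene_difference_score(
    sample_expr: pd.Series,
    mitotic_sig: SignatureDefinition,
    ceramide_sig: SignatureDefinition,
) -> float:
    """Paclitaxel-response metagene: mitotic module − ceramide module."""
    return module_score(sample_expr, mitotic_sig) - module_score(
        sample_expr, ceramide_sig
    )


def score_cohort_signatures(
    m: pd.DataFrame, signatures: list[SignatureDefinition], **kwargs
) -> pd.DataFrame:
    """Module/mean scores for each signature across a genes × samples cohort."""
    rows = {}
    for sig in signatures:
        if sig.combinator == "mean":
            rows[sig.name] = [
                mean_expression_score(m[s], sig.gene_ids) for s in m.columns
            ]
        else:
            rows[sig.name] = [module_score(m[s], sig, **kwargs) for s in m.columns]
    return pd.DataFrame(rows, index=m.columns)
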