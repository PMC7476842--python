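"""Pathway annotation of a learned signature: walking-sum enrichment of
gene sets along the weight-ranked gene list, and correlation of sample
scores with tumor-microenvironment component estimates.

ES = (Σᵢ gᵢ·dᵢ / (n·N) − 0.5)·2 over the hit ranks r₁ < … < rₙ of a gene
set inside the N-gene ranked signature, where gᵢ = i is the cumulative hit
count and dᵢ = rᵢ₊₁ − rᵢ with the sentinel rₙ₊₁ = N + 1. Hits concentrated
at the top give ES → +1, at the bottom ES → −1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (deduplicated), e.g. parsed from a GMT file."""

    sets: dict  # name -> list of gene ids
    source: str = ""

    def __len__(self):
        return len(self.sets)


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    es: float
    n_hits_used: int
    direction: str  # 'up' if hits concentrate among up-weighted genes


def read_gmt(path) -> GeneSetCollection:
    """Parse an MSigDB-style GMT file (name, description, genes...)."""
    sets = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields"
                )
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            sets[name] = genes
    if not sets:
        warnings.warn(f"{path}: empty gene-set collection")
    return GeneSetCollection(sets=sets, source=str(path))


def filter_gene_sets(
    gsc: GeneSetCollection, ranked_genes, min_size: int = 20
) -> GeneSetCollection:
    """Restrict sets to the ranked universe; drop sets smaller than
    ``min_size`` after the intersection."""
    universe = set(map(str, ranked_genes))
    if not universe:
        raise ValueError("ranked gene list is empty")
    kept = {}
    for name, genes in gsc.sets.items():
        present = [g for g in genes if g in universe]
        if len(present) >= min_size:
            kept[name] = present
    return GeneSetCollection(sets=kept, source=gsc.source)


def rank_signature_genes(weights: pd.DataFrame) -> list[str]:
    """Order the signature's genes descending by signed weight w⁺ − w⁻.

    Zero-weight genes are retained (stable gene-id tie-break) so N matches
    the full gene universe of the signature.
    """
    signed = weights["w_plus"] - weights["w_minus"]
    gene_ids = signed.index.to_numpy(dtype=str)
    order = np.lexsort((gene_ids, -signed.to_numpy(dtype=float)))
    return [gene_ids[i] for i in order]


def enrichment_score(gene_set, ranked_genes) -> EnrichmentResult:
    """Walking-sum enrichment of ``gene_set`` within ``ranked_genes``."""
    ranked = list(map(str, ranked_genes))
    big_n = len(ranked)
    positions = {g: i + 1 for i, g in enumerate(ranked)}  # 1-based ranks
    hits = sorted(positions[g] for g in set(map(str, gene_set)) if g in positions)
    n = len(hits)
    if n == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    ranks = np.asarray(hits + [big_n + 1])
    g_i = np.arange(1, n + 1)
    d_i = np.diff(ranks)
    es = (float((g_i * d_i).sum()) / (n * big_n) - 0.5) * 2.0
    name = getattr(gene_set, "name", "")
    return EnrichmentResult(
        set_name=str(name),
        es=es,
        n_hits_used=n,
        direction="up" if es >= 0 else "down",
    )


def enrich_collection(
    gsc: GeneSetCollection, ranked_genes, min_size: int = 20
) -> pd.DataFrame:
    """Filter a collection and score every retained set; tabulated result."""
    kept = filter_gene_sets(gsc, ranked_genes, min_size=min_size)
    rows = []
    for name, genes in kept.sets.items():
        res = enrichment_score(genes, ranked_genes)
        rows.append(
            {
                "set_name": name,
                "es": res.es,
                "n_hits_used": res.n_hits_used,
                "direction": res.direction,
            }
        )
    return pd.DataFrame(rows, columns=["set_name", "es", "n_hits_used", "direction"])


def correlate_components(scores, components: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of sample scores with microenvironment
    components (e.g. immune and stromal abundance, proliferation).

    ``components`` columns are component names; returns a frame with
    ``rho`` and ``p`` per component. Ties receive average ranks.
    """
    s = np.asarray(scores, dtype=float)
    if len(s) != len(components):
        raise ValueError("scores and components disagree on sample count")
    if len(s) < 4:
        raise ValueError("need at least 4 paired samples")
    rows = {}
    for col in components.columns:
        v = components[col].to_numpy(dtype=float)
        if np.ptp(v) == 0 or np.ptp(s) == 0:
            raise ValueError(f"constant vector for component {col!r}")
        rho, p = stats.spearmanr(s, v)
        rows[col] = {"rho": float(rho), "p": float(p)}
    return pd.DataFrame(rows).T


def proliferation_proxy(m: pd.DataFrame, gene: str = "MKI67") -> pd.Series:
    """Median-centered per-sample expression of a proliferation marker."""
    if gene not in m.index:
        raise ValueError(f"gene {gene!r} absent from the expression matrix")
    row = m.loc[gene]
    return row - row.median()
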