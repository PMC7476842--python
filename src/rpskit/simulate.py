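"""Synthetic two-class cohorts with the statistical structure the scoring
framework assumes: Gaussian log2 microarray-style intensities, a planted set
of differentially expressed (DE) genes split between up- and down-regulation
in responders, per-batch intensity shifts, and clinical covariates tilted
toward response.

Defaults mirror a mid-sized neoadjuvant cohort: 2000 genes, 120 samples,
30% pCR (the responder rate reported for chemotherapy), 200 DE genes at a
1-SD shift, two batches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection

_STAGE_LEVELS = np.array(["I", "II", "III", "IV"])
_STAGE_BASE = np.array([0.15, 0.45, 0.30, 0.10])
_GRADE_LEVELS = np.array(["I", "II", "III"])
_GRADE_BASE = np.array([0.20, 0.40, 0.40])


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 2000
    n_samples: int = 120
    pcr_fraction: float = 0.3
    n_de_genes: int = 200
    effect_size: float = 1.0  # mean log2 shift in pCR samples, in noise-SD units
    noise_sd: float = 1.0
    n_batches: int = 2
    batch_shift_sd: float = 0.5
    clinical_effect: float = 1.0  # log-odds tilt of stage/grade toward pCR
    seed: int = 0

    def validate(self):
        for name in ("n_genes", "n_samples", "n_batches"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.pcr_fraction < 1:
            raise ValueError("pcr_fraction must lie in (0, 1)")
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes cannot exceed n_genes")
        if self.n_de_genes < 0 or self.noise_sd <= 0:
            raise ValueError("invalid n_de_genes or noise_sd")


@dataclass(frozen=True)
class SimulationTruth:
    de_genes: pd.Series  # gene_id -> +1 (up in pCR) or -1 (down in pCR)
    propensity: pd.Series  # per-sample latent response probability
    batches: pd.Series  # per-sample batch label
    gene_ids: tuple = field(repr=False, default=())

    @property
    def up_genes(self):
        return list(self.de_genes.index[self.de_genes > 0])

    @property
    def down_genes(self):
        return list(self.de_genes.index[self.de_genes < 0])


def simulate_cohort(cfg: SimulationConfig):
    """Generate (expression genes × samples, annotations, truth).

    Expression: per-gene baseline ~ N(7, 1.5) on the log2 scale plus
    N(0, noise_sd) noise; DE genes are shifted by ±effect_size·noise_sd in
    pCR samples (half up, half down); each batch adds a per-gene
    N(0, batch_shift_sd) offset. Stage and grade are drawn with their
    category log-odds tilted by ``clinical_effect`` toward pCR; receptor
    statuses are independent of response. Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    width = len(str(cfg.n_genes))
    gene_ids = pd.Index(
        [f"g{i:0{width}d}" for i in range(cfg.n_genes)], name="gene_id"
    )
    sample_ids = pd.Index(
        [f"s{i:04d}" for i in range(cfg.n_samples)], name="sample_id"
    )

    n_pcr = int(round(cfg.n_samples * cfg.pcr_fraction))
    n_pcr = min(max(n_pcr, 1), cfg.n_samples - 1)
    response = np.array(["RD"] * cfg.n_samples, dtype=object)
    response[rng.choice(cfg.n_samples, size=n_pcr, replace=False)] = "pCR"
    is_pcr = response == "pCR"

    de_idx = rng.choice(cfg.n_genes, size=cfg.n_de_genes, replace=False)
    signs = np.ones(cfg.n_de_genes)
    signs[cfg.n_de_genes // 2 :] = -1.0
    de_genes = pd.Series(signs, index=gene_ids[de_idx]).sort_index()

    batch_codes = rng.permutation(np.arange(cfg.n_samples) % cfg.n_batches)
    batch_labels = np.array([f"batch{b}" for b in batch_codes], dtype=object)

    baseline = rng.normal(7.0, 1.5, size=cfg.n_genes)
    batch_shift = rng.normal(0.0, cfg.batch_shift_sd, size=(cfg.n_genes, cfg.n_batches))
    noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, cfg.n_samples))
    values = baseline[:, None] + batch_shift[:, batch_codes] + noise
    shift = np.zeros((cfg.n_genes, cfg.n_samples))
    shift[np.ix_(de_idx, np.where(is_pcr)[0])] = (
        signs[:, None] * cfg.effect_size * cfg.noise_sd
    )
    values += shift

    expr = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    annotations = pd.DataFrame(
        {
            "response": response,
            "er_status": rng.choice(
                ["negative", "positive"], size=cfg.n_samples, p=[0.55, 0.45]
            ),
            "pr_status": rng.choice(
                ["negative", "positive"], size=cfg.n_samples, p=[0.60, 0.40]
            ),
            "her2_status": rng.choice(
                ["negative", "positive"], size=cfg.n_samples, p=[0.80, 0.20]
            ),
            "stage": _tilted_categorical(
                rng, _STAGE_LEVELS, _STAGE_BASE, is_pcr, cfg.clinical_effect
            ),
            "grade": _tilted_categorical(
                rng, _GRADE_LEVELS, _GRADE_BASE, is_pcr, cfg.clinical_effect
            ),
            "age": np.clip(np.round(rng.normal(50, 10, cfg.n_samples)), 25, 85),
            "batch": batch_labels,
        },
        index=sample_ids,
    )
    truth = SimulationTruth(
        de_genes=de_genes,
        propensity=pd.Series(cfg.pcr_fraction, index=sample_ids),
        batches=pd.Series(batch_labels, index=sample_ids),
        gene_ids=tuple(gene_ids),
    )
    return expr, annotations, truth


def _tilted_categorical(rng, levels, base_probs, is_pcr, effect):
    """Draw ordered categories; pCR samples get log-odds tilted toward the
    higher levels by ``effect`` per standardized level step."""
    k = np.arange(len(levels), dtype=float)
    centered = (k - k.mean()) / max(k.std(), 1.0)
    out = np.empty(len(is_pcr), dtype=object)
    logits = np.log(base_probs)
    for i, pcr in enumerate(is_pcr):
        lg = logits + (effect * centered if pcr else 0.0)
        p = np.exp(lg - lg.max())
        p /= p.sum()
        out[i] = rng.choice(levels, p=p)
    return out


def embed_gene_sets(
    truth: SimulationTruth,
    n_sets: int,
    set_size: int,
    overlap_with_de: float,
    direction: str = "up",
    seed: int = 0,
) -> GeneSetCollection:
    """Emit gene sets with a controlled overlap with the planted DE genes.

    Each set contains ``round(overlap_with_de * set_size)`` genes drawn from
    the DE genes of the requested ``direction`` ('up' or 'down'), the rest
    from non-DE genes. A set fully inside the up-DE genes should receive a
    strongly positive enrichment score on a recovered signature.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if not 0 <= overlap_with_de <= 1:
        raise ValueError("overlap_with_de must lie in [0, 1]")
    universe = list(truth.gene_ids)
    if set_size > len(universe):
        raise ValueError("set_size exceeds the gene universe")
    de_pool = truth.up_genes if direction == "up" else truth.down_genes
    other_pool = sorted(set(universe) - set(truth.de_genes.index))
    n_de = int(round(overlap_with_de * set_size))
    n_other = set_size - n_de
    if n_de > len(de_pool) or n_other > len(other_pool):
        raise ValueError(
            f"infeasible overlap: need {n_de} DE and {n_other} non-DE genes, "
            f"have {len(de_pool)} and {len(other_pool)}"
        )
    rng = np.random.default_rng(seed)
    sets = {}
    for i in range(n_sets):
        de_part = rng.choice(de_pool, size=n_de, replace=False) if n_de else []
        other_part = (
            rng.choice(other_pool, size=n_other, replace=False) if n_other else []
        )
        sets[f"set_{i + 1}"] = sorted(map(str, [*de_part, *other_part]))
    return GeneSetCollection(sets=sets, source="synthetic")
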