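# rpskit

Response-probability scoring of neoadjuvant chemotherapy (NCT) response
from pretreatment gene-expression profiles.

Only about a third of breast-cancer patients — and triple-negative
breast-cancer (TNBC) patients in particular — achieve a pathologic complete
response (pCR) to neoadjuvant chemotherapy; the rest are left with residual
disease (RD) and the side effects. `rpskit` implements a whole-transcriptome
framework for predicting that response before treatment:

1. **Signature construction.** On a labelled training cohort, each gene is
   fit with a univariate logistic regression
   `logit P(pCR) = β₀ + β₁·x` on its log2 expression. Genes up-regulated in
   responders (β₁ > 0) receive weight `w⁺ = −log₁₀ p`, down-regulated genes
   `w⁻ = −log₁₀ p`; weights are trimmed at 10 and min-max rescaled into
   [0, 1] on a scale shared by the two profiles.
2. **Single-sample scoring.** Each sample's median-centered profile is
   sorted in descending order and two cumulative curves compared:
   a foreground `f(i) = Σ_{k≤i} eₖwₖ / Σ_k eₖwₖ` and a background `b(i)`
   accumulating `eₖ(1−wₖ)`. The signed maximum deviation between the curves
   is z-normalized against a 1000-permutation null (expression values
   shuffled across gene labels), once with w⁺ and once with w⁻; the
   response-probability score is `RPS = RPS⁺ − RPS⁻`.
3. **Evaluation and annotation.** ROC/AUC threshold sweeps, rank-sum and
   tertile chi-square statistics, random-forest integration with clinical
   predictors (age, stage, grade) under repeated stratified 10-fold CV with
   balanced class sampling, walking-sum pathway enrichment of the learned
   signature, and Spearman correlation with tumor-microenvironment
   component estimates.

The package also ships comparator machinery (weighted Module scores
`Σwᵢeᵢ/Σwᵢ` and composite signatures built from them), microarray
preprocessing (probe collapse, quantile normalization, empirical-Bayes
batch adjustment), and a synthetic-cohort generator so the whole pipeline
is testable without external downloads.

## Worked example

```python
import rpskit as rk
from rpskit.evaluation import roc_curve

cfg = rk.SimulationConfig(n_genes=2000, n_samples=240, n_de_genes=200,
                          effect_size=1.0, seed=0)
expr, ann, truth = rk.simulate_cohort(cfg)          # genes × samples, log2
train = truth.batches.index[truth.batches == "batch0"]
test = truth.batches.index[truth.batches == "batch1"]

scorer = rk.ResponseProbabilityScorer(n_permutations=1000, random_state=1)
scorer.fit(expr[train].T, ann.loc[train, "response"])
rps = scorer.decision_function(expr[test].T)

y = (ann.loc[test, "response"] == "pCR").astype(float).to_numpy()
print(f"held-out AUC = {roc_curve(rps, y).auc:.2f}")
```

```
held-out AUC = 1.00
```

On this synthetic cohort the planted 1-SD effect across 200 of 2000 genes
is strong enough that the held-out area under the ROC curve saturates at
1.0 — a random pCR sample always outscores a random RD sample. On real
microarray cohorts, where effects are weaker and unevenly spread, AUCs in
the 0.6–0.9 range are the realistic regime the evaluation module is built
for.

The same estimator composes with scikit-learn pipelines
(`Pipeline([("qn", rk.QuantileNormalizer()), ("rps", scorer)])`), and every
step is also available functionally (`rk.fit_logistic_weights`,
`rk.build_weight_profiles`, `rk.score_cohort`, ...). A thin CLI mirrors the
workflow:

```sh
rps-kit simulate --config sim.yaml -o cohort/
rps-kit build --expr cohort/expression.tsv --annot cohort/annotations.tsv \
        --subset er_status=negative,pr_status=negative,her2_status=negative \
        -o tnbc_weights.tsv
rps-kit score --expr cohort/expression.tsv --weights tnbc_weights.tsv \
        --n-perm 1000 --seed 17 -o scores.tsv
rps-kit evaluate --scores scores.tsv --annot cohort/annotations.tsv \
        --cv-features rps,age,stage,grade -o report.json
```

## Documentation

See `docs/methods.md` for the model, its assumptions, parameter defaults,
numerical conventions, and known limitations.
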