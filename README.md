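# prognoscore

Discovery and application of weighted-sum gene-expression prognostic
scores from multi-cohort survival studies.

## The problem

Transcriptome cohorts of the same cancer (e.g. gastric adenocarcinoma
profiled by TCGA and several GEO series) each come with right-censored
overall survival (OS), sometimes a second endpoint (disease-free or
relapse-free survival), and cohort-specific clinical covariates.  A gene
signature intended for clinical risk stratification should be supported in
*every* cohort, not just pooled data.  `prognoscore` implements that
full-replication workflow as a tested Python library:

1. **Gene screen.**  For each gene in each cohort, expression is
   dichotomized at the optimal cutoff of a time-dependent
   (cumulative/dynamic) survival ROC at a fixed horizon, constrained so
   that both groups keep ≥ 20 % of the cohort; cutoff ties go to the value
   nearest the marker median.  The high/low indicator must then clear
   AUC > 0.5 and two-sided p < 0.05 in both a univariate and a
   covariate-adjusted Cox model — in every cohort, with a consistent
   direction — and replicate against the second endpoint where one exists.
2. **Coefficient pooling.**  Per-cohort univariate log-hazard coefficients
   β are pooled by inverse-variance fixed effects, switching to
   DerSimonian–Laird random effects when Cochran's Q (p < 0.05) or
   Higgins' I² (> 50 %) indicates heterogeneity.
3. **Score search.**  Every non-empty combination of the surviving genes
   defines a candidate score  `S = Σ_g β_g · x_g`  (x z-scored per cohort).
   A candidate passes only if, in every cohort, its dichotomized form
   achieves univariate HR > 2 (p < 0.05), multivariate HR > 1.5
   (p < 0.05), AUC > 0.5, sensitivity > 0.5 and specificity > 0.5.  Among
   passers, the score with the fewest genes wins (ties: largest minimum
   univariate HR, then lexicographic).
4. **Application.**  The chosen score is divided by the per-cohort median
   and binned into low (< 0.9) / intermediate (0.9–1.1) / high (≥ 1.1)
   categories, integrated with AJCC TNM stage into combined risk groups,
   benchmarked against arbitrary published gene-weight signatures via a
   tertile-3-vs-1 Cox harness, and correlated with cell-line drug IC50
   panels (Spearman |ρ| > 0.25, p < 0.05).

A synthetic multi-cohort generator with planted prognostic genes, Weibull
proportional-hazards event times, independent censoring and between-cohort
effect heterogeneity gives every stage a ground-truth recovery test.

## Worked example

```python
from prognoscore import (
    PlantedGene, SimulationConfig, simulate_multicohort,
    ScreenCriteria, ScoreThresholds, screen_all, pool_all, search_scores,
)

planted = tuple(PlantedGene(f"PG{i}", beta=0.7) for i in range(7))
cfg = SimulationConfig(cohort_sizes=(345, 297, 433, 260, 320),
                       n_genes=200, planted_genes=planted, seed=1)
cohorts, truth = simulate_multicohort(cfg)

criteria = ScreenCriteria()                      # horizon 36 mo, 20% rule
records, genes = screen_all(cohorts, criteria)
print(genes)
# ['PG0', 'PG1', 'PG2', 'PG3', 'PG4', 'PG5', 'PG6']

pooled = pool_all(records)
weights = {g: p.beta_pooled for g, p in pooled.items()}
evals, winner = search_scores(cohorts, weights, ScoreThresholds(), criteria)
print(sum(e.passes for e in evals), winner.genes)
# 102 ('PG1', 'PG6')
```

The screen recovers exactly the seven planted genes out of 200; 102 of the
127 candidate combinations clear all thresholds in all five cohorts, and
the parsimony rule settles on the smallest passing subset (here two genes
— at a planted effect of 0.7 log-hazard per SD, even gene pairs separate
survival decisively; see `docs/methods.md` on what this implies).  In the
largest cohort the winning score splits median OS 14.1 vs 83.9 months
(high vs low group).

The same stages are available from the shell:

```bash
prognoscore simulate --config sim.yaml --out run/
prognoscore screen   --config run.yaml --out run/
prognoscore pool     --config run.yaml --out run/
prognoscore search   --config run.yaml --out run/
prognoscore apply    --config run.yaml --out run/ --score run/winner.json
prognoscore compare  --config run.yaml --out run/ --registry signatures.tsv
```

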