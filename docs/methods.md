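# Methods

## Survival model and estimators

**Kaplan–Meier, log-rank, Cox.**  Survival curves are product-limit
estimates (lifelines); group comparisons use the Mantel–Haenszel log-rank
test with chi-square reference on (groups − 1) degrees of freedom.  Cox
proportional-hazards models are fit by partial-likelihood maximization
with Efron tie handling (lifelines, Newton convergence tightened to 1e-9
so small flat-likelihood problems still reach the maximizer); Breslow ties
are available through `fit_cox(..., ties="breslow")` (statsmodels PHReg).
Categorical covariates are expanded against the first level in sorted
order; rows with missing values are dropped per model (complete case), so
univariate screening keeps the full cohort while multivariate adjustment
uses the samples with complete covariates.  Non-convergence and monotone
likelihood (|β| ≥ 20, complete separation) are flagged on the returned
fit, never silently reported as significant.

**Time-dependent ROC.**  The marker-vs-survival ROC at horizon t* uses the
cumulative/dynamic definition: cases are subjects with an event by t*,
controls are subjects event-free past t*.  Censoring before the horizon is
handled with the Kaplan–Meier estimator of Heagerty, Lumley and Pepe:
with F the empirical marker CDF and S subgroup KM survival at t*,

    sens(c) = (1 − F(c)) · (1 − S(t* | X > c)) / (1 − S(t*))
    spec(c) = F(c) · S(t* | X ≤ c) / S(t*)

evaluated at every midpoint between consecutive distinct marker values
(the high group is X > c, so results are invariant to within-group
jitter).  The raw subgroup-KM curve can be locally non-monotone under
heavy censoring; the curve is repaired by a cumulative-maximum (isotonic)
pass along the traversal and flagged when repair occurred.  AUC is the
trapezoidal area anchored at (0,0) and (1,1).  The subgroup KM values for
all cutoffs are computed simultaneously from a 2-D histogram over (event
time, marker rank) with cumulative sums, so a full per-gene ROC costs
O(events × distinct values) vectorized work — this is what keeps
2,000-gene screens cheap.  Smoothed (nearest-neighbour) variants are not
implemented; the raw KM estimator with isotonic repair is the default and
only estimator.

**Constrained optimal cutoff.**  Among candidate cutoffs whose low and
high groups both retain at least ⌈f·n⌉ samples (f = 0.20 by default), the
cutoff maximizing Youden's J = sens + spec − 1 is chosen.  Cutoffs tied
within 1e-9 of the maximum J resolve to the one nearest the marker median;
an exact distance tie takes the smaller value (logged).  Infeasibility
(no cutoff satisfies the group-size constraint) is an error, surfaced as
"not evaluable" at the screening level.

## Gene screen

Each gene is dichotomized per cohort at its own constrained cutoff at one
fixed horizon per run (default 36 months; the analyses all use a single
horizon, configurable in `ScreenCriteria`).  A gene passes overall
survival only if AUC > 0.5 and both Cox p-values < 0.05 hold in **every**
cohort with the same direction (adverse-high vs favorable-high) —
direction consistency is required so that pooled coefficients do not mix
opposite effects.  Genes passing OS are re-tested against the second
endpoint (DFS/RFS) in the cohorts that carry one, with the cutoff
re-optimized per endpoint (configurable in principle; re-optimization is
the implemented default since a cutoff tuned on OS has no claim to
optimality for relapse).  No per-gene multiple-testing correction is
applied: replication of raw p < 0.05 across five independent cohorts
(twice, with AUC and direction constraints) is the error control.  The
all-null suite quantifies what that buys: in 2,000 null genes across five
cohorts, zero reach the final pass.

Covariates with a per-cohort missing rate above 50 % are excluded from
that cohort's multivariate model (logged).  Evaluation is lazy by default:
cohorts are processed in order and a gene is abandoned at its first
failure, with multivariate fits run only after AUC and univariate checks
pass.  Verdicts are identical to exhaustive evaluation (the pass rule is
an AND over cohorts); evidence tables carry NaN for skipped statistics,
and `lazy=False` forces complete evidence.

## Coefficient pooling

Per-gene, per-cohort **univariate** dichotomized-group β's are pooled on
the log-hazard scale.  The univariate choice keeps the score computable
from expression alone (no clinical covariates at application time); the
multivariate coefficients remain in the evidence table.  Heterogeneity:
Q = Σ wᵢ(βᵢ − β_fixed)², wᵢ = 1/seᵢ², I² = max(0, (Q − df)/Q)·100.  With
Q-test p ≥ 0.05 and I² ≤ 50 % (both configurable) the fixed-effects
inverse-variance mean is used; otherwise DerSimonian–Laird random effects
with τ² = max(0, (Q − df)/(Σw − Σw²/Σw)) and weights 1/(se² + τ²).
No Hartung–Knapp adjustment or REML τ².  The implementation is verified
against hand arithmetic and against frozen values from R metafor 4.8-0.

## Score construction and selection

A candidate score is Σ_g β_pooled,g · x_g with x the per-cohort z-scored
expression (mean 0, SD 1 per gene within cohort).  Z-scoring is the
default because the pooled weights derive from dichotomized fits and raw
scales are incomparable across RNA-seq and microarray platforms; raw and
log2 scales are selectable per `ScoreDefinition`.  All 2^k − 1 non-empty
subsets of the k screened genes are enumerated (deterministic order: size,
then lexicographic; hard cap k ≤ 20) over memoized scaled matrices.  Each
candidate is dichotomized at its own constrained optimal cutoff per cohort
and must clear, in every cohort: univariate HR > 2 (p < 0.05),
multivariate HR > 1.5 (p < 0.05), AUC > 0.5, sensitivity > 0.5,
specificity > 0.5 — sensitivity and specificity read at the chosen cutoff.
Among passers the fewest-gene score wins; ties break by the largest
minimum univariate HR across cohorts, then by lexicographic gene list
(all ties logged).  An empty passing set is an explicit result with its
own exit code, not an error.

A consequence worth stating plainly: parsimony-first selection returns the
*smallest* subset that clears the absolute thresholds.  When planted
per-gene effects are strong (≥ 0.7 log-hazard per SD), pairs of true genes
already clear HR > 2 in every cohort, so the winner is typically 2 genes
even though the screen recovers all planted genes perfectly — the
recovery suite asserts full screen-level recovery and threshold compliance
of the winner, and the winner-vs-planted Jaccard check documents this
regime.  Signature-sized winners arise when per-gene effects are weak
enough that only larger combinations pass, which is the regime real
cohorts occupy.

## Score application

Normalization divides raw scores by the cohort's own median (validation
cohorts use their own median too, by default), so the normalized median is
exactly 1; categories use half-open intervals low < 0.9 ≤ intermediate
< 1.1 ≤ high.  A zero median is an error instructing a shift/scale
configuration rather than silent renormalization.  Stage integration
applies a total (stage × category) → risk-group map; the shipped default
(early stages favorable unless score-high; IIIA intermediate unless high;
IIIB adverse; IV adverse, very-adverse when high) is a declared
configuration, and `integrate_tnm` emits per-group KM medians plus
pairwise log-rank p-values so any candidate map can be audited.  External
signatures are benchmarked by weighted-sum score → tertile split (type-7
quantiles, ties to the lower tertile) → univariate Cox of tertile 3 vs 1,
robust iff HR > 1 with p < 0.05 in every evaluable cohort; cohorts
covering < 60 % of a signature's genes are marked not evaluable rather
than zero-filled, since zero-filling silently shifts tertile boundaries.
Drug sensitivity uses pairwise-complete Spearman correlation per drug with
the |ρ| > 0.25 and p < 0.05 conjunction.

## Synthetic data generator

The generator emulates a five-cohort gastric-cancer discovery setting:
cohort sizes 345/297/433/93/192; gene expression standard normal, null
genes in equicorrelated blocks (ρ = 0.2, block size 10) to mimic
co-expression, planted genes independent; event times Weibull
proportional-hazards (shape 1.2 so hazards are non-constant and KM curves
visibly bend; cohort-specific scales 60–90 months so median OS differs by
cohort); linear predictor = Σ β_c,g·x_g + 0.3·(age−62)/10 + 0.1·male +
stage effects (0/0.3/0.7/1.2 for I–IV); per-cohort realized β_c,g =
β_true,g + N(0, τ), τ = 0.1 by default.  Censoring is an independent
uniform draw on (0, 120 months) plus a 120-month administrative cap,
yielding roughly 40–60 % censoring so that 36-month AUC is estimable —
the censoring fraction is a generator choice, not an empirical claim.
The second endpoint (DFS in cohorts 1–2, RFS in cohort 4) is an
accelerated copy of the latent event process (factor 0.8) coupled to OS
through a Gaussian copula (correlation 0.8); the OS↔DFS dependence in
real cohorts is unknown, so this is an explicit free parameter.  Covariate
availability differs by cohort (stage missing in two cohorts) to exercise
per-cohort multivariate model construction.

What the generator does **not** model: platform-specific noise, probe
saturation, batch effects, missing expression values, informative
censoring, or non-proportional hazards.  Passing recovery tests therefore
demonstrates correctness of the estimators and the pipeline logic under
the model's own assumptions, not robustness to real-data violations of
them.

The cell-line companion generates standard-normal expression for ≥ 8
lines, a signature score, and log-normal IC50 values whose rank
correlation with the score is planted per drug through a Gaussian copula
(|ρ| = 1 is generated noise-free, so Spearman recovers ±1 exactly).

## Numerical and design notes

- All p-values are two-sided; significance level 0.05 throughout.
- ROC candidate cutoffs are midpoints of consecutive distinct marker
  values; constant markers are an error ("uninformative marker").
- Youden ties use tolerance 1e-9; table serialization uses 10 significant
  digits (write→read round-trips to that precision).
- Problem sizes in the test suite (cohorts of 93–433 samples, 200–2,000
  genes, 100–1,000 replicate loops) are chosen so the full suite completes
  in a few minutes on one core while keeping every statistical assertion
  comfortably powered.
- Times are months internally; day-scaled inputs are converted at load
  (÷ 30.44, logged).

## Known limitations

- No time-varying covariates, frailty terms, interval censoring, or
  competing risks.
- The ROC estimator is the raw KM cumulative/dynamic form; incident/
  dynamic and IPCW variants are out of scope.
- Multi-probe microarray collapsing is assumed done upstream; inputs are
  gene-level.
- Lazy screening means evidence tables for non-passing genes are partial
  by default (rerun with `lazy=False` for exhaustive evidence).
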