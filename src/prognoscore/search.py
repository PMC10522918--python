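"""Stage 3: exhaustive enumeration and selection of weighted-sum scores.

Every non-empty subset of the prognostic genes defines a candidate score

    score_s = sum_g  beta_pooled_g * x_{g,s}

where x is the per-cohort z-scored expression (configurable to raw or
log2).  Each candidate is dichotomized at its own constrained optimal
cutoff in each cohort and must clear, in EVERY cohort: univariate HR and
p-value, multivariate HR and p-value, AUC, sensitivity and specificity
thresholds.  Among passing scores the most parsimonious (fewest genes)
wins; ties go to the largest minimum univariate HR across cohorts, then to
the lexicographically smallest gene list.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import CohortDataset, ScoreThresholds, ScreenCriteria
from .screen import _multivariate_covariates
from .survival import EstimationError, fit_cox, optimal_cutoff

logger = logging.getLogger("prognoscore")

__all__ = [
    "ScoreDefinition",
    "CohortScoreMetrics",
    "ScoreEvaluation",
    "enumerate_combinations",
    "compute_score",
    "evaluate_score",
    "select_scores",
    "pick_parsimonious",
    "search_scores",
]

MAX_GENES = 20  # 2^20 - 1 combinations; hard cap against runaway enumeration


@dataclass(frozen=True)
class ScoreDefinition:
    """A weighted-sum gene signature."""

    score_id: str
    genes: tuple[str, ...]
    weights: tuple[float, ...]
    expression_scale: str = "zscore"  # zscore | raw | log2

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.weights) or len(self.genes) == 0:
            raise ValueError("genes and weights must be non-empty and aligned")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in score definition")

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass
class CohortScoreMetrics:
    cohort_id: str
    cutoff: float = math.nan
    auc: float = math.nan
    sensitivity: float = math.nan
    specificity: float = math.nan
    uni_hr: float = math.nan
    uni_p: float = math.nan
    multi_hr: float = math.nan
    multi_p: float = math.nan
    evaluable: bool = True
    reason: str | None = None


@dataclass
class ScoreEvaluation:
    score_id: str
    n_genes: int
    per_cohort: dict[str, CohortScoreMetrics] = field(default_factory=dict)
    passes: bool = False

    @property
    def min_uni_hr(self) -> float:
        vals = [m.uni_hr for m in self.per_cohort.values() if np.isfinite(m.uni_hr)]
        return min(vals) if vals else math.nan


def enumerate_combinations(
    genes: list[str],
    weights: dict[str, float],
    expression_scale: str = "zscore",
    max_genes: int = MAX_GENES,
) -> list[ScoreDefinition]:
    """All non-empty gene subsets, ordered by size then lexicographically."""
    if not 1 <= len(genes) <= max_genes:
        raise ValueError(
            f"{len(genes)} genes would enumerate 2^{len(genes)}-1 combinations; "
            f"cap is {max_genes} (pass max_genes to override)"
        )
    ordered = sorted(genes)
    defs = []
    for size in range(1, len(ordered) + 1):
        for combo in itertools.combinations(ordered, size):
            defs.append(
                ScoreDefinition(
                    score_id="+".join(combo),
                    genes=combo,
                    weights=tuple(weights[g] for g in combo),
                    expression_scale=expression_scale,
                )
            )
    return defs


def _scale_expression(expr: pd.DataFrame, scale: str) -> pd.DataFrame:
    if scale == "raw":
        return expr
    if scale == "log2":
        return np.log2(expr + 1.0)
    if scale == "zscore":
        mu = expr.mean(axis=1)
        sd = expr.std(axis=1, ddof=1)
        return expr.sub(mu, axis=0).div(sd, axis=0)
    raise ValueError(f"unknown expression scale {scale!r}")


def compute_score(
    expression: pd.DataFrame, definition: ScoreDefinition
) -> pd.Series:
    """Per-sample weighted-sum score on one cohort's expression matrix."""
    missing = [g for g in definition.genes if g not in expression.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing}")
    sub = _scale_expression(expression.loc[list(definition.genes)],
                            definition.expression_scale)
    w = np.asarray(definition.weights, dtype=float)
    return pd.Series(w @ sub.to_numpy(), index=expression.columns,
                     name=definition.score_id)


def evaluate_score(
    definition: ScoreDefinition,
    cohorts: list[CohortDataset],
    thresholds: ScoreThresholds,
    criteria: ScreenCriteria,
    lazy: bool = True,
    _scaled: dict[str, pd.DataFrame] | None = None,
) -> ScoreEvaluation:
    """Evaluate one candidate score against the pass thresholds.

    ``_scaled`` optionally carries memoized scaled expression matrices
    (cohort_id -> genes x samples) to avoid re-scaling per candidate.
    """
    ev = ScoreEvaluation(score_id=definition.score_id, n_genes=definition.n_genes)
    all_ok = True
    for cohort in cohorts:
        m = CohortScoreMetrics(cohort_id=cohort.cohort_id)
        ev.per_cohort[cohort.cohort_id] = m
        if _scaled is not None:
            sub = _scaled[cohort.cohort_id].loc[list(definition.genes)]
            score = pd.Series(
                np.asarray(definition.weights) @ sub.to_numpy(),
                index=cohort.samples,
            )
        else:
            score = compute_score(cohort.expression, definition)
        time, event = cohort.endpoint("os")
        try:
            choice = optimal_cutoff(
                score.to_numpy(), time.to_numpy(), event.to_numpy(),
                criteria.horizon_months, criteria.min_group_frac,
            )
        except EstimationError as exc:
            m.evaluable = False
            m.reason = str(exc)
            all_ok = False
            if lazy:
                break
            continue
        m.cutoff = choice.cutoff
        m.auc = choice.roc.auc
        m.sensitivity = choice.sensitivity
        m.specificity = choice.specificity
        cheap_ok = (
            m.auc > thresholds.auc_min
            and m.sensitivity > thresholds.sens_min
            and m.specificity > thresholds.spec_min
        )
        if not cheap_ok:
            all_ok = False
            if lazy:
                break

        high = (score > choice.cutoff).astype(float)
        high.name = "score_high"
        try:
            uni = fit_cox(high.to_frame(), time, event)
            c = uni.coef("score_high")
            m.uni_hr, m.uni_p = c["hr"], c["p"]
        except EstimationError as exc:
            m.evaluable = False
            m.reason = str(exc)
            all_ok = False
            if lazy:
                break
            continue
        if not (m.uni_hr > thresholds.uni_hr_min and m.uni_p < thresholds.alpha):
            all_ok = False
            if lazy:
                break

        design = pd.concat([high.to_frame(), _multivariate_covariates(cohort)],
                           axis=1)
        try:
            multi = fit_cox(design, time, event)
            c = multi.coef("score_high")
            m.multi_hr, m.multi_p = c["hr"], c["p"]
        except EstimationError as exc:
            m.evaluable = False
            m.reason = f"multivariate: {exc}"
            all_ok = False
            if lazy:
                break
            continue
        if not (m.multi_hr > thresholds.multi_hr_min
                and m.multi_p < thresholds.alpha):
            all_ok = False
            if lazy:
                break
    ev.passes = all_ok and len(ev.per_cohort) == len(cohorts) and all(
        met.evaluable for met in ev.per_cohort.values()
    )
    return ev


def select_scores(evaluations: list[ScoreEvaluation]) -> list[ScoreEvaluation]:
    """All evaluations that cleared every threshold in every cohort."""
    return [e for e in evaluations if e.passes]


def pick_parsimonious(
    passing: list[ScoreEvaluation],
    definitions: dict[str, ScoreDefinition],
) -> ScoreDefinition | None:
    """Fewest genes; ties by largest min univariate HR, then gene list.

    Returns ``None`` when no score passed (an explicit result, not an
    error).
    """
    if not passing:
        logger.warning("no score passed the selection thresholds")
        return None

    def key(ev: ScoreEvaluation):
        return (ev.n_genes, -ev.min_uni_hr, definitions[ev.score_id].genes)

    ranked = sorted(passing, key=key)
    if len(ranked) > 1 and key(ranked[0])[:2] == key(ranked[1])[:2]:
        logger.info("parsimony tie between %s and %s broken lexicographically",
                    ranked[0].score_id, ranked[1].score_id)
    return definitions[ranked[0].score_id]


def search_scores(
    cohorts: list[CohortDataset],
    pooled_weights: dict[str, float],
    thresholds: ScoreThresholds,
    criteria: ScreenCriteria,
    expression_scale: str = "zscore",
    max_genes: int = MAX_GENES,
    lazy: bool = True,
) -> tuple[list[ScoreEvaluation], ScoreDefinition | None]:
    """Enumerate, evaluate and select; returns all evaluations + winner."""
    genes = sorted(pooled_weights)
    defs = enumerate_combinations(genes, pooled_weights, expression_scale,
                                  max_genes)
    logger.info("evaluating %d score combinations over %d genes",
                len(defs), len(genes))
    scaled = {
        c.cohort_id: _scale_expression(c.expression.loc[genes], expression_scale)
        for c in cohorts
    }
    evaluations = [
        evaluate_score(d, cohorts, thresholds, criteria, lazy=lazy, _scaled=scaled)
        for d in defs
    ]
    by_id = {d.score_id: d for d in defs}
    winner = pick_parsimonious(select_scores(evaluations), by_id)
    return evaluations, winner


def evaluations_to_frame(evaluations: list[ScoreEvaluation]) -> pd.DataFrame:
    rows = []
    for ev in evaluations:
        for cid, m in ev.per_cohort.items():
            rows.append({
                "score_id": ev.score_id, "n_genes": ev.n_genes, "cohort": cid,
                "cutoff": m.cutoff, "auc": m.auc,
                "sensitivity": m.sensitivity, "specificity": m.specificity,
                "uni_hr": m.uni_hr, "uni_p": m.uni_p,
                "multi_hr": m.multi_hr, "multi_p": m.multi_p,
                "passes": ev.passes,
            })
    return pd.DataFrame(rows)
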