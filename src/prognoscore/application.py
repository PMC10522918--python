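"""Stage 4: applying a chosen score.

Covers median normalization with low/intermediate/high categories,
integration with AJCC TNM staging into combined risk groups, a tertile
benchmark harness for arbitrary published gene-weight signatures, and the
Spearman score-vs-IC50 drug-sensitivity rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CohortDataset, ScreenCriteria
from .search import ScoreDefinition, compute_score
from .survival import EstimationError, fit_cox, km_estimate, logrank_test

logger = logging.getLogger("prognoscore")

__all__ = [
    "normalize_and_categorize",
    "RiskGroupMap",
    "default_risk_map",
    "integrate_tnm",
    "ExternalSignature",
    "evaluate_external_signature",
    "drug_correlation",
]

CATEGORIES = ("low", "intermediate", "high")
RISK_GROUPS = ("favorable", "intermediate", "adverse", "very-adverse")


# ======================================================================
# Normalization and categorization
# ======================================================================
def normalize_and_categorize(
    scores: pd.Series,
    cutoffs: tuple[float, float] = (0.9, 1.1),
) -> pd.DataFrame:
    """Divide raw scores by the cohort median and bin into categories.

    Categories use half-open intervals: low iff normalized < ``cutoffs[0]``,
    intermediate iff ``cutoffs[0] <= normalized < cutoffs[1]``, high iff
    normalized >= ``cutoffs[1]``.
    """
    if scores.empty:
        raise EstimationError("no scores to normalize")
    low_below, high_at = cutoffs
    med = float(scores.median())
    if med == 0:
        raise EstimationError(
            "cohort score median is 0; normalization by the median is "
            "undefined — configure a shift/scale of the raw score first"
        )
    normalized = scores / med
    category = pd.Series(
        np.select(
            [normalized < low_below, normalized < high_at],
            ["low", "intermediate"],
            default="high",
        ),
        index=scores.index,
    )
    return pd.DataFrame(
        {"raw": scores, "normalized": normalized, "category": category}
    )


# ======================================================================
# TNM integration
# ======================================================================
@dataclass
class RiskGroupMap:
    """Total mapping (AJCC stage label, score category) -> risk group."""

    mapping: dict[tuple[str, str], str]

    def group_for(self, stage: str, category: str) -> str:
        key = (stage, category)
        if key not in self.mapping:
            raise KeyError(f"unmapped stage/category combination: {key}")
        return self.mapping[key]

    def validate_total(self, stages) -> None:
        missing = sorted(
            {(s, c) for s in set(stages) for c in CATEGORIES}
            - set(self.mapping)
        )
        if missing:
            raise EstimationError(f"risk map missing cells: {missing}")


def default_risk_map(stages=("I", "II", "IIIA", "IIIB", "IV")) -> RiskGroupMap:
    """A declared default interpretation of stage x category integration.

    Early stages are favorable unless the score is high; IIIA is
    intermediate unless high (then adverse); IIIB is adverse; IV is adverse
    unless high (then very-adverse).  This is configuration, not a claim of
    a unique clinically correct assignment; audit it with the per-group
    KM/log-rank summary that :func:`integrate_tnm` emits.
    """
    mapping = {}
    for s in stages:
        for c in CATEGORIES:
            if s in ("I", "II"):
                grp = "intermediate" if c == "high" else "favorable"
            elif s == "IIIA":
                grp = "adverse" if c == "high" else "intermediate"
            elif s == "IIIB":
                grp = "adverse"
            else:  # IV and beyond
                grp = "very-adverse" if c == "high" else "adverse"
            mapping[(s, c)] = grp
    return RiskGroupMap(mapping)


def integrate_tnm(
    stages: pd.Series,
    categories: pd.Series,
    risk_map: RiskGroupMap,
    time: pd.Series,
    event: pd.Series,
) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame]:
    """Combine staging with score categories into risk groups.

    Returns ``(groups, km_summary, pairwise_logrank)`` where ``km_summary``
    has one row per group (n, events, KM median survival) and
    ``pairwise_logrank`` the log-rank p for every group pair, so any
    candidate map can be audited against the data.
    """
    risk_map.validate_total(stages.dropna().unique())
    groups = pd.Series(
        [risk_map.group_for(s, c) for s, c in zip(stages, categories)],
        index=stages.index,
        name="risk_group",
    )

    rows = []
    for g in pd.unique(groups):
        mask = (groups == g).to_numpy()
        km = km_estimate(time[mask], event[mask])
        rows.append({
            "group": g, "n": int(mask.sum()), "events": int(event[mask].sum()),
            "median_os": km.median if km.median_reached else math.inf,
        })
    km_summary = pd.DataFrame(rows)

    pairs = []
    labels = list(pd.unique(groups))
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            mask = groups.isin([a, b]).to_numpy()
            try:
                chi2, _, p = logrank_test(
                    groups[mask], time[mask], event[mask]
                )
            except EstimationError:
                chi2, p = math.nan, math.nan
            pairs.append({"group_a": a, "group_b": b, "chi2": chi2, "p": p})
    return groups, km_summary, pd.DataFrame(pairs)


# ======================================================================
# External signature benchmark (tertile harness)
# ======================================================================
@dataclass
class ExternalSignature:
    """A published gene-weight signature to benchmark."""

    signature_id: str
    genes: tuple[str, ...]
    weights: tuple[float, ...]
    publication: str = ""

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in signature")
        if len(self.genes) != len(self.weights):
            raise ValueError("genes and weights misaligned")
        if not np.isfinite(self.weights).all():
            raise ValueError("non-finite weights")


@dataclass
class SignatureCohortResult:
    cohort_id: str
    coverage: float
    evaluable: bool
    hr: float = math.nan
    p: float = math.nan
    reason: str | None = None


def _tertile_labels(score: pd.Series) -> pd.Series:
    """Tertile assignment: type-7 quantile boundaries, ties to the lower
    tertile (label 1 = lowest scores, 3 = highest)."""
    q1, q2 = score.quantile([1 / 3, 2 / 3], interpolation="linear")
    labels = np.select([score <= q1, score <= q2], [1, 2], default=3)
    return pd.Series(labels, index=score.index)


def evaluate_external_signature(
    signature: ExternalSignature,
    cohorts: list[CohortDataset],
    alpha: float = 0.05,
    min_coverage: float = 0.6,
    expression_scale: str = "zscore",
) -> tuple[list[SignatureCohortResult], bool]:
    """Tertile-based benchmark of an arbitrary gene-weight signature.

    Per cohort: weighted-sum score on the signature genes present (cohorts
    covering fewer than ``min_coverage`` of the genes are marked
    not-evaluable), tertile split, univariate Cox of tertile 3 vs tertile 1
    (middle excluded).  The signature is robust iff HR > 1 with p < alpha
    in every evaluable cohort.
    """
    results = []
    for cohort in cohorts:
        present = [g for g in signature.genes if g in cohort.genes]
        coverage = len(present) / len(signature.genes) if signature.genes else 0.0
        res = SignatureCohortResult(cohort.cohort_id, coverage, True)
        results.append(res)
        if coverage < min_coverage:
            res.evaluable = False
            res.reason = f"only {coverage:.0%} of signature genes present"
            continue
        weights = tuple(
            w for g, w in zip(signature.genes, signature.weights) if g in present
        )
        definition = ScoreDefinition(
            score_id=signature.signature_id, genes=tuple(present),
            weights=weights, expression_scale=expression_scale,
        )
        score = compute_score(cohort.expression, definition)
        tert = _tertile_labels(score)
        mask = tert.isin([1, 3])
        time, event = cohort.endpoint("os")
        if event[mask].sum() < 2:
            res.evaluable = False
            res.reason = "<2 events in tertiles 1 and 3"
            continue
        ind = (tert[mask] == 3).astype(float)
        ind.name = "tertile3"
        try:
            fit = fit_cox(ind.to_frame(), time[mask], event[mask])
        except EstimationError as exc:
            res.evaluable = False
            res.reason = str(exc)
            continue
        c = fit.coef("tertile3")
        res.hr, res.p = c["hr"], c["p"]
    evaluable = [r for r in results if r.evaluable]
    robust = bool(evaluable) and all(r.hr > 1 and r.p < alpha for r in evaluable)
    return results, robust


# ======================================================================
# Drug-sensitivity correlation
# ======================================================================
def drug_correlation(
    scores: pd.Series,
    ic50: pd.DataFrame,
    rho_min: float = 0.25,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation of the score with each drug's IC50.

    A drug is a hit iff |rho| > ``rho_min`` and p < ``alpha``.  Lines
    missing IC50 for a drug are excluded pairwise; all-tied IC50 rows are
    skipped with a warning.
    """
    common = scores.index.intersection(ic50.columns)
    if len(common) < 8:
        raise EstimationError("need >= 8 cell lines with both score and IC50")
    rows = []
    for drug in ic50.index:
        vals = ic50.loc[drug, common]
        mask = vals.notna()
        if mask.sum() < 8:
            logger.warning("drug %s: <8 lines with IC50; skipped", drug)
            continue
        y = vals[mask].to_numpy(dtype=float)
        x = scores.loc[common][mask].to_numpy(dtype=float)
        if np.unique(y).size < 2:
            logger.warning("drug %s: all IC50 values tied; rho undefined", drug)
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append({
            "drug": drug, "rho": float(rho), "p": float(p),
            "n": int(mask.sum()),
            "hit": bool(abs(rho) > rho_min and p < alpha),
        })
    return pd.DataFrame(rows, columns=["drug", "rho", "p", "n", "hit"])
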