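"""Stage 1: per-gene prognostic screening across cohorts.

For each gene and cohort, expression is dichotomized at the constrained
Youden-optimal cutoff of the time-dependent ROC, then the high/low
indicator is tested with a univariate Cox model and a multivariate Cox
model adjusted for the cohort's available covariates.  A gene passes the
overall-survival screen only if, in EVERY cohort, the ROC AUC exceeds the
threshold and both Cox p-values fall below alpha, with a consistent effect
direction across cohorts.  Genes passing OS are then re-tested against the
second endpoint (DFS/RFS) in the cohorts that carry one; only genes passing
both filters enter the signature search.

No per-gene multiple-testing correction is applied: replication of raw
p < alpha across all independent cohorts is the error control, and the run
report records this choice.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import CohortDataset, ScreenCriteria
from .survival import EstimationError, build_design, fit_cox, optimal_cutoff

logger = logging.getLogger("prognoscore")

__all__ = ["CohortGeneEvidence", "GeneScreenRecord", "screen_gene", "screen_all",
           "cross_endpoint_filter", "records_to_frame"]

#: covariates missing in more than this fraction of a cohort are dropped
#: from that cohort's multivariate model
MAX_COVARIATE_MISSING = 0.5


@dataclass
class CohortGeneEvidence:
    """Evidence for one gene in one cohort at one endpoint."""

    cohort_id: str
    cutoff: float = math.nan
    auc: float = math.nan
    uni_beta: float = math.nan
    uni_se: float = math.nan
    uni_hr: float = math.nan
    uni_p: float = math.nan
    multi_beta: float = math.nan
    multi_se: float = math.nan
    multi_hr: float = math.nan
    multi_p: float = math.nan
    direction: str | None = None  # adverse-high | favorable-high
    evaluable: bool = True
    reason: str | None = None

    def passes(self, criteria: ScreenCriteria) -> bool:
        return (
            self.evaluable
            and self.auc > criteria.auc_min
            and self.uni_p < criteria.alpha
            and self.multi_p < criteria.alpha
        )


@dataclass
class GeneScreenRecord:
    """Per-gene verdict across all cohorts and endpoints."""

    gene: str
    os_evidence: dict[str, CohortGeneEvidence] = field(default_factory=dict)
    ep2_evidence: dict[str, CohortGeneEvidence] = field(default_factory=dict)
    direction: str | None = None
    os_pass: bool = False
    ep2_pass: bool | None = None  # None until the cross-endpoint filter ran
    evaluable: bool = True

    @property
    def final_pass(self) -> bool:
        return bool(self.os_pass and self.ep2_pass)


def _multivariate_covariates(cohort: CohortDataset) -> pd.DataFrame:
    """The cohort's adjustment covariates, dropping those mostly missing."""
    cols = []
    for name in cohort.available_covariates:
        col = cohort.covariates[name]
        if col.isna().mean() > MAX_COVARIATE_MISSING:
            logger.info(
                "cohort %s: covariate %s missing in >%d%% of samples; excluded",
                cohort.cohort_id, name, int(MAX_COVARIATE_MISSING * 100),
            )
            continue
        cols.append(name)
    return build_design(cohort.covariates[cols], cohort.covariate_kinds)


def evaluate_marker_in_cohort(
    cohort: CohortDataset,
    marker: pd.Series,
    criteria: ScreenCriteria,
    endpoint: str = "os",
    lazy: bool = True,
    label: str = "marker",
) -> CohortGeneEvidence:
    """Dichotomize a marker and run both Cox models in one cohort.

    With ``lazy=True`` the (expensive) multivariate fit is skipped as soon
    as a cheaper criterion already fails; the evidence record then carries
    NaN for the skipped statistics.
    """
    ev = CohortGeneEvidence(cohort_id=cohort.cohort_id)
    time, event = cohort.endpoint(endpoint)
    x = marker.loc[cohort.samples]
    try:
        choice = optimal_cutoff(
            x.to_numpy(), time.to_numpy(), event.to_numpy(),
            criteria.horizon_months, criteria.min_group_frac,
        )
    except EstimationError as exc:
        ev.evaluable = False
        ev.reason = str(exc)
        return ev
    ev.cutoff = choice.cutoff
    ev.auc = choice.roc.auc
    if lazy and ev.auc <= criteria.auc_min:
        return ev

    high = (x > choice.cutoff).astype(float)
    high.name = label
    try:
        uni = fit_cox(high.to_frame(), time, event)
    except EstimationError as exc:
        ev.evaluable = False
        ev.reason = str(exc)
        return ev
    c = uni.coef(label)
    ev.uni_beta, ev.uni_se, ev.uni_hr, ev.uni_p = (
        c["beta"], c["se"], c["hr"], c["p"]
    )
    ev.direction = "adverse-high" if ev.uni_hr > 1.0 else "favorable-high"
    if lazy and ev.uni_p >= criteria.alpha:
        return ev

    design = pd.concat([high.to_frame(), _multivariate_covariates(cohort)], axis=1)
    try:
        multi = fit_cox(design, time, event)
        c = multi.coef(label)
        ev.multi_beta, ev.multi_se, ev.multi_hr, ev.multi_p = (
            c["beta"], c["se"], c["hr"], c["p"]
        )
    except EstimationError as exc:
        ev.evaluable = False
        ev.reason = f"multivariate: {exc}"
    return ev


def screen_gene(
    cohorts: list[CohortDataset],
    gene: str,
    criteria: ScreenCriteria,
    lazy: bool = True,
) -> GeneScreenRecord:
    """Screen one gene against overall survival in every cohort.

    With ``lazy=True``, cohorts are evaluated in order and evaluation stops
    at the first cohort that fails (the verdict is already decided by the
    all-cohorts rule); pass with ``lazy=False`` to force full evidence.
    """
    rec = GeneScreenRecord(gene=gene)
    for cohort in cohorts:
        if gene not in cohort.genes:
            rec.evaluable = False
            rec.os_pass = False
            return rec
    for cohort in cohorts:
        ev = evaluate_marker_in_cohort(
            cohort, cohort.expression.loc[gene], criteria, "os", lazy, gene
        )
        rec.os_evidence[cohort.cohort_id] = ev
        if not ev.evaluable:
            rec.evaluable = False
            rec.os_pass = False
            if lazy:
                return rec
            continue
        cohort_ok = ev.passes(criteria)
        direction_ok = rec.direction is None or ev.direction == rec.direction
        if ev.direction is not None and rec.direction is None:
            rec.direction = ev.direction
        if not (cohort_ok and direction_ok):
            rec.os_pass = False
            if lazy:
                return rec
            rec.direction = rec.direction if direction_ok else "inconsistent"
    rec.os_pass = rec.evaluable and all(
        e.evaluable and e.passes(criteria) for e in rec.os_evidence.values()
    ) and len({e.direction for e in rec.os_evidence.values()}) == 1
    if not criteria.require_all_cohorts:
        # relaxed mode kept for exploration; default contract is all-cohorts
        rec.os_pass = rec.evaluable and any(
            e.evaluable and e.passes(criteria) for e in rec.os_evidence.values()
        )
    return rec


def cross_endpoint_filter(
    records: list[GeneScreenRecord],
    cohorts: list[CohortDataset],
    criteria: ScreenCriteria,
    lazy: bool = True,
    allow_skip: bool = True,
) -> list[str]:
    """Re-test OS-passing genes against the second endpoint (DFS/RFS).

    The cutoff is re-optimized per endpoint.  Returns the final gene list:
    genes with ``os_pass`` and a pass in every endpoint-carrying cohort.
    """
    ep2_cohorts = [c for c in cohorts if c.has_second_endpoint]
    if not ep2_cohorts:
        msg = "no cohort carries a second endpoint; cross-endpoint filter skipped"
        if not allow_skip:
            raise EstimationError(msg)
        logger.warning(msg.upper())
        for rec in records:
            if rec.os_pass:
                rec.ep2_pass = True
        return sorted(r.gene for r in records if r.final_pass)

    for rec in records:
        if not rec.os_pass:
            rec.ep2_pass = False
            continue
        ok = True
        for cohort in ep2_cohorts:
            ev = evaluate_marker_in_cohort(
                cohort, cohort.expression.loc[rec.gene], criteria, "ep2",
                lazy, rec.gene,
            )
            rec.ep2_evidence[cohort.cohort_id] = ev
            if not (ev.evaluable and ev.passes(criteria)
                    and ev.direction == rec.direction):
                ok = False
                if lazy:
                    break
        rec.ep2_pass = ok
    return sorted(r.gene for r in records if r.final_pass)


def screen_all(
    cohorts: list[CohortDataset],
    criteria: ScreenCriteria,
    lazy: bool = True,
    progress: bool = False,
) -> tuple[list[GeneScreenRecord], list[str]]:
    """Screen every gene common to all cohorts; run the cross-endpoint filter.

    Genes are processed in lexicographic order; returns the full evidence
    records and the final prognostic gene list.
    """
    common = cohorts[0].genes
    for cohort in cohorts[1:]:
        common = common.intersection(cohort.genes)
    genes = sorted(common)
    if not genes:
        raise EstimationError("no genes common to all cohorts")
    logger.info("screening %d genes across %d cohorts", len(genes), len(cohorts))

    records = []
    for i, gene in enumerate(genes):
        records.append(screen_gene(cohorts, gene, criteria, lazy=lazy))
        if progress and (i + 1) % 200 == 0:
            logger.info("  screened %d/%d genes", i + 1, len(genes))
    final = cross_endpoint_filter(records, cohorts, criteria, lazy=lazy)
    logger.info("%d genes pass OS in all cohorts; %d pass the final filter",
                sum(r.os_pass for r in records), len(final))
    return records, final


def records_to_frame(records: list[GeneScreenRecord]) -> pd.DataFrame:
    """Flatten screen records into a tidy evidence table (one row per
    gene x endpoint x cohort)."""
    rows = []
    for rec in records:
        for endpoint, evidence in (("OS", rec.os_evidence), ("EP2", rec.ep2_evidence)):
            for cid, ev in evidence.items():
                rows.append({
                    "gene": rec.gene, "endpoint": endpoint, "cohort": cid,
                    "cutoff": ev.cutoff, "auc": ev.auc,
                    "uni_beta": ev.uni_beta, "uni_se": ev.uni_se,
                    "uni_hr": ev.uni_hr, "uni_p": ev.uni_p,
                    "multi_beta": ev.multi_beta, "multi_se": ev.multi_se,
                    "multi_hr": ev.multi_hr, "multi_p": ev.multi_p,
                    "direction": ev.direction, "evaluable": ev.evaluable,
                    "os_pass": rec.os_pass, "ep2_pass": rec.ep2_pass,
                    "final_pass": rec.final_pass,
                })
    cols = ["gene", "endpoint", "cohort", "cutoff", "auc", "uni_beta", "uni_se",
            "uni_hr", "uni_p", "multi_beta", "multi_se", "multi_hr", "multi_p",
            "direction", "evaluable", "os_pass", "ep2_pass", "final_pass"]
    return pd.DataFrame(rows, columns=cols)
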