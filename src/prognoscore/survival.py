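"""Censoring-aware survival statistics.

The central primitive is the time-dependent (cumulative/dynamic) ROC curve
for a continuous marker under right censoring, estimated with the
Kaplan-Meier method of Heagerty, Lumley and Pepe: at a fixed horizon t*,
cases are subjects with an event by t*, controls are subjects event-free
past t*, and censoring before the horizon is handled by estimating the
case/control probabilities on either side of each candidate cutoff with
subgroup Kaplan-Meier curves.  On top of it sits the constrained optimal
cutoff: the Youden-maximizing cutoff among those keeping at least a
configurable fraction (default 20%) of the cohort in both the low and the
high group, with ties broken toward the marker median.

Kaplan-Meier estimation, the log-rank test and Cox proportional-hazards
fitting are delegated to lifelines; Mann-Whitney and Fisher tests to scipy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "KMEstimate",
    "TdRocResult",
    "CutoffChoice",
    "CoxFit",
    "km_estimate",
    "logrank_test",
    "td_roc",
    "optimal_cutoff",
    "select_cutoff_index",
    "fit_cox",
    "mann_whitney",
    "fisher_exact",
]

#: |beta| above which a Cox coefficient is treated as monotone-likelihood
#: (complete separation) territory and flagged.
_BETA_CAP = 20.0


class EstimationError(ValueError):
    """Raised when a statistic is not estimable from the given data."""


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise EstimationError(f"{name} is empty")
    return arr


# ======================================================================
# Kaplan-Meier
# ======================================================================
@dataclass
class KMEstimate:
    """Product-limit survival estimate.

    ``times``/``survival`` describe the right-continuous step function;
    ``survival[i]`` is S(t) for t in [times[i], times[i+1]).  S(0) = 1.
    ``median`` is the smallest t with S(t) <= 0.5, ``inf`` if never reached.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    median: float

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def median_reached(self) -> bool:
        return math.isfinite(self.median)


def km_estimate(time, event) -> KMEstimate:
    """Kaplan-Meier product-limit estimator of the survival function."""
    t = _as_1d(time, "time")
    e = _as_1d(event, "event")
    if (t < 0).any():
        raise EstimationError("negative survival times")
    if t.max() == 0 and e.sum() == 0:
        raise EstimationError("no risk time: all times zero and censored")

    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    table = kmf.event_table
    # keep event times only (where the curve can drop)
    surv = kmf.survival_function_["KM_estimate"]
    times = surv.index.to_numpy(dtype=float)
    s = surv.to_numpy(dtype=float)
    med = kmf.median_survival_time_
    return KMEstimate(
        times=times,
        survival=s,
        at_risk=table["at_risk"].to_numpy(dtype=float),
        events=table["observed"].to_numpy(dtype=float),
        median=float(med),
    )


def logrank_test(groups, time, event) -> tuple[float, int, float]:
    """Log-rank (Mantel-Haenszel) test across >= 2 groups.

    Returns ``(chi2, df, p)`` with df = (number of groups) - 1.
    """
    t = _as_1d(time, "time")
    e = _as_1d(event, "event")
    g = np.asarray(groups)
    labels = pd.unique(g)
    if len(labels) < 2:
        raise EstimationError("log-rank test requires >= 2 groups")
    if e.sum() == 0:
        raise EstimationError("log-rank test requires >= 1 event")
    res = multivariate_logrank_test(t, g, e)
    df = len(labels) - 1
    return float(res.test_statistic), df, float(res.p_value)


# ======================================================================
# Time-dependent ROC (cumulative/dynamic, Kaplan-Meier estimator)
# ======================================================================
@dataclass
class TdRocResult:
    """Survival ROC at a fixed horizon.

    ``points`` holds one row per candidate cutoff (ascending cutoff):
    columns ``cutoff``, ``sensitivity``, ``specificity`` (after monotonicity
    repair).  ``auc`` is the trapezoidal area under the curve traversed over
    all cutoffs, anchored at (0,0) and (1,1).  ``n_cases``/``n_controls``
    are KM-weighted effective counts n*(1-S(t*)) and n*S(t*).
    """

    horizon: float
    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_cases: float
    n_controls: float
    group_sizes_low: np.ndarray = field(repr=False, default=None)
    repaired: bool = False

    @property
    def points(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def _km_at_horizon_by_cutoff(time, event, rank, horizon, n_ranks):
    """Subgroup KM survival at the horizon for every cutoff, both sides.

    For each cutoff k (between marker rank k and k+1) computes the KM
    estimate at ``horizon`` within the low group (rank <= k) and the high
    group (rank > k), fully vectorized over cutoffs via 2-D dominance
    counts on (event time, marker rank).

    Returns ``(s_low, s_high, s_all)``; the first two of length
    ``n_ranks - 1``, ``s_all`` the overall KM survival at the horizon.
    """
    uniq_ev = np.unique(time[(event == 1) & (time <= horizon)])
    q = uniq_ev.size
    m = n_ranks
    if q == 0:
        return np.ones(m - 1), np.ones(m - 1), 1.0

    # time_bin[i] = number of unique event times <= time[i]
    time_bin = np.searchsorted(uniq_ev, time, side="right")
    # at risk at uniq_ev[j] <=> time >= uniq_ev[j] <=> time_bin >= j+1 or
    # time == uniq_ev[j]; since uniq_ev[j] <= time iff time_bin > j.
    # Build histogram over (time_bin, rank) then suffix-sum over time bins.
    H = np.zeros((q + 1, m))
    np.add.at(H, (time_bin, rank), 1.0)
    # at_risk_by_rank[j, r] = #{i: time_i >= uniq_ev[j], rank_i = r}
    # time_i >= uniq_ev[j] iff time_bin_i >= j (time_bin counts <=; if
    # time_i == uniq_ev[j], time_bin_i >= j+1 > j; if time_i <
    # uniq_ev[j], time_bin_i <= j-1 < j ... careful with equality)
    # time_bin_i = #{ev <= time_i}; time_i >= uniq_ev[j] (1-based j+1?):
    # For 0-based j: time_i >= uniq_ev[j]  <=>  time_bin_i >= j+1.
    suffix = np.flipud(np.cumsum(np.flipud(H), axis=0))  # suffix[j] = sum bins >= j
    at_risk = suffix[1:, :]  # shape (q, m): bins >= j+1

    # deaths at uniq_ev[j] by rank
    D = np.zeros((q, m))
    ev_mask = (event == 1) & (time <= horizon)
    ev_idx = np.searchsorted(uniq_ev, time[ev_mask])
    np.add.at(D, (ev_idx, rank[ev_mask]), 1.0)

    # cumulative over rank: low group = rank <= k
    n_low = np.cumsum(at_risk, axis=1)[:, :-1]  # (q, m-1)
    d_low = np.cumsum(D, axis=1)[:, :-1]
    n_tot = at_risk.sum(axis=1, keepdims=True)
    d_tot = D.sum(axis=1, keepdims=True)
    n_high = n_tot - n_low
    d_high = d_tot - d_low

    f_low = np.where(n_low > 0, 1.0 - d_low / np.where(n_low > 0, n_low, 1.0), 1.0)
    f_high = np.where(
        n_high > 0, 1.0 - d_high / np.where(n_high > 0, n_high, 1.0), 1.0
    )
    s_low = np.prod(f_low, axis=0)
    s_high = np.prod(f_high, axis=0)
    s_all = float(np.prod(1.0 - d_tot / n_tot))
    return s_low, s_high, s_all


def td_roc(marker, time, event, horizon: float) -> TdRocResult:
    """Time-dependent ROC at ``horizon`` (cumulative cases, dynamic controls).

    Candidate cutoffs are the midpoints between consecutive distinct marker
    values; the high group is ``marker > cutoff``.  Sensitivity and
    specificity at each cutoff are estimated via subgroup Kaplan-Meier
    survival at the horizon (Bayes decomposition), then repaired to a
    monotone ROC by cumulative maximum along the traversal when the raw
    KM-based curve is non-monotone.
    """
    x = _as_1d(marker, "marker")
    t = _as_1d(time, "time")
    e = _as_1d(event, "event")
    if horizon <= 0:
        raise EstimationError("horizon must be > 0")
    if not (x.size == t.size == e.size):
        raise EstimationError("marker/time/event length mismatch")

    distinct = np.unique(x)
    m = distinct.size
    if m < 2:
        raise EstimationError("uninformative marker: fewer than 2 distinct values")

    n = x.size
    rank = np.searchsorted(distinct, x)
    cutoffs = (distinct[:-1] + distinct[1:]) / 2.0

    s_low, s_high, s_all = _km_at_horizon_by_cutoff(t, e, rank, horizon, m)
    if s_all >= 1.0:
        raise EstimationError("no estimable cases at horizon (no events by horizon)")
    if s_all <= 0.0:
        raise EstimationError("no estimable controls at horizon")

    counts = np.bincount(rank, minlength=m).astype(float)
    n_low = np.cumsum(counts)[:-1]  # samples with marker <= cutoff k
    frac_low = n_low / n

    sens = (1.0 - frac_low) * (1.0 - s_high) / (1.0 - s_all)
    spec = frac_low * s_low / s_all
    sens = np.clip(sens, 0.0, 1.0)
    spec = np.clip(spec, 0.0, 1.0)

    # Monotonicity repair: traversing cutoffs from high to low, both TPR
    # and FPR must be non-decreasing.  The raw subgroup-KM curve can
    # violate this under heavy censoring; repair by cumulative maximum.
    tpr_desc = sens[::-1]
    fpr_desc = (1.0 - spec)[::-1]
    tpr_fix = np.maximum.accumulate(tpr_desc)
    fpr_fix = np.maximum.accumulate(fpr_desc)
    repaired = bool(
        np.any(tpr_fix != tpr_desc) or np.any(fpr_fix != fpr_desc)
    )
    sens = tpr_fix[::-1]
    spec = 1.0 - fpr_fix[::-1]

    fpr = np.concatenate(([0.0], fpr_fix, [1.0]))
    tpr = np.concatenate(([0.0], tpr_fix, [1.0]))
    auc = float(np.trapezoid(tpr, fpr))

    return TdRocResult(
        horizon=float(horizon),
        cutoffs=cutoffs,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        n_cases=float(n * (1.0 - s_all)),
        n_controls=float(n * s_all),
        group_sizes_low=n_low,
        repaired=repaired,
    )


# ======================================================================
# Constrained optimal cutoff
# ======================================================================
@dataclass
class CutoffChoice:
    """The chosen dichotomization cutoff and its diagnostics."""

    cutoff: float
    youden: float
    sensitivity: float
    specificity: float
    group_sizes: tuple[int, int]  # (n_low, n_high)
    satisfied_constraint: bool
    tie_broken: bool
    roc: TdRocResult = field(repr=False, default=None)


def select_cutoff_index(
    cutoffs: np.ndarray,
    youden: np.ndarray,
    feasible: np.ndarray,
    median: float,
    tol: float = 1e-9,
) -> tuple[int, bool]:
    """Pick the best feasible cutoff index under the tie rules.

    Maximizes Youden's J among feasible cutoffs; candidates within ``tol``
    of the maximum are resolved toward the cutoff closest to ``median``,
    and an exact distance tie takes the smaller cutoff value.  Returns
    ``(index, tie_broken)``.
    """
    j_feas = np.where(feasible, youden, -np.inf)
    j_max = j_feas.max()
    tied = np.flatnonzero(j_feas >= j_max - tol)
    dist = np.abs(cutoffs[tied] - median)
    order = np.lexsort((cutoffs[tied], dist))
    return int(tied[order[0]]), len(tied) > 1


def optimal_cutoff(
    marker,
    time,
    event,
    horizon: float,
    min_group_frac: float = 0.20,
    tol: float = 1e-9,
) -> CutoffChoice:
    """Youden-optimal cutoff subject to a minimum group-size constraint.

    Among candidate cutoffs whose low and high groups both keep at least
    ``ceil(min_group_frac * n)`` samples, returns the cutoff maximizing
    Youden's J = sensitivity + specificity - 1 at the horizon.  Cutoffs
    tied within ``tol`` are resolved toward the one closest to the marker
    median; an exact distance tie takes the smaller cutoff.
    """
    if not 0 < min_group_frac <= 0.5:
        raise EstimationError("min_group_frac must be in (0, 0.5]")
    roc = td_roc(marker, time, event, horizon)
    x = np.asarray(marker, dtype=float).ravel()
    n = x.size
    min_n = math.ceil(min_group_frac * n)

    n_low = roc.group_sizes_low
    n_high = n - n_low
    feasible = (n_low >= min_n) & (n_high >= min_n)
    if not feasible.any():
        raise EstimationError(
            "constraint infeasible: no cutoff leaves both groups with "
            f">= {min_n} samples"
        )

    j = roc.sensitivity + roc.specificity - 1.0
    med = float(np.median(x))
    best, tie_broken = select_cutoff_index(roc.cutoffs, j, feasible, med, tol)

    return CutoffChoice(
        cutoff=float(roc.cutoffs[best]),
        youden=float(j[best]),
        sensitivity=float(roc.sensitivity[best]),
        specificity=float(roc.specificity[best]),
        group_sizes=(int(n_low[best]), int(n_high[best])),
        satisfied_constraint=True,
        tie_broken=tie_broken,
        roc=roc,
    )


# ======================================================================
# Cox proportional hazards
# ======================================================================
@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model.

    ``beta``/``se``/``hr``/``p`` are indexed by coefficient name;
    categorical covariates are expanded against a reference level.
    """

    beta: pd.Series
    se: pd.Series
    hr: pd.Series
    ci95: pd.DataFrame  # columns: lower, upper (HR scale)
    p: pd.Series
    n_used: int
    n_events: int
    converged: bool
    flags: list[str] = field(default_factory=list)

    def coef(self, name: str | None = None) -> dict:
        """Summary for one coefficient (the first, by default)."""
        name = self.beta.index[0] if name is None else name
        return {
            "beta": float(self.beta[name]),
            "se": float(self.se[name]),
            "hr": float(self.hr[name]),
            "p": float(self.p[name]),
        }


def build_design(
    covariates: pd.DataFrame, kinds: dict[str, str]
) -> pd.DataFrame:
    """Expand categorical covariates against a reference level.

    The reference is the first level in sorted order.  Continuous
    covariates pass through unchanged.  Rows with missing values are NOT
    dropped here (complete-case filtering happens at fit time).
    """
    cols = []
    for name in covariates.columns:
        kind = kinds.get(name, "continuous")
        col = covariates[name]
        if kind == "continuous":
            cols.append(col.astype(float))
        else:
            levels = sorted(col.dropna().unique(), key=str)
            for lev in levels[1:]:
                dummy = (col == lev).astype(float)
                dummy[col.isna()] = np.nan
                dummy.name = f"{name}[{lev}]"
                cols.append(dummy)
    return pd.concat(cols, axis=1) if cols else pd.DataFrame(index=covariates.index)


def fit_cox(
    design: pd.DataFrame,
    time,
    event,
    ties: str = "efron",
) -> CoxFit:
    """Fit a Cox model by partial-likelihood maximization.

    ``design`` must already be numeric (use :func:`build_design` to expand
    categorical covariates).  Rows with any missing value are dropped
    (complete-case).  Efron tie handling by default; ``ties="breslow"``
    uses the Breslow approximation.  Non-convergence and monotone
    likelihood (|beta| >= 20) are flagged, never silently reported.
    """
    if design.shape[1] == 0:
        raise EstimationError("empty design matrix")
    df = design.astype(float).copy()
    df["_t"] = np.asarray(time, dtype=float)
    df["_e"] = np.asarray(event, dtype=float)
    df = df.dropna()
    n_used = len(df)
    n_events = int(df["_e"].sum())
    if n_events < 1:
        raise EstimationError("Cox fit requires at least one event")

    const = [c for c in design.columns if df[c].nunique() <= 1]
    if const:
        raise EstimationError(f"constant column(s) in design: {const}")

    flags: list[str] = []
    if n_events < 10 * design.shape[1]:
        flags.append("few_events_per_coefficient")

    converged = True
    if ties == "efron":
        cph = CoxPHFitter()
        fit_options = {"precision": 1e-9}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="_t", event_col="_e",
                        fit_options=fit_options)
        except ConvergenceError:
            converged = False
            cph = CoxPHFitter(penalizer=1e-6)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="_t", event_col="_e",
                        fit_options=fit_options)
            flags.append("non_convergence_ridge_fallback")
        beta = cph.params_.copy()
        se = cph.standard_errors_.copy()
    elif ties == "breslow":
        import statsmodels.api as sm

        mod = sm.PHReg(
            df["_t"].to_numpy(),
            df[list(design.columns)].to_numpy(),
            status=df["_e"].to_numpy(),
            ties="breslow",
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = mod.fit()
        beta = pd.Series(res.params, index=list(design.columns))
        se = pd.Series(res.bse, index=list(design.columns))
    else:
        raise ValueError(f"unknown tie method {ties!r}")

    if (beta.abs() >= _BETA_CAP).any():
        beta = beta.clip(-_BETA_CAP, _BETA_CAP)
        flags.append("monotone_likelihood_suspected")
        converged = False

    z = beta / se
    p = pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=beta.index)
    hr = np.exp(beta)
    ci = pd.DataFrame(
        {
            "lower": np.exp(beta - 1.959963984540054 * se),
            "upper": np.exp(beta + 1.959963984540054 * se),
        },
        index=beta.index,
    )
    return CoxFit(
        beta=beta,
        se=se,
        hr=hr,
        ci95=ci,
        p=p,
        n_used=n_used,
        n_events=n_events,
        converged=converged,
        flags=flags,
    )


# ======================================================================
# Plain two-group tests
# ======================================================================
def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns ``(U, p)``."""
    xa = _as_1d(x, "x")
    ya = _as_1d(y, "y")
    res = stats.mannwhitneyu(xa, ya, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table; returns ``(OR, p)``."""
    tab = np.asarray(table)
    if tab.shape != (2, 2):
        raise EstimationError("fisher_exact requires a 2x2 table")
    if (tab < 0).any() or not np.issubdtype(tab.dtype, np.integer):
        tab = tab.astype(float)
        if (tab < 0).any() or not np.allclose(tab, np.round(tab)):
            raise EstimationError("table entries must be non-negative integers")
        tab = tab.astype(int)
    odds, p = stats.fisher_exact(tab, alternative="two-sided")
    return float(odds), float(p)
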