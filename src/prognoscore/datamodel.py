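"""Core data containers for multi-cohort prognostic-score analysis.

A :class:`CohortDataset` bundles one cohort's gene-expression matrix
(genes x samples) with right-censored survival endpoints and clinical
covariates.  Every pipeline stage (gene screening, coefficient pooling,
score search, score application) consumes a list of these.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortDataset",
    "ScreenCriteria",
    "ScoreThresholds",
    "HeterogeneityRule",
    "RunConfig",
]

#: Recognised second-endpoint labels (besides ``"none"``).
SECOND_ENDPOINT_KINDS = ("none", "DFS", "RFS")

COVARIATE_KINDS = ("continuous", "categorical")


class ValidationError(ValueError):
    """Raised when a dataset or configuration violates its contract."""


@dataclass
class CohortDataset:
    """One cohort: expression matrix, survival endpoints and covariates.

    Parameters
    ----------
    cohort_id : str
        Short label, e.g. ``"TCGA"``.
    expression : pandas.DataFrame
        Genes (rows, unique identifiers) x samples (columns, unique
        identifiers); values finite reals.
    os_time, os_event : pandas.Series
        Overall survival follow-up (months, >= 0) and event indicator
        (1 = death, 0 = censored), indexed by sample.
    second_endpoint_kind : str
        ``"none"``, ``"DFS"`` or ``"RFS"``.
    ep2_time, ep2_event : pandas.Series or None
        Second endpoint, present iff ``second_endpoint_kind != "none"``.
    covariates : pandas.DataFrame
        One row per sample; missing values allowed (``NaN``).
    covariate_kinds : dict
        Maps covariate name -> ``"continuous"`` or ``"categorical"``.
    available_covariates : list of str
        Covariates usable for multivariate adjustment in this cohort.
    """

    cohort_id: str
    expression: pd.DataFrame
    os_time: pd.Series
    os_event: pd.Series
    second_endpoint_kind: str = "none"
    ep2_time: pd.Series | None = None
    ep2_event: pd.Series | None = None
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    covariate_kinds: dict[str, str] = field(default_factory=dict)
    available_covariates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[0]

    @property
    def samples(self) -> pd.Index:
        return self.expression.columns

    @property
    def genes(self) -> pd.Index:
        return self.expression.index

    @property
    def has_second_endpoint(self) -> bool:
        return self.second_endpoint_kind != "none"

    # ------------------------------------------------------------------
    def validate(self) -> None:
        expr = self.expression
        if expr.index.has_duplicates:
            dups = sorted(expr.index[expr.index.duplicated()].unique())
            raise ValidationError(
                f"cohort {self.cohort_id!r}: duplicate gene ids {dups}"
            )
        if expr.columns.has_duplicates:
            dups = sorted(expr.columns[expr.columns.duplicated()].unique())
            raise ValidationError(
                f"cohort {self.cohort_id!r}: duplicate sample ids {dups}"
            )
        vals = expr.to_numpy()
        if vals.size and not np.isfinite(vals.astype(float)).all():
            raise ValidationError(
                f"cohort {self.cohort_id!r}: non-finite expression values"
            )

        samples = expr.columns
        for name, series in (("os_time", self.os_time), ("os_event", self.os_event)):
            missing = samples.difference(series.index)
            if len(missing):
                raise ValidationError(
                    f"cohort {self.cohort_id!r}: samples missing {name}: "
                    f"{sorted(missing)[:5]}"
                )
        t = self.os_time.loc[samples].to_numpy(dtype=float)
        e = self.os_event.loc[samples].to_numpy(dtype=float)
        if (t < 0).any() or not np.isfinite(t).all():
            raise ValidationError(f"cohort {self.cohort_id!r}: negative or non-finite OS times")
        if not np.isin(e, (0.0, 1.0)).all():
            raise ValidationError(f"cohort {self.cohort_id!r}: OS events not in {{0,1}}")

        if self.second_endpoint_kind not in SECOND_ENDPOINT_KINDS:
            raise ValidationError(
                f"second_endpoint_kind must be one of {SECOND_ENDPOINT_KINDS}"
            )
        if self.has_second_endpoint:
            if self.ep2_time is None or self.ep2_event is None:
                raise ValidationError(
                    f"cohort {self.cohort_id!r}: second endpoint declared but missing data"
                )
            t2 = self.ep2_time.loc[samples].to_numpy(dtype=float)
            e2 = self.ep2_event.loc[samples].to_numpy(dtype=float)
            if (t2 < 0).any() or not np.isin(e2, (0.0, 1.0)).all():
                raise ValidationError(
                    f"cohort {self.cohort_id!r}: invalid second-endpoint data"
                )

        for name in self.available_covariates:
            if name not in self.covariates.columns:
                raise ValidationError(
                    f"cohort {self.cohort_id!r}: available covariate {name!r} "
                    "absent from covariate table"
                )
            kind = self.covariate_kinds.get(name)
            if kind not in COVARIATE_KINDS:
                raise ValidationError(
                    f"cohort {self.cohort_id!r}: covariate {name!r} has no declared "
                    f"kind (continuous/categorical)"
                )
            if kind == "categorical":
                nlev = self.covariates[name].dropna().nunique()
                if nlev < 2:
                    raise ValidationError(
                        f"cohort {self.cohort_id!r}: categorical covariate {name!r} "
                        f"has {nlev} observed level(s); >=2 required"
                    )

    # ------------------------------------------------------------------
    def endpoint(self, which: str = "os") -> tuple[pd.Series, pd.Series]:
        """Return ``(time, event)`` aligned to the expression columns."""
        if which == "os":
            return (self.os_time.loc[self.samples], self.os_event.loc[self.samples])
        if which == "ep2":
            if not self.has_second_endpoint:
                raise ValidationError(
                    f"cohort {self.cohort_id!r} carries no second endpoint"
                )
            return (self.ep2_time.loc[self.samples], self.ep2_event.loc[self.samples])
        raise ValueError(f"unknown endpoint {which!r}")


# ----------------------------------------------------------------------
@dataclass
class ScreenCriteria:
    """Thresholds governing the per-gene screen.

    ``horizon_months`` is the fixed time point of the survival ROC;
    ``min_group_frac`` is the minimum fraction of the cohort each of the
    dichotomized groups must retain (default 20%).
    """

    horizon_months: float = 36.0
    min_group_frac: float = 0.20
    alpha: float = 0.05
    auc_min: float = 0.5
    require_all_cohorts: bool = True

    def __post_init__(self) -> None:
        if self.horizon_months <= 0:
            raise ValidationError("horizon_months must be > 0")
        if not 0 < self.min_group_frac <= 0.5:
            raise ValidationError("min_group_frac must be in (0, 0.5]")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")


@dataclass
class ScoreThresholds:
    """Pass thresholds for a candidate score, applied in every cohort."""

    uni_hr_min: float = 2.0
    multi_hr_min: float = 1.5
    auc_min: float = 0.5
    sens_min: float = 0.5
    spec_min: float = 0.5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("uni_hr_min", "multi_hr_min", "auc_min", "sens_min", "spec_min"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")


@dataclass
class HeterogeneityRule:
    """Fixed- vs random-effects decision rule for coefficient pooling.

    Fixed effects are used when the Cochran Q p-value is >= ``q_p_threshold``
    AND I^2 <= ``i2_threshold`` (percent); otherwise DerSimonian-Laird
    random effects.
    """

    q_p_threshold: float = 0.05
    i2_threshold: float = 50.0


@dataclass
class RunConfig:
    """Complete run configuration."""

    criteria: ScreenCriteria = field(default_factory=ScreenCriteria)
    score_thresholds: ScoreThresholds = field(default_factory=ScoreThresholds)
    category_cutoffs: tuple[float, float] = (0.9, 1.1)
    heterogeneity_rule: HeterogeneityRule = field(default_factory=HeterogeneityRule)
    expression_scale: str = "zscore"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.category_cutoffs
        if not (0 < low < high):
            raise ValidationError("category cutoffs must satisfy 0 < low < high")
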