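"""Stage 2: meta-analytic pooling of per-cohort Cox coefficients.

Each prognostic gene carries one univariate dichotomized-group log-hazard
coefficient per cohort.  These are pooled on the log-hazard scale with an
inverse-variance fixed-effects mean when the cohorts look homogeneous
(Cochran Q p >= threshold and Higgins I^2 <= threshold), and with a
DerSimonian-Laird random-effects model otherwise.  The pooled beta is the
gene's weight in every candidate score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import HeterogeneityRule

__all__ = ["PooledCoefficient", "cochran_q", "i_squared", "pool_beta", "pool_all"]


class PoolingError(ValueError):
    pass


@dataclass
class PooledCoefficient:
    gene: str
    betas: np.ndarray
    ses: np.ndarray
    q: float
    q_df: int
    q_p: float
    i2: float  # percent
    tau2: float
    model: str  # fixed | random
    beta_pooled: float
    se_pooled: float

    @property
    def hr_pooled(self) -> float:
        return float(np.exp(self.beta_pooled))

    def ci95(self) -> tuple[float, float]:
        half = 1.959963984540054 * self.se_pooled
        return (self.beta_pooled - half, self.beta_pooled + half)


def _check(betas, ses):
    b = np.asarray(betas, dtype=float).ravel()
    s = np.asarray(ses, dtype=float).ravel()
    if b.size < 2:
        raise PoolingError("pooling requires >= 2 studies")
    if b.size != s.size:
        raise PoolingError("betas and ses length mismatch")
    if (s <= 0).any() or not np.isfinite(s).all():
        raise PoolingError("standard errors must be positive and finite")
    return b, s


def cochran_q(betas, ses) -> tuple[float, int, float]:
    """Cochran's heterogeneity Q = sum w_i (b_i - b_fixed)^2, w_i = 1/se_i^2.

    Returns ``(q, df, p)`` with p from chi-square(k-1).
    """
    b, s = _check(betas, ses)
    w = 1.0 / s**2
    b_fixed = float(np.sum(w * b) / np.sum(w))
    q = float(np.sum(w * (b - b_fixed) ** 2))
    df = b.size - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, p


def i_squared(q: float, df: int) -> float:
    """Higgins I^2 in percent: max(0, (Q - df)/Q) * 100; 0 when Q = 0."""
    if q < 0:
        raise PoolingError("Q must be >= 0")
    if df < 1:
        raise PoolingError("df must be >= 1")
    if q == 0:
        return 0.0
    return float(max(0.0, (q - df) / q) * 100.0)


def pool_beta(
    betas, ses, rule: HeterogeneityRule | None = None, gene: str = ""
) -> PooledCoefficient:
    """Pool per-cohort log-hazard coefficients.

    Fixed-effects inverse-variance mean when the heterogeneity rule is
    satisfied; otherwise DerSimonian-Laird random effects with
    tau2 = max(0, (Q - df) / (sum w - sum w^2 / sum w)) and weights
    1/(se^2 + tau2).
    """
    rule = rule or HeterogeneityRule()
    b, s = _check(betas, ses)
    q, df, q_p = cochran_q(b, s)
    i2 = i_squared(q, df)

    w = 1.0 / s**2
    if q_p >= rule.q_p_threshold and i2 <= rule.i2_threshold:
        model = "fixed"
        tau2 = 0.0
        w_star = w
    else:
        model = "random"
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = float(max(0.0, (q - df) / denom)) if denom > 0 else 0.0
        w_star = 1.0 / (s**2 + tau2)
    beta_pooled = float(np.sum(w_star * b) / np.sum(w_star))
    se_pooled = float(1.0 / np.sqrt(np.sum(w_star)))
    return PooledCoefficient(
        gene=gene, betas=b, ses=s, q=q, q_df=df, q_p=q_p, i2=i2, tau2=tau2,
        model=model, beta_pooled=beta_pooled, se_pooled=se_pooled,
    )


def pool_all(
    records, rule: HeterogeneityRule | None = None, genes: list[str] | None = None
) -> dict[str, PooledCoefficient]:
    """Pool the univariate OS betas of the given genes from screen records.

    Uses the UNIVARIATE dichotomized-group coefficients so that the
    resulting score is computable from expression alone.
    """
    by_gene = {r.gene: r for r in records}
    genes = genes if genes is not None else sorted(
        r.gene for r in records if r.final_pass
    )
    pooled = {}
    for g in genes:
        rec = by_gene[g]
        evs = list(rec.os_evidence.values())
        betas = [e.uni_beta for e in evs]
        ses = [e.uni_se for e in evs]
        if any(not np.isfinite(v) for v in betas + ses):
            raise PoolingError(
                f"gene {g!r}: incomplete univariate evidence; rerun the screen "
                "with lazy=False or restrict to fully evaluated genes"
            )
        pooled[g] = pool_beta(betas, ses, rule, gene=g)
    return pooled


def pooled_to_frame(pooled: dict[str, PooledCoefficient]) -> pd.DataFrame:
    rows = [
        {
            "gene": p.gene, "model": p.model, "q": p.q, "q_df": p.q_df,
            "q_p": p.q_p, "i2": p.i2, "tau2": p.tau2,
            "beta_pooled": p.beta_pooled, "se_pooled": p.se_pooled,
        }
        for p in pooled.values()
    ]
    return pd.DataFrame(
        rows, columns=["gene", "model", "q", "q_df", "q_p", "i2", "tau2",
                       "beta_pooled", "se_pooled"],
    )
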