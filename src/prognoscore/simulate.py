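"""Synthetic multi-cohort expression + survival data with known ground truth.

The generator emulates the structure of a multi-cohort gastric-cancer
transcriptome study: five discovery cohorts of unequal size, right-censored
overall survival, a second endpoint (DFS or RFS) available only in some
cohorts, cohort-specific covariate availability, a handful of planted
prognostic genes and mild between-cohort heterogeneity of their effects.

Event times follow a Weibull proportional-hazards model

    T = scale * (-log U / exp(lp))**(1/shape),   U ~ Uniform(0,1)

with linear predictor ``lp = sum_g beta_{c,g} x_g + covariate effects``,
where ``beta_{c,g} = beta_true_g + Normal(0, tau)`` realizes per-cohort
heterogeneity.  Censoring is an independent uniform draw plus an
administrative cap (non-informative).  The second endpoint is an
accelerated copy of the latent event process, coupled to overall survival
through a Gaussian copula.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CohortDataset

__all__ = [
    "PlantedGene",
    "SimulationConfig",
    "GroundTruth",
    "simulate_multicohort",
    "CellLineConfig",
    "simulate_celllines",
]


@dataclass(frozen=True)
class PlantedGene:
    """A gene with a true prognostic effect.

    ``beta`` is the log-hazard per standard deviation of expression;
    ``on_ep2`` controls whether the gene also drives the second endpoint.
    """

    gene: str
    beta: float
    on_ep2: bool = True


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic multi-cohort generator.

    Defaults mirror a five-cohort gastric-cancer discovery setting:
    cohort sizes 345/297/433/93/192, Weibull baseline (shape 1.2,
    cohort-specific scale in months), uniform censoring to 120 months, and
    a DFS/RFS second endpoint in the first, second and fourth cohorts.
    """

    n_cohorts: int = 5
    cohort_sizes: tuple[int, ...] = (345, 297, 433, 93, 192)
    n_genes: int = 200
    planted_genes: tuple[PlantedGene, ...] = ()
    block_rho: float = 0.2
    block_size: int = 10
    weibull_shape: float = 1.2
    weibull_scales: tuple[float, ...] = (70.0, 90.0, 75.0, 65.0, 60.0)
    censor_upper: tuple[float, ...] = (120.0, 120.0, 120.0, 120.0, 120.0)
    admin_cap_months: float = 120.0
    age_effect_per_decade: float = 0.3
    sex_effect: float = 0.1
    stage_effects: tuple[float, float, float, float] = (0.0, 0.3, 0.7, 1.2)
    between_cohort_sd: float = 0.1
    endpoint2_cohorts: tuple[int, ...] = (0, 1, 3)
    endpoint2_kinds: tuple[str, ...] = ("DFS", "DFS", "RFS")
    ep2_association: float = 0.8  # Gaussian-copula correlation to OS
    ep2_acceleration: float = 0.8  # ep2 latent times = accel * OS-scale times
    available_covariates: tuple[tuple[str, ...], ...] = (
        ("age", "sex", "stage"),
        ("age", "sex", "stage"),
        ("age", "sex"),
        ("age", "sex", "stage"),
        ("age", "sex"),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cohort_sizes) != self.n_cohorts:
            raise ValueError("cohort_sizes length must equal n_cohorts")
        if any(n < 30 for n in self.cohort_sizes):
            raise ValueError("cohort sizes must all be >= 30")
        if any(c <= 0 for c in self.censor_upper):
            raise ValueError("censoring bounds must be > 0")
        if not 0 <= self.block_rho < 1:
            raise ValueError("block_rho must be in [0, 1)")
        genes = self.gene_ids()
        for pg in self.planted_genes:
            if pg.gene not in genes:
                raise ValueError(f"planted gene {pg.gene!r} absent from gene universe")

    def gene_ids(self) -> list[str]:
        planted = [pg.gene for pg in self.planted_genes]
        n_null = self.n_genes - len(planted)
        if n_null < 0:
            raise ValueError("more planted genes than n_genes")
        width = len(str(max(self.n_genes - 1, 1)))
        nulls = [f"G{idx:0{width}d}" for idx in range(n_null)]
        return planted + nulls


@dataclass
class GroundTruth:
    """What the generator actually planted, recorded per seed."""

    realized_betas: pd.DataFrame  # planted genes x cohorts (log-HR per SD)
    on_ep2: dict[str, bool]
    covariate_effects: dict[str, float | tuple]
    latent_event_times: dict[str, np.ndarray]
    seed: int

    @property
    def planted_genes(self) -> list[str]:
        return list(self.realized_betas.index)


def _draw_expression(rng, n_genes_null, n_planted, n_samples, rho, block_size):
    """Planted genes independent N(0,1); null genes in equicorrelated blocks."""
    planted = rng.standard_normal((n_planted, n_samples))
    if n_genes_null == 0:
        return planted, np.empty((0, n_samples))
    eps = rng.standard_normal((n_genes_null, n_samples))
    if rho > 0:
        n_blocks = -(-n_genes_null // block_size)
        z_block = rng.standard_normal((n_blocks, n_samples))
        block_of = np.arange(n_genes_null) // block_size
        nulls = np.sqrt(rho) * z_block[block_of] + np.sqrt(1 - rho) * eps
    else:
        nulls = eps
    return planted, nulls


def _weibull_times(rng, lp, shape, scale, u=None):
    if u is None:
        u = rng.uniform(size=lp.shape)
    return scale * (-np.log(u) / np.exp(lp)) ** (1.0 / shape), u


def simulate_multicohort(
    config: SimulationConfig,
) -> tuple[list[CohortDataset], GroundTruth]:
    """Generate the cohorts plus a record of the planted truth.

    Deterministic for a fixed config (including seed).
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_ids()
    planted = list(config.planted_genes)
    n_planted = len(planted)

    # per-cohort realized effects
    realized = np.array(
        [
            [pg.beta + rng.normal(0.0, config.between_cohort_sd)
             for _ in range(config.n_cohorts)]
            for pg in planted
        ]
    ).reshape(n_planted, config.n_cohorts)
    realized_df = pd.DataFrame(
        realized,
        index=[pg.gene for pg in planted],
        columns=[f"C{i}" for i in range(config.n_cohorts)],
    )

    stage_labels = np.array(["I", "II", "III", "IV"])
    stage_probs = np.array([0.15, 0.30, 0.35, 0.20])
    stage_eff = dict(zip(stage_labels, config.stage_effects))

    cohorts: list[CohortDataset] = []
    latent: dict[str, np.ndarray] = {}
    ep2_index = {c: k for c, k in zip(config.endpoint2_cohorts, config.endpoint2_kinds)}

    for c in range(config.n_cohorts):
        n = config.cohort_sizes[c]
        cid = f"C{c}"
        sample_ids = [f"{cid}_S{j:04d}" for j in range(n)]

        expr_planted, expr_null = _draw_expression(
            rng, len(genes) - n_planted, n_planted, n,
            config.block_rho, config.block_size,
        )
        expr = np.vstack([expr_planted, expr_null])

        age = rng.normal(62.0, 10.0, n)
        sex = rng.choice(["M", "F"], size=n, p=[0.65, 0.35])
        stage = rng.choice(stage_labels, size=n, p=stage_probs)

        lp_cov = (
            config.age_effect_per_decade * (age - 62.0) / 10.0
            + config.sex_effect * (sex == "M")
            + np.vectorize(stage_eff.get)(stage)
        )
        lp_os = lp_cov.copy()
        lp_ep2 = lp_cov.copy()
        for gi, pg in enumerate(planted):
            b = realized[gi, c]
            lp_os += b * expr_planted[gi]
            if pg.on_ep2:
                lp_ep2 += b * expr_planted[gi]

        scale = config.weibull_scales[c]
        z1 = rng.standard_normal(n)
        u_os = stats.norm.cdf(z1)
        t_os_latent, _ = _weibull_times(
            rng, lp_os, config.weibull_shape, scale, u=u_os
        )
        cens = np.minimum(
            rng.uniform(0.0, config.censor_upper[c], n), config.admin_cap_months
        )
        os_time = np.minimum(t_os_latent, cens)
        os_event = (t_os_latent <= cens).astype(int)
        latent[cid] = t_os_latent

        ep2_time = ep2_event = None
        kind = ep2_index.get(c, "none")
        if kind != "none":
            rho = config.ep2_association
            z2 = rho * z1 + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
            u2 = stats.norm.cdf(z2)
            t2_latent, _ = _weibull_times(
                rng, lp_ep2, config.weibull_shape,
                scale * config.ep2_acceleration, u=u2,
            )
            cens2 = np.minimum(
                rng.uniform(0.0, config.censor_upper[c], n), config.admin_cap_months
            )
            ep2_time = pd.Series(np.minimum(t2_latent, cens2), index=sample_ids)
            ep2_event = pd.Series((t2_latent <= cens2).astype(int), index=sample_ids)

        covariates = pd.DataFrame(
            {"age": age, "sex": sex, "stage": stage}, index=sample_ids
        )
        cohorts.append(
            CohortDataset(
                cohort_id=cid,
                expression=pd.DataFrame(expr, index=genes, columns=sample_ids),
                os_time=pd.Series(os_time, index=sample_ids),
                os_event=pd.Series(os_event, index=sample_ids),
                second_endpoint_kind=kind,
                ep2_time=ep2_time,
                ep2_event=ep2_event,
                covariates=covariates,
                covariate_kinds={
                    "age": "continuous", "sex": "categorical", "stage": "categorical"
                },
                available_covariates=list(config.available_covariates[c]),
            )
        )

    truth = GroundTruth(
        realized_betas=realized_df,
        on_ep2={pg.gene: pg.on_ep2 for pg in planted},
        covariate_effects={
            "age_per_decade": config.age_effect_per_decade,
            "sex_M": config.sex_effect,
            "stage": config.stage_effects,
        },
        latent_event_times=latent,
        seed=config.seed,
    )
    return cohorts, truth


# ======================================================================
# Cell-line panel with drug sensitivities
# ======================================================================
@dataclass
class CellLineConfig:
    """Toy cell-line expression + drug-IC50 panel.

    Planted drugs' log-IC50 is generated as a (noisy) monotone function of
    the signature score with target Spearman correlation ``rho``; null
    drugs are independent of the score.
    """

    n_lines: int = 16
    n_genes: int = 30
    signature: dict[str, float] = field(default_factory=dict)
    planted_drugs: tuple[tuple[str, float], ...] = ()  # (drug_id, rho)
    n_null_drugs: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 8:
            raise ValueError("need >= 8 cell lines (rank correlation unstable)")
        if not self.signature:
            width = len(str(max(self.n_genes - 1, 1)))
            self.signature = {f"G{idx:0{width}d}": 0.5 for idx in range(5)}


def simulate_celllines(config: CellLineConfig):
    """Return (expression genes x lines, ic50 drugs x lines, ground truth)."""
    rng = np.random.default_rng(config.seed)
    width = len(str(max(config.n_genes - 1, 1)))
    genes = [f"G{idx:0{width}d}" for idx in range(config.n_genes)]
    for g in config.signature:
        if g not in genes:
            raise ValueError(f"signature gene {g!r} absent from gene universe")
    lines = [f"L{j:02d}" for j in range(config.n_lines)]
    expr = pd.DataFrame(
        rng.standard_normal((config.n_genes, config.n_lines)),
        index=genes, columns=lines,
    )
    w = pd.Series(config.signature)
    z = expr.loc[w.index].sub(expr.loc[w.index].mean(axis=1), axis=0)
    z = z.div(expr.loc[w.index].std(axis=1, ddof=1), axis=0)
    score = w @ z
    s_std = (score - score.mean()) / score.std(ddof=1)

    rows = {}
    truth_rho = {}
    for drug, rho in config.planted_drugs:
        if abs(rho) >= 1.0:
            y = np.sign(rho) * s_std.to_numpy()
        else:
            y = rho * s_std.to_numpy() + np.sqrt(1 - rho**2) * rng.standard_normal(
                config.n_lines
            )
        rows[drug] = np.exp(y)  # log-normal IC50 scale; monotone in y
        truth_rho[drug] = rho
    for d in range(config.n_null_drugs):
        rows[f"null_drug_{d:02d}"] = np.exp(rng.standard_normal(config.n_lines))
        truth_rho[f"null_drug_{d:02d}"] = 0.0

    ic50 = pd.DataFrame(rows, index=lines).T
    truth = {"score": score, "rho": truth_rho, "seed": config.seed}
    return expr, ic50, truth
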