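"""Reading and writing the on-disk formats.

Expression matrices are tab-separated, genes in rows (first column = gene
identifier, header row = sample identifiers).  Clinical tables are
tab-separated with one row per sample.  A column-mapping dict declares
which clinical columns carry the endpoints and covariates, so arbitrary
source tables can be ingested without renaming.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import CohortDataset, ValidationError

logger = logging.getLogger("prognoscore")

__all__ = ["ClinicalMapping", "read_cohort", "write_table", "read_table", "load_yaml"]

DAYS_PER_MONTH = 30.44


@dataclass
class ClinicalMapping:
    """Column mapping for a clinical table.

    ``covariates`` maps source column name -> (canonical name, kind), with
    kind ``"continuous"`` or ``"categorical"``.
    """

    sample_id: str = "sample_id"
    os_time: str = "os_time"
    os_event: str = "os_event"
    second_endpoint_kind: str = "none"  # none | DFS | RFS
    ep2_time: str | None = None
    ep2_event: str | None = None
    covariates: dict[str, tuple[str, str]] = field(default_factory=dict)
    time_unit: str = "months"  # months | days

    @classmethod
    def from_dict(cls, d: dict) -> "ClinicalMapping":
        cov = {
            src: (spec["name"], spec["kind"]) if isinstance(spec, dict) else tuple(spec)
            for src, spec in d.get("covariates", {}).items()
        }
        return cls(
            sample_id=d.get("sample_id", "sample_id"),
            os_time=d.get("os_time", "os_time"),
            os_event=d.get("os_event", "os_event"),
            second_endpoint_kind=d.get("second_endpoint_kind", "none"),
            ep2_time=d.get("ep2_time"),
            ep2_event=d.get("ep2_event"),
            covariates=cov,
            time_unit=d.get("time_unit", "months"),
        )


def _read_expression(path: str | Path) -> pd.DataFrame:
    expr = pd.read_csv(path, sep="\t", index_col=0)
    if expr.index.has_duplicates:
        dups = sorted(expr.index[expr.index.duplicated()].unique())
        raise ValidationError(f"{path}: duplicate gene ids: {dups}")
    if expr.columns.has_duplicates:
        dups = sorted(expr.columns[expr.columns.duplicated()].unique())
        raise ValidationError(f"{path}: duplicate sample ids: {dups}")
    for col in expr.columns:
        if not pd.api.types.is_numeric_dtype(expr[col]):
            bad = expr[col][pd.to_numeric(expr[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValidationError(
                f"{path}: non-numeric expression cell at gene {row!r}, "
                f"sample {col!r}"
            )
    return expr.astype(float)


def read_cohort(
    expression_path: str | Path,
    clinical_path: str | Path,
    mapping: ClinicalMapping | dict,
    cohort_id: str | None = None,
    available_covariates: list[str] | None = None,
) -> CohortDataset:
    """Load one cohort from an expression TSV plus a clinical TSV.

    The returned dataset is restricted to samples present in BOTH files;
    dropped samples are logged.  Missing covariate values are preserved as
    missing (complete-case filtering happens per model downstream).
    """
    if isinstance(mapping, dict):
        mapping = ClinicalMapping.from_dict(mapping)
    expr = _read_expression(expression_path)
    clin = pd.read_csv(clinical_path, sep="\t", dtype={mapping.sample_id: str})
    if clin[mapping.sample_id].duplicated().any():
        dups = sorted(clin[mapping.sample_id][clin[mapping.sample_id].duplicated()])
        raise ValidationError(f"{clinical_path}: duplicate sample ids: {dups}")
    clin = clin.set_index(mapping.sample_id)

    common = expr.columns.intersection(clin.index)
    if len(common) == 0:
        raise ValidationError(
            f"no overlapping samples between {expression_path} and {clinical_path}"
        )
    n_drop_expr = expr.shape[1] - len(common)
    n_drop_clin = clin.shape[0] - len(common)
    if n_drop_expr or n_drop_clin:
        logger.info(
            "cohort %s: dropped %d expression-only and %d clinical-only samples",
            cohort_id,
            n_drop_expr,
            n_drop_clin,
        )
    expr = expr[common]
    clin = clin.loc[common]

    factor = DAYS_PER_MONTH if mapping.time_unit == "days" else 1.0
    if factor != 1.0:
        logger.info("cohort %s: converting times from days to months", cohort_id)
    os_time = pd.to_numeric(clin[mapping.os_time]) / factor
    os_event = pd.to_numeric(clin[mapping.os_event])

    ep2_time = ep2_event = None
    kind = mapping.second_endpoint_kind
    if kind != "none":
        ep2_time = pd.to_numeric(clin[mapping.ep2_time]) / factor
        ep2_event = pd.to_numeric(clin[mapping.ep2_event])

    cov_frames = {}
    kinds = {}
    for src, (name, ckind) in mapping.covariates.items():
        col = clin[src]
        cov_frames[name] = pd.to_numeric(col) if ckind == "continuous" else col
        kinds[name] = ckind
    covariates = pd.DataFrame(cov_frames, index=clin.index)

    avail = (
        available_covariates
        if available_covariates is not None
        else list(covariates.columns)
    )
    return CohortDataset(
        cohort_id=cohort_id or Path(expression_path).stem,
        expression=expr,
        os_time=os_time,
        os_event=os_event,
        second_endpoint_kind=kind,
        ep2_time=ep2_time,
        ep2_event=ep2_event,
        covariates=covariates,
        covariate_kinds=kinds,
        available_covariates=avail,
    )


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with deterministic column order.

    Floats are written with 10 significant digits so that write -> read
    round-trips to within formatting precision.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"directory does not exist: {path.parent}")
    records.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_expression(expr: pd.DataFrame, path: str | Path, index_label="gene") -> None:
    expr.to_csv(path, sep="\t", index=True, index_label=index_label,
                float_format="%.10g")


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
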