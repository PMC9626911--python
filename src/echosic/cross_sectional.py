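"""Cohort description and per-SD adjusted linear associations with HS-SIC.

Continuous variables are normalised by their sample standard deviation so
that estimates read "per 1-SD"; binary covariates enter raw (0/1).  The SD
used is always the overall analysis-sample SD, also in sex-stratified
models, so that "1 SD" is a single unit across all result tables (a
config switch selects stratum-specific SDs for sensitivity analysis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "StandardizationParams",
    "AssocEstimate",
    "standardize_columns",
    "cohort_summary",
    "adjusted_linear_assoc",
    "association_table",
    "is_binary",
    "complete_cases",
]

#: Continuous / binary split of the standard cohort columns.
CONTINUOUS_COLUMNS = (
    "age", "bmi", "sbp", "dbp", "tc_hdl_ratio", "egfr", "lvef",
    "e_over_eprime", "rwt", "hs_sic",
)
BINARY_COLUMNS = (
    "sex", "diabetes", "smoker", "antihtn_tx", "lipid_tx", "glucose_tx",
)


@dataclass(frozen=True)
class StandardizationParams:
    """Per-column mean and SD of the z-scaling transform.

    The SDs define the "per 1-SD" unit of all downstream per-SD estimates.
    """

    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for col, mu in self.means.items():
            out[col] = (out[col] - mu) / self.sds[col]
        return out

    def inverse(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for col, mu in self.means.items():
            out[col] = out[col] * self.sds[col] + mu
        return out


@dataclass(frozen=True)
class AssocEstimate:
    """One adjusted linear-regression association with the HS-SIC outcome."""

    predictor: str
    estimate: float
    se: float
    p_value: float
    adjustment: tuple[str, ...]
    stratum: str = "total"
    per_sd: bool = True
    n: int = 0


def is_binary(x: pd.Series) -> bool:
    vals = pd.unique(x.dropna())
    return len(vals) <= 2 and set(np.asarray(vals).tolist()) <= {0, 1, 0.0, 1.0}


def complete_cases(table: pd.DataFrame, columns: Iterable[str]) -> pd.DataFrame:
    """Complete-case filter over the modelling columns, logging exclusions."""
    cols = [c for c in columns if c in table.columns]
    kept = table.dropna(subset=cols)
    n_dropped = len(table) - len(kept)
    if n_dropped:
        logger.info("complete-case filter removed %d of %d rows", n_dropped, len(table))
    return kept


def standardize_columns(
    table: pd.DataFrame, columns: Sequence[str]
) -> tuple[pd.DataFrame, StandardizationParams]:
    """Z-scale the given columns (sample SD, n-1 denominator).

    Returns the transformed table and the parameters needed to invert the
    transform exactly.  A zero-variance column raises a ValueError naming it.
    """
    means, sds = {}, {}
    out = table.copy()
    for col in columns:
        x = table[col].astype(float)
        sd = float(x.std(ddof=1))
        if not np.isfinite(sd) or sd == 0.0:
            raise ValueError(f"column {col!r} has zero variance; cannot standardize")
        mu = float(x.mean())
        means[col], sds[col] = mu, sd
        out[col] = (x - mu) / sd
    return out, StandardizationParams(means=means, sds=sds)


def cohort_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Clinical-characteristics table: mean +/- SD for continuous variables,
    n (%) for binaries, overall and by sex (sex: 1 = woman).
    """
    if table.empty:
        raise ValueError("cannot summarise an empty cohort")
    strata = {"total": table}
    if "sex" in table.columns:
        strata["women"] = table[table["sex"] == 1]
        strata["men"] = table[table["sex"] == 0]
    rows = []
    skip = {"subject_id", "time", "event"}
    for col in table.columns:
        if col in skip:
            continue
        x = table[col]
        if not pd.api.types.is_numeric_dtype(x):
            continue
        binary = is_binary(x)
        row: dict = {"variable": col, "kind": "binary" if binary else "continuous"}
        for name, sub in strata.items():
            xs = sub[col].astype(float)
            if binary:
                n_pos = int(xs.sum())
                row[f"{name}_n"] = n_pos
                row[f"{name}_pct"] = 100.0 * n_pos / len(xs) if len(xs) else np.nan
            else:
                row[f"{name}_mean"] = float(xs.mean()) if len(xs) else np.nan
                row[f"{name}_sd"] = float(xs.std(ddof=1)) if len(xs) > 1 else np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["n"] = {name: len(sub) for name, sub in strata.items()}
    return out


def adjusted_linear_assoc(
    table: pd.DataFrame,
    predictor: str,
    outcome: str = "hs_sic",
    adjust: Sequence[str] = (),
    stratum: str = "total",
    per_sd: bool = True,
    sd_anchor: Optional[float] = None,
) -> AssocEstimate:
    """OLS association of one predictor with HS-SIC, adjusted for covariates.

    Continuous predictors enter per SD (overall-sample SD unless
    ``sd_anchor`` overrides it); binary predictors enter 0/1.  Adjusters are
    entered raw — only the focal predictor's scaling affects its estimate.
    For sex-stratified runs the caller must exclude sex from the adjusters.
    """
    if stratum not in ("total", "women", "men"):
        raise ValueError(f"unknown stratum {stratum!r}")
    data = complete_cases(table, [predictor, outcome, *adjust])
    pred_full = data[predictor].astype(float)
    if stratum != "total":
        if "sex" in adjust or predictor == "sex":
            raise ValueError("sex cannot appear in a sex-stratified model")
        data = data[data["sex"] == (1 if stratum == "women" else 0)]
    binary = is_binary(table[predictor])
    x = data[predictor].astype(float)
    scale = 1.0
    if per_sd and not binary:
        scale = sd_anchor if sd_anchor is not None else float(pred_full.std(ddof=1))
        if scale == 0:
            raise ValueError(f"predictor {predictor!r} has zero variance")
        x = x / scale
    X = pd.DataFrame({predictor: x})
    for cov in adjust:
        X[cov] = data[cov].astype(float)
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X.values) < X.shape[1]:
        raise ValueError(
            f"rank-deficient design for predictor {predictor!r} with adjusters {tuple(adjust)}"
        )
    fit = sm.OLS(data[outcome].astype(float), X).fit()
    return AssocEstimate(
        predictor=predictor,
        estimate=float(fit.params[predictor]),
        se=float(fit.bse[predictor]),
        p_value=float(fit.pvalues[predictor]),
        adjustment=tuple(adjust),
        stratum=stratum,
        per_sd=per_sd and not binary,
        n=int(fit.nobs),
    )


def association_table(
    table: pd.DataFrame,
    predictors: Sequence[str] = (
        "sex", "age", "bmi", "tc_hdl_ratio", "sbp",
        "antihtn_tx", "diabetes", "smoker", "lvef", "e_over_eprime",
    ),
    outcome: str = "hs_sic",
) -> pd.DataFrame:
    """Age- and sex-adjusted associations of risk factors with HS-SIC,
    overall and by sex (risk-factor table shape).

    The sex row is adjusted for age only and the age row for sex only;
    every other predictor is adjusted for both.  Stratified models drop sex
    from the adjustment set.
    """
    rows = []
    for predictor in predictors:
        if predictor == "sex":
            adjust: tuple[str, ...] = ("age",)
        elif predictor == "age":
            adjust = ("sex",)
        else:
            adjust = ("age", "sex")
        strata = ["total"] if predictor == "sex" else ["total", "women", "men"]
        for stratum in strata:
            adj = tuple(a for a in adjust if a != "sex") if stratum != "total" else adjust
            est = adjusted_linear_assoc(
                table, predictor, outcome=outcome, adjust=adj, stratum=stratum
            )
            rows.append({
                "predictor": predictor,
                "stratum": stratum,
                "estimate": est.estimate,
                "se": est.se,
                "p_value": est.p_value,
                "per_sd": est.per_sd,
                "n": est.n,
            })
    return pd.DataFrame(rows)
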