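"""Product-of-coefficients mediation of risk-factor effects through HS-SIC.

For exposure X, mediator M (HS-SIC) and binary heart-failure indicator Y,
two standardised-coefficient linear models are fitted:

    M = a * X + covariates + error            (mediator model)
    Y = c' * X + b * M + covariates + error   (outcome model, linear
                                               probability scale)

The indirect (mediated) effect is ``a*b``, the direct effect ``c'``, and
the total effect ``c' + a*b`` — which, with a common covariate set, equals
exactly the exposure coefficient of the reduced model ``Y ~ X + covariates``
(the additivity that makes "proportion mediated = indirect/total" well
defined).  Standard errors come from the multivariate delta method (Sobel)
by default, or from a seeded percentile bootstrap.

The linear-probability outcome scale is the package default because it
yields the exact additive decomposition; an additive-hazard (Aalen) outcome
backend is available for sensitivity analysis, where additivity holds only
approximately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "MediationResult",
    "MediationModel",
    "fit_mediation",
    "proportion_mediated",
    "mediation_table",
    "TABLE_EXPOSURES",
]

#: Default risk-factor set decomposed through the mediator.
TABLE_EXPOSURES = (
    "age", "sex", "bmi", "tc_hdl_ratio", "sbp", "antihtn_tx", "diabetes", "smoker",
)


@dataclass
class MediationResult:
    """Direct / indirect / total decomposition for one exposure.

    ``total = direct + indirect`` exactly (linear-probability backend).
    """

    exposure: str
    direct: float
    direct_se: float
    direct_p: float
    indirect: float
    indirect_se: float
    indirect_p: float
    total: float
    total_se: float
    total_p: float
    a: float
    b: float
    adjustment: tuple[str, ...]
    n: int
    method: str = "delta"
    n_boot: int = 0
    seed: Optional[int] = None
    backend: str = "linear"

    @property
    def proportion_mediated(self) -> float:
        return proportion_mediated(self)

    @property
    def inconsistent(self) -> bool:
        """True when direct and indirect effects have opposite signs."""
        return self.direct * self.indirect < 0

    def summary(self) -> str:
        rows = [
            ("direct (c')", self.direct, self.direct_se, self.direct_p),
            ("indirect (a*b)", self.indirect, self.indirect_se, self.indirect_p),
            ("total", self.total, self.total_se, self.total_p),
        ]
        lines = [
            f"Mediation of {self.exposure!r} through the mediator "
            f"(n={self.n}, {self.method} SEs, {self.backend} outcome model)",
            f"{'effect':<16}{'estimate':>10}{'SE':>10}{'p':>10}",
        ]
        for name, est, se, p in rows:
            lines.append(f"{name:<16}{est:>10.4f}{se:>10.4f}{p:>10.4f}")
        try:
            pm = self.proportion_mediated
            note = " (inconsistent mediation)" if self.inconsistent else ""
            lines.append(f"proportion mediated = {pm:.3f}{note}")
        except ValueError:
            lines.append("proportion mediated undefined (zero total effect)")
        return "\n".join(lines)


def proportion_mediated(result: MediationResult) -> float:
    """indirect / total; raises on a zero total effect."""
    if result.total == 0:
        raise ValueError("total effect is zero; proportion mediated undefined")
    return result.indirect / result.total


def _standardize_continuous(data: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    out = data.copy()
    for c in cols:
        x = out[c].astype(float)
        uniq = np.unique(x.dropna())
        if len(uniq) <= 2 and set(uniq.tolist()) <= {0.0, 1.0}:
            continue  # binaries enter raw
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError(f"column {c!r} has zero variance")
        out[c] = (x - x.mean()) / sd
    return out


def _ols(y: np.ndarray, X: pd.DataFrame):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


class MediationModel:
    """Model object for one exposure -> mediator -> outcome decomposition.

    Parameters
    ----------
    data
        Cohort table with exposure, mediator and binary outcome columns.
    exposure, mediator, outcome
        Column names; mediator defaults to ``hs_sic`` and outcome to the
        heart-failure ``event`` indicator.
    covariates
        Adjustment set shared by both regressions.
    standardize
        Standardise all continuous variables by their sample SD (the
        "standardised coefficient model"); binaries enter 0/1.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        exposure: str,
        mediator: str = "hs_sic",
        outcome: str = "event",
        covariates: Sequence[str] = (),
        standardize: bool = True,
    ):
        if exposure == mediator:
            raise ValueError("mediator must differ from the exposure")
        y = data[outcome].dropna()
        if not set(np.unique(y.astype(float))) <= {0.0, 1.0}:
            raise ValueError("outcome must be a binary 0/1 event indicator")
        cols = [exposure, mediator, outcome, *covariates]
        data = data.dropna(subset=[c for c in cols if c in data.columns])
        if standardize:
            data = _standardize_continuous(data, [exposure, mediator, *covariates])
        self.data = data.reset_index(drop=True)
        self.exposure = exposure
        self.mediator = mediator
        self.outcome = outcome
        self.covariates = tuple(covariates)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, exposure: str, **kwargs) -> "MediationModel":
        return cls(data, exposure, **kwargs)

    # -- internals ---------------------------------------------------------

    def _paths(self, data: pd.DataFrame):
        """(a, sa, b, sb, c', sc, total, s_total, p-values) on one dataset."""
        Xm = data[[self.exposure, *self.covariates]]
        med_fit = _ols(data[self.mediator].astype(float).values, Xm)
        a, sa = med_fit.params[self.exposure], med_fit.bse[self.exposure]

        Xy = data[[self.exposure, self.mediator, *self.covariates]]
        out_fit = _ols(data[self.outcome].astype(float).values, Xy)
        b, sb = out_fit.params[self.mediator], out_fit.bse[self.mediator]
        c_prime, sc = out_fit.params[self.exposure], out_fit.bse[self.exposure]

        red_fit = _ols(data[self.outcome].astype(float).values, Xm)
        total_se = red_fit.bse[self.exposure]
        total_p = red_fit.pvalues[self.exposure]
        return {
            "a": float(a), "sa": float(sa),
            "b": float(b), "sb": float(sb),
            "c_prime": float(c_prime), "sc": float(sc),
            "c_p": float(out_fit.pvalues[self.exposure]),
            "total_se": float(total_se), "total_p": float(total_p),
        }

    def _paths_additive_hazard(self, data: pd.DataFrame):
        """Outcome paths from an Aalen additive-hazard model.

        Effects are average additive hazard increments per year (cumulative
        coefficient at the end of follow-up divided by the horizon).  The
        decomposition is only approximately additive on this scale.
        """
        from lifelines import AalenAdditiveFitter

        Xm = data[[self.exposure, *self.covariates]]
        med_fit = _ols(data[self.mediator].astype(float).values, Xm)
        a, sa = med_fit.params[self.exposure], med_fit.bse[self.exposure]

        def _aalen(cols):
            df = data[[*cols, "time", self.outcome]].astype(float)
            aaf = AalenAdditiveFitter(coef_penalizer=0.5, fit_intercept=True)
            aaf.fit(df, duration_col="time", event_col=self.outcome)
            tau = aaf.cumulative_hazards_.index[-1]
            slopes = aaf.cumulative_hazards_.iloc[-1] / tau
            var = aaf.cumulative_variance_.iloc[-1] / tau**2
            return slopes, np.sqrt(var)

        slopes, ses = _aalen([self.exposure, self.mediator, *self.covariates])
        red_slopes, red_ses = _aalen([self.exposure, *self.covariates])
        b, sb = slopes[self.mediator], ses[self.mediator]
        c_prime, sc = slopes[self.exposure], ses[self.exposure]
        z = abs(c_prime) / sc if sc > 0 else np.nan
        zt = abs(red_slopes[self.exposure]) / red_ses[self.exposure]
        return {
            "a": float(a), "sa": float(sa),
            "b": float(b), "sb": float(sb),
            "c_prime": float(c_prime), "sc": float(sc),
            "c_p": float(2 * stats.norm.sf(z)),
            "total_se": float(red_ses[self.exposure]),
            "total_p": float(2 * stats.norm.sf(zt)),
        }

    def fit(
        self,
        method: str = "delta",
        n_boot: int = 2000,
        seed: Optional[int] = None,
        backend: str = "linear",
    ) -> MediationResult:
        """Fit both regressions and assemble the decomposition.

        ``method`` is ``"delta"`` (Sobel SE for the indirect effect) or
        ``"bootstrap"`` (seeded percentile bootstrap for the indirect
        effect's SE and p).  ``backend`` selects the outcome-model scale:
        ``"linear"`` (linear probability; exact additivity) or
        ``"additive-hazard"`` (Aalen sensitivity backend; requires a
        ``time`` column, approximate additivity).
        """
        if backend == "linear":
            est = self._paths(self.data)
        elif backend == "additive-hazard":
            if "time" not in self.data.columns:
                raise ValueError("additive-hazard backend needs a 'time' column")
            est = self._paths_additive_hazard(self.data)
        else:
            raise ValueError(f"unknown backend {backend!r}")
        a, b = est["a"], est["b"]
        indirect = a * b
        direct = est["c_prime"]
        total = direct + indirect
        if method == "delta":
            ind_se = float(np.sqrt(a**2 * est["sb"] ** 2 + b**2 * est["sa"] ** 2))
            ind_p = float(2 * stats.norm.sf(abs(indirect) / ind_se)) if ind_se > 0 else np.nan
        elif method == "bootstrap":
            if backend != "linear":
                raise ValueError("bootstrap SEs are implemented for the linear backend")
            rng = np.random.default_rng(seed)
            n = len(self.data)
            draws = np.empty(n_boot)
            for i in range(n_boot):
                idx = rng.integers(0, n, n)
                e = self._paths(self.data.iloc[idx])
                draws[i] = e["a"] * e["b"]
            ind_se = float(draws.std(ddof=1))
            # percentile-bootstrap two-sided p via sign crossing
            frac = np.mean(draws < 0) if indirect > 0 else np.mean(draws > 0)
            ind_p = float(min(1.0, 2 * frac))
        else:
            raise ValueError(f"unknown method {method!r}")
        return MediationResult(
            exposure=self.exposure,
            direct=direct, direct_se=est["sc"], direct_p=est["c_p"],
            indirect=indirect, indirect_se=ind_se, indirect_p=ind_p,
            total=total, total_se=est["total_se"], total_p=est["total_p"],
            a=a, b=b,
            adjustment=self.covariates,
            n=len(self.data),
            method=method,
            n_boot=n_boot if method == "bootstrap" else 0,
            seed=seed,
            backend=backend,
        )


def fit_mediation(
    table: pd.DataFrame,
    exposure: str,
    mediator: str = "hs_sic",
    outcome: str = "event",
    covariates: Sequence[str] = (),
    method: str = "delta",
    n_boot: int = 2000,
    seed: Optional[int] = None,
) -> MediationResult:
    """Convenience wrapper: build a :class:`MediationModel` and fit it."""
    model = MediationModel(
        table, exposure, mediator=mediator, outcome=outcome, covariates=covariates
    )
    return model.fit(method=method, n_boot=n_boot, seed=seed)


def mediation_table(
    table: pd.DataFrame,
    exposures: Sequence[str] = TABLE_EXPOSURES,
    mediator: str = "hs_sic",
    outcome: str = "event",
    adjustment: str = "mutual",
    method: str = "delta",
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """One mediation decomposition per risk factor.

    With ``adjustment="mutual"`` (default) each exposure's models adjust for
    all the other listed risk factors; ``adjustment="age_sex"`` adjusts for
    age and sex only.  Additivity direct + indirect = total holds row-wise.
    """
    missing = [e for e in exposures if e not in table.columns]
    if missing:
        raise ValueError(f"exposures absent from table: {missing}")
    rows = []
    for exposure in exposures:
        if adjustment == "mutual":
            covs = tuple(e for e in exposures if e != exposure)
        elif adjustment == "age_sex":
            covs = tuple(c for c in ("age", "sex") if c != exposure)
        else:
            raise ValueError(f"unknown adjustment scheme {adjustment!r}")
        res = fit_mediation(
            table, exposure, mediator=mediator, outcome=outcome,
            covariates=covs, method=method, seed=seed,
        )
        try:
            pm = res.proportion_mediated
        except ValueError:
            pm = np.nan
        rows.append({
            "exposure": exposure,
            "direct": res.direct, "direct_se": res.direct_se, "direct_p": res.direct_p,
            "indirect": res.indirect, "indirect_se": res.indirect_se,
            "indirect_p": res.indirect_p,
            "total": res.total, "total_se": res.total_se, "total_p": res.total_p,
            "proportion_mediated": pm,
            "inconsistent": res.inconsistent,
            "n": res.n,
        })
    return pd.DataFrame(rows)
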