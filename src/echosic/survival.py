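"""Cox proportional-hazards modelling of incident heart failure.

Implements the covariate ladder used for the HS-SIC / RWT exposures:

* model 0 — exposure(s) alone;
* model 1 — + sex, with the baseline hazard stratified by age quartile
  (age enters as stratification because it fails the proportional-hazards
  assumption as a covariate);
* model 2 — model 1 + antihypertensive treatment;
* model 3 — model 2 + BMI, systolic blood pressure, diabetes, smoking and
  total/HDL cholesterol ratio.

Each ladder cell is fitted in the total sample and separately in women and
men; pooled fits optionally carry a sex x exposure interaction.  Partial
likelihoods use the Efron tie correction.  Continuous covariates are
expected standardised (per overall-sample SD) so hazard ratios read
"per 1-SD".

Diagnostics: a Grambsch–Therneau scaled-Schoenfeld test of proportional
hazards (per covariate and global, identity time transform by default) and
a restricted-cubic-spline likelihood-ratio test of exposure non-linearity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

__all__ = [
    "LADDER_COVARIATES",
    "ModelSpec",
    "CoxFit",
    "PHDiagnostics",
    "IncidenceCurves",
    "CoxHazardsModel",
    "age_quartile_strata",
    "fit_cox",
    "sex_interaction_test",
    "schoenfeld_ph_test",
    "rcs_basis",
    "rcs_nonlinearity_test",
    "model_ladder",
    "cumulative_incidence_curves",
]

#: Nested adjustment sets of ladder stages 0-3 (age is handled by
#: stratification, not as a covariate).
LADDER_COVARIATES: dict[int, tuple[str, ...]] = {
    0: (),
    1: ("sex",),
    2: ("sex", "antihtn_tx"),
    3: ("sex", "antihtn_tx", "bmi", "sbp", "diabetes", "smoker", "tc_hdl_ratio"),
}

AGE_STRATUM_COL = "age_stratum"


@dataclass(frozen=True)
class ModelSpec:
    """One cell of the model ladder."""

    exposures: tuple[str, ...] = ("hs_sic",)
    model: int = 0
    stratum: str = "total"          # total | women | men
    interaction: bool = False       # sex x exposure terms (pooled fits only)
    strata_col: Optional[str] = None  # baseline-hazard strata (age quartiles)
    extra_covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.model not in LADDER_COVARIATES:
            raise ValueError(f"model stage must be 0-3, got {self.model}")
        if self.stratum not in ("total", "women", "men"):
            raise ValueError(f"unknown stratum {self.stratum!r}")
        if self.interaction and self.stratum != "total":
            raise ValueError("sex interaction requires the pooled sample")
        object.__setattr__(self, "exposures", tuple(self.exposures))
        object.__setattr__(self, "extra_covariates", tuple(self.extra_covariates))

    @property
    def covariates(self) -> tuple[str, ...]:
        cov = LADDER_COVARIATES[self.model] + self.extra_covariates
        if self.stratum != "total":
            cov = tuple(c for c in cov if c != "sex")
        return cov


@dataclass
class CoxFit:
    """Results of one Cox partial-likelihood fit.

    ``summary_frame`` has one row per coefficient with columns ``coef``,
    ``se``, ``hr``, ``ci_low``, ``ci_high``, ``p`` (Wald, log-HR scale).
    """

    spec: ModelSpec
    summary_frame: pd.DataFrame
    n: int
    n_events: int
    log_likelihood: float
    converged: bool
    fitter: CoxPHFitter = field(repr=False, default=None)
    training_frame: pd.DataFrame = field(repr=False, default=None)
    warnings_: tuple[str, ...] = ()

    def hr(self, term: str) -> float:
        return float(self.summary_frame.loc[term, "hr"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.summary_frame.loc[term]
        return float(row["ci_low"]), float(row["ci_high"])

    def p(self, term: str) -> float:
        return float(self.summary_frame.loc[term, "p"])

    def coef(self, term: str) -> float:
        return float(self.summary_frame.loc[term, "coef"])

    def se(self, term: str) -> float:
        return float(self.summary_frame.loc[term, "se"])

    def summary(self) -> str:
        lines = [
            f"Cox PH fit — model {self.spec.model}, stratum {self.spec.stratum}",
            f"n = {self.n}, events = {self.n_events}, "
            f"partial log-likelihood = {self.log_likelihood:.3f}",
            "",
            self.summary_frame.round(4).to_string(),
        ]
        if self.warnings_:
            lines += ["", "warnings:"] + [f"  - {w}" for w in self.warnings_]
        return "\n".join(lines)


@dataclass(frozen=True)
class PHDiagnostics:
    """Scaled-Schoenfeld proportional-hazards test results."""

    per_covariate: pd.DataFrame  # rows: covariate; cols: chi2, p
    global_chi2: float
    global_p: float
    transform: str = "identity"


@dataclass
class IncidenceCurves:
    """Kaplan–Meier complement (1 - S(t)) per exposure group."""

    group_col: str
    curves: dict[str, pd.DataFrame]  # label -> frame(time, cum_incidence)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for label, frame in self.curves.items():
            ax.step(frame["time"], frame["cum_incidence"], where="post", label=label)
        ax.set_xlabel("years")
        ax.set_ylabel("cumulative incidence")
        ax.legend()
        return ax


def age_quartile_strata(
    table: pd.DataFrame, age_col: str = "age", label_col: str = AGE_STRATUM_COL
) -> pd.DataFrame:
    """Label each subject with its age-quartile stratum Q1-Q4.

    Quartile cut points use linear-interpolation sample quantiles; boundary
    ties go to the lower stratum (right-closed intervals).
    """
    if age_col not in table.columns:
        raise ValueError(f"no {age_col!r} column")
    age = table[age_col].astype(float)
    if len(age) < 4:
        raise ValueError("need at least 4 subjects to form age quartiles")
    qs = np.quantile(age, [0.25, 0.5, 0.75])
    if len(np.unique(qs)) < 3 or age.min() == age.max():
        raise ValueError("degenerate age quartiles (ties at the cut points)")
    bins = [-np.inf, *qs, np.inf]
    labels = ["Q1", "Q2", "Q3", "Q4"]
    out = table.copy()
    out[label_col] = pd.cut(age, bins=bins, labels=labels, right=True).astype(str)
    counts = out[label_col].value_counts()
    empty = [l for l in labels if counts.get(l, 0) == 0]
    if empty:
        raise ValueError(f"empty age strata: {empty}")
    return out


def _subset_for_stratum(table: pd.DataFrame, stratum: str) -> pd.DataFrame:
    if stratum == "total":
        return table
    return table[table["sex"] == (1 if stratum == "women" else 0)]


def _prepare_design(
    table: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.DataFrame, list[str]]:
    data = _subset_for_stratum(table, spec.stratum)
    terms = list(spec.exposures) + [c for c in spec.covariates if c not in spec.exposures]
    if spec.interaction:
        for exp in spec.exposures:
            name = f"{exp}_x_sex"
            data = data.assign(**{name: data[exp] * data["sex"]})
            terms.append(name)
        if "sex" not in terms:
            terms.append("sex")
    cols = terms + ["time", "event"]
    if spec.strata_col:
        cols.append(spec.strata_col)
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"missing columns for Cox fit: {missing}")
    design = data[cols].copy()
    if design["event"].sum() == 0:
        raise ValueError(
            f"no events in the {spec.stratum!r} subset; cannot fit"
        )
    X = design[terms].astype(float).values
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X])) < X.shape[1] + 1:
        raise ValueError(f"rank-deficient design (collinear terms among {terms})")
    return design, terms


def fit_cox(table: pd.DataFrame, spec: ModelSpec) -> CoxFit:
    """Fit one Cox model (Efron ties, optional age-quartile baseline strata).

    Raises on empty event sets and rank-deficient designs; convergence and
    separation problems surface as recorded warnings on the result, never
    silently.
    """
    design, terms = _prepare_design(table, spec)
    cph = CoxPHFitter()
    caught: list[str] = []
    converged = True
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        try:
            cph.fit(
                design,
                duration_col="time",
                event_col="event",
                strata=[spec.strata_col] if spec.strata_col else None,
            )
        except Exception as exc:
            raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc
        for w in wlist:
            msg = str(w.message)
            caught.append(msg)
            if "convergence" in msg.lower() or "complete separation" in msg.lower():
                converged = False
    s = cph.summary
    frame = pd.DataFrame({
        "coef": s["coef"],
        "se": s["se(coef)"],
        "hr": s["exp(coef)"],
        "ci_low": s["exp(coef) lower 95%"],
        "ci_high": s["exp(coef) upper 95%"],
        "p": s["p"],
    })
    return CoxFit(
        spec=spec,
        summary_frame=frame,
        n=int(cph._n_examples),
        n_events=int(design["event"].sum()),
        log_likelihood=float(cph.log_likelihood_),
        converged=converged,
        fitter=cph,
        training_frame=design,
        warnings_=tuple(caught),
    )


class CoxHazardsModel:
    """Model object for the heart-failure Cox analyses of one cohort.

    Construct from a cohort table whose continuous covariates are already
    standardised (see :func:`echosic.cross_sectional.standardize_columns`);
    ``fit`` returns a :class:`CoxFit` results object, ``fit_ladder`` the
    full ladder results table.
    """

    def __init__(self, data: pd.DataFrame, stratify_age: bool = True):
        if stratify_age and AGE_STRATUM_COL not in data.columns:
            data = age_quartile_strata(data)
        self.data = data
        self.stratify_age = stratify_age

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "CoxHazardsModel":
        return cls(data, **kwargs)

    def _spec(self, **kwargs) -> ModelSpec:
        model = kwargs.get("model", 0)
        # model 0 is the exposure alone; stages 1+ stratify by age quartile
        if "strata_col" not in kwargs:
            kwargs["strata_col"] = (
                AGE_STRATUM_COL if (self.stratify_age and model >= 1) else None
            )
        return ModelSpec(**kwargs)

    def fit(self, **kwargs) -> CoxFit:
        return fit_cox(self.data, self._spec(**kwargs))

    def fit_ladder(self, **kwargs) -> pd.DataFrame:
        return model_ladder(self.data, stratify_age=self.stratify_age, **kwargs)


def sex_interaction_test(
    table: pd.DataFrame, spec: ModelSpec, exposure: Optional[str] = None
) -> float:
    """Wald p-value of the sex x exposure coefficient in the pooled model."""
    if table["sex"].nunique() < 2:
        raise ValueError("sex interaction needs both sexes present")
    for s in (0, 1):
        if table.loc[table["sex"] == s, "event"].sum() == 0:
            raise ValueError("sex interaction needs events in both sexes")
    exposure = exposure or spec.exposures[0]
    ispec = ModelSpec(
        exposures=spec.exposures,
        model=spec.model,
        stratum="total",
        interaction=True,
        strata_col=spec.strata_col,
        extra_covariates=spec.extra_covariates,
    )
    fit = fit_cox(table, ispec)
    return fit.p(f"{exposure}_x_sex")


_TIME_TRANSFORMS = {
    "identity": lambda t: t,
    "rank": lambda t: stats.rankdata(t),
    "log": np.log,
    "km": None,  # filled per-fit below
}


def schoenfeld_ph_test(
    fit: CoxFit, transform: str = "identity"
) -> PHDiagnostics:
    """Grambsch–Therneau proportional-hazards test from scaled Schoenfeld
    residuals: per-covariate chi-square (1 df) for association of the
    residuals with (transformed) event time, plus the global test.

    With ``g_k`` the centred transformed event times, ``s*_k`` the scaled
    Schoenfeld residuals, ``d`` the event count and ``V`` the coefficient
    covariance, the statistic is ``u' (d * sum(g^2) * V)^{-1} u`` with
    ``u = sum_k g_k s*_k``; the per-covariate version uses the diagonal.
    """
    if fit.fitter is None or fit.training_frame is None:
        raise ValueError("fit carries no training data")
    if fit.n_events < 2:
        raise ValueError("need at least 2 events to test proportional hazards")
    p = len(fit.summary_frame)
    if fit.n_events <= p:
        raise ValueError("fewer events than covariates; PH test undefined")
    resid = fit.fitter.compute_residuals(fit.training_frame, "scaled_schoenfeld")
    cols = list(fit.summary_frame.index)
    times = fit.training_frame.loc[resid.index, "time"].astype(float).values
    order = np.argsort(times)
    times = times[order]
    S = resid[cols].values[order]
    if transform == "km":
        km = KaplanMeierFitter().fit(
            fit.training_frame["time"], fit.training_frame["event"]
        )
        g = 1.0 - km.survival_function_at_times(times).values
    else:
        try:
            g = np.asarray(_TIME_TRANSFORMS[transform](times), dtype=float)
        except KeyError:
            raise ValueError(f"unknown time transform {transform!r}") from None
    g = g - g.mean()
    d = len(S)
    V = fit.fitter.variance_matrix_.loc[cols, cols].values
    u = S.T @ g
    denom = d * float(np.sum(g * g))
    per_chi2 = u**2 / (denom * np.diag(V))
    per_p = stats.chi2.sf(per_chi2, df=1)
    global_chi2 = float(u @ np.linalg.solve(denom * V, u))
    global_p = float(stats.chi2.sf(global_chi2, df=p))
    frame = pd.DataFrame({"chi2": per_chi2, "p": per_p}, index=cols)
    return PHDiagnostics(
        per_covariate=frame, global_chi2=global_chi2, global_p=global_p,
        transform=transform,
    )


def rcs_basis(
    x: np.ndarray, knots: Sequence[float]
) -> np.ndarray:
    """Restricted cubic spline basis (Harrell's truncated-power form).

    Returns the k-2 non-linear basis columns for knots t_1..t_k; the full
    spline design is the linear term plus these columns.  The basis is
    linear beyond the boundary knots and is normalised by (t_k - t_1)^2.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(sorted(knots), dtype=float)
    k = len(t)
    if k < 3:
        raise ValueError("restricted cubic spline needs at least 3 knots")
    norm = (t[-1] - t[0]) ** 2
    if norm == 0:
        raise ValueError("degenerate knots")
    cube = lambda u: np.maximum(u, 0.0) ** 3
    cols = []
    for j in range(k - 2):
        col = (
            cube(x - t[j])
            - cube(x - t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
            + cube(x - t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2])
        ) / norm
        cols.append(col)
    return np.column_stack(cols)


def rcs_nonlinearity_test(
    table: pd.DataFrame,
    exposure: str = "hs_sic",
    n_knots: int = 4,
    knot_quantiles: Optional[Sequence[float]] = None,
    covariates: Sequence[str] = (),
    strata_col: Optional[str] = None,
) -> float:
    """Likelihood-ratio test of spline vs linear exposure effect in Cox.

    Knots sit at the (0.05, 0.35, 0.65, 0.95) exposure quantiles for the
    default 4 knots (Harrell's recommended placement); the test has k-2
    degrees of freedom.
    """
    x = table[exposure].astype(float).values
    if len(np.unique(x)) < n_knots:
        raise ValueError(
            f"exposure {exposure!r} has fewer distinct values than knots"
        )
    if knot_quantiles is None:
        knot_quantiles = {
            3: (0.10, 0.50, 0.90),
            4: (0.05, 0.35, 0.65, 0.95),
            5: (0.05, 0.275, 0.50, 0.725, 0.95),
        }.get(n_knots)
        if knot_quantiles is None:
            knot_quantiles = tuple(np.linspace(0.05, 0.95, n_knots))
    knots = np.quantile(x, knot_quantiles)
    if len(np.unique(knots)) < n_knots:
        raise ValueError("tied knots; exposure distribution too discrete")
    basis = rcs_basis(x, knots)
    spline_cols = [f"{exposure}_rcs{j + 1}" for j in range(basis.shape[1])]
    data = table.copy()
    for j, c in enumerate(spline_cols):
        data[c] = basis[:, j]

    def _ll(exposures: tuple[str, ...]) -> float:
        spec = ModelSpec(
            exposures=exposures, model=0, strata_col=strata_col,
            extra_covariates=tuple(covariates),
        )
        return fit_cox(data, spec).log_likelihood

    ll_lin = _ll((exposure,))
    ll_spl = _ll((exposure, *spline_cols))
    lr = 2.0 * (ll_spl - ll_lin)
    return float(stats.chi2.sf(max(lr, 0.0), df=len(spline_cols)))


def model_ladder(
    table: pd.DataFrame,
    exposure_sets: Sequence[tuple[str, ...]] = (("hs_sic",), ("rwt",), ("hs_sic", "rwt")),
    stratify_age: bool = True,
) -> pd.DataFrame:
    """Run models 0-3 x {total, women, men} x exposure sets.

    Returns a tidy frame with one row per (exposure set, model, stratum,
    exposure term): hazard ratio per 1-SD, Wald CI and p, the pooled-sample
    sex-interaction p, and the n / event counts.
    """
    if stratify_age and AGE_STRATUM_COL not in table.columns:
        table = age_quartile_strata(table)
    rows = []
    for exposures in exposure_sets:
        for model in sorted(LADDER_COVARIATES):
            strata_col = AGE_STRATUM_COL if (stratify_age and model >= 1) else None
            interaction_p: dict[str, float] = {}
            for stratum in ("total", "women", "men"):
                spec = ModelSpec(
                    exposures=tuple(exposures), model=model, stratum=stratum,
                    strata_col=strata_col,
                )
                fit = fit_cox(table, spec)
                if stratum == "total":
                    for exp in exposures:
                        try:
                            interaction_p[exp] = sex_interaction_test(
                                table, spec, exposure=exp
                            )
                        except ValueError:
                            interaction_p[exp] = np.nan
                for exp in exposures:
                    rows.append({
                        "exposure_set": "+".join(exposures),
                        "model": model,
                        "stratum": stratum,
                        "term": exp,
                        "hr": fit.hr(exp),
                        "ci_low": fit.ci(exp)[0],
                        "ci_high": fit.ci(exp)[1],
                        "p": fit.p(exp),
                        "interaction_p": interaction_p.get(exp, np.nan)
                        if stratum == "total" else np.nan,
                        "n": fit.n,
                        "n_events": fit.n_events,
                    })
    return pd.DataFrame(rows)


def cumulative_incidence_curves(
    table: pd.DataFrame,
    exposure: str = "hs_sic",
    quantile: float = 0.75,
    by_sex: bool = False,
) -> IncidenceCurves:
    """Unadjusted cumulative incidence (1 - KM survival) comparing the top
    fourth of the exposure with the lower three-fourths."""
    x = table[exposure].astype(float)
    cut = float(np.quantile(x, quantile))
    top = x > cut
    groups: dict[str, pd.DataFrame] = {}
    subsets = {"": table.assign(_top=top)}
    if by_sex:
        subsets = {
            "women ": table.assign(_top=top)[table["sex"] == 1],
            "men ": table.assign(_top=top)[table["sex"] == 0],
        }
    for prefix, sub in subsets.items():
        for label, flag in (("top fourth", True), ("lower three-fourths", False)):
            grp = sub[sub["_top"] == flag]
            if grp.empty:
                raise ValueError(f"empty exposure group {prefix}{label!r}")
            km = KaplanMeierFitter().fit(grp["time"], grp["event"])
            sf = km.survival_function_
            groups[f"{prefix}{label}"] = pd.DataFrame({
                "time": sf.index.values,
                "cum_incidence": 1.0 - sf.iloc[:, 0].values,
            })
    return IncidenceCurves(group_col=f"{exposure}>{cut:.4g}", curves=groups)
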