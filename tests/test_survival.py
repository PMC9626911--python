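"""Cox model ladder, proportional-hazards and non-linearity diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from echosic.simulate import CohortSimConfig, synth_cohort
from echosic.survival import (
    AGE_STRATUM_COL,
    CoxHazardsModel,
    ModelSpec,
    age_quartile_strata,
    cumulative_incidence_curves,
    fit_cox,
    model_ladder,
    rcs_basis,
    rcs_nonlinearity_test,
    schoenfeld_ph_test,
    sex_interaction_test,
)


def _toy_survival(rng, n=400, beta=(0.3, -0.2), rate=2.0, cmax=10.0):
    df = pd.DataFrame({f"x{i+1}": rng.normal(size=n) for i in range(len(beta))})
    lp = sum(b * df[f"x{i+1}"] for i, b in enumerate(beta))
    te = rng.exponential(np.exp(-(lp - math.log(1.0 / rate))))
    c = rng.uniform(cmax / 5, cmax, n)
    df["time"] = np.minimum(te, c)
    df["event"] = (te <= c).astype(int)
    return df


class TestAgeQuartiles:
    def test_even_split(self):
        df = pd.DataFrame({"age": np.arange(1, 101, dtype=float)})
        out = age_quartile_strata(df)
        assert out[AGE_STRATUM_COL].value_counts().tolist() == [25, 25, 25, 25]

    def test_degenerate_ages_rejected(self):
        with pytest.raises(ValueError):
            age_quartile_strata(pd.DataFrame({"age": [50.0] * 20}))

    def test_matches_rank_based_oracle(self):
        ages = np.arange(1, 102, dtype=float)
        out = age_quartile_strata(pd.DataFrame({"age": ages}))
        qs = np.quantile(ages, [0.25, 0.5, 0.75])
        # independent assignment: count ranks on each side of the cuts,
        # boundary ties to the lower stratum
        expected = np.searchsorted(qs, ages, side="left")
        exp_sizes = pd.Series(expected).value_counts().sort_index().tolist()
        got_sizes = (
            out[AGE_STRATUM_COL].value_counts().reindex(["Q1", "Q2", "Q3", "Q4"]).tolist()
        )
        assert got_sizes == exp_sizes

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            age_quartile_strata(pd.DataFrame({"age": [1.0, 2.0]}))


class TestFitCox:
    def test_duplicate_covariate_rejected(self, rng):
        df = _toy_survival(rng)
        df["x1_copy"] = df["x1"]
        with pytest.raises(ValueError, match="rank"):
            fit_cox(df, ModelSpec(exposures=("x1", "x1_copy"), model=0))

    def test_no_events_rejected(self, rng):
        df = _toy_survival(rng, n=50)
        df["event"] = 0
        with pytest.raises(ValueError, match="events"):
            fit_cox(df, ModelSpec(exposures=("x1",), model=0))

    def test_per_sd_hr_invariant_to_rescaling(self, rng):
        """Rescaling a raw covariate leaves its per-SD hazard ratio unchanged."""
        df = _toy_survival(rng)
        def per_sd_hr(frame):
            z = frame.assign(x1=(frame.x1 - frame.x1.mean()) / frame.x1.std(ddof=1))
            return fit_cox(z, ModelSpec(exposures=("x1",), model=0)).hr("x1")
        hr1 = per_sd_hr(df)
        hr2 = per_sd_hr(df.assign(x1=df.x1 * 37.5))
        assert hr1 == pytest.approx(hr2, rel=1e-9)

    def test_null_type_one_error(self, rng):
        """Exposure permuted against outcomes: ~5% Wald rejections."""
        hits = 0
        R = 200
        df = _toy_survival(rng, n=150, beta=(0.5,))
        for _ in range(R):
            perm = df.assign(x1=rng.permutation(df.x1.values))
            hits += fit_cox(perm, ModelSpec(exposures=("x1",), model=0)).p("x1") < 0.05
        assert 0.02 <= hits / R <= 0.09

    def test_women_hr_recovery_at_large_n(self, large_cohort):
        """Women-specific per-SD HS-SIC log-HR within 2 SE of the configured
        truth (exp = 1.67) in the fully adjusted fit."""
        df, truth = large_cohort
        z = df.copy()
        for c in ("hs_sic", "rwt", "age", "bmi", "sbp", "tc_hdl_ratio"):
            z[c] = (z[c] - z[c].mean()) / z[c].std(ddof=1)
        extra = ("age", "bmi", "sbp", "tc_hdl_ratio", "diabetes", "smoker",
                 "antihtn_tx", "rwt")
        fit = fit_cox(z, ModelSpec(exposures=("hs_sic",), model=0,
                                   stratum="women", extra_covariates=extra))
        true_lhr = truth.config["log_hr_women"]
        assert abs(fit.coef("hs_sic") - true_lhr) < 2 * fit.se("hs_sic")

    def test_stratified_fit_matches_unstratified_under_shared_baseline(self, rng):
        """With a common baseline hazard, stratifying changes nothing but
        efficiency: coefficients agree closely at moderate n."""
        df = _toy_survival(rng, n=4000, beta=(0.4,))
        df["grp"] = rng.integers(0, 4, len(df)).astype(str)
        plain = fit_cox(df, ModelSpec(exposures=("x1",), model=0))
        strat = fit_cox(df, ModelSpec(exposures=("x1",), model=0, strata_col="grp"))
        assert strat.coef("x1") == pytest.approx(plain.coef("x1"), abs=0.05)


class TestSexInteraction:
    def test_power_under_true_difference(self):
        cfg = CohortSimConfig(n=20_000, log_hr_women=math.log(2.0),
                              log_hr_men=0.0, seed=31)
        df, _ = synth_cohort(cfg)
        df["hs_sic"] = (df.hs_sic - df.hs_sic.mean()) / df.hs_sic.std(ddof=1)
        df = age_quartile_strata(df)
        p = sex_interaction_test(
            df, ModelSpec(model=1, strata_col=AGE_STRATUM_COL)
        )
        assert p < 0.01

    def test_null_calibration_small(self):
        """Equal sex effects: interaction test rejects at ~nominal rate."""
        hits, R = 0, 60
        for seed in range(R):
            cfg = CohortSimConfig(n=600, log_hr_women=0.3, log_hr_men=0.3,
                                  target_event_fraction=0.15, seed=5000 + seed)
            df, _ = synth_cohort(cfg)
            df["hs_sic"] = (df.hs_sic - df.hs_sic.mean()) / df.hs_sic.std(ddof=1)
            p = sex_interaction_test(df, ModelSpec(model=1))
            hits += p < 0.05
        assert hits / R <= 0.15

    def test_sex_relabelling_symmetry(self, std_cohort):
        df, _ = std_cohort
        spec = ModelSpec(model=1, strata_col=AGE_STRATUM_COL)
        p1 = sex_interaction_test(df, spec)
        flipped = df.assign(sex=1 - df["sex"])
        p2 = sex_interaction_test(flipped, spec)
        assert p1 == pytest.approx(p2, rel=1e-6)

    def test_single_sex_rejected(self, std_cohort):
        df, _ = std_cohort
        with pytest.raises(ValueError):
            sex_interaction_test(df[df.sex == 1], ModelSpec(model=1))


class TestSchoenfeld:
    def test_matches_lifelines_reference(self, rng):
        from lifelines.statistics import proportional_hazard_test

        df = _toy_survival(rng, n=500, beta=(0.4, -0.3))
        fit = fit_cox(df, ModelSpec(exposures=("x1", "x2"), model=0))
        mine = schoenfeld_ph_test(fit)
        ref = proportional_hazard_test(fit.fitter, fit.training_frame,
                                       time_transform="identity")
        np.testing.assert_allclose(
            mine.per_covariate["chi2"].values,
            ref.summary["test_statistic"].values, rtol=1e-8,
        )

    def test_constructed_violation_detected(self, rng):
        """A covariate whose effect flips sign mid-follow-up violates PH."""
        n = 6000
        x = rng.normal(size=n)
        # piecewise hazard: beta=+1 before t*=1, -1 after
        u = rng.exponential(size=n)
        h1 = 0.5 * np.exp(x)
        t = u / h1
        late = t > 1.0
        h2 = 0.5 * np.exp(-x[late])
        t[late] = 1.0 + (u[late] - h1[late]) / np.maximum(h2, 1e-9)
        t = np.abs(t) + 1e-6
        c = rng.uniform(0.5, 4.0, n)
        df = pd.DataFrame({
            "x1": x, "time": np.minimum(t, c), "event": (t <= c).astype(int),
        })
        fit = fit_cox(df, ModelSpec(exposures=("x1",), model=0))
        diag = schoenfeld_ph_test(fit)
        assert diag.per_covariate.loc["x1", "p"] < 0.01
        assert diag.global_p < 0.01

    def test_single_event_rejected(self, rng):
        df = _toy_survival(rng, n=30)
        df["event"] = 0
        df.loc[0, "event"] = 1
        fit_df = df
        with pytest.raises(ValueError):
            fit = fit_cox(fit_df, ModelSpec(exposures=("x1",), model=0))
            schoenfeld_ph_test(fit)

    def test_rank_transform_available(self, rng):
        df = _toy_survival(rng, n=300)
        fit = fit_cox(df, ModelSpec(exposures=("x1", "x2"), model=0))
        diag = schoenfeld_ph_test(fit, transform="rank")
        assert ((0 <= diag.per_covariate["p"]) & (diag.per_covariate["p"] <= 1)).all()


class TestSplines:
    def test_basis_matches_textbook_recursion(self):
        """The spline basis equals the truncated-power restricted-cubic
        form computed independently, term by term (1e-10)."""
        knots = [-1.2, 0.1, 0.9, 2.3]
        x = np.linspace(-3, 4, 101)
        got = rcs_basis(x, knots)
        t = knots
        norm = (t[3] - t[0]) ** 2

        def plus3(v):
            return max(v, 0.0) ** 3

        for j in range(2):
            expected = [
                (
                    plus3(xi - t[j])
                    - plus3(xi - t[2]) * (t[3] - t[j]) / (t[3] - t[2])
                    + plus3(xi - t[3]) * (t[2] - t[j]) / (t[3] - t[2])
                ) / norm
                for xi in x
            ]
            np.testing.assert_allclose(got[:, j], expected, atol=1e-10)

    def test_basis_linear_beyond_boundary_knots(self):
        knots = [0.0, 1.0, 2.0, 3.0]
        x = np.linspace(4, 8, 50)
        b = rcs_basis(x, knots)
        for j in range(b.shape[1]):
            slopes = np.diff(b[:, j]) / np.diff(x)
            np.testing.assert_allclose(slopes, slopes[0], rtol=1e-8)

    def test_quadratic_hazard_detected(self, rng):
        """A quadratic log-hazard in the exposure rejects linearity."""
        n = 20_000
        x = rng.normal(size=n)
        lp = 0.4 * x**2
        te = rng.exponential(np.exp(-lp) / 0.15)  # baseline rate 0.15/y
        c = rng.uniform(1, 8, n)
        df = pd.DataFrame({
            "hs_sic": x, "time": np.minimum(te, c), "event": (te <= c).astype(int),
        })
        assert rcs_nonlinearity_test(df) < 0.01

    def test_insufficient_distinct_values(self):
        df = pd.DataFrame({
            "hs_sic": [1.0, 2.0, 1.0, 2.0] * 10,
            "time": np.arange(1, 41, dtype=float),
            "event": [1, 0] * 20,
        })
        with pytest.raises(ValueError):
            rcs_nonlinearity_test(df)


class TestLadderAndCurves:
    def test_model0_row_equals_direct_fit(self, std_cohort):
        df, _ = std_cohort
        ladder = model_ladder(df, exposure_sets=(("hs_sic",),))
        row = ladder.query("model == 0 and stratum == 'total' and term == 'hs_sic'")
        direct = fit_cox(df, ModelSpec(exposures=("hs_sic",), model=0))
        assert row["hr"].iloc[0] == pytest.approx(direct.hr("hs_sic"), rel=1e-9)

    def test_event_counts_partition_by_sex(self, std_cohort):
        df, _ = std_cohort
        ladder = model_ladder(df, exposure_sets=(("hs_sic",),))
        m1 = ladder[(ladder.model == 1) & (ladder.term == "hs_sic")].set_index("stratum")
        assert (
            m1.loc["women", "n_events"] + m1.loc["men", "n_events"]
            == m1.loc["total", "n_events"]
        )

    def test_loglik_nesting(self, std_cohort):
        """Partial log-likelihood never decreases up the covariate ladder."""
        df, _ = std_cohort
        lls = [
            fit_cox(df, ModelSpec(exposures=("hs_sic",), model=m,
                                  strata_col=AGE_STRATUM_COL)).log_likelihood
            for m in range(4)
        ]
        assert all(b >= a - 1e-8 for a, b in zip(lls, lls[1:]))

    def test_sex_reversal_direction_recovery(self):
        """HS-SIC effect only in women + RWT effect only in men reproduces
        the qualitative sexual dimorphism in the fitted ladder."""
        cfg = CohortSimConfig(
            n=20_000,
            log_hr_women=math.log(1.8), log_hr_men=0.0,
            log_hr_rwt_women=0.0, log_hr_rwt_men=math.log(1.8),
            seed=77,
        )
        df, _ = synth_cohort(cfg)
        for c in ("hs_sic", "rwt", "bmi", "sbp", "tc_hdl_ratio"):
            df[c] = (df[c] - df[c].mean()) / df[c].std(ddof=1)
        df = age_quartile_strata(df)
        ladder = model_ladder(df, exposure_sets=(("hs_sic", "rwt"),))
        m3 = ladder[ladder.model == 3].set_index(["stratum", "term"])
        assert m3.loc[("women", "hs_sic"), "hr"] > m3.loc[("men", "hs_sic"), "hr"]
        assert m3.loc[("men", "rwt"), "hr"] > m3.loc[("women", "rwt"), "hr"]

    def test_km_hand_worked_product_limit(self):
        """KM complement on a 5-subject dataset matches hand arithmetic."""
        df = pd.DataFrame({
            "hs_sic": [10.0, 10.0, 1.0, 1.0, 1.0],
            "time": [1.0, 3.0, 2.0, 4.0, 5.0],
            "event": [1, 1, 1, 0, 1],
        })
        curves = cumulative_incidence_curves(df, quantile=0.5)
        top = curves.curves["top fourth"].set_index("time")["cum_incidence"]
        # top group: events at t=1 (2 at risk) and t=3 (1 at risk)
        assert top.loc[1.0] == pytest.approx(0.5)
        assert top.loc[3.0] == pytest.approx(1.0)
        low = curves.curves["lower three-fourths"].set_index("time")["cum_incidence"]
        # lower group: event t=2 (3 at risk) -> 1/3; censor t=4; event t=5
        assert low.loc[2.0] == pytest.approx(1.0 / 3.0)
        assert low.loc[5.0] == pytest.approx(1.0)

    def test_no_events_flat_curves(self):
        df = pd.DataFrame({
            "hs_sic": np.linspace(0, 4, 40),
            "time": np.full(40, 5.0),
            "event": np.zeros(40, dtype=int),
        })
        curves = cumulative_incidence_curves(df)
        for frame in curves.curves.values():
            assert np.allclose(frame["cum_incidence"], 0.0)


def test_model_object_surface(std_cohort):
    """CoxHazardsModel exposes the fit/summary results-object workflow."""
    df, _ = std_cohort
    model = CoxHazardsModel.from_dataframe(df)
    res = model.fit(model=1, stratum="women")
    assert res.n_events <= res.n
    assert res.hr("hs_sic") == pytest.approx(math.exp(res.coef("hs_sic")))
    lo, hi = res.ci("hs_sic")
    assert lo < res.hr("hs_sic") < hi
    assert "Cox PH fit" in res.summary()
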