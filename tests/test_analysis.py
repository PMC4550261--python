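"""Collinearity screen, hurdle fits, LRT machinery, re-leveling, ZI check."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from pregsignal.analysis import (
    ModelSpec,
    fit_glmm,
    fit_hurdle,
    fit_lme,
    lrt,
    screen_collinearity,
    zero_inflation_check,
)
from pregsignal.mixedglm import Binomial, Gaussian


def sim_focal_frame(rng, nf=5, nd=30, b1=0.0, b2=0.0, base=-0.5,
                    re_f=0.5, re_d=0.5):
    """Study-shaped occurrence data: 5 females x 30 dates, 3 period blocks."""
    fem = np.repeat(np.arange(nf), nd)
    dat = np.tile(np.arange(nd), nf)
    period = np.where(dat < nd // 3, "PCP",
                      np.where(dat < 2 * nd // 3, "month1", "month2"))
    uf = rng.normal(0, re_f, nf)
    ud = rng.normal(0, re_d, nd)
    ages = np.resize(np.array([8.0, 9, 11, 13, 17]), nf)
    eta = base + b1 * (period == "month1") + b2 * (period == "month2")
    eta = eta + uf[fem] + ud[dat]
    y = (rng.random(nf * nd) < expit(eta)).astype(int)
    return pd.DataFrame(
        {
            "female_id": [f"F{i+1}" for i in fem],
            "date": dat,
            "period": period,
            "age": ages[fem],
            "beh_count": y,  # occurrence-only behavior (counts 0/1)
        }
    )


class TestScreenCollinearity:
    def test_perfectly_associated_flags_give_phi_one(self):
        # 2x2 table [[5,0],[0,5]] as two identical binary behaviors
        df = pd.DataFrame({"a_count": [1] * 5 + [0] * 5,
                           "b_count": [1] * 5 + [0] * 5})
        report, retained, dropped = screen_collinearity(df, ["a", "b"])
        assert report["phi"].iloc[0] == pytest.approx(1.0)
        assert len(retained) == 1

    def test_independent_flags_have_small_phi(self, rng):
        n = 10_000
        df = pd.DataFrame({
            "a_count": (rng.random(n) < 0.3).astype(int),
            "b_count": (rng.random(n) < 0.3).astype(int),
        })
        report, retained, dropped = screen_collinearity(df, ["a", "b"])
        assert abs(report["phi"].iloc[0]) < 0.05
        assert retained == ["a", "b"] and not dropped

    def test_contact_dropped_grooming_retained(self, default_study):
        """Planted grooming-contact collinearity (~0.77) is caught and the
        aggregate (contact) is dropped in favor of grooming."""
        report, retained, dropped = screen_collinearity(
            default_study.focals,
            ["female_approach", "grooming_female", "grooming_male",
             "estrus_call", "male_holding", "contact"],
        )
        assert dropped.get("contact") == "grooming_female"
        assert "grooming_female" in retained
        row = report[(report["behavior_a"] == "grooming_female")
                     & (report["behavior_b"] == "contact")]
        assert 0.6 < row["phi"].iloc[0] < 0.9

    def test_zero_variance_behavior_reported_not_screened(self, default_study):
        report, retained, _ = screen_collinearity(
            default_study.focals, ["female_approach", "female_presentation",
                                   "grooming_female"],
        )
        assert "female_presentation" not in retained
        assert (report["behavior_a"] == "female_presentation").any()

    def test_too_small_input_rejected(self):
        df = pd.DataFrame({"a_count": [1, 0], "b_count": [0, 1]})
        with pytest.raises(ValueError):
            screen_collinearity(df, ["a", "b"])


class TestHurdle:
    def test_all_zero_response_degenerate_and_refused(self, rng):
        df = sim_focal_frame(rng)
        df["beh_count"] = 0
        fit = fit_hurdle(df, ModelSpec(response="beh"))
        assert fit.binary is None and fit.count is None
        assert any("degenerate" in f for f in fit.flags)
        assert any("refused" in f for f in fit.flags)

    def test_sparse_count_part_refused_with_message(self, rng):
        df = sim_focal_frame(rng)
        df["beh_count"] = 0
        df.loc[df.index[:3], "beh_count"] = 2
        fit = fit_hurdle(df, ModelSpec(response="beh"))
        assert fit.count is None
        assert any("only 3 positive" in f for f in fit.flags)

    def test_loglik_decomposes_exactly(self, default_study):
        roster = default_study.roster
        df = default_study.focals.merge(
            roster[["female_id", "age"]], on="female_id")
        fit = fit_hurdle(df, ModelSpec(response="female_approach"))
        assert fit.binary is not None and fit.count is not None
        assert fit.loglik == pytest.approx(fit.binary.loglik + fit.count.loglik,
                                           abs=1e-12)
        assert fit.df_model == fit.binary.df_model + fit.count.df_model


class TestLme:
    def test_exact_linear_status_effect_zero_residual(self, rng):
        df = sim_focal_frame(rng)
        df["y"] = (1.0 + 0.5 * (df["period"] == "month1")
                   - 0.3 * (df["period"] == "month2"))
        fit = fit_lme(df, ModelSpec(response="y"))
        assert fit.aux["sigma_resid"] < 1e-3
        assert fit.beta[1] == pytest.approx(0.5, abs=1e-3)

    def test_null_effect_ci_coverage(self):
        """95% CI for the month1 coefficient covers 0 at ~nominal rate."""
        cover = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            df = sim_focal_frame(rng, re_f=0.3, re_d=0.3)
            df["y"] = rng.normal(1.0, 0.5, len(df)) + \
                rng.normal(0, 0.3, 5)[pd.factorize(df["female_id"])[0]]
            fit = fit_lme(df, ModelSpec(response="y"))
            i = fit.beta_names.index("status[month1]")
            se = fit.bse()[i]
            if abs(fit.beta[i]) <= 1.96 * se:
                cover += 1
        assert 0.89 <= cover / n_rep <= 0.99


class TestLrt:
    def _dummy(self, ll, df, n=100):
        return SimpleNamespace(loglik=ll, df_model=df, n_obs=n)

    def test_identical_models_give_zero_statistic(self):
        res = lrt(self._dummy(-50.0, 5), self._dummy(-50.0, 3))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_chi_square_quantile(self):
        res = lrt(self._dummy(-50.0, 4), self._dummy(-51.92, 3))
        assert res.delta_df == 1
        assert res.p_value == pytest.approx(0.050, abs=0.002)

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError):
            lrt(self._dummy(-50, 3), self._dummy(-51, 3))
        with pytest.raises(ValueError):
            lrt(self._dummy(-50, 4, n=100), self._dummy(-51, 3, n=90))


class TestRelevel:
    def test_reparameterization_invariance(self, rng):
        df = sim_focal_frame(rng, b1=-1.0, b2=-0.5)
        spec = ModelSpec(response="beh")
        y = (df["beh_count"] > 0).astype(float)
        base = fit_glmm(df, spec, Binomial(), y=y)
        relev = fit_glmm(df, spec.releveled("month1"), Binomial(), y=y)
        assert relev.loglik == pytest.approx(base.loglik, abs=1e-4)
        # PCP-vs-month1 = -(month1-vs-PCP)
        i = base.beta_names.index("status[month1]")
        j = relev.beta_names.index("status[PCP]")
        assert relev.beta[j] == pytest.approx(-base.beta[i], abs=0.01)

    def test_contrast_matches_pairwise_subset_refit(self, rng):
        df = sim_focal_frame(rng, b1=-1.0, b2=-0.4, re_f=0.0, re_d=0.0)
        spec = ModelSpec(response="beh")
        y = (df["beh_count"] > 0).astype(float)
        relev = fit_glmm(df, spec.releveled("month1"), Binomial(), y=y)
        k = relev.beta_names.index("status[month2]")
        sub = df[df["period"].isin(["month1", "month2"])]
        subspec = ModelSpec(response="beh", levels=("month1", "month2"),
                            baseline="month1")
        direct = fit_glmm(sub, subspec, Binomial(),
                          y=(sub["beh_count"] > 0).astype(float))
        kd = direct.beta_names.index("status[month2]")
        assert relev.beta[k] == pytest.approx(direct.beta[kd], abs=0.35)

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(response="beh").releveled("month9")


class TestZeroInflation:
    def _sim(self, seed, pi=0.0, n=1500):
        # inflation is only identifiable when the occurrence probability
        # varies with a model covariate, so age drives occurrence here
        rng = np.random.default_rng(seed)
        ages = rng.uniform(8, 17, n)
        p = expit(-0.5 + 0.6 * (ages - 12.0))
        y = (rng.random(n) < p).astype(int)
        if pi > 0:
            y[rng.random(n) < pi] = 0
        return pd.DataFrame({
            "female_id": "F1", "date": np.arange(n),
            "period": rng.choice(["PCP", "month1", "month2"], n),
            "age": ages, "beh_count": y,
        })

    @pytest.mark.parametrize("pi,expect", [(0.0, "binomial"), (0.4, "zero_inflated")])
    def test_structure_selection(self, pi, expect):
        spec = ModelSpec(response="beh", groups=())
        wins = 0
        n_rep = 100
        for seed in range(n_rep):
            df = self._sim(seed, pi=pi)
            rep = zero_inflation_check(df, spec)
            wins += rep.chosen == expect
        assert wins / n_rep >= 0.90


class TestConsistency:
    def test_status_coefficient_mse_shrinks_with_n(self):
        """Estimator consistency: error shrinks as focals per female grow."""
        truth = -1.5
        mse = {}
        for nd in (30, 90, 300):  # 10/30/100 dates per period block
            errs = []
            for seed in range(30):
                rng = np.random.default_rng(1000 * nd + seed)
                df = sim_focal_frame(rng, nd=nd, b1=truth, b2=-0.8, base=0.5)
                fit = fit_glmm(df, ModelSpec(response="beh"), Binomial(),
                               y=(df["beh_count"] > 0).astype(float))
                errs.append(fit.beta[fit.beta_names.index("status[month1]")] - truth)
            mse[nd] = float(np.mean(np.square(errs)))
        assert mse[300] < mse[30]
        assert abs(np.sqrt(mse[300])) < 0.45
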