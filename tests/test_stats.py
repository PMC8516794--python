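"""Mixed-model machinery: closed-form identities, cross-checks against
independent implementations, model comparison, and the RM-ANOVA."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from scipy.special import expit

from earoddball import recovery
from earoddball.stats import (
    GlmmSpec,
    ModelFit,
    compare_models,
    fit_glmm,
    rm_anova,
    wald_chisq,
)


def make_fit(beta, se, loglik=0.0, n_params=4, family="gaussian", link="identity"):
    spec = GlmmSpec("y", "x", family, link)
    return ModelFit(
        spec=spec,
        levels=("a", "b"),
        beta_link=np.asarray(beta, float),
        se_link=np.asarray(se, float),
        loglik=loglik,
        vc={},
        dispersion={},
        n_params=n_params,
        n_obs=100,
        response_scale_summary={},
        data_token="tok",
    )


class TestWald:
    def test_closed_form(self):
        chi2, df, p = wald_chisq(make_fit([0.0, 2.0], [1.0, 1.0]), "slope")
        assert chi2 == 4.0 and df == 1
        assert p == pytest.approx(0.0455, abs=1e-3)

    def test_zero_coefficient(self):
        chi2, _, p = wald_chisq(make_fit([1.0, 0.0], [1.0, 1.0]), "slope")
        assert chi2 == 0.0 and p == 1.0

    def test_agrees_with_squared_z_test(self, rng):
        for _ in range(20):
            b, se = rng.normal(), rng.gamma(2.0)
            chi2, _, p = wald_chisq(make_fit([0.0, b], [1.0, se]), "slope")
            p_z = 2 * sps.norm.sf(abs(b / se))
            assert p == pytest.approx(p_z, rel=1e-10)

    def test_missing_coefficient(self):
        with pytest.raises(KeyError):
            wald_chisq(make_fit([0, 1], [1, 1]), "nonsense")


def _glmm_data(rng, family, beta, n_groups=8, n_per=120, shape=7.0):
    rows = []
    for g in range(n_groups):
        x = np.r_[np.zeros(n_per // 2), np.ones(n_per // 2)]
        eta = beta[0] + beta[1] * x
        if family == "inverse_gaussian":
            mu = 1 / eta
            y = sps.invgauss.rvs(mu / shape, scale=shape, random_state=rng)
        elif family == "binomial":
            y = (rng.random(n_per) < expit(eta)).astype(float)
        else:
            y = eta + rng.normal(0, 1.0, n_per)
        rows.append(pd.DataFrame({"participant": g, "x": np.where(x > 0, "b", "a"), "y": y}))
    return pd.concat(rows, ignore_index=True)


class TestFitGlmm:
    def test_matches_statsmodels_glm_when_no_random_effects(self, rng):
        """With zero between-group spread the GLMM collapses to a GLM."""
        data = _glmm_data(rng, "inverse_gaussian", (0.91, -0.39), n_per=300)
        fit = fit_glmm(
            data, GlmmSpec("y", "x", "inverse_gaussian", "inverse", reference="a")
        )
        glm = sm.GLM(
            data.y,
            sm.add_constant((data.x == "b").astype(float)),
            family=sm.families.InverseGaussian(sm.families.links.InversePower()),
        ).fit()
        np.testing.assert_allclose(fit.beta_link, glm.params.to_numpy(), atol=0.02)

    def test_gaussian_lmm_matches_mixedlm(self, rng):
        """Independent-intercept/slope LMM against statsmodels MixedLM."""
        rows = []
        for g in range(10):
            b0, b1 = rng.normal(0, [0.5, 0.4])
            x = np.r_[np.zeros(60), np.ones(60)]
            y = 1.0 + b0 + (2.0 + b1) * x + rng.normal(0, 1.0, 120)
            rows.append(pd.DataFrame({"participant": g, "x": np.where(x > 0, "b", "a"), "y": y}))
        data = pd.concat(rows, ignore_index=True)
        fit = fit_glmm(data, GlmmSpec("y", "x", "gaussian", "identity", reference="a"))
        data["xb"] = (data.x == "b").astype(float)
        mlm = smf.mixedlm(
            "y ~ xb",
            data,
            groups="participant",
            re_formula="1",
            vc_formula={"slope": "0 + xb"},
        ).fit(reml=False)
        np.testing.assert_allclose(
            fit.beta_link, mlm.params[["Intercept", "xb"]].to_numpy(), atol=0.02
        )
        np.testing.assert_allclose(
            fit.se_link, mlm.bse[["Intercept", "xb"]].to_numpy(), rtol=0.15
        )

    def test_binomial_recovers_logit_coefficients(self, rng):
        data = _glmm_data(rng, "binomial", (-2.0, 1.0), n_groups=12, n_per=400)
        fit = fit_glmm(data, GlmmSpec("y", "x", "binomial", "logit", reference="a"))
        np.testing.assert_allclose(fit.beta_link, [-2.0, 1.0], atol=0.25)

    def test_response_scale_identities(self, rng):
        data = _glmm_data(rng, "inverse_gaussian", (0.91, -0.39))
        fit = fit_glmm(
            data, GlmmSpec("y", "x", "inverse_gaussian", "inverse", reference="a")
        )
        s = fit.response_scale_summary
        assert s["mean_a"] == pytest.approx(1 / fit.beta_link[0])
        assert s["mean_b"] == pytest.approx(1 / fit.beta_link.sum())

    def test_requires_two_levels_and_groups(self, rng):
        data = _glmm_data(rng, "gaussian", (0.0, 0.0))
        with pytest.raises(ValueError, match="2 levels"):
            fit_glmm(data.assign(x="a"), GlmmSpec("y", "x"))
        with pytest.raises(ValueError, match="groups"):
            fit_glmm(data[data.participant == 0], GlmmSpec("y", "x"))

    def test_inadmissible_family_link(self):
        with pytest.raises(ValueError, match="not admissible"):
            GlmmSpec("y", "x", "binomial", "inverse")


class TestCompareModels:
    def test_identical_models_lr_zero(self, rng):
        data = _glmm_data(rng, "gaussian", (1.0, 0.5))
        fit = fit_glmm(data, GlmmSpec("y", "x", "gaussian", "identity"))
        table = compare_models([fit, fit])
        assert table.lr_vs_best.iloc[0] == 0.0

    def test_true_family_ranks_first(self, rng):
        """Inverse-Gaussian data should prefer the inverse-Gaussian fit."""
        wins = 0
        for rep in range(10):
            data = _glmm_data(rng, "inverse_gaussian", (0.91, -0.39), n_per=200)
            fits = [
                fit_glmm(data, GlmmSpec("y", "x", "inverse_gaussian", "inverse", reference="a")),
                fit_glmm(data, GlmmSpec("y", "x", "gaussian", "identity", reference="a")),
            ]
            table = compare_models(fits)
            wins += table.family.iloc[0] == "inverse_gaussian"
        assert wins >= 9

    def test_different_data_raises(self, rng):
        a = make_fit([0, 1], [1, 1])
        b = make_fit([0, 1], [1, 1])
        b.data_token = "other"
        with pytest.raises(ValueError, match="identical data"):
            compare_models([a, b])

    def test_non_nested_flagged(self):
        a = make_fit([0, 1], [1, 1], loglik=-10, family="gaussian")
        b = make_fit([0, 1], [1, 1], loglik=-12, n_params=5, family="gamma", link="log")
        table = compare_models([a, b])
        assert not table.nested_in_best.iloc[1]
        assert np.isnan(table.lr_p.iloc[1])


class TestRmAnova:
    @staticmethod
    def toy_table():
        # 3 participants x 2 blocks, hand-checkable sums of squares
        return pd.DataFrame(
            {
                "participant": [0, 0, 1, 1, 2, 2],
                "block": ["b1", "b2"] * 3,
                "value": [1.0, 3.0, 2.0, 5.0, 3.0, 6.0],
            }
        )

    def test_matches_hand_computed_sums_of_squares(self):
        out = rm_anova(self.toy_table())
        # grand mean 10/3; SS_effect = 3*((2-10/3)^2+(14/3-10/3)^2) = 16/3... done
        # by hand: SS_block = 24.0 - 2*... verified below numerically from raw sums
        d = self.toy_table()
        gm = d.value.mean()
        ss_block = sum(
            2 * 0 + len(sub) * (sub.value.mean() - gm) ** 2
            for _, sub in d.groupby("block")
        )
        ss_subj = sum(
            len(sub) * (sub.value.mean() - gm) ** 2
            for _, sub in d.groupby("participant")
        )
        ss_tot = ((d.value - gm) ** 2).sum()
        ss_err = ss_tot - ss_block - ss_subj
        f_manual = (ss_block / 1) / (ss_err / 2)
        ges_manual = ss_block / (ss_block + ss_subj + ss_err)
        assert out.F == pytest.approx(f_manual)
        assert out.ges == pytest.approx(ges_manual)
        assert out.df == (1.0, 2.0)

    def test_identical_values_degenerate(self):
        d = self.toy_table().assign(value=2.0)
        out = rm_anova(d)
        assert out.degenerate
        assert out.ges == 0.0

    def test_missing_cell_raises(self):
        with pytest.raises(ValueError, match="incomplete"):
            rm_anova(self.toy_table().iloc[:-1])

    def test_planted_block_effect_posthocs(self, rng):
        # rapid blocks (1,3,5) near zero, sporadic (2,4) high
        rows = []
        for p in range(8):
            for b, mu in zip([1, 2, 3, 4, 5], [0.0, 5.0, 0.0, 5.0, 0.0]):
                rows.append(
                    {"participant": p, "block": f"b{b}", "value": mu + rng.normal(0, 0.2)}
                )
        out = rm_anova(pd.DataFrame(rows))
        assert out.p < 0.001
        ph = out.posthoc
        rapid = {"b1", "b3", "b5"}
        for _, row in ph.iterrows():
            pair = {row["A"], row["B"]}
            if pair <= rapid:  # rapid vs rapid: no effect planted
                assert row["p_corr"] > 0.01
            elif len(pair & rapid) == 1:  # rapid vs sporadic
                assert row["p_corr"] < 0.001

    def test_bonferroni_never_below_raw(self, rng):
        rows = [
            {"participant": p, "block": f"b{b}", "value": rng.normal()}
            for p in range(6)
            for b in range(4)
        ]
        out = rm_anova(pd.DataFrame(rows))
        if not out.posthoc.empty:
            assert (out.posthoc["p_corr"] >= out.posthoc["p_unc"] - 1e-12).all()


class TestRecovery:
    """Fast sanity versions; the full-size recoveries run in acceptance."""

    def test_rt_recovery_small(self):
        df = recovery.recover_rt(8, seed=5)
        assert df.converged.all()
        assert df.rapid_mean_s.mean() == pytest.approx(1.09, rel=0.05)
        assert df.increase_s.mean() == pytest.approx(0.83, rel=0.15)

    def test_miss_recovery_small(self):
        df = recovery.recover_miss(8, seed=5)
        assert df.rapid_miss_pct.mean() == pytest.approx(3.5, rel=0.4)

    def test_erp_amplitude_recovery_small(self):
        df = recovery.recover_erp_amplitudes("rapid", 10, seed=5)
        assert df.standard_uv.mean() == pytest.approx(1.07, abs=0.15)
        assert df.delta_uv.mean() == pytest.approx(1.75, abs=0.2)
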