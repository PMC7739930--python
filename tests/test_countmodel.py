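import dataclasses

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from conservebias.countmodel import (
    DispersionReport,
    FixedEffectEstimate,
    ModelSpec,
    NBFit,
    dispersion_check,
    fit_count_glmm,
    select_family,
    significance_table,
)
from oracles import marginal_loglik_quadrature


def _make_fit(y, mu, n_fixed=1, family="poisson", converged=True, fixed=None):
    """Hand-assembled fit object for testing the downstream reports."""
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    return NBFit(
        family=family,
        fixed=fixed or [FixedEffectEstimate("(Intercept)", 0.0, 1.0, 0.0, 1.0)],
        random_sd={},
        theta=None if family == "poisson" else 1.0,
        loglik=0.0,
        converged=converged,
        n_obs=len(y),
        n_fixed_params=n_fixed,
        fitted_mu=mu,
        response=y,
        diagnostics={},
        random_effects={},
    )


class TestFitBasics:
    def test_intercept_only_poisson_recovers_log_mean(self):
        table = pd.DataFrame({"n_projects": [3] * 25})
        spec = ModelSpec(fixed=(), categorical=None, random=())
        fit = fit_count_glmm(table, spec)
        assert fit.coef("(Intercept)").beta == pytest.approx(np.log(3), abs=1e-6)

    def test_likelihood_never_below_start(self, model_table):
        fit = fit_count_glmm(model_table, ModelSpec(family="negative_binomial"))
        assert fit.converged
        assert fit.loglik >= fit.diagnostics["loglik_start"] - 1e-6

    def test_wald_z_is_beta_over_se(self, model_table):
        fit = fit_count_glmm(model_table, ModelSpec())
        estimable = [fe for fe in fit.fixed if np.isfinite(fe.se)]
        assert len(estimable) >= 3
        for fe in estimable:
            assert fe.z == pytest.approx(fe.beta / fe.se, abs=1e-9)

    def test_single_level_random_factor_dropped_with_note(self):
        table = pd.DataFrame(
            {"n_projects": [1, 2, 0, 3, 1, 2], "x": [0.1, -0.2, 0.5, 0.0, 0.3, -0.1],
             "grp": ["only"] * 6}
        )
        spec = ModelSpec(fixed=("x",), categorical=None, random=("grp",))
        fit = fit_count_glmm(table, spec)
        assert fit.random_sd == {}
        assert any("grp" in note for note in fit.diagnostics["notes"])

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            fit_count_glmm(pd.DataFrame(), ModelSpec())


class TestLaplaceVsQuadrature:
    """The Laplace marginal likelihood against adaptive integration.

    Fixtures use moderate-to-large counts, where the Gaussian
    approximation of each group's integrand is accurate.
    """

    @staticmethod
    def _simulate(n_per_group, intercept, sigma, theta, seed):
        rng = np.random.default_rng(seed)
        groups = np.repeat(["g1", "g2", "g3"], n_per_group)
        x = rng.normal(0, 1, len(groups))
        b = dict(zip(["g1", "g2", "g3"], rng.normal(0, sigma, 3)))
        mu = np.exp(intercept + 0.4 * x + np.array([b[g] for g in groups]))
        if theta is None:
            y = rng.poisson(mu)
        else:
            y = rng.poisson(rng.gamma(theta, mu / theta))
        return pd.DataFrame({"n_projects": y, "x": x, "grp": groups})

    @pytest.mark.parametrize(
        "n_per_group,theta,seed",
        [(4, None, 1), (4, None, 2), (16, 15.0, 1), (16, 15.0, 3)],
        ids=["poisson-a", "poisson-b", "negbin-a", "negbin-b"],
    )
    def test_laplace_loglik_matches_quadrature_at_fit(self, n_per_group, theta, seed):
        table = self._simulate(n_per_group, intercept=5.0, sigma=0.3, theta=theta, seed=seed)
        family = "poisson" if theta is None else "negative_binomial"
        spec = ModelSpec(fixed=("x",), categorical=None, random=("grp",), family=family)
        fit = fit_count_glmm(table, spec)
        beta = np.array([fe.beta for fe in fit.fixed])
        eta0 = beta[0] + beta[1] * table["x"].to_numpy()
        sigma_hat = max(fit.random_sd["grp"], 1e-3)
        ll_quad = marginal_loglik_quadrature(
            table["n_projects"], eta0, table["grp"], sigma_hat, fit.theta
        )
        # re-evaluate the Laplace objective at the same clamped sigma
        from conservebias.countmodel import _LaplaceProblem

        X = np.column_stack([np.ones(len(table)), table["x"]])
        Z = (table["grp"].to_numpy()[:, None] == np.array(["g1", "g2", "g3"])).astype(float)
        prob = _LaplaceProblem(
            table["n_projects"].to_numpy(float), X, Z, np.zeros(3, dtype=int), 1,
            family, None,
        )
        params = list(beta) + [np.log(sigma_hat)]
        if theta is not None:
            params.append(np.log(fit.theta))
        ll_laplace = prob.laplace_loglik(np.array(params))
        assert ll_laplace == pytest.approx(ll_quad, abs=1e-3)

    def test_laplace_matches_quadrature_at_true_parameters(self):
        table = self._simulate(4, intercept=5.0, sigma=0.3, theta=None, seed=4)
        from conservebias.countmodel import _LaplaceProblem

        X = np.column_stack([np.ones(len(table)), table["x"]])
        Z = (table["grp"].to_numpy()[:, None] == np.array(["g1", "g2", "g3"])).astype(float)
        prob = _LaplaceProblem(
            table["n_projects"].to_numpy(float), X, Z, np.zeros(3, dtype=int), 1,
            "poisson", None,
        )
        ll_laplace = prob.laplace_loglik(np.array([5.0, 0.4, np.log(0.3)]))
        eta0 = 5.0 + 0.4 * table["x"].to_numpy()
        ll_quad = marginal_loglik_quadrature(table["n_projects"], eta0, table["grp"], 0.3)
        assert ll_laplace == pytest.approx(ll_quad, abs=1e-3)


class TestNbPoissonLimit:
    def test_huge_fixed_theta_reproduces_poisson_fit(self, model_table):
        pois = fit_count_glmm(model_table, ModelSpec(family="poisson"))
        nb = fit_count_glmm(
            model_table, ModelSpec(family="negative_binomial", fixed_theta=1e6)
        )
        for fe_p, fe_nb in zip(pois.fixed, nb.fixed):
            assert fe_nb.beta == pytest.approx(fe_p.beta, abs=1e-4)


class TestStatsmodelsCrossCheck:
    def test_fixed_effects_only_nb_agrees_with_statsmodels(self):
        rng = np.random.default_rng(7)
        n, theta = 2000, 1.5
        x = rng.normal(0, 1, n)
        mu = np.exp(0.5 + 0.3 * x)
        y = rng.poisson(rng.gamma(theta, mu / theta))
        table = pd.DataFrame({"n_projects": y, "x": x})
        ours = fit_count_glmm(
            table, ModelSpec(fixed=("x",), categorical=None, random=(), family="negative_binomial")
        )
        ref = sm.NegativeBinomial(y, np.column_stack([np.ones(n), x])).fit(disp=0)
        assert ours.coef("(Intercept)").beta == pytest.approx(ref.params[0], abs=1e-4)
        assert ours.coef("x").beta == pytest.approx(ref.params[1], abs=1e-4)
        assert ours.theta == pytest.approx(1 / ref.params[-1], rel=1e-3)


class TestDispersion:
    def test_perfect_fit_has_zero_chi2(self):
        fit = _make_fit([2, 3, 4], [2.0, 3.0, 4.0])
        report = dispersion_check(fit)
        assert report.pearson_chi2 == 0.0
        assert report.dispersion_ratio == 0.0

    def test_two_term_arithmetic(self):
        fit = _make_fit([0, 4], [2.0, 2.0], n_fixed=1)
        report = dispersion_check(fit)
        assert report.pearson_chi2 == pytest.approx(4.0)
        assert report.residual_df == 1
        assert report.dispersion_ratio == pytest.approx(4.0)

    def test_poisson_simulated_data_near_unit_ratio(self):
        from conservebias.experiments import dispersion_null

        report = dispersion_null(n_species=500, seed=3)
        assert 0.8 <= report.dispersion_ratio <= 1.2

    def test_requires_poisson_family(self):
        fit = _make_fit([1], [1.0], family="negative_binomial")
        with pytest.raises(ValueError):
            dispersion_check(fit)

    def test_invariant_ratio_definition(self):
        fit = _make_fit([0, 1, 5, 2], [1.0, 1.0, 2.0, 2.0], n_fixed=2)
        r = dispersion_check(fit)
        assert r.dispersion_ratio == pytest.approx(r.pearson_chi2 / r.residual_df, abs=1e-12)


class TestSelectFamily:
    def test_overdispersed_counts_trigger_switch(self):
        from conservebias.experiments import family_switch

        sel = family_switch(theta=0.8, n_species=500, seed=1)
        assert sel.switched
        assert sel.final.family == "negative_binomial"
        assert sel.dispersion.p_overdispersion < 0.05
        assert sel.final.theta < 3.0  # strongly overdispersed truth recovered

    def test_equidispersed_counts_keep_poisson(self):
        from conservebias.experiments import dispersion_null  # noqa: F401  (same generator)
        from conservebias import experiments, synthio

        cfg = synthio.SynthConfig(
            n_species=500, theta=1e9, multi_species_fraction=0.0, seed=3
        )
        table = experiments.make_model_table(synthio.generate_dataset(cfg))
        sel = select_family(table, ModelSpec())
        assert not sel.switched
        assert sel.final.family == "poisson"

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            select_family(pd.DataFrame(), ModelSpec())


class TestSignificanceTable:
    def test_wald_statistics_from_estimates(self):
        fe = FixedEffectEstimate("log_popularity", 0.19, 0.03, 0.19 / 0.03, 0.0)
        fit = _make_fit([1], [1.0], fixed=[fe])
        out = significance_table(fit).set_index("term")
        assert out.loc["log_popularity", "z"] == pytest.approx(6.333, abs=1e-3)
        # a slope six SEs from zero is overwhelming evidence
        from scipy import stats

        assert 2 * stats.norm.sf(6.333) < 1e-9

    def test_null_effect_has_unit_p(self, model_table):
        fit = fit_count_glmm(model_table, ModelSpec())
        tab = significance_table(fit)
        assert set(tab.columns) == {"term", "beta", "se", "z", "p"}
        for _, row in tab.iterrows():
            if row["beta"] == 0:
                assert row["p"] == 1.0

    def test_unconverged_fit_refused(self):
        fit = _make_fit([1], [1.0], converged=False)
        with pytest.raises(ValueError, match="unconverged"):
            significance_table(fit)


class TestParameterRecovery:
    def test_true_effects_covered_in_most_replicates(self):
        from conservebias.experiments import parameter_recovery

        df = parameter_recovery(n_species=500, n_replicates=5, seed=77)
        assert df["converged"].all()
        coverage = df.groupby("term")["covered"].mean()
        # quick check at 5 replicates; the full 20-replicate study backs
        # the 90% coverage claim
        assert (coverage >= 0.6).all()
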