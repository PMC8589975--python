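"""Hierarchical measurement-error models: likelihood, sampler, diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest

from snowphen import hier
from snowphen.hier import (HierPriors, build_model_data, coefficient_table,
                           convergence_report, fit_hier,
                           partial_effect_curves,
                           posterior_predictive_check,
                           prior_mass_in_breeding_season, unstandardize)


def simple_frame(n=400, seed=0, sigma=4.0, sigma_year=0.0, width=0.0,
                 beta_elev=2.0, beta_obs=1.0, n_years=10):
    """Synthetic brood table with exact (error-free) covariates."""
    rng = np.random.default_rng(seed)
    region = rng.choice(["EA", "WA"], n)
    year = rng.choice(np.arange(2000, 2000 + n_years), n)
    elev = rng.normal(2450, 250, n)
    obs_day = rng.normal(170, 15, n)
    ze = (elev - elev.mean()) / np.std(elev, ddof=1)
    zo = (obs_day - obs_day.mean()) / np.std(obs_day, ddof=1)
    zy = (year - year.mean()) / np.std(year, ddof=1)
    gamma = rng.normal(0, sigma_year, n_years)
    mu = (np.where(region == "EA", 175.0, 171.0) + beta_elev * ze
          + 0.5 * ze ** 2 + beta_obs * zo - 0.7 * zy + 0.2 * ze * zy
          + gamma[year - 2000])
    h = mu + rng.normal(0, sigma, n)
    h_obs = h + rng.normal(0, width / 4.0, n) if width > 0 else h
    return pd.DataFrame({
        "hatch_mean": h_obs, "hatch_width": width, "region": region,
        "year": year, "elevation_mean": elev, "elevation_sd": 0.0,
        "observer_day": obs_day,
    })


class TestModelData:
    def test_width_quarter_rule(self):
        df = simple_frame(50, width=40.0)
        data = build_model_data(df, "spatiotemporal")
        np.testing.assert_allclose(data.h_sd, 10.0)

    def test_standardized_columns_have_unit_scale(self):
        data = build_model_data(simple_frame(300), "spatiotemporal")
        for name, z in data.z_obs.items():
            assert abs(z.mean()) < 1e-9
            assert np.std(z, ddof=1) == pytest.approx(1.0)

    def test_environmental_model_needs_extra_columns(self):
        with pytest.raises(KeyError, match="winter_intensity"):
            build_model_data(simple_frame(50), "environmental")

    def test_zero_width_fixes_latent_hatch(self):
        df = simple_frame(80, width=0.0, seed=3)
        data = build_model_data(df, "spatiotemporal")
        post = fit_hier(data, chains=2, n_iter=300, seed=0)
        h = post.flat("h")
        np.testing.assert_allclose(h, np.broadcast_to(data.h_obs, h.shape))


class TestSampler:
    @pytest.fixture(scope="class")
    def fit(self):
        data = build_model_data(simple_frame(400, seed=1, width=12.0),
                                "spatiotemporal")
        return data, fit_hier(data, chains=4, n_iter=1200, seed=5)

    def test_reproducible_given_seed(self):
        data = build_model_data(simple_frame(120, seed=2), "spatiotemporal")
        a = fit_hier(data, chains=2, n_iter=300, seed=7)
        b = fit_hier(data, chains=2, n_iter=300, seed=7)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.sigma, b.sigma)

    def test_posterior_means_match_mixed_model_oracle(self, fit):
        import statsmodels.api as sm
        from statsmodels.regression.mixed_linear_model import MixedLM
        data, post = fit
        # with exact covariates the model reduces to a linear mixed model;
        # REML point estimates are the independent oracle
        X = np.column_stack([
            (data.region_idx == 0).astype(float),
            (data.region_idx == 1).astype(float),
            data.z_obs["elevation"], data.z_obs["elevation"] ** 2,
            data.z_obs["observer_day"], data.z_obs["year"],
            data.z_obs["elevation"] * data.z_obs["year"]])
        res = MixedLM(data.h_obs, X, groups=data.year_idx).fit(reml=True)
        ref = np.asarray(res.fe_params)
        est = np.concatenate([post.flat("alpha").mean(axis=0),
                              post.flat("beta").mean(axis=0)])
        sds = np.concatenate([post.flat("alpha").std(axis=0, ddof=1),
                              post.flat("beta").std(axis=0, ddof=1)])
        np.testing.assert_array_less(np.abs(est - ref), 0.35 * sds + 0.02)

    def test_sigma_recovered(self, fit):
        data, post = fit
        s = post.flat("sigma")
        # generating residual SD 4, plus uniform-vs-normal width slack
        assert 3.5 < s.mean() < 4.6

    def test_year_variance_shrinks_to_zero_when_absent(self):
        df = simple_frame(500, seed=4, sigma_year=0.0)
        data = build_model_data(df, "spatiotemporal")
        post = fit_hier(data, chains=4, n_iter=1000, seed=1)
        q95 = np.quantile(post.flat("sigma_year"), 0.95)
        assert q95 < 1.5

    def test_wider_intervals_inflate_posterior_uncertainty(self):
        # doubling the hatching-interval widths must not shrink the
        # posterior SD of the intercept; widths are heterogeneous (some
        # precise, monitoring-like records) so the residual SD stays
        # identified and the information loss is strict
        for seed in range(2):
            rng = np.random.default_rng(seed)
            df = simple_frame(250, seed=seed, width=20.0)
            widths = np.where(rng.random(len(df)) < 0.3, 0.0, 20.0)
            df = df.assign(hatch_width=widths)
            d1 = build_model_data(df, "spatiotemporal")
            d2 = build_model_data(df.assign(hatch_width=widths * 2),
                                  "spatiotemporal")
            p1 = fit_hier(d1, chains=2, n_iter=800, seed=seed)
            p2 = fit_hier(d2, chains=2, n_iter=800, seed=seed)
            sd1 = p1.flat("alpha").mean(axis=1).std(ddof=1)
            sd2 = p2.flat("alpha").mean(axis=1).std(ddof=1)
            assert sd2 >= sd1


class TestConvergenceReport:
    def _posterior_from_draws(self, draws_by_chain):
        """Wrap iid draws into a minimal HierPosterior-like object."""
        data = build_model_data(simple_frame(60, seed=0), "spatiotemporal")
        chains, kept = draws_by_chain.shape
        rng = np.random.default_rng(0)
        return hier.HierPosterior(
            data, HierPriors(175.0),
            alpha=rng.normal(175, 1, (chains, kept, data.n_regions)),
            beta=rng.normal(0, 1, (chains, kept, len(data.predictors))),
            sigma=np.abs(draws_by_chain) + 5.0,
            sigma_year=np.abs(rng.normal(2, 0.1, (chains, kept))),
            gamma=rng.normal(0, 1, (chains, kept, data.n_years)),
            h_latent=np.zeros((chains, kept, data.n)),
            accept_elev=0.5, seed=0)

    def test_iid_draws_pass(self):
        rng = np.random.default_rng(1)
        post = self._posterior_from_draws(rng.normal(size=(4, 800)))
        rep = convergence_report(post)
        assert rep.attrs["passed"]

    def test_separated_chains_fail(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(size=(2, 500))
        draws[0] += 5.0
        post = self._posterior_from_draws(draws)
        rep = convergence_report(post)
        assert not rep.attrs["passed"]
        assert (rep.loc[rep.parameter == "sigma", "rhat"] > 1.01).all()

    def test_single_chain_rejected(self):
        rng = np.random.default_rng(3)
        post = self._posterior_from_draws(rng.normal(size=(1, 500)))
        with pytest.raises(ValueError, match="2 chains"):
            convergence_report(post)

    def test_rhat_matches_split_formula_oracle(self):
        rng = np.random.default_rng(4)
        post = self._posterior_from_draws(rng.normal(size=(4, 600)))
        rep = convergence_report(post)

        def split_rhat(draws):
            m, n = draws.shape
            half = n // 2
            c = np.concatenate([draws[:, :half], draws[:, half:2 * half]])
            k, n2 = c.shape
            W = c.var(axis=1, ddof=1).mean()
            B = n2 * c.mean(axis=1).var(ddof=1)
            return math.sqrt(((n2 - 1) / n2 * W + B / n2) / W)

        expected = split_rhat(post.sigma)
        got = float(rep.loc[rep.parameter == "sigma", "rhat"].iloc[0])
        assert got == pytest.approx(expected, abs=1e-8)


class TestPriors:
    def test_prior_mass_closed_form(self):
        # Normal(175, 50) mass over [121, 243] via the error function
        expected = 0.5 * (math.erf((243 - 175) / (50 * math.sqrt(2)))
                          - math.erf((121 - 175) / (50 * math.sqrt(2))))
        assert prior_mass_in_breeding_season() == pytest.approx(
            expected, abs=1e-12)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            HierPriors(175.0, intercept_sd=0.0)


class TestUnstandardize:
    def test_zero_coefficient_stays_zero(self):
        assert unstandardize(0.0, 16.97, 7.0) == 0.0

    def test_linearity_in_factor(self):
        a = unstandardize(1.5, 3.0, 10.0)
        assert a == pytest.approx(10 * unstandardize(1.5, 3.0, 1.0))

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            unstandardize(1.0, 0.0)

    def test_coefficient_table_round_trip(self, hier_posterior):
        data, post = hier_posterior
        tab = coefficient_table(post, precip_window_days=61)
        for p, raw_sd, factor in (("elevation", data.scales["elevation"][1],
                                   100.0),
                                  ("year", data.scales["year"][1], 10.0)):
            row = tab[tab.parameter == p].iloc[0]
            assert row.unstd == pytest.approx(
                unstandardize(row.std_mean, raw_sd, factor))


@pytest.fixture(scope="module")
def hier_posterior(enriched):
    eb = enriched["broods"]
    data = build_model_data(eb[~eb.excluded_env], "environmental")
    return data, fit_hier(data, chains=2, n_iter=800, seed=2)


class TestPosteriorPredictive:
    def test_self_consistent_fit_is_calibrated(self, hier_posterior):
        _, post = hier_posterior
        ppc = posterior_predictive_check(post, n_rep=150, seed=0)
        # data generated from (a superset of) the fitted model: no extreme
        # tail probabilities expected
        assert ((ppc.tail_prob > 0.01) & (ppc.tail_prob < 0.99)).all()

    def test_shifted_response_flagged(self, hier_posterior):
        data, post = hier_posterior
        shifted = hier.HierPosterior(
            data, post.priors, post.alpha + 30.0, post.beta, post.sigma,
            post.sigma_year, post.gamma, post.h_latent + 30.0,
            post.accept_elev, post.seed)
        # replicates now sit 30 days later than the observations
        ppc = posterior_predictive_check(shifted, n_rep=150, seed=0)
        mean_row = ppc[ppc.statistic == "mean"].iloc[0]
        assert mean_row.tail_prob > 0.99

    def test_deterministic_given_seed(self, hier_posterior):
        _, post = hier_posterior
        a = posterior_predictive_check(post, n_rep=50, seed=3)
        b = posterior_predictive_check(post, n_rep=50, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestPartialEffects:
    def test_zeroed_coefficient_gives_flat_curve(self, hier_posterior):
        data, post = hier_posterior
        j = data.predictors.index("winter")
        zeroed = hier.HierPosterior(
            data, post.priors, post.alpha, post.beta.copy(), post.sigma,
            post.sigma_year, post.gamma, post.h_latent, post.accept_elev,
            post.seed)
        zeroed.beta[:, :, j] = 0.0
        curve = partial_effect_curves(zeroed, "winter")
        np.testing.assert_allclose(curve["mean"], curve["mean"].iloc[0],
                                   atol=1e-9)

    def test_linear_slope_equals_coefficient(self, hier_posterior):
        data, post = hier_posterior
        curve = partial_effect_curves(post, "precipitation")
        slope_z = np.polyfit(curve.z, curve["mean"], 1)[0]
        j = data.predictors.index("precipitation")
        assert slope_z == pytest.approx(
            float(post.flat("beta")[:, j].mean()), abs=1e-8)

    def test_bands_widen_at_range_edges(self, hier_posterior):
        _, post = hier_posterior
        curve = partial_effect_curves(post, "temperature", n_grid=41)
        width = (curve.upper - curve.lower).to_numpy()
        assert width[0] > width[20] and width[-1] > width[20]

    def test_unknown_variable_rejected(self, hier_posterior):
        _, post = hier_posterior
        with pytest.raises(KeyError):
            partial_effect_curves(post, "moon_phase")
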