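"""Bayesian fits: prior construction, posterior math, sampler contracts."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fishgrowth import (
    GrowthParams,
    LITERATURE_PRIORS,
    MCMCSettings,
    build_priors,
    fit_fabens_nls,
    log_posterior,
    sample_posterior,
    simulate_mark_recapture,
    summarize_posterior,
)
from fishgrowth.bayes import PosteriorDraws

from conftest import FABENS_BAYES_TRUTH


class TestBuildPriors:
    def test_packaged_table_statistics(self):
        """Column means/SDs of the 11 published studies, hand-verified."""
        pr = build_priors()
        assert pr.means["l_inf"] == pytest.approx(445.50, abs=0.01)
        assert pr.sds["l_inf"] == pytest.approx(62.65, abs=0.01)
        assert pr.means["k"] == pytest.approx(0.2864, abs=0.0005)
        assert pr.sds["k"] == pytest.approx(0.0988, abs=0.0005)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            build_priors(LITERATURE_PRIORS.iloc[:1])

    def test_zero_variance_rejected(self):
        dup = pd.DataFrame({"l_inf": [400.0, 400.0], "k": [0.2, 0.3]})
        with pytest.raises(ValueError):
            build_priors(dup)

    def test_t0_column_optional(self):
        pr = build_priors(LITERATURE_PRIORS[["l_inf", "k"]])
        assert "t0" not in pr.means


class TestLogPosterior:
    def test_no_data_is_prior_only(self):
        pr = build_priors()
        p = GrowthParams(450.0, 0.25, sigma=20.0)
        lp = log_posterior(p, None, "Fabens", pr)
        expected = (
            -0.5 * ((450.0 - pr.means["l_inf"]) / pr.sds["l_inf"]) ** 2
            - 0.5 * ((0.25 - pr.means["k"]) / pr.sds["k"]) ** 2
            - 0.5 * (20.0 / pr.sigma_scale) ** 2
        )
        assert lp == pytest.approx(expected, abs=1e-10)

    def test_on_curve_observation_contributes_gaussian_mode(self):
        pr = build_priors()
        p = GrowthParams(500.0, 0.3, sigma=12.0)
        from fishgrowth import fabens_expected_recapture

        l_r = fabens_expected_recapture(250.0, p, 0.7)
        data = pd.DataFrame({"l_m": [250.0], "dt": [0.7], "l_r": [l_r]})
        with_data = log_posterior(p, data, "Fabens", pr)
        without = log_posterior(p, None, "Fabens", pr)
        assert with_data - without == pytest.approx(
            -math.log(12.0 * math.sqrt(2 * math.pi)), abs=1e-10
        )

    def test_agrees_with_independent_density_oracle(self):
        """Cross-check against a scipy.stats composition on random points."""
        pr = build_priors()
        rng = np.random.default_rng(5)
        data = simulate_mark_recapture(FABENS_BAYES_TRUTH, n=17, seed=2)
        for _ in range(5):
            l_inf = rng.uniform(350, 650)
            k = rng.uniform(0.05, 0.9)
            sigma = rng.uniform(3, 60)
            p = GrowthParams(l_inf, k, sigma=sigma)
            mu = data["l_m"] + (l_inf - data["l_m"]) * (1 - np.exp(-k * data["dt"]))
            oracle = (
                stats.norm.logpdf(data["l_r"], mu, sigma).sum()
                + stats.norm.logpdf(l_inf, pr.means["l_inf"], pr.sds["l_inf"])
                + stats.norm.logpdf(k, pr.means["k"], pr.sds["k"])
                + stats.norm.logpdf(sigma, 0.0, pr.sigma_scale)
            )
            mine = log_posterior(p, data, "Fabens", pr)
            # both are unnormalised: compare up to the constant terms
            const = (
                -math.log(pr.sds["l_inf"] * math.sqrt(2 * math.pi))
                - math.log(pr.sds["k"] * math.sqrt(2 * math.pi))
                - math.log(pr.sigma_scale * math.sqrt(2 * math.pi))
            )
            assert mine + const == pytest.approx(oracle, abs=1e-10)

    def test_outside_support_is_minus_inf(self):
        pr = build_priors()
        data = simulate_mark_recapture(FABENS_BAYES_TRUTH, n=5, seed=1)
        p = GrowthParams(500.0, 0.3, sigma=0.0)  # sigma at boundary
        assert log_posterior(p, data, "Fabens", pr) == -np.inf


class TestSampler:
    def test_retained_draw_count_contract(self):
        pr = build_priors()
        dr = sample_posterior(
            "Fabens", None, pr,
            MCMCSettings(iterations=50_000, burn_in=25_000, thin=10, chains=1, seed=0),
        )
        assert dr.draws["l_inf"].shape == (1, 2500)

    @pytest.mark.parametrize("iters,burn,thin", [(4000, 1000, 3), (999, 0, 7)])
    def test_retained_count_for_odd_schedules(self, iters, burn, thin):
        pr = build_priors()
        s = MCMCSettings(iterations=iters, burn_in=burn, thin=thin, chains=1, seed=1)
        dr = sample_posterior("Fabens", None, pr, s)
        assert dr.draws["k"].shape[1] == (iters - burn) // thin

    def test_prior_recovery_without_data(self):
        """With no observations the posterior is the (truncated) prior."""
        pr = build_priors()
        dr = sample_posterior("Fabens", None, pr, MCMCSettings(chains=2, seed=3))
        s = dr.stacked("l_inf")
        mc_se = pr.sds["l_inf"] / np.sqrt(max(min(dr.ess.values()), 10.0))
        assert np.mean(s) == pytest.approx(pr.means["l_inf"], abs=4 * mc_se)
        assert np.std(s) == pytest.approx(pr.sds["l_inf"], rel=0.15)

    def test_seeded_reproducibility(self):
        pr = build_priors()
        data = simulate_mark_recapture(FABENS_BAYES_TRUTH, n=40, seed=4)
        s = MCMCSettings(iterations=4000, burn_in=2000, thin=4, chains=2, seed=9)
        a = sample_posterior("Fabens", data, pr, s)
        b = sample_posterior("Fabens", data, pr, s)
        np.testing.assert_array_equal(a.draws["l_inf"], b.draws["l_inf"])

    def test_likelihood_dominates_with_big_low_noise_sample(self):
        p = GrowthParams(536.82, 0.38, sigma=4.0)
        data = simulate_mark_recapture(p, n=800, seed=6)
        nls = fit_fabens_nls(data)
        pr = build_priors()
        dr = sample_posterior(
            "Fabens", data, pr,
            MCMCSettings(iterations=12_000, burn_in=6_000, thin=5, chains=2, seed=6),
        )
        res = summarize_posterior(dr)
        assert res.estimates["l_inf"] == pytest.approx(nls.estimates["l_inf"], rel=0.02)
        assert res.estimates["k"] == pytest.approx(nls.estimates["k"], rel=0.02)

    def test_posterior_concentrates_with_sample_size(self):
        pr = build_priors()
        widths = []
        for n in (15, 60, 240):
            data = simulate_mark_recapture(FABENS_BAYES_TRUTH, n=n, seed=12)
            dr = sample_posterior(
                "Fabens", data, pr,
                MCMCSettings(iterations=8000, burn_in=4000, thin=4, chains=2, seed=12),
            )
            lo, hi = summarize_posterior(dr).intervals["l_inf"]
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]


class TestSummaries:
    def _draws(self, arr):
        arr = np.asarray(arr, dtype=float)[None, :]
        return PosteriorDraws(
            draws={"l_inf": arr + 400, "k": np.abs(arr) * 0.01 + 0.2,
                   "sigma": np.abs(arr) + 1},
            acceptance_rate=0.3, rhat={}, ess={}, model="Fabens", n_obs=10,
        )

    def test_symmetric_draws_have_median_equal_mean(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(20001)
        z = np.concatenate([z, -z])  # exactly symmetric
        res = summarize_posterior(self._draws(z))
        assert res.estimates["l_inf"] == pytest.approx(
            res.fit_stats["posterior_mean"]["l_inf"], abs=1e-9
        )

    def test_constant_draws_zero_width_interval(self):
        res = summarize_posterior(self._draws(np.zeros(100)))
        lo, hi = res.intervals["l_inf"]
        assert lo == hi == res.estimates["l_inf"]

    def test_standard_normal_quantiles(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal(100_000)
        res = summarize_posterior(self._draws(z))
        lo, hi = res.intervals["l_inf"]
        assert lo - 400 == pytest.approx(-1.96, abs=0.05)
        assert hi - 400 == pytest.approx(1.96, abs=0.05)
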