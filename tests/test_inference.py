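import math

import numpy as np
import pytest

import gypaetus as g
from gypaetus.inference import NonIdentifiableError, _expand_logit_p
from gypaetus.model import _dataset_loglik_kernel

from conftest import make_dataset


def _sim(n, T, seed, sigma=0.3, first=1987, **kw):
    cfg = g.SimulationConfig(
        design=g.StudyDesign(tuple(range(first, first + T))),
        n_individuals=n, sigma_year=sigma, seed=seed, **kw,
    )
    return g.simulate_dataset(cfg)


FIXED = g.ModelSpec(p_structure="constant", random_year_effect=False)


class TestGelmanRubin:
    def test_hand_computed_value(self):
        chains = np.array([[1.0, 2, 3, 4], [1.0, 2, 3, 4]])
        # equal chain means: B=0, W=5/3, var+ = 1.25, Rhat = sqrt(0.75)
        assert g.gelman_rubin(chains) == pytest.approx(math.sqrt(0.75), abs=1e-12)

    def test_zero_within_variance_rejected(self):
        chains = np.array([[0.0, 0, 0, 0], [5.0, 5, 5, 5]])
        with pytest.raises(ValueError):
            g.gelman_rubin(chains)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            g.gelman_rubin(np.array([[1.0, 2, 3, 4]]))

    def test_stationary_chains_approach_one(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(3, 10_000))
        assert g.gelman_rubin(chains) == pytest.approx(1.0, abs=0.01)


class TestEffectiveSampleSize:
    def test_independent_draws_near_total(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(2, 10_000))
        ess = g.effective_sample_size(chains)
        assert abs(ess - 20_000) < 2_000

    def test_alternating_chain_is_finite(self):
        x = np.tile([1.0, -1.0], 50)
        ess = g.effective_sample_size(np.stack([x, -x]))
        assert np.isfinite(ess) and ess > 0

    def test_never_exceeds_pooled_draws(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(2, 500)).cumsum(axis=1)  # strong autocorrelation
        assert g.effective_sample_size(x) <= 1000

    def test_constant_chain_rejected(self):
        with pytest.raises(ValueError):
            g.effective_sample_size(np.ones((2, 100)))


class TestMle:
    def test_recovery_on_moderate_data(self):
        ds = _sim(800, 12, seed=21, sigma=0.0)
        res = g.fit_mle(ds, FIXED)
        assert res.converged
        assert np.all(np.abs(res.survival - np.array([0.907, 0.958, 0.924])) < 0.04)
        assert abs(res.p[0] - 0.88) < 0.04

    def test_saturated_data_hits_boundary(self):
        ds = _sim(40, 6, seed=3, sigma=0.0,
                  survival_by_class=(1.0, 1.0, 1.0), resight_prob=1.0)
        res = g.fit_mle(ds, FIXED)
        assert res.boundary
        # only juvenile and subadult are identified over 6 occasions
        # (no bird reaches age 7); those estimates sit at the boundary
        assert np.all(res.survival[:2] > 0.99)
        assert np.all(res.p > 0.99)

    def test_singleton_histories_rejected(self, adult_design):
        rows = [(f"i{k}", 1990, (1, 0, 0, 0)) for k in range(5)]
        with pytest.raises(NonIdentifiableError):
            g.fit_mle(make_dataset(adult_design, rows), FIXED)

    def test_random_effect_spec_rejected(self):
        ds = _sim(50, 6, seed=4)
        with pytest.raises(ValueError):
            g.fit_mle(ds, g.ModelSpec(random_year_effect=True))

    def test_argmax_agrees_with_marray_fit(self):
        """Dual route: the m-array multinomial and the individual-history
        likelihood must share their maximiser for the tied model."""
        from scipy import optimize
        from gypaetus.model import marray_loglik, invlogit

        # all-adult birds so a single survival class is identified
        ds = _sim(600, 8, seed=31, sigma=0.0,
                  survival_by_class=(0.9, 0.9, 0.9), resight_prob=0.8)
        histories = tuple(
            g.EncounterHistory(h.individual_id, h.birth_year - 10, h.detections)
            for h in ds.histories
        )
        ds = g.EncounterDataset(ds.design, histories)
        ma = g.build_m_array(ds)
        K = ds.design.n_intervals

        def nll(x):
            params = g.CJSParameters(
                beta=(x[0],) * 3, eps=(0.0,) * K, sigma=0, p=(invlogit(x[1]),) * 3
            )
            return -marray_loglik(ma, params)

        res = optimize.minimize(nll, np.array([1.0, 1.0]), method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        mle = g.fit_mle(ds, FIXED)
        assert mle.beta[2] == pytest.approx(res.x[0], abs=1e-5)
        assert mle.logit_p[0] == pytest.approx(res.x[1], abs=1e-5)


class TestMcmc:
    def test_config_protocol_defaults(self):
        cfg = g.McmcConfig()
        assert (cfg.n_iterations, cfg.burn_in, cfg.thin, cfg.n_chains) == (
            150_000, 5_000, 3, 3
        )

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            g.McmcConfig(n_chains=1)
        with pytest.raises(ValueError):
            g.McmcConfig(burn_in=10, n_iterations=10)
        with pytest.raises(ValueError):
            g.McmcConfig(thin=0)

    def test_empty_dataset_rejected(self, adult_design):
        ds = g.EncounterDataset(adult_design, ())
        with pytest.raises(ValueError):
            g.run_mcmc(ds, g.ModelSpec(), g.McmcConfig(n_iterations=100, burn_in=10))

    def test_seeded_determinism(self):
        ds = _sim(60, 6, seed=8)
        cfg = g.McmcConfig(n_iterations=400, burn_in=100, thin=2, seed=5)
        a = g.run_mcmc(ds, g.ModelSpec(), cfg)
        b = g.run_mcmc(ds, g.ModelSpec(), cfg)
        assert np.array_equal(a.draws, b.draws)
        assert np.array_equal(a.log_posterior, b.log_posterior)

    def test_retained_draw_count_and_names(self):
        ds = _sim(30, 5, seed=9)
        cfg = g.McmcConfig(n_iterations=1000, burn_in=100, thin=3, seed=0)
        ch = g.run_mcmc(ds, g.ModelSpec(p_structure="constant"), cfg)
        assert ch.draws.shape == (3, cfg.n_retained, 3 + 1 + 1 + 4)
        assert ch.param_names[:4] == (
            "beta_juvenile", "beta_subadult", "beta_adult", "logit_p"
        )
        assert "eps_1987" in ch.param_names

    def test_stored_log_posterior_matches_recomputation(self):
        ds = _sim(40, 5, seed=10)
        cfg = g.McmcConfig(n_iterations=300, burn_in=50, thin=5, seed=2)
        spec = g.ModelSpec(p_structure="constant")
        ch = g.run_mcmc(ds, spec, cfg)
        det, frst, ac = ds.to_arrays()
        j = 3  # chain 0, draw 3
        x = ch.draws[0, j]
        beta, lp = x[:3], x[3:4]
        sigma, eps = x[4], x[5:]
        ll = _dataset_loglik_kernel(det, frst, ac, beta, _expand_logit_p(lp), eps)
        prior = -np.sum(beta**2) / 200 - np.sum(lp**2) / 200
        prior += -np.sum(eps**2) / (2 * sigma**2) - len(eps) * np.log(sigma)
        assert ch.log_posterior[0, j] == pytest.approx(ll + prior, abs=1e-8)

    def test_posterior_matches_grid_integration(self):
        """Sampler correctness: on a tiny fixed-effects problem the chain
        mean must match direct numerical integration of the posterior."""
        ds = _sim(20, 3, seed=12, sigma=0.0,
                  survival_by_class=(0.8, 0.8, 0.8), resight_prob=0.7)
        # make every bird an adult so one (beta, p) pair carries all the data
        ds = g.EncounterDataset(
            ds.design,
            tuple(
                g.EncounterHistory(h.individual_id, h.birth_year - 10, h.detections)
                for h in ds.histories
            ),
        )
        det, frst, ac = ds.to_arrays()
        # a tight prior keeps the weakly-informed posterior inside the grid
        prior_sd = 2.5
        bgrid = np.linspace(-12, 14, 521)
        pgrid = np.linspace(-12, 12, 481)
        logpost = np.empty((bgrid.size, pgrid.size))
        eps = np.zeros(ds.design.n_intervals)
        for i, b in enumerate(bgrid):
            for j, q in enumerate(pgrid):
                ll = _dataset_loglik_kernel(
                    det, frst, ac, np.array([0.0, 0.0, b]), np.full(3, q), eps
                )
                logpost[i, j] = ll - (b * b + q * q) / (2 * prior_sd**2)
        w = np.exp(logpost - logpost.max())
        w /= w.sum()
        surv_grid = float((w.sum(axis=1) * g.invlogit(bgrid)).sum())
        p_grid = float((w.sum(axis=0) * g.invlogit(pgrid)).sum())

        cfg = g.McmcConfig(n_iterations=60_000, burn_in=5_000, thin=2, seed=4,
                           prior_sd=prior_sd)
        ch = g.run_mcmc(ds, FIXED, cfg)
        surv_mc = g.invlogit(ch.pooled("beta_adult")).mean()
        p_mc = g.invlogit(ch.pooled("logit_p")).mean()
        assert surv_mc == pytest.approx(surv_grid, abs=0.01)
        assert p_mc == pytest.approx(p_grid, abs=0.01)

    def test_posterior_mode_agrees_with_mle(self):
        ds = _sim(400, 8, seed=14, sigma=0.0)
        cfg = g.McmcConfig(n_iterations=8_000, burn_in=2_000, thin=2, seed=6)
        ch = g.run_mcmc(ds, FIXED, cfg)
        flat = ch.draws.reshape(-1, ch.draws.shape[-1])
        mode = flat[np.argmax(ch.log_posterior.ravel())]
        mle = g.fit_mle(ds, FIXED)
        # adult class is barely observed over 8 occasions; compare the
        # well-identified parameters
        assert np.all(np.abs(g.invlogit(mode[:2]) - mle.survival[:2]) < 0.01)
        assert abs(g.invlogit(mode[3]) - mle.p[0]) < 0.01


class TestSummaries:
    def _tiny_chains(self, draws, names=("beta_juvenile",)):
        spec = g.ModelSpec(p_structure="constant", random_year_effect=False)
        design = g.StudyDesign((2000, 2001, 2002))
        full_names = (
            "beta_juvenile", "beta_subadult", "beta_adult", "logit_p"
        )
        return g.McmcChains(
            draws=draws, log_posterior=np.zeros(draws.shape[:2]),
            param_names=full_names, design=design, spec=spec,
            config=g.McmcConfig(n_iterations=10, burn_in=1, seed=0),
        )

    def test_point_mass_summary(self):
        draws = np.zeros((2, 10, 4))  # beta = 0 -> survival 0.5
        s = g.summarize_posterior(self._tiny_chains(draws))
        row = s["survival_juvenile"]
        assert row["mean"] == 0.5
        assert row["q97.5"] - row["q2.5"] == 0.0

    def test_quantile_equivariance_under_invlogit(self):
        rng = np.random.default_rng(3)
        draws = rng.normal(1.0, 0.5, size=(2, 400, 4))
        s = g.summarize_posterior(self._tiny_chains(draws))
        raw = draws[:, :, 0].ravel()
        # order-statistic quantiles commute exactly with monotone maps
        for q, col in ((0.025, "q2.5"), (0.975, "q97.5")):
            assert s["survival_juvenile"][col] == pytest.approx(
                g.invlogit(np.quantile(raw, q, method="inverted_cdf")), abs=1e-12
            )

    def test_annual_survival_rows_present(self):
        ds = _sim(40, 5, seed=15)
        cfg = g.McmcConfig(n_iterations=300, burn_in=100, thin=2, seed=3)
        ch = g.run_mcmc(ds, g.ModelSpec(), cfg)
        s = g.summarize_posterior(ch)
        for y in ds.design.occasion_years[:-1]:
            assert f"survival_juvenile_{y}" in s.table.index
        assert "sigma" in s.table.index
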