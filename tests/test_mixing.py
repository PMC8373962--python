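import numpy as np
import pytest
from scipy import stats

from nitratrace import (
    BayesianMixingModel,
    MCMCConfig,
    SourceProfile,
    convergence_diagnostics,
    fit_mixing_model,
    log_likelihood,
    log_prior,
    summarize_posterior,
)
from nitratrace.mixing import pack_sources, split_rhat
from nitratrace.synthetic import SyntheticGroup, SyntheticSpec, generate_mixture_samples, illustrative_sources
from helpers import grid_posterior_p1, marginal_loglik_quadrature, split_rhat_reference

ONE_TRACER = ("d15N_NO3",)


def one_tracer_sources(m1=0.0, m2=10.0, sd=1.0):
    return [
        SourceProfile("low", mean={"d15N_NO3": m1}, sd={"d15N_NO3": sd}),
        SourceProfile("high", mean={"d15N_NO3": m2}, sd={"d15N_NO3": sd}),
    ]


class TestLogLikelihood:
    def test_single_source_reduces_to_normal_pdf(self):
        mu = np.array([[5.0], [2.0]])
        omega = np.array([[1.5], [0.5]])
        X = np.array([[4.0, 2.5], [6.0, 1.0]])
        sigma = np.array([1.0, 2.0])
        got = log_likelihood(np.array([1.0]), sigma, X, mu, omega)
        expected = sum(
            stats.norm.logpdf(X[i, j], mu[j, 0], np.sqrt(omega[j, 0] ** 2 + sigma[j] ** 2))
            for i in range(2)
            for j in range(2)
        )
        assert got == pytest.approx(expected)

    def test_identical_sources_make_likelihood_constant_in_P(self):
        mu = np.array([[3.0, 3.0], [1.0, 1.0]])
        omega = np.zeros((2, 2))
        X = np.array([[3.5, 0.5]])
        sigma = np.array([1.0, 1.0])
        vals = [
            log_likelihood(np.array([p, 1 - p]), sigma, X, mu, omega)
            for p in (0.1, 0.5, 0.9)
        ]
        assert max(vals) - min(vals) < 1e-12

    def test_matches_quadrature_over_latent_normals(self, rng):
        """The closed-form marginal equals numerical integration of the
        un-marginalized model over the latent source/fractionation draws."""
        mu = rng.normal(0, 5, size=(2, 2))
        omega = rng.uniform(0.5, 2.0, size=(2, 2))
        lam = rng.normal(0, 1, size=(2, 2))
        tau = rng.uniform(0.1, 1.0, size=(2, 2))
        X = rng.normal(0, 3, size=(3, 2))
        P = np.array([0.35, 0.65])
        sigma = np.array([0.8, 1.3])
        got = log_likelihood(P, sigma, X, mu, omega, lam, tau)
        ref = marginal_loglik_quadrature(P, sigma, X, mu, omega, lam, tau)
        assert got == pytest.approx(ref, abs=1e-6)

    def test_non_simplex_P_rejected(self):
        mu = np.zeros((1, 2))
        omega = np.ones((1, 2))
        with pytest.raises(ValueError):
            log_likelihood(np.array([0.7, 0.7]), np.array([1.0]), [[0.0]], mu, omega)

    def test_zero_variance_off_mean_is_minus_inf(self):
        mu = np.array([[5.0]])
        omega = np.zeros((1, 1))
        got = log_likelihood(np.array([1.0]), np.array([0.0]), [[4.0]], mu, omega)
        assert got == -np.inf


class TestLogPrior:
    def test_flat_over_simplex_interior(self):
        s = np.array([1.0])
        a = log_prior(np.array([0.2, 0.8]), s)
        b = log_prior(np.array([0.7, 0.3]), s)
        assert a == pytest.approx(b)

    def test_sigma_tail_and_boundary(self):
        assert log_prior(np.array([0.5, 0.5]), np.array([1e6])) < -1e6
        assert log_prior(np.array([0.0, 1.0]), np.array([1.0])) == -np.inf
        assert log_prior(np.array([0.5, 0.5]), np.array([-1.0])) == -np.inf


class TestFit:
    def test_single_source_is_degenerate(self, fast_mcmc):
        model = BayesianMixingModel(
            sources=[SourceProfile("CF", mean={"d15N_NO3": 2.0}, sd={"d15N_NO3": 1.0})],
            tracers=ONE_TRACER,
            mcmc=fast_mcmc,
        ).fit(np.array([[2.1], [1.9]]))
        assert (model.draws_P_ == 1.0).all()

    def test_identical_sources_recover_symmetric_prior(self, fast_mcmc):
        """With indistinguishable sources the posterior equals the prior:
        each proportion has mean 1/K."""
        srcs = [
            SourceProfile("a", mean={"d15N_NO3": 5.0}, sd={"d15N_NO3": 2.0}),
            SourceProfile("b", mean={"d15N_NO3": 5.0}, sd={"d15N_NO3": 2.0}),
        ]
        cfg = MCMCConfig(n_chains=2, n_iter=12000, n_burn=4000, thin=2, rng_seed=5)
        model = BayesianMixingModel(sources=srcs, tracers=ONE_TRACER, mcmc=cfg).fit(
            np.array([[5.2], [4.8], [5.0]])
        )
        se = model.draws_P_[:, 0].std() / np.sqrt(len(model.draws_P_) / 20)
        assert model.draws_P_[:, 0].mean() == pytest.approx(0.5, abs=3 * max(se, 0.01))

    def test_simplex_conservation_every_draw(self, two_sources, fast_mcmc, rng):
        X = rng.normal([5.0, 5.0], 1.0, size=(10, 2))
        model = BayesianMixingModel(sources=two_sources, mcmc=fast_mcmc).fit(X)
        assert np.abs(model.draws_P_.sum(axis=1) - 1.0).max() < 1e-12
        assert (model.draws_P_ >= 0).all()
        assert (model.draws_sigma_ > 0).all()

    def test_well_separated_sources_recover_truth(self):
        """Data at true P = (0.7, 0.3) between endmembers at 0 and 20 per mil."""
        rng = np.random.default_rng(3)
        srcs = [
            SourceProfile("low", mean={"d15N_NO3": 0.0, "d18O_NO3": 0.0},
                          sd={"d15N_NO3": 0.5, "d18O_NO3": 0.5}),
            SourceProfile("high", mean={"d15N_NO3": 20.0, "d18O_NO3": 20.0},
                          sd={"d15N_NO3": 0.5, "d18O_NO3": 0.5}),
        ]
        X = rng.normal(6.0, 0.7, size=(60, 2))  # 0.7*0 + 0.3*20 = 6
        cfg = MCMCConfig(n_chains=2, n_iter=8000, n_burn=3000, thin=2, rng_seed=9)
        model = BayesianMixingModel(sources=srcs, mcmc=cfg).fit(X)
        assert model.draws_P_[:, 0].mean() == pytest.approx(0.7, abs=0.10)
        assert model.draws_P_[:, 1].mean() == pytest.approx(0.3, abs=0.10)

    def test_posterior_matches_grid_oracle(self):
        """K=2, one tracer: MCMC marginal of P1 agrees with direct grid
        evaluation of prior x likelihood (CDF sup-distance <= 0.02)."""
        rng = np.random.default_rng(21)
        srcs = one_tracer_sources(0.0, 10.0, sd=1.0)
        X = rng.normal(6.5, 1.2, size=(25, 1))
        cfg = MCMCConfig(n_chains=3, n_iter=30000, n_burn=5000, thin=2, rng_seed=17)
        model = BayesianMixingModel(
            sources=srcs, tracers=ONE_TRACER, sigma_prior_scale=5.0, mcmc=cfg
        ).fit(X)
        mu, omega, _, _, _ = pack_sources(srcs, ONE_TRACER)
        p1_grid, cdf = grid_posterior_p1(X, mu, omega, sigma_scale=5.0)
        draws = np.sort(model.draws_P_[:, 0])
        ecdf_at_grid = np.searchsorted(draws, p1_grid, side="right") / len(draws)
        assert np.abs(ecdf_at_grid - cdf).max() <= 0.02

    def test_determinism_bit_identical(self, two_sources, fast_mcmc, rng):
        X = rng.normal([8.0, 8.0], 1.0, size=(8, 2))
        m1 = BayesianMixingModel(sources=two_sources, mcmc=fast_mcmc).fit(X)
        m2 = BayesianMixingModel(sources=two_sources, mcmc=fast_mcmc).fit(X)
        assert (m1.draws_P_ == m2.draws_P_).all()
        assert (m1.draws_sigma_ == m2.draws_sigma_).all()

    def test_non_finite_data_rejected(self, two_sources, fast_mcmc):
        with pytest.raises(ValueError):
            BayesianMixingModel(sources=two_sources, mcmc=fast_mcmc).fit(
                np.array([[np.nan, 1.0]])
            )

    def test_parameter_recovery_mean_absolute_error(self):
        """Across seeded 4-source datasets (n=60, separated signatures) the
        posterior-mean proportions track the ground truth."""
        sources = illustrative_sources()
        cfg = MCMCConfig(n_chains=2, n_iter=6000, n_burn=2500, thin=2, rng_seed=2)
        errs = []
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            true_P = rng.dirichlet([4.0, 4.0, 4.0, 4.0])
            grp = SyntheticGroup(
                "g", "surface", dict(zip(["CF", "MS", "NP", "SN"], true_P)), n=60
            )
            ds = generate_mixture_samples(
                SyntheticSpec(sources=sources, groups=[grp], rng_seed=2000 + seed)
            )
            post = fit_mixing_model(ds.samples, sources, mcmc=cfg)
            means = post.draws_P.mean(axis=0)
            truth = np.array([grp.true_P[s] for s in post.source_ids])
            errs.extend(np.abs(means - truth))
        assert np.mean(errs) <= 0.10


class TestDiagnosticsAndSummary:
    def test_split_rhat_identical_chains_is_one(self, rng):
        draws = rng.normal(size=400)
        chains = np.stack([draws, draws])
        # split-R-hat compares chain halves, so even exact copies sit a
        # hair above 1 for finite stationary draws
        assert split_rhat(chains) == pytest.approx(1.0, abs=0.01)

    def test_split_rhat_disjoint_chains_explodes(self, rng):
        chains = np.stack(
            [rng.normal(0, 0.01, 200), rng.normal(100, 0.01, 200)]
        )
        assert split_rhat(chains) > 10

    def test_split_rhat_matches_reference_formula(self, rng):
        chains = rng.normal(size=(4, 500)) + rng.normal(0, 0.05, size=(4, 1))
        assert split_rhat(chains) == pytest.approx(split_rhat_reference(chains), rel=1e-12)

    def test_split_rhat_matches_arviz(self, rng):
        arviz = pytest.importorskip("arviz")
        chains = rng.normal(size=(3, 400)).cumsum(axis=1) * 0.01 + rng.normal(
            size=(3, 400)
        )
        ours = split_rhat(chains)
        theirs = float(arviz.rhat(chains[:, :, None][:, :, 0]))
        assert ours == pytest.approx(theirs, rel=0.01)

    def test_convergence_diagnostics_requires_multiple_chains(self, rng):
        with pytest.raises(ValueError):
            convergence_diagnostics(rng.normal(size=(1, 100, 2)))

    def test_summary_matches_independent_recomputation(self, two_sources, fast_mcmc, rng):
        X = rng.normal([4.0, 4.0], 1.0, size=(12, 2))
        model = BayesianMixingModel(sources=two_sources, mcmc=fast_mcmc).fit(X)
        table = summarize_posterior(model.posterior_)
        for k, sid in enumerate(model.source_ids_):
            pct = model.draws_P_[:, k] * 100
            row = table[table["source"] == sid].iloc[0]
            assert row["mean_pct"] == round(float(np.mean(pct)), 1)
            assert row["sd_pct"] == round(float(np.std(pct)), 1)
        assert table["mean_pct"].sum() == pytest.approx(100.0, abs=0.5)

    def test_summary_orders_canonical_sources(self, fast_mcmc, rng):
        sources = illustrative_sources()[::-1]  # scrambled input order
        X = rng.normal([8.0, 6.0], 1.5, size=(8, 2))
        model = BayesianMixingModel(sources=sources, mcmc=fast_mcmc).fit(X)
        assert model.source_ids_ == ["CF", "MS", "NP", "SN"]

    def test_degenerate_single_source_summary(self, fast_mcmc):
        model = BayesianMixingModel(
            sources=[SourceProfile("CF", mean={"d15N_NO3": 2.0}, sd={"d15N_NO3": 1.0})],
            tracers=ONE_TRACER,
            mcmc=fast_mcmc,
        ).fit(np.array([[2.0], [2.2]]))
        table = summarize_posterior(model.posterior_)
        assert table.iloc[0]["mean_pct"] == 100.0
        assert table.iloc[0]["sd_pct"] == 0.0
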