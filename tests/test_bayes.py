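"""Bayesian core: likelihood identity, priors, shrinkage behavior, posterior summaries."""

import numpy as np
import pytest
from scipy import stats

from bayesmr import (
    ObservedData,
    PriorSpec,
    StructuralParams,
    fit_single_exposure,
    prior_predictive_beta,
    shrinkage_weight,
    simulate_dataset,
    simulate_genotypes,
    summarize_posterior,
    benchmark_scenario,
    draw_structural_params,
)
from bayesmr.bayes import PosteriorSamples, draw_horseshoe_locals, marginal_loglik


# ---------------------------------------------------------------------------
# likelihood identity: marginalized bivariate normal == latent-U quadrature
# ---------------------------------------------------------------------------


from _oracles import latent_u_loglik_quadrature


def test_marginalized_likelihood_equals_quadrature():
    rng = np.random.default_rng(1)
    G = simulate_genotypes(5, 3, seed=2)
    params = StructuralParams(
        theta=0.35,
        alpha=np.array([0.4, -0.1, 0.2]),
        beta=np.array([0.05, 0.0, -0.02]),
        omega_X=3.3, omega_Y=0.9,
        delta_X=-0.1, delta_Y=-0.12, sigma_X=0.1, sigma_Y=0.3,
    )
    data = simulate_dataset(params, G, rng)
    direct = marginal_loglik(params, data)
    oracle = latent_u_loglik_quadrature(params, data)
    assert direct == pytest.approx(oracle, rel=1e-6)


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------


class TestShrinkageWeight:
    @pytest.mark.parametrize("phi,expected", [(0.0, 1.0), (1.0, 0.5), (3.0, 0.1)])
    def test_values(self, phi, expected):
        assert shrinkage_weight(phi) == pytest.approx(expected)

    def test_monotone_decreasing(self):
        phis = np.linspace(0, 10, 50)
        k = shrinkage_weight(phis)
        assert (np.diff(k) < 0).all()

    def test_negative_phi_rejected(self):
        with pytest.raises(ValueError):
            shrinkage_weight(-0.5)


class TestPriorPredictiveBeta:
    def test_point_zero_is_exactly_zero(self):
        draws = prior_predictive_beta(PriorSpec(beta_prior="point_zero"), J=4, n_draws=10)
        assert (draws == 0.0).all()

    def test_laplace_absolute_median_is_log_two(self):
        draws = prior_predictive_beta(
            PriorSpec(beta_prior="laplace"), J=1, n_draws=100_000,
            rng=np.random.default_rng(3), fixed_scale=1.0,
        )
        # |beta| ~ Exp(1) under Laplace(0, 1): median ln 2
        assert (np.abs(draws) > np.log(2)).mean() == pytest.approx(0.5, abs=0.01)

    def test_horseshoe_kappa_is_beta_half_half(self):
        rng = np.random.default_rng(4)
        locals_ = draw_horseshoe_locals(100_000, rng, gamma=1.0)
        ks = stats.kstest(locals_.kappa, stats.beta(0.5, 0.5).cdf).statistic
        assert ks < 0.01

    def test_prior_independent_of_exposure_model(self):
        # instrument-effects orthogonality: beta prior draws uncorrelated with alpha draws
        rng = np.random.default_rng(5)
        beta = prior_predictive_beta(PriorSpec(), J=1, n_draws=100_000, rng=rng)[:, 0]
        alpha = rng.normal(-0.07, 0.02, size=100_000)
        # guard against heavy tails dominating the sample correlation
        r = np.corrcoef(np.tanh(beta), alpha)[0, 1]
        assert abs(r) < 0.02


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------


def _samples_from(draws: dict) -> PosteriorSamples:
    return PosteriorSamples({k: np.asarray(v) for k, v in draws.items()})


class TestSummarizePosterior:
    def test_degenerate_draws(self):
        s = _samples_from({"theta": np.full((2, 50), 1.7)})
        out = summarize_posterior(s, "theta")
        assert out.mean == pytest.approx(1.7)
        assert out.lower == 1.7 and out.upper == 1.7

    def test_standard_normal_quantiles(self):
        rng = np.random.default_rng(6)
        s = _samples_from({"x": rng.standard_normal((1, 1_000_000))})
        out = summarize_posterior(s, "x", level=0.95)
        assert out.lower == pytest.approx(-1.96, abs=0.01)
        assert out.upper == pytest.approx(1.96, abs=0.01)

    def test_expression_two_point_law(self):
        t2 = np.array([[0.0, 1.0] * 50])
        t3 = np.ones((1, 100))
        s = _samples_from({"theta2": t2, "theta3": t3})
        out = summarize_posterior(s, "theta2*theta3")
        assert out.mean == pytest.approx(0.5)

    def test_unknown_parameter(self):
        s = _samples_from({"theta": np.zeros((1, 10))})
        with pytest.raises(KeyError):
            summarize_posterior(s, "nonexistent")


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def beta_zero_fit():
    """Scenario-3-style data with all pleiotropic effects zero, n=2000."""
    spec = benchmark_scenario(3)
    rng = np.random.default_rng(42)
    params = draw_structural_params(spec, "alternative", rng)
    params.beta[:] = 0.0
    G = simulate_genotypes(2000, 60, seed=9)
    data = simulate_dataset(params, G, rng)
    samples = fit_single_exposure(data, PriorSpec(), chains=2, warmup=500, iterations=500, seed=1)
    return params, data, samples


def test_theta_recovery_on_clean_data(beta_zero_fit):
    params, _, samples = beta_zero_fit
    pooled = samples.pooled("theta")
    z = abs(pooled.mean() - params.theta) / pooled.std()
    assert z < 3.0


def test_kappa_recomputable_from_phi(beta_zero_fit):
    _, _, samples = beta_zero_fit
    phi = samples.draws["phi"]
    assert np.array_equal(samples.draws["kappa"], 1.0 / (1.0 + phi**2))


def test_diagnostics_table(beta_zero_fit):
    _, _, samples = beta_zero_fit
    df = samples.diagnostics()
    assert df.loc["theta", "rhat"] < 1.05
    assert df.loc["theta", "ess"] > 100


def test_point_zero_interval_narrower_than_horseshoe():
    """With no true pleiotropy the beta=0 model is better identified."""
    spec = benchmark_scenario(7)
    rng = np.random.default_rng(10)
    widths_hs, widths_pz = [], []
    G = simulate_genotypes(500, 20, seed=11)
    for i in range(20):
        params = draw_structural_params(spec, "alternative", rng)
        params.beta[:] = 0.0
        data = simulate_dataset(params, G, rng)
        for prior, acc in ((PriorSpec(), widths_hs), (PriorSpec(beta_prior="point_zero"), widths_pz)):
            s = fit_single_exposure(data, prior, chains=1, warmup=300, iterations=300, seed=i)
            out = summarize_posterior(s, "theta")
            acc.append(out.upper - out.lower)
    assert np.mean(widths_pz) < np.mean(widths_hs)


def test_selective_shrinkage_separates_true_pleiotropy():
    """Posterior |beta_j| smaller for truly-zero instruments than pleiotropic ones."""
    spec = benchmark_scenario(1)  # mu_beta = 0.012, 40% of 60 instruments pleiotropic
    rng = np.random.default_rng(12)
    G = simulate_genotypes(500, 60, seed=13)
    diffs = []
    for i in range(20):
        params = draw_structural_params(spec, "alternative", rng)
        data = simulate_dataset(params, G, rng)
        s = fit_single_exposure(data, PriorSpec(), chains=1, warmup=300, iterations=300, seed=i)
        post_abs = np.abs(s.pooled("beta")).mean(axis=0)
        nonzero = params.beta != 0
        diffs.append(post_abs[nonzero].mean() - post_abs[~nonzero].mean())
    assert np.mean(diffs) > 0


def test_interaction_model_recovers_effect_modification():
    """Sex-by-exposure interaction (psi_YXW) recovered at a realistic magnitude."""
    rng = np.random.default_rng(14)
    n, J = 5000, 20
    G = simulate_genotypes(n, J, seed=15)
    W = rng.integers(0, 2, size=n)
    alpha = rng.normal(-0.07, 0.05, size=J)
    U = rng.standard_normal(n)
    psi_xw, psi_yw, psi_yxw, theta = 0.05, 0.1, -0.14, 0.3
    X = 3.3 + G.doses @ alpha + psi_xw * W - 0.1 * U + 0.1 * rng.standard_normal(n)
    Y = 0.9 + (theta + psi_yxw * W) * X + psi_yw * W - 0.1 * U + 0.3 * rng.standard_normal(n)
    data = ObservedData(Y=Y, X=X, Z=G.doses, W=W)
    s = fit_single_exposure(
        data, PriorSpec(), chains=2, warmup=400, iterations=400, seed=16, interaction=True
    )
    pooled = s.pooled("psi_YXW")
    assert abs(pooled.mean() - psi_yxw) / pooled.std() < 3.0
    pooled_t = s.pooled("theta")
    assert abs(pooled_t.mean() - theta) / pooled_t.std() < 3.5


def test_point_zero_beta_draws_are_zero(beta_zero_fit):
    _, data, _ = beta_zero_fit
    s = fit_single_exposure(
        data, PriorSpec(beta_prior="point_zero"), chains=1, warmup=100, iterations=100, seed=2
    )
    assert (s.pooled("beta") == 0.0).all()


def test_fit_is_deterministic_given_seed():
    spec = benchmark_scenario(7)
    rng = np.random.default_rng(20)
    params = draw_structural_params(spec, "null", rng)
    G = simulate_genotypes(300, 20, seed=21)
    data = simulate_dataset(params, G, rng)
    a = fit_single_exposure(data, PriorSpec(), chains=1, warmup=100, iterations=100, seed=5)
    b = fit_single_exposure(data, PriorSpec(), chains=1, warmup=100, iterations=100, seed=5)
    assert np.array_equal(a.pooled("theta"), b.pooled("theta"))


# ---------------------------------------------------------------------------
# cross-check of the Gibbs sampler against an independent MCMC implementation
# ---------------------------------------------------------------------------


def test_gibbs_posterior_matches_emcee_on_small_model():
    """Same flat-prior posterior sampled by the ensemble sampler (beta = 0 model)."""
    import emcee

    rng = np.random.default_rng(30)
    G = simulate_genotypes(300, 2, seed=31)
    true = StructuralParams(
        theta=0.5, alpha=np.array([0.3, 0.25]), beta=np.zeros(2),
        omega_X=1.0, omega_Y=0.0, delta_X=-0.1, delta_Y=-0.1, sigma_X=0.15, sigma_Y=0.2,
    )
    data = simulate_dataset(true, G, rng)

    def logpost(v):
        ox, a1, a2, oy, th, dx, dy, sx, sy = v
        if sx <= 0 or sy <= 0:
            return -np.inf
        p = StructuralParams(
            theta=th, alpha=np.array([a1, a2]), beta=np.zeros(2),
            omega_X=ox, omega_Y=oy, delta_X=dx, delta_Y=dy, sigma_X=sx, sigma_Y=sy,
        )
        return marginal_loglik(p, data)

    start = np.array([1.0, 0.3, 0.25, 0.0, 0.5, -0.05, -0.05, 0.15, 0.2])
    nwalkers = 36
    p0 = start + 1e-3 * np.random.default_rng(32).standard_normal((nwalkers, 9))
    sampler = emcee.EnsembleSampler(nwalkers, 9, logpost)
    sampler.run_mcmc(p0, 4000, progress=False)
    chain = sampler.get_chain(discard=2000, flat=True)
    theta_emcee = chain[:, 4]

    s = fit_single_exposure(
        data, PriorSpec(beta_prior="point_zero", alpha_hierarchical=False),
        chains=2, warmup=1000, iterations=2000, seed=33,
    )
    theta_gibbs = s.pooled("theta")
    sd = theta_gibbs.std()
    assert theta_gibbs.mean() == pytest.approx(theta_emcee.mean(), abs=0.3 * sd)
    assert theta_gibbs.std() == pytest.approx(theta_emcee.std(), rel=0.2)


def test_diagnostics_agree_with_arviz():
    import arviz as az

    rng = np.random.default_rng(40)
    # AR(1) chains with known autocorrelation
    chains = np.empty((4, 2000))
    for c in range(4):
        e = rng.standard_normal(2000)
        x = np.empty(2000)
        x[0] = e[0]
        for t in range(1, 2000):
            x[t] = 0.6 * x[t - 1] + e[t]
        chains[c] = x
    from bayesmr._diag import ess, split_rhat

    assert split_rhat(chains) == pytest.approx(float(az.rhat(chains.copy())), abs=0.02)
    assert ess(chains) == pytest.approx(float(az.ess(chains.copy())), rel=0.2)
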