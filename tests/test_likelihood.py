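"""Conditional and marginal likelihoods: closed forms vs independent oracles."""

import numpy as np
import pytest
from scipy import integrate, stats

from megh import (
    ClusteredDataset,
    LogLogistic,
    MEGHParams,
    NormalRandomEffects,
    PowerGeneralisedWeibull,
    cluster_cond_loglik,
    cluster_marginal_loglik,
    conditional_cumhaz,
    conditional_log_hazard,
    marginal_loglik,
    profile_random_effect,
)
from megh.likelihood import ClusterLogLik, scaled_integrand


def _params(sd=1.0, beta=(0.5, -0.3), alpha=(0.4,)):
    return MEGHParams(
        beta=np.array(beta),
        alpha=np.array(alpha),
        baseline=PowerGeneralisedWeibull(0.4, 1.3, 2.0),
        re=NormalRandomEffects(sd_u=sd) if sd else None,
    )


def _toy_dataset(rng, r=5, ni=8):
    n = r * ni
    X = rng.standard_normal((n, 2))
    Xt = X[:, :1]
    t = rng.exponential(0.5, n) + 0.01
    d = (rng.random(n) < 0.75).astype(int)
    cl = np.repeat(np.arange(r), ni)
    return ClusteredDataset(time=t, status=d, cluster=cl, X=X, X_time=Xt)


# ---------------------------------------------------------------------------
# conditional quantities


def test_null_covariates_recover_baseline():
    p = _params(beta=(0.0, 0.0), alpha=(0.0,))
    t = 0.7
    lh = conditional_log_hazard(t, [0.0, 0.0], [0.0], p, "megh1", u=0.0)
    assert lh == pytest.approx(float(p.baseline.log_hazard(t)), rel=1e-12)


def test_megh1_alpha_zero_is_proportional_hazards():
    """With alpha=0 structure I is the PH-with-frailty hazard
    h0(t) e^{x'beta + u}."""
    p = _params(alpha=(0.0,))
    x, xt, u, t = np.array([1.0, 2.0]), np.array([1.0]), 0.3, 0.9
    lh = conditional_log_hazard(t, x, xt, p, "megh1", u=u)
    expected = float(p.baseline.log_hazard(t)) + x @ p.beta + u
    assert lh == pytest.approx(expected, rel=1e-12)
    H = conditional_cumhaz(t, x, xt, p, "megh1", u=u)
    assert H == pytest.approx(float(p.baseline.cumhaz(t)) * np.exp(x @ p.beta + u))


def test_megh2_alpha_equals_beta_is_aft():
    """Structure II with alpha=beta and shared covariates has the AFT
    log-hazard log h0(t e^{x'beta+u}) + x'beta + u."""
    beta = np.array([0.5, -0.3])
    p = MEGHParams(
        beta=beta,
        alpha=beta.copy(),
        baseline=PowerGeneralisedWeibull(0.4, 1.3, 2.0),
        re=NormalRandomEffects(1.0),
    )
    x = np.array([0.7, -1.1])
    u, t = -0.4, 1.3
    acc = float(x @ beta + u)
    lh = conditional_log_hazard(t, x, x, p, "megh2", u=u)
    assert lh == pytest.approx(
        float(p.baseline.log_hazard(t * np.exp(acc))) + acc, rel=1e-12
    )
    # cumulative hazard loses the hazard-scale factor entirely
    H = conditional_cumhaz(t, x, x, p, "megh2", u=u)
    assert H == pytest.approx(float(p.baseline.cumhaz(t * np.exp(acc))), rel=1e-12)


@pytest.mark.parametrize("structure", ["megh1", "megh2"])
def test_cumhaz_is_integral_of_hazard(structure, rng):
    p = _params()
    x, xt = rng.standard_normal(2), rng.standard_normal(1)
    u = 0.6
    for t in [0.3, 1.7]:
        val, _ = integrate.quad(
            lambda s: np.exp(
                conditional_log_hazard(s, x, xt, p, structure, u=u)
            ),
            0.0,
            t,
            limit=200,
        )
        H = conditional_cumhaz(t, x, xt, p, structure, u=u)
        assert H == pytest.approx(val, rel=1e-5)
    assert conditional_cumhaz(0.0, x, xt, p, structure, u=u) == 0.0


# ---------------------------------------------------------------------------
# cluster conditional log-likelihood


@pytest.mark.parametrize("structure", ["gh", "megh1", "megh2"])
def test_cluster_loglik_matches_per_subject_loop(structure, rng):
    data = _toy_dataset(rng)
    p = _params()
    u = 0.37
    got = cluster_cond_loglik(data, p, structure, u)
    expected = np.zeros(data.r)
    for j in range(data.n):
        i = data.cluster[j]
        uu = 0.0 if structure == "gh" else u
        lh = conditional_log_hazard(
            data.time[j], data.X[j], data.X_time[j], p, structure, u=uu
        )
        H = conditional_cumhaz(
            data.time[j], data.X[j], data.X_time[j], p, structure, u=uu
        )
        expected[i] += data.status[j] * lh - H
    np.testing.assert_allclose(got, expected, rtol=1e-10)


def test_fully_censored_cluster_loglik_is_negative(rng):
    data = _toy_dataset(rng, r=2, ni=5)
    data.status[:] = 0.0
    p = _params()
    ll = cluster_cond_loglik(data, p, "megh1", 0.1)
    assert np.all(ll < 0)


# ---------------------------------------------------------------------------
# marginal likelihood


def _mc_log_marginal_with_se(data, params, structure, n_mc, seed):
    """Independent Monte Carlo oracle with a delta-method standard error."""
    ell = ClusterLogLik(data, params, structure)
    draws = params.re.sample(n_mc, np.random.default_rng(seed))
    vals = ell(np.broadcast_to(draws, (ell.r, n_mc)))
    m = vals.max(axis=1, keepdims=True)
    w = np.exp(vals - m)
    mean_w = w.mean(axis=1)
    se_logm = w.std(axis=1, ddof=1) / (np.sqrt(n_mc) * mean_w)
    return m[:, 0] + np.log(mean_w), se_logm


@pytest.mark.parametrize("structure", ["megh1", "megh2"])
@pytest.mark.parametrize("method", ["agh", "quad"])
def test_marginal_loglik_within_3_mc_se(structure, method, rng):
    data = _toy_dataset(rng, r=4, ni=10)
    p = _params(sd=0.8)
    got = cluster_marginal_loglik(data, p, structure, method=method)
    oracle, se = _mc_log_marginal_with_se(data, p, structure, 10**6, 99)
    assert np.all(np.abs(got - oracle) <= 3 * se)


def test_agh_and_quad_agree_tightly(rng):
    data = _toy_dataset(rng, r=5, ni=12)
    p = _params(sd=1.2)
    for structure in ["megh1", "megh2"]:
        a = cluster_marginal_loglik(data, p, structure, method="agh")
        q = cluster_marginal_loglik(data, p, structure, method="quad")
        np.testing.assert_allclose(a, q, rtol=1e-6, atol=1e-6)


def test_scaled_integrand_attains_one_at_inner_maximiser(rng):
    data = _toy_dataset(rng)
    p = _params()
    u_star, logK = profile_random_effect(data, p, "megh1")
    vals = scaled_integrand(data, p, "megh1", u_star[:, None])
    np.testing.assert_allclose(vals[:, 0], 1.0, rtol=1e-8)
    # and never exceeds one nearby
    grid = np.linspace(-3, 3, 41)
    assert np.all(scaled_integrand(data, p, "megh1", grid) <= 1.0 + 1e-10)


def test_sigma_to_zero_limit_is_fixed_effects_loglik(rng):
    """As sd -> 0 the marginal likelihood degenerates to the conditional
    likelihood at u = 0."""
    data = _toy_dataset(rng)
    p = _params(sd=1e-8)
    logm = cluster_marginal_loglik(data, p, "megh1", method="agh")
    at_zero = cluster_cond_loglik(data, p, "megh1", 0.0)
    np.testing.assert_allclose(logm, at_zero, atol=1e-4)


def test_single_cluster_marginal_equals_total(rng):
    data = _toy_dataset(rng, r=1, ni=10)
    p = _params()
    assert marginal_loglik(data, p, "megh1") == pytest.approx(
        float(cluster_marginal_loglik(data, p, "megh1")[0])
    )


def test_gh_structure_needs_no_integral(rng):
    data = _toy_dataset(rng)
    p = _params(sd=None)
    total = marginal_loglik(data, p, "gh")
    assert total == pytest.approx(float(np.sum(cluster_cond_loglik(data, p, "gh", 0.0))))


def test_cluster_permutation_invariance(rng):
    data = _toy_dataset(rng)
    p = _params()
    base = marginal_loglik(data, p, "megh1")
    perm = rng.permutation(data.n)
    shuffled = ClusteredDataset(
        time=data.time[perm],
        status=data.status[perm],
        cluster=data.cluster[perm],
        X=data.X[perm],
        X_time=data.X_time[perm],
    )
    assert marginal_loglik(shuffled, p, "megh1") == pytest.approx(base, rel=1e-12)


# ---------------------------------------------------------------------------
# nesting against independent oracles


def test_megh1_without_time_covariates_matches_meph_oracle(rng):
    """Structure I with an empty time-scale design is the mixed-effects PH
    model; oracle built directly from the PH likelihood and quadrature."""
    data = _toy_dataset(rng, r=4, ni=8)
    data = ClusteredDataset(
        time=data.time, status=data.status, cluster=data.cluster,
        X=data.X, X_time=None,
    )
    p = MEGHParams(
        beta=np.array([0.5, -0.3]),
        alpha=np.empty(0),
        baseline=LogLogistic(0.3, 0.8),
        re=NormalRandomEffects(0.7),
    )
    got = marginal_loglik(data, p, "megh1", method="quad")

    def oracle():
        total = 0.0
        b = p.baseline
        for i in range(data.r):
            rows = data.cluster == i
            t, d, X = data.time[rows], data.status[rows], data.X[rows]
            eta = X @ p.beta

            def integrand(u):
                ll = np.sum(
                    d * (b.log_hazard(t) + eta + u)
                    - b.cumhaz(t) * np.exp(eta + u)
                )
                return np.exp(ll) * stats.norm.pdf(u, scale=0.7)

            val, _ = integrate.quad(integrand, -8, 8, limit=400)
            total += np.log(val)
        return total

    assert got == pytest.approx(oracle(), rel=1e-6)


def test_megh2_shared_coefficients_matches_meaft_oracle(rng):
    """Structure II with x~ = x and alpha = beta is the mixed-effects AFT
    model; oracle built from the scipy log-logistic (Fisk) distribution."""
    data = _toy_dataset(rng, r=4, ni=8)
    beta = np.array([0.5, -0.3])
    mu, tau = 0.3, 0.8
    p = MEGHParams(
        beta=beta, alpha=beta.copy(), baseline=LogLogistic(mu, tau),
        re=NormalRandomEffects(0.7),
    )
    data_shared = ClusteredDataset(
        time=data.time, status=data.status, cluster=data.cluster,
        X=data.X, X_time=data.X,
    )
    got = marginal_loglik(data_shared, p, "megh2", method="quad")

    dist = stats.fisk(c=1.0 / tau, scale=np.exp(mu))

    def oracle():
        total = 0.0
        for i in range(data.r):
            rows = data.cluster == i
            t, d, X = data.time[rows], data.status[rows], data.X[rows]
            acc = X @ beta

            def integrand(u):
                v = t * np.exp(acc + u)
                ll = np.sum(
                    d * (dist.logpdf(v) + acc + u) + (1 - d) * dist.logsf(v)
                )
                return np.exp(ll) * stats.norm.pdf(u, scale=0.7)

            val, _ = integrate.quad(integrand, -8, 8, limit=400)
            total += np.log(val)
        return total

    assert got == pytest.approx(oracle(), rel=1e-6)
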