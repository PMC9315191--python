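"""MMLE fitting, standard errors, AIC and the scikit-learn estimator."""

import numpy as np
import pytest
from scipy import integrate, optimize, stats
from sklearn.base import clone

from megh import (
    ClusteredDataset,
    LogLogistic,
    MEGHModel,
    aic,
    fit_mmle,
    marginal_loglik,
    simulate_dataset,
    table1_design,
)
from megh.simulate import default_cluster_sizes


def test_fit_recovers_truth_roughly(small_design, small_data, small_fit):
    """Correct-structure fit lands near the generating parameters on a
    single small replicate (weak sanity band; the study harness does the
    quantitative recovery check)."""
    truth = np.concatenate(
        [
            small_design.beta,
            small_design.alpha,
            small_design.baseline.theta,
            [small_design.re.sd],
        ]
    )
    assert small_fit.converged
    # regression coefficients within generous absolute bands
    np.testing.assert_allclose(small_fit.estimates[:5], truth[:5], atol=0.6)
    assert 0.3 < small_fit.re_sd < 2.5


def test_loglik_at_mmle_dominates_truth(small_design, small_data, small_fit):
    """The maximised marginal log-likelihood is at least its value at the
    generating parameters."""
    ll_truth = marginal_loglik(small_data, small_design.params, "megh1")
    assert small_fit.loglik >= ll_truth - 1e-6


def test_standard_errors_positive_and_finite(small_fit):
    assert np.all(np.isfinite(small_fit.se))
    assert np.all(small_fit.se > 0)


def test_aic_arithmetic(small_fit):
    assert aic(small_fit) == pytest.approx(
        2 * small_fit.n_params - 2 * small_fit.loglik, rel=1e-12
    )


def test_gh_and_mixed_k_differ_by_one(tiny_data):
    gh = fit_mmle(tiny_data, structure="gh", baseline="loglogistic", compute_se=False)
    mixed = fit_mmle(
        tiny_data, structure="megh1", baseline="loglogistic",
        starts="gh", compute_se=False,
    )
    assert mixed.n_params - gh.n_params == 1
    # nested models: the mixed fit can only improve the likelihood
    assert mixed.loglik >= gh.loglik - 1e-6


def test_zero_variance_truth_shrinks_to_boundary():
    """Without a true random effect the mixed fit collapses onto the
    fixed-effects model: the likelihood gain is negligible on every
    replicate and the variance estimate hits the boundary on some."""
    design = table1_design(sigma_u=0).replace(
        cluster_sizes=default_cluster_sizes(240, 12)
    )
    sds, gains = [], []
    for seed in range(6):
        data = simulate_dataset(design, seed=10 + seed)
        gh = fit_mmle(data, structure="gh", compute_se=False)
        mixed = fit_mmle(data, structure="megh1", starts="gh", compute_se=False)
        sds.append(mixed.re_sd)
        gains.append(mixed.loglik - gh.loglik)
    assert min(sds) <= 0.02
    assert all(g > -1e-6 for g in gains)  # nested: never worse
    assert np.median(gains) < 0.1


def test_fitted_maximum_beats_direct_oracle_optimiser(tiny_data):
    """Maximised log-likelihood matches an independent optimisation of the
    mixed-effects PH oracle likelihood (structure I, no time covariates)."""
    data = ClusteredDataset(
        time=tiny_data.time, status=tiny_data.status, cluster=tiny_data.cluster,
        X=tiny_data.X, X_time=None,
    )
    fit = fit_mmle(
        data, structure="megh1", baseline="loglogistic", compute_se=False
    )

    def neg_oracle(z):
        beta, mu, ltau, lsd = z[:4], z[4], z[5], z[6]
        b = LogLogistic(mu, np.exp(ltau))
        sd = np.exp(lsd)
        total = 0.0
        for i in range(data.r):
            rows = data.cluster == i
            t, d, X = data.time[rows], data.status[rows], data.X[rows]
            eta = X @ beta
            base_lh = b.log_hazard(t)
            base_H = b.cumhaz(t)

            def ll(u):
                return np.sum(d * (base_lh + eta + u) - base_H * np.exp(eta + u))

            # rescale the integrand so adaptive quadrature keeps precision
            K = max(ll(u) for u in np.linspace(-6 * sd, 6 * sd, 121))

            def integrand(u):
                return np.exp(ll(u) - K) * stats.norm.pdf(u, scale=sd)

            val, _ = integrate.quad(integrand, -np.inf, np.inf, limit=400)
            total += K + np.log(max(val, 1e-300))
        return -total

    # polish the oracle likelihood from the fitted point: the value must
    # agree and the oracle optimiser must not be able to improve on it
    z0 = np.concatenate(
        [
            fit.params.beta,
            [fit.params.baseline.mu, np.log(fit.params.baseline.tau),
             np.log(fit.params.re.sd)],
        ]
    )
    assert neg_oracle(z0) == pytest.approx(-fit.loglik, abs=1e-4)
    res = optimize.minimize(neg_oracle, z0, method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-7, "fatol": 1e-10})
    assert fit.loglik == pytest.approx(-res.fun, abs=1e-4)


def test_bias_shrinks_with_more_clusters():
    """Consistency in the number of clusters: average absolute bias of the
    regression coefficients falls as r grows from 10 to 40 (fixed cluster
    size)."""
    reps = 8
    biases = {}
    for r in (10, 40):
        design = table1_design(sigma_u=0.5).replace(
            cluster_sizes=default_cluster_sizes(20 * r, r)
        )
        errs = []
        for k in range(reps):
            data = simulate_dataset(design, seed=300 + k)
            f = fit_mmle(data, structure="megh1", starts="gh", compute_se=False)
            est = np.concatenate([f.params.beta, f.params.alpha])
            truth = np.concatenate([design.beta, design.alpha])
            errs.append(est - truth)
        biases[r] = np.abs(np.mean(errs, axis=0)).mean()
    assert biases[40] < biases[10]


# ---------------------------------------------------------------------------
# scikit-learn estimator surface


def _xy(data):
    y = np.empty(data.n, dtype=[("event", "?"), ("time", "<f8")])
    y["event"] = data.status.astype(bool)
    y["time"] = data.time
    return data.X, y, np.asarray(data.cluster_labels)[data.cluster]


def test_estimator_fits_structured_y(tiny_data):
    X, y, groups = _xy(tiny_data)
    est = MEGHModel(structure="megh1", baseline="loglogistic", time_cols=[0],
                    starts="gh")
    est.fit(X, y, groups=groups)
    assert est.coef_.shape == (4,)
    assert est.time_coef_.shape == (1,)
    assert est.re_sd_ > 0
    assert est.aic_ == pytest.approx(2 * est.result_.n_params - 2 * est.loglik_)
    # score returns the fitted log marginal likelihood on the same data
    assert est.score(X, y, groups=groups) == pytest.approx(est.loglik_, rel=1e-10)


def test_estimator_clone_and_get_params():
    est = MEGHModel(structure="megh2", baseline="gamma", n_quad=31)
    params = est.get_params()
    assert params["structure"] == "megh2" and params["n_quad"] == 31
    cloned = clone(est)
    assert cloned.get_params() == params


def test_predicted_survival_is_decreasing(tiny_data):
    X, y, groups = _xy(tiny_data)
    est = MEGHModel(structure="megh1", baseline="loglogistic", time_cols=[0],
                    starts="gh").fit(X, y, groups=groups)
    times = np.linspace(0.05, 5, 40)
    S = est.predict_survival(X[:3], times)
    assert S.shape == (3, 40)
    assert np.all(np.diff(S, axis=1) <= 1e-12)
    assert np.all((S >= 0) & (S <= 1))


def test_estimator_accepts_two_column_y(tiny_data):
    y2 = np.column_stack([tiny_data.time, tiny_data.status])
    est = MEGHModel(structure="gh", baseline="loglogistic", time_cols=[0])
    est.fit(tiny_data.X, y2, groups=tiny_data.cluster)
    assert est.re_sd_ is None
    assert np.isfinite(est.loglik_)
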