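"""Marginal maximum likelihood estimation of mixed-effects general hazard models.

``fit_mmle`` maximises the log marginal likelihood over the unconstrained
reparameterised space (positive parameters on the log scale) with L-BFGS-B,
optionally from several starts, and reports delta-method standard errors
from the inverse numerical Hessian.  ``MEGHModel`` wraps the same machinery
in a scikit-learn style estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator
from statsmodels.tools.numdiff import approx_hess1

from .baselines import BaselineHazard, make_baseline
from .data import ClusteredDataset
from .likelihood import (
    MEGHParams,
    Structure,
    as_structure,
    cluster_marginal_loglik,
    conditional_cumhaz,
    marginal_loglik,
)
from .random_effects import RandomEffects, make_random_effects

__all__ = ["FitResult", "fit_mmle", "aic", "MEGHModel"]

_BIG = 1e10
_LOG_SD_BOUNDS = (np.log(1e-6), np.log(50.0))
_LOG_THETA_BOUNDS = (-20.0, 20.0)


# ---------------------------------------------------------------------------
# parameter vector <-> unconstrained optimisation space


def _pack(params: MEGHParams) -> np.ndarray:
    z = [params.beta, params.alpha, params.baseline.to_unconstrained()]
    if params.re is not None:
        z.append(params.re.to_unconstrained())
    return np.concatenate([np.atleast_1d(v) for v in z])


def _unpack(z: np.ndarray, template: MEGHParams) -> MEGHParams:
    p = template.beta.size
    pt = template.alpha.size
    k0 = template.baseline.n_params
    beta = z[:p]
    alpha = z[p : p + pt]
    baseline = template.baseline.from_unconstrained(z[p + pt : p + pt + k0])
    re = None
    if template.re is not None:
        re = template.re.from_unconstrained(z[p + pt + k0 :])
    return MEGHParams(beta=beta, alpha=alpha, baseline=baseline, re=re)


def _bounds(template: MEGHParams):
    out = [(None, None)] * (template.beta.size + template.alpha.size)
    for is_log in template.baseline.log_transformed:
        out.append(_LOG_THETA_BOUNDS if is_log else (None, None))
    if template.re is not None:
        out.extend([_LOG_SD_BOUNDS] * template.re.n_params)
    return out


def _param_names(data: ClusteredDataset, template: MEGHParams) -> list[str]:
    names = list(data.x_names[: template.beta.size])
    names += [f"alpha:{n}" for n in data.x_time_names[: template.alpha.size]]
    names += list(template.baseline.param_names)
    if template.re is not None:
        names += list(template.re.free_names)
    return names


def _transform_jacobian(params: MEGHParams) -> np.ndarray:
    parts = [
        np.ones(params.beta.size + params.alpha.size),
        params.baseline.transform_jacobian(),
    ]
    if params.re is not None:
        parts.append(params.re.transform_jacobian())
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# results


@dataclass
class FitResult:
    """Marginal maximum likelihood fit of one model specification."""

    params: MEGHParams
    structure: Structure
    loglik: float
    param_names: list[str]
    estimates: np.ndarray
    se: np.ndarray
    hessian: np.ndarray | None
    converged: bool
    n_iter: int
    n_params: int
    message: str = ""
    quadrature: str = "agh"
    n_quad: int = 25

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    @property
    def re_sd(self) -> float | None:
        return None if self.params.re is None else self.params.re.sd

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"estimate": self.estimates, "se": self.se}, index=self.param_names
        )
        lo = df["estimate"] - 1.959963984540054 * df["se"]
        hi = df["estimate"] + 1.959963984540054 * df["se"]
        df["ci_low"], df["ci_high"] = lo, hi
        return df

    def to_dict(self) -> dict:
        return {
            "structure": self.structure.value,
            "baseline": type(self.params.baseline).__name__,
            "random_effects": (
                None if self.params.re is None else type(self.params.re).__name__
            ),
            "loglik": self.loglik,
            "aic": self.aic,
            "n_params": self.n_params,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "estimates": dict(zip(self.param_names, map(float, self.estimates))),
            "se": dict(zip(self.param_names, map(float, self.se))),
        }


def aic(fit: FitResult) -> float:
    """Akaike information criterion, ``2k - 2 loglik``."""
    return fit.aic


# ---------------------------------------------------------------------------
# initial values


def _init_baseline(baseline: BaselineHazard, t: np.ndarray) -> BaselineHazard:
    lt = np.log(t)
    mu, tau = float(np.mean(lt)), float(max(np.std(lt), 0.1))
    name = type(baseline).__name__
    if name == "PowerGeneralisedWeibull":
        return baseline.with_theta([float(np.median(t)), 1.0, 1.0])
    if name in ("LogLogistic", "LogNormal"):
        return baseline.with_theta([mu, tau])
    if name == "Gamma":
        return baseline.with_theta([1.0, 1.0 / float(np.mean(t))])
    return baseline


def _minimize(fun, z0, bounds, maxiter):
    return optimize.minimize(
        fun,
        z0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "maxfun": 10 * maxiter, "ftol": 1e-11},
    )


# ---------------------------------------------------------------------------
# fitting


def fit_mmle(
    data: ClusteredDataset,
    structure="megh1",
    baseline="pgw",
    random_effects="normal",
    df: float = 4.0,
    init: MEGHParams | None = None,
    quadrature: str = "agh",
    n_quad: int = 25,
    starts: str = "multi",
    maxiter: int = 500,
    compute_se: bool = True,
) -> FitResult:
    """Fit a mixed-effects (or fixed-effects) general hazard model by MMLE.

    Parameters
    ----------
    structure : 'gh', 'megh1' or 'megh2'.
    baseline : baseline family name or a :class:`BaselineHazard` instance
        used both as family choice and as initial value.
    random_effects : random-effects family name or instance (ignored for
        the 'gh' structure).
    starts : 'multi' (warm start from the fixed-effects fit plus a null
        start), 'gh' (warm start only) or 'null'.
    """
    structure = as_structure(structure)
    p, pt = data.X.shape[1], data.X_time.shape[1]
    b0 = make_baseline(baseline)
    b0 = _init_baseline(b0, data.time) if not isinstance(baseline, BaselineHazard) else b0

    def negloglik_factory(template):
        def nll(z):
            try:
                params = _unpack(z, template)
            except ValueError:
                return _BIG
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ll = marginal_loglik(
                    data, params, structure, method=quadrature, n_quad=n_quad
                )
            return -ll if np.isfinite(ll) else _BIG

        return nll

    # fixed-effects fit: both a model in its own right and a warm start
    gh_template = MEGHParams(beta=np.zeros(p), alpha=np.zeros(pt), baseline=b0)
    if structure is Structure.GH:
        template = init if init is not None else gh_template
        start_list = [_pack(template)]
    else:
        re0 = make_random_effects(random_effects, sd=0.2, df=df)
        if init is not None:
            template = init
            start_list = [_pack(init)]
        else:
            template = MEGHParams(
                beta=np.zeros(p), alpha=np.zeros(pt), baseline=b0, re=re0
            )
            start_list = []
            if starts in ("multi", "gh"):
                gh_fit = fit_mmle(
                    data,
                    structure="gh",
                    baseline=b0,
                    quadrature=quadrature,
                    n_quad=n_quad,
                    maxiter=maxiter,
                    compute_se=False,
                )
                warm = MEGHParams(
                    beta=gh_fit.params.beta,
                    alpha=gh_fit.params.alpha,
                    baseline=gh_fit.params.baseline,
                    re=re0,
                )
                start_list.append(_pack(warm))
            if starts in ("multi", "null"):
                null = template.replace(
                    re=make_random_effects(random_effects, sd=0.5, df=df)
                )
                start_list.append(_pack(null))

    nll = negloglik_factory(template)
    bounds = _bounds(template)
    best = None
    for z0 in start_list:
        res = _minimize(nll, z0, bounds, maxiter)
        if best is None or res.fun < best.fun:
            best = res

    params_hat = _unpack(best.x, template)
    loglik = -float(best.fun)
    names = _param_names(data, template)
    estimates = np.concatenate(
        [
            params_hat.beta,
            params_hat.alpha,
            params_hat.theta,
            params_hat.xi,
        ]
    )

    se = np.full(estimates.size, np.nan)
    hess = None
    if compute_se:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                hess = approx_hess1(best.x, nll)
                cov_z = np.linalg.inv(hess)
                var_z = np.diag(cov_z)
                if np.all(var_z > 0):
                    se = np.sqrt(var_z) * np.abs(_transform_jacobian(params_hat))
            except np.linalg.LinAlgError:
                pass
        if np.any(~np.isfinite(se)):
            warnings.warn(
                "Hessian is singular or not positive definite; some standard "
                "errors are reported as NaN",
                stacklevel=2,
            )

    return FitResult(
        params=params_hat,
        structure=structure,
        loglik=loglik,
        param_names=names,
        estimates=estimates,
        se=se,
        hessian=hess,
        converged=bool(best.success),
        n_iter=int(best.nit),
        n_params=params_hat.n_params,
        message=str(best.message),
        quadrature=quadrature,
        n_quad=n_quad,
    )


# ---------------------------------------------------------------------------
# scikit-learn estimator


def _as_survival_arrays(y):
    """Accept (time, event) tuples, 2-column arrays, or structured arrays
    with 'event'/'status' and 'time' fields (scikit-survival convention)."""
    if isinstance(y, tuple) and len(y) == 2:
        return np.asarray(y[0], dtype=float), np.asarray(y[1])
    y = np.asarray(y)
    if y.dtype.names:
        names = {n.lower(): n for n in y.dtype.names}
        time_key = names.get("time") or names.get("t")
        ev_key = names.get("event") or names.get("status") or names.get("d")
        if time_key is None or ev_key is None:
            raise ValueError("structured y must have 'time' and 'event' fields")
        return y[time_key].astype(float), y[ev_key].astype(float)
    if y.ndim == 2 and y.shape[1] == 2:
        return y[:, 0].astype(float), y[:, 1]
    raise ValueError(
        "y must be a (time, event) tuple, an (n, 2) array with columns "
        "[time, event], or a structured array with time/event fields"
    )


class MEGHModel(BaseEstimator):
    """Mixed-effects general hazard survival regression.

    The conditional hazard for a subject in cluster ``i`` is
    ``h0(t e^{xt'alpha + ut_i}) e^{x'beta + u_i}`` with a parametric
    baseline ``h0`` and a zero-mean cluster random effect; estimation
    maximises the marginal likelihood (random effect integrated out
    numerically per cluster).

    Parameters
    ----------
    structure : {'megh1', 'megh2', 'gh'}
        'megh1' puts the random effect on the hazard scale only,
        'megh2' puts the same effect on both scales, 'gh' drops it.
    baseline : {'pgw', 'loglogistic', 'lognormal', 'gamma'}
    random_effects : {'normal', 'student_t', 'two_piece_normal'}
    df : Student-t degrees of freedom (fixed, not estimated).
    time_cols : indices of the columns of ``X`` that also act on the time
        scale, or None to pass a separate ``X_time`` to :meth:`fit`.
    quadrature : {'agh', 'quad'} integration back-end.
    n_quad : number of Gauss–Hermite nodes for 'agh'.
    starts : {'multi', 'gh', 'null'} starting strategy for the optimiser.

    Attributes
    ----------
    coef_ : hazard-scale coefficients (beta).
    time_coef_ : time-scale coefficients (alpha).
    baseline_ : fitted baseline hazard object.
    re_sd_ : fitted random-effect standard deviation (None for 'gh').
    loglik_, aic_, se_, converged_, n_iter_, result_ : fit metadata.
    """

    def __init__(
        self,
        structure: str = "megh1",
        baseline: str = "pgw",
        random_effects: str = "normal",
        df: float = 4.0,
        time_cols=None,
        quadrature: str = "agh",
        n_quad: int = 25,
        starts: str = "multi",
        maxiter: int = 500,
    ):
        self.structure = structure
        self.baseline = baseline
        self.random_effects = random_effects
        self.df = df
        self.time_cols = time_cols
        self.quadrature = quadrature
        self.n_quad = n_quad
        self.starts = starts
        self.maxiter = maxiter

    # -- data assembly --------------------------------------------------
    def _build_dataset(self, X, y, groups, X_time) -> ClusteredDataset:
        if isinstance(X, ClusteredDataset):
            return X
        time, status = _as_survival_arrays(y)
        x_names = None
        if isinstance(X, pd.DataFrame):
            x_names = list(X.columns)
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        if groups is None:
            groups = np.zeros(X.shape[0], dtype=int)
        xt_names = None
        if X_time is None:
            cols = [] if self.time_cols is None else list(self.time_cols)
            X_time = X[:, cols]
            if x_names is not None:
                xt_names = [x_names[c] for c in cols]
        elif isinstance(X_time, pd.DataFrame):
            xt_names = list(X_time.columns)
            X_time = X_time.to_numpy(dtype=float)
        return ClusteredDataset(
            time=time,
            status=status,
            cluster=np.asarray(groups),
            X=X,
            X_time=X_time,
            x_names=x_names or [],
            x_time_names=xt_names or [],
        )

    # -- estimator API ---------------------------------------------------
    def fit(self, X, y=None, groups=None, X_time=None):
        data = self._build_dataset(X, y, groups, X_time)
        result = fit_mmle(
            data,
            structure=self.structure,
            baseline=self.baseline,
            random_effects=self.random_effects,
            df=self.df,
            quadrature=self.quadrature,
            n_quad=self.n_quad,
            starts=self.starts,
            maxiter=self.maxiter,
        )
        self.result_ = result
        self.params_ = result.params
        self.coef_ = result.params.beta
        self.time_coef_ = result.params.alpha
        self.baseline_ = result.params.baseline
        self.re_sd_ = result.re_sd
        self.loglik_ = result.loglik
        self.aic_ = result.aic
        self.se_ = result.se
        self.param_names_ = result.param_names
        self.converged_ = result.converged
        self.n_iter_ = result.n_iter
        self.n_features_in_ = data.X.shape[1]
        return self

    def score(self, X, y=None, groups=None, X_time=None) -> float:
        """Log marginal likelihood of the data under the fitted parameters."""
        data = self._build_dataset(X, y, groups, X_time)
        return marginal_loglik(
            data,
            self.params_,
            self.result_.structure,
            method=self.quadrature,
            n_quad=self.n_quad,
        )

    def predict_cumulative_hazard(self, X, times, X_time=None, u: float = 0.0):
        """Conditional cumulative hazard H(t | x, u) on a grid of times.

        Evaluated at random effect ``u`` (0 by default, i.e. the median
        cluster).  Returns an (n_samples, n_times) array.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X_time is None:
            cols = [] if self.time_cols is None else list(self.time_cols)
            X_time = X[:, cols]
        X_time = np.asarray(X_time, dtype=float)
        times = np.asarray(times, dtype=float)
        out = np.empty((X.shape[0], times.size))
        for k in range(X.shape[0]):
            out[k] = conditional_cumhaz(
                times, X[k], X_time[k], self.params_, self.result_.structure, u=u
            )
        return out

    def predict_survival(self, X, times, X_time=None, u: float = 0.0):
        """Conditional survival ``exp(-H(t | x, u))``."""
        return np.exp(-self.predict_cumulative_hazard(X, times, X_time=X_time, u=u))

    def cluster_loglik(self, X, y=None, groups=None, X_time=None) -> np.ndarray:
        data = self._build_dataset(X, y, groups, X_time)
        return cluster_marginal_loglik(
            data,
            self.params_,
            self.result_.structure,
            method=self.quadrature,
            n_quad=self.n_quad,
        )
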