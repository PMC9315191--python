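"""Diagnostics for the random-effects part of the model.

Two tools are provided:

* the **gradient function** ``Delta(G, u)``, a directional-derivative
  diagnostic for the assumed random-effects distribution G.  It compares,
  pointwise in ``u``, the conditional likelihood of each cluster to its
  marginal likelihood under G:

      Delta(u) = (1/r) * sum_i exp{ l_i(eta_hat, u) } / m_i(eta_hat)

  If ``Delta`` exceeds 1 somewhere, moving probability mass of G towards
  that ``u`` would increase the marginal likelihood, i.e. G can be
  improved; a curve staying at or below 1 supports the assumed G.  By
  construction ``int Delta(u) dG(u) = 1`` (the derivative of the marginal
  log-likelihood in the direction of G itself vanishes), which the test
  suite verifies numerically.  Pointwise confidence bands are obtained by
  a cluster-level nonparametric bootstrap.

* the **boundary likelihood ratio test** for a zero random-effect
  variance.  Because the null value lies on the boundary of the parameter
  space, the LR statistic is asymptotically a chi-bar-square mixture:
  ``1/2 chi2_0 + 1/2 chi2_1`` when one variance is tested (the constrained
  structures I/II) and ``1/4 chi2_0 + 1/2 chi2_1 + 1/4 chi2_2`` when two
  variances are tested jointly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats

from .data import ClusteredDataset
from .likelihood import ClusterLogLik, Structure, as_structure, cluster_marginal_loglik
from .model import FitResult, fit_mmle

__all__ = [
    "GradientCurve",
    "LRTResult",
    "VarianceCase",
    "gradient_function",
    "gradient_bands",
    "mixture_pvalue",
    "lrt_random_effect",
]


# ---------------------------------------------------------------------------
# gradient function


@dataclass
class GradientCurve:
    """Gradient-function diagnostic evaluated on a grid of random-effect
    values, with optional bootstrap confidence bands.  The reference level
    is the constant 1."""

    grid: np.ndarray
    delta: np.ndarray
    band_lower: np.ndarray | None = None
    band_upper: np.ndarray | None = None
    threshold: float = 1.0

    def exceeds_threshold(self) -> np.ndarray:
        """Boolean mask of grid points where the point estimate exceeds 1
        (or where the lower band does, if bands are available)."""
        ref = self.delta if self.band_lower is None else self.band_lower
        return ref > self.threshold


def _default_grid(fit: FitResult, n: int = 101) -> np.ndarray:
    sd = fit.re_sd if fit.re_sd is not None else 0.25
    half = 4.0 * max(sd, 0.25)
    return np.linspace(-half, half, n)


def _gradient_values(data, params, structure, grid, n_quad) -> np.ndarray:
    ell = ClusterLogLik(data, params, structure)
    logm = cluster_marginal_loglik(data, params, structure, method="agh", n_quad=n_quad)
    G = np.broadcast_to(grid, (ell.r, grid.size))
    log_ratio = ell(G) - logm[:, None]
    # mean over clusters of exp(l_i(u)) / m_i
    m = log_ratio.max(axis=0)
    return np.exp(m) * np.mean(np.exp(log_ratio - m), axis=0)


def gradient_function(
    data: ClusteredDataset, fit: FitResult, grid=None
) -> GradientCurve:
    """Evaluate the gradient-function diagnostic at the fitted parameters."""
    if not fit.converged:
        raise ValueError(
            "refusing to compute the gradient diagnostic on an unconverged fit"
        )
    if fit.params.re is None:
        raise ValueError("the gradient diagnostic needs a mixed structure")
    grid = _default_grid(fit) if grid is None else np.asarray(grid, dtype=float)
    delta = _gradient_values(data, fit.params, fit.structure, grid, fit.n_quad)
    return GradientCurve(grid=grid, delta=delta)


def gradient_bands(
    data: ClusteredDataset,
    fit: FitResult,
    grid=None,
    n_boot: int = 200,
    seed=None,
    refit: bool = True,
    level: float = 0.95,
) -> GradientCurve:
    """Pointwise bootstrap confidence bands for the gradient function.

    Clusters are resampled with replacement; by default the model is
    refitted on each resample (warm-started at the original estimate).
    ``refit=False`` keeps the fitted parameters fixed and only recomputes
    the gradient curve on the resampled clusters, which is much cheaper.
    The band quantiles include the point estimate, so the band always
    contains it.
    """
    if n_boot < 50:
        warnings.warn("fewer than 50 bootstrap resamples gives unstable bands")
    curve = gradient_function(data, fit, grid=grid)
    rng = np.random.default_rng(seed)
    curves = [curve.delta]
    for _ in range(n_boot):
        ids = rng.integers(0, data.r, size=data.r)
        bdata = data.resample_clusters(ids)
        params = fit.params
        if refit:
            try:
                bfit = fit_mmle(
                    bdata,
                    structure=fit.structure,
                    baseline=fit.params.baseline,
                    init=fit.params,
                    quadrature=fit.quadrature,
                    n_quad=fit.n_quad,
                    compute_se=False,
                )
                params = bfit.params
            except Exception:  # keep the resample with fixed parameters
                pass
        curves.append(
            _gradient_values(bdata, params, fit.structure, curve.grid, fit.n_quad)
        )
    arr = np.vstack(curves)
    a = (1.0 - level) / 2.0
    curve.band_lower = np.quantile(arr, a, axis=0)
    curve.band_upper = np.quantile(arr, 1.0 - a, axis=0)
    return curve


# ---------------------------------------------------------------------------
# boundary likelihood ratio test


class VarianceCase(str, Enum):
    ONE_VARIANCE = "one"
    TWO_VARIANCES = "two"


def mixture_pvalue(r_obs: float, case=VarianceCase.ONE_VARIANCE) -> float:
    """Chi-bar-square p-value for the boundary LRT.

    One variance tested:  null is ``1/2 chi2_0 + 1/2 chi2_1``.
    Two variances tested: null is ``1/4 chi2_0 + 1/2 chi2_1 + 1/4 chi2_2``.
    ``chi2_0`` is a point mass at zero, so ``p = 1`` when ``r_obs = 0``.
    """
    if r_obs < 0:
        raise ValueError("the likelihood ratio statistic must be non-negative")
    case = VarianceCase(case)
    if r_obs == 0.0:
        return 1.0
    if case is VarianceCase.ONE_VARIANCE:
        return 0.5 * stats.chi2.sf(r_obs, 1)
    return 0.5 * stats.chi2.sf(r_obs, 1) + 0.25 * stats.chi2.sf(r_obs, 2)


@dataclass
class LRTResult:
    """Boundary likelihood ratio test for zero random-effect variance."""

    r_obs: float
    p_value: float
    case: VarianceCase
    fit_alt: FitResult | None = field(default=None, repr=False)
    fit_null: FitResult | None = field(default=None, repr=False)
    converged: bool = True

    @property
    def weights(self) -> dict[int, float]:
        """Mixture weights over chi-square degrees of freedom."""
        if self.case is VarianceCase.ONE_VARIANCE:
            return {0: 0.5, 1: 0.5}
        return {0: 0.25, 1: 0.5, 2: 0.25}

    def reject(self, level: float = 0.05) -> bool:
        return self.p_value < level


def lrt_random_effect(
    data: ClusteredDataset,
    structure="megh1",
    baseline="pgw",
    random_effects="normal",
    df: float = 4.0,
    fit_alt: FitResult | None = None,
    fit_null: FitResult | None = None,
    **fit_kwargs,
) -> LRTResult:
    """Test ``H0: sigma_u = 0`` against the mixed structure.

    Fits the mixed model and its fixed-effects reduction (sharing the
    fixed-effects structure), forms ``R = max(0, 2 (ll_alt - ll_null))``
    and returns the chi-bar-square p-value (one variance: the constrained
    structures share a single random effect).  Pre-computed fits can be
    supplied to avoid refitting.
    """
    structure = as_structure(structure)
    if structure is Structure.GH:
        raise ValueError("the alternative must be a mixed structure")
    if fit_alt is None:
        fit_alt = fit_mmle(
            data,
            structure=structure,
            baseline=baseline,
            random_effects=random_effects,
            df=df,
            **fit_kwargs,
        )
    if fit_null is None:
        fit_null = fit_mmle(data, structure="gh", baseline=baseline, **fit_kwargs)
    converged = fit_alt.converged and fit_null.converged
    if not converged:
        warnings.warn("one of the fits did not converge; p-value not reported")
        return LRTResult(
            r_obs=np.nan,
            p_value=np.nan,
            case=VarianceCase.ONE_VARIANCE,
            fit_alt=fit_alt,
            fit_null=fit_null,
            converged=False,
        )
    # optimisers can return tiny negative differences for nested models
    r_obs = max(0.0, 2.0 * (fit_alt.loglik - fit_null.loglik))
    p = mixture_pvalue(r_obs, VarianceCase.ONE_VARIANCE)
    return LRTResult(
        r_obs=r_obs,
        p_value=p,
        case=VarianceCase.ONE_VARIANCE,
        fit_alt=fit_alt,
        fit_null=fit_null,
    )
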