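"""Parametric baseline hazard families.

Each family provides the hazard ``h0(t | theta)``, its logarithm, the
closed-form cumulative hazard ``H0`` and its inverse.  The inverse is what
makes exact simulation of event times by inversion of the conditional
cumulative hazard possible, and the closed forms are what keep the marginal
likelihood of the mixed-effects general hazard model cheap to evaluate.

The Weibull family is deliberately absent: under the general hazard
structure the Weibull baseline makes the time-scale and hazard-scale
coefficients non-identifiable (the two scales collapse into one), so only
families outside the Weibull class are offered.  The Power Generalised
Weibull (PGW) contains the Weibull on the boundary ``delta = 1``; that
degeneracy is used as a numerical cross-check in the test-suite but is not
a fittable family on its own.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import ClassVar

import numpy as np
from scipy import special, stats

__all__ = [
    "BaselineHazard",
    "PowerGeneralisedWeibull",
    "LogLogistic",
    "LogNormal",
    "Gamma",
    "BASELINE_FAMILIES",
    "make_baseline",
]


def _softplus(x):
    # log(1 + exp(x)), stable for large |x|
    return np.logaddexp(0.0, x)


def _check_time(t, *, allow_zero: bool):
    t = np.asarray(t, dtype=float)
    if allow_zero:
        if np.any(t < 0):
            raise ValueError("times must be non-negative")
    else:
        if np.any(t <= 0):
            raise ValueError("times must be strictly positive")
    return t


@dataclass(frozen=True)
class BaselineHazard:
    """Abstract parametric baseline hazard.

    Concrete subclasses are frozen dataclasses whose fields are the family
    parameters on their natural (constrained) scale.  ``log_transformed``
    marks which parameters are positive and therefore optimised on the log
    scale.
    """

    #: parameter names in the order used by :meth:`theta`
    param_names: ClassVar[tuple[str, ...]] = ()
    #: True where the parameter is positive and log-transformed for fitting
    log_transformed: ClassVar[tuple[bool, ...]] = ()

    # -- parameter vector plumbing ------------------------------------
    @property
    def theta(self) -> np.ndarray:
        return np.array([getattr(self, p) for p in self.param_names], dtype=float)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def with_theta(self, theta) -> "BaselineHazard":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise ValueError(f"theta must have length {self.n_params}")
        return dataclasses.replace(
            self, **{p: float(v) for p, v in zip(self.param_names, theta)}
        )

    def to_unconstrained(self) -> np.ndarray:
        z = self.theta.copy()
        for k, is_log in enumerate(self.log_transformed):
            if is_log:
                z[k] = np.log(z[k])
        return z

    def from_unconstrained(self, z) -> "BaselineHazard":
        z = np.asarray(z, dtype=float)
        theta = z.copy()
        for k, is_log in enumerate(self.log_transformed):
            if is_log:
                theta[k] = np.exp(theta[k])
        return self.with_theta(theta)

    def transform_jacobian(self) -> np.ndarray:
        """d(theta)/d(z) for the delta method, evaluated at ``self``."""
        return np.where(np.asarray(self.log_transformed), self.theta, 1.0)

    # -- hazard interface ---------------------------------------------
    def log_hazard(self, t):
        raise NotImplementedError

    def hazard(self, t):
        t = _check_time(t, allow_zero=False)
        return np.exp(self.log_hazard(t))

    def cumhaz(self, t):
        raise NotImplementedError

    def cumhaz_inv(self, s):
        raise NotImplementedError


@dataclass(frozen=True)
class PowerGeneralisedWeibull(BaselineHazard):
    """Power Generalised Weibull baseline.

    ``H0(t) = [1 + (t/eta)^nu]^(1/delta) - 1`` with scale ``eta > 0``,
    power ``nu > 0`` and tilt ``delta > 0``.  Depending on (nu, delta) the
    hazard is increasing, decreasing, unimodal or bathtub-shaped; at
    ``delta = 1`` it degenerates to the Weibull hazard (nu/eta)(t/eta)^(nu-1).
    """

    eta: float = 1.0
    nu: float = 1.0
    delta: float = 1.0
    param_names: ClassVar[tuple[str, ...]] = ("eta", "nu", "delta")
    log_transformed: ClassVar[tuple[bool, ...]] = (True, True, True)

    def __post_init__(self):
        if not (self.eta > 0 and self.nu > 0 and self.delta > 0):
            raise ValueError("PGW parameters eta, nu, delta must be positive")

    def log_hazard(self, t):
        t = _check_time(t, allow_zero=False)
        w = self.nu * (np.log(t) - np.log(self.eta))  # log (t/eta)^nu
        return (
            np.log(self.nu)
            - np.log(self.delta)
            - self.nu * np.log(self.eta)
            + (self.nu - 1.0) * np.log(t)
            + (1.0 / self.delta - 1.0) * _softplus(w)
        )

    def cumhaz(self, t):
        t = _check_time(t, allow_zero=True)
        w = self.nu * (np.log(np.where(t > 0, t, 1.0)) - np.log(self.eta))
        out = np.expm1(_softplus(w) / self.delta)
        return np.where(t > 0, out, 0.0)

    def cumhaz_inv(self, s):
        s = np.asarray(s, dtype=float)
        if np.any(s < 0):
            raise ValueError("cumulative hazard must be non-negative")
        # t = eta * ((1+s)^delta - 1)^(1/nu)
        inner = np.expm1(self.delta * np.log1p(s))
        return self.eta * np.power(inner, 1.0 / self.nu)


@dataclass(frozen=True)
class LogLogistic(BaselineHazard):
    """Log-logistic baseline with log-location ``mu`` and scale ``tau > 0``.

    ``H0(t) = log(1 + exp((log t - mu)/tau))``; the hazard is unimodal for
    ``tau < 1`` and decreasing otherwise.
    """

    mu: float = 0.0
    tau: float = 1.0
    param_names: ClassVar[tuple[str, ...]] = ("mu", "tau")
    log_transformed: ClassVar[tuple[bool, ...]] = (False, True)

    def __post_init__(self):
        if not self.tau > 0:
            raise ValueError("log-logistic scale tau must be positive")

    def log_hazard(self, t):
        t = _check_time(t, allow_zero=False)
        z = (np.log(t) - self.mu) / self.tau
        return z - np.log(self.tau) - np.log(t) - _softplus(z)

    def cumhaz(self, t):
        t = _check_time(t, allow_zero=True)
        z = (np.log(np.where(t > 0, t, 1.0)) - self.mu) / self.tau
        return np.where(t > 0, _softplus(z), 0.0)

    def cumhaz_inv(self, s):
        s = np.asarray(s, dtype=float)
        if np.any(s < 0):
            raise ValueError("cumulative hazard must be non-negative")
        with np.errstate(divide="ignore"):
            # log(e^s - 1); -inf at s=0 maps to t=0
            le = np.where(s > 0, np.log(np.expm1(s)), -np.inf)
        return np.exp(self.mu + self.tau * le)


@dataclass(frozen=True)
class LogNormal(BaselineHazard):
    """Log-normal baseline: unimodal (up-then-down) hazard."""

    mu: float = 0.0
    tau: float = 1.0
    param_names: ClassVar[tuple[str, ...]] = ("mu", "tau")
    log_transformed: ClassVar[tuple[bool, ...]] = (False, True)

    def __post_init__(self):
        if not self.tau > 0:
            raise ValueError("log-normal scale tau must be positive")

    def log_hazard(self, t):
        t = _check_time(t, allow_zero=False)
        z = (np.log(t) - self.mu) / self.tau
        return stats.norm.logpdf(z) - np.log(self.tau) - np.log(t) - stats.norm.logsf(z)

    def cumhaz(self, t):
        t = _check_time(t, allow_zero=True)
        z = (np.log(np.where(t > 0, t, 1.0)) - self.mu) / self.tau
        return np.where(t > 0, -stats.norm.logsf(z), 0.0)

    def cumhaz_inv(self, s):
        s = np.asarray(s, dtype=float)
        if np.any(s < 0):
            raise ValueError("cumulative hazard must be non-negative")
        # S(t) = exp(-s)  =>  z = isf(exp(-s))
        with np.errstate(divide="ignore"):
            z = stats.norm.isf(np.exp(-s))
        return np.where(s > 0, np.exp(self.mu + self.tau * z), 0.0)


@dataclass(frozen=True)
class Gamma(BaselineHazard):
    """Gamma baseline: monotone (increasing, decreasing or flat) hazard."""

    shape: float = 1.0
    rate: float = 1.0
    param_names: ClassVar[tuple[str, ...]] = ("shape", "rate")
    log_transformed: ClassVar[tuple[bool, ...]] = (True, True)

    def __post_init__(self):
        if not (self.shape > 0 and self.rate > 0):
            raise ValueError("gamma shape and rate must be positive")

    def log_hazard(self, t):
        t = _check_time(t, allow_zero=False)
        dist = stats.gamma(self.shape, scale=1.0 / self.rate)
        return dist.logpdf(t) - dist.logsf(t)

    def cumhaz(self, t):
        t = _check_time(t, allow_zero=True)
        # -log of the upper regularised incomplete gamma function
        q = special.gammaincc(self.shape, self.rate * np.where(t > 0, t, 0.0))
        with np.errstate(divide="ignore"):
            out = -np.log(q)
        return np.where(t > 0, out, 0.0)

    def cumhaz_inv(self, s):
        s = np.asarray(s, dtype=float)
        if np.any(s < 0):
            raise ValueError("cumulative hazard must be non-negative")
        return stats.gamma.isf(np.exp(-s), self.shape, scale=1.0 / self.rate)


BASELINE_FAMILIES: dict[str, type[BaselineHazard]] = {
    "pgw": PowerGeneralisedWeibull,
    "loglogistic": LogLogistic,
    "lognormal": LogNormal,
    "gamma": Gamma,
}


def make_baseline(family: str | BaselineHazard, theta=None) -> BaselineHazard:
    """Build a baseline hazard from a family name and optional parameters."""
    if isinstance(family, BaselineHazard):
        return family if theta is None else family.with_theta(theta)
    key = family.lower().replace("-", "").replace("_", "")
    if key == "weibull":
        raise ValueError(
            "the Weibull baseline is not identifiable under the general "
            "hazard structure; use 'pgw' (Weibull is its delta=1 boundary)"
        )
    if key not in BASELINE_FAMILIES:
        raise ValueError(
            f"unknown baseline family {family!r}; "
            f"choose from {sorted(BASELINE_FAMILIES)}"
        )
    b = BASELINE_FAMILIES[key]()
    return b if theta is None else b.with_theta(theta)
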