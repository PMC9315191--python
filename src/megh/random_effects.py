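"""Zero-mean random-effects (frailty-on-the-log-scale) distributions.

The cluster-level random effect enters the hazard additively on the log
scale, so its distribution G must be continuous on the whole real line with
mean zero and finite variance.  Three families are provided:

* normal — the default modelling choice;
* Student-t with fixed degrees of freedom — heavier tails, scaled so that
  its variance equals ``sd**2`` (hence ``df > 2`` is required);
* two-piece normal — different left/right scales to capture asymmetry,
  location-shifted so its mean is exactly zero.

Only the scale parameters are estimated; the Student-t degrees of freedom
are fixed by the user (default 4) so that the variance parameter stays
one-dimensional and the boundary test for a zero variance is well defined.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import ClassVar

import numpy as np
from scipy import stats

__all__ = [
    "RandomEffects",
    "NormalRandomEffects",
    "StudentTRandomEffects",
    "TwoPieceNormalRandomEffects",
    "RE_FAMILIES",
    "make_random_effects",
]

_SQRT_2_OVER_PI = np.sqrt(2.0 / np.pi)


@dataclass(frozen=True)
class RandomEffects:
    """Abstract zero-mean random-effects distribution."""

    free_names: ClassVar[tuple[str, ...]] = ()

    # -- parameter plumbing (free = estimated, all positive/log scale) --
    @property
    def xi(self) -> np.ndarray:
        return np.array([getattr(self, p) for p in self.free_names], dtype=float)

    @property
    def n_params(self) -> int:
        return len(self.free_names)

    def with_xi(self, xi) -> "RandomEffects":
        xi = np.asarray(xi, dtype=float)
        if xi.shape != (self.n_params,):
            raise ValueError(f"xi must have length {self.n_params}")
        return dataclasses.replace(
            self, **{p: float(v) for p, v in zip(self.free_names, xi)}
        )

    def to_unconstrained(self) -> np.ndarray:
        return np.log(self.xi)

    def from_unconstrained(self, z) -> "RandomEffects":
        return self.with_xi(np.exp(np.asarray(z, dtype=float)))

    def transform_jacobian(self) -> np.ndarray:
        return self.xi.copy()

    # -- distribution interface ----------------------------------------
    @property
    def sd(self) -> float:
        """Standard deviation of the random effect."""
        raise NotImplementedError

    def logpdf(self, u):
        raise NotImplementedError

    def pdf(self, u):
        return np.exp(self.logpdf(u))

    def sample(self, n: int, rng) -> np.ndarray:
        raise NotImplementedError


@dataclass(frozen=True)
class NormalRandomEffects(RandomEffects):
    sd_u: float = 1.0
    free_names: ClassVar[tuple[str, ...]] = ("sd_u",)

    def __post_init__(self):
        if not self.sd_u > 0:
            raise ValueError("random-effect standard deviation must be positive")

    @property
    def sd(self) -> float:
        return self.sd_u

    def logpdf(self, u):
        return stats.norm.logpdf(np.asarray(u, dtype=float), scale=self.sd_u)

    def sample(self, n, rng):
        rng = np.random.default_rng(rng)
        return rng.normal(0.0, self.sd_u, size=n)


@dataclass(frozen=True)
class StudentTRandomEffects(RandomEffects):
    """Student-t random effects with fixed ``df > 2`` and Var = ``sd_u**2``."""

    sd_u: float = 1.0
    df: float = 4.0
    free_names: ClassVar[tuple[str, ...]] = ("sd_u",)

    def __post_init__(self):
        if not self.sd_u > 0:
            raise ValueError("random-effect standard deviation must be positive")
        if not self.df > 2:
            raise ValueError("Student-t df must exceed 2 for a finite variance")

    @property
    def sd(self) -> float:
        return self.sd_u

    @property
    def scale(self) -> float:
        # t(df, scale=s) has variance s^2 df/(df-2)
        return self.sd_u * np.sqrt((self.df - 2.0) / self.df)

    def logpdf(self, u):
        return stats.t.logpdf(np.asarray(u, dtype=float), self.df, scale=self.scale)

    def sample(self, n, rng):
        rng = np.random.default_rng(rng)
        return self.scale * rng.standard_t(self.df, size=n)


@dataclass(frozen=True)
class TwoPieceNormalRandomEffects(RandomEffects):
    """Two-piece normal with left scale ``sd1`` and right scale ``sd2``.

    The density is ``2/(sd1+sd2) * phi((u-m)/sd1)`` left of the mode ``m``
    and ``2/(sd1+sd2) * phi((u-m)/sd2)`` right of it.  The mode is fixed at
    ``m = -sqrt(2/pi) (sd2 - sd1)`` so that the mean is exactly zero; the
    symmetric case ``sd1 = sd2`` collapses to the normal distribution.
    """

    sd1: float = 1.0
    sd2: float = 1.0
    free_names: ClassVar[tuple[str, ...]] = ("sd1", "sd2")

    def __post_init__(self):
        if not (self.sd1 > 0 and self.sd2 > 0):
            raise ValueError("two-piece normal scales must be positive")

    @property
    def mode(self) -> float:
        return -_SQRT_2_OVER_PI * (self.sd2 - self.sd1)

    @property
    def variance(self) -> float:
        d = self.sd2 - self.sd1
        return (1.0 - 2.0 / np.pi) * d * d + self.sd1 * self.sd2

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))

    def logpdf(self, u):
        u = np.asarray(u, dtype=float)
        z = u - self.mode
        scale = np.where(z < 0, self.sd1, self.sd2)
        return (
            np.log(2.0)
            - np.log(self.sd1 + self.sd2)
            + stats.norm.logpdf(z / scale)
        )

    def sample(self, n, rng):
        rng = np.random.default_rng(rng)
        left = rng.random(n) < self.sd1 / (self.sd1 + self.sd2)
        half = np.abs(rng.standard_normal(n))
        return self.mode + np.where(left, -self.sd1 * half, self.sd2 * half)


RE_FAMILIES: dict[str, type[RandomEffects]] = {
    "normal": NormalRandomEffects,
    "student_t": StudentTRandomEffects,
    "two_piece_normal": TwoPieceNormalRandomEffects,
}


def make_random_effects(
    family: str | RandomEffects, sd: float | None = None, df: float = 4.0
) -> RandomEffects:
    """Build a random-effects distribution from a family name.

    ``sd`` initialises every scale parameter (both scales for the
    two-piece normal, which therefore starts symmetric).
    """
    if isinstance(family, RandomEffects):
        return family
    key = family.lower().replace("-", "_")
    if key not in RE_FAMILIES:
        raise ValueError(
            f"unknown random-effects family {family!r}; "
            f"choose from {sorted(RE_FAMILIES)}"
        )
    if key == "normal":
        return NormalRandomEffects(sd_u=1.0 if sd is None else sd)
    if key == "student_t":
        return StudentTRandomEffects(sd_u=1.0 if sd is None else sd, df=df)
    s = 1.0 if sd is None else sd
    return TwoPieceNormalRandomEffects(sd1=s, sd2=s)
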