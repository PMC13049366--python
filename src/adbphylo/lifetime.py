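"""Gamma/Erlang lifetime model shared by all other modules.

Cell lifetimes are modelled as Gamma(k, theta) random variables: ``k`` is
the shape parameter (integer shape gives the Erlang distribution, which is
the sum of k exponential stages) and ``theta`` the scale, so that the mean
lifetime is ``ell = k * theta``.  At the end of its lifetime a cell dies
with probability ``d`` and divides into two daughters otherwise; extant
cells at the present are sampled independently with probability ``rho``.
The classical constant-rate birth--death model is the ``k = 1`` special
case with birth rate ``lambda = (1 - d) / theta`` and death rate
``mu = d / theta``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import special
from scipy.stats import gamma as _gamma_dist

__all__ = [
    "ADBParams",
    "lifetime_pdf",
    "lifetime_logpdf",
    "lifetime_cdf",
    "lifetime_sf",
    "birth_death_map",
]


@dataclass(frozen=True)
class ADBParams:
    """Population-dynamic parameters of the age-dependent branching process.

    Parameters
    ----------
    k : float
        Lifetime shape parameter, ``k >= 1``.  Real values are allowed
        (generalized Erlang); an integer restriction may be imposed at the
        inference level.
    ell : float
        Mean lifetime ``ell = k * theta`` in time units, ``> 0``.
    d : float
        Probability that a cell dies (rather than divides) at the end of
        its lifetime.  Must satisfy ``0 <= d < 1/2`` so the process is
        supercritical.
    rho : float
        Sampling probability of extant cells at the present, ``(0, 1]``.
    """

    k: float
    ell: float
    d: float
    rho: float

    def __post_init__(self) -> None:
        if not self.k >= 1:
            raise ValueError(f"shape k must be >= 1, got {self.k}")
        if not self.ell > 0:
            raise ValueError(f"mean lifetime must be > 0, got {self.ell}")
        if not 0 <= self.d < 0.5:
            raise ValueError(f"death probability must lie in [0, 0.5), got {self.d}")
        if not 0 < self.rho <= 1:
            raise ValueError(f"sampling probability must lie in (0, 1], got {self.rho}")

    @property
    def theta(self) -> float:
        """Scale parameter of the lifetime distribution, ``ell / k``."""
        return self.ell / self.k

    def with_(self, **kwargs) -> "ADBParams":
        return replace(self, **kwargs)


def _check_age(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("age must be non-negative")
    return a


def lifetime_pdf(a, k: float, theta: float):
    """Density of the Gamma(k, theta) lifetime distribution at age ``a``."""
    a = _check_age(a)
    return _gamma_dist.pdf(a, k, scale=theta)


def lifetime_logpdf(a, k: float, theta: float):
    """Log-density of Gamma(k, theta); safe for very large shapes."""
    a = _check_age(a)
    return _gamma_dist.logpdf(a, k, scale=theta)


def lifetime_cdf(a, k: float, theta: float):
    """Cumulative distribution of Gamma(k, theta): regularized lower
    incomplete gamma function evaluated at ``a / theta``."""
    a = _check_age(a)
    return special.gammainc(k, a / theta)


def lifetime_sf(a, k: float, theta: float):
    """Survival function ``1 - F(a)`` of Gamma(k, theta)."""
    a = _check_age(a)
    return special.gammaincc(k, a / theta)


def birth_death_map(params: ADBParams) -> tuple[float, float]:
    """Map ``k = 1`` parameters to constant birth--death rates.

    With exponential lifetimes the process is the Markovian birth--death
    model with birth rate ``lambda = (1 - d) / theta`` and death rate
    ``mu = d / theta``.
    """
    if params.k != 1:
        raise ValueError(f"birth-death mapping requires k = 1, got k = {params.k}")
    theta = params.theta
    return (1.0 - params.d) / theta, params.d / theta
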