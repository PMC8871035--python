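"""Inverted exponentiated Rayleigh distribution (IERD).

A positive random variable ``X`` follows IERD(theta, lam) when its cdf is

    F(x) = 1 - (1 - exp(-lam / x**2))**theta,   x > 0,

with shape ``theta > 0`` and scale ``lam > 0``.  The density is

    f(x) = 2 * theta * lam * x**-3 * exp(-lam/x**2)
           * (1 - exp(-lam/x**2))**(theta - 1)

and the hazard rate f / (1 - F) is non-monotone (rises then falls), which
makes the family a useful alternative to Weibull-type models for device
lifetimes and treatment durations.

Numerics: the recurring factor ``g(x) = 1 - exp(-lam/x**2)`` is always
evaluated as ``-expm1(-lam/x**2)`` so that it stays accurate for large ``x``
where the exponential is close to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "IERDParams",
    "pdf",
    "logpdf",
    "cdf",
    "sf",
    "hazard",
    "ppf",
    "rvs",
]

_LOG2 = float(np.log(2.0))


@dataclass(frozen=True)
class IERDParams:
    """Parameter pair of one IERD population.

    Attributes
    ----------
    theta : float
        Shape parameter, strictly positive.
    lam : float
        Scale parameter, strictly positive.
    """

    theta: float
    lam: float

    def __post_init__(self) -> None:
        for name in ("theta", "lam"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be a positive finite real, got {v!r}")


def _check_x(x):
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0) or np.any(~np.isfinite(x)):
        raise ValueError("x must be strictly positive and finite")
    return x


def log_g(x, lam):
    """log(1 - exp(-lam/x**2)), the log of the recurring survival factor."""
    return np.log(-np.expm1(-lam / np.square(x)))


def logpdf(x, p: IERDParams):
    """Log-density, computed without forming the unlogged density."""
    x = _check_x(x)
    lx2 = p.lam / np.square(x)
    return (
        _LOG2
        + np.log(p.theta)
        + np.log(p.lam)
        - 3.0 * np.log(x)
        - lx2
        + (p.theta - 1.0) * np.log(-np.expm1(-lx2))
    )


def pdf(x, p: IERDParams):
    """Density 2*theta*lam*x^-3*exp(-lam/x^2)*(1-exp(-lam/x^2))^(theta-1)."""
    return np.exp(logpdf(x, p))


def cdf(x, p: IERDParams):
    """Distribution function 1 - (1 - exp(-lam/x^2))^theta."""
    x = _check_x(x)
    return -np.expm1(p.theta * log_g(x, p.lam))


def sf(x, p: IERDParams):
    """Survival function (1 - exp(-lam/x^2))^theta."""
    x = _check_x(x)
    return np.exp(p.theta * log_g(x, p.lam))


def hazard(x, p: IERDParams):
    """Hazard rate 2*theta*lam*x^-3*exp(-lam/x^2)/(1-exp(-lam/x^2))."""
    x = _check_x(x)
    lx2 = p.lam / np.square(x)
    return np.exp(
        _LOG2
        + np.log(p.theta)
        + np.log(p.lam)
        - 3.0 * np.log(x)
        - lx2
        - np.log(-np.expm1(-lx2))
    )


def ppf(prob, p: IERDParams):
    """Quantile function, the analytic inverse of :func:`cdf`.

    x = sqrt(lam / (-log(1 - (1 - prob)**(1/theta)))).
    """
    prob = np.asarray(prob, dtype=float)
    if np.any(prob <= 0) or np.any(prob >= 1):
        raise ValueError("prob must lie strictly inside (0, 1)")
    # q = (1-prob)**(1/theta) via exp(log1p(-prob)/theta); then
    # lam/x**2 = -log(1 - q), kept accurate deep in both tails via log1p
    y = np.log1p(-prob) / p.theta
    t = -np.log1p(-np.exp(y))
    return np.sqrt(p.lam / t)


def rvs(count: int, p: IERDParams, seed=None):
    """Draw ``count`` i.i.d. variates by inverse-transform sampling.

    ``seed`` may be an int, a Generator, or None; a fixed int seed makes the
    output reproducible.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    u = rng.uniform(size=int(count))
    # keep u away from the closed endpoints (probability-zero events)
    u = np.clip(u, np.finfo(float).tiny, 1.0 - 1e-16)
    return ppf(u, p)
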