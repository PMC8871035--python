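"""Complete-sample fitting and model checks.

Single-sample IERD maximum likelihood uses the profile identity
theta_hat(lam) = -n / sum(log(1 - exp(-lam/x_i**2))), reducing the fit to a
one-dimensional search over lam.  Goodness of fit uses the two-sided
Kolmogorov-Smirnov sup distance against the fitted cdf with the asymptotic
95% critical value 1.36/sqrt(n); equality of the two samples' scale
parameters is tested with a likelihood-ratio statistic against chi-square
with one degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .distribution import IERDParams, cdf, log_g, logpdf
from .em import FitResult, _bounded_log_search, direct_fit
from .jpc import JPCDesign, apply_jpc

__all__ = [
    "KSResult",
    "LRTResult",
    "complete_mle",
    "complete_loglik",
    "joint_common_scale_fit",
    "ks_test",
    "lrt_common_scale",
    "pooled_complete_record",
]


@dataclass(frozen=True)
class KSResult:
    """Kolmogorov-Smirnov distance against a fitted IERD."""

    distance: float
    critical: float
    fitted: IERDParams

    @property
    def passed(self) -> bool:
        return self.distance < self.critical


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test of a common scale parameter (1 df)."""

    statistic: float
    df: int
    p_value: float
    loglik_full: float
    loglik_reduced: float


def complete_loglik(sample, p: IERDParams) -> float:
    """Sum of IERD log-densities over a complete sample."""
    return float(np.sum(logpdf(np.asarray(sample, dtype=float), p)))


def complete_mle(sample) -> IERDParams:
    """Two-parameter IERD MLE from a complete sample.

    The shape is profiled out analytically; the scale is found by bounded
    scalar search on log(lam) with bracket expansion.
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two observations")
    if np.any(x <= 0):
        raise ValueError("observations must be positive")
    n = len(x)

    def theta_of(lam):
        return -n / float(np.sum(log_g(x, lam)))

    def neg_profile(log_lam):
        lam = float(np.exp(log_lam))
        return -complete_loglik(x, IERDParams(theta=theta_of(lam), lam=lam))

    lam0 = float(np.log(2.0) * np.median(x) ** 2)
    res = _bounded_log_search(neg_profile, np.log(lam0), half_width=np.log(1000.0))
    lam_hat = float(np.exp(res.x))
    return IERDParams(theta=theta_of(lam_hat), lam=lam_hat)


def pooled_complete_record(sampleA, sampleB):
    """Pool two complete samples into an uncensored JPC record (r = 0, k = m+n)."""
    a = np.asarray(sampleA, dtype=float)
    b = np.asarray(sampleB, dtype=float)
    design = JPCDesign(m=len(a), n=len(b), k=len(a) + len(b), removals=(0,) * (len(a) + len(b)))
    return apply_jpc(a, b, design, seed=0)  # no removals, so the seed is inert


def joint_common_scale_fit(sampleA, sampleB) -> FitResult:
    """MLE of (theta1, theta2, lam) with a common scale across two complete samples."""
    return direct_fit(pooled_complete_record(sampleA, sampleB))


def ks_test(sample, p: IERDParams) -> KSResult:
    """Two-sided K-S sup distance between the empirical and fitted cdfs.

    distance = max_i max(|F(x_(i)) - i/n|, |F(x_(i)) - (i-1)/n|);
    the 95% critical value is the asymptotic 1.36/sqrt(n).
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("sample must be nonempty")
    fx = cdf(x, p)
    i = np.arange(1, n + 1)
    distance = float(np.max(np.maximum(np.abs(fx - i / n), np.abs(fx - (i - 1) / n))))
    return KSResult(distance=distance, critical=1.36 / np.sqrt(n), fitted=p)


def lrt_common_scale(sampleA, sampleB) -> LRTResult:
    """Likelihood-ratio test of H0: the two scale parameters are equal.

    Full model: separate (theta, lam) per sample.  Reduced model: separate
    shapes, one common lam.  The statistic 2*(l_full - l_reduced) is
    referred to chi-square with 1 df.
    """
    pA = complete_mle(sampleA)
    pB = complete_mle(sampleB)
    loglik_full = complete_loglik(sampleA, pA) + complete_loglik(sampleB, pB)
    reduced = joint_common_scale_fit(sampleA, sampleB)
    stat = 2.0 * (loglik_full - reduced.loglik)
    stat = max(stat, 0.0)  # guard tiny negative from optimizer tolerance
    return LRTResult(
        statistic=float(stat),
        df=1,
        p_value=float(stats.chi2.sf(stat, df=1)),
        loglik_full=float(loglik_full),
        loglik_reduced=float(reduced.loglik),
    )
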