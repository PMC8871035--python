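"""Observed Fisher information by the missing-information principle.

For JPC data the complete information minus the information carried by the
withdrawn (missing) lifetimes gives the observed information:

    I_o = m*I_1 + n*I_2 - sum_i [ s_i*I_{U|w_i} + t_i*I_{V|w_i} ],

ordered (theta1, theta2, lam).  I_1 (one unit from sample A) and I_2 (one
unit from B) are negative expected Hessians of the IERD log-density; the
missing blocks use the left-truncated density of a unit surviving past w_i.
Each block has a zero (theta1, theta2) cross entry because a single unit's
likelihood involves only its own shape.

All second derivatives are analytic; the expectations are integrals over
the probability transform T = 1 - exp(-lam/X**2) ~ Beta(theta, 1) (full
unit) or its truncation to (0, tau_i), tau_i = 1 - exp(-lam/w_i**2)
(missing unit), evaluated by adaptive quadrature.  With x^2 = lam/(-log(1-t)):

    -d2/dtheta2 log f        = 1/theta^2                       (exact)
    -d2/dtheta dlam log f    = -(1-t)(-log(1-t)) / (lam*t)
    -d2/dlam2 log f          = 1/lam^2 + (theta-1)*(1-t)*log(1-t)^2/(lam^2*t^2)

and the truncated blocks pick up the derivative of theta*log(tau) in the
normalizer (see :func:`_missing_block`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

__all__ = ["ObservedInfo", "ConditioningError", "observed_info", "covariance"]

_LABELS = ("theta1", "theta2", "lam")


class ConditioningError(ArithmeticError):
    """The information matrix is singular or numerically non-invertible."""

    def __init__(self, eigvals):
        self.eigvals = np.asarray(eigvals)
        super().__init__(
            f"information matrix is not positive definite / well conditioned; "
            f"eigenvalues {self.eigvals.tolist()}"
        )


@dataclass(frozen=True)
class ObservedInfo:
    """Symmetric 3x3 observed information matrix, ordered (theta1, theta2, lam)."""

    matrix: np.ndarray
    labels: tuple[str, ...] = _LABELS

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "matrix": np.asarray(self.matrix).tolist(),
        }


def _quad(fn, lo, hi):
    val, err = integrate.quad(fn, lo, hi, epsabs=1e-10, epsrel=1e-10, limit=300)
    if not np.isfinite(val):
        raise ArithmeticError("non-finite quadrature in information matrix")
    return val


def _cross_integrand(t):
    # (1-t)*(-log(1-t))/t, the lam-free part of -d2 logf/dtheta dlam; -> 1 at t=0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = -(1.0 - t) * np.log1p(-t) / t
    return np.where(t == 0.0, 1.0, out)


def _lam_integrand(t):
    # (1-t)*log(1-t)^2/t^2, the lam-free part of the (theta-1) term; -> 1 at t=0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (1.0 - t) * np.log1p(-t) ** 2 / t**2
    return np.where(t == 0.0, 1.0, out)


def _full_block(theta: float, lam: float) -> np.ndarray:
    """Per-unit information of a single complete IERD observation.

    Rows/cols ordered (shape, lam); embedded into the right 3x3 slots by
    the caller.  Expectations are over T ~ Beta(theta, 1).
    """
    dens = lambda t: theta * t ** (theta - 1.0)
    e_cross = _quad(lambda t: _cross_integrand(t) * dens(t), 0.0, 1.0)
    e_lam = _quad(lambda t: _lam_integrand(t) * dens(t), 0.0, 1.0)
    i_tt = 1.0 / theta**2
    i_tl = -e_cross / lam  # -E[d2 logf / dtheta dlam]
    i_ll = 1.0 / lam**2 + (theta - 1.0) * e_lam / lam**2
    return np.array([[i_tt, i_tl], [i_tl, i_ll]])


def _missing_block(theta: float, lam: float, w: float) -> np.ndarray:
    """Per-unit information of a lifetime left-truncated at w.

    The truncated log-density is log f(u) - theta*log(tau) with
    tau = 1 - exp(-lam/w**2), so relative to the full-unit block the cross
    and lam-lam entries gain the derivatives of theta*log(tau):

        d2/dtheta dlam [  -theta*log tau ] = -dlog tau/dlam
        d2/dlam2    [  -theta*log tau ] = theta * (1-tau)/(lam^2 ...)

    computed below via log(1-tau) = -lam/w**2.
    """
    tau = -np.expm1(-lam / w**2)
    dens = lambda t: theta * t ** (theta - 1.0) / tau**theta
    e_cross = _quad(lambda t: _cross_integrand(t) * dens(t), 0.0, tau)
    e_lam = _quad(lambda t: _lam_integrand(t) * dens(t), 0.0, tau)
    # derivatives of log tau wrt lam, using 1-tau = exp(-lam/w^2)
    dlog_tau = (1.0 - tau) * (-np.log1p(-tau)) / (lam * tau)  # dlog(tau)/dlam
    d2log_tau = -(1.0 - tau) * np.log1p(-tau) ** 2 / (lam**2 * tau**2)  # d2log(tau)/dlam2
    i_tt = 1.0 / theta**2
    i_tl = -e_cross / lam + dlog_tau
    i_ll = 1.0 / lam**2 + (theta - 1.0) * e_lam / lam**2 + theta * d2log_tau
    return np.array([[i_tt, i_tl], [i_tl, i_ll]])


def _embed(block2: np.ndarray, shape_idx: int) -> np.ndarray:
    out = np.zeros((3, 3))
    out[shape_idx, shape_idx] = block2[0, 0]
    out[shape_idx, 2] = out[2, shape_idx] = block2[0, 1]
    out[2, 2] = block2[1, 1]
    return out


def observed_info(p, data) -> ObservedInfo:
    """Observed information matrix m*I1 + n*I2 - sum of missing blocks."""
    m, n = data.design.m, data.design.n
    total = m * _embed(_full_block(p.theta1, p.lam), 0)
    total += n * _embed(_full_block(p.theta2, p.lam), 1)
    for i in range(data.design.k):
        if data.s[i] > 0:
            total -= data.s[i] * _embed(_missing_block(p.theta1, p.lam, data.w[i]), 0)
        if data.t[i] > 0:
            total -= data.t[i] * _embed(_missing_block(p.theta2, p.lam, data.w[i]), 1)
    if not np.all(np.isfinite(total)):
        raise ArithmeticError("non-finite entries in observed information")
    return ObservedInfo(matrix=total)


def covariance(p, data) -> np.ndarray:
    """Inverse observed information: the estimator covariance approximation.

    Raises :class:`ConditioningError` (with the eigenvalues) when the matrix
    is not positive definite or is numerically singular; no silent
    pseudo-inverse.
    """
    info = observed_info(p, data).matrix
    eigvals = np.linalg.eigvalsh(info)
    if eigvals.min() <= 0 or eigvals.max() / eigvals.min() > 1e12:
        raise ConditioningError(eigvals)
    return np.linalg.inv(info)
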