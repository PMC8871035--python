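"""Maximum likelihood for two IERD samples under JPC, via EM.

Sample A (size m) follows IERD(theta1, lam), sample B (size n) follows
IERD(theta2, lam) with a common scale.  The observed-data log-likelihood
(normalizing constant dropped) is

    l(theta1, theta2, lam) = k*log(2*lam) + k1*log(theta1) + k2*log(theta2)
        + sum_i [ -3*log(w_i) - lam/w_i**2
                  + (z_i*theta1 + (1-z_i)*theta2 - 1) * log(g_i) ]
        + sum_i [ (theta1*s_i + theta2*t_i) * log(g_i) ],

with g_i = 1 - exp(-lam/w_i**2).  When k1 = 0 (or k2 = 0) the likelihood is
strictly decreasing in theta1 (theta2) and no MLE exists.

EM treats the withdrawn units' lifetimes as missing.  The key analytic fact
(substitute T = 1 - exp(-lam/U**2)): if U ~ IERD(theta, lam) then
T ~ Beta(theta, 1), and conditioning on U > w truncates T to (0, tau) with
tau = 1 - exp(-lam/w**2).  Hence

    E[log(1 - exp(-lam/U**2)) | U > w] = log(tau) - 1/theta           (exact)
    E[U**-2 | U > w] = 1/w**2 - tau * 2F1(1, theta+1; theta+2; tau)
                               / (lam * (theta + 1))                  (exact)

and E[log U | U > w] is evaluated by adaptive quadrature.  The M-step
profiles both shapes out analytically, leaving a one-dimensional search
over log(lam); the shapes are then refreshed from the closed-form E-step
identity.  Iteration stops when all three parameter changes are <= tol
(default 1e-4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize

from .distribution import log_g
from .jpc import JPCData

__all__ = [
    "TwoSampleParams",
    "EMConfig",
    "FitResult",
    "ConditionalMoments",
    "DegenerateDataError",
    "observed_loglik",
    "conditional_moments",
    "em_fit",
    "direct_fit",
]


class DegenerateDataError(ValueError):
    """All observed failures came from a single sample; MLEs do not exist.

    With k1 = 0 the likelihood is strictly decreasing in theta1 for any
    fixed (theta2, lam) (and symmetrically for k2 = 0), so the maximum is
    on the boundary theta -> 0 and no interior MLE exists.
    """


@dataclass(frozen=True)
class TwoSampleParams:
    """Parameter triple (theta1, theta2, lam), all strictly positive."""

    theta1: float
    theta2: float
    lam: float

    def __post_init__(self) -> None:
        for name in ("theta1", "theta2", "lam"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be a positive finite real, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.theta1, self.theta2, self.lam])


@dataclass
class EMConfig:
    """Settings for :func:`em_fit`.

    ``init=None`` uses a data-driven heuristic: lam0 = log(2)*median(w)**2
    (the scale a unit-shape IERD would need to put its median at the sample
    median) and shapes from the observed-likelihood profile at lam0.
    """

    init: TwoSampleParams | None = None
    tol: float = 1e-4
    max_iter: int = 500
    quad_tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class FitResult:
    """Point estimates plus diagnostics from one likelihood maximization."""

    estimates: TwoSampleParams
    loglik: float
    iterations: int
    converged: bool
    trace: np.ndarray = field(repr=False)  # (iterations+1, 3) parameter triples
    method: str = "em"

    def to_dict(self) -> dict:
        e = self.estimates
        return {
            "theta1": e.theta1,
            "theta2": e.theta2,
            "lam": e.lam,
            "loglik": self.loglik,
            "iterations": self.iterations,
            "converged": self.converged,
            "method": self.method,
        }


@dataclass(frozen=True)
class ConditionalMoments:
    """Truncated expectations of one withdrawn unit given survival past w."""

    e_log_u: float  # E[log U | U > w]
    e_inv_u2: float  # E[U^-2 | U > w], always < w^-2
    e_log_g: float  # E[log(1 - exp(-lam/U^2)) | U > w], always < 0


def _check_nondegenerate(data: JPCData) -> None:
    if data.is_degenerate:
        raise DegenerateDataError(
            f"k1={data.k1}, k2={data.k2}: the likelihood is monotone in the "
            "shape of the unrepresented sample and no MLE exists"
        )


def _loglik_unchecked(p: TwoSampleParams, data: JPCData) -> float:
    """The log-likelihood expression itself, without the existence guard.

    On degenerate records (k1 = 0 or k2 = 0) this is a perfectly valid
    function — it is just strictly decreasing in the unrepresented shape,
    so it has no maximizer; callers wanting estimation must go through
    :func:`observed_loglik`.
    """
    w, s, t, z = data.w, data.s, data.t, data.z
    k = data.design.k
    lg = log_g(w, p.lam)
    k1 = data.k1
    shape_terms = 0.0
    if k1 > 0:
        shape_terms += k1 * np.log(p.theta1)
    if k - k1 > 0:
        shape_terms += (k - k1) * np.log(p.theta2)
    return float(
        k * np.log(2.0 * p.lam)
        + shape_terms
        + np.sum(-3.0 * np.log(w) - p.lam / np.square(w))
        + np.sum((z * p.theta1 + (1 - z) * p.theta2 - 1.0) * lg)
        + np.sum((p.theta1 * s + p.theta2 * t) * lg)
    )


def observed_loglik(p: TwoSampleParams, data: JPCData) -> float:
    """Observed-data log-likelihood (normalizing constant omitted)."""
    _check_nondegenerate(data)
    return _loglik_unchecked(p, data)


# Gauss-Legendre rule reused by the truncated-moment integral below.
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(96)
_GL_NODES = (_GL_NODES + 1.0) / 2.0  # map to (0, 1)
_GL_WEIGHTS = _GL_WEIGHTS / 2.0


def _trunc_neglog_mean(L, theta):
    """E[-log(1-T) | T < tau] for T ~ Beta(theta, 1), tau = 1 - exp(-L).

    Uses the cancellation-free representation (substitute y = -log(1-t))

        int_0^L  [1 - ((1 - e^-y)/tau)^theta]  dy,

    whose integrand lies in [0, 1], decays like theta*e^-y for large y, and
    stays finite for every L including tau -> 1 where naive forms overflow.
    Vectorized over L.
    """
    L = np.atleast_1d(np.asarray(L, dtype=float))
    log_tau = np.log(-np.expm1(-L))
    # integrand is ~0 beyond y ~ log(theta) + 45; cap the range accordingly
    y_hi = np.minimum(L, np.log(theta + 1.0) + 45.0)
    if theta >= 1.0:
        # integrand smooth enough for fixed Gauss-Legendre (rel err < 1e-6)
        y = y_hi[:, None] * _GL_NODES[None, :]
        vals = -np.expm1(theta * (np.log(-np.expm1(-y)) - log_tau[:, None]))
        return y_hi * (vals @ _GL_WEIGHTS)
    # theta < 1: the y**theta branch point at 0 defeats Gauss-Legendre;
    # tanh-sinh quadrature absorbs the endpoint singularity
    res = integrate.tanhsinh(
        lambda y, lt: -np.expm1(theta * (np.log(-np.expm1(-y)) - lt)),
        np.zeros_like(y_hi),
        y_hi,
        args=(log_tau,),
        atol=1e-12,
        rtol=1e-11,
    )
    return np.atleast_1d(res.integral)


def _e_inv_u2(w, theta, lam):
    """E[U^-2 | U > w] for U ~ IERD(theta, lam), truncated below at w.

    Equals (1/lam) * E[-log(1-T) | T < tau]; always < 1/w**2 because the
    integrand above is < 1.  Vectorized over w.
    """
    w = np.asarray(w, dtype=float)
    L = lam / np.square(w)
    return _trunc_neglog_mean(L, theta) / lam


def conditional_moments(
    w: float, theta: float, lam: float, quad_tol: float = 1e-10
) -> ConditionalMoments:
    """Truncated expectations of U | U > w for U ~ IERD(theta, lam).

    ``e_log_g`` and ``e_inv_u2`` use exact reductions (see module
    docstring); ``e_log_u`` integrates over the uniform probability
    transform p = (T/tau)^theta, which maps (w, inf) to (0, 1).
    """
    if w <= 0:
        raise ValueError("w must be positive")
    ln_tau = float(log_g(w, lam))
    e_log_g = ln_tau - 1.0 / theta
    e_inv = float(np.atleast_1d(_e_inv_u2(w, theta, lam))[0])
    tau = -np.expm1(-lam / w**2)

    def integrand(pp):
        tt = tau * pp ** (1.0 / theta)
        # log U = 0.5*(log lam - log(-log(1-T)))
        return 0.5 * (np.log(lam) - np.log(-np.log1p(-tt)))

    val, err = integrate.quad(
        integrand, 0.0, 1.0, epsabs=quad_tol, epsrel=quad_tol, limit=200
    )
    if not np.isfinite(val) or err > max(1e-6, 1e-4 * abs(val)):
        raise ArithmeticError(
            f"quadrature for E[log U | U > {w}] did not converge (err={err})"
        )
    return ConditionalMoments(e_log_u=float(val), e_inv_u2=e_inv, e_log_g=e_log_g)


def _e_log_g_free_lam(w, theta_p, lam_p, lam):
    """E_(theta_p, lam_p)[log(1 - exp(-lam/U**2)) | U > w], vectorized over w.

    The conditional density is frozen at the previous iterate (theta_p,
    lam_p) while the integrand keeps the free M-step lam — the combination
    the EM gradient identity needs for the fixed point to be the MLE.  With
    T = 1 - exp(-lam_p/U**2) truncated-Beta and rho = lam/lam_p the target
    is E[log(1 - (1-T)**rho)], split as

        log(rho) + log(tau) - 1/theta_p + E[ h(T) ],
        h(t) = log( (1 - (1-t)**rho) / (rho*t) ),

    where the first terms are exact and h is smooth (h(0) = 0), so the
    remainder integrates accurately with fixed Gauss-Legendre nodes under
    the uniform probability transform t = tau * p**(1/theta_p).
    """
    w = np.asarray(w, dtype=float)
    rho = lam / lam_p
    ln_tau = log_g(w, lam_p)  # log(tau), stable
    tau = -np.expm1(-lam_p / np.square(w))
    t = tau[:, None] * _GL_NODES[None, :] ** (1.0 / theta_p)
    h = np.log(-np.expm1(rho * np.log1p(-t))) - np.log(rho) - np.log(t)
    return np.log(rho) + ln_tau - 1.0 / theta_p + h @ _GL_WEIGHTS


def _default_init(data: JPCData) -> TwoSampleParams:
    lam0 = float(np.log(2.0) * np.median(data.w) ** 2)
    lg = log_g(data.w, lam0)
    th1 = -data.k1 / float(np.sum((data.z + data.s) * lg))
    th2 = -data.k2 / float(np.sum((data.t + 1 - data.z) * lg))
    return TwoSampleParams(theta1=max(th1, 1e-3), theta2=max(th2, 1e-3), lam=lam0)


def _bounded_log_search(neg_obj, log_x0, half_width=np.log(100.0), xatol=1e-9, max_expand=6):
    """Minimize neg_obj over log-x in a bracket around log_x0, expanding on boundary hits."""
    lo, hi = log_x0 - half_width, log_x0 + half_width
    for _ in range(max_expand):
        res = optimize.minimize_scalar(
            neg_obj, bounds=(lo, hi), method="bounded", options={"xatol": xatol}
        )
        x = res.x
        if x - lo < 10 * xatol:
            lo -= half_width
        elif hi - x < 10 * xatol:
            hi += half_width
        else:
            return res
    return res


def em_fit(data: JPCData, cfg: EMConfig | None = None) -> FitResult:
    """EM maximum-likelihood fit of (theta1, theta2, lam).

    Each iteration first maximizes the pseudo log-likelihood over lam alone
    (shapes held at the previous iterate inside the conditional
    expectations, and profiled out of the objective analytically), then
    refreshes theta1, theta2 from the closed-form E-step identity at the new
    lam.  Exceeding ``max_iter`` returns an unconverged result rather than
    raising.
    """
    cfg = cfg or EMConfig()
    _check_nondegenerate(data)
    w, s, t, z = data.w, data.s, data.t, data.z
    m, n = data.design.m, data.design.n
    inv_w2 = 1.0 / np.square(w)
    has_s = s > 0
    has_t = t > 0

    cur = cfg.init or _default_init(data)
    trace = [cur.as_array()]
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        th1p, th2p, lamp = cur.theta1, cur.theta2, cur.lam
        # E-step: conditional second inverse moments frozen at (q-1)
        A = float(np.sum(inv_w2))
        if np.any(has_s):
            A += float(np.sum(s[has_s] * _e_inv_u2(w[has_s], th1p, lamp)))
        if np.any(has_t):
            A += float(np.sum(t[has_t] * _e_inv_u2(w[has_t], th2p, lamp)))

        def neg_profile(log_lam):
            lam = np.exp(log_lam)
            lg = log_g(w, lam)
            # E[log g_lam(U)] with the density frozen at (q-1), lam free
            if np.any(has_s):
                phi1 = _e_log_g_free_lam(w[has_s], th1p, lamp, lam)
                S1 = float(np.sum(s[has_s] * phi1))
            else:
                S1 = 0.0
            if np.any(has_t):
                phi2 = _e_log_g_free_lam(w[has_t], th2p, lamp, lam)
                S2 = float(np.sum(t[has_t] * phi2))
            else:
                S2 = 0.0
            D1 = S1 + float(np.sum(z * lg))
            D2 = S2 + float(np.sum((1 - z) * lg))
            # profiled shapes; D1, D2 < 0 because the expectations of log(g) are < 0
            th1 = -m / D1
            th2 = -n / D2
            val = (
                (m + n) * (np.log(2.0) + log_lam)
                + m * np.log(th1)
                + n * np.log(th2)
                - lam * A
                - S1
                - S2
                - float(np.sum(lg))
            )
            return -val if np.isfinite(val) else np.inf

        res = _bounded_log_search(neg_profile, np.log(lamp))
        lam_q = float(np.exp(res.x))
        lg_q = log_g(w, lam_q)
        th1_q = -m / float(np.sum(s * (lg_q - 1.0 / th1p)) + np.sum(z * lg_q))
        th2_q = -n / float(np.sum(t * (lg_q - 1.0 / th2p)) + np.sum((1 - z) * lg_q))
        nxt = TwoSampleParams(theta1=th1_q, theta2=th2_q, lam=lam_q)
        trace.append(nxt.as_array())
        if np.all(np.abs(nxt.as_array() - cur.as_array()) <= cfg.tol):
            cur = nxt
            converged = True
            break
        cur = nxt

    return FitResult(
        estimates=cur,
        loglik=observed_loglik(cur, data),
        iterations=it,
        converged=converged,
        trace=np.asarray(trace),
        method="em",
    )


def direct_fit(data: JPCData, init: TwoSampleParams | None = None) -> FitResult:
    """Maximize the observed-data log-likelihood directly (EM cross-check).

    The shapes are stationary at theta1 = -k1/sum((z+s)*log g),
    theta2 = -k2/sum((t+1-z)*log g) for any fixed lam, so the problem
    reduces to a bounded scalar search over log(lam); a Nelder-Mead polish
    in full 3-D log-parameter space follows.
    """
    _check_nondegenerate(data)
    w, s, t, z = data.w, data.s, data.t, data.z
    k1, k2 = data.k1, data.k2

    def profile_params(lam):
        lg = log_g(w, lam)
        th1 = -k1 / float(np.sum((z + s) * lg))
        th2 = -k2 / float(np.sum((t + 1 - z) * lg))
        return th1, th2

    def neg_profile(log_lam):
        lam = float(np.exp(log_lam))
        th1, th2 = profile_params(lam)
        return -observed_loglik(TwoSampleParams(th1, th2, lam), data)

    lam0 = init.lam if init is not None else float(np.log(2.0) * np.median(w) ** 2)
    res = _bounded_log_search(neg_profile, np.log(lam0), half_width=np.log(1000.0))
    lam_hat = float(np.exp(res.x))
    th1_hat, th2_hat = profile_params(lam_hat)

    def neg_full(log_params):
        th1, th2, lam = np.exp(log_params)
        return -observed_loglik(TwoSampleParams(th1, th2, lam), data)

    x0 = np.log([th1_hat, th2_hat, lam_hat])
    polish = optimize.minimize(
        neg_full, x0, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12}
    )
    if not np.all(np.isfinite(polish.x)):
        raise ArithmeticError("direct likelihood maximization failed")
    x = polish.x if polish.fun <= neg_full(x0) else x0
    est = TwoSampleParams(*np.exp(x))
    return FitResult(
        estimates=est,
        loglik=observed_loglik(est, data),
        iterations=int(polish.nit),
        converged=True,
        trace=np.vstack([np.exp(x0), np.exp(x)]),
        method="direct",
    )
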