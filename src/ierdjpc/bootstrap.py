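"""Parametric Bootstrap-p and Bootstrap-t confidence intervals.

Both methods fit the MLE triple, simulate N fresh JPC datasets from the
fitted parameters under the same design, and refit each replicate.
Bootstrap-p returns per-parameter order statistics of the replicate
estimates; Bootstrap-t studentizes each replicate by its own inverse
observed information and rescales by the original fit's standard errors.

Degenerate replicates (all failures from one sample, where no MLE exists)
are redrawn with fresh randomness and counted; exceeding ``max_redraws``
raises.  Replicates whose information matrix fails conditioning are dropped
from Bootstrap-t (error if more than 20% drop).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .em import EMConfig, FitResult, em_fit
from .fisher import ConditioningError, covariance
from .jpc import JPCData, simulate_jpc

__all__ = ["BootstrapConfig", "IntervalEstimate", "BootstrapResult", "bootstrap_p", "bootstrap_t"]

_LABELS = ("theta1", "theta2", "lam")


@dataclass
class BootstrapConfig:
    """Replicate count, confidence level, seeding, and degeneracy budget."""

    n_boot: int = 1000
    level: float = 0.90
    seed: int | None = None
    max_redraws: int | None = None  # default 10 * n_boot

    def __post_init__(self) -> None:
        if not (0.0 < self.level < 1.0):
            raise ValueError("level must lie in (0, 1)")
        if self.n_boot < 2:
            raise ValueError("n_boot must be >= 2")
        if self.max_redraws is None:
            self.max_redraws = 10 * self.n_boot


@dataclass(frozen=True)
class IntervalEstimate:
    """A (lower, upper) interval for one parameter at a given level."""

    lower: float
    upper: float
    level: float
    method: str
    parameter: str

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower must not exceed upper")

    @property
    def length(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass
class BootstrapResult:
    """Intervals plus the raw replicate estimates that produced them."""

    intervals: dict[str, IntervalEstimate]
    replicates: np.ndarray = field(repr=False)  # (N, 3) refit estimates
    fit: FitResult
    n_degenerate: int = 0
    n_dropped: int = 0


def _order_indices(n: int, level: float) -> tuple[int, int]:
    """1-based floor indices into the sorted replicate vector, clamped to [1, N]."""
    alpha = 1.0 - level
    # epsilon guards the floor against binary round-off (0.05*120 -> 5.999...)
    lb = int(np.floor(alpha / 2.0 * n + 1e-9))
    hb = int(np.floor((1.0 - alpha / 2.0) * n + 1e-9))
    return min(max(lb, 1), n), min(max(hb, 1), n)


def _replicate_fits(data: JPCData, cfg: BootstrapConfig, fit: FitResult):
    """Simulate and refit N parametric-bootstrap replicates.

    Replicate refits are initialized at the parent MLE.  Returns the
    replicate datasets, their fits, and the degenerate-redraw count.
    """
    rng = np.random.default_rng(cfg.seed)
    est = fit.estimates
    pA = _ierd(est.theta1, est.lam)
    pB = _ierd(est.theta2, est.lam)
    em_cfg = EMConfig(init=est)
    datasets, fits = [], []
    redraws = 0
    for _ in range(cfg.n_boot):
        while True:
            rep = simulate_jpc(data.design, pA, pB, rng)
            if not rep.is_degenerate:
                break
            redraws += 1
            if redraws > cfg.max_redraws:
                raise RuntimeError(
                    f"exceeded max_redraws={cfg.max_redraws} degenerate bootstrap replicates"
                )
        datasets.append(rep)
        fits.append(em_fit(rep, em_cfg))
    return datasets, fits, redraws


def _ierd(theta, lam):
    from .distribution import IERDParams

    return IERDParams(theta=theta, lam=lam)


def bootstrap_p(data: JPCData, cfg: BootstrapConfig | None = None, fit: FitResult | None = None) -> BootstrapResult:
    """Percentile parametric bootstrap intervals for (theta1, theta2, lam)."""
    cfg = cfg or BootstrapConfig()
    fit = fit or em_fit(data)
    _, fits, redraws = _replicate_fits(data, cfg, fit)
    reps = np.array([f.estimates.as_array() for f in fits])
    lb, hb = _order_indices(cfg.n_boot, cfg.level)
    intervals = {}
    for j, name in enumerate(_LABELS):
        col = np.sort(reps[:, j])
        intervals[name] = IntervalEstimate(
            lower=float(col[lb - 1]),
            upper=float(col[hb - 1]),
            level=cfg.level,
            method="boot-p",
            parameter=name,
        )
    return BootstrapResult(intervals=intervals, replicates=reps, fit=fit, n_degenerate=redraws)


def bootstrap_t(data: JPCData, cfg: BootstrapConfig | None = None, fit: FitResult | None = None) -> BootstrapResult:
    """Studentized parametric bootstrap intervals for (theta1, theta2, lam).

    Pivots T = (estimate* - estimate)/sqrt(Var*) use each replicate's own
    inverse observed information; the interval rescales the pivot order
    statistics by the original fit's standard errors.
    """
    cfg = cfg or BootstrapConfig()
    fit = fit or em_fit(data)
    base_sd = np.sqrt(np.diag(covariance(fit.estimates, data)))
    datasets, fits, redraws = _replicate_fits(data, cfg, fit)
    est0 = fit.estimates.as_array()
    pivots, kept = [], []
    for rep_data, rep_fit in zip(datasets, fits):
        try:
            rep_cov = covariance(rep_fit.estimates, rep_data)
        except ConditioningError:
            continue
        rep_est = rep_fit.estimates.as_array()
        pivots.append((rep_est - est0) / np.sqrt(np.diag(rep_cov)))
        kept.append(rep_est)
    n_dropped = cfg.n_boot - len(pivots)
    if n_dropped > 0.2 * cfg.n_boot:
        raise RuntimeError(
            f"{n_dropped}/{cfg.n_boot} bootstrap replicates dropped for ill-conditioned "
            "information matrices"
        )
    pivots = np.asarray(pivots)
    n_eff = len(pivots)
    lb, hb = _order_indices(n_eff, cfg.level)
    intervals = {}
    for j, name in enumerate(_LABELS):
        tcol = np.sort(pivots[:, j])
        lo = est0[j] - base_sd[j] * tcol[hb - 1]
        hi = est0[j] - base_sd[j] * tcol[lb - 1]
        intervals[name] = IntervalEstimate(
            lower=float(lo), upper=float(hi), level=cfg.level, method="boot-t", parameter=name
        )
    return BootstrapResult(
        intervals=intervals,
        replicates=np.asarray(kept),
        fit=fit,
        n_degenerate=redraws,
        n_dropped=n_dropped,
    )
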