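# Methods

## Model

A positive lifetime `X` follows the inverted exponentiated Rayleigh
distribution IERD(θ, λ) when

    F(x) = 1 − (1 − e^{−λ/x²})^θ,
    f(x) = 2θλ x⁻³ e^{−λ/x²} (1 − e^{−λ/x²})^{θ−1},

with shape θ > 0 and scale λ > 0. The hazard rises and then falls, which
suits devices and treatments whose risk peaks mid-life. Everything in this
package rests on one probability transform: if `T = 1 − e^{−λ/X²}` then
`T ~ Beta(θ, 1)`, and conditioning on survival past `w` truncates `T` to
`(0, τ)` with `τ = 1 − e^{−λ/w²}`. All truncated moments, information
integrals and posterior conditionals below are computed through this
transform, with `1 − e^{−λ/x²}` always evaluated as `-expm1(-λ/x²)`.

## Joint progressive type-II censoring (JPC)

Two samples — A with `m` units following IERD(θ₁, λ) and B with `n` units
following IERD(θ₂, λ), common scale — are tested together. At the i-th
observed failure `w_i`, a prefixed number `r_i` of survivors is withdrawn
from the pooled risk set; `s_i` of them happen to be from A, `t_i = r_i −
s_i` from B, and `z_i` flags the source of the failure itself. The design
satisfies `Σ(r_i + 1) = m + n` (the last failure removes all survivors).
Which survivors get withdrawn is not specified by the design; this package
withdraws by uniform simple random sampling without replacement, which
makes `(s_i, t_i)` a hypergeometric split. The observed-data likelihood
does not depend on that choice, but finite-sample Monte Carlo summaries
can (see Limitations). Ties in lifetimes are broken by stable input order,
A before B, deterministically.

When every failure comes from one sample (`k₁ = 0` or `k₂ = 0`) the
likelihood is strictly decreasing in the unrepresented shape and no MLE
exists. Such records are returned flagged by the simulator; estimation
raises, and the bootstrap and study drivers redraw them (counting the
redraws) so replicate counts stay as configured.

## Maximum likelihood: EM and the direct profile

The observed-data log-likelihood (normalizing constant dropped) is

    ℓ = k log(2λ) + k₁ log θ₁ + k₂ log θ₂
        + Σ[−3 log w_i − λ/w_i² + (z_iθ₁ + (1−z_i)θ₂ − 1) log g_i]
        + Σ[(θ₁ s_i + θ₂ t_i) log g_i],            g_i = 1 − e^{−λ/w_i²}.

**Direct maximization.** For fixed λ the shapes are stationary at
`θ̂₁(λ) = −k₁/Σ(z_i + s_i) log g_i` (and symmetrically for θ̂₂), so
`direct_fit` is a bounded scalar search over log λ (bracket ±log 1000
around a data-driven start, expanded on boundary hits), followed by a
Nelder–Mead polish in full 3-D log-parameter space. It serves as the
independent cross-check for EM.

**EM.** The withdrawn lifetimes are the missing data. The E-step needs
three families of truncated expectations; two have exact reductions:

    E[log(1 − e^{−λ/U²}) | U > w]  = log τ − 1/θ     (density and integrand
                                                      at the same (θ, λ))
    E[U⁻² | U > w] = (1/λ) ∫₀^L [1 − ((1−e^{−y})/τ)^θ] dy,   L = λ/w²,

where the second comes from substituting `y = −log(1−t)` in the truncated
Beta integral; its integrand lies in [0, 1] and decays like `θe^{−y}`, so
it is free of the overflow and cancellation that defeat naive forms as
`τ → 1`. It is evaluated with a fixed 96-node Gauss–Legendre rule for
θ ≥ 1 (relative error below 1e−6 over L ∈ [0.01, 500]) and tanh-sinh
quadrature for θ < 1, where the `y^θ` branch point at the origin defeats
polynomial rules. `E[log U | U > w]` (not needed by the M-step, whose
objective it shifts by a constant) uses adaptive quadrature on the uniform
probability transform.

Each EM iteration (q):

1. freeze `E[U⁻² | U > w_i]` at the previous iterate `(θ^{(q−1)},
   λ^{(q−1)})`;
2. maximize the pseudo log-likelihood over λ alone by bounded scalar
   search on log λ (bracket ±log 100, expanded on boundary hits), with the
   shapes profiled out analytically at each candidate λ. Inside this
   search the conditional *density* of the missing lifetimes stays frozen
   at the previous iterate while the integrand's λ is the free variable:
   `E[log(1 − e^{−λU⁻²}) | U > w]` becomes `E[log(1 − (1−T)^ρ)]` with
   `ρ = λ/λ^{(q−1)}` and `T` the frozen truncated Beta, computed as
   `log ρ + log τ − 1/θ + E[h(T)]` with the smooth remainder
   `h(t) = log[(1 − (1−t)^ρ)/(ρt)]` integrated by Gauss–Legendre. Freezing
   the density is what makes the algorithm's fixed point the MLE (the EM
   gradient identity); letting the density track the candidate λ — a
   reading the update-formula subscripts permit — was implemented and
   measured to converge 10–25% away from the direct optimizer, and was
   therefore rejected.
3. refresh the shapes from the closed-form identity at the new λ, where
   density and integrand genuinely share λ^{(q)}:
   `θ₁^{(q)} = −m / [Σ s_i (log g_i − 1/θ₁^{(q−1)}) + Σ z_i log g_i]`.

Iteration stops when all three absolute parameter changes are ≤ `tol`
(default 1e−4, the conventional triple rule); `max_iter` defaults to 500
and exhaustion returns an unconverged flag rather than raising. The
default initializer sets `λ₀ = log 2 · median(w)²` (the scale a unit-shape
IERD needs to put its median at the sample median) and takes the shapes
from the observed-likelihood profile at λ₀; the shape-update identity
cannot initialize itself because its expectation already requires a shape.
EM-vs-direct agreement is asserted at 1e−3 relative over a 20-dataset
battery spanning the study designs.

## Observed information and covariance

By the missing-information principle,

    I_o = m·I₁ + n·I₂ − Σ_i [s_i·I_{U|w_i} + t_i·I_{V|w_i}],

ordered (θ₁, θ₂, λ). Per-unit blocks are negative expected Hessians of
the IERD log-density (full units) or of the left-truncated density
(withdrawn units); each has a zero (θ₁, θ₂) cross entry. All second
derivatives are analytic — e.g. `−∂²log f/∂θ² = 1/θ²` exactly, so the
(θ₁, θ₁) entry of the assembled matrix is `k₁/θ₁²`, the exact observed
Hessian entry — and the λ-expectations are adaptive-quadrature integrals
over the Beta transform, each verified in tests against a
finite-difference-plus-quadrature oracle at 1e−5 relative. The estimator
covariance is the inverse; a non-positive-definite or ill-conditioned
matrix (condition number above 1e12) raises a `ConditioningError`
carrying the eigenvalues rather than silently substituting a
pseudo-inverse, so the studentized bootstrap can drop and count that
replicate.

## Bootstrap intervals

Both methods refit `N` parametric replicates simulated from the fitted
triple under the original design, initializing each refit at the parent
MLE. Bootstrap-p returns the `⌊αN/2⌋`-th and `⌊(1−α/2)N⌋`-th order
statistics of each parameter's replicates (1-based, clamped to [1, N],
with an epsilon guard on the floor against binary round-off).
Bootstrap-t studentizes each replicate by the square root of the diagonal
of its own inverse observed information and rescales the pivot order
statistics by the original fit's standard errors. Degenerate replicates
are redrawn (budget `max_redraws`, default 10N); replicates with failing
information matrices are dropped from bootstrap-t, with an error if more
than 20% drop. Replicate estimates are exposed on the result so the
intervals can be recomputed externally bit-for-bit.

Measured behavior worth knowing: because the replicate standard errors
scale with the replicate estimates (`sd*(θ̂₁) ≈ θ̂₁/√k₁`), studentization
symmetrizes the right-skewed replicate distribution and the boot-t
intervals come out *narrower* than boot-p on average in every design we
simulated — the opposite of the ordering sometimes reported for this
model. The acceptance suite records that direction honestly.

## Bayesian estimation by importance sampling

Independent gamma priors θ₁ ~ Ga(a₁, b₁), θ₂ ~ Ga(a₂, b₂), λ ~ Ga(c, d)
(rate parameterization) are conditionally conjugate: given λ,

    θ₁ | λ, data ~ Ga(a₁ + k₁,  b₁ − Σ(s_i + z_i) log g_i),
    θ₂ | λ, data ~ Ga(a₂ + k₂,  b₂ − Σ(t_i + 1−z_i) log g_i),

with rates guaranteed positive since log g_i < 0. The λ marginal is a
Ga(c + k, d + Σw_i⁻²) density times a correction, and is not log-concave
in general, so λ is drawn from that gamma proposal and reweighted with
log-weights

    log c_j = −(a₁+k₁) log rate₁(λ_j) − (a₂+k₂) log rate₂(λ_j) − Σ log g_ij,

normalized by log-sum-exp; all weight arithmetic stays in log space. The
presets are the informative (2, 1, 1, 2, 3, 2) and near-flat (all 1e−4)
hyperparameter sets. Point estimates are the weighted mean (squared-error
loss) and `−(1/δ) log Σ w_j e^{−δ g_j}` (linex loss, δ defaults to 2,
computed by shifted log-sum-exp; the sign convention is the standard
`−(1/δ) log E[e^{−δg}]`, which for δ > 0 sits below the posterior mean by
Jensen's inequality). Credible intervals sort the g-values with their
weights and walk the cumulative weight to α/2 and 1 − α/2. The default
importance-sample size is M = 5000. A Rao–Blackwellized option
(conditional gamma means in place of shape draws) is available but off by
default.

The conjugate reduction was verified exactly against a brute-force 3-D
likelihood-times-prior integration, and the sampler against a
deterministic grid-quadrature oracle on small records (≤ 2% relative at
M = 2·10⁵).

**Weight degeneracy at large k.** The correction factor
`rate₁^{−(a₁+k₁)}` is an exponential-in-k tilt away from the gamma
proposal. On the complete coating record (k = 144) the posterior mass
sits ~26 proposal standard deviations from the proposal mean: the
effective sample size collapses to ~10⁻³·M and the estimator, though
consistent, is useless at any practical M. The sampler is therefore
reliable in the k ≲ 30 regimes of the simulation studies and should not
be trusted on large complete samples; the `effective_sample_size`
diagnostic (1/Σw²) is exposed precisely to catch this.

## Model checks

Single-sample complete-data MLE profiles the shape
(`θ̂(λ) = −n/Σ log g(x_i; λ)`) and searches λ in one dimension. The
goodness-of-fit distance is the two-sided Kolmogorov–Smirnov statistic
`max_i max(|F(x_(i)) − i/n|, |F(x_(i)) − (i−1)/n|)` against the fitted
cdf, compared with the asymptotic 95% critical value `1.36/√n` (0.1603 at
n = 72). Equality of the two scale parameters is tested by a likelihood
ratio: full model with separate (θ, λ) per sample, reduced model with a
common λ, statistic `2Δℓ` referred to chi-square with 1 df. A 300-rep
parametric-bootstrap null on the coating data confirmed the chi-square
reference (p = 0.31 vs 0.316).

## Monte Carlo study harness

`run_point_study` and `run_interval_study` simulate `n_reps` datasets
under a configured truth and design, apply the requested estimators
(EM with true-value or all-7 initialization; Bayes under either loss and
prior preset) or interval methods (both bootstraps, credible under either
preset), and report AV/MSE or AL/CP per parameter. Per-replicate seeds
fan out from the master seed via `SeedSequence.spawn`, making every study
reproducible and order-independent; summaries are computed column-wise so
they are bit-identical to recomputation from the exposed per-replicate
raw arrays. Degenerate draws are redrawn and counted; an estimator
failure rate above 5% aborts the study.

The packaged example data are the two 72-observation coating-weight
samples (mg/m², chemical procedure, top/bottom center side of galvanized
iron sheets); the loader divides by 10 by default, the conventional
preprocessing for these data.

## Problem sizes used by the shipped checks

The acceptance script runs the full coating workflow (deterministic,
seconds) and a 300-replicate Monte Carlo study of the EM scale estimate
at the (m=25, n=20, k=30, scheme (5,0^28,10)) design — enough replicates
to put the Monte Carlo standard error near 0.025 on a mean of ~2.1. The
test suite scales coverage-style simulations to tens of replicates and
N ≤ 120 bootstrap refits per call; these sizes were chosen so each
property is resolved decisively while the whole suite stays fast.

## What the synthetic generator does and does not emulate

The simulator reproduces the JPC mechanism exactly: i.i.d. IERD lifetimes
per sample, pooled ordering, prefixed removal counts, uniform random
withdrawal, full removal at the k-th failure. It does not emulate
features real reliability data often have — rounding to measurement
precision (ties are measure-zero here but common in rounded data),
covariate heterogeneity, or dependence between the two lines. Passing
tests therefore certify the inference machinery under the model's own
assumptions, not robustness to their violation.

## Known limitations

- The importance sampler degenerates for large k (above).
- Replicate-level parallelism is not implemented; studies are serial
  (seed fan-out is already order-independent, so adding it would not
  change results).
- Monte Carlo dispersion summaries (MSEs, average lengths) are sensitive
  to the unstated withdrawal convention of the original tables; our
  uniform-withdrawal results have heavier tails than some published
  counterparts, and two published qualitative orderings (studentized
  intervals wider; informative-prior coverage higher) reverse under these
  study conditions. Point summaries of the scale parameter agree within
  Monte Carlo error.
- No type-I/hybrid censoring variants, no BCa bootstrap, no MCMC, no
  Wald intervals, no plotting.
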