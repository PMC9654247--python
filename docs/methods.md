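# Methods

This note records the statistical model implemented by `censmix`, the
numerical choices behind it, and what the bundled synthetic benchmarks
do and do not demonstrate.

## Likelihood for censored and truncated observations

Concentrations are strictly positive. Observations are grouped into
*strata* sharing one (LDL, UDL, cut) combination; the log-likelihood is
the sum of independent stratum contributions.

For a stratum with window (L, U) and mixture parameters
(q_j, Θ_j), a quantified value x contributes

log Σ_j q_j · f(x; Θ_j) / (F_j(U) − F_j(L)),

i.e. each component is conditioned on the window separately. A
**censored** stratum with counts (n_LDL, n_LU, n_UDL) adds the
multinomial log-mass of those counts under the cell probabilities
(p_LDL, p_LU, p_UDL) from the *mixture* CDF at the limits, including
the multinomial coefficient — a parameter-free constant that makes the
printed likelihood comparable to the standard censored formulation: the
conditional-plus-multinomial form differs from
Σ log f(x) + n_LDL·log F(L) + n_UDL·log S(U) by exactly that
coefficient, because the (F(U) − F(L))^n_LU window factor cancels
against p_LU^n_LU. The test suite verifies this identity to 1e−8 on
random instances. A **truncated** stratum contributes the conditional
densities only; the count of removed values is, by definition, unknown.

Two deliberate consequences of this formulation:

- *Per-component conditioning vs the exact conditional.* The likelihood
  conditions each component on the window separately. When component
  window masses differ, this is not the same density as the conditional
  of the pooled mixture, Σ q_j f_j(x) / Σ q_j P_j(window). Everywhere a
  *sample* must be drawn from the model given the censoring event —
  imputation draws, truncated-stratum replicates, conditional means —
  the exact conditional (components reweighted by q_j·P_j) is used,
  because per-component conditioning is not a coherent generative
  distribution for that purpose. The likelihood itself follows the
  stated mixture form so fitted parameters remain comparable with the
  reference methodology.
- *Right truncation is refused.* With the upper tail removed and no
  record of how many values were lost, the mass above the UDL cannot be
  identified in practice; `fit_mle` and the CLI reject truncated data
  with a finite UDL and suggest the censored encoding instead.

The zero-truncation of the normal family composes with LDL/UDL
conditioning into a single window (max(0, L), U); the zero-mass
normalizer cancels algebraically, so it is absorbed rather than tracked
separately.

Boundary convention: a value exactly equal to a detection limit counts
as quantified (windows are closed at the limits for validation). This
is a measure-zero choice for continuous data but matters for rounded
inputs.

## Distributions

Log-density is the primitive (`pdf = exp(logpdf)`): censored likelihood
sums would underflow otherwise. Densities and CDFs are written directly
with `scipy.special` primitives (`gammainc`, `ndtr`, `gammaln`) rather
than through `scipy.stats` distribution objects; the generic argument
machinery there costs more than the computation itself in the
optimizer/sampler hot loop, and the closed forms are exact. Quadrature
appears only as an independent oracle in the tests. Random generation
is inverse-CDF on uniforms rescaled to [F(L), F(U)], which is exact for
any window with positive mass — no accept/reject step that could stall
in far tails.

The gamma is parameterized (shape k, scale θ) and the generalized gamma
(a, d, p) with density (p/a^d)x^(d−1)e^(−(x/a)^p)/Γ(d/p); the
reductions gengamma(a, d, p=1) = gamma(d, a) and gengamma(a, d=p) =
weibull(p, a) are property-tested to 1e−10.

## Maximum likelihood

Optimization runs on an unconstrained scale — log for positive
parameters, raw for the normal/lognormal location, logit stick-breaking
fractions for the J−1 free weights — under L-BFGS-B with box bounds
±20 on the log scale and a 1e−8 tolerance on the log-likelihood.
Initialization slices the sorted quantified values into J quantile
bands and applies method-of-moments per band (for the Weibull, the
shape solves the CV equation by bracketing; the generalized gamma is
seeded at its gamma special case p = 1). Mixture likelihoods are
multimodal, so 5 jittered restarts (sd 0.3 on the transformed scale)
surround the deterministic start and the best optimum is kept, then
polished once. Components are sorted by mean ascending afterwards so
the reported labelling is unique (label switching).

Parameter count for information criteria: p = J·dim(family) + (J−1),
counting the free weights. The sample size n is the full row count for
censored strata (UnQ rows carry likelihood) and the quantified count
for truncated strata. AICc = AIC + 2p(p+1)/(n−p−1) when n > p+1, else
reported as infinite.

Model weights use the standard Akaike form w_j = exp(−Δ_j/2)/Σ
exp(−Δ_i/2) (min-shifted for stability). The homogeneity *w-value*
compares the BIC of a pooled fit against the sum of the per-group BICs
(each part penalized with its own sample size); w < 0.001 is reported
as "the groups differ".

## Posterior sampling

One-parameter-at-a-time Gaussian random-walk Metropolis on the same
transformed scale as the optimizer, started at the MLE. Priors are
uniform on the natural scale — [m/1000, 1000m] around each positive
MLE value m, a symmetric box of half-width 1000·max(|m|, 1) for real
locations, (0, 1) for each stick-breaking fraction — so the
transformed-scale target carries the change-of-variables Jacobian. All
bounds are user-overridable.

Adaptation: per-parameter proposal sds are initialized from the
diagonal curvature of the log-posterior at the start (2.4/√(−H_ii), the
near-optimal scaling for a one-dimensional update) and then follow
Robbins–Monro updates log s ← log s + t^(−1/2)·(accept − 0.234) during
burn-in only; freezing them afterwards keeps the retained chain
Markovian. Starting at the mode with curvature-matched scales is what
makes a 100-sweep burn-in sufficient for a 5000-iteration run; the
post-burn-in acceptance rate lands in [0.15, 0.35] on all bundled
fixtures. Defaults (5000 iterations, burn-in 100) follow the reference
protocol; a single chain is run, and summaries are empirical means, sds
and quantiles of the post-burn-in draws. The consecutive-rejection
diagnostic (warning after 1000 straight rejections) flags stuck chains.
No Raftery–Lewis-style run-length diagnostic is implemented.

## Posterior-predictive checks and imputation

Goodness-of-fit: for parameter draws θ_i thinned evenly along the chain
(sampled with replacement if more replicates than draws are requested),
a replicate dataset with the observed size, strata and cut regimes is
simulated — censored strata by drawing from the full mixture and
marking out-of-window values, truncated strata by drawing from the
window conditional. The p-value is the fraction of replicates whose
likelihood under θ_i is below the observed likelihood, ties split
50/50. Values near 0 or 1 flag incompatibility; the statistic is
invariant to component relabelling since the likelihood is.

Imputation: `mode="random"` resamples chain parameters per draw and
fills each UnQ cell from the mixture conditional on its censoring side
— (0, LDL) or (UDL, ∞) for that row — so completed datasets propagate
both parameter and sampling uncertainty. `mode="point"` fills each UnQ
cell with the posterior-mean conditional expectation E[X | side],
computed by adaptive quadrature per unique window and averaged over at
most 500 evenly spaced chain draws (the quadrature is deterministic;
500 draws bound the cost while leaving the posterior-mean Monte Carlo
error far below the quadrature tolerance). Bound compliance (imputed
cells strictly inside their censoring side) is asserted in the tests
for 100% of cells. Default 1000 random draws mirrors the
repeated-reanalysis use-case for downstream models.

`predictive_band` evaluates the unconditioned mixture density on a grid
per chain draw and returns pointwise means and quantiles, for
histogram-overlay plots of the fit with a credible envelope.

## Synthetic benchmark

The reference scenario pools 100 draws from gamma(10, 20) with 100 from
gamma(5, 10): pooled mean 125, sd √7875 ≈ 88.7, with the lower
component partly (LDL = 20) or wholly (LDL = 100) hidden. The bundle
regenerated by `fictive_reference_datasets(seed)` contains the censored and
truncated LDL = 20 variants, an LDL = 20/UDL = 300 doubly censored
variant, two 90:10 / 10:90 homogeneity groups censored at LDL = 30
(200 rows per group), and the LDL = 100 hidden-bimodal case.

Draws use NumPy's PCG64 generator; a given seed fixes the dataset, but
no cross-language RNG stream is emulated, so benchmarks on these data
are distributional — moments within sampling error, AIC *orderings*,
coverage rates — never value-exact reproductions of any specific
historical sample. What passing them shows: the estimator recovers
known parameters under realistic censoring, the selection machinery
finds the hidden second component from censored counts, and the
credible intervals have close-to-nominal coverage *when the model
family is correctly specified and observations are i.i.d.* Real assay
data add features the generator does not emulate — measurement
rounding, batch effects, detection limits correlated with
concentration — on which these guarantees are silent.

## Problem sizes in the shipped validations

The test suite fits the full 10-model sweep on 10 regenerated datasets
(200 rows each), runs 100 recovery replicates at n = 1000 with
5000-iteration chains, and uses 50 random instances for the likelihood
identity; these sizes give stable pass/fail behaviour at interactive
runtimes. `scripts/acceptance.py` uses the 200-row benchmark datasets
and a single 5000-iteration chain, matching the reference protocol.
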