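# Methods

## Model

Voxels live on a 3-D lattice; contiguity is face adjacency
(6-connectivity), the minimal standard choice for isotropic voxel grids.
The latent association indicators Θ ∈ {0,1}^m follow a two-parameter
Ising model, Pr(Θ=θ) ∝ exp(γᵀH(θ)) with sufficient statistics
H(θ) = (Σ_{(s,t)∈S₁} θ_s θ_t, Σ_s θ_s): γ₁ ≥ 0 rewards agreeing
neighbors, γ₂ sets prevalence.  The normalizer C(γ) is never computed
except by exact enumeration on lattices with m ≤ 16, which serves as the
test oracle for the samplers.

Given Θ, statistics are conditionally independent.  The null density f₀
is N(0, c_n²) with c_n = √(n/(n₁n₂)), or the scaled central t with
n − 2 df for small samples; the nonnull density f₁ is a mixture over a
discrete effect-size distribution g on mass points t₁ < … < t_B (none
exactly zero), with normal or noncentral-t components.  t-family
densities are always evaluated on the y/c_n scale with an explicit
1/c_n Jacobian.  The mass grid is equally spaced over
[min(y) − c_n, max(y) + c_n]; a grid point landing exactly at zero is
nudged by half a step (downward at the left endpoint so the grid still
covers the data range).  A degenerate data range is padded by
max(c_n, 1e−6).  Equal spacing was chosen over quantile spacing for
determinism and because the roughening estimate is insensitive to the
layout of a dense grid; B defaults to 200 and results are stable down to
a few dozen points.

scipy's noncentral-t log-density can return NaN deep in the tail
opposite the noncentrality at large df; those entries are replaced by
the asymptotic normal approximation N(nc, df/(df−2)), which is accurate
precisely in the regime where the failure occurs and only affects
log-densities that are astronomically small.

## Fitting

Parameters φ = (γ₁, γ₂, p) are estimated by a generalized EM:

* **E-step** — single-site Gibbs sampling of Θ | Y in fixed raster
  order; the full-conditional logit of site s is
  γ₂ + γ₁·(#active neighbors) + log f₁(y_s) − log f₀(y_s), computed in
  log space.  Per-voxel weights ω_s are the retained-draw means.
  Default E-step chain: 400 sweeps, 100 burn-in; initialization is
  independent Bernoulli(0.5); all randomness derives from one seed,
  re-seeded deterministically per outer iteration.
* **M-step for p** — smoothing-by-roughening: n_inner = 20 weighted
  NPMLE fixed-point iterations per outer iteration
  (r_sb ∝ p_b f_b(y_s); p_b ← Σ_s ω_s r_sb / Σ_s ω_s), continuing from
  the current p rather than restarting from uniform, so the cumulative
  iteration count plays the role of the smoothing parameter (the fit
  starts from a uniform g and roughens gradually toward the NPMLE).
* **M-step for γ** (optional) — stochastic approximation on the score
  E[H(θ)|y] − E[H(θ)], both terms Monte Carlo estimates (posterior
  draws from the E-step, prior draws from a 300-sweep chain).  The step
  is preconditioned by the Bernoulli information of each statistic's
  per-unit fraction (score divided by p̂(1−p̂), clipped to ±1), which
  makes one step approximately a Newton step under the
  independent-field approximation and removes the slow crawl a fixed
  small step exhibits near the optimum.  A candidate γ under which all
  prior draws of Θ coincide — the phase-transition regime, where the
  likelihood in γ is degenerate — is rejected and the previous value
  retained.  Options allow holding all of γ fixed (the usual choice in
  simulation protocols, and the cheapest) or only γ₁.

Outer loop: at most 50 iterations; convergence when the total-variation
change in p falls below 1e−4 and max|Δγ| < 1e−3.  Initialization:
p uniform; γ₁ = 0.1; γ₂ = logit of the fraction of |y| above the null
95% quantile.  Joint estimation of γ and g from a poor starting point
can settle at a biased fixed point (mass of g near zero absorbing null
voxels and inflating ω); starting γ₂ from the exceedance rule or below
avoids this in practice, and holding γ fixed side-steps it entirely.

The component-density matrix log f_b(y_s) (m × B) depends only on the
data and grid, so it is computed once per fit and cached; this is what
makes the t-family fit affordable.

## Calibration of γ₂

For simulation designs the external field is calibrated so the prior
nonnull fraction matches a target: Monte Carlo bisection using the
monotonicity of the stationary nonnull fraction in γ₂, 300-sweep
chains (100 burn-in) per evaluation, stopping within half a tolerance
of 0.01 on the realized proportion.

## Inference

LIS_s is the fraction of posterior draws with Θ_s = 0, from one chain
(default 2500 sweeps, 500 burn-in); ℓ_s = 1 − LIS_s comes from the same
draws, so LIS + ℓ = 1 holds exactly.  The rejection rule sorts LIS
ascending (ties broken by voxel index, stable) and rejects the largest
prefix with Σ LIS_(j) ≤ α·i — the multiplicative form of the running
mean, which avoids one rounding step at exact ties.  The pooled variant
concatenates per-region LIS vectors from separately fitted models and
applies the rule once.

d_s is the convex combination of mass points weighted by p_b f_b(y_s),
computed with max-subtraction in log space so extreme statistics never
underflow; δ̂_s = d_s ℓ_s, so |δ̂_s| ≤ |d_s| always.  Signed estimates
are reported; restricting attention to positive effects (natural when
atrophy implies one-sided effects) is a display choice left downstream.

## Covariate adjustment

Intensities are first standardized per voxel by the pooled two-group
within-group standard deviation (this convention is kept even when
covariates are present; the GLM then runs on standardized data).  The
design matrix is n × (p+1) with the intercept first and the binary
disease indicator second — enforced at construction because the
sampling scale is defined as the (2,2) entry of (WᵀW)⁻¹.  All voxels
share one design, so the fit is a single least-squares solve against
the intensity matrix.  The family defaults to t (df = n − p − 1) for
n ≤ 100 and the normal approximation above, the usual large-sample
guidance; both can be forced.

## Synthetic data

The generator reproduces the structure of the evaluation design:
15×15×15 lattice (the size of a typical parcellation subregion);
γ₁ ∈ {0.05, 0.15, 0.25} for weak/intermediate/strong dependency; γ₂
calibrated to 10/20/50% nonnull; effects δ_s ~ N(0.3, 0.1²) where
θ_s = 1 and exactly zero elsewhere; statistics Y_s/c_n drawn noncentral
t with n − 2 df and noncentrality δ_s/c_n, n ∈ {50, 100, 200} split
evenly.  Latent fields come from a 500-sweep Gibbs burn-in.  Two
misspecification scenarios: (1) θ independent Bernoulli(target) with
effects drawn i.i.d. over the grid and smoothed by a 3-D Gaussian
kernel (σ = 1 voxel, truncated at 3σ — the kernel width is a package
choice, exposed in the config); (2) θ from the Ising model with
smoothed effects.  Smoothing is applied to the full-grid draw before
zeroing nulls, so nonnull effects are spatially correlated with mean
0.3 and reduced dispersion.

What the generator does *not* emulate: registration/segmentation error,
intensity non-normality, heteroscedastic groups, long-range functional
correlation, and region-to-region heterogeneity of g.  Passing tests
therefore demonstrate the statistical machinery under the stated
generative model, not robustness to real acquisition artifacts —
except as probed by the two misspecification scenarios.

Evaluation is rank-wise: voxels ordered by descending Y_s, bias
(estimate − truth) recorded per rank, averaged across replicates by
rank rather than by voxel identity (the selected voxels differ across
replicates; the selection, not the voxel, is the unit of interest).
The replicated study records per-replicate false discovery proportion
and power at the nominal level; replicates whose fit fails are
recorded and skipped.

## Problem sizes and defaults

The replicated studies shipped in the tests and the acceptance script
use 20 replicates at m = 3375, with the fitting model's Ising
parameters held at their true (calibrated) values, 15 EM iterations of
400-sweep chains, B = 200, and a 2500-sweep inference chain — sizes
chosen so a full study completes in minutes on one CPU while keeping
Monte Carlo error well below the tolerances being tested.  One hundred
replicates with free γ reproduce the full protocol when more precision
is wanted.

## Known limitations

* MCMC-EM with free γ inherits the usual difficulties of Markov-random-
  field likelihoods: a biased fixed point from bad initialization, and
  no γ updates beyond the phase transition (by design — candidates are
  rejected there).
* The LIS plug-in controls FDR only to the accuracy of the fitted
  model; with n = 100 and 20% nonnull the replicated empirical FDR sits
  just below the nominal 5%.
* Per-region fitting is sequential; the pooled-LIS helper combines
  results but the package does not parallelize across regions.
* Exact enumeration (the oracle) is limited to m ≤ 16 by construction.
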