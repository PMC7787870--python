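"""Generalized EM estimation of the full model parameters.

The parameter set is ``phi = (gamma1, gamma2, p)``: Ising interaction and
external field, plus the mixing probabilities ``p`` of the discrete
effect-size distribution ``g``.  The algorithm alternates:

* **E-step** — Gibbs sampling of the latent field from its posterior given
  the current parameters; the per-voxel posterior nonnull probabilities
  ``omega_s`` are Monte Carlo averages of the draws.
* **M-step for p** — smoothing-by-roughening: a few weighted NPMLE
  fixed-point iterations on the mixing probabilities, with the per-voxel
  nonnull weights ``omega_s``.  Starting from a uniform distribution and
  stopping early regularizes the estimate; the cumulative iteration count
  plays the role of a smoothing parameter (more iterations = rougher,
  closer to the unpenalized NPMLE).
* **M-step for gamma** (optional) — a stochastic-approximation step matching
  the prior expectation of the Ising sufficient statistics to their
  posterior expectation, with a degeneracy guard: a candidate ``gamma``
  under which all prior draws of the field coincide (the phase-transition
  regime) is rejected and the previous value retained.

The component-density matrix ``logF[s, b]`` is computed once per fit and
cached, since it does not depend on any parameter being estimated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .core_model import (
    EffectSizeDistribution,
    SummaryData,
    component_logpdf_matrix,
    make_mass_grid,
    null_logpdf,
)
from .ising_field import (
    IsingParams,
    LatentFieldSamples,
    VoxelLattice,
    _run_chain,
    gibbs_prior,
)

__all__ = ["ModelParams", "FitConfig", "FitResult", "fit", "update_g", "update_gamma"]


@dataclass
class ModelParams:
    """Full parameter set: Ising parameters plus the effect-size distribution."""

    ising: IsingParams
    g: EffectSizeDistribution


@dataclass
class FitConfig:
    """Settings for the generalized EM fit.

    Attributes
    ----------
    B
        Number of mass points of the effect-size grid (200 is a standard
        choice; estimates are insensitive down to a few dozen).
    max_iter
        Maximum outer EM iterations.
    tol_gamma, tol_p
        Convergence: stop when ``max |delta gamma| < tol_gamma`` and the
        total-variation change in ``p`` is below ``tol_p``.
    n_inner
        Roughening (fixed-point) iterations per outer EM iteration.
    e_sweeps, e_burn_in
        Posterior Gibbs chain length / burn-in per E-step.
    fix_gamma
        Skip the gamma update (used when the Ising parameters are treated
        as known constants, as in simulation protocols).
    fix_gamma1
        Update only the external field ``gamma2``, holding the interaction
        ``gamma1`` at its current value.
    gamma_init
        Starting (or fixed) Ising parameters; defaults to a data-driven
        initialization.
    gamma_step
        Stochastic-approximation step size for the gamma update.
    gamma_sweeps, gamma_burn_in
        Prior Gibbs chain length / burn-in per gamma-update evaluation.
    """

    B: int = 200
    max_iter: int = 50
    tol_gamma: float = 1e-3
    tol_p: float = 1e-4
    n_inner: int = 20
    e_sweeps: int = 400
    e_burn_in: int = 100
    fix_gamma: bool = False
    fix_gamma1: bool = False
    gamma_init: IsingParams | None = None
    gamma_step: float = 1.0
    gamma_sweeps: int = 300
    gamma_burn_in: int = 100


@dataclass
class FitResult:
    """Outcome of a generalized EM fit."""

    params: ModelParams
    n_iterations: int
    converged: bool
    trajectory: list
    posterior_nonnull: np.ndarray
    seed: int


def _roughen(
    logF: np.ndarray, weights: np.ndarray, probs: np.ndarray, n_inner: int
) -> np.ndarray:
    """Weighted NPMLE fixed-point iterations on the mixing probabilities.

    One step: responsibilities ``r_sb ∝ p_b f_b(y_s)`` (normalized over b),
    then ``p_b <- sum_s w_s r_sb / sum_s w_s``.  Rows are normalized with a
    max-subtraction in log space, so density underflow is harmless.
    """
    wsum = weights.sum()
    if wsum == 0:
        return probs.copy()
    p = probs.copy()
    for _ in range(n_inner):
        with np.errstate(divide="ignore"):
            logw = logF + np.log(p)[None, :]
        logw -= logw.max(axis=1, keepdims=True)
        r = np.exp(logw)
        r /= r.sum(axis=1, keepdims=True)
        p = (weights @ r) / wsum
        p = np.clip(p, 0.0, None)
        p /= p.sum()
    return p


def update_g(
    data: SummaryData,
    weights: np.ndarray,
    g_current: EffectSizeDistribution,
    n_inner: int = 20,
) -> EffectSizeDistribution:
    """Smoothing-by-roughening update of the effect-size distribution.

    Runs ``n_inner`` weighted NPMLE fixed-point iterations from
    ``g_current``, with per-voxel nonnull weights in [0, 1].  If all weights
    are zero the current distribution is returned unchanged.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.size != data.m:
        raise ValueError("weights must align with data")
    if np.any((weights < 0) | (weights > 1)):
        raise ValueError("weights must lie in [0, 1]")
    logF = component_logpdf_matrix(data.y, g_current.mass_points, data)
    p = _roughen(logF, weights, g_current.probs, n_inner)
    return g_current.with_probs(p)


def _mean_suff_stats(draws: np.ndarray, lattice: VoxelLattice) -> np.ndarray:
    """Monte Carlo mean of H(theta) = (pair stat, ones) over draws."""
    p = lattice.neighbor_pairs
    d = draws.astype(np.float64)
    pair = (d[:, p[:, 0]] * d[:, p[:, 1]]).sum(axis=1).mean() if len(p) else 0.0
    ones = d.sum(axis=1).mean()
    return np.array([pair, ones])


def update_gamma(
    current: IsingParams,
    posterior_draws: LatentFieldSamples,
    lattice: VoxelLattice,
    config: FitConfig,
    seed: int,
    candidate: IsingParams | None = None,
) -> IsingParams:
    """Stochastic-approximation update of the Ising parameters.

    The gradient of the expected complete-data log-likelihood in ``gamma``
    is ``E[H(theta) | y] - E[H(theta)]`` (posterior minus prior moments of
    the sufficient statistics).  Both expectations are Monte Carlo
    estimates; the step is scaled by the number of pairs / voxels so the
    two components are comparable.  A ``candidate`` may be supplied
    directly, bypassing the gradient step.  Any candidate under which all
    prior draws of the field are identical — the phase-transition regime,
    where the likelihood in ``gamma`` is degenerate — is rejected and the
    current value retained.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
    n_pairs = max(len(lattice.neighbor_pairs), 1)
    if candidate is None:
        h_post = _mean_suff_stats(posterior_draws.draws, lattice)
        prior = gibbs_prior(
            current, lattice, config.gamma_sweeps, seeds[0],
            burn_in=config.gamma_burn_in,
        )
        h_prior = _mean_suff_stats(prior.draws, lattice)
        grad = (h_post - h_prior) / np.array([n_pairs, lattice.m])
        # precondition by the Bernoulli information of each statistic's
        # per-unit fraction (quasi-Newton scaling; keeps steps comparable
        # across sparse and dense regimes), clipped for stability
        qbar = min(max(h_prior[0] / n_pairs, 0.02), 0.98)
        pbar = min(max(h_prior[1] / lattice.m, 0.02), 0.98)
        step1 = np.clip(grad[0] / (qbar * (1 - qbar)), -1.0, 1.0)
        step2 = np.clip(grad[1] / (pbar * (1 - pbar)), -1.0, 1.0)
        g1_step = 0.0 if config.fix_gamma1 else config.gamma_step * step1
        candidate = IsingParams(
            current.gamma1 + g1_step,
            current.gamma2 + config.gamma_step * step2,
        )
    check = gibbs_prior(
        candidate, lattice, config.gamma_sweeps, seeds[1],
        burn_in=config.gamma_burn_in,
    )
    if check.all_equal():
        return current
    return candidate


def _init_gamma(data: SummaryData) -> IsingParams:
    """Data-driven start: modest interaction, field from the exceedance rate."""
    from scipy import stats

    if data.family == "t":
        q = stats.t.ppf(0.95, data.df) * data.c_n
    else:
        q = stats.norm.ppf(0.95) * data.c_n
    frac = float(np.clip(np.mean(np.abs(data.y) > q), 0.01, 0.8))
    return IsingParams(0.1, float(np.log(frac / (1 - frac))))


def fit(
    data: SummaryData,
    lattice: VoxelLattice,
    config: FitConfig | None = None,
    seed: int = 0,
) -> FitResult:
    """Fit the full model by generalized EM.

    Alternates posterior Gibbs sampling of the latent field (E-step),
    smoothing-by-roughening updates of ``g`` and, unless ``fix_gamma``,
    stochastic-approximation updates of the Ising parameters.  All
    randomness derives from ``seed``; the E-step chain is re-seeded
    deterministically each outer iteration.
    """
    if config is None:
        config = FitConfig()
    if data.m != lattice.m:
        raise ValueError("data and lattice sizes differ")
    if not np.all(np.isfinite(data.y)):
        raise ValueError("y contains non-finite values")

    grid = make_mass_grid(data.y, config.B, pad=data.c_n)
    g = EffectSizeDistribution(grid, np.full(config.B, 1.0 / config.B))
    gamma = config.gamma_init if config.gamma_init is not None else _init_gamma(data)

    logF = component_logpdf_matrix(data.y, grid, data)
    logf0 = null_logpdf(data.y, data)

    ss = np.random.SeedSequence(seed)
    trajectory: list = []
    omega = np.zeros(data.m)
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        sub = ss.spawn(1)[0]
        e_seed, g_seed = (int(s.generate_state(1)[0] % (2**31)) for s in sub.spawn(2))

        with np.errstate(divide="ignore"):
            logf1 = logsumexp(logF + np.log(g.probs)[None, :], axis=1)
        llr = logf1 - logf0
        eta = gamma.gamma2 + llr
        draws = _run_chain(
            gamma.gamma1, eta, lattice, config.e_sweeps, config.e_burn_in, 1,
            np.random.default_rng(e_seed),
        )
        samples = LatentFieldSamples(draws, config.e_burn_in, 1, e_seed)
        omega = samples.mean

        p_new = _roughen(logF, omega, g.probs, config.n_inner)
        dp = 0.5 * np.abs(p_new - g.probs).sum()
        g = g.with_probs(p_new)

        dgamma = 0.0
        if not config.fix_gamma:
            gamma_new = update_gamma(gamma, samples, lattice, config, g_seed)
            dgamma = max(
                abs(gamma_new.gamma1 - gamma.gamma1),
                abs(gamma_new.gamma2 - gamma.gamma2),
            )
            gamma = gamma_new

        trajectory.append(
            {
                "iteration": it,
                "gamma1": gamma.gamma1,
                "gamma2": gamma.gamma2,
                "g_mean": float(g.probs @ g.mass_points),
                "delta_p_tv": dp,
                "delta_gamma": dgamma,
            }
        )
        if dp < config.tol_p and (config.fix_gamma or dgamma < config.tol_gamma):
            converged = True
            break

    return FitResult(
        params=ModelParams(ising=gamma, g=g),
        n_iterations=it,
        converged=converged,
        trajectory=trajectory,
        posterior_nonnull=omega,
        seed=seed,
    )
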