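"""Hidden Markov random field over the voxel lattice.

The latent null/nonnull indicators ``theta in {0,1}^m`` follow an Ising model

    Pr(theta) = exp(gamma1 * sum_{(s,t) in S1} theta_s theta_t
                    + gamma2 * sum_s theta_s) / C(gamma)

where ``S1`` is the set of unordered pairs of face-adjacent in-mask voxels
(6-connectivity) and ``C(gamma)`` is an intractable normalizer.  ``gamma1``
controls spatial clustering of associated voxels; ``gamma2`` controls their
overall prevalence.

Sampling is by single-site Gibbs updates in raster order.  The posterior
sampler tilts each site's full conditional by the per-voxel log-likelihood
ratio ``log f1(y_s) - log f0(y_s)``.  Exact enumeration over all ``2^m``
configurations is available for tiny lattices and serves as the correctness
oracle for both samplers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numba
import numpy as np
from scipy.special import logit, softmax

from . import core_model
from .core_model import SummaryData

if TYPE_CHECKING:  # pragma: no cover
    from .em_fitting import ModelParams

__all__ = [
    "VoxelLattice",
    "IsingParams",
    "LatentFieldSamples",
    "ExactDistribution",
    "suff_stats",
    "gibbs_prior",
    "gibbs_posterior",
    "exact_distribution",
    "calibrate_gamma2",
]


@dataclass(frozen=True)
class IsingParams:
    """Ising parameters: pairwise interaction ``gamma1``, external field ``gamma2``."""

    gamma1: float
    gamma2: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.gamma1) and np.isfinite(self.gamma2)):
            raise ValueError("Ising parameters must be finite")


class VoxelLattice:
    """3-D voxel grid geometry: mask, neighbor pairs, optional region labels.

    In-mask voxels are numbered ``0..m-1`` in raster (C) order of the grid.
    Contiguity is face adjacency (6-neighborhood).
    """

    def __init__(
        self,
        dims: tuple[int, int, int],
        mask: np.ndarray,
        region_labels: np.ndarray | None = None,
    ):
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim != 3 or mask.shape != tuple(dims):
            raise ValueError("mask must be a 3-D array matching dims")
        if not mask.any():
            raise ValueError("mask must contain at least one voxel")
        self.dims = tuple(int(d) for d in dims)
        self.mask = mask
        self.m = int(mask.sum())
        # raster-order flat grid indices of in-mask voxels
        self._flat = np.flatnonzero(mask.ravel())
        if region_labels is not None:
            region_labels = np.asarray(region_labels)
            if region_labels.size != self.m:
                raise ValueError("region_labels must have one entry per in-mask voxel")
        self.region_labels = region_labels
        self.neighbor_pairs = self._build_pairs()
        self._adjacency: tuple[np.ndarray, np.ndarray] | None = None

    @classmethod
    def full(cls, dims: tuple[int, int, int]) -> "VoxelLattice":
        """Lattice with every grid cell in the mask."""
        return cls(dims, np.ones(dims, dtype=bool))

    @classmethod
    def from_coords(
        cls,
        coords: np.ndarray,
        region_labels: np.ndarray | None = None,
    ) -> "VoxelLattice":
        """Build from an (m, 3) array of 0-based integer grid coordinates.

        Voxels are re-ordered to raster order internally; ``raster_order``
        maps input rows to lattice positions.
        """
        coords = np.asarray(coords, dtype=int)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be an (m, 3) array")
        if coords.min() < 0:
            raise ValueError("coordinates must be nonnegative")
        dims = tuple(coords.max(axis=0) + 1)
        mask = np.zeros(dims, dtype=bool)
        mask[tuple(coords.T)] = True
        if mask.sum() != coords.shape[0]:
            raise ValueError("duplicate coordinates")
        flat = np.ravel_multi_index(tuple(coords.T), dims)
        order = np.argsort(flat, kind="stable")
        labels = None
        if region_labels is not None:
            labels = np.asarray(region_labels)[order]
        lat = cls(dims, mask, labels)
        lat.input_order = order  # lattice position i came from input row order[i]
        return lat

    def _build_pairs(self) -> np.ndarray:
        """Unordered face-adjacent in-mask pairs, as indices into 0..m-1."""
        idx = -np.ones(self.dims, dtype=np.int64)
        idx[self.mask] = np.arange(self.m)
        pairs = []
        for ax in range(3):
            a = np.moveaxis(idx, ax, 0)
            u, v = a[:-1].ravel(), a[1:].ravel()
            ok = (u >= 0) & (v >= 0)
            if ok.any():
                pairs.append(np.stack([u[ok], v[ok]], axis=1))
        if not pairs:
            return np.empty((0, 2), dtype=np.int64)
        return np.concatenate(pairs, axis=0)

    @property
    def adjacency(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR neighbor structure ``(indptr, indices)`` over in-mask voxels."""
        if self._adjacency is None:
            counts = np.zeros(self.m, dtype=np.int64)
            p = self.neighbor_pairs
            np.add.at(counts, p[:, 0], 1)
            np.add.at(counts, p[:, 1], 1)
            indptr = np.zeros(self.m + 1, dtype=np.int64)
            np.cumsum(counts, out=indptr[1:])
            indices = np.empty(indptr[-1], dtype=np.int64)
            cursor = indptr[:-1].copy()
            for u, v in p:
                indices[cursor[u]] = v
                cursor[u] += 1
                indices[cursor[v]] = u
                cursor[v] += 1
            self._adjacency = (indptr, indices)
        return self._adjacency

    def subsets_by_region(self) -> dict:
        """Map region label -> index array of member voxels (raster order)."""
        if self.region_labels is None:
            raise ValueError("lattice has no region labels")
        out: dict = {}
        for lab in np.unique(self.region_labels):
            out[lab] = np.flatnonzero(self.region_labels == lab)
        return out


@dataclass
class LatentFieldSamples:
    """Post-burn-in Gibbs draws of the latent field.

    ``draws`` has shape (n_draws, m) with values in {0, 1}.
    """

    draws: np.ndarray
    burn_in: int
    thinning: int
    seed: int

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=np.int8)
        if self.draws.ndim != 2 or self.draws.shape[0] == 0:
            raise ValueError("draws must be a nonempty (n_draws, m) array")
        if not np.isin(self.draws, (0, 1)).all():
            raise ValueError("draws must be binary")

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    @property
    def mean(self) -> np.ndarray:
        """Per-voxel posterior/prior probability of being nonnull."""
        return self.draws.mean(axis=0)

    def all_equal(self) -> bool:
        """True when every draw is the identical configuration (frozen chain)."""
        return bool((self.draws == self.draws[0]).all())


def suff_stats(theta: np.ndarray, lattice: VoxelLattice) -> tuple[int, int]:
    """Ising sufficient statistics ``H(theta)``.

    Returns ``(number of neighbor pairs with both ends 1, number of ones)``.
    """
    theta = np.asarray(theta)
    if theta.size != lattice.m:
        raise ValueError("theta length must equal the number of in-mask voxels")
    p = lattice.neighbor_pairs
    both = int((theta[p[:, 0]] * theta[p[:, 1]]).sum()) if len(p) else 0
    return both, int(theta.sum())


@numba.njit(cache=False)
def _gibbs_sweep(theta, indptr, indices, gamma1, eta, rand):  # pragma: no cover
    for s in range(theta.size):
        acc = 0.0
        for j in range(indptr[s], indptr[s + 1]):
            acc += theta[indices[j]]
        z = gamma1 * acc + eta[s]
        p = 1.0 / (1.0 + np.exp(-z))
        theta[s] = 1 if rand[s] < p else 0


def _run_chain(
    gamma1: float,
    eta: np.ndarray,
    lattice: VoxelLattice,
    n_sweeps: int,
    burn_in: int,
    thinning: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Raster-order single-site Gibbs; returns retained draws (n_kept, m)."""
    if n_sweeps <= burn_in:
        raise ValueError("n_sweeps must exceed burn_in")
    indptr, indices = lattice.adjacency
    theta = (rng.random(lattice.m) < 0.5).astype(np.int8)
    kept = []
    for sweep in range(n_sweeps):
        _gibbs_sweep(theta, indptr, indices, gamma1, eta, rng.random(lattice.m))
        if sweep >= burn_in and (sweep - burn_in) % thinning == 0:
            kept.append(theta.copy())
    return np.stack(kept)


def gibbs_prior(
    params: IsingParams,
    lattice: VoxelLattice,
    n_sweeps: int,
    seed: int,
    burn_in: int = 500,
    thinning: int = 1,
) -> LatentFieldSamples:
    """Sample the latent field from the Ising prior.

    ``n_sweeps`` is the total sweep count including ``burn_in``; draws after
    burn-in are retained every ``thinning`` sweeps.  The full conditional of
    site ``s`` is Bernoulli with logit ``gamma2 + gamma1 * (#active
    neighbors)``.  Reproducible given ``seed``.
    """
    rng = np.random.default_rng(seed)
    eta = np.full(lattice.m, params.gamma2, dtype=float)
    draws = _run_chain(params.gamma1, eta, lattice, n_sweeps, burn_in, thinning, rng)
    return LatentFieldSamples(draws, burn_in, thinning, seed)


def _llr(params: "ModelParams", data: SummaryData) -> np.ndarray:
    """Per-voxel log-likelihood ratio log f1(y_s) - log f0(y_s)."""
    return np.asarray(
        core_model.nonnull_logpdf(data.y, params.g, data)
    ) - core_model.null_logpdf(data.y, data)


def gibbs_posterior(
    params: "ModelParams",
    data: SummaryData,
    lattice: VoxelLattice,
    n_sweeps: int,
    seed: int,
    burn_in: int = 500,
    thinning: int = 1,
    llr: np.ndarray | None = None,
) -> LatentFieldSamples:
    """Sample the latent field from its posterior given the statistics.

    The full conditional logit gains the data term: ``gamma2 + gamma1 *
    (#active neighbors) + log f1(y_s) - log f0(y_s)``.  The log-likelihood
    ratio may be passed in (``llr``) when the caller has it cached; computed
    in log space throughout, so density underflow never raises.
    """
    if data.m != lattice.m:
        raise ValueError("data and lattice sizes differ")
    if llr is None:
        llr = _llr(params, data)
    rng = np.random.default_rng(seed)
    eta = params.ising.gamma2 + np.asarray(llr, dtype=float)
    draws = _run_chain(
        params.ising.gamma1, eta, lattice, n_sweeps, burn_in, thinning, rng
    )
    return LatentFieldSamples(draws, burn_in, thinning, seed)


@dataclass
class ExactDistribution:
    """Exact probability table over all ``2^m`` latent configurations."""

    states: np.ndarray  # (2^m, m) binary
    probs: np.ndarray  # (2^m,), sums to 1

    @property
    def marginals(self) -> np.ndarray:
        """Exact per-voxel probability of being nonnull."""
        return self.probs @ self.states


def exact_distribution(
    params,
    lattice: VoxelLattice,
    data: SummaryData | None = None,
) -> ExactDistribution:
    """Enumerate the latent-field distribution exactly (tiny lattices only).

    ``params`` is either :class:`IsingParams` (prior) or a ``ModelParams``
    (with ``data``, the posterior: each state's energy gains
    ``sum_s theta_s * (log f1(y_s) - log f0(y_s))``).  Refuses ``m > 16``.
    """
    m = lattice.m
    if m > 16:
        raise ValueError("exact enumeration is limited to m <= 16 voxels")
    if hasattr(params, "ising"):
        ising, tilt = params.ising, (None if data is None else _llr(params, data))
    else:
        ising, tilt = params, None
    states = (np.arange(2**m)[:, None] >> np.arange(m)[None, :]) & 1
    states = states.astype(np.int8)
    p = lattice.neighbor_pairs
    pair_term = (
        (states[:, p[:, 0]] * states[:, p[:, 1]]).sum(axis=1)
        if len(p)
        else np.zeros(2**m)
    )
    field = np.full(m, ising.gamma2, dtype=float)
    if tilt is not None:
        field = field + tilt
    energy = ising.gamma1 * pair_term + states @ field
    return ExactDistribution(states, softmax(energy))


def calibrate_gamma2(
    gamma1: float,
    target_prop: float,
    lattice: VoxelLattice,
    seed: int,
    tol: float = 0.01,
    n_sweeps: int = 300,
    burn_in: int = 100,
    max_iter: int = 30,
) -> float:
    """Find ``gamma2`` so the prior nonnull fraction matches ``target_prop``.

    Monte Carlo bisection: the mean nonnull fraction under ``gibbs_prior`` is
    nondecreasing in ``gamma2``, so a sign change brackets the root.  Each
    evaluation runs a short chain (``n_sweeps`` total, ``burn_in`` discarded).
    Stops when the realized fraction is within ``tol/2`` of target or the
    bracket is exhausted.
    """
    if not 0.0 < target_prop < 1.0:
        raise ValueError("target_prop must lie in (0, 1)")
    ss = np.random.SeedSequence(seed)

    def frac(g2: float) -> float:
        sub = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        s = gibbs_prior(
            IsingParams(gamma1, g2), lattice, n_sweeps, sub, burn_in=burn_in
        )
        return float(s.draws.mean())

    base = float(logit(target_prop))
    lo, hi = base - 6.0 * abs(gamma1) - 0.5, base + 0.5
    flo, fhi = frac(lo), frac(hi)
    for _ in range(10):
        if flo <= target_prop:
            break
        lo -= 2.0
        flo = frac(lo)
    for _ in range(10):
        if fhi >= target_prop:
            break
        hi += 2.0
        fhi = frac(hi)
    if flo > target_prop or fhi < target_prop:
        raise RuntimeError("could not bracket the target proportion")
    mid = 0.5 * (lo + hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f = frac(mid)
        if abs(f - target_prop) <= 0.5 * tol:
            return mid
        if f < target_prop:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-4:
            break
    return mid
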