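"""Probabilistic building blocks of the hierarchical mixture model.

A voxel-wise association study summarises each voxel ``s`` by a standardized
mean difference ``Y_s`` between two subject groups.  Conditional on the latent
null/nonnull indicator, ``Y_s`` follows either

* the null sampling density ``f0``: normal ``N(0, c_n^2)`` for large samples,
  or a scaled central t with ``n - 2`` degrees of freedom, where
  ``c_n = sqrt(n / (n1 * n2))``; or
* the nonnull density ``f1``: a mixture over a discrete effect-size
  distribution ``g`` with mass points ``t_1 < ... < t_B`` and probabilities
  ``p_1, ..., p_B``; each component is normal ``N(t_b, c_n^2)`` (large-sample
  approximation) or a scaled noncentral t with noncentrality ``t_b / c_n``.

Everything here is pure computation on arrays; the spatial model, fitting and
inference live in the sibling modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "SummaryData",
    "EffectSizeDistribution",
    "compute_cn",
    "null_density",
    "null_logpdf",
    "nonnull_density",
    "component_logpdf_matrix",
    "make_mass_grid",
]

_FAMILIES = ("normal", "t")


def compute_cn(n1: int, n2: int) -> float:
    """Sampling scale ``c_n = sqrt((n1 + n2) / (n1 * n2))`` of the statistic.

    This is the standard error of a difference of two means with unit
    within-group variance; ``Y_s / c_n`` is the ordinary two-sample
    t-statistic.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError(f"group sizes must be >= 1, got n1={n1}, n2={n2}")
    return float(np.sqrt((n1 + n2) / (n1 * n2)))


@dataclass
class SummaryData:
    """Per-voxel summary statistics plus their sampling-model metadata.

    Parameters
    ----------
    y
        Standardized mean differences, one per voxel (unitless).
    n1, n2
        Group sizes (e.g. diseased / control subject counts).
    family
        ``"normal"`` for the large-sample normal approximation, ``"t"`` for
        the exact (non)central-t sampling model.
    df
        Degrees of freedom for the t family.  Defaults to ``n - 2`` (the
        two-group design); a covariate-adjusted fit supplies ``n - p - 1``.
    c_n
        Sampling scale.  Defaults to ``compute_cn(n1, n2)``; a GLM-based
        statistic supplies the design-derived value instead.
    voxel_ids
        Identifiers aligned with ``y``; defaults to ``0..m-1``.
    """

    y: np.ndarray
    n1: int
    n2: int
    family: str = "normal"
    df: int | None = None
    c_n: float | None = None
    voxel_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.atleast_1d(np.asarray(self.y, dtype=float))
        if self.y.ndim != 1 or self.y.size == 0:
            raise ValueError("y must be a nonempty 1-D vector")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("y contains non-finite values")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("group sizes must be >= 1")
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")
        if self.c_n is None:
            self.c_n = compute_cn(self.n1, self.n2)
        if self.c_n <= 0:
            raise ValueError("c_n must be strictly positive")
        if self.family == "t":
            if self.df is None:
                self.df = self.n - 2
            if self.df < 1:
                raise ValueError("t family requires df >= 1")
        if self.voxel_ids is None:
            self.voxel_ids = np.arange(self.y.size)
        else:
            self.voxel_ids = np.asarray(self.voxel_ids)
            if self.voxel_ids.size != self.y.size:
                raise ValueError("voxel_ids must align with y")

    @property
    def n(self) -> int:
        return self.n1 + self.n2

    @property
    def m(self) -> int:
        return self.y.size

    def with_family(self, family: str, df: int | None = None) -> "SummaryData":
        """Copy with a different assumed sampling family (same data)."""
        return SummaryData(
            y=self.y.copy(),
            n1=self.n1,
            n2=self.n2,
            family=family,
            df=df,
            c_n=self.c_n,
            voxel_ids=self.voxel_ids.copy(),
        )


@dataclass
class EffectSizeDistribution:
    """Discrete nonparametric effect-size distribution ``g``.

    ``g`` puts probability ``probs[b]`` on mass point ``mass_points[b]``.
    Mass points are strictly increasing and none is exactly zero (zero is the
    null and belongs to ``f0``, not to ``g``).
    """

    mass_points: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.mass_points = np.asarray(self.mass_points, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.mass_points.shape != self.probs.shape or self.mass_points.ndim != 1:
            raise ValueError("mass_points and probs must be equal-length vectors")
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(self.probs.sum() - 1.0) > 1e-10:
            raise ValueError("probabilities must sum to 1")
        if np.any(self.mass_points == 0.0):
            raise ValueError("no mass point may be exactly 0")
        if np.any(np.diff(self.mass_points) <= 0):
            raise ValueError("mass_points must be strictly increasing")

    @property
    def B(self) -> int:
        return self.mass_points.size

    @property
    def mean(self) -> float:
        """Mean of g, ``sum_b p_b t_b``."""
        return float(self.probs @ self.mass_points)

    def with_probs(self, probs: np.ndarray) -> "EffectSizeDistribution":
        return EffectSizeDistribution(self.mass_points.copy(), probs)


def make_mass_grid(y: np.ndarray, B: int, pad: float = 0.0) -> np.ndarray:
    """Equally spaced mass points covering the observed range of ``y``.

    The grid spans ``[min(y) - pad, max(y) + pad]`` (``pad`` is typically the
    sampling scale ``c_n`` so the support comfortably covers plausible
    effects).  A degenerate range is widened by ``max(pad, 1e-6)`` on each
    side.  Any grid point landing exactly at zero is nudged up by half a grid
    step, because the nonnull distribution excludes a zero effect.
    Deterministic given ``(y, B, pad)``.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("y must be nonempty")
    lo, hi = float(y.min()) - pad, float(y.max()) + pad
    if hi <= lo:
        w = max(pad, 1e-6)
        lo, hi = lo - w, hi + w
    grid = np.linspace(lo, hi, B)
    step = (hi - lo) / (B - 1)
    zero = np.flatnonzero(grid == 0.0)
    if zero.size:
        # nudge by half a step, downward at the left endpoint so the grid
        # still covers [min(y), max(y)]
        b = zero[0]
        grid[b] += -0.5 * step if b == 0 else 0.5 * step
    return grid


def _check_meta(meta: SummaryData) -> None:
    if meta.family == "t" and meta.df is None:
        raise ValueError("t family requires df")


def _nct_logpdf(x: np.ndarray, df: int, nc: np.ndarray) -> np.ndarray:
    """Noncentral-t log-density, robust in the far tails.

    scipy's implementation can return NaN deep in the tail opposite the
    noncentrality at large df; those entries are replaced by the asymptotic
    normal approximation (mean nc, variance df/(df-2)), which is accurate
    exactly in the large-df regime where the failure occurs and in any case
    only affects log-densities that are astronomically small.
    """
    out = stats.nct.logpdf(x, df, nc)
    bad = ~np.isfinite(out)
    if np.any(bad):
        scale = np.sqrt(df / (df - 2)) if df > 2 else 1.0
        approx = stats.norm.logpdf(x, loc=nc, scale=scale)
        out = np.where(bad, np.broadcast_to(approx, out.shape), out)
    return out


def null_logpdf(y, meta: SummaryData) -> np.ndarray:
    """Log of the null density ``f0`` evaluated at ``y``.

    Normal family: ``N(0, c_n^2)``.  t family: ``Y/c_n ~ t_df``, so the
    density of ``Y`` carries a ``1/c_n`` Jacobian.
    """
    _check_meta(meta)
    y = np.asarray(y, dtype=float)
    c = meta.c_n
    if meta.family == "normal":
        return stats.norm.logpdf(y, loc=0.0, scale=c)
    return stats.t.logpdf(y / c, meta.df) - np.log(c)


def null_density(y, meta: SummaryData) -> np.ndarray:
    """Null density ``f0(y)``."""
    return np.exp(null_logpdf(y, meta))


def component_logpdf_matrix(
    y: np.ndarray, mass_points: np.ndarray, meta: SummaryData
) -> np.ndarray:
    """Matrix ``logF[s, b] = log f_b(y_s)`` of per-mass-point densities.

    ``f_b`` is the sampling density of ``Y`` given effect size ``t_b``:
    ``N(t_b, c_n^2)`` for the normal family, or the scaled noncentral t with
    noncentrality ``t_b / c_n`` for the t family.  This matrix depends only
    on the data and grid — not on the mixing weights — so callers cache it
    across EM iterations.
    """
    _check_meta(meta)
    y = np.asarray(y, dtype=float)[:, None]
    t = np.asarray(mass_points, dtype=float)[None, :]
    c = meta.c_n
    if meta.family == "normal":
        return stats.norm.logpdf(y, loc=t, scale=c)
    return _nct_logpdf(y / c, meta.df, t / c) - np.log(c)


def nonnull_logpdf(y, g: EffectSizeDistribution, meta: SummaryData) -> np.ndarray:
    """Log of the marginal nonnull density ``f1(y) = sum_b p_b f_b(y)``."""
    y_arr = np.atleast_1d(y)
    logF = component_logpdf_matrix(y_arr, g.mass_points, meta)
    with np.errstate(divide="ignore"):
        logp = np.log(g.probs)
    out = logsumexp(logF + logp[None, :], axis=1)
    return out if np.ndim(y) else float(out[0])


def nonnull_density(y, g: EffectSizeDistribution, meta: SummaryData) -> np.ndarray:
    """Marginal nonnull density ``f1(y)`` under the mixture over ``g``."""
    return np.exp(nonnull_logpdf(y, g, meta))
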