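"""Covariate-adjusted per-voxel effect statistics via general linear models.

When subject-level covariates (age, sex, intracranial volume, ...) must be
adjusted for, the per-voxel statistic is the disease coefficient of a
voxel-wise general linear model fitted to intensities that were first
standardized to unit pooled within-group variance:

    x_{i,s} = beta_0 + beta_1 * disease_i + beta_2 * w_{i,2} + ... + eps

``Y_s,adj = beta_1_hat`` with sampling scale ``c_n = sqrt((W'W)^{-1}_{22})``
— the square root of the (2,2) entry of the inverse Gram matrix of the
design, the disease column being the second column by convention.  With no
extra covariates and balanced groups this reduces to the plain standardized
mean difference.  For small samples ``Y_s,adj / c_n`` is treated as t with
``n - p - 1`` degrees of freedom.

The design is shared across voxels, so all voxel fits reduce to one
least-squares solve against the intensity matrix (mass-univariate form).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import SummaryData

__all__ = ["SubjectData", "standardize_intensities", "fit_voxel_glm"]


@dataclass
class SubjectData:
    """Subject-level intensities and design matrix.

    ``design`` is the n x (p+1) matrix W: first column all ones, second the
    binary disease indicator, remaining columns covariates.  Intensities are
    expected to be standardized per voxel (see
    :func:`standardize_intensities`).
    """

    intensities: np.ndarray
    design: np.ndarray
    covariate_names: list | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.design = np.asarray(self.design, dtype=float)
        if self.intensities.ndim != 2 or self.design.ndim != 2:
            raise ValueError("intensities and design must be 2-D")
        n = self.intensities.shape[0]
        if self.design.shape[0] != n:
            raise ValueError("design rows must match the number of subjects")
        if not np.allclose(self.design[:, 0], 1.0):
            raise ValueError("first design column must be the intercept (all ones)")
        ind = self.design[:, 1]
        if not np.isin(ind, (0.0, 1.0)).all():
            raise ValueError("second design column must be the binary disease indicator")
        if np.linalg.matrix_rank(self.design) < self.design.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def n(self) -> int:
        return self.design.shape[0]

    @property
    def group(self) -> np.ndarray:
        return self.design[:, 1].astype(int)


def standardize_intensities(raw: np.ndarray, group: np.ndarray) -> np.ndarray:
    """Scale each voxel to unit pooled within-group variance.

    The pooled estimator is ``sigma_s^2 = (SS_1 + SS_2) / (n - 2)`` with
    group-wise centered sums of squares; each voxel column is divided by
    ``sigma_s``.  A voxel with zero within-group variance is degenerate and
    raises, naming the offending voxel.
    """
    raw = np.asarray(raw, dtype=float)
    group = np.asarray(group).astype(int)
    if raw.ndim != 2 or group.size != raw.shape[0]:
        raise ValueError("raw must be subjects x voxels with one group label per subject")
    if not np.isin(group, (0, 1)).all():
        raise ValueError("group must be binary")
    n1, n0 = int((group == 1).sum()), int((group == 0).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("need at least 2 subjects per group")
    ss = np.zeros(raw.shape[1])
    for gval in (0, 1):
        sub = raw[group == gval]
        ss += ((sub - sub.mean(axis=0)) ** 2).sum(axis=0)
    pooled_var = ss / (n1 + n0 - 2)
    bad = np.flatnonzero(pooled_var <= 0)
    if bad.size:
        raise ValueError(f"zero within-group variance at voxel(s) {bad[:5].tolist()}")
    return raw / np.sqrt(pooled_var)


def fit_voxel_glm(subject_data: SubjectData, family: str | None = None) -> SummaryData:
    """Voxel-wise least squares; returns the adjusted statistics as data.

    ``Y_s,adj`` is the fitted disease coefficient per voxel; ``c_n`` is
    ``sqrt((W'W)^{-1}_{22})``.  ``family`` defaults to ``"t"`` (df =
    n - p - 1) for n <= 100 and ``"normal"`` otherwise, following the usual
    large-sample guidance; pass it explicitly to override.
    """
    W = subject_data.design
    X = subject_data.intensities
    n, q = W.shape
    p = q - 1
    if n <= q:
        raise ValueError("need more subjects than design columns")
    gram_inv = np.linalg.inv(W.T @ W)
    beta = gram_inv @ (W.T @ X)
    y_adj = beta[1]
    c_n = float(np.sqrt(gram_inv[1, 1]))
    if family is None:
        family = "t" if n <= 100 else "normal"
    group = subject_data.group
    return SummaryData(
        y=y_adj,
        n1=int((group == 1).sum()),
        n2=int((group == 0).sum()),
        family=family,
        df=n - p - 1 if family == "t" else None,
        c_n=c_n,
    )
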