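"""Exact likelihood of the reciprocal graphical model from summary statistics.

The structural model is

    y = A y + B x + e,      e ~ N(0, diag(sigma2)),

where ``A`` (p x p, zero diagonal) holds the possibly-cyclic causal effects
among responses, ``B`` (p x k, supported on the instrument-assignment
pattern D) holds instrument effects, and the errors are independent across
responses.  Solving for y introduces the change-of-variables Jacobian
|det(I - A)|, so the log-likelihood of n observations is

    ll = n log|det(I - A)| - (n/2) sum_i log(2 pi sigma2_i)
         - (n/2) sum_i R_ii / sigma2_i,

    R  = (I-A) Syy (I-A)' - (I-A) Syx B' - B Syx' (I-A)' + B Sxx B',

which depends on the data only through the cross-moment matrices
Syy = Y'Y/n, Syx = Y'X/n, Sxx = X'X/n — algebraically identical to the
per-observation Gaussian log-likelihood of e_t = (I-A) y_t - B x_t.

Single-entry Metropolis moves on A change I - A by a rank-one matrix, so
the determinant and inverse are maintained by the matrix-determinant lemma
and the Sherman–Morrison formula instead of O(p^3) refactorisations; the
workspace is rebuilt from scratch periodically to bound floating-point
drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import SummaryStatistics

__all__ = [
    "StructuralParameters",
    "SingularModelError",
    "log_abs_det",
    "residual_cross_products",
    "log_likelihood",
    "impute_syy",
    "log_likelihood_regression_path",
    "DeterminantWorkspace",
    "rank_one_logdet_update",
]

SINGULARITY_TOL = 1e-12

_LOG_2PI = float(np.log(2.0 * np.pi))


class SingularModelError(ValueError):
    """det(I - A) is (numerically) zero: the structural system has no
    unique equilibrium and the likelihood is undefined."""


@dataclass
class StructuralParameters:
    """The causal machinery (A, B, sigma2) of y = Ay + Bx + e."""

    A: np.ndarray
    B: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        self.sigma2 = np.atleast_1d(np.asarray(self.sigma2, dtype=float))
        p = self.A.shape[0]
        if self.A.shape != (p, p):
            raise ValueError("A must be square")
        if np.abs(np.diag(self.A)).max(initial=0.0) != 0.0:
            raise ValueError("A must have a zero diagonal (no self-loops)")
        if self.B.shape[0] != p or self.sigma2.shape != (p,):
            raise ValueError("B rows and sigma2 length must match A's dimension")
        if (self.sigma2 <= 0).any():
            raise ValueError("error variances sigma2 must be positive")

    @property
    def p(self) -> int:
        return self.A.shape[0]

    @property
    def k(self) -> int:
        return self.B.shape[1]


def log_abs_det(A: np.ndarray) -> float:
    """log|det(I - A)|; raises SingularModelError at (numerical) singularity."""
    A = np.asarray(A, dtype=float)
    sign, ld = np.linalg.slogdet(np.eye(A.shape[0]) - A)
    if sign == 0 or not np.isfinite(ld):
        raise SingularModelError("det(I - A) = 0")
    return float(ld)


def residual_cross_products(
    A: np.ndarray, B: np.ndarray, S: SummaryStatistics
) -> np.ndarray:
    """R = average cross-product matrix of the structural residuals
    e = (I-A) y - B x, computed from summary statistics."""
    M = np.eye(A.shape[0]) - A
    MSyx = M @ S.Syx
    return M @ S.Syy @ M.T - MSyx @ B.T - B @ MSyx.T + B @ S.Sxx @ B.T


def _gauss_ll(logdet: float, Rdiag: np.ndarray, sigma2: np.ndarray, n: int) -> float:
    return float(
        n * logdet
        - 0.5 * n * np.sum(np.log(2.0 * np.pi * sigma2))
        - 0.5 * n * np.sum(Rdiag / sigma2)
    )


def log_likelihood(theta: StructuralParameters, S: SummaryStatistics) -> float:
    """Exact log-likelihood from complete summary statistics.

    Equals the sum over observations of log N((I-A) y_t - B x_t; 0, Sigma)
    plus n log|det(I-A)|, for any (X, Y) with these cross-moments.
    """
    if S.missing_offdiag:
        raise ValueError(
            "Syy has unavailable off-diagonals; use log_likelihood_regression_path"
        )
    ld = log_abs_det(theta.A)
    Rdiag = np.diag(residual_cross_products(theta.A, theta.B, S))
    return _gauss_ll(ld, Rdiag, theta.sigma2, S.n)


def impute_syy(theta: StructuralParameters, S: SummaryStatistics) -> np.ndarray:
    """Fill unavailable Syy cells with the model-implied covariance
    [(I-A)^-1 (B Sxx B' + diag(sigma2)) (I-A)^-T] at the given theta."""
    Minv = np.linalg.inv(np.eye(theta.p) - theta.A)
    implied = Minv @ (theta.B @ S.Sxx @ theta.B.T + np.diag(theta.sigma2)) @ Minv.T
    Syy = np.asarray(S.Syy, dtype=float).copy()
    mask = np.isnan(Syy)
    Syy[mask] = implied[mask]
    return Syy


def log_likelihood_regression_path(
    theta: StructuralParameters, S_partial: SummaryStatistics
) -> float:
    """Approximate log-likelihood when Syy off-diagonals were never observed.

    The missing cells are replaced by the model-implied covariance at the
    current theta (a self-consistent plug-in, recomputed at every
    evaluation) and the exact formula is applied to the completed matrix.
    Reduces to :func:`log_likelihood` whenever no missing cell enters the
    residual diagonal — in particular at A = 0, where R_ii involves only
    row i of Syy.
    """
    Syy = impute_syy(theta, S_partial)
    S_full = SummaryStatistics(
        Syy=Syy, Syx=S_partial.Syx, Sxx=S_partial.Sxx, n=S_partial.n
    )
    return log_likelihood(theta, S_full)


class DeterminantWorkspace:
    """Running log|det(I - A)| and (I - A)^-1 under single-entry updates.

    The workspace owns its copy of ``A``.  A proposed change
    A[i, j] += delta multiplies det(I - A) by r = 1 - delta * inv[j, i]
    (matrix-determinant lemma); on acceptance the inverse is refreshed by
    Sherman–Morrison.  Every ``refresh_interval`` accepted updates (default
    500) both quantities are recomputed from scratch to bound drift.
    """

    def __init__(self, A: np.ndarray, refresh_interval: int = 500):
        self.A = np.array(A, dtype=float, copy=True)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError("A must be square")
        self.refresh_interval = int(refresh_interval)
        self._accepted_since_refresh = 0
        self._refresh()

    def _refresh(self) -> None:
        M = np.eye(self.A.shape[0]) - self.A
        sign, ld = np.linalg.slogdet(M)
        if sign == 0 or not np.isfinite(ld):
            raise SingularModelError("det(I - A) = 0")
        self.logabsdet = float(ld)
        self.inv = np.linalg.inv(M)
        self._accepted_since_refresh = 0

    def det_ratio(self, i: int, j: int, delta: float) -> float:
        """det(I - A') / det(I - A) for the proposal A[i, j] += delta."""
        return 1.0 - delta * self.inv[j, i]

    def is_valid(self, i: int, j: int, delta: float) -> bool:
        return abs(self.det_ratio(i, j, delta)) > SINGULARITY_TOL

    def apply(self, i: int, j: int, delta: float) -> "DeterminantWorkspace":
        """Commit A[i, j] += delta, updating determinant and inverse in O(p^2)."""
        if delta == 0.0:
            return self
        r = self.det_ratio(i, j, delta)
        if abs(r) <= SINGULARITY_TOL:
            raise SingularModelError(
                f"update A[{i},{j}] += {delta} makes det(I - A) vanish"
            )
        self.A[i, j] += delta
        self._accepted_since_refresh += 1
        if self._accepted_since_refresh >= self.refresh_interval:
            self._refresh()
            return self
        self.logabsdet += float(np.log(abs(r)))
        self.inv = self.inv + (delta / r) * np.outer(self.inv[:, i], self.inv[j, :])
        return self


def rank_one_logdet_update(
    workspace: DeterminantWorkspace, i: int, j: int, delta: float
) -> DeterminantWorkspace:
    """Functional alias for :meth:`DeterminantWorkspace.apply`."""
    return workspace.apply(i, j, delta)
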