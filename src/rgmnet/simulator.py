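"""Synthetic data generator for the reciprocal graphical model.

The generator mirrors the benchmark design used to validate the method:
a p-node network whose off-diagonal effects A are placed uniformly at a
chosen sparsity with magnitudes +/- effect_size, instrument effects
B = identity (one private standard-normal instrument per response), and
error variances calibrated so that each response's private instrument
explains a chosen fraction of its structural variance.  Default design:
p = 5, 25% sparsity, effects of magnitude 0.1, n = 10 000, variance
explained 10%, normal errors.  Student-t and Laplace error families are
available for normality-sensitivity studies and are rescaled to match the
calibrated variance exactly, so only the shape changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data_model import (
    IndividualData,
    InstrumentAssignment,
    RegressionSummaries,
    SummaryStatistics,
    compute_summary_statistics,
)

__all__ = [
    "SimulationDesign",
    "SimulatedTruth",
    "sample_network_structure",
    "calibrate_noise_sd",
    "simulate_dataset",
    "simulate",
    "bundle_input_formats",
]

_ERROR_FAMILIES = ("normal", "student_t", "laplace")


@dataclass(frozen=True)
class SimulationDesign:
    """Design knobs for one synthetic scenario.

    sparsity is the fraction of the p(p-1) off-diagonal A cells that are
    nonzero; effect_size the common magnitude of those entries (signs
    random); variance_explained the fraction of each response's structural
    variance Var(b x + e) attributable to its private instrument.
    """

    p: int = 5
    sparsity: float = 0.25
    effect_size: float = 0.1
    n: int = 10000
    variance_explained: float = 0.10
    error_family: str = "normal"
    t_df: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.p < 2:
            raise ValueError("p must be >= 2")
        if not (0 < self.sparsity <= 1):
            raise ValueError("sparsity must lie in (0, 1]")
        if not (0 < self.variance_explained < 1):
            raise ValueError("variance_explained must lie in (0, 1)")
        if self.error_family not in _ERROR_FAMILIES:
            raise ValueError(f"error_family must be one of {_ERROR_FAMILIES}")
        if self.error_family == "student_t" and self.t_df <= 2:
            raise ValueError("student_t errors need df > 2 for a finite variance")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass(frozen=True)
class SimulatedTruth:
    """Ground-truth parameters plus the generated individual-level data."""

    A_true: np.ndarray
    B_true: np.ndarray
    Sigma_true: np.ndarray  # error variances, length p
    gamma_true: np.ndarray
    D: InstrumentAssignment
    data: IndividualData
    design: SimulationDesign


def sample_network_structure(
    design: SimulationDesign, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (A_true, gamma_true): exactly round(sparsity * p(p-1)) nonzero
    off-diagonal cells at uniform positions, each +/- effect_size with an
    independent random sign.  Structures with det(I - A) = 0 are redrawn."""
    if rng is None:
        rng = np.random.default_rng(design.seed)
    p = design.p
    n_cells = p * (p - 1)
    n_edges = int(round(design.sparsity * n_cells))
    offdiag = [(i, j) for i in range(p) for j in range(p) if i != j]
    while True:
        A = np.zeros((p, p))
        gamma = np.zeros((p, p), dtype=np.int8)
        chosen = rng.choice(n_cells, size=n_edges, replace=False)
        signs = rng.choice((-1.0, 1.0), size=n_edges)
        for idx, s in zip(chosen, signs):
            i, j = offdiag[idx]
            A[i, j] = s * design.effect_size
            gamma[i, j] = 1
        if abs(np.linalg.det(np.eye(p) - A)) > 1e-12:
            return A, gamma


def calibrate_noise_sd(design: SimulationDesign) -> np.ndarray:
    """Error variances achieving the target variance explained.

    With B = I and unit-variance instruments, the structural equation for
    response i is y_i = (Ay)_i + x_i + e_i; the private instrument explains
    VE = 1 / (1 + sigma^2) of Var(x_i + e_i), so sigma^2 = (1 - VE)/VE for
    every response (network propagation is not included in the
    calibration).
    """
    ve = design.variance_explained
    sigma2 = (1.0 - ve) / ve
    return np.full(design.p, sigma2)


def _draw_errors(
    rng: np.random.Generator, n: int, p: int, sigma2: np.ndarray, design: SimulationDesign
) -> np.ndarray:
    """n x p error draws with exact target variances; non-normal families
    are rescaled so the variance matches sigma2 and only the shape differs."""
    sd = np.sqrt(sigma2)
    if design.error_family == "normal":
        return rng.standard_normal((n, p)) * sd
    if design.error_family == "student_t":
        df = design.t_df
        scale = math.sqrt((df - 2.0) / df)  # Var(t_df) = df/(df-2)
        return rng.standard_t(df, size=(n, p)) * scale * sd
    # laplace: Var = 2 b^2
    return rng.laplace(0.0, 1.0 / math.sqrt(2.0), size=(n, p)) * sd


def simulate_dataset(
    A_true: np.ndarray,
    B_true: np.ndarray,
    Sigma_true: np.ndarray,
    design: SimulationDesign,
    rng: np.random.Generator | None = None,
) -> IndividualData:
    """Generate (X, Y): x_t iid standard normal, e_t from the design's
    error family, y_t = (I - A)^-1 (B x_t + e_t)."""
    if rng is None:
        rng = np.random.default_rng(design.seed)
    p = A_true.shape[0]
    k = B_true.shape[1]
    X = rng.standard_normal((design.n, k))
    E = _draw_errors(rng, design.n, p, np.asarray(Sigma_true, dtype=float), design)
    Minv = np.linalg.inv(np.eye(p) - A_true)
    Y = (X @ B_true.T + E) @ Minv.T
    return IndividualData(X=X, Y=Y)


def simulate(design: SimulationDesign) -> SimulatedTruth:
    """Full scenario draw: network structure, calibrated noise, identity
    instrument pattern (instrument j private to response j), and data."""
    rng = np.random.default_rng(design.seed)
    A, gamma = sample_network_structure(design, rng)
    B = np.eye(design.p)
    sigma2 = calibrate_noise_sd(design)
    data = simulate_dataset(A, B, sigma2, design, rng)
    D = InstrumentAssignment(np.eye(design.p, dtype=int))
    return SimulatedTruth(
        A_true=A, B_true=B, Sigma_true=sigma2, gamma_true=gamma,
        D=D, data=data, design=design,
    )


def bundle_input_formats(
    data: IndividualData, D: InstrumentAssignment | np.ndarray
) -> dict[str, object]:
    """The same dataset in all three input representations.

    ``exact_summary`` is the sufficient-statistics reduction of
    ``individual``; ``regression_summary`` fits one no-intercept simple
    regression per D = 1 cell (coefficient Syx_ij / Sxx_jj, mean square
    error with denominator n) so the reconstruction identities hold
    exactly.
    """
    if not isinstance(D, InstrumentAssignment):
        D = InstrumentAssignment(D)
    S = compute_summary_statistics(data)
    mask = D.D == 1
    sxx_diag = np.diag(S.Sxx)
    Beta = np.where(mask, S.Syx / sxx_diag[None, :], 0.0)
    SigmaHat = np.where(
        mask, np.diag(S.Syy)[:, None] - Beta**2 * sxx_diag[None, :], 1.0
    )
    reg = RegressionSummaries(Beta=Beta, SigmaHat=SigmaHat, Sxx=S.Sxx, n=data.n)
    return {"individual": data, "exact_summary": S, "regression_summary": reg}
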