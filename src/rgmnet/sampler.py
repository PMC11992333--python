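"""Metropolis-within-Gibbs sampler for the reciprocal graphical model.

Each sweep updates, in a fixed systematic order: every off-diagonal entry
of A (random-walk Metropolis with a rank-one determinant update), the
edge-inclusion indicators gamma (or the thresholds under the Threshold
prior), the slab variances tau2, the edge probability rho, every D = 1
entry of B, then phi / eta2 / psi, and finally the error variances sigma2.
All conditionally conjugate blocks (gamma, tau2, eta2, rho, psi, sigma2)
are Gibbs draws from closed-form full conditionals; A and B entries and
the thresholds move by Metropolis–Hastings.

Two graph priors are supported.  Under the continuous spike-and-slab
prior an entry a_ij is N(0, tau2_ij) when its indicator gamma_ij = 1 and
N(0, nu1 * tau2_ij) (a narrow spike) otherwise, with gamma_ij ~
Bernoulli(rho).  Under the Threshold prior a latent unthresholded matrix
A0 carries N(0, tau2) effects and the observed effect is
A0_ij * 1(|A0_ij| > tA), with tA uniform on (0, tMaxA); the indicator
gamma is then a deterministic function of (A0, tA).  The same structure
applies to B with (phi, eta2, psi, nu2, tB).

Individual-level input is reduced to its exact summary statistics before
the first random draw, so fits from the two representations are
bit-identical under equal seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import (
    IndividualData,
    InstrumentAssignment,
    RegressionSummaries,
    SummaryStatistics,
    compute_summary_statistics,
    reconstruct_summary,
    validate_instrument_assignment,
)
from .likelihood import (
    SINGULARITY_TOL,
    DeterminantWorkspace,
    StructuralParameters,
    impute_syy,
    log_abs_det,
    residual_cross_products,
)

__all__ = [
    "PriorHyperparameters",
    "SamplerConfig",
    "LatentState",
    "PosteriorResult",
    "init_state",
    "run_mcmc",
    "spike_slab_inclusion_probability",
    "slab_variance_posterior",
    "edge_probability_posterior",
    "noise_variance_posterior",
    "update_inclusion_gamma",
    "update_slab_variance",
    "update_edge_probability",
    "update_noise_variance",
    "update_effect_entry_A",
    "update_effect_entry_B",
    "update_threshold",
]


@dataclass(frozen=True)
class PriorHyperparameters:
    """Prior and proposal constants; the published names are kept.

    aRho/bRho and aPsi/bPsi parameterize Beta priors on the edge
    probabilities rho (among responses) and psi (instrument edges).
    nu1/nu2 in (0, 1) shrink the slab variance to form the spike.
    aSigma/bSigma, aTau/bTau, aEta/bEta parameterize inverse-gamma priors
    on the error variances and the slab variances.  PropVarA/PropVarB are
    the random-walk proposal variances; tMaxA/tMaxB bound the uniform
    threshold priors.

    The slab-variance prior defaults to IG(2, 2), a proper prior with unit
    mean whose marginal effect distribution is a t with 4 degrees of
    freedom; paired with the spike ratio nu = 1e-4 it separates effects of
    typical MR magnitude (~0.1) from noise.  A heavier-tailed choice such
    as IG(0.5, 0.5) makes the marginal spike Cauchy-like, which can absorb
    genuine small effects and defeat edge selection.
    """

    aRho: float = 1.0
    bRho: float = 1.0
    aPsi: float = 1.0
    bPsi: float = 1.0
    nu1: float = 1e-4
    nu2: float = 1e-4
    aSigma: float = 0.01
    bSigma: float = 0.01
    aTau: float = 2.0
    bTau: float = 2.0
    aEta: float = 2.0
    bEta: float = 2.0
    PropVarA: float = 0.01
    PropVarB: float = 0.01
    tMaxA: float = 1.0
    tMaxB: float = 1.0

    def __post_init__(self):
        for name in ("aRho", "bRho", "aPsi", "bPsi", "aSigma", "bSigma",
                     "aTau", "bTau", "aEta", "bEta", "PropVarA", "PropVarB",
                     "tMaxA", "tMaxB"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.nu1 < 1 and 0 < self.nu2 < 1):
            raise ValueError("nu1 and nu2 must lie in (0, 1)")


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC run controls.  Defaults: 10 000 iterations, 2000 burn-in,
    thinning 1, spike-and-slab prior."""

    nIter: int = 10000
    nBurnin: int = 2000
    Thin: int = 1
    prior: str = "SpikeSlab"  # or "Threshold"
    seed: int = 0
    hyper: PriorHyperparameters = field(default_factory=PriorHyperparameters)
    store_effect_samples: bool = False

    def __post_init__(self):
        if self.nBurnin >= self.nIter:
            raise ValueError("nBurnin must be smaller than nIter")
        if self.Thin < 1:
            raise ValueError("Thin must be >= 1")
        if self.prior not in ("SpikeSlab", "Threshold"):
            raise ValueError("prior must be 'SpikeSlab' or 'Threshold'")

    @property
    def n_retained(self) -> int:
        return (self.nIter - self.nBurnin) // self.Thin


@dataclass
class LatentState:
    """All sampled quantities at one MCMC iteration."""

    A: np.ndarray
    B: np.ndarray
    A0: np.ndarray
    B0: np.ndarray
    gamma: np.ndarray
    phi: np.ndarray
    tau2: np.ndarray
    eta2: np.ndarray
    rho: float
    psi: float
    sigma2: np.ndarray
    tA: float
    tB: float

    @property
    def theta(self) -> StructuralParameters:
        return StructuralParameters(A=self.A, B=self.B, sigma2=self.sigma2)


@dataclass
class PosteriorResult:
    """Posterior means, reported graphs, diagnostics and retained samples.

    All *Est fields are posterior means; zAEst/zBEst threshold the
    inclusion-probability matrices GammaEst/PhiEst at 0.5 (strictly
    greater).  Accpt* are acceptance fractions over all iterations
    including burn-in.  LLPst holds the retained log-likelihood samples
    and GammaPst the retained gamma draws (input to motif scoring).
    """

    AEst: np.ndarray
    BEst: np.ndarray
    A0Est: np.ndarray
    B0Est: np.ndarray
    GammaEst: np.ndarray
    PhiEst: np.ndarray
    TauEst: np.ndarray
    EtaEst: np.ndarray
    SigmaEst: np.ndarray
    RhoEst: float
    PsiEst: float
    tAEst: float
    tBEst: float
    zAEst: np.ndarray
    zBEst: np.ndarray
    AccptA: float
    AccptB: float
    AccpttA: float
    AccpttB: float
    LLPst: np.ndarray
    GammaPst: np.ndarray
    Graph: list
    seed: int | None = None
    APst: np.ndarray | None = None
    BPst: np.ndarray | None = None
    Tau2Pst: np.ndarray | None = None


# ---------------------------------------------------------------------------
# closed-form full-conditional pieces (shared by the sweep and by tests)
# ---------------------------------------------------------------------------


def spike_slab_inclusion_probability(a, slab_var, rho, nu):
    """P(gamma = 1 | a, tau2, rho) for the continuous spike-and-slab prior.

    w = rho N(a; 0, tau2) / [rho N(a; 0, tau2) + (1-rho) N(a; 0, nu tau2)];
    the likelihood cancels because the effect itself is unchanged.
    Vectorizes elementwise.
    """
    a = np.asarray(a, dtype=float)
    slab_var = np.asarray(slab_var, dtype=float)
    log_slab = -0.5 * np.log(2.0 * np.pi * slab_var) - a**2 / (2.0 * slab_var)
    log_spike = -0.5 * np.log(2.0 * np.pi * nu * slab_var) - a**2 / (2.0 * nu * slab_var)
    m = np.maximum(log_slab, log_spike)
    num = rho * np.exp(log_slab - m)
    den = num + (1.0 - rho) * np.exp(log_spike - m)
    return num / den


def slab_variance_posterior(a, included, a0, b0, nu):
    """Inverse-gamma full-conditional (shape, rate) for a slab variance:
    tau2 ~ InvGamma(a0 + 1/2, b0 + a^2/(2c)), c = 1 if included else nu."""
    a = np.asarray(a, dtype=float)
    c = np.where(np.asarray(included) == 1, 1.0, nu)
    shape = a0 + 0.5
    rate = b0 + a**2 / (2.0 * c)
    return np.broadcast_to(np.asarray(shape, dtype=float), rate.shape).copy(), rate


def edge_probability_posterior(n_on: int, n_slots: int, a0: float, b0: float):
    """Beta full-conditional (alpha, beta) for an edge probability."""
    return a0 + n_on, b0 + n_slots - n_on


def noise_variance_posterior(n: int, Rii, aSigma: float, bSigma: float):
    """Inverse-gamma full-conditional (shape, rate) for sigma2_i:
    InvGamma(aSigma + n/2, bSigma + n R_ii / 2)."""
    Rii = np.asarray(Rii, dtype=float)
    if (Rii < -1e-10).any():
        raise RuntimeError("negative residual cross-product: internal algebra error")
    Rii = np.clip(Rii, 0.0, None)
    return aSigma + n / 2.0, bSigma + n * Rii / 2.0


def _invgamma_draw(rng: np.random.Generator, shape, rate):
    g = rng.gamma(np.asarray(shape, dtype=float), 1.0 / np.asarray(rate, dtype=float))
    # tiny-shape draws can underflow to 0; keep the reciprocal finite
    return 1.0 / np.maximum(g, np.finfo(float).tiny)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def init_state(
    S: SummaryStatistics, D: InstrumentAssignment, config: SamplerConfig
) -> LatentState:
    """Deterministic starting point: empty graph (A = 0), B = 0 on its
    support, unit slab variances, prior-mean edge probabilities, error
    variances from the Syy diagonal, thresholds at mid-support."""
    h = config.hyper
    p, k = D.p, D.k
    syy_diag = np.diag(np.asarray(S.Syy, dtype=float)).copy()
    sigma2 = np.where(np.isfinite(syy_diag) & (syy_diag > 0), syy_diag, 1.0)
    return LatentState(
        A=np.zeros((p, p)),
        B=np.zeros((p, k)),
        A0=np.zeros((p, p)),
        B0=np.zeros((p, k)),
        gamma=np.zeros((p, p), dtype=np.int8),
        phi=D.D.astype(np.int8).copy(),
        tau2=np.ones((p, p)),
        eta2=np.ones((p, k)),
        rho=h.aRho / (h.aRho + h.bRho),
        psi=h.aPsi / (h.aPsi + h.bPsi),
        sigma2=sigma2,
        tA=h.tMaxA / 2.0,
        tB=h.tMaxB / 2.0,
    )


# ---------------------------------------------------------------------------
# scalar update operations (the sweep uses the same formulas vectorized)
# ---------------------------------------------------------------------------


def update_inclusion_gamma(
    state: LatentState, i: int, j: int, hyper: PriorHyperparameters,
    rng: np.random.Generator,
) -> LatentState:
    """Gibbs draw of a single gamma_ij from its Bernoulli full conditional."""
    if i == j:
        raise ValueError("gamma diagonal is fixed at 0")
    w = float(spike_slab_inclusion_probability(
        state.A[i, j], state.tau2[i, j], state.rho, hyper.nu1))
    state.gamma[i, j] = 1 if rng.random() < w else 0
    return state


def update_slab_variance(
    state: LatentState, i: int, j: int, hyper: PriorHyperparameters,
    rng: np.random.Generator, which: str = "A",
) -> LatentState:
    """Gibbs draw of a single slab variance tau2_ij (or eta2_ij)."""
    if which == "A":
        shape, rate = slab_variance_posterior(
            state.A[i, j], state.gamma[i, j], hyper.aTau, hyper.bTau, hyper.nu1)
        state.tau2[i, j] = float(_invgamma_draw(rng, shape, rate))
    else:
        shape, rate = slab_variance_posterior(
            state.B[i, j], state.phi[i, j], hyper.aEta, hyper.bEta, hyper.nu2)
        state.eta2[i, j] = float(_invgamma_draw(rng, shape, rate))
    return state


def update_edge_probability(
    state: LatentState, hyper: PriorHyperparameters, rng: np.random.Generator,
    D: InstrumentAssignment | None = None,
) -> LatentState:
    """Gibbs draws of rho and psi from their Beta full conditionals."""
    p = state.A.shape[0]
    n_gamma = int(state.gamma.sum())  # diagonal fixed at 0
    a, b = edge_probability_posterior(n_gamma, p * (p - 1), hyper.aRho, hyper.bRho)
    state.rho = float(rng.beta(a, b))
    if D is not None:
        n_slots = int(D.D.sum())
        n_phi = int(state.phi[D.D == 1].sum())
        a, b = edge_probability_posterior(n_phi, n_slots, hyper.aPsi, hyper.bPsi)
        state.psi = float(rng.beta(a, b))
    return state


def update_noise_variance(
    state: LatentState, S: SummaryStatistics, hyper: PriorHyperparameters,
    rng: np.random.Generator,
) -> LatentState:
    """Gibbs draw of all sigma2_i from the inverse-gamma full conditional."""
    if S.missing_offdiag:
        anchor = StructuralParameters(
            A=np.zeros_like(state.A), B=state.B, sigma2=state.sigma2)
        S = SummaryStatistics(Syy=impute_syy(anchor, S), Syx=S.Syx,
                              Sxx=S.Sxx, n=S.n)
    Rdiag = np.diag(residual_cross_products(state.A, state.B, S))
    shape, rate = noise_variance_posterior(S.n, Rdiag, hyper.aSigma, hyper.bSigma)
    state.sigma2 = _invgamma_draw(rng, np.full_like(rate, shape), rate)
    return state


# ---------------------------------------------------------------------------
# the sweep engine
# ---------------------------------------------------------------------------


class _FitContext:
    """Shared likelihood state for one MCMC run: summary matrices, the
    determinant workspace (which owns A), and the cached residual diagonal.

    On the regression-summary path the unavailable Syy off-diagonals are
    completed with the instrument-driven covariance (B Sxx B' + diag
    sigma2) at the current (B, sigma2) — the model-implied covariance with
    the network terms omitted (``Syy_work``).  The completion is refreshed
    *between* sweeps, never inside a Metropolis comparison, and it
    deliberately does not depend on A: a completion that tracks A lets
    every proposed edge manufacture the cross-covariance that justifies
    it, cancelling the residual penalty so the determinant reward drives
    the chain to a dense graph with diverging error variances.
    """

    def __init__(self, S: SummaryStatistics, D: InstrumentAssignment,
                 state: LatentState, refresh_interval: int = 500):
        self.S = S
        self.D = D
        self.n = S.n
        self.missing = S.missing_offdiag
        self.ws = DeterminantWorkspace(state.A, refresh_interval=refresh_interval)
        state.A = self.ws.A  # share storage: workspace commits are visible
        self.state = state
        self.Syy_work = S.Syy
        self.refresh_imputation()
        self.refresh_rdiag()

    # -- likelihood plumbing ------------------------------------------------

    def refresh_imputation(self) -> None:
        if self.missing:
            st = self.state
            anchor = StructuralParameters(
                A=np.zeros_like(st.A), B=st.B, sigma2=st.sigma2)
            self.Syy_work = impute_syy(anchor, self.S)

    def rdiag(self, A=None, B=None) -> np.ndarray:
        st = self.state
        A = st.A if A is None else A
        B = st.B if B is None else B
        M = np.eye(A.shape[0]) - A
        MSyx = M @ self.S.Syx
        return (
            np.einsum("ij,ij->i", M @ self.Syy_work, M)
            - 2.0 * np.einsum("ij,ij->i", MSyx, B)
            + np.einsum("ij,ij->i", B @ self.S.Sxx, B)
        )

    def refresh_rdiag(self) -> None:
        self.Rdiag = self.rdiag()

    def loglik(self) -> float:
        st = self.state
        n = self.n
        if n == 0:
            return 0.0
        return float(
            n * self.ws.logabsdet
            - 0.5 * n * np.sum(np.log(2.0 * np.pi * st.sigma2))
            - 0.5 * n * np.sum(self.Rdiag / st.sigma2)
        )

    def loglik_at(self, A: np.ndarray, B: np.ndarray) -> float:
        """Full evaluation at an arbitrary (A, B) with the current sigma2
        and the current Syy completion; raises SingularModelError when
        det(I - A) = 0."""
        st = self.state
        ld = log_abs_det(A)
        n = self.n
        if n == 0:
            return 0.0
        Rdiag = self.rdiag(A=A, B=B)
        return float(
            n * ld
            - 0.5 * n * np.sum(np.log(2.0 * np.pi * st.sigma2))
            - 0.5 * n * np.sum(Rdiag / st.sigma2)
        )


def _row_residual_exact(ctx: _FitContext, i: int, m: np.ndarray,
                        b: np.ndarray) -> float:
    """R_ii for structural row m = (I - A)[i, :], instrument row b."""
    Syy = ctx.Syy_work
    return float(m @ Syy @ m - 2.0 * (m @ (ctx.S.Syx @ b)) + b @ ctx.S.Sxx @ b)


def update_effect_entry_A(
    state: LatentState, ctx: _FitContext, i: int, j: int,
    hyper: PriorHyperparameters, rng: np.random.Generator,
) -> bool:
    """One random-walk Metropolis update of A[i, j] under the
    spike-and-slab prior.  Returns True on acceptance."""
    if i == j:
        raise ValueError("A diagonal is fixed at 0")
    a = state.A[i, j]
    delta = rng.normal(0.0, math.sqrt(hyper.PropVarA))
    u = rng.random()
    r = ctx.ws.det_ratio(i, j, delta)
    if abs(r) <= SINGULARITY_TOL:
        return False
    a_new = a + delta
    c = state.tau2[i, j] * (1.0 if state.gamma[i, j] else hyper.nu1)
    dlp = (a * a - a_new * a_new) / (2.0 * c)
    n = ctx.n
    if n == 0:
        dll, rii_new = 0.0, None
    else:
        m = -state.A[i, :].copy()
        m[i] += 1.0
        m[j] -= delta
        rii_new = _row_residual_exact(ctx, i, m, state.B[i])
        dll = n * math.log(abs(r)) - 0.5 * n * (rii_new - ctx.Rdiag[i]) / state.sigma2[i]
    if math.log(u) < dll + dlp:
        ctx.ws.apply(i, j, delta)
        if rii_new is not None:
            ctx.Rdiag[i] = rii_new
        return True
    return False


def update_effect_entry_B(
    state: LatentState, ctx: _FitContext, i: int, j: int,
    hyper: PriorHyperparameters, rng: np.random.Generator,
) -> bool:
    """One random-walk Metropolis update of B[i, j] (requires D[i, j] = 1);
    the determinant term is untouched because B does not enter I - A."""
    if ctx.D.D[i, j] != 1:
        raise ValueError("B entries outside the instrument-assignment support stay 0")
    b_old = state.B[i, j]
    delta = rng.normal(0.0, math.sqrt(hyper.PropVarB))
    u = rng.random()
    b_new = b_old + delta
    c = state.eta2[i, j] * (1.0 if state.phi[i, j] else hyper.nu2)
    dlp = (b_old * b_old - b_new * b_new) / (2.0 * c)
    n = ctx.n
    if n == 0:
        dll, rii_new = 0.0, None
    else:
        m = -state.A[i, :].copy()
        m[i] += 1.0
        brow = state.B[i].copy()
        brow[j] = b_new
        rii_new = _row_residual_exact(ctx, i, m, brow)
        dll = -0.5 * n * (rii_new - ctx.Rdiag[i]) / state.sigma2[i]
    if math.log(u) < dll + dlp:
        state.B[i, j] = b_new
        if rii_new is not None:
            ctx.Rdiag[i] = rii_new
        return True
    return False


def _reflect(t: float, t_max: float) -> float:
    """Fold a real proposal back into (0, t_max) by reflection at the bounds."""
    period = 2.0 * t_max
    t = abs(t) % period
    return period - t if t > t_max else t


def update_threshold(
    state: LatentState, ctx: _FitContext, which: str,
    hyper: PriorHyperparameters, rng: np.random.Generator,
) -> bool:
    """Metropolis update of a hard threshold (tA or tB) under the
    Threshold prior; the effective effect matrix and its indicator are
    recomputed from the latent matrix."""
    if which == "A":
        t_old, t_max, pv = state.tA, hyper.tMaxA, hyper.PropVarA
        latent = state.A0
    else:
        t_old, t_max, pv = state.tB, hyper.tMaxB, hyper.PropVarB
        latent = state.B0
    t_prop = _reflect(t_old + rng.normal(0.0, math.sqrt(pv)), t_max)
    u = rng.random()
    ind = (np.abs(latent) > t_prop).astype(np.int8)
    if which == "A":
        np.fill_diagonal(ind, 0)
        A_prop = latent * ind
        try:
            ll_prop = ctx.loglik_at(A_prop, state.B)
        except Exception:
            return False
        dll = ll_prop - ctx.loglik()
        if math.log(u) < dll:  # uniform prior on t: likelihood-only ratio
            state.tA = t_prop
            state.A[...] = A_prop
            state.gamma = ind
            ctx.ws._refresh()
            ctx.refresh_rdiag()
            return True
        return False
    ind = ind * ctx.D.D
    B_prop = latent * ind
    dll = ctx.loglik_at(state.A, B_prop) - ctx.loglik()
    if math.log(u) < dll:
        state.tB = t_prop
        state.B = B_prop
        state.phi = ind
        ctx.refresh_rdiag()
        return True
    return False


def _update_latent_entry_threshold(
    state: LatentState, ctx: _FitContext, i: int, j: int, which: str,
    hyper: PriorHyperparameters, rng: np.random.Generator,
) -> bool:
    """Random-walk update of one latent entry (A0 or B0) under the
    Threshold prior; the effective effect changes only when the proposal
    crosses the threshold."""
    if which == "A":
        latent, t, pv = state.A0, state.tA, hyper.PropVarA
        tau2 = state.tau2[i, j]
    else:
        latent, t, pv = state.B0, state.tB, hyper.PropVarB
        tau2 = state.eta2[i, j]
    x = latent[i, j]
    x_new = x + rng.normal(0.0, math.sqrt(pv))
    u = rng.random()
    eff_old = x if abs(x) > t else 0.0
    eff_new = x_new if abs(x_new) > t else 0.0
    delta = eff_new - eff_old
    dlp = (x * x - x_new * x_new) / (2.0 * tau2)
    n = ctx.n
    if which == "A" and delta != 0.0:
        r = ctx.ws.det_ratio(i, j, delta)
        if abs(r) <= SINGULARITY_TOL:
            return False
        if n == 0:
            dll, rii_new = 0.0, None
        else:
            m = -state.A[i, :].copy()
            m[i] += 1.0
            m[j] -= delta
            rii_new = _row_residual_exact(ctx, i, m, state.B[i])
            dll = n * math.log(abs(r)) - 0.5 * n * (rii_new - ctx.Rdiag[i]) / state.sigma2[i]
    elif which == "B" and delta != 0.0:
        if n == 0:
            dll, rii_new = 0.0, None
        else:
            m = -state.A[i, :].copy()
            m[i] += 1.0
            brow = state.B[i].copy()
            brow[j] += delta
            rii_new = _row_residual_exact(ctx, i, m, brow)
            dll = -0.5 * n * (rii_new - ctx.Rdiag[i]) / state.sigma2[i]
    else:
        dll, rii_new = 0.0, None
    if math.log(u) < dll + dlp:
        latent[i, j] = x_new
        if which == "A":
            if delta != 0.0:
                ctx.ws.apply(i, j, delta)
            state.gamma[i, j] = 1 if eff_new != 0.0 else 0
        else:
            state.B[i, j] += delta
            state.phi[i, j] = 1 if eff_new != 0.0 else 0
        if delta != 0.0 and rii_new is not None:
            ctx.Rdiag[i] = rii_new
        return True
    return False


# ---------------------------------------------------------------------------
# main driver
# ---------------------------------------------------------------------------


def _infer_path(data) -> str:
    if isinstance(data, IndividualData):
        return "individual"
    if isinstance(data, SummaryStatistics):
        return "exact_summary"
    if isinstance(data, RegressionSummaries):
        return "regression_summary"
    raise TypeError(
        "data must be IndividualData, SummaryStatistics or RegressionSummaries"
    )


def run_mcmc(
    data: IndividualData | SummaryStatistics | RegressionSummaries,
    D: InstrumentAssignment | np.ndarray,
    config: SamplerConfig | None = None,
) -> PosteriorResult:
    """Fit the reciprocal graphical model by MCMC.

    ``data`` may be individual-level, exact-summary, or regression-summary
    input; all three reduce to a :class:`SummaryStatistics` bundle before
    the first random draw.  Identifiability of ``D`` is checked first: a
    missing private instrument raises on the regression-summary path and
    warns (the fit proceeds) on the other two.
    """
    if config is None:
        config = SamplerConfig()
    if not isinstance(D, InstrumentAssignment):
        D = InstrumentAssignment(D)
    path = _infer_path(data)
    validate_instrument_assignment(D, path).raise_or_warn()
    if path == "individual":
        S = compute_summary_statistics(data)
    elif path == "exact_summary":
        S = data
    else:
        S = reconstruct_summary(data, D)
    if (S.p, S.k) != (D.p, D.k):
        raise ValueError(
            f"summary dimensions {(S.p, S.k)} do not match D {(D.p, D.k)}"
        )

    h = config.hyper
    p, k = D.p, D.k
    rng = np.random.default_rng(config.seed)
    state = init_state(S, D, config)
    ctx = _FitContext(S, D, state)
    threshold = config.prior == "Threshold"

    offdiag = [(i, j) for i in range(p) for j in range(p) if i != j]
    support = [tuple(map(int, ij)) for ij in np.argwhere(D.D == 1)]
    d_mask = D.D == 1
    n_slots_B = len(support)

    acc_A = prop_A = acc_B = prop_B = 0
    acc_tA = prop_tA = acc_tB = prop_tB = 0

    nret = config.n_retained
    gamma_pst = np.empty((nret, p, p), dtype=np.int8)
    ll_pst = np.empty(nret)
    a_pst = np.empty((nret, p, p)) if config.store_effect_samples else None
    b_pst = np.empty((nret, p, k)) if config.store_effect_samples else None
    tau2_pst = np.empty((nret, p, p)) if config.store_effect_samples else None

    sums = {name: 0.0 for name in
            ("A", "B", "A0", "B0", "gamma", "phi", "tau2", "eta2",
             "sigma2", "rho", "psi", "tA", "tB")}
    kept = 0

    for it in range(1, config.nIter + 1):
        if ctx.missing:
            # new completion from the latest (A, B, sigma2); held fixed
            # through this sweep's Metropolis comparisons
            ctx.refresh_imputation()
            ctx.refresh_rdiag()
        # -- A block --------------------------------------------------------
        if threshold:
            for (i, j) in offdiag:
                acc_A += _update_latent_entry_threshold(state, ctx, i, j, "A", h, rng)
                prop_A += 1
            prop_tA += 1
            acc_tA += update_threshold(state, ctx, "A", h, rng)
        else:
            for (i, j) in offdiag:
                acc_A += update_effect_entry_A(state, ctx, i, j, h, rng)
                prop_A += 1
            # gamma | A, tau2, rho  (vectorized Bernoulli full conditional)
            w = spike_slab_inclusion_probability(state.A, state.tau2, state.rho, h.nu1)
            g = (rng.random((p, p)) < w).astype(np.int8)
            np.fill_diagonal(g, 0)
            state.gamma = g
        # tau2 | A(0), gamma
        src = state.A0 if threshold else state.A
        incl = np.ones((p, p), dtype=np.int8) if threshold else state.gamma
        shape, rate = slab_variance_posterior(src, incl, h.aTau, h.bTau, h.nu1)
        tau2 = _invgamma_draw(rng, shape, rate)
        np.fill_diagonal(tau2, 1.0)
        state.tau2 = tau2
        # rho | gamma
        a_post, b_post = edge_probability_posterior(
            int(state.gamma.sum()), p * (p - 1), h.aRho, h.bRho)
        state.rho = float(rng.beta(a_post, b_post))

        # -- B block --------------------------------------------------------
        if threshold:
            for (i, j) in support:
                acc_B += _update_latent_entry_threshold(state, ctx, i, j, "B", h, rng)
                prop_B += 1
            prop_tB += 1
            acc_tB += update_threshold(state, ctx, "B", h, rng)
        else:
            for (i, j) in support:
                acc_B += update_effect_entry_B(state, ctx, i, j, h, rng)
                prop_B += 1
            w = spike_slab_inclusion_probability(state.B, state.eta2, state.psi, h.nu2)
            ph = (rng.random((p, k)) < w).astype(np.int8)
            state.phi = np.where(d_mask, ph, 0).astype(np.int8)
        src = state.B0 if threshold else state.B
        incl = np.ones((p, k), dtype=np.int8) if threshold else state.phi
        shape, rate = slab_variance_posterior(src, incl, h.aEta, h.bEta, h.nu2)
        eta2 = _invgamma_draw(rng, shape, rate)
        state.eta2 = np.where(d_mask, eta2, 1.0)
        # psi | phi
        n_phi = int(state.phi[d_mask].sum())
        a_post, b_post = edge_probability_posterior(n_phi, n_slots_B, h.aPsi, h.bPsi)
        state.psi = float(rng.beta(a_post, b_post))

        # -- sigma2 ---------------------------------------------------------
        ctx.refresh_rdiag()  # fresh residuals: also kills incremental drift
        rd = np.clip(ctx.Rdiag, 0.0, None) if ctx.missing else ctx.Rdiag
        shape, rate = noise_variance_posterior(ctx.n, rd, h.aSigma, h.bSigma)
        state.sigma2 = _invgamma_draw(rng, np.full_like(rate, shape), rate)

        # -- retention ------------------------------------------------------
        if it > config.nBurnin and (it - config.nBurnin) % config.Thin == 0:
            if ctx.missing:
                ctx.refresh_imputation()  # completion at the retained state
                ctx.refresh_rdiag()
            gamma_pst[kept] = state.gamma
            ll_pst[kept] = ctx.loglik()
            if a_pst is not None:
                a_pst[kept] = state.A
                b_pst[kept] = state.B
                tau2_pst[kept] = state.tau2
            # flat-likelihood (n = 0) runs can draw astronomically large
            # variances from their diffuse priors; keep accumulation silent
            with np.errstate(over="ignore"):
                for name in ("A", "B", "tau2", "eta2", "sigma2"):
                    sums[name] += getattr(state, name)
            sums["A0"] += state.A0 if threshold else state.A
            sums["B0"] += state.B0 if threshold else state.B
            sums["gamma"] += state.gamma
            sums["phi"] += state.phi
            sums["rho"] += state.rho
            sums["psi"] += state.psi
            sums["tA"] += state.tA
            sums["tB"] += state.tB
            kept += 1

    assert kept == nret
    means = {name: val / nret for name, val in sums.items()}
    gamma_est = np.asarray(means["gamma"], dtype=float)
    phi_est = np.asarray(means["phi"], dtype=float)
    zA = (gamma_est > 0.5).astype(np.int8)
    np.fill_diagonal(zA, 0)
    zB = (phi_est > 0.5).astype(np.int8)
    a_est = np.asarray(means["A"])
    eff = a_est * zA
    graph = [
        (int(j), int(i), float(eff[i, j]), float(gamma_est[i, j]))
        for i in range(p) for j in range(p) if zA[i, j]
    ]  # A[i, j] is the effect of response j on response i

    nan = float("nan")
    return PosteriorResult(
        AEst=a_est,
        BEst=np.asarray(means["B"]),
        A0Est=np.asarray(means["A0"]),
        B0Est=np.asarray(means["B0"]),
        GammaEst=gamma_est,
        PhiEst=phi_est,
        TauEst=np.asarray(means["tau2"]),
        EtaEst=np.asarray(means["eta2"]),
        SigmaEst=np.asarray(means["sigma2"]),
        RhoEst=float(means["rho"]),
        PsiEst=float(means["psi"]),
        tAEst=float(means["tA"]) if threshold else nan,
        tBEst=float(means["tB"]) if threshold else nan,
        zAEst=zA,
        zBEst=zB,
        AccptA=acc_A / prop_A if prop_A else nan,
        AccptB=acc_B / prop_B if prop_B else nan,
        AccpttA=acc_tA / prop_tA if prop_tA else nan,
        AccpttB=acc_tB / prop_tB if prop_tB else nan,
        LLPst=ll_pst,
        GammaPst=gamma_pst,
        Graph=graph,
        seed=config.seed,
        APst=a_pst,
        BPst=b_pst,
        Tau2Pst=tau2_pst,
    )
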