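# Methods

## Model

`rgmnet` fits a Gaussian reciprocal graphical model to p response
variables (gene expression, protein levels, phenotypes) and k genetic
instruments (e.g. SNP dosages):

    y = A y + B x + e,        e ~ N(0, diag(sigma_1^2 .. sigma_p^2))

`A` (p x p, zero diagonal) collects the directed causal effects among
responses and may contain cycles — reciprocal causation and feedback
loops are first-class, which is what separates this model from DAG-based
multivariate Mendelian randomization.  `B` (p x k) collects instrument
effects and is supported on a user-declared binary assignment matrix `D`:
`D[i, j] = 1` means instrument j is allowed to affect response i, and
only those cells of `B` are estimated.  Solving the structural equations,

    y = (I - A)^{-1} (B x + e),

so the density of y given x carries the Jacobian |det(I - A)|.  For n
observations the log-likelihood is

    ll = n log|det(I - A)| - (n/2) sum_i log(2 pi sigma_i^2)
         - (n/2) sum_i R_ii / sigma_i^2,

    R = (I-A) Syy (I-A)' - (I-A) Syx B' - B Syx' (I-A)' + B Sxx B',

with `Syy = Y'Y/n`, `Syx = Y'X/n`, `Sxx = X'X/n`.  The data enter only
through these cross-moments, which is why individual-level input and
exact summary-level input give bit-identical fits: both are reduced to
the same `SummaryStatistics` before the first random draw.

We use |det|, not det: cyclic models can cross sign regions legitimately,
and only det(I - A) = 0 (within 1e-12) is invalid — such proposals are
rejected by the sampler.

### Identifiability

Each response must have at least one *private* instrument: a column of D
with a single 1, in that response's row.  Without it, causal directions
among responses are not identified.  A violation raises an error on the
regression-summary path (the reconstruction needs private instruments)
and a warning on the other two paths, where the fit proceeds and the
user is told directions may not be uniquely determined.

## Input formats

1. **Individual-level** — matrices X (n x k) and Y (n x p).
2. **Exact summary** — Syy, Syx, Sxx and n.  All matrices are
   cross-products over n (no mean-centering, matching the no-intercept
   structural model); the likelihood multiplies by n internally, which is
   the only place n is needed.
3. **Regression summaries** — per-cell no-intercept simple-regression
   coefficients `Beta[i, j]` and mean square errors `SigmaHat[i, j]`
   (denominator n), plus Sxx and n, for settings where two responses were
   never measured together.  The identities
   `Syx[i, j] = Beta[i, j] * Sxx[j, j]` and
   `Syy[i, i] = SigmaHat[i, j] + Beta[i, j]^2 * Sxx[j, j]` reconstruct the
   observable part exactly (a response with several private instruments
   averages its diagonal estimates); the Syy off-diagonals are genuinely
   unobserved.

### Completion of missing cross-covariances

`log_likelihood_regression_path` evaluates the likelihood with the
missing Syy cells replaced by the model-implied covariance
`[(I-A)^{-1}(B Sxx B' + diag sigma^2)(I-A)^{-T}]` at the supplied
parameters.  Inside the sampler a more conservative scheme is used: the
completion is the instrument-driven covariance `B Sxx B' + diag sigma^2`
at the current (B, sigma^2) — the model-implied value with network terms
omitted — refreshed between sweeps and held fixed across both sides of
every Metropolis comparison.  Two alternatives were rejected after
testing.  Re-imputing at the proposed parameters inside a Metropolis
ratio lets every proposed edge manufacture exactly the cross-covariance
that justifies it, and the fit returns the complete graph.  Refreshing
from the full current parameters (including A) between sweeps removes
that artifact but leaves the determinant term unopposed — the
A-dependent completion cancels the residual penalty — and the chain
drifts to a dense graph with diverging error variances.  With the
instrument-driven completion the path recovers B and sigma^2 accurately
and is conservative about A.

**Limitation.** Per-response regressions on private instruments carry
almost no information about response-response edges when D is (near)
diagonal: expect a near-empty response network from this path unless D
links instruments across responses.  This is a property of the input
format, not of the sampler — the "approximate solution" this path
promises is approximate precisely because the cross-information is
missing.

## Priors and defaults

**Spike-and-slab (default).**  Each off-diagonal effect has
`a_ij | gamma_ij, tau2_ij ~ N(0, c tau2_ij)` with `c = 1` for the slab
(`gamma_ij = 1`) and `c = nu1` for the continuous spike, and
`gamma_ij ~ Bernoulli(rho)`.  The same structure applies to the D = 1
cells of B with (phi, eta2, psi, nu2).  Hyperpriors and defaults:

| parameter | default | role |
|---|---|---|
| aRho, bRho / aPsi, bPsi | 1, 1 | Beta prior on edge probabilities rho, psi |
| nu1, nu2 | 1e-4 | spike/slab variance ratio |
| aTau, bTau / aEta, bEta | 2, 2 | IG prior on slab variances tau2, eta2 |
| aSigma, bSigma | 0.01, 0.01 | IG prior on error variances |
| PropVarA, PropVarB | 0.01 | random-walk proposal variances |
| tMaxA, tMaxB | 1.0 | threshold-prior support bound |

The slab-variance prior IG(2, 2) is proper with unit mean, making the
marginal slab a t distribution with 4 degrees of freedom; with
nu = 1e-4 (a standard stochastic-search variable-selection ratio) the
marginal spike has scale ~0.01 and effects of typical MR magnitude
(~0.1) land clearly in the slab.  Heavier-tailed hyperpriors such as
IG(0.5, 0.5) make the marginal spike Cauchy-like: it absorbs genuine
small effects, posterior inclusion probabilities stay near zero, and
edge selection fails even though effect ranking stays good — we verified
this analytically (posterior odds at the benchmark design ~0.3) and
empirically (30k-iteration runs).  All values are overridable.

**Threshold prior.**  A latent matrix A0 carries N(0, tau2) values; the
effective effect is `A0_ij 1(|A0_ij| > tA)` with tA uniform on
(0, tMaxA), and the inclusion indicator is the deterministic
`gamma = 1(|A0| > tA)` (same for B0, tB, tMaxB, phi).  Choose tMax near
the scale of plausible effects: an edge can only activate by a proposal
crossing the cutoff, so a bound far above the true effect magnitudes
strands the cutoff (lowering it would activate latent noise, which the
likelihood rejects) and the graph stays empty.  Entry-wise hard-threshold
samplers mix slowly near the cutoff in general; the spike-and-slab prior
is the recommended default.

## Sampler

One sweep updates, in fixed order: every off-diagonal A entry
(random-walk Metropolis), gamma (vectorized Bernoulli full conditional)
or the tA threshold, tau2 (inverse-gamma full conditional), rho (Beta
full conditional), every D = 1 entry of B, phi / eta2 / psi, and sigma2
(inverse-gamma full conditional, `InvGamma(aSigma + n/2, bSigma +
n R_ii/2)`).  Defaults: 10 000 iterations, 2000 burn-in, thinning 1, so
8000 retained draws.  Acceptance fractions are reported over all
iterations including burn-in, as tuning diagnostics.

A single-entry change of A is a rank-one change of I - A, so the
determinant and inverse are maintained by the matrix-determinant lemma
and the Sherman–Morrison formula (O(p^2) per accepted move instead of
O(p^3)); the workspace is rebuilt from scratch every 500 accepted
updates to bound floating-point drift, and the residual diagonal is
recomputed fresh at every sigma2 step for the same reason.  Only the
diagonal entry R_ii of the residual cross-product matrix changes when a
row-i quantity moves, so each Metropolis evaluation costs O(p + k) dot
products.

A single RNG stream is seeded once from the configuration; equal seeds
and inputs reproduce every output bit-for-bit, and both data
representations converge to the same code path before any draw, making
the individual/summary equivalence exact rather than statistical.

Initialization is deterministic: A = A0 = 0 (so det(I - A) = 1), B = 0,
gamma = 0, phi = D, tau2 = eta2 = 1, rho and psi at their prior means,
sigma_i^2 = Syy[i, i], thresholds at tMax/2.

## Reported outputs

All `*Est` fields are posterior means over retained draws.  The reported
graph thresholds the inclusion-probability matrices at 0.5 — strictly
greater, so exactly 0.5 stays out — with the diagonal forced to zero for
the response graph; `AEst * zAEst` (elementwise) gives effects with
negligible-probability edges zeroed.  `GammaPst`, the stack of retained
gamma draws, feeds motif scoring: the posterior probability of a motif
is the fraction of retained graphs containing all of its edges
(containment; exact adjacency match is available as `mode="exact"`).
`LLPst` holds retained log-likelihoods for convergence inspection.

## Synthetic-data generator

The generator reproduces the benchmark design used to validate the
method: p responses (default 5), exactly `round(sparsity * p(p-1))`
off-diagonal effects (default sparsity 25%) of magnitude `effect_size`
(default 0.1) with independent random signs (structures with
det(I - A) = 0 are redrawn), B = I with one private standard-normal
instrument per response, and error variances set so each instrument
explains a fraction VE (default 10%) of its response's structural
variance: sigma^2 = (1 - VE)/VE, i.e. sigma = 3 at VE = 10%.  The
calibration is on the structural equation, before network propagation;
feedback slightly perturbs realized equilibrium variances.  Default
n = 10 000.  Student-t (df > 2, default 5) and Laplace error families
are rescaled to the calibrated variance exactly, so normality
sensitivity is isolated from scale.

What the generator does **not** emulate: linkage disequilibrium among
instruments (x is iid standard normal), pleiotropy (instrument effects
obey D exactly), measurement error, and non-Gaussian responses beyond
the error families above.  Passing the recovery tests therefore shows
the sampler recovers the model's own data generated under valid
instruments; it does not certify robustness to invalid-instrument
violations in real GWAS data.

## Evaluation

Graphs are scored over the p(p-1) off-diagonal cells: TP/FP/FN/TN, TPR,
FPR, FDR, Matthews correlation, and a ranking AUC computed from the
inclusion probabilities by the Mann–Whitney statistic with ties counted
one half.  Zero-denominator conventions: MCC = 0 when a confusion
marginal is zero, FDR = 0 when nothing is predicted positive, TPR (FPR)
is NaN when there are no true positives (negatives).

## Problem sizes in the test suite

The automated checks run the full benchmark configuration — p = 5, 25%
sparsity, effects ±0.1, VE = 10%, B = I, n = 10 000, default sampler
settings — averaged over three seeds per error family, which this
implementation completes in a few seconds per fit.  Likelihood
identities are checked to 1e-8 against per-observation oracles; prior
recovery uses a 50k-iteration flat-likelihood (n = 0) run with
batch-means Monte-Carlo standard errors and a widened proposal variance
(a mixing knob only) so the random walk traverses the slab.

## Known limitations

- No parallel chains, adaptive proposal tuning, or built-in convergence
  diagnostics beyond the retained log-likelihood trace.
- Error covariance is diagonal; latent confounding among responses is
  not modeled.
- The regression-summary path is conservative about response-response
  edges (see above).
- The Threshold prior needs tMax on the scale of plausible effects and
  mixes more slowly than spike-and-slab; it is provided for completeness.
- Instruments are taken as valid by construction; instrument selection
  and pleiotropy-robust variants are out of scope.
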