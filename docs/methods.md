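# Methods

This note documents the statistical models, the numerical choices behind
the fitter, what the synthetic-data generators do and do not emulate, and
the design decisions taken where the procedure left room.

## The paired designs

**Motility.** Each of n = 18 males contributes one dyed and one undyed
CASA summary: motile/total cell counts and seven kinematic traits (VAP,
VSL, VCL in μm/s; STR = VSL/VCL and LIN = VAP/VCL dimensionless; ALH in
μm; BCF in Hz). Percent motile is compared with a paired *t*-test
(df = n − 1). The seven traits are strongly inter-correlated, so the
per-male undyed − dyed differences are reduced by PCA before testing:

* Differences are taken **undyed − dyed**, fixing all downstream signs.
* The normality of each trait's differences is screened with
  Shapiro–Wilk at α = 0.05; flagged traits are square-root transformed
  **on the raw per-sample values before differencing** (differences can
  be negative, so transforming them is not defined) and re-screened.
* PCA runs on the **correlation** matrix of the difference columns:
  loadings are then variable–component correlations bounded by 1 in
  magnitude and the eigenvalues sum to the number of traits — the
  convention under which the reference results (eigenvalues 3.93/2.29
  summing toward 7, all loadings ≤ 1) are coherent. Components with
  eigenvalue > 1 are retained (Kaiser criterion; threshold configurable).
  Each component is oriented so its largest-magnitude loading is
  positive, making output deterministic across linear-algebra backends.
* One-sample *t*-tests are applied to retained component scores.

A structural caveat, reported rather than silently repaired: PCA scores
of centred data have mean exactly zero, so a one-sample *t*-test of a
score column against zero is ~0 (order 10⁻¹⁶) for *any* input. The
pipeline reproduces the published procedure and attaches this note to its
report; the test is asserted as a property in the suite.

**Competitive fertilisation.** Each pair of males (focal, rival) is
crossed three times with one female's eggs: A (focal dyed, success *X*),
B (rival dyed, success *Y*), C (undyed, overall fertilisation rate *Z*).
Under the null *X* = *Z* − *Y*. Success is modelled as the focal male's
share of fertilised eggs — proportions with denominator *Z*:

* dyed observation: k = labelled eggs in A, m = fertilised eggs in A;
* undyed observation: share (Z − Y)/Z converted to counts over
  m = fertilised eggs in C (round-half-even).

Two conventions for measuring *Y* are supported. The default (`share`)
takes *Y* as the rival's share of fertilised eggs in B, giving undyed
share 1 − Y ∈ [0, 1] always. The alternative (`rate`) takes *Y* per egg
scored and computes (Z − Y)/Z directly; sampling noise can then push the
implied share negative, in which case it is truncated to 0 and the pair
flagged — never dropped, preserving the paired design. Pairs with zero
fertilised eggs in cross C are excluded with a logged reason.

A consequence of the reciprocal design worth knowing: if dyeing reduces
the dyed male's share by δ in whichever cross he is dyed, the assembled
dyed-vs-undyed contrast estimates **2δ** — the rival's depressed share in
cross B inflates the focal male's implied undyed success by δ. The power
simulation below instead implements the published simulation protocol,
in which the two arms differ by exactly δ.

## The binomial logit GLMM

For observation j of pair i: k_ij ~ Binomial(m_ij, p_ij) with
logit(p_ij) = β₀ + β₁x_ij + u_i, u_i ~ N(0, σ_u²); the OLRE variant adds
e_ij ~ N(0, σ_obs²) with one level per observation.

**Laplace likelihood.** The per-group random-effect integral is
approximated at its mode: the joint log-density is maximised over the
group's random vector by damped Newton iteration (the objective is
strictly concave, so step-halving makes the iteration globally
convergent; near the mode, where objective changes fall below round-off,
the undamped Newton step is taken — its basin is guaranteed there), and
−½ log det(−H) is added at the mode. For the OLRE variant the per-group
Hessian is an arrow matrix (pair intercept bordering a diagonal OLRE
block); the Newton step and determinant use its Schur complement in
closed form, so both variants are vectorised across groups. At
σ_u = 0 the marginal likelihood is computed exactly as the binomial GLM
likelihood. Agreement with 51-node adaptive Gauss–Hermite quadrature is
~O(G/(m p q)): about 2–4 × 10⁻³ total for 3–5 groups with m ≈ 100–200,
and the fitted parameters match lme4's Laplace fits to ~10⁻³.

**Fitting.** Parameters (β₀, β₁, log σ) are maximised by L-BFGS-B with
finite-difference gradients from an IRLS logistic-GLM warm start
(gtol 10⁻⁶, ftol 10⁻¹³; a tighter gradient tolerance is noise-dominated
under finite differencing). Bounds |β| ≤ 15 keep separated data finite
(separation is detected and flagged). A fit whose log σ_u reaches the
lower bound is refitted exactly at σ_u = 0 and flagged as a boundary fit.

**Inference.** Wald *t* on β₁ with residual df = n_obs − n_fixed −
n_variance_components; for the study design (20 observations, intercept +
dye, one pair variance) this gives 17, and the OLRE variance is not
counted, matching the convention under which 17 df is reported for both
model variants. SEs come from the observed information of the β block
with variance components held at their estimates (the conditional
covariance lme4 reports); this is well defined at the σ_u = 0 boundary.
A Wald Z variant and an optional √dispersion SE inflation switch are
provided for sensitivity checks; inflation is off by default, since the
reference analysis addresses overdispersion through the *t* reference
and the OLRE model rather than quasi-likelihood SEs.

**Dispersion.** Deviance and Pearson residuals are evaluated at the
conditional fit (fixed effects + conditional modes, including OLRE
modes); both D/df and χ²/df are always reported — the reference values
(3.13 base, 0.18 OLRE) are not attributable to a single flavour, so no
silent choice is made. Note that with model-based SEs an overdispersed
base model rejects a true null more often than α; the calibrated type-I
behaviour asserted in the tests uses the well-specified (pure binomial)
regime.

## Power analysis

Per effect size δ ∈ {0.01, …, 0.10}: 1000 replicates, each 10 pairs with
two binomial observations of 100 eggs (undyed share 0.5, dyed share
0.5 − δ, subtracted on the probability scale), GLMM refit, two-sided
Wald *t* (17 df) at α = 0.05. Power is the significant fraction;
Monte-Carlo SE is √(p(1−p)/n). Replicates that fail to converge are
excluded from the denominator and counted (rows losing > 1% are
flagged); in practice convergence is universal. Replicate seeds derive
from the master seed via `SeedSequence(master, spawn_key=(delta_index,
replicate))`, so the curve is bit-reproducible and parallelisable. The
minimum detectable effect is the grid bracket where the isotonically
smoothed curve (pool-adjacent-violators) crosses the target power 0.8.

The egg count per simulated observation is not printed in the reference;
m = 100 was fixed by reverse calibration — with 10 pairs, pure binomial
noise and a 17-df *t* criterion, the closed-form normal approximation
Φ(|Δlogit|/se − t_crit) gives power 0.72 at δ = 0.06 and 0.85 at
δ = 0.07, matching the printed 72%/84%. The closed form serves as an
independent oracle in the tests, never as the implementation.

## Synthetic data

**Motility generator.** Each male has a latent 7-trait profile drawn
from a multivariate normal whose covariance has a two-factor structure
(overall speed, path vigour) with realistic mussel CASA means
(VAP 60, VSL 45, VCL 95 μm/s, STR 0.80, LIN 0.55, ALH 2.5 μm,
BCF 32 Hz) — positive semidefinite by construction. Both treatments
share the profile; dyeing adds a configurable 7-vector shift (default
zero) plus within-male measurement noise drawn with the **same**
correlation structure (SD 30% of the trait SD), so trait differences
remain strongly correlated and the difference-PCA concentrates ~80% of
variance in two components, as in the reference data. VCL is taken as
the max of the three velocities, enforcing VSL ≤ VCL and VAP ≤ VCL by
construction. Motile counts are normal around 149 (SD 70, the reported
per-sample mean), percent motile ~75% on a logit-normal male effect.

**Fertilisation generator.** Per pair, a fertilisation probability z_i
is drawn from a Beta with mean 0.733 and SD 0.158 truncated to
(0.46, 0.94) — the reported between-pair mean and spread. The focal
male's undyed share is logistic(logit(baseline) + pair effect); each
cross's realised share carries its own observation-level logit noise
(independent noise per cross is what creates extra-binomial variation in
the paired contrast — a single shared noise term would cancel). Dyeing
subtracts δ on the probability scale (a logit-scale option exists),
shares are clamped to [0.001, 0.999] to avoid degenerate binomials, and
counts are drawn binomially: fertilised eggs from z_i in every cross,
labelled eggs from the dyed male's share among them.

Two named presets bracket the plausible regimes. The **power preset**
(100 eggs, no pair or observation noise) is the pure-binomial regime of
the power simulation. The **realistic preset** reproduces the observed
dataset's signatures — base-model Pearson dispersion ≈ 3.1 and paired
dyed − undyed s.e.m. ≈ 0.055 — with 120 eggs per trial, pair SD 0.25 and
observation SD 0.47 on the logit scale. The observation SD is calibrated
empirically against the fitted GLMM rather than by a moment formula: the
pair intercept absorbs roughly half of the observation-level noise, so a
naive 1 + (m−1)·var(p)/p̄q̄ calculation understates the noise needed by
about a factor √2.

What the generators do **not** emulate: sperm trajectories or
chemoattraction, gamete ageing, polyspermy, sperm:egg ratios, or any
image-derived measurement error — only the statistical observation
model. Passing tests therefore show that the pipeline recovers what it
assumes, not that those assumptions hold for any particular real
dataset.

## Degenerate inputs and tie-breaks

* A paired *t* on identical samples returns t = 0, P = 1 (0/0 resolved
  to "no evidence") rather than NaN.
* Constant difference columns make Shapiro–Wilk W undefined and PCA
  standardisation impossible; both raise typed errors naming the trait.
* Share-to-count conversion uses round-half-even.
* Deviance residuals at saturated fits use xlogy(0, 0) = 0, so a
  saturated model has residual deviance exactly 0.
* Validation never silently drops rows: structural violations raise
  errors naming the row or identifier; soft violations (kinematic
  ordering in input files) and pair exclusions (Z = 0) are logged.

## Problem sizes used by the test suite

The suite reruns the full 1000-replicate power simulation at the two
headline effect sizes (~35 s), 200-replicate parameter-recovery and
type-I studies, and 15–20-seed averages for the dispersion signatures;
a GLMM fit of the study design takes ~12 ms, so the whole suite runs in
about a minute on one CPU.
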