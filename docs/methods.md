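# Methods

This note records the model, the estimation machinery, the synthetic-data
conventions and the numerical choices behind `neocefpk`, in enough detail
that a pharmacometrician can judge what the package's tests do and do not
demonstrate.

## Structural and statistical model

Cefotaxime disposition in neonates is described by a one-compartment model
with first-order elimination, parameterised by clearance CL (L/h) and volume
of distribution V (L). Dosing is by constant-rate intravenous infusion;
concentrations are evaluated with the closed-form single-infusion solution
superposed over the dose history — during an infusion started at t₀ with
rate R, the contribution is (R/CL)(1 − e^(−ke(t−t₀))); after it ends at
t₀+D it decays as (R/CL)(1 − e^(−keD))·e^(−ke(t−t₀−D)), with ke = CL/V.
There is no discretisation grid anywhere; steady state uses the analytic
accumulation factor 1/(1 − e^(−keτ)) applied to the post-infusion profile,
with the still-running current dose handled separately during the infusion.

Covariates enter as power functions normalised to the study medians, fixed
at 2310 g (current weight) and 1 day (postnatal age) so that a parameter set
is portable across datasets rather than tied to a particular cohort's
medians:

- CL = θ2 · (CW/2310)^θ3 · (PNA/1)^θ4 · e^η_CL
- V = θ1 · e^η_V (no covariates on V in the final model)

Inter-individual variability is exponential with a diagonal Ω (no CL–V
correlation); residual error is proportional, y = f·(1+ε). Reported percent
CVs are 100·√ω² and 100·√σ². The shipped preset carries θ1 = 0.873 L,
θ2 = 0.0803 L/h, θ3 = 1.68, θ4 = 0.444, ω_CL = 0.200, ω_V = 0.211,
σ = 0.142.

## FOCE-I estimation

The marginal likelihood has no closed form. The objective function value
(OFV) is the FOCE-with-interaction approximation of −2 log L: for each
subject, the conditional mode η̂ of the random effects is found, the model
is linearised about η̂ with the analytic derivatives ∂f/∂η (the
concentration kernel returns them in closed form), and the subject
contribution is log|C| + e'C⁻¹e + n·log 2π with C = GΩG' + R(η̂),
e = y − f(η̂) + Gη̂, and R the proportional residual variance evaluated at
the conditional prediction (the interaction term). The n·log 2π constant is
included so the OFV is directly comparable to an exact marginal likelihood;
model comparisons by ΔOFV are unaffected.

The inner per-subject 2-d problem is solved by Gauss–Newton with per-subject
Levenberg–Marquardt damping, batched across all subjects as one vectorised
iteration; convergence is |step| < 1e-8 with at most 60 iterations, and an
active set drops converged subjects from further kernel evaluations. A
variance component below 1e-12 pins its η at zero. The test suite checks
this approximation against dense two-dimensional Gauss–Hermite quadrature of
the exact marginal likelihood (41² nodes) on small datasets; agreement is
well within 2 OFV units under the study design, which is why quadrature is
used as the oracle rather than a second estimation route.

The outer problem minimises the OFV over (θ, ω², σ²) by Nelder–Mead on a
transformed scale: log θ1, log θ2, raw exponents, and log ω / log σ. Two
numerical guards matter in practice:

- variance floors (ω² ≥ 1e-4, σ² ≥ 1e-6, i.e. 1% and 0.1% CV): when a
  variance component collapses toward zero — common in bootstrap
  replicates — the unfloored log-scale profile is an endless flat valley
  that stalls the optimiser; the floors are far below anything estimable
  from sparse clinical data;
- staged optimisation: Nelder–Mead runs in stages of at most 800
  evaluations, rebuilding the simplex at the incumbent between stages;
  convergence is declared on optimiser success or when a restart improves
  the OFV by less than 0.05 units.

Starting values are reproducible and data-derived: V from the median of
dose/peak per subject, CL from V at a half-life guess of ~7 h, a short
naive-pooled log-scale least-squares polish of the fixed effects, then 30%
IIV and 20% residual error. Standard errors come from the central-difference
Hessian of the OFV on the natural parameter scale (covariance = 2H⁻¹);
RSE% = 100·SE/estimate. Terms with a non-positive variance from an
indefinite Hessian are reported as NaN rather than silently dropped.

Empirical Bayes estimates are the conditional modes η̂; a subject with no
observations gets (0, 0), and η̂ shrinks toward zero as data are removed or
ω² → 0.

## Covariate selection

Candidates are power functions of BW, GA, CW, PNA and PMA on CL (V targets
are allowed but the shipped generator carries no such effect), normalised to
dataset medians, with the exponent estimated (or fixed at 0.75 for the
fixed-allometry comparison). Forward inclusion tests one candidate per fit
and admits the largest ΔOFV exceeding χ²₁(0.05) = 3.84; ties break toward
fewer added parameters, then lexicographic name. All admitted covariates
enter simultaneously before backward elimination, which removes the
cheapest deletion while its OFV increase is ≤ χ²₁(0.01) = 6.635. Every step
records the tested model's OFV, the reference OFV and the threshold, so a
trace can be re-audited mechanically (`replay_decisions`).

## Model evaluation

- **CWRES**: per subject L⁻¹(y − ŷ_c) with ŷ_c = f(η̂) − Gη̂ and L the
  Cholesky factor of GΩG' + R(η̂); approximately N(0,1) pooled under a
  correct model. At finite σ² the conditional mode of noise-free data is
  displaced by O(σ²) (the interaction term), so "zero residuals" holds only
  in the σ² → 0 limit; the tests check both regimes.
- **Bootstrap**: plain nonparametric subject resampling to the original
  subject count, refit per replicate, medians and 5th–95th percentiles over
  converged replicates (non-converged ones are dropped and counted, not
  imputed). Duplicated subjects in a resample contribute identical
  likelihood terms, so each replicate fits the unique subjects with
  multiplicity weights — an exact reformulation that roughly halves the
  cost. Replicates warm-start at the original estimates.
- **NPDE**: K simulated replicates of the design; per subject the observed
  and simulated vectors are decorrelated with the simulation mean and the
  Cholesky square root of the simulation covariance; each decorrelated
  observation's rank among its simulations maps through (rank+0.5)/(K+1)
  and Φ⁻¹. Defaults K = 1000, with K = 500 used in the desk-scale checks.
  At n = 101 observations the sampling standard deviation of the NPDE
  variance is ≈ 0.10, which bounds how tightly "variance ≈ 1" can be
  asserted from a single realisation.
- **pcVPC**: equal-count bins (default 6) on time after the most recent
  dose; observed and simulated values are rescaled by (bin-median population
  prediction / own population prediction); the envelope is the 2.5–97.5%
  band of each percentile (5/50/95) across simulated replicates.

All simulation-based diagnostics draw through the same concentration kernel
the estimator and the cohort generator use — there is a single
implementation of the structural profile in the package — and all are
deterministic given their seed.

## Synthetic cohorts and datasets

The generator emulates the study conditions: GA ~ truncated normal
(mean 35.7, sd 3 wk, bounds 30.0–41.1); CW log-linear in GA
(slope 0.08 per week, log-sd 0.12) calibrated so the median sits near 2310 g,
clipped to 1220–3970 g; BW = CW at these ages; PNA ∈ {1, 2, 3} days with
probabilities {0.5, 0.3, 0.2} to respect the reported median 1 and range
1–3; PMA = GA + PNA/7. Dosing is 50 mg/kg q12h as 0.5-h infusions over the
first three treatment days; sampling is ~2 draws per subject uniform over
(0.5 h, 72 h) after the first dose, mimicking opportunistic leftover-blood
sampling whose true time distribution is unreported. The canonical
"study-like" preset is 51 subjects with one observation dropped at random to
give 101 in total.

What the generator does **not** reproduce: the real joint distribution of
covariates (only the reported marginals are matched; the GA–CW link is a
plausible convention), true opportunistic sampling times (tied to clinical
care, not uniform), below-LOQ observations (none are generated; the reader
excludes concentrations < 0.5 mg/L with a logged warning), metabolite
kinetics, and any covariate the study did not report. Passing tests
therefore demonstrate internal consistency of the machinery under the
study's published design and parameters — not that the model is correct for
any particular real neonate.

## Dose evaluation

Attainment is free concentration above MIC at the instant 0.7τ measured
from infusion start, at steady state, using the analytic accumulation
formula (a superposition cross-check exists in the tests). Because the
post-infusion decline is monotone, this instant-based criterion equals
fT>MIC ≥ 70% whenever 0.7τ falls after the infusion ends (it does: 8.4 h vs
0.5 h). Free fraction defaults to 0.6 — protein binding is reported between
27% and 50%, and 40% is the conventional midpoint — and is exposed as a
parameter. Population attainment defaults to Monte-Carlo η sampling, since
the original subject-level empirical Bayes estimates cannot be reconstructed
without the raw data; supplying EBEs is supported. AUC₀₋₂₄ is daily dose
over clearance.

## Problem sizes and determinism

The desk-scale defaults used by the test suite and the acceptance script
are: 51-subject/101-observation fits; 20 replicates for recovery bias; 200
bootstrap replicates; K = 500 NPDE simulations; 300–500 VPC simulations;
1000-subject PTA cohorts. Every stochastic routine takes an explicit seed
and derives all randomness from it; estimation itself is deterministic.

## Known limitations

- FOCE-I is an approximation; its equivalence is claimed against the
  package's stated formulation and the quadrature oracle, not against any
  specific NONMEM version bit-for-bit.
- Nelder–Mead is derivative-free and can terminate within ~1e-3 of the
  optimum on hard bootstrap replicates; this is far below bootstrap
  sampling variability but visible if one compares OFVs at full precision.
- Single observation compartment, IV infusion only; no inter-occasion
  variability, no SAEM/Bayesian alternatives, no metabolite model.
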