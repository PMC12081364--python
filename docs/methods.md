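# Methods

`mtxppk` implements a population-pharmacokinetic (PPK) analysis pipeline
for high-dose methotrexate (HD-MTX) given as a split intravenous
infusion, of the kind used in intracranial germ-cell-tumor chemotherapy:
a structural disposition model, a covariate model, nonlinear
mixed-effects (NLME) estimation, stepwise covariate selection, and
simulation-based model diagnostics. Because no patient-level data are
distributable, a first-class synthetic-cohort generator emulates the
study design; every downstream stage is exercised and calibrated on
those cohorts.

## Structural model

Drug disposition is a two-compartment model with first-order elimination,
parameterized by clearance CL (L/h), central volume Vc (L),
inter-compartmental clearance Q (L/h) and peripheral volume Vp (L).
Amounts are carried in μmol and volumes in L, so central concentrations
are natively in μmol/L (the clinical assay unit; methotrexate molar mass
454.44 g/mol converts g/m² doses, configurable).

The central concentration after any sequence of constant-rate infusions
is evaluated in closed form: the unit impulse response is
`h(t) = A e^(−αt) + B e^(−βt)` with α, β the roots of
`s² − (k10+k12+k21)s + k10·k21 = 0`, and each infusion segment
contributes `R·Σ_m C_m (1−e^(−λ_m t_e)) e^(−λ_m (τ−t_e))/λ_m`
(`t_e = clip(τ, 0, duration)`). Superposition over segments makes the
profile exactly linear in dose. The analytic evaluator is the primary
path because the diagnostics run thousands of replicate simulations; a
stiff ODE integration of the mass balance serves as an independent test
oracle (agreement ≤ 1e-6 relative on random draws). Degenerate `q = 0`
reduces exactly to the one-compartment mono-exponential (the λ → 0
branch is evaluated by its limit, never as 0/0). One- and
three-compartment options exist for structural model comparison; the
three-compartment variant uses the general mammillary eigen-expansion.

## Covariate and variability model

Typical values are products of multiplicative covariate factors:
continuous covariates enter as powers of their median-normalized value,
the binary bleomycin flag as `exp(β·flag)`:

    CL = θ_CL · (eGFR/102.2)^0.23 · (BW/47)^0.39 · e^(0.08·BLM)
              · (TBIL/15.3)^(−0.05) · (ALB/40.9)^(−0.18)
    Vc = θ_Vc · (BW/47)^0.31,   Q = 1.08 L/h,  Vp = 94.94 L (fixed)

with θ_CL = 12.88 L/h and θ_Vc = 72.04 L at the reference medians.
Between-subject variability is log-normal (`θ_i = θ_TV e^η`,
`η ~ N(0, ω²)`) on CL and Vc; Q and Vp carry no variability (they were
fixed after boundary shrinkage in the source analysis). The shipped
defaults use ω_CL = 0.30 and ω_Vc = 0.32 as log-scale SDs: the reported
IIV magnitudes are not interpretable as CV% at face value, so these are
exposed as user-settable quantities, not treated as verbatim published
values. Residual error supports additive, proportional (default,
σ = 0.37) and combined forms; simulated proportional draws truncate ε at
−0.999 so a concentration cannot flip sign (configurable), while the
estimation likelihood never truncates.

## Synthetic cohorts

The generator emulates the study conditions: 505 subjects, 73.3%
children, 58.67% bleomycin co-medication, 1.3 g/m² dosed by Mosteller
BSA with one-third infused over 1 h and the remainder over 11 h, and
serum samples at 36, 48, 60, 72 h after each course start with
independent Bernoulli retention (1.0, 0.5307, 0.2653, 0.0139) matching
the reported record availability; values below the 0.3 μmol/L
quantitation limit are flagged but retained. Six courses at 504 h
spacing reproduce the study's overall density of ~10.8 observations per
subject (5,470/505).

Only medians and ranges of the demographics are published, so the joint
distribution is a modeling choice: age (children mildly right-weighted
on 3–18 y, adults right-skewed on 18–48 y) drives height through a
piecewise-linear growth curve; body weight follows height through a
log-normal BMI (log-SD 0.2 from the published BMI range, median
calibrated to 21.1 so the cohort BW median lands on the 47 kg
reference); a log-normal renal-function factor (log-SD 0.45, set by the
published eGFR range 41.6–446.2) is inverted through the age-appropriate
formula — Schwartz bedside for children, race-free 2021 CKD-EPI for
adults — to give serum creatinine, so eGFR recomputed from creatinine is
formula-consistent; TBIL is log-normal (log-SD 0.5) and ALB truncated
normal. All marginals are clipped to the published ranges.

Two published summaries cannot be reproduced simultaneously: the
height/creatinine medians (155 cm, 62 μmol/L) imply a Schwartz eGFR of
~91, not the published 102.2. The generator prioritizes eGFR — the PK
covariate — so the creatinine median lands ~12% low; likewise the BMI
median sits above its published value so that body weight (the PK
covariate) is exact. What passing tests show is therefore calibration of
the *procedures* under a design faithful to the published medians,
ranges and sampling pattern — not distributional identity with the real
cohort, whose joint covariate structure (and within-subject covariate
variation across courses) is unknown.

## Estimation

The marginal likelihood is approximated FOCE-style with interaction.
For each subject the conditional mode of η is located by a damped
Newton search, vectorized across all subjects: the Hessian of the
conditional objective is taken by finite differences (with a
Gauss-Newton fallback wherever it is not positive definite), steps are
norm-capped without bending the direction, and backtracking uses a
geometric scale ladder evaluated in one batched call. The objective is

    OFV_i = Σ_j [log 2πσ²_ij + r²_ij/σ²_ij] + log|Ω| + η̂ᵀΩ⁻¹η̂
            + log|Ω⁻¹ + Σ_j g_j g_jᵀ/σ²_ij|

with the residual variance σ²(f) evaluated at the conditional
prediction and g = ∂f/∂η. With `n_quad > 1` the Laplace value is
replaced by adaptive Gauss-Hermite quadrature centered at the mode and
scaled by the local curvature; the implementation was validated against
brute-force two-dimensional integration of the marginal density on a
tiny cohort (9-node quadrature within 0.006 of the exact value).
Laplace (`n_quad = 1`) is the default — it is what ΔOFV-based selection
uses — while final-model estimates in the recovery experiments use
`n_quad = 3`, which removes a ~2% upward σ bias visible on this sparse
design. With ω = 0 the code path reduces exactly to the closed-form
Gaussian likelihood.

The outer search runs L-BFGS-B on log-transformed positive parameters
(power/log-scale coefficients unconstrained), tolerance 1e-8 relative on
the OFV. Far-off trial points under proportional error can be
astronomically bad (predictions near zero), so two numerical guards
apply: a tiny additive variance floor tied to the data scale
(`(1e-4 · median|DV|)²`), and a monotone log-compression of the
objective above its starting value — both leave the minimizer unchanged
while keeping line searches on a sane scale. Standard errors come from
the finite-difference Hessian of the OFV at the optimum (delta method
back to the natural scale); ω estimated below 1e-4 is reported as 0
with a boundary flag. Below-quantitation observations enter the
likelihood as ordinary values, matching the assay's behavior of
reporting concentrations below 0.3 μmol/L.

CWRES uses the FOCE linearization with the full within-subject
covariance: `L⁻¹(y − E)` with `E = f(η̂) − Gη̂` and `L` the Cholesky
factor of `GΩGᵀ + diag σ²`. The matrix form matters: diagonal scaling
leaves a visible positive pooled mean (the log-normal curvature of the
conditional mean), while the whitened version is calibrated.

TAD (time after dose) counts from the start of the most recent
*administration block*: chained infusion rows (a dose starting at or
before the previous infusion's end) form one administration, so the
1 h + 11 h split infusion is one dose and the first sample has
TAD = 36 h.

## Covariate selection

Forward inclusion accepts the candidate with the largest OFV drop if it
reaches 6.64 (χ²₁ at P = 0.01); backward elimination removes the least
supported covariate unless its removal raises the OFV by more than
10.83 (χ²₁ at P = 0.001), repeating until stable. Ties within 1e-6 are
broken by a canonical order (eGFR, BW, BLM, TBIL, ALB, then
alphabetical). Mutually exclusive candidate groups handle collinear
alternatives (the body-weight vs body-surface-area situation): once one
member enters, the rest leave the pool. Trial fits warm-start from the
current model's estimates; the full trail (model number, action, OFV,
ΔOFV, decision) is exportable as a model-development table.

## Diagnostics

*Bootstrap* resamples subjects (the hierarchical unit) with replacement
to the original cohort size and refits; failed replicates are excluded
and counted. *VPC* simulates replicates of the dataset at its own
design and compares observed 5th/50th/95th percentiles per exact
nominal-TAD bin against the central 95% interval of the same percentile
across replicates (no smoothing, no prediction correction). *NPDE*
decorrelates each subject's observed and simulated vectors with the
inverse lower-triangular Cholesky factor of the empirical simulated
covariance; the rank of the decorrelated observation in its ensemble
(clipped to (1/(2K), 1−1/(2K)) for K simulations) maps through the
standard-normal quantile. The pooled NPDE is tested for mean zero
(Wilcoxon signed-rank), unit variance, and normality (Shapiro-Wilk;
pooled samples beyond 5,000 are deterministically subsampled to the
test's domain of definition). The variance test is a subject-clustered
one-sample t-test of the per-subject mean squared NPDE against 1 rather
than the textbook χ² variance test: decorrelation removes within-subject
correlation only linearly, the rank transform leaves residual
dependence, and on this design the χ² test's null rejection rate is
inflated severalfold (measured ~30% vs ~10% at 20 null replicates,
nominal 5%), while the clustered test stays calibrated.

All simulation draws are keyed per (seed, subject id), so diagnostic
simulations are invariant to subject ordering and to subsetting the
cohort, and reruns with the same seed are identical.

## Problem sizes and runtimes

Package defaults keep research-scale sizes (1,000 bootstrap runs, 1,000
NPDE simulations). The shipped test suite and acceptance script use
smaller sizes chosen as a practical screen: parameter recovery refits 5
cohorts of 505 subjects (~5,400 observations each, adaptive quadrature,
~2 min per fit); stepwise power uses 10 replicate 400-subject
single-course cohorts and type-I control 20 null 100-subject cohorts;
NPDE calibration uses 10 replicate 200-subject cohorts at 1,000
simulations; the ODE-oracle check uses 100 random draws. A full-size
rerun is a matter of raising the counts.  The single-course stepwise
design keeps refits fast while the subject count carries the
between-subject covariate information that selection power depends on.

## Known limitations

- Inter-occasion variability, covariance between random effects,
  censored-likelihood handling of below-quantitation values, and
  SAEM-type estimators are out of scope; the spec's optional censored
  mode is not enabled by default anywhere.
- The FOCE/Laplace OFV is an approximation: no claim is made of
  numerical equality with any specific commercial implementation, only
  of statistical equivalence (parameter recovery within the published
  confidence intervals).
- The generator draws covariates independently of the random effects
  and keeps them constant across courses; real cohorts have
  within-patient covariate drift and correlations the published
  summaries do not constrain.
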