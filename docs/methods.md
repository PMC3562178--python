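# Methods

## The model

`dyadstat` analyses *distinguishable* dyads: pairs whose members occupy
fixed, non-interchangeable roles (here a person living with HIV/AIDS,
member 1, and their primary caregiver, member 2). Each member contributes
a predictor score X (perceived HIV stigma, a 0–27 composite) and an
outcome score Y (a WHOQOL-BREF domain, 4–20). The Actor–Partner
Interdependence Model is the two-equation path model

    Y1 = b01 + A1·X1 + P1·X2 + β1′C1 + E1
    Y2 = b02 + A2·X2 + P2·X1 + β2′C2 + E2

with cov(X1, X2) = φ12 free (members' stigma levels may covary) and
cov(E1, E2) = ψ12 free (residual non-independence of the dyad). A1/A2
are actor effects, P1/P2 partner effects. Covariates C are age, gender
(female = 1), marital status (married = 1) and education (middle school
or above = 1).

### Covariate scope and degrees of freedom

The exogenous covariance matrix Φ is always saturated, so testable
degrees of freedom come only from omitted paths and equality constraints.
The default `covariate_scope="own_member_only"` regresses each member's
outcome on that member's own covariates and fixes the eight cross-member
covariate paths at zero — with 12 observed variables this gives df = 8
per model. This is a conventional restriction, exposed as configuration
(`both_members` gives a saturated df = 0 regression block, `none` drops
covariates entirely), not a claim that it is the only defensible one.

## Estimation

The model is fitted to the sample covariance matrix S (listwise-complete
dyads, divisor N−1) by minimising the normal-theory ML discrepancy

    F(θ) = ln|Σ(θ)| + tr(S Σ(θ)⁻¹) − ln|S| − p ,
    Σ_yy = ΓΦΓ′ + Ψ,  Σ_yx = ΓΦ,  Σ_xx = Φ .

Because the Gaussian likelihood factorises as f(x)·f(y|x) with
variation-free parameter blocks, two blocks have closed-form conditional
solutions at the optimum: Φ̂ = S_xx exactly, and, given the paths Γ,
Ψ̂(Γ) = S_yy − ΓS_xy − S_yxΓ′ + ΓS_xxΓ′. The implementation exploits
this: the free paths are found by minimising the profile objective
ln|Ψ(Γ)| with its analytic gradient (BFGS, gradient-norm tolerance
1e−8, least-squares start values, equality-constrained pairs estimated
as a single shared parameter), after which Σ̂ is assembled and
F evaluated. This reaches the same optimum as a quasi-Newton search over
the full parameter vector but reduces each fit to a handful of
milliseconds, which is what makes the 1,000-replicate calibration runs
practical. The estimator coincides with maximum-likelihood seemingly
unrelated regression, and the test suite verifies the coefficients
against an independently coded iterated-FGLS oracle to 1e−4.

The model chi-square is T = c·F with c = N−1 by default; c = N is
available (`chi2_scale="n"`) because software conventions differ and the
O(1/N) difference should be explicit rather than hidden.

**Standard errors.** The asymptotic covariance of θ̂ is (2/c)·H⁻¹ with H
the Hessian of F at the optimum. The factorisation above makes H exactly
block-diagonal between (Γ, Ψ) and Φ, so only the (Γ, Ψ) block is
computed (central finite differences, relative step 1e−4). Reported 95%
intervals are the symmetric estimate ± 1.96·se. These are ML standard
errors without a small-sample degrees-of-freedom correction; at n = 148
the simulated coverage of the 95% intervals is ≈ 0.93–0.95.

**Fit indices.** The baseline (independence) model — all covariances
zero, variances free — has the closed-form ML solution σ̂ii = s_ii, hence
T_b = −c·ln|R| on p(p−1)/2 df, with R the sample correlation matrix.
Then

    CFI  = 1 − max(T − df, 0) / max(T_b − df_b, T − df, 0)
    SRMR = sqrt( mean over unique moments of ((s_ij − σ̂_ij)/sqrt(s_ii s_jj))² )

and χ²/df is undefined (reported as null) for saturated models. The
conventional adequacy thresholds for this design are χ²/df < 2,
CFI ≥ 0.9, SRMR ≤ 0.06.

**Equality-constraint tests.** A constrained model (actor effects equal,
or partner effects equal) is refitted with the pair as one shared
parameter; Δχ² = T_c − T_u is referred to χ² with Δdf = df_c − df_u.
Nesting is verified structurally (identical variable ordering; the
constrained parameter map must merge, never move, the unconstrained
cells). Negative Δχ² within 1e−6 is clamped to zero with a warning
(optimizer noise); anything more negative raises an error. Simulated
type-I error of the actor-equality test at n = 148 is ≈ 0.05–0.06 over
1,000 replicates — the familiar mild small-sample inflation of
likelihood-ratio chi-squares, vanishing in larger samples.

## Scale scoring

The stigma composite is the sum of nine items coded 0–3, range 0–27;
a file coded 1–4 is rejected rather than silently re-anchored. WHOQOL-BREF
domains are the mean of the domain's items × 4 (range 4–20 on 1–5
coding); the two overall items are excluded from the four domains. The
shipped WHOQOL-BREF preset reverse-codes the standard items (q3, q4,
q26), since instrument convention requires it even when an analysis
reports nothing about it; the reverse list is explicit configuration, so
either handling is reproducible. Missing items are never imputed: any
missing item makes the composite or domain score missing, and analyses
delete listwise. Cronbach's alpha uses the item-variance formula with
n−1 divisors and listwise-complete respondents; it is reported as
computed (possibly negative), never clamped.

## The synthetic-data generator

`DyadScenario` runs the actor–partner equations forward: (X1, X2)
correlated bivariate normal (default means 6.3/3.8, SDs 5.8/5.3,
ρ = 0.15), covariates drawn independently per role (age ≈ 40.7/37.5 ±
11.4/11.2; female 30%/61%; married 70%/80%; ≥ middle school 74%/77%),
residuals correlated bivariate normal (ρ_e = 0.15). Residual SDs are not
free inputs: they are solved so each outcome hits its target marginal SD
given the paths and covariate effects, which enforces the
positive-implied-variance constraint by construction. The
`paper_magnitude` preset sets the four domains' actor effects at
−0.11…−0.21 and partner effects at −0.06…0.02 with the domain means/SDs
of the emulated survey; `null` zeroes all four paths; `strong_partner`
adds −0.12 to the partner effects as a counterfactual. Default n = 148
dyads.

Item-level stigma responses are parallel items λ·latent + √(1−λ²)·noise
cut at fixed thresholds into 0–3 (category probabilities .55/.25/.12/.08,
right-skewed like a stigma scale scored near its floor). The shipped
loading λ = 0.754 was calibrated once so the *discretised* items reach
α ≈ 0.89; it exceeds the continuous-scale Spearman–Brown value (0.688)
because categorisation attenuates inter-item correlations.

All streams derive from one integer seed through
`numpy.random.SeedSequence`, so every fixture and report is
byte-reproducible.

**What the generator does not emulate.** Scores are continuous normal by
default — the estimator's own assumption — so generated stigma values can
stray slightly outside the 0–27 instrument range and are not integers;
`clip=True` rounds and truncates for realism at the cost of slight moment
distortion. Real stigma composites are right-skewed and floor-heavy;
covariates here are mutually independent within role, whereas real
demographics correlate; refusal and site structure are not modelled.
Passing tests therefore certify the estimator under its stated
assumptions, not robustness to the ways real survey data violate them.

## Numerical choices and degenerate inputs

- Convergence: BFGS gradient norm < 1e−8 (one tightened retry before a
  hard error reporting the last gradient norm).
- Non-positive-definite S raises an error suggesting a listwise audit;
  fewer complete dyads than free parameters is refused up front.
- Paired t with zero-variance differences: t = 0 / p = 1 when members are
  identical, ±∞ / p = 0 when they differ by a constant. McNemar with no
  discordant pairs is an explicit undefined-result error; the Edwards
  continuity correction is off by default and available by flag.
- Correlations use pairwise-complete deletion (each r well-defined on its
  own n); model fits use listwise deletion per outcome. Two-sided
  p-values throughout.
- Welch (unequal-variance) summary t-test is the default for comparisons
  against externally published means; the pooled variant is a flag.

## Problem sizes used in validation

Saturated/oracle checks run at n = 200–500; parameter recovery at
n = 10,000 (±0.03 tolerance); type-I-error calibration at 1,000
replicates of n = 148; CI coverage at 500 replicates of n = 148;
reliability at n = 2,000 respondents. These sizes put Monte-Carlo error
comfortably inside each check's tolerance band.
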