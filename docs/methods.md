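# Methods

## Data model

A cohort is a long-format table, one row per family member (twin1, twin2,
oldest sibling, mother, father), with zygosity recorded on the twins and a
0/1/NA lifetime status per condition. Missing statuses are never imputed:
pair analyses use complete twin pairs, family-aggregation analyses use
families complete across all five members, and prevalence uses all
individually responding twins (including twins whose co-twin did not
respond). Sample sizes therefore differ legitimately across analyses, and
every reduction reports its exclusion count.

## Pair similarity likelihood

A twin pair with statuses (Y1, Y2) and marginal affection probability *q*
follows a trinomial over {both, exactly one, neither} with cell
probabilities (p11, 2(q − p11), 1 − 2q + p11). The three association
parameterisations differ only in how p11 is tied to *q*:

| measure | link | MLE (closed form) |
|---|---|---|
| casewise concordance C | p11 = qC | 2N_c / (2N_c + N_d) |
| correlation rho | p11 = q² + rho·q(1−q) | phi of the double-entered table |
| pair odds ratio psi | p11 = Plackett cell(q, q, psi) | N_c·N_00 / (N_d/2)² |

Casewise concordance is the conditional probability of affection given an
affected co-twin; the pair odds ratio is the odds of affection given an
affected co-twin over the odds given an unaffected co-twin. The Plackett
cell solver takes the root of the cross-product quadratic inside the
Fréchet bounds, with the psi = 1 branch handled as the independence
product; inverting it recovers psi to better than 1e-10 of relative error
across margins 0.05–0.95 and psi 0.1–100 (tested).

Standard errors come from the delta method on the multinomial (p11, p_d)
covariance. Confidence intervals are untransformed Wald intervals truncated
to the natural range for C and rho, and log-scale Wald intervals for psi.
With N_d = 0 the odds ratio is infinite and is flagged as a boundary case
with no interval rather than continuity-corrected; no corrections are
applied anywhere.

### Covariate adjustment

Adjusted fits give each twin a marginal p_i = expit(b0 + b_age·age +
b_sex·female) while the association parameter stays common to all pairs
(no association-by-covariate interaction). With unequal margins p11 is
p1·p2 + rho·sqrt(p1(1−p1)p2(1−p2)) for the correlation, the Plackett cell
for psi, and C·(p1+p2)/2 for casewise concordance — the natural
generalisation of p11 = qC that keeps C the affected-co-twin conditional
probability averaged over the two orderings; all cells are constrained to
the Fréchet bounds inside the likelihood.

### MZ-vs-DZ likelihood-ratio test

The unconstrained model fits each zygosity its own marginal parameters and
association; the constrained model shares the association and keeps
separate marginals (the association, not the prevalence, is the quantity
under test), giving 1 df against chi-square. For count data the
unconstrained maximum equals the saturated trinomial log-likelihood, so
only the constrained model needs numerical optimisation.

### Optimisation

All pair likelihoods are maximised by Nelder–Mead on transformed
parameters (logit for q and C, Fisher-z for rho, log for psi) with
xatol 1e-10 / fatol 1e-12 and deterministic plug-in initial values. A
derivative-free simplex was chosen over quasi-Newton because the
likelihood has hard walls where a cell probability reaches zero and
finite-difference gradients are unreliable there; against an independent
grid-search maximiser the constrained optimum agrees to <2e-3 on the LR
statistic. Observed-information standard errors come from a central-
difference Hessian on the working scale, delta-transformed back. The
statistic is floored at 0; a constrained likelihood exceeding the
unconstrained one by more than 1e-6 raises instead of being masked.

## Family-association models

Fixed-effects logistic models are fitted by an in-house IRLS/Newton solver
with step halving, converging when the maximum score component is below
1e-8. Rank-deficient designs are rejected up front; fitted log-odds beyond
±15 raise a separation error (the MLE is at infinity; no Firth or exact
correction is attempted, by design). Wald inference per term.

The family random-intercept model integrates a normal intercept per family
out of the likelihood by adaptive Gauss–Hermite quadrature: 21 nodes,
centred at each family's posterior mode (found by a vectorised per-family
Newton iteration) and scaled by the local curvature, accumulated on the
log scale. The outer optimisation over (beta, log sigma) uses BFGS. With
the random-intercept variance at zero the quadrature reproduces the plain
logistic log-likelihood to below 1e-4, and on clustered test data the fit
matches `lme4::glmer` (nAGQ = 21) to a few 1e-3 on coefficients, sigma and
log-likelihood.

Design choices following the study's analysis plan:

* **Index-twin scans** select one twin per complete five-member family
  uniformly at random (seed required, selection logged). One twin per
  family means no repeated family membership, so the univariate and
  multivariate member scans are plain logistic fits; the random-intercept
  machinery is exercised by the two-twins-per-family prevalence contrast.
* **"Adjusted for age and gender whenever significant"** is operationalised
  as: include a covariate when its own Wald p < 0.05 in a covariates-only
  model for that outcome. The policy is configurable (`always` / `never` /
  `when_significant`) because the source convention is underspecified.
* Sex is coded female = 1; age in years, uncentred (centring does not
  change the member-status ORs of interest).

## Liability-threshold ACE simulator

Each member's liability per condition is standard normal, split into
additive-genetic (a²), shared-environment (c²) and unique (e² = 1 − a² −
c²) fractions. Member-pair correlations are a²·k + c²·s with kinship k =
1 (MZ co-twins), 0.5 (DZ co-twins, twin–sibling, parent–child), 0
(spouses), and shared-environment overlap s = 1 among the co-resident
children, configurable (default 0) between parents and children, 0 between
spouses. Dominance and assortative mating are not modelled (ACE/AE/CE
only). An optional cross-condition genetic correlation matrix couples the
additive components of different conditions (Kronecker structure); C and E
stay condition-specific.

Affection is liability > tau with tau the upper-K normal quantile,
optionally shifted on the probit scale by per-role-centred age and by sex.
Defaults mirror the study cohort's composition: ~49.5% MZ pairs, 51.2%
female, twin ages uniform on 3–18, sibling older by 1–8 years, parent ages
normal (42.6 ± 6.3 mothers, 44.8 ± 6.5 fathers, clipped to plausible
ranges) — demographic realism only. MZ pairs are forced same-sex.
Covariate effect sizes have no published anchor and default to zero; any
nonzero choice is illustrative. Missingness is applied independently per
member-condition cell at a configured rate (MCAR). A single seeded
generator with a fixed draw order makes output byte-identical per seed.

Expected casewise concordance has the closed form P(both > tau)/K with the
bivariate-normal orthant probability at correlation r = a²·k + c²; its
numerical inverse provides a tetrachoric-style correlation estimate used
in the Falconer-style recovery check 2(r_MZ − r_DZ) ≈ a².

What the generator does **not** emulate: questionnaire measurement error
and recall bias, the ~26% response-rate selection process, singleton-twin
responders (every simulated pair is complete unless masked by MCAR
missingness), non-random missingness, age-dependent cumulative incidence,
and zygosity misclassification. Tests passing on synthetic cohorts
therefore validate the estimators under the liability-threshold model's
assumptions, not robustness to those survey artefacts.

## Rendering conventions

Percentages print at 3 significant figures, association estimates at 2
decimals, odds ratios at 3 significant figures, p-values at 3 decimals
with "<0.001" below that; rounding is half-away-from-zero throughout
(configurable at the formatter level). Report bundles include a manifest
with the seed, configuration and an input SHA-256 so identical runs are
byte-identical.

## Validation scales and known limitations

* Closed-form estimators and CIs are validated directly against the
  published per-zygosity pair counts; two printed cells do not follow from
  their own counts (one concordance cell prints 0.48 where the counts give
  0.4748, and one prevalence cell prints 17.4% where the counts give
  17.35%) and are asserted at their recomputed values.
* The published pair odds ratios were produced by an estimation procedure
  not recoverable from the printed summaries; this package's saturated
  estimator agrees with some printed cells and not others, so the
  odds-ratio machinery is validated by exact inversion and calibration
  properties instead of by table reproduction.
* Null calibration of the zygosity LR test uses 1000 replicates of 500
  pairs per zygosity (rejection within 0.05 ± 0.02); the power regression
  check uses 60 replicates of 800 pairs per zygosity at a² = 0.6, K = 0.15;
  simulator-vs-oracle concordance checks use ~5000 pairs per zygosity.
  These sizes give Monte-Carlo error comfortably below the asserted
  tolerances.
* The constrained LR model's choice to share only the association (not the
  marginals) across zygosities reproduces the published growing-pains
  p-value (0.0092 vs printed 0.009) and tracks the others closely, but is
  a modelling choice, validated only at that level.
* Heritability point estimates (ACE path coefficients) are deliberately
  out of scope; the package reports similarity contrasts and lets the
  MZ/DZ comparison carry the genetic inference.
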