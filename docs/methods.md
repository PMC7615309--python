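# Methods

## Model and assumptions

Every scenario is a linear-Gaussian structural model over named variables:
each variable equals a linear combination of its parents plus an independent
Gaussian error, with no interactions, no measurement error and correctly
specified regressions throughout. The four built-in presets encode the
M-structure scenarios the package studies:

* **fig1** — outcome Y partially observed; edges `Y<-X, Y<-Z, W<-Z, W<-U,
  R<-X, R<-U`. W is a collider between Y (through Z) and the latent
  missingness variable R (through U).
* **fig4** — exposure X partially observed; `Y<-X, X<-Z, W<-Z, W<-U, R<-U`.
* **fig6** — as fig4 plus `R<-Y` (outcome-driven missingness; complete
  records analysis is invalid here).
* **fig8-theoretical** — fig1 relabelled with cohort variable names
  (`bmi7, mated, pregsize, bwt`).

All preset coefficients and error variances default to 1 and all means to 0;
these defaults are the study conditions for every simulation in the test
suite and the acceptance script.

Missingness is probit: the observed-data indicator is `R_ind = 1{R <= r}`
for the latent normal R, so the missing proportion is
`pi0 = 1 - Phi((r - mu_R)/sqrt(V_R))`. Binary variables are generated by
thresholding a latent normal (never by a logistic draw), which is the
construction under which the continuous-case results transfer approximately
to binary variables; the logit-to-probit constant 0.6 used to convert odds
ratios into latent-scale covariances is a module constant and an explicit
argument everywhere it enters, since the approximation degrades when the
proportion of complete records approaches 0 or 1.

## Exact moments rather than simulation

Implied means and covariances are computed in closed form from the
reduced-form map `v = (I - B)^(-1)(nu + e)`, not estimated by simulation, so
every downstream formula (conditional regressions via the normal equations,
bias bounds, SE endpoints) is exact. Two independent routes to the same
quantity are kept deliberately distinct and cross-checked in tests: the
maximum bias is computed both from the direct effect-size product formula and
as `|beta_YX|W,R - beta_YX|` by Gaussian conditioning on the implied joint
including the latent R, and the covariance-form (plug-in) expression is
verified against both on randomly drawn M-structure models.

### The selection oracle

Complete records are the sub-population `R <= r`. Because every variable has
a linear Gaussian regression on R with residuals independent of R, selection
shifts means along `Cov(V, R)/V_R` and shrinks the covariance by a rank-one
term proportional to the truncated-normal variance loss. The resulting
moments are exact (the selected joint is not normal, but population least
squares needs only first and second moments), which yields the probability
limit of any complete-records OLS coefficient at *any* missing proportion —
in particular the exact bias curve of the MI estimator against `pi0`, of
which the familiar `pi0 -> 1` maximum is the endpoint. The curve is monotone
and close to straight on the plotted range (best-line deviation under 0.02
against a maximum of 0.2 in the canonical scenario) but not exactly
proportional: it rises slightly faster than linearly at small `pi0` and
approaches the bound only logarithmically slowly near `pi0 = 1`.

## Multiple imputation engine

Imputation is the standard proper Bayesian normal-linear scheme under the
noninformative prior: residual variance drawn from its scaled
inverse-chi-square posterior, coefficients from their Gaussian posterior
given that draw, missing values as linear predictor plus Gaussian noise.
Pooling follows Rubin's rules with the classical small-m degrees of freedom
`(m - 1)(1 + W/((1 + 1/m)B))^2`; the source results do not state a
degrees-of-freedom rule, so the classical one is used and documented here.
Calling the imputer on data with nothing missing is an error rather than a
no-op, because a silent no-op masks pipeline bugs. A Bayesian-logistic
binary imputer is provided for the binary-outcome extension but flagged
experimental: the theory transfers only approximately. OLS fits use the
normal equations directly (the Monte-Carlo harness performs on the order of
a million small fits; per-call overhead matters), with the `n - p - 1`
residual-variance denominator.

The pooled MI estimate converges to the complete-records imputation-model
coefficient `alpha_1^OBS`, but the per-dataset gap has two components:
imputation noise of order `1/sqrt(m)`, and a finite-sample term of order
`1/sqrt(n)` that arises because the analysis model omits W — the
completed-data slope picks up the imputation coefficient on W times the
in-sample `Cov(W, X)`, which vanishes only in population. Convergence tests
therefore run at large n with moderate m rather than at enormous m.

## Simulation conventions

* **Observed records fixed.** Along a missing-proportion sweep the number of
  observed outcome values is held fixed (total rows inflated to
  `n/(1 - pi0)`), so the analytic SE endpoint formulas, which are stated per
  observed record, overlay the whole sweep. Fixing total n instead changes
  the SE curves; the convention is recorded in every sweep's metadata.
* **Threshold calibration.** The missingness threshold is set from the
  implied moments of R by default ("theoretical", exact in expectation); an
  "empirical" mode uses the realized quantile when a fixed realized missing
  fraction matters at small n.
* **Seeding.** All randomness descends from one root seed through
  `numpy.random.SeedSequence`. Per-variable child streams are keyed by a
  stable hash of the variable name, so adding or removing a variable never
  perturbs the draws of the others; per-replicate streams are spawned once
  and reused across grid points (common random numbers), which makes sweep
  curves smooth in the swept parameter.
* **Scale.** Default desk-scale sizes (500 replicates, 1,000 observed
  records, m = 20) keep each study in the minutes range on one CPU; the
  Monte-Carlo tolerance used in tests is four empirical standard errors.

## The SE crossover

In scenarios where including the collider barely improves prediction (the
Y–Z and W–Z paths weakened to 0.5), the MI-with-collider SE starts below the
CRA SE and overtakes it as missingness grows. The quantity being located is
the crossing of the *large-m* SE curves — the theory describes the MI SE "as
the number of imputations increases", and at finite m the pooled estimate
carries an extra `B/m` noise floor that would otherwise hide the crossing
entirely. The default estimator therefore measures the SD across replicates
of the complete-records imputation-model coefficient (exactly the large-m MI
estimator, and free of imputation noise, so tens of thousands of replicates
are affordable); an alternative runs the full m-imputation pipeline and
subtracts the mean between-imputation variance over m. The SE difference is
evaluated on a `pi0` grid with common random numbers, a quadratic is fitted,
and the first root is bracketed. With 24,000 replicates per grid point the
located crossover has a Monte-Carlo SD of roughly 1.5 percentage points;
repeated runs place it near 43% missingness in this scenario.

## Synthetic cohort fixture

`make_alspac_like` generates a cohort-style dataset mirroring the applied
example's structure, not its microdata: binary exposure `mated` (prevalence
0.64, binomial variance ~0.23), rare binary direct predictor `pregsize`
(twin birth, prevalence 0.025, lowering birth weight by 0.91 kg), continuous
collider `bwt` (variance ~0.286 kg^2), continuous outcome `bmi7`, and a
latent U standing for family-level factors that raise birth weight and later
BMI and make follow-up more likely; 40% of outcomes are missing by default.
Parameter values were chosen once to reproduce the headline marginals and
the qualitative applied-example pattern — a detectable collider signature in
screening, a small positive plug-in maximum bias (toward the null), and
visible attenuation of the MI estimate when the collider enters the
imputation model. Because U affects both the outcome and missingness, the
fixture's outcome is mildly missing-not-at-random, as is plausible in the
real setting; complete records there are *not* exactly unbiased, so the
fixture demonstrates patterns, not estimator validity. What passing fixture
tests show is that the workflow detects and quantifies the collider
signature under a realistic generating process; they say nothing about
unmodelled features of real cohorts (clustered twins, skewed BMI,
nonlinearity, multiple incomplete variables).

## Applied workflow choices

* The screening step fits only pairs consistent with a *user-declared*
  causal ordering. Causal direction is a judgment call; the tool does not
  infer it.
* A candidate is flagged as a potential collider when another auxiliary's
  association with the missingness indicator strengthens upon conditioning
  on it by more than 2 standard errors of the change, where the SD of the
  change between nested fits is approximated by
  `sqrt(se_adj^2 - se_unadj^2)` (floored at `0.2 se_adj`). The margin guards
  against "strengthening" that is pure noise around two null associations;
  both the margin and the floor are arguments.
* The plug-in CI is `max bias +/- 1.96 x SE` of the MI estimate that
  includes the collider, with the multiplier configurable; the direction
  note ("towards/away from the null") compares the sign of the maximum bias
  with the sign of the substantive estimate.
* The collider's log odds ratio from screening is conditional on the
  exposure, while the covariance form is written for the marginal
  `Cov(W, R)`; the substitution mirrors applied practice and is carried into
  the result with an explanatory note rather than silently.
* The plug-in value is a *maximum* bias under the assumed structure;
  unmodelled paths can make the realized bias exceed it, which is why the
  result object carries its inputs and caveats rather than a bare number.

## Numerical choices

* Positive-semidefiniteness tolerance for implied covariances: smallest
  eigenvalue >= -1e-10 x largest.
* Collinear predictor sets are rejected (condition number above 1e12), not
  pseudo-inverted.
* The covariance-form denominator can be non-positive for extreme inputs;
  this raises a domain error naming the cause instead of returning a signed
  infinity.
* Degenerate inputs — zero-variance screening dependents, logistic
  separation — produce per-cell error entries in the screen table rather
  than aborting the whole screen.
* Variable order is the topological order of the DAG with declaration-order
  tie-breaks, so all outputs are deterministic.

## Known limitations

Only one variable is ever missing; chained-equations imputation for multiple
incomplete variables is out of scope, as are predictive mean matching,
sensitivity analyses under missing-not-at-random mechanisms, interactions
and non-linear structural equations. The binary imputer is approximate by
construction. The exposure-case maximum-bias expression applies to the
imputation-model coefficient, not the final MI estimator, whose exposure-case
bias is assessed by simulation only.
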