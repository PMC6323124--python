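# Methods

## The question and the estimands

Human lifespan is weakly heritable, but survival into extreme old age
("longevity") clusters in families. The analyses implemented here ask, on
three-generation family data: beyond which birth-cohort survival percentile
do long-lived relatives predict a survival advantage for their kin — i.e.
where is the longevity threshold — and is the association additive in the
number of long-lived relatives, as expected if longevity is transmitted as a
quantitative genetic trait?

The unit structure is a family around one *index person* (IP, generation F2):
their parents (F1), siblings (F2), one spouse (F2), and children (F3).

## Survival percentiles from cohort lifetables

For one sex and birth year, yearly hazards `h_x` define, under the
piecewise-constant-hazard convention, `H_{x+1} = H_x + h_x`, `H_0 = 0`, and
`S_x = exp(-H_x)`. A person's survival percentile is `100 * S(age)` at their
age at death (or last observation); smaller percentile = longer-lived; "top
x%" means percentile <= x. Censored relatives are classified top-x only when
their censoring age already exceeds the threshold age — they have outlived
it — and not-top otherwise; nothing is imputed. Relatives with no age at all
are excluded from both numerators and denominators of every count.

Percentile lookup defaults to integer ages; a flag switches to linear
interpolation of `H` within years. The interpolated variant is what makes
continuous-age calibration exact: sampling lifetimes from a table's own
survival curve and classifying them reproduces the nominal top-10% fraction.
Integer-age lookup (the default, matching yearly registry tables) shifts the
effective boundary by less than one year of hazard; this is irrelevant for
the comparative analyses, which use the same rule on both sides.

Real HMD-dialect cohort lifetables are read directly (`mx` used as the
hazard, `110+` open group kept as the closing interval, `.` imputed by the
last observed value and flagged). A Gompertz–Makeham synthesizer
(`h(t) = lambda + a e^{bt}`, midpoint-discretized) provides a download-free
mortality regime; the defaults `lambda = 0.01`, `a = 5e-5`, `b = 0.1`/year
give a 19th-century-like schedule (top-10% threshold near age 81, consistent
with the ~76–83-year thresholds of historical European cohort tables).

## Exposures, groups, and analytical weights

* **Top-x counts.** Parents counted exactly (0/1/2); siblings and
  aunts/uncles capped at the 2+ category.
* **Mutually exclusive groups.** Units are grouped by the survival percentile
  `p*` of their most long-lived relevant relative into g1..g6 with boundaries
  1, 5, 10, 15, 20: `p* <= 1 -> g1`, `1 < p* <= 5 -> g2`, ..., `p* > 20 ->
  g6`. Intervals are left-open/right-closed so that "belonging to percentile
  p" consistently means percentile <= p (a sibling exactly at the 1st
  percentile is a top-1% survivor, hence g1).
* **Analytical weights.** In sibling-based analyses a unit with `k`
  qualifying siblings out of `S` classifiable contributes `w = k/S`,
  preventing large sibships from dominating extreme exposure categories. An
  IP with siblings at percentiles {1, 6, 8, 30} carries w = 3/4 in a top-10%
  analysis, w = 1/4 at top-5%, and w = 1/4 in the exclusive-group analysis
  (assigned g1, one of four siblings in g1). Reference-category units
  (k = 0) carry w = 1 by default so the comparison group keeps its size; a
  switch provides w = 1/S for sensitivity. Parent-based exposures are
  unweighted (everyone has two parents).
* **Left truncation.** IPs and spouses enter the risk set at the later of
  marriage age and age at first child (they were selected on having both);
  children enter at birth. Rows violating entry < exit are dropped and
  ledgered; exclusion ledgers reconcile exactly with input unit counts.

## Survival models

**Weighted Cox PH with delayed entry.** The partial likelihood uses Efron
tie handling (yearly registry ages make ties common; Efron is the low-bias
default) and risk sets `entry < t <= exit`; a Breslow option backed by the
package's own risk-set engine is exact under the row-duplication identity
(duplicating every row at half weight reproduces the unweighted fit).
Estimates are reported as hazard ratios with 95% Wald CIs; likelihood-ratio
p-values are available per term. Weighted fits use robust (sandwich)
standard errors: analytical weights are importance-style, for which
model-based information is mis-sized (with w <= 1 it typically understates
precision); the sandwich estimator restores nominal type-I calibration.
Constant covariates are dropped and recorded; constant exposures raise;
monotone likelihoods (separation) raise instead of returning a silent
estimate.

**Log-normal shared frailty.** For F3 children the hazard is
`u_i * lambda0(t) * exp(beta' Z)` with `log u_i ~ N(0, theta)` shared within
an IP's sibship. Fitting is penalized partial likelihood: Newton steps in
(beta, b) with the exact covariate block and exact covariate–frailty
cross-block, and a per-subject ("sparse") diagonal approximation of the
frailty block — off-diagonal risk-set couplings between families are
O((family share of risk set)^2) and negligible at hundreds of families. The
variance theta is profiled on the Laplace-approximate marginal likelihood
`l_ppl - 1/2 sum_f log(1 + theta K_ff)`; its SE comes from the numerical
curvature of that profile. Breslow ties are used inside the frailty engine
(simulated ages are continuous, so ties are measure-zero). Recovery checks:
at truth theta = 0.3 the estimator is unbiased to Monte-Carlo error and its
95% CI covers the truth at nominal rate; at theta = 0 the estimate collapses
to the boundary (reported as 0).

**Diagnostics.** Kaplan–Meier and Nelson–Aalen baselines are
left-truncation-aware. Proportional hazards are checked by the
Grambsch–Therneau scaled-Schoenfeld trend test (rank time transform by
default), computed on the package's own risk-set machinery because residuals
under delayed entry are otherwise unavailable; failing covariates are
recommended for stratification.

## The five analyses

1. **Cumulative sweep** (x = 1..60): separate parent (unweighted) and
   sibling (weighted) fits per x, cross-adjusted for the *top-10%* count of
   the other relative kind (fixed cross-adjustment; a switch uses top-x) and
   for the covariate list: sex, birth cohort, sibship size, SES score,
   mother's age at birth, birth order, birth interval, twin birth, religion
   where present. Fits are independent across x.
2. **Exclusive groups**: g1..g5 vs g6, sibling version weighted. The
   threshold is the upper bound of the highest-index group with HR < 1 and
   p < 0.05; non-significant more-extreme groups are treated as power gaps
   (group sizes shrink rapidly toward g1), not vetoes. No multiplicity
   correction here or in analyses 1/3/4 — only the spouse post-hoc is
   corrected.
3. **Top-10% integrated**: joint parent/sibling counts, plus a companion fit
   in the 0-top-10%-parent stratum (transmission without parental longevity).
4. **Children verification**: shared-frailty fit of F3 survival on top-10%
   IP, top-10% spouse, and aunt/uncle counts, with a non-longevous-parents
   stratum variant.
5. **Spouse analysis**: spouses grouped by the IP's own percentile, g1..g5 vs
   g6, then all 15 pairwise Wald contrasts at the Bonferroni threshold
   0.05/15. Contrasts use the fitted covariance; they equal re-referenced
   refits exactly.

Sensitivity variants: maternal/paternal exposure split, exposure-by-sex
interaction, and a seeded half-sample refit with CI-overlap concordance.

## The synthetic data generator

The simulator emulates the family structure the analyses assume. Defaults
are the study conditions: zero-truncated-Poisson sibships with mean 6.3;
founders born 1740–1845 (middle generation ≈ 1767–1902); administrative
censoring in 1940 plus a small loss-to-follow-up rate (≈10–30% censoring
among relatives, ≈1% missing ages); Gompertz–Makeham mortality as above;
covariates (sex, SES 0–9 with a missing code, religion 0–3, twin births at
1.5%, birth intervals averaging 2.5 years) generated independently with
configurable log-hazard effects (all zero by default, so covariates are
clean unless a confounded regime is requested).

Transmission is the additive infinitesimal model on log-frailty: founders
`a ~ N(0, sigma_g2)`; children inherit the mid-parent value plus segregation
noise `N(0, sigma_g2/2)`; individual log-frailty adds `N(0, sigma_e2)`.
Parent–offspring regression of log-frailty then has slope `h2/2` with
`h2 = sigma_g2/(sigma_g2+sigma_e2)`. Defaults `sigma_g2 = sigma_e2 = 0.3`
put half the log-frailty variance under genetic control — deliberately at
the familial-clustering end of the evidence, since the pipeline's job is to
detect transmission when present; null and stronger regimes are single-field
changes. A `lineage_weights` knob makes transmission asymmetric
(maternal/paternal power checks), and `assortative_corr` correlates the
spouse's genetic value with the IP's (emulating a related-spouses region vs
an outbred one). Founders, IPs and spouses are drawn conditional on
surviving to the ages their role implies; siblings and children are
unconditional, so infant mortality appears where registries show it.

What the generator does **not** emulate: secular mortality trends within the
birth-year window (one hazard regime serves all cohorts), marriage markets
and remarriage, migration, sibling-specific shared environment beyond the
genetic component, and informative censoring. Passing tests therefore show
that the statistical machinery recovers known generative structure — not
that real registry estimates are reproduced; the real-data hazard ratios
come from restricted registries and are out of scope.

A separate direct generator (`simulate_frailty_cohort`) draws sibships
straight from the shared-frailty model for variance-recovery studies,
isolating the estimator from the pedigree machinery.

## Numerical choices

* Lifetime sampling is inverse-transform: solve `H0(t) = -log(U)/exp(eta)`
  by 52-step bisection on [0, 135] for Gompertz–Makeham (precision ~3e-14 of
  the bracket) or piecewise-linear inversion for lifetables; conditional
  draws add `H0(t_min)` to the target.
* Cox fits run lifelines' Newton at precision 1e-9 (the default tolerance
  leaves third-decimal coefficient error on small weighted fixtures).
* The frailty profile is maximized on log-theta in [1e-4, 3] to xatol 0.02,
  far below the sampling SE of theta at any realistic family count;
  estimates at the boundary report 0. The covariate Hessian is refreshed
  every fourth inner iteration (it varies slowly; the gradient is exact, so
  the optimum is unchanged).
* Group boundaries are closed on the right (percentile exactly 20 is g5);
  entry-age ties (`entry >= exit`) drop the row with a ledger count rather
  than perturbing ages.
* Mean imputation is used for missing covariate values (SES missing code,
  spouses' unknown demographic fields) — exposures are never imputed.

## Problem sizes in the shipped checks

The test suite and acceptance script run the full designs at desk scale,
chosen as the smallest sizes at which the checked properties have
comfortable statistical margins: null calibration pools exposure-term CIs
over 40 replicates of 1,000 families across all five analyses; threshold
recovery uses 10 seeds x 2,500 families per relative kind; additive ordering
4,000 families at high heritability; frailty recovery 24 seeds x 1,000
sibships (truth 0.3) plus a 1,500-sibship null; spouse regimes 2,500
families per regime. Larger runs sharpen nothing qualitative; all sizes are
single-argument changes.

## Known limitations

* The frailty block's diagonal approximation slightly misstates the Laplace
  determinant when single families dominate risk sets (tiny q with large
  sibships); at the intended scale (hundreds+ of families) the bias is below
  Monte-Carlo resolution.
* Robust SEs for weighted fits are asymptotic; categories with a handful of
  events (e.g. two top-1% parents in small cohorts) keep the usual Wald
  small-sample anti-conservatism.
* The threshold rule inherits the per-group 5% level: with five groups, a
  spurious threshold at g5 appears in roughly 5% of null datasets — by
  design, mirroring the uncorrected group comparisons of the study design.
* One spouse per IP; no competing risks; no time-varying covariates;
  parametric survival regression is out of scope.
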