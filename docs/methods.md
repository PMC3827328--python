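# Methods

## The problem

Selection into medical school (and similar high-stakes pipelines) is judged
by how well a selection measure predicts later performance, but the
correlation observable in entrants understates the measure's worth for three
reasons: entrants are a range-restricted slice of the applicant pool, both
predictor and outcome carry measurement error, and grade inflation piles
candidates against a ceiling, right-censoring the predictor.  The
construct-level predictive validity (CLPV) is the correlation between the
latent constructs behind predictor and outcome across the whole applicant
pool — the quantity a selector actually cares about.  This package estimates
it, attaches honest uncertainty to it, pools it across studies, and turns it
into concrete out-of-range predictions.

## The estimation model

**Seven-parameter censored model.**  The applicant predictor is modelled as
normal with mean and SD (mu_a, sigma_a), observed with right-censoring at a
known ceiling c: uncensored values contribute the normal density, values at
c contribute the upper-tail probability (a Tobit likelihood).  Entrant
(predictor, outcome) pairs are bivariate normal with entrant moments
(mu_i, sigma_i, mu_y, sigma_y) and correlation r_i; censored predictor
values contribute the marginal density of y times the conditional upper
tail of x given y.  Ordinal and binary outcomes are handled through a latent
standard normal cut at thresholds tau (so mu_y, sigma_y are fixed at 0/1):
uncensored-x cells are polyserial-type terms (density of x times the
conditional probability of the category band), censored-x cells are
bivariate-normal rectangle probabilities.  The applicant and entrant
likelihoods are summed; selection is not modelled explicitly — the
correction below handles it afterwards.

Thresholds are fixed in advance from the marginal category frequencies
(two-step, as in standard polychoric practice) rather than sampled jointly;
this is stable, testable, and identifies the remaining parameters cleanly.

**Posterior sampling.**  The posterior uses flat priors on means, a flat
prior on log sigma (density 1/sigma) and uniform(-1, 1) on r_i, and is
sampled with a single-chain delayed-rejection adaptive Metropolis (DRAM)
sampler: a random-walk Metropolis whose proposal covariance is re-estimated
from the chain history every `adapt_interval` (default 100) iterations with
the classic 2.38^2/d scaling, plus one delayed-rejection retry with the
proposal SD shrunk by `dr_shrink` when a proposal is rejected.  The retry
acceptance probability includes the first-stage proposal-density ratio, so
the stationary distribution is preserved (verified against a known Gaussian
target in the test suite).  Chains default to 5,000 iterations with
summaries over exactly the final 2,000: posterior means are the estimates,
posterior SDs the standard errors, and the 2.5th/97.5th percentiles the 95%
interval.  Burn-in is therefore `length - use_last` with no separate knob.
The chain is initialised at the joint maximum-likelihood fit (Nelder-Mead
on transformed parameters: log sigma, atanh r) with the proposal covariance
seeded by the inverse of a central-difference Hessian of the log-posterior.

Equilibrium is checked automatically: each retained parameter trace, thinned
to about 100 near-independent points, is regressed on iteration number, and
a slope significant at p < .01 flags the chain.  `dr_shrink` defaults to
0.5; smaller values make the rescue stage accept almost always, which keeps
the chain technically correct but pushes the overall acceptance rate far
above the informative range — 0.5 keeps default seven-parameter runs at an
acceptance rate of roughly .5 and mixing indistinguishable from the
Hessian-implied posterior scale.

**The correction.**  Per retained draw, the selection ratio is
u = sigma_i/sigma_a computed from the *decensored* (latent) SDs — censoring
shrinks observed SDs, so using observed SDs would overstate selection.  The
indirect range-restriction correction then runs:

1. restricted predictor reliability: r_XXi = 1 - (1 - r_XXa)/u^2
   (selection shrinks true-score variance, not error variance);
2. true-score selection ratio: u_T = sqrt((u^2 - (1 - r_XXa))/r_XXa);
3. disattenuation in entrants: r_TPi = r_i / sqrt(r_XXi * r_YYi);
4. range-restriction reversal on the true-score metric:
   rho = (r_TPi/u_T) / sqrt(1 + r_TPi^2 (1/u_T^2 - 1)).

With reliabilities of one and u of one this collapses to rho = r_i, and for
valid inputs the corrected value is never smaller in magnitude than r_i;
lowering either reliability or u only raises it.  Per-draw values outside
(-1, 1) — possible in extreme draws — are clipped with a warning rather than
rejected, so the chain summary survives; if more than 5% of draws violate
the preconditions the whole estimate is flagged unreliable.  The CLPV
estimate is the mean of per-draw values, its SE their SD, its CI their
percentiles, and the "equivalent N" inverts SE(r) = (1 - r^2)/sqrt(n - 1)
so the estimate can enter a correlation meta-analysis with an honest weight.

Default reliabilities (predictor .815 in applicants, outcome .834 in
entrants) are the observed averages across the selection and examination
measures this package targets; they are used only when a study supplies
none, and their use is always logged.  Cohorts with no applicant data fall
back to median selection ratios by predictor class (A-levels .664,
GCSEs/O-levels .690, aptitude tests .750), also logged.  The restricted
outcome reliability r_YYi is a user input: published reliabilities
sometimes need their own range-restriction adjustment before entry, and
that adjustment is left to the user rather than guessed.

## Meta-regression

Validity coefficients enter as Fisher z with within-study variance
1/(n - 3), where n is the actual N for plain correlations and the
equivalent N for CLPVs; a variance can instead be supplied directly, e.g.
derived from a published CI.  Between-study variance tau^2 uses the
DerSimonian-Laird moment estimator (its weighted-least-squares
generalisation when moderators are present), coefficients come from WLS
with weights 1/(v_i + tau^2), Q_B is the Wald chi-square that all
non-intercept coefficients vanish, and Q_E the residual heterogeneity
statistic.  Pooled means are back-transformed to r.  The Fisher-z/DL route
is the standard Hedges-Olkin random-effects path; a raw-r, sample-size
weighted pooling mode is provided behind a flag as a Hunter-Schmidt-style
sensitivity check.  Intercept-only pooling is verified against the
statsmodels DerSimonian-Laird implementation, and the moderator test's
type-I error is checked by permutation simulation.  Moderator p-values are
two-tailed.

## Closed-form predictions

Attenuation maps a CLPV back to the observed scale:
r_att = rho * sqrt(r_XX * r_YY).  A grade profile's tariff points are
placed in the decensored applicant pool as z = (points - mean)/SD, the
expected standardized outcome is r_att * z, and a baseline tail rate p
(failure or retake among conventional students) maps to a predicted rate
Phi(Phi^-1(p) - r_att * z).  That last step models the outcome of a student
at predictor z as normal with mean r_att * z and **unit** SD; the strict
conditional-normal variant with residual SD sqrt(1 - r_att^2) is available
behind a flag, but the unit-SD convention is the one that reproduces the
published worked examples this module is validated against, and it is the
natural choice when the baseline rate is itself measured on the marginal
outcome scale.  Grade-increment projections are r_att * delta/SD.  The
power formula is the Fisher-z approximation
n = ((z_alpha + z_power)/atanh(r))^2 + 3, reported to the nearest integer
(rounding up instead would disagree with the published worked value by one).

In golden tests the expected-outcome values are checked with the predictor
z rounded to two decimals before multiplying — the convention of the
published table they replicate; rates are checked from full-precision
intermediates.

## The synthetic-data generator

`simulate_cohort` draws latent construct pairs (T, P) bivariate normal with
correlation `rho_true` (default .65), adds measurement error to give
observed scores X and Y with reliabilities `r_XXa` (.815) and `r_YYa`
(.834), admits the top `selection_fraction` (.25) of applicants on a
selection composite, censors X at the `ceiling_quantile` (.90) point of the
applicant pool, and optionally bins Y to an ordinal (default cuts
.03/.15/.90, a fail/resit/pass/honours shape) or binary scale.  The truth
block records the implied seven-parameter values, the realised decensored
selection ratio and the realised restricted reliabilities so recovery tests
can assert against known quantities.

The selection composite has weight `w` (default .8) on the applicant's
standing and sqrt(1 - w^2) on independent other information.  Its basis is
configurable and matters:

- `selection_basis="construct"` (default): the composite weights the true
  score T.  This is exactly the suitability-selection structure the
  indirect (Case IV) correction assumes — selection is independent of the
  predictor's measurement error — and under it the full pipeline recovers
  `rho_true` (the flagship recovery test).
- `selection_basis="observed"`: the composite weights the error-laden
  observed score X; with w = 1 this is classical direct selection, under
  which the *direct* (Thorndike Case II) correction is exact — used as a
  cross-validating oracle in the tests.  Applying the indirect correction
  to cohorts selected this way overcorrects (selection on X also restricts
  X's error variance, violating the unchanged-error assumption), which the
  generator makes easy to demonstrate.

All randomness flows from a single seed; every cohort is regenerable
bit-exactly.  What the generator does not emulate: non-normal latent
constructs, reliability varying across the score range, multi-school offer
dynamics, or the wider never-applied population.  Passing recovery tests
therefore show the estimator is correct *under its own assumptions*; they
cannot show those assumptions hold in any particular real cohort.

## Numerical choices

- Bivariate normal CDF via Owen's T (scipy's `owens_t`), accurate to well
  below the 1e-7 rectangle-probability target; arguments of exactly zero
  are nudged by 1e-12 (error ~4e-13) to avoid the branch ambiguity, and
  |rho| >= 1 - 1e-12 falls back to the degenerate closed forms.  Verified
  against `scipy.stats.multivariate_normal.cdf` and against direct
  quadrature.
- Likelihoods return -inf (not exceptions) for out-of-support parameters so
  the sampler can propose freely; category probabilities are floored at
  1e-300 before logs.
- The joint MLE runs Nelder-Mead on transformed parameters to ~1e-9
  simplex tolerance; with censoring and ordinality disabled it reproduces
  closed-form sample moments to better than 1e-6.
- The log-posterior caches sufficient statistics of the uncensored
  applicant values and (continuous case) uncensored entrant pairs, so a
  posterior evaluation costs O(number of censored points) rather than O(n).
- EM imputation converges when the largest parameter change drops below
  1e-6 (default cap 500 iterations, reported on failure); every column must
  be at least half observed.  The composite is the first principal
  component of the correlation matrix of the standardized, completed table,
  sign-fixed to correlate positively with the row mean.
- z-scoring uses the sample (n - 1) SD throughout.
- Ties at the ceiling are treated as censored (flag = value >= c), which
  covers data reported as "maximum points".

## Problem sizes in the test suite

The recovery test uses ten cohorts of 20,000 applicants (5,000 entrants)
for bias/RMSE and one hundred cohorts of 5,000 applicants for interval
coverage; the censorship-severity and calibration checks use smaller
cohorts and 200 permutation replicates.  These sizes give Monte-Carlo error
comfortably inside the asserted tolerances while keeping the whole suite a
desk-scale run.

## Known limitations

- The entrant pool after selection on a correlated composite is not exactly
  bivariate normal; the censored-normal entrant fit is therefore a
  pseudo-true approximation.  At the default design this contributes a
  small upward tilt (about +.01 on rho at very large n, measured by
  simulation), well inside the reported uncertainty at realistic sizes.
- Left-censoring, interval-censored outcomes and non-normal latent families
  are out of scope.
- The correction takes reliabilities as known constants; their own sampling
  error is not propagated.
- Single-chain sampling by design; no multi-chain convergence statistics.
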