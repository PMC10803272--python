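# Methods

## The model

All pooling happens on the natural-log relative-risk scale. For
observation *i* in study *s(i)*,

    y_i = beta + X_i b + u_{s(i)} + eps_i,
    u_s ~ N(0, gamma),   eps_i ~ N(0, se_i^2),

where `y_i = ln(RR_i)`, `se_i` is the reported sampling standard error
(or `ln(ci_upper/ci_lower)/(2·1.96)` when only a 95% CI is reported),
`X_i` is a row of 0/1 bias covariates, `u_s` a study-level random effect
shared by all observations of a study, and `gamma` the unexplained
between-study variance. Because the exposure is dichotomous, a study-level
random slope on the exposed-vs-unexposed contrast and a study-level random
intercept coincide on the modelled contrast; we implement the single
random effect `u_s`, which also carries the within-study correlation
between a study's repeated observations. `beta` is always reported at the
gold-standard covariate level (all `X = 0`).

Fixed effects are profiled out by generalized least squares;
`gamma` maximizes the restricted likelihood (REML; plain ML available via
`method="ml"`) over a log-scale parameterization with the `gamma = 0`
boundary checked explicitly. The study-blocked covariance
`V_s = diag(se^2) + gamma·11'` is inverted by the Sherman–Morrison
identity, so one likelihood evaluation is O(n). The scalar optimizer runs
bounded Brent with an `xatol` of 1e-10 on `log10(gamma)`, which at the
optima met in practice corresponds to objective changes far below the
1e-8 working tolerance. `beta_se` comes from `(X' V^-1 X)^-1`; the
uncertainty of gamma from the inverse Fisher information, which for this
covariance structure is the closed form

    I(gamma) = 1/2 · sum_s (S_s / (1 + gamma·S_s))^2,   S_s = sum_{i in s} 1/se_i^2,

and is what makes the heterogeneity penalty sensitive to the number of
studies and their reported uncertainty. A single-study dataset fixes
`gamma = 0` with a warning rather than estimating an unidentified
variance.

## Selection cascade and repeat down-weighting

Studies report several non-exclusive effect sizes; the cascade retains,
within each study × outcome: (1) the best-available exposure definition,
judged attribute-by-attribute (smoking status, then location, source,
timing) against ordered priority *tiers* — tiers rather than flat ranks
because, e.g., home-only and work-only exposure are equal-rank components
of the home-or-work reference definition and must be allowed to coexist;
(2) the least granular analysis (whole population over subgroups,
combined endpoints over incidence- or mortality-only, aggregate outcomes
over configured subtype labels); (3) the most-adjusted remainder. Rows
identical on every cascade attribute and group key are true duplicates
and collapse deterministically (smallest SE, then lexicographic id).
Every elimination is written to an audit log with the rule that caused
it.

Retained non-mutually-exclusive repeats within an age–sex–smoking-status
group (`group_key`) are down-weighted by multiplying each of the k
repeats' SEs by √k, so the group's summed inverse-variance weight equals
one observation's. The literal reading — multiplying by k itself — is
exposed as `factor="k"`; √k is the default because it is the
information-preserving correction. Inflation is applied after cascade
selection, to retained records only.

## Bias-covariate selection

Candidate covariates need at least two observations at each level;
identical columns are collapsed to one by a seeded draw. The default
selection strategy ranks candidates by order of entry into the active set
of an L1-penalized weighted regression (LARS-Lasso path on standardized
columns, inverse-variance weights folded into the least-squares problem),
then walks that order adding each candidate to the unpenalized mixed
model and keeping it only if its two-sided Wald test is significant at
alpha = 0.05. No multiple-testing correction is applied. Because the
published description of the step-wise Lasso leaves the composition of
the two ingredients open, two variants ship alongside the default:
`stepwise` (pure forward selection by smallest p-value) and `lasso_refit`
(all path entrants refit jointly, then backward-pruned at alpha).
Coefficients are always reported on the original 0/1 scale from the
unpenalized refit.

## Trimming

Likelihood-based trimming removes `floor(trim_fraction · n)` observations
(default 10%). The algorithm alternates (a) fitting on the current inlier
set and (b) re-ranking *all* observations by their negative marginal
log-likelihood — each observation scored with its study effect integrated
out, i.e. under `N(beta + X_i b, se_i^2 + gamma)` — until the trimmed set
is stable; ties break by observation id so the result is independent of
input order. This hard 0/1 trimming is a deliberate simplification of
continuous trimming-weight schemes; it is labelled as such and behaves
identically in the regimes tested (gross outliers get weight 0 either
way). Datasets with fewer than ten observations are never trimmed, and
trimming never removes more than the stated fraction. Non-convergence
after 100 alternations returns the current iterate flagged
`converged=False`.

## Evidence scoring

With `gamma_q95 = gamma + 1.645·gamma_sd` (a normal approximation to the
95th quantile of heterogeneity, truncated below at the point estimate; an
empirical-draws variant is provided and agrees to Monte-Carlo error):

* interval without heterogeneity: `exp(beta ± 1.96·beta_se)`;
* conservative interval: `exp(beta ± 1.96·sqrt(beta_se² + gamma_q95))`;
* BPRF (harmful): `exp(beta − 1.645·sqrt(beta_se² + gamma_q95))` — the
  5% quantile of the heterogeneity-inclusive risk closest to the null;
  protective risks mirror to the 95% quantile. Computed analytically from
  the normal model; a draws-based cross-check is in the test suite;
* ROS = signed `log(BPRF)/2`; star bands are lower-exclusive /
  upper-inclusive: ≤0 → 1, (0, 0.14] → 2, (0.14, 0.41] → 3,
  (0.41, 0.62] → 4, >0.62 → 5. A ROS of exactly 0.14 is therefore two
  stars;
* zero-star rule: if the interval *without* heterogeneity contains 1, no
  BPRF/ROS is computed and the rating is 0;
* reported rounding: RR and BPRF to 2 decimals; ROS to 2 decimals, 3 when
  |ROS| < 0.01; minimum percent change `(BPRF − 1)·100` to the nearest
  integer.

## Publication-bias diagnostics

Egger's regression is run on post-trim, bias-adjusted model residuals
against their total standard deviations `sqrt(se² + gamma)` — the
quantities the modified funnel plots display — weighted by inverse total
variance. A two-sided slope p-value below alpha flags the pair; nothing
is ever corrected. Fewer than three untrimmed observations, or a
degenerate regressor (all total SDs equal), yields a not-evaluable
result. The residual form (rather than raw effects) keeps the test
consistent with the funnel-plot definition; with a single pooled mean the
two differ only by a constant shift, which the slope is invariant to.

## Synthetic data

The generator emits extraction tables with exactly the structure the
model assumes: per-study Gaussian random effects, Bernoulli bias-covariate
indicators with additive log-RR shifts, log-uniform sampling SEs,
optional planted outliers (fixed shift, optionally random-signed),
optional k-fold non-mutually-exclusive repeats sharing a `group_key`, and
an optional publication-bias mode in which results below the true mean
from the noisier half of studies (SE above the geometric midpoint of the
SE range) are censored. A master seed fans out to per-study substreams,
so lengthening a table never perturbs earlier studies.

Defaults are one fixed choice echoing the secondhand-smoke literature's
regime: 40 studies of 1–3 observations, true pooled RR 1.2
(`beta0 = ln 1.2`), `gamma = 0.04`, SEs log-uniform on [0.05, 0.3]
(CI width ratios of roughly 1.2–3.2), no outliers, no repeats.
Simulation studies state their own sizes: parameter recovery and coverage
use 200 replicates of 100 studies; trimming robustness 200 replicates of
50 studies with 10% outliers shifted +2; covariate selection 200
replicates of 50 two-observation studies with one real (+0.5) and two
null covariates; Egger calibration 500 symmetric replicates of 30
single-observation studies and 200 censored replicates of 50 studies.

What the generator does *not* emulate — and hence what passing tests do
not establish about real extractions: correlated bias covariates,
non-Gaussian study effects, SEs correlated with effect size under the
null, misreported CIs, or the literature-screening process itself.
Parameter recovery on this generator shows the estimator is correct under
its own assumptions, not that those assumptions hold for any given
literature.

## Known limitations

* The cascade implements the documented priority rules; real extractions
  contain judgment calls (e.g. which of two publications on one cohort to
  keep) that are treated as upstream curation.
* Wald-based covariate tests at alpha = 0.05 are slightly anticonservative
  when gamma is poorly identified (few studies); observed null selection
  is ≈5–6% in the tested regime.
* The BPRF quantile uses the normal approximation throughout; heavy-tailed
  deviations from the mixed model are only addressed through trimming.
* Asymmetric CIs inconsistent with a lognormal sampling model are
  converted with the symmetric-in-log formula without adjustment.
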