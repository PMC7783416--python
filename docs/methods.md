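# Methods

This note documents the generative model, the analysis conventions, and
the numerical choices behind `emosub`, in the order the pipeline runs
them.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Cohort generator

**Latent model.**  Each participant carries three domain abilities
(recognition, learning, regulation) in SD units:

    ability = group_shift + B' (age − 14, IQ − 100, male) + noise_sd · u
              − deficit_shift · d,

with `u ~ MVN(0, domain_corr)` and `d ∈ {0,1}³` drawn from a group-specific
mixture over the eight deficit cells (the subsets of
{recognition, learning, regulation}).  This is the minimal model under
which the person-centered classifier's estimand — the prevalence of each
cell — is well defined: the generator owns the truth the pipeline is
asked to recover.  The real study provides no generative model, so
`domain_corr` (default 0.3 off-diagonal) and the covariate slopes are
free parameters; they are removed again by the adjustment stage and only
shape realism, not the estimand.

**Defaults and units.**
- `deficit_shift = 1.8` SD: places a deficient domain's expected factor
  score well below the −1.28 SD normative cutoff while keeping
  classification imperfect (misclassification in both directions), so
  recovery is a genuine test.
- `group_shift_cd = −0.15` SD for all CD draws: produces the small
  dimensional case–control effects typical of this literature without
  touching the cell mixture.
- Ages uniform on [9, 19); brackets closed on the left: [9,13), [13,16),
  [16,19), labelled 9–12 / 13–15 / 16–18.  IQ is drawn truncated at 70
  (the exclusion criterion), SES and sex ratios per group from the
  published sample table.
- The TDC cell mixture defaults to independence at 10% per domain — the
  neutral assumption for a screened control population.
- The shipped `fixtures/replication.yaml` sets the CD mixture from the
  published prevalences (margins 23/13/18%, no deficit 56.3%, all three
  1%).  The three pairwise cells are not published; they are fixed at
  4.0/2.3/2.0% — any split satisfying the margin identities gives the
  same margins and aggregates.  The fixture also sets `noise_sd = 0.5`
  (high separability): parameter-recovery runs are meant to test the
  pipeline's wiring, not the noise floor of a particular task battery.

**Risk structure.**  Risk factors are drawn *conditional on* the latent
deficit flags (e.g. maternal smoking with a log-odds ratio of ln 3.2
given a learning deficit, CD only), which plants recoverable
associations without distorting the configured margins.  Optional
per-domain logit tilts of the cell mixture by sex or IQ exist for
planting demographic effects; they are off in the replication fixture.

**Questionnaires.**  YPI items follow a graded (ordered-logit) response
model on a participant-level callous-unemotional latent; the group means
of that latent are solved numerically (Gauss quadrature + Brent root
finding) so that the *scored* LPE proxy — two or more of the three
CU-trait subscales containing at least one "applies very well" (4)
response — hits the configured prevalences (43.7% CD / 18.3% TDC).
Because the YPI has no 1–50 item numbering that is stable across
versions and translations, the 3 × 5 CU
item map in `emosub.scales` is this package's own fixed convention and
is the single source of truth for generator and scorer alike.  RPQ items
use the published 11 reactive / 12 proactive split with ordered-logit
models on an aggression latent.  CD symptom counts are 3 + Binomial(12,
0.204) for cases (matching the published mean of ~5.45) and 0 with rare
subthreshold exceptions for controls.

## Task simulators and scoring

All twenty analyzed variables are error scores; reaction times are not
simulated because no RT variable enters the analysis.

**Emotion Hexagon.**  5 blocks × 30 morphs (6 continua × 5 morph levels).
P(correct label) = logistic(intercept_morph + 1.1 · ability), with 90:10
morphs easier than 70:30 (intercepts 2.2 / 1.3); errors fall on the
continuum's other prototype with probability 0.7, otherwise uniformly on
the remaining four labels; 1% timeouts.  Scoring: each expression is
scored on its 90:10 and 70:30 morphs over both continua containing it
(4 per block × 5 blocks = 20 trials), 50:50 morphs are never scored, and
timeouts count as incorrect — the only assignment consistent with the
0–20 per-expression range.  Note the *log* contains 30 trials at 50:50
(6 continua × 5 blocks); they are design filler, not data.

**Passive Avoidance.**  10 blocks × 8 stimuli (4 reward, 4 punishment
magnitudes 1/700/1,400/2,000); block 1 is practice and never scored
("including one practice block" implies it is not test data).  Each
stimulus has a response propensity starting at logistic(bias), where
`bias ~ N(0, 1)` is a participant response-bias trait; feedback arrives
only on responses (the defining asymmetry of passive avoidance):
rewarded responses push the propensity up, punished responses down, by a
learning rate `logistic(−0.3 + 0.8·mag/2000 + 1.2·ability)` for
punishment and a 0.25-weighted ability term for reward.  This is the
simplest model producing magnitude-sensitive commission gradients, and
the bias trait reproduces the empirical signature of this task: reward
omission errors anti-correlate with punishment commission errors, so the
learning component loads them with opposite signs.  The point bank
(start 10,000) is tracked in the log.

**Emotional Go/Nogo.**  6 pairing blocks × (35 go + 13 nogo).  P(false
alarm | nogo) = logistic(−1.4 + interference_pairing − 1.0 · ability),
with small per-pairing interference offsets; go responses occur with
probability 0.97 and are logged but unused (only nogo false alarms are
analyzed).  Scoring: 100 × nogo responses / 13 per pairing.

**Batch samplers.**  For cohort-scale runs the scored variables are drawn
directly from the same trial distributions (binomial counts; the PA
propensity recursion vectorized over participants), which is
distributionally identical to simulating logs and scoring them; the test
suite checks that equivalence against the trial-level simulators.  Task
psychometric slopes were fixed once so that each variable block clears
the conventional internal-consistency floor (Cronbach's α ≥ 0.70, reward
variables reverse-keyed) on a default cohort.

## Adjustment

Per variable, OLS of the raw score on age, IQ and a sex indicator;
residuals for all rows are standardized by the fit-sample residual SD
(population convention, ddof = 0), giving columns with mean 0 and SD 1
over the fit sample and zero sample correlation with each covariate.
The fit sample defaults to the pooled case–control sample (the analysis
adjusted all scores before a PCA that included everyone);
`controls_only` implements the normative alternative, in which case
scores are case-shifted relative to the control norm.  Complete cases
only; zero-variance and covariate-collinear inputs raise typed errors.

## Factor model

**Diagnostics.**  Pearson correlations of the 20 z-scores; the
Olkin–Pratt correction `G(r) = r · ₂F₁(1/2, 1/2; (n−2)/2; 1−r²)` is
applied element-wise before averaging within/between the three domain
blocks.  For (n−2)/2 ≥ 100 the hypergeometric factor is summed directly
from its Gauss series (a few terms suffice; SciPy's `hyp2f1` is slow and
inaccurate in the z → 1 regime of near-zero correlations at large n).
CIs come from a 2,000-resample percentile bootstrap over participants;
the within-vs-between contrast is a Fisher r-to-z statistic
`(atanh r̄_w − atanh r̄_b) / sqrt(2/(n−3))` (the study does not state its
CI or contrast method; these are the package's conventions).  KMO is the
standard partial-correlation ratio (pseudo-inverse with a warning when
the correlation matrix is singular); Bartlett's statistic is
`−(n−1−(2p+5)/6)·ln|R|` with df = p(p−1)/2 (= 190 for the 20-variable
battery), undefined (typed error) for singular R.

**PCA + varimax.**  Eigendecomposition of the correlation matrix, k = 3
retained a priori (no eigenvalue-greater-than-one rule).  Varimax with
Kaiser normalization is iterated by pairwise planar rotations;
convergence requires both a criterion change < 1e−8 *and* a maximal
sweep rotation angle < 1e−9 (the criterion is flat at the optimum, so
the angle condition is what buys loading-level accuracy);
non-convergence after 1,000 sweeps raises an error carrying the
criterion trajectory.  Column signs are oriented majority-positive over
salient loadings (|λ| ≥ 0.30), ties broken by the salient sum — signs
are reported, never forced, so the learning component's opposite-sign
reward loadings survive.  Components are sorted by rotated eigenvalue
(post-rotation column sums of squared loadings — the "eigenvalues"
reported by the pipeline are explicitly post-rotation) and assigned to
domains by a bijective assignment maximizing mean |loading| per task
block.  Rotation preserves communalities and total retained variance;
both are asserted in the tests.

**Scores.**  Anderson–Rubin scores are computed as the regression-method
transform `Z R⁻¹ Λ` orthonormalized by the symmetric inverse square root
of its sample covariance — mean 0, SD 1, exactly uncorrelated, by
construction.  For the deficit stage the scores are *performance
oriented*: a component whose salient loadings point in the error
direction is negated, so "bottom of the distribution" always means
"worst performers".

## Deficit classification

Cutoffs are empirical q-quantiles (default q = 0.10) of the control
factor scores within each age bracket.  Conventions the study leaves
unstated, fixed and exposed here:

- Quantile rule: linear interpolation of order statistics (the common
  statistics-software default); `nearest_rank` available by config.
- Boundary: a score exactly at the cutoff is deficient ("within the
  bottom 10%" read inclusively).
- Controls are classified in-sample against their own bracket cutoffs
  (no leave-one-out), so the control per-domain flag rate equals q
  exactly when bracket sizes divide 1/q.
- Brackets below 20 controls warn; empty brackets raise.

The Venn summary reports per-group cell counts/proportions, domain
margins, and {≥1, exactly 1, exactly 2, all 3, none} aggregates, plus
Pearson chi-square contrasts (no continuity correction) of per-domain
deficit frequency between groups.  `independence_expectation` gives the
binomial closed forms P(≥1) = 1−(1−q)^k and P(exactly m) = C(k,m) qᵐ
(1−q)^{k−m}; at q = 0.10, k = 3 these are 27.1% and (for all three)
0.1%.  A published aside expects "≥30%" of controls deficient in at
least one domain under independence; the closed form is 27.1%, and this
package reports the closed form.

## Group statistics

**Mixed ANOVA.**  3 (domain, within) × 2 (group, between).  Sums of
squares are computed by model comparison with sum-to-zero coding: the
between-subject stratum on subject means (group vs. subjects-within-
groups), the within stratum on subject-centered data with the domain
effect entered before the interaction — an additive decomposition
(SS_total is asserted to split exactly) that coincides with Type III in
the balanced case; the test suite cross-checks a balanced fit against
`pingouin.mixed_anova` to machine precision.  Partial η² =
SS_effect/(SS_effect+SS_error) with 95% CIs by noncentral-F inversion
(Smithson construction; lower bound clamped at 0), benchmark labels at
0.01/0.06/0.14, Greenhouse–Geisser ε reported alongside uncorrected df.
Published df for this design (2,500)/(1,250) are internally inconsistent
with n = 1,252 (they would require n = 1,251 complete cases); the
package reports the df implied by its actual n.  Post-hoc per-domain
group contrasts are pooled-variance t tests, Bonferroni-corrected over
the three domains.

**Logistic discrimination.**  Newton/IRLS fit (tol 1e−10) of group on
the three domain scores; complete separation is detected per predictor
and raised as a typed error, and a stationary point with a numerically
zero gradient is accepted when the step-halving criterion trips on flat
likelihoods (rare outcomes).  Reported: likelihood-ratio model χ²(3),
per-predictor Wald χ² and odds ratios, Hosmer–Lemeshow over 10 risk
deciles (df = groups − 2), and sensitivity (CD correct) / specificity
(TDC correct) at a 0.5 posterior cutoff (configurable; whether the
original analysis used 0.5 or the base rate is unstated) with Wilson
score CIs.

## Correlates

LPE/CU and RPQ scoring as defined under the generator (same item maps).
Association layer, CD subset: one linear (continuous outcome) or
logistic (binary outcome) model per clinical variable with the three
deficit flags as simultaneous predictors; deficient-vs-intact contrasts
per flag (chi-square for proportions, Welch t for means — the variance
assumption is not stated in the source analysis, Welch is the safer
default; a pooled option exists); one logistic model per domain flag on
the seven risk factors.  P-values are uncorrected, as in the original
exploratory analysis; a Benjamini–Hochberg option exists but is off by
default.  Degenerate inputs (constant outcomes or flags, separation,
singular Hessians) are skipped with a record in the result rather than
failing the run.  Missing YPI items are a validation error — no
prorating, since the endorsement rule's behavior under missingness is
undefined.

## Orchestration and reproducibility

One global seed spawns independent substreams (NumPy `SeedSequence`) for
the cohort, the task simulators and the bootstrap; all other stages are
deterministic functions of their inputs, so a rerun with the same config
and seed is byte-identical at the file level (asserted in the tests).
The manifest records the config hash and per-file SHA-256 digests.

## Problem sizes

The test suite exercises the full pipeline at the design's published
sample sizes (542 + 710) and the acceptance script at tenfold size
(5,420 + 7,100), where multinomial standard errors on the cell
prevalences drop below one point; independence simulations use 10⁵
controls; oracle fixtures use 6–20 rows.  These sizes are the package's
reference configurations for stable Monte-Carlo estimates.

## What passing tests do and do not show

The generator emulates the *statistical skeleton* of a multisite
case–control study: marginal demographics, a latent deficit mixture,
psychometrically plausible task error distributions, calibrated scale
prevalences, planted risk associations.  It does not emulate site
effects, attrition, missing data, practice/order effects, RT dynamics,
item-level scale semantics beyond the scoring rules, or any real
covariance between demographics and task engagement.  Passing recovery
tests therefore show that the pipeline's statistics are implemented
correctly and that the person-centered estimand is recoverable under
the stated model — not that the model is true of any real cohort.

## Known limitations

- The three pairwise deficit-overlap cells of the replication mixture
  are conventions (the source publishes only margins and aggregates).
- The Fisher contrast of mean correlations treats the two means as
  independent; a dependent-correlations contrast would be slightly
  conservative here.
- Unbalanced-group within-stratum SS use the sequential (domain-first)
  decomposition; software defaulting to Type III will differ in the
  third decimal for markedly unbalanced designs.
- The logistic stage reports in-sample classification; no ROC/threshold
  optimization or cross-validation is attempted by design.
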