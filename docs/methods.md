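# Methods

`peerlca` re-creates, end to end, a baseline analysis pattern used in
school-based peer-led physical-activity interventions: identify "peer
supporters" by peer nomination, profile the whole cohort with a latent class
model over psychosocial and activity indicators, and ask how supporters are
drawn from those classes. Because the motivating cohort data are not public,
the package ships a first-class synthetic-data generator whose defaults
encode the published study conditions, and every downstream stage is
validated against it.

## The model

For individual $i$ with indicator vector $x_i$ (8 continuous on $[0,1]$,
4 binary) the likelihood is a $K$-component mixture

$$f(x_i) = \sum_{k=1}^K \pi_k \prod_{j \in \mathrm{obs}(i)} f_{kj}(x_{ij}),$$

with class-specific normal densities $N(\mu_{kj}, \sigma^2_{kj})$ for
continuous indicators and Bernoulli$(\theta_{kj})$ for binary ones.
Indicators are conditionally independent given class, with one exception:
weekday MVPA and sedentary minutes are bivariate normal within class with a
single covariance $c$ **shared across classes**, reflecting the mechanical
coupling of the two quantities (both are derived from the same bounded wear
time). Within class $k$ the pair's covariance matrix is
$[[\sigma^2_{k,\mathrm{mvpa}}, c], [c, \sigma^2_{k,\mathrm{sed}}]]$.

Missing cells drop out of the row's likelihood (full-information maximum
likelihood under MAR): a row contributes only its observed cells, a row with
one member of the covariance pair observed contributes that member's
univariate marginal, and a fully missing row contributes nothing (its
posterior is the prior $\pi$).

### Estimation

EM with random multi-start. Starts are Dirichlet-random posterior matrices;
every start runs a fixed number of short iterations (default 30) and the
best few continue to convergence (relative log-likelihood change below
`tol`, default 1e-7). E-steps are log-sum-exp stabilized. M-steps are
posterior-weighted moments over observed cells; the shared covariance pools
the posterior-weighted cross-moment over classes using only rows where both
pair members are observed (rows with one member missing inform the means and
variances through the marginal — exact FIML for the bivariate block reduces
to the marginal in that case).

Numerical guards: a variance floor (1e-4 on the unit-interval scale) and a
Bernoulli clamp (1e-4) prevent degenerate spikes; the pooled shared
covariance is shrunk, if necessary, to keep every class's 2x2 block positive
definite. These constrained updates make the M-step a *generalized* EM step:
the likelihood can, rarely, dip — at convergence by ~1e-7 relative, or more
visibly on degenerate starts where a class collapses. The EM loop therefore
refuses any decreasing step: it reverts to the previous (better) state and
stops that run, so reported trajectories are monotone by construction; the
largest refused dip is recorded in `FitResult.max_ll_decrease`. Multi-start
makes ending a run early harmless.

Classes are relabelled canonically (descending mixing weight, ties broken by
the first continuous mean) so fits are reproducible; simulation studies map
fitted classes back to generating classes by Hungarian matching on the mean
profiles.

Parameter count for the default structure: $(K-1) + 8K + 8K + 1 + 4K$
(mixing, means, variances, shared covariance, Bernoulli probabilities) —
105 parameters at $K=5$.

### Class enumeration

`select_classes` fits a K range and reports, per K: log likelihood, BIC
($-2\ell + p\ln n$), relative entropy
($1 - \sum_{ik} -p_{ik}\ln p_{ik} / (n \ln K)$; 1 = perfect classification,
0 = random; undefined at $K=1$), the smallest estimated class share, and two
K vs K-1 tests. No automatic winner is declared beyond a min-BIC convenience
flag, since enumeration in practice combines statistics with parsimony and
interpretability.

- **Bootstrap likelihood-ratio test (primary).** Complete datasets of size
  $n$ are simulated from the fitted $K-1$ model, the observed missingness
  pattern is re-applied (the simplest pattern-preserving choice), both
  models are refitted with reduced starts, and
  $p = (1 + \#\{LRT_b \ge LRT_{obs}\}) / (B_{used} + 1)$. Non-converging
  replicates are dropped and logged. Default $B$ at desk scale is 49-99.
- **Adjusted likelihood-ratio test (secondary).** The exact
  Lo–Mendell–Rubin construction used by commercial software is not
  reproducible here; the variant implemented and documented is
  $2\Delta\ell \cdot (n - 2 - \Delta p)/n$ referred to a chi-square with
  $\Delta p$ degrees of freedom — a Bartlett-style small-sample rescaling
  with a reference distribution of convenience. It is reported as a
  secondary descriptive criterion only; calibration claims rest on the
  bootstrap test.

### Distal outcome (BCH)

With a fit in hand, the proportion of each class selected as peer
supporters is estimated by the Bolck–Croon–Hagenaars correction:
$Q_{ks} = \sum_i p_{ik}\mathbb{1}(\mathrm{modal}_i{=}s) / \sum_i p_{ik}$ is
the classification-error matrix, and individual $i$ receives weight row
$(Q^{-1})_{\mathrm{modal}_i,\cdot}$. Weights may be negative by
construction; their column sums estimate class sizes, and
$\hat\rho_k = \sum_i w_{ik} y_i / \sum_i w_{ik}$, truncated to $[0,1]$ after
estimation (the weights are untouched, preserving the estimator). When
classification is perfect the correction reduces exactly to the modal
crosstab. A near-singular $Q$ (condition number > 1e8) is refused with a
diagnostic: classification entropy is too low for the correction.

Uncertainty: a percentile **cluster bootstrap resampling whole schools**
(default 500 resamples) rather than analytic sandwich standard errors. This
is a deliberate divergence from the analytic cluster-robust BCH machinery of
commercial SEM software: the bootstrap is transparent, assumption-light, and
honours the clustering of pupils within schools, which is the design feature
that matters here. Per-individual weights are held fixed across resamples.

## Indicator construction

- Scale scores are means of answered items, missing when fewer than half the
  items were answered (the source instruments' own missing-item rule is not
  published; half-items is the conventional default).
- Amotivation (0-5 scale) is dichotomized at <= 0.25 = "very low" (zero or
  near-zero responses dominate the instrument in this population, so it
  cannot be treated as normal); the peer-norm scores (0-6) at low (0-2) vs
  high (3-6), the midpoint of the range. Values strictly above the low band
  (e.g. 2.5) are high. Both cuts are monotone by construction.
- Continuous indicators are affinely rescaled to $[0,1]$ with *declared*
  ranges — instrument ranges for psychosocial scores, fixed physiological
  maxima for minutes (MVPA 0-300, sedentary 0-1080, screen 0-960/weekday) —
  so the transform is data-independent, invertible and stable across runs.
  Observed values outside a declared range are an error, never clipped.
- No rows are deleted: the matrix keeps every participant with a missingness
  mask, since the model consumes partial rows via FIML.

## Accelerometry

Count streams are collapsed to 10 s epochs (trailing partial window dropped
and logged), non-wear is removed as maximal runs of >= 60 min of zero counts
(strict zeros, no interruption tolerance), and wear epochs are classified
with youth count thresholds scaled proportionally from counts-per-minute
(sedentary <= 100 cpm, MVPA >= 2296 cpm; i.e. 16.7 and 382.7 counts per
10 s). Whether the original thresholds should be re-derived rather than
proportionally scaled for 10 s epochs is not settled; proportional scaling
is the default and the values are configurable. A valid day has >= 500 wear
minutes between 06:00 and midnight (a 06:00-noon reading of the window would
be arithmetically impossible: 360 min cannot contain 500), participants need
>= 2 valid days, weekday averages use valid weekdays only (missing, not
zero, when none exist), and the 60 min/day guideline flag averages MVPA over
all valid days including weekends. Days are local calendar days; epochs
belong to the day of their start time with half-open intervals.

## Nomination

Up to five names for each of four questions (respect, leader, trust,
lookup). Cleaning drops out-of-roster names, cross-school nominations,
self-nominations, exact duplicates, and ambiguous names (never guessed). A
nominee receives at most one vote per nominator regardless of question
multiplicity. Each school's cutoff is the vote count at rank
$\lceil 0.18\, n \rceil$ of the descending vote distribution, floored at one
vote; everyone at or above the cutoff is a supporter. Ceiling plus tie
inclusion means the supporter fraction is always >= 18% and typically
19-23%. The denominator is the full roster of participants by default
(whether the original procedure counted non-participants is ambiguous; the
fraction is configurable). Ballot-only nominators (pupils who nominate but
contribute no data) are representable and included by default (54 in the
default configuration).

## The synthetic cohort generator

Defaults encode the study conditions: 20 schools with sizes in [31, 142]
fixed to sum to 1558; five classes with mixing (0.19, 0.18, 0.28, 0.23,
0.12); eight continuous and four binary indicators generated from the
mixture above with shared MVPA-sedentary covariance -600 min^2
(correlation about -0.35); questionnaire missingness 2-4% and activity
missingness 8% (as MCAR masks, or structurally through wear compliance when
the epoch-level stage is enabled); MAR-given-class available as a mechanism;
demographic passengers (family affluence via Binomial(9, p_k) matching the
published class contrast 7.5 vs 6.1; free-school-meals 5% vs 21%; ethnicity
89/11 class-independent and flagged uncalibrated — the source reports no
further demographic-by-class structure).

Class mean profiles follow the published narrative (an autonomous/confident
class down to an amotivated/low-confidence class) and are centred so
mixing-weighted marginal means reproduce the published whole-sample table
exactly (MVPA 51 min, sedentary 591, screen 390, self-esteem 0.67, ...).
Two calibration points were fixed once against published properties of the
real 5-class fit and then frozen:

1. **Separation.** Within-class SDs for bounded scores are capped so that
   boundary clipping stays rare (<1% of continuous draws overall; clipping
   is logged) — which means marginal SDs of bounded scores undershoot the
   published SDs (a normal mixture on [0,1] cannot reproduce both). The
   contrast between the two low-confidence classes runs through controlled
   motivation and amotivation — the distinction the published 4-class model
   failed to make — which yields min-BIC at K=5 and relative entropy ~0.82
   on default cohorts (published fit: entropy 0.750, all average
   classification probabilities >80%, BIC still decreasing past 5 classes).
2. **Nomination attractiveness** is class propensity times individual
   lognormal popularity (log-SD 1.0). Pure class propensity makes selection
   near-deterministic; with heterogeneity the default cohort yields a
   supporter share of ~0.195 and supporter composition of ~40% from the
   most autonomous class and ~5% from the amotivated class (published:
   23%, 42%, 7%).

What the generator does **not** emulate: friendship-network topology (no
degrees, transitivity or cliques — nomination attractiveness is the minimal
class-dependent structure), skewed/zero-inflated response distributions
(bounded normals with clipping instead), longitudinal follow-up, and any
demographic-by-class structure beyond the two published contrasts. Passing
tests therefore demonstrate correctness of the estimators under the model's
own assumptions plus mild boundary misspecification — not robustness to the
full messiness of real questionnaire and accelerometer data.

Determinism: one root seed; every component (cohort, missingness, ballots,
epochs, model starts, bootstraps) draws from its own child stream via fixed
spawn keys, so adding a component never perturbs the others, and the full
pipeline is bit-reproducible (asserted by checksum comparison).

## Problem sizes used in validation

Chosen as desk-scale defaults: parameter recovery and FIML robustness at the
default cohort size (n = 1558, one fit each); enumeration consistency over
20 seeds with K in 3-7 and 6 starts per fit; bootstrap-LRT calibration with
50 null replicates of n = 250 and B = 49 (plus 10 power replicates);
BCH recovery at n = 1558 with supporter probabilities 0.40-0.07 and a
shrunken-separation variant (entropy ~0.57) for the modal-vs-BCH bias
comparison; interval coverage over 100 cohorts of 20 schools x 40 pupils
with 300 bootstrap resamples; determinism on two full pipeline runs.

## Known limitations

- The shared covariance is estimated from complete pairs only; under MAR
  missingness concentrated on one pair member this is mildly inefficient
  (not biased under MCAR; the acceptance experiments cover the study's
  missingness pattern).
- The adjusted LRT variant is not the one used by commercial software;
  treat its p-values as descriptive.
- BCH interval coverage is by cluster bootstrap with fixed weights; with
  very few schools (<10) percentile intervals will undercover.
- Bounded scores are clipped normals, so extreme-class means carry a small
  (documented, <0.02 on the unit scale) clipping bias that the recovery
  tolerances absorb.
- 9-10 class fits on default cohorts routinely fail to converge or hit
  floors (mirroring the instability such over-fitted models show in
  practice); the selection table flags them rather than hiding them.
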