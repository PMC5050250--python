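# Methods

This note documents the statistical models implemented by `replibayes`, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot establish.

## The scientific question

A collection of original psychology studies was independently replicated by
outside teams. Some original publications contained *internal conceptual
replications* — the same effect demonstrated more than once, with varied
designs, inside the original paper. Two accounts make opposite predictions
about whether internal replication should predict independent replication
success:

* **Unknown-moderator account.** Effects are real but context-dependent;
  an effect that survived intentional design variation (internal conceptual
  replication) should also survive the smaller procedural differences of a
  direct replication. Prediction: internally replicated effects replicate
  *more* often.
* **QRP account.** Questionable research practices (optional stopping,
  publication bias, HARKing) can manufacture both the original finding and
  its internal replications, so internal replication carries no signal.
  Prediction: *no difference* in replication success.

The package turns this contrast into a Bayes-factor model comparison on a
2×2 contingency table, plus supporting analyses of nine reproducibility
predictors, and provides a generative simulation of both accounts so the
whole pipeline can be validated end to end without the external dataset.

## Contingency Bayes factors (`contingency_bayes`)

Sampling plan: independent multinomial — the two group totals are fixed by
design, each row is binomial. Priors are Dirichlet with concentration
`a = 1` (uniform): independent Beta(a, a) per row under the alternative, a
single shared Beta(a, a) success probability under the null. Marginal
likelihoods are closed-form Beta functions; the multinomial coefficient is
omitted because it cancels from every Bayes factor. `a = 1` with the group
totals as the fixed margin mirrors the standard default for a designed
two-group comparison.

One-sided (order-restricted) factors use posterior restriction:

    BF_+0 = BF_10 × P(p_d > p_o | data, alternative) / (1/2),

with the posterior direction probability computed from the independent
Beta(a + y_i, a + n_i − y_i) posteriors. Two routes are implemented:
Monte-Carlo sampling (default, 100,000 draws, seeded) and deterministic
1-D quadrature of `∫ f_d(p) F_o(p) dp`. Sampled ties (p_d = p_o exactly)
count one half; the event has measure zero and the rule exists only so the
estimator is fully specified. At 100,000 draws the Monte-Carlo standard
error of a direction probability near 0.1 is ≈ 0.001, which moves the
one-sided BF by well under 5%.

Estimation draws the two success probabilities from the same posteriors and
summarises `logit(p1) − logit(p2)` (log-odds ratio) or `p1 − p2` by the
median and an equal-tailed 95% interval. Percentile intervals are used here
(the estimands are smooth unimodal functionals of Beta draws); HDIs are
reserved for the robust model below. The published predictor rows print
medians on the proportion-difference scale while the headline
reproducibility row prints a log-odds median; since the source is ambiguous
about which estimand belongs where, every categorical report row carries
both, explicitly labelled.

## Group-difference Bayes factors (`group_difference_bayes`)

**JZS t-test.** The standardized effect δ = (μ1 − μ2)/σ has a Cauchy(0, r)
prior with r = √2/2 ("medium", the conventional default at the time the
reference analysis was run), σ² a Jeffreys prior. Conditional on δ the
pooled-variance t statistic is noncentral-t with df = n1 + n2 − 2 and
noncentrality δ·√(n1 n2/(n1 + n2)), so BF_10 is a single adaptive-quadrature
integral of the noncentral-t density against the Cauchy prior, split at 0
and at the δ maximising the likelihood so the quadrature never misses a
mass concentration. Directional factors again use posterior restriction.
The test suite checks this route against the independent g-mixture form of
the same marginal and against an external implementation.

**Robust estimation (BEST-style).** Each group's observations are
Student-t with group-specific mean and scale and a shared normality
parameter ν, so heavy tails do not drive the estimated difference. Priors
follow the BEST conventions relative to the pooled data: means are normal
centred on the pooled mean with SD 1000 × pooled SD; scales are uniform on
[pooled SD/1000, pooled SD × 1000]; ν = 1 + η with η exponential of mean 29
(prior mean ν ≈ 30, straddling near-normal and heavy-tailed regimes).
The sampler is a single-chain Metropolis-within-Gibbs with per-parameter
random-walk steps adapted toward ≈ 40% acceptance during burn-in and frozen
afterwards — chosen for desk-scale reproducibility, not sampler novelty.
Scales and η are sampled on the log scale with the Jacobian included.
Convergence is monitored by a potential-scale-reduction diagnostic on four
equal splits of the chain; a value above 1.05 flags the result as
non-converged rather than failing silently. Intervals are 95% HDIs by
default (the BEST convention), percentile optionally. Calibration is
verified empirically: across 200 synthetic two-group datasets (n = 50 per
group, unit scales, true difference 0.5) the 95% interval covers the truth
at the nominal rate within ±4 points.

## QRP simulations (`qrp_simulator`)

Observations are unit-variance normal; tests are standard t-tests with
closed-form p-values. Everything is vectorised over simulated studies and
bit-reproducible under a fixed seed.

* **Optional stopping**: test at per-group sizes n_min, n_min+step, …,
  n_max and stop at the first p < α. The default schedule — peek after
  every added observation from 10 to 50 per group — echoes the designs in
  the simulation literature this mechanism comes from; the per-candidate
  false-positive rate it produces (≈ 0.22 at α = .05) sits in the range
  that literature reports. The schedule is fully configurable, and the test
  suite asserts the band, not a point value.
* **Publication bias**: significant results always survive; non-significant
  ones survive with a configurable probability (0 by default — a hard file
  drawer).
* **HARKing**: every effect estimate is sign-aligned with the post-hoc
  hypothesis, i.e. reported as |d|.
* **Publication records**: one lab runs k candidate studies for one effect
  under the enabled QRPs; an effect counts as internally replicated when at
  least two published significant studies exist.

Common-random-number comparisons are available by reusing a seed across
peeking schedules: schedules share the underlying data matrix, which makes
the monotonicity of the false-positive rate in the number of peeks exact
rather than statistical.

## The synthetic dataset generator (`synthetic_osc`)

Each study gets a latent true effect on the correlation scale: null with
probability 0.45, otherwise drawn from a normal with location 0.30 and
scale 0.10, truncated to [0.05, 0.90]. The null fraction and effect
distribution were chosen so that, after QRP inflation and clean
replication, overall independent replication success lands in the low
range observed in large replication projects; they are generator defaults,
not fitted quantities. Correlations convert to standardized mean
differences via d = 2r/√(1−r²) (equal groups), and back via r = d/√(d²+4).

**Original studies** run through the optional-stopping simulator at the
study's true effect; the published estimate is HARKed (|d|), giving
`p_original`, `r_original` and `n_original`.

**Internal replications** are the crux of the design. In `qrp_world` the
internal-replication channel is simulated *at a null effect*, independent
of the study's own latent truth: the QRP account taken at face value says
internal replications are manufactured by the practices and carry no
signal. (Simulating them at the study's own effect would make internal
replication a strong proxy for truth — P(≥2 significant candidates) is
about .78 for a true effect versus .10 for a null one under the default
design — and the "no difference" world would not be null at all.) Each lab
runs k ~ Poisson(λ) candidate internal studies; because the number of
significant candidates is then Poisson(λs), λ = −ln(1 − f)/s makes the
probability of at least one significant internal study exactly the
configured internally-replicated fraction f (default .44). The
per-candidate significance rate s of the configured stopping design is
estimated once by a seeded 20,000-run probe, so the calibration is
deterministic. With `exact_margins=True` (the default, for fixture-sized
tables) the internally-replicated *status* is instead assigned to a
uniformly random subset of exactly round(f·n) studies — still independent
of truth — with count magnitudes drawn from the QRP channel's conditional
distribution.

**Independent replications** are run cleanly (no QRPs): per-group sizes are
chosen by bisection so the two-sample t-test has the target power (default
.92) for the *claimed* original effect size (floored at r = .05 so the
required n stays finite; configs whose cap cannot reach the target raise a
config error). The latent effect seen by the replication is attenuated by
`base_attenuation` (default 0.5) — in `moderator_world`, internally
replicated effects are attenuated by `base_attenuation × (1 − coupling)`
instead, which is this package's own formalisation of the verbal
moderator story. `coupling = 0` reduces `moderator_world` to `qrp_world`
draw for draw.

Missing replication outcomes (default two per group, matching the 42/54
usable split) and the covariate columns (discipline mix, effect type,
surprisingness, challenge, power-analysis flag) are filled independently of
the replication machinery.

Randomness is organised as one master seed spawning six per-stage child
streams (latent effects, originals, internal channel, replications,
covariates, missingness), so each stage is independently reproducible.
Per-study substreams were considered and rejected: they would force a
Python-level loop over studies and make the 2000-study discrimination runs
an order of magnitude slower, and stage-level streams already give bit
reproducibility for a fixed configuration.

What the generator does **not** emulate: correlations between covariates
and internal replication present in the real data (e.g. the field-of-study
imbalance), rater-level structure behind the surprisingness and challenge
composites, the long right tail of real sample sizes, and heterogeneous
replication designs. Passing tests on synthetic data therefore validate the
statistical machinery and the discrimination logic, not any claim about the
real dataset's covariate structure.

## Directional conventions in the pipeline

For every categorical variable the one-sided alternative asserts that a
coded level's share is larger among internally replicated effects; the
coded levels are success (P < .05), social, interaction, and
power-analysis-present, which reproduces the published Bayes factors row
for row. Continuous predictors name the group the moderator account
predicts to score higher, and the robust-estimation contrast is signed so a
positive median always means support for that alternative. Original sample
size is analysed on the natural-log scale for the Bayes factor (raw values
are heavily right-skewed), with any study of N ≥ 200,000 flagged and
excluded from the BF — the flag-not-delete rule keeps the same table usable
with and without the exclusion — while robust estimation stays on the raw
scale. For effect type, the coding treats main effects as the
reproducibility-favouring level, following the cited replication
literature; it is overridable like every other direction.

Bayes factors are labelled on Jeffreys' bands applied to max(BF, 1/BF):
anecdotal below 3, substantial to 10, strong to 30, very strong beyond;
boundary values fall in the higher band and BF = 1 is anecdotal.

## The packaged fixture

`replibayes.fixtures.reference_margins_table()` deterministically
constructs a synthetic 100-study table whose categorical cross-tabs equal
the published summary margins (group sizes, success counts, field split,
power-analysis counts, internal-count distribution, two missing outcomes
per group). Continuous columns are filler indexed through a fixed
permutation so they stay balanced across the group strata. The fixture
makes the headline Bayes factors exactly recomputable in tests without any
download; it is not the real dataset and its continuous columns carry no
information.

## Problem sizes and tolerances

Default posterior sample counts are 100,000 (contingency posteriors) and
100,000 with 2,000 burn-in (robust model); the test suite uses 2,500–10,000
MCMC draws and 2,000-study generated tables, sizes at which every check
runs on a single CPU in about two minutes total. Monte-Carlo tolerances for
matching published values are ±5% relative (or ±0.05 absolute) for Bayes
factors, ±0.03 for posterior medians and ±0.05 for interval endpoints —
the sampling error implied by 100,000 draws. Quadrature agreements are
asserted to 10⁻⁴–10⁻⁶.

## Known limitations

* The robust-model sampler is a single adaptive chain; the split-chain
  diagnostic catches gross non-convergence but multi-chain R-hat would be
  stricter.
* The moderator-world coupling is a one-parameter attenuation model — a
  formalisation of a verbal account, not an estimate of any real
  moderation process.
* Continuous-predictor Bayes factors assume normality after at most the
  documented log transform; where the assumption fails the robust posterior
  is the quantity to read (the reports say so in their notes).
* The Gunel–Dickey implementation covers exactly the 2×2
  independent-multinomial case used here; Poisson, joint-multinomial and
  hypergeometric sampling plans, and larger tables, are out of scope.
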