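# Methods

`feederdef` implements, end to end, an analysis of resource defense and
monopolization in a marked hummingbird population feeding on a grid of
RFID-equipped nectar feeders: detections are merged into visits, visits
into space-use indices and a bird-feeder-day response table,
randomization tests ask whether use is concentrated and dominated at
all, and a set of linear mixed models with individual-specific defense
slopes quantifies what drives the number of visits by competitors
(NVC).  Because the underlying three-season field dataset was never
deposited, the package carries a synthetic study system whose defaults
reproduce the published study's design and printed magnitudes; all
quantitative validation is against in-table arithmetic or against
simulated data with known ground truth.

## Sessionization

Detectors scan once per second, so a feeding bout appears as a run of
per-second readings with occasional skips (birds shuffle on the perch;
readers miss scans).  Two consecutive readings of the same tag at the
same feeder strictly less than 21 s apart belong to the same visit; a
gap of 21 s or more starts a new visit.  Decisions worth stating:

* The gap is measured between consecutive reading timestamps (i.e. the
  last reading of the current run vs the next reading), with a strict
  `< 21` comparison, so readings exactly 21 s apart split.
* Duration is inclusive: a single reading is a 1-s visit.
* A visit spanning midnight belongs to the calendar day it starts.
* Duplicate (timestamp, tag, feeder) rows are dropped with a logged
  warning; reader chatter must not inflate reading counts.

Invariants tested: reading conservation, threshold monotonicity,
no merging across tags or feeders, and boundary-structure idempotence.
One caveat discovered in testing: collapsing a visit to *only* its
first and last reading is not idempotent for visits longer than the
threshold (the two readings are then themselves ≥ 21 s apart), so the
idempotence test thins visits to anchors every 15 s instead.

## Space-use indices and the analysis table

* **Spatial concentration** — visits by a bird at a feeder on a day,
  over its total visits that day; sums to 1 over feeders per bird-day.
* **Seasonal concentration** — same ratio over the bird's entire
  followed period within a season (a calendar year).
* **Spatial stability** — the Pearson correlation between daily and
  seasonal concentration, paired over every (feeder, day) combination
  where the feeder is one the bird visited at least once that season;
  days on which the bird skipped a feeder contribute a daily value of 0
  (the zeros are information: skipping a usually-favoured feeder is
  instability).  Stability needs ≥ 3 followed days, and is undefined
  (flagged and excluded) when either vector has zero variance — e.g. a
  bird using a single feeder all season.  The index is reported as
  computed, without clamping, even though it is described as ranging
  over [0, 1]; negative values are possible in principle.
* **Grid usage** — the mean daily visit total over individuals active
  that day, a day-level proxy for weather-driven reliance on feeders.
* **Feeder rank** — feeders ranked (ascending, ties averaged) by the
  number of distinct adult individuals of the competitor sex detected
  there over a season; rank 1 is the busiest feeder.

The analysis table takes every adult of the focal sex followed on ≥ 3
distinct days as, in turn, the focal (potential defender) at each
feeder-day it visited.  NVC counts visits that day at that feeder by
*other* adults of the competitor sex; all adults count as competitors
regardless of how long they were followed, juveniles never do.  Rows
with NVC = 0 — including feeder-days where the focal was alone — are
excluded: a feeder nobody else visits more likely reflects low
attractiveness than perfect defense, and the log response requires
NVC ≥ 1.  `n_competitors` is the number of distinct competitor-sex
adults at the feeder that day excluding the focal (whether the original
count included the focal is ambiguous; excluding it is a definition,
and only shifts the covariate by a constant 1 on retained rows).

## Randomization nulls

Two 100-replicate procedures, both conditioned on observed totals:

* **Concentration null** — the statistic is the mean, over bird-days,
  of the visit share at the bird-day's most-visited feeder; each
  replicate reassigns every visit of each bird-day independently and
  uniformly among the feeders that bird visited that day.
* **Dominance null** — the statistic is the mean, over feeder-days, of
  the top visitor's visit count; each replicate reassigns every visit
  of a feeder-day uniformly among its visitors.

"Randomly assigning" is implemented as an independent uniform
multinomial redraw.  A permutation of the existing count vector would
leave both statistics unchanged — the redraw is the only reading under
which the null differs from the data.  One-sided p-values use the
add-one convention `(1 + #{null ≥ observed}) / (n_rep + 1)`, so an
observed value beyond every replicate reports p = 1/101 ≈ 0.0099,
never zero.

Calibration is a real property with real limits.  The nulls condition
on the visited set and on totals, so they are calibrated when, under
"no preference", allocation really is uniform-multinomial over the
options and the options are exchangeable.  Two structural effects break
this outside that world: (1) if birds spread few visits over many
feeders, the observed data are implicitly conditioned on every visited
feeder having ≥ 1 visit while null replicates are not, biasing the
observed statistic low; with realistic small daily repertoires (~5
feeders) and ~35 visits/day this effect is negligible.  (2) The
dominance null additionally requires visitors of a feeder-day to have
equal expected rates there; heterogeneous rates or repertoires make it
anticonservative.  The type-I calibration study therefore runs in the
exchangeable world (equal rates, shared repertoire, no fidelity, no
defense), where both tests cover ≈ 95%.  On real-like data the
dominance test should be read as strongly directional evidence, not as
an exact test under rate heterogeneity.

## The mixed model and multimodel inference

The response is the natural log of NVC.  All ten candidate models share
the random structure: a feeder intercept, crossed with a correlated
per-individual intercept and spatial-concentration slope — the random
slope *is* the biological claim that individuals differ in defense
capacity.  Fixed structures range from a controls-only baseline (year,
grid usage, number of competitors, feeder rank, sucrose) to the full
model adding the focal's space-use terms, habitat visibility, and five
interactions with spatial concentration, including the three-way
concentration × openness × lateral-visibility term parameterized as
separate concentration × visibility slopes within each openness level
(visibility should matter in closed habitat, where sight lines are
obstructed, and not in the open).

### Estimation engine

Crossed random effects with a correlated intercept+slope in one factor
are outside what the available Python mixed-model implementations can
express, so the package fits the model directly by profiled (RE)ML.
With `G = σ² Λθ Λθ'` (Λ block-diagonal: a feeder scale, and a shared
2×2 lower-triangular factor per individual), β and σ² are profiled out
analytically and each objective evaluation reduces, via the Woodbury
identity, to dense Cholesky algebra on the q×q system
`A = I + Λ' Z'Z Λ`, q = n_feeders + 2·n_individuals.  All data-size
dependence is in one-time sparse cross-products, so a 15 000-row fit
with 88 individuals and 45 feeders takes well under a second per
objective evaluation and ~1 s overall.  Optimization is L-BFGS-B over
the 4 relative parameters with a bounded Nelder-Mead polish; variance
parameters estimated below 1e-6 of the residual scale flag the fit as
singular.  BLUPs are the conditional modes `Λ A⁻¹ Λ' Z' (y − Xβ̂)`.

The engine is cross-checked in the test suite against `lme4` (via
Rscript) on a simulated dataset — ML and REML log-likelihoods,
coefficients, SEs and variance components agree to at least 3
significant figures (observed: ~7) — and against OLS in the
zero-variance limit, where the profiled GLS at θ = 0 reproduces least
squares exactly.

### Selection, averaging, BLUP slopes

AICc uses maximum-likelihood fits (fixed structures differ across
models); model averaging uses REML coefficients.  K counts fixed
effects + 4 random-effect (co)variance parameters + the residual
variance (marginal AIC — selection here compares population-level fixed
structures; a conditional AIC would instead target individual-level
prediction).  Averaging substitutes 0 for a term absent from a model
and averages over the full set (zero-substitution), with the
unconditional SE `Σᵢ wᵢ √(seᵢ² + (θᵢ − θ̄)²)` and normal 1.96 CIs —
verified to reproduce the published averaged table's bounds from its
printed coefficient/SE pairs to the printed precision.  Natural
averaging (renormalizing over containing models) is available as an
option.  Non-converged fits are dropped from averaging with a warning
and the weights renormalized.

Per-individual defense is summarized as the model-averaged total
concentration slope: the fixed concentration effect with numeric
covariates at their means and factors at reference (year = first,
sucrose = low, openness = closed) plus the individual's averaged slope
BLUP, also expressed as the predicted percent NVC reduction when
concentration goes 0 → 1, `100·(1 − e^slope)`.

### Degenerate designs

Constant design columns (the sucrose dummy in a season without the
treatment; a single-year run's year dummy) and aliased columns (the
concentration × competitors product when every retained feeder-day has
exactly one competitor, as happens in very small simulations) are
pruned before fitting, so small runs degrade gracefully instead of
producing singular normal equations.

## The synthetic study system

The generator reproduces the study design exactly where it is stated:
45 feeders in rows of 12/12/7/7/7 at 100 m spacing; 8 hayfield, 6
fallow, 31 forest feeders; all open-habitat feeders plus exactly 14
forest feeders in canopy gaps coded "open"; and, in the treatment year,
9 weekly randomizations in 3 blocks with 15 of 45 feeders high-sucrose
per week and every feeder high exactly once per block.  Where the
design is not stated, defaults are one-time choices at the magnitudes
the published summaries imply:

| parameter | default | basis |
|---|---|---|
| mean daily visit rate λ | 35 visits/day | top-feeder visit count 19.29 at concentration 0.631 ⇒ ≈ 31 visits/day |
| daily repertoire | feeders within 150 m of home (≈ 5) | null mean max-share 0.378 implies ~4 visited feeders per bird-day |
| visit duration | log-normal, median 8 s, σ = 0.6 | strictly positive and right-skewed; no durations are published |
| activity window | 05:00–21:00 | detectors ran 24 h/day but hummingbirds do not |
| lateral visibility | U[1, 15] m forest, U[10, 30] m open | plausible ranges; none published |
| dropout | 5%/s, boundaries kept | readers "occasionally skipped readings" |

Visit counts per individual-day are Poisson with the home feeder's
habitat/sucrose attractiveness scaling the rate; visits are allocated
over the repertoire by a multinomial whose weights put `(1 + κ)` on the
home feeder (κ = fidelity; κ → ∞ pins all visits to home, κ = 0 is
uniform).  An optional Dirichlet layer (`allocation_concentration`) can
add day-to-day overdispersion in the allocation; its default is the
multinomial limit because the permutation nulls' uniform-multinomial
assumption is exactly the κ = 0 world the calibration study must
target — any finite Dirichlet mass overdisperses counts and would make
a correctly implemented test look miscalibrated.  Defense thins the
stream afterwards: at each feeder-day the top user's realized
(pre-thinning) concentration C and defense β remove each competitor
visit with probability `1 − e^(−βC)`; using pre-thinning concentrations
avoids circular dependence.  Dropout never removes a visit's first or
last second and caps consecutive drops at 19 s, so the sessionizer
recovers the generated visits exactly — the generator's visit count
stays identifiable for testing.

What the generator does *not* emulate: spatially explicit flight paths
between feeders, weather, within-day temporal clustering of visits,
and behavioral feedback (birds do not re-allocate after being
excluded).  Passing tests therefore demonstrate correctness of the
pipeline's accounting and inference under the stated generative
assumptions, not fidelity of those assumptions to wild hummingbirds.

## Verification experiments

* **Parameter recovery** (full size: 100 replicates, 15 000 rows, 88
  individuals, 45 feeders; the published averaged coefficients as
  ground truth plus realistic variance components).  Bias is measured
  with a control variate — the GLS estimator at the true relative
  variance parameters, exactly unbiased and nearly identical to the
  REML estimate — so the 100-replicate bias estimate carries negligible
  Monte-Carlo error; CI coverage uses the independent replicates'
  plug-in Wald intervals.  Per-coefficient true coverage measured at
  0.92–0.97: plug-in intervals ignore variance-parameter uncertainty,
  exactly as the standard tools do.
* **Random-slope support**: ΔAICc between full models without and with
  the individual random slope is ≈ −4…0 when data are generated with
  zero slope variance (pure parameter penalty) and far above 10 (tens)
  under the default slope variance 0.25.
* **Type-I calibration** of both permutation nulls in the exchangeable
  world, as described above.

Problem sizes in the analysis drivers are scaled-down versions of these
studies (e.g. 20 recovery replicates at 6 000 rows) chosen to keep each
driver a quick interactive run; the full-size studies live in the test
suite and the acceptance script.

## Known limitations

* REML Wald CIs are plug-in; no Satterthwaite/Kenward-Roger df
  correction, matching the era's standard toolchain.
* Whether the published analysis log-transformed with base e or 10 is
  not stated; natural log is used (base only rescales coefficients).
* Marginal vs conditional AIC is undecidable from the source; marginal
  is used (see above).
* The dominance permutation test is anticonservative under
  between-individual rate heterogeneity (documented above).
* Cross-feeder visit stitching, antenna efficiency modelling, and
  within-day temporal overlap of visits are out of scope.
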