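# Methods

## The question and the estimand

Momentary wellbeing instruments record two components per episode: intensity
(an integer 0–10 score for happiness or worthwhileness) and duration (how
long the activity lasted).  If time spent feeling good matters, a
duration-weighted aggregate should differ from a plain mean.  The package's
estimand is the per-person paired difference between the duration-weighted
and unweighted aggregate, under two aggregation families (pooled over the
whole study, or averaged day by day), for each reporting method (EMA, DRM)
and each measure (happiness, worthwhileness).

The analysis is an *equivalence* problem, not a difference problem: the
claim "duration weighting does not matter" is established positively by the
TOST procedure against a margin of ±0.1 points, i.e. 1% of the 0–10 scale
(a deliberately permissive bar, given that major life events shift wellbeing
on the order of 5%).  `equivalent = True` means the larger of the two
one-sided p-values is below α, which is exactly the condition that the
(1−2α) confidence interval of the mean difference lies inside the margin.
The plain 95% CI is reported alongside so the result can also be read as CI
inspection or as a t-test against the margin.  No multiple-testing
correction is applied across the eight cells; each cell is its own claim.

## Why a zero difference is expected: the covariance identity

For one person, weighted minus unweighted mean equals
`cov(Dur, SWB)/mean(Dur)` with the population (1/Q) covariance — an exact
algebraic identity, verified in tests to 1e-10 on random integer streams.
Everything downstream follows from it: equal durations force a zero
difference; a weak intensity–duration correlation forces a near-zero one;
and the candidate "drivers" of a non-zero difference are precisely r,
sd(intensity) and sd(duration) (with mean duration in the denominator).

## Preprocessing

Fixed order, full provenance, strict boundary semantics:

1. drop reports longer than 12 h (720 min survives, 721 does not) on raw
   durations;
2. deduplicate EMA reports started within <15 min of each other inside a
   person-day (exactly 15 min apart survives).  The scan is sequential and
   compares against the last *surviving* report, keeping the earlier one —
   the source procedure does not say which of a near-duplicate pair was
   kept, nor whether the rule chains; both choices here are explicit
   package decisions;
3. keep persons with >20 EMA (strict) and ≥5 DRM (inclusive) reports;
4. double EMA durations (a prompt interrupts the activity roughly
   mid-episode, so the elapsed duration undercounts the episode by about
   half); DRM episodes, which record start and end clocks, are untouched.
   Doubling is flagged and a second application refuses.

DRM diaries describe the *previous* day; `day_index` refers to the day
described, aligning EMA and DRM on the same experienced day.  Episodes
crossing midnight use the `clock_end = clock_start + span` convention
(validation checks the span modulo 1440).

## Aggregation details

The daily formula divides each day's score sum by that day's own report
count Q_j, then averages day means with equal weight.  (A printed version
of this formula elsewhere divides every day by the first day's count; that
is a typographic slip — "average of daily SWB scores" forces Q_j.)  All four
scores are convex combinations of the inputs, hence bounded by the observed
score range, and invariant to report order.  Descriptives are report-level
pooled mean, SD, median and a t-based 95% CI of the mean; the "±" column in
such tables is the SD, not the CI half-width.

## Synthetic cohort generator

The generator stands in for access-restricted raw data, so its defaults are
the study conditions the analyses assume: 14 days; 5 EMA prompts/day on a
10-minute picker grid (10–250 min, pre-doubling); one DRM diary/day of 6
episodes partitioning a 16-h waking window (so every day covers ≥12 h by
construction); latent mean intensity 7.17 with within-person SD 1.6 and
between-person SD 0.9 (pooled ≈ 1.84); raw EMA durations lognormal with
mean 78 min and SD 60 min, so that *doubled* EMA durations (~156 min mean)
land near the DRM episode mean of 960/6 = 160 min — matching the reported
pattern of right-skewed durations with means in the 150–170 min range and
DRM slightly longer than doubled EMA.  No distributional forms for
intensity or duration are published; truncated-normal and lognormal are the
package's stand-ins and are config-swappable in spirit (all moments are
`SyntheticConfig` fields).

Mechanics per person (a stable per-person RNG substream is derived by
hashing the person id, so cohorts are insertion-order independent and
bit-reproducible from the seed):

* person effects shift mean intensity (per measure) and log mean duration;
  the person-level correlation is `rho + N(0, rho_between_person_sd)`,
  clipped to ±0.99;
* a latent bivariate-Gaussian pair (intensity innovation, log-duration) with
  correlation ρ is drawn per episode (Gaussian copula); the intensity latent
  follows an AR(1) chain `x_t = φ x_{t−1} + √(1−φ²) ε_t` across consecutive
  episodes within a day, resetting overnight (overnight persistence is not
  modelled);
* intensities are `clip(round(μ + σ·x), 0, 10)`; EMA durations are
  `exp(latent)` snapped to the 10-min grid; DRM episode lengths are
  logistic-normal weights (exponentiated correlated latents, normalised over
  the day) times the waking window, rounded to whole minutes with the last
  episode absorbing the remainder.  A plain symmetric Dirichlet partition
  would guarantee coverage equally well but cannot carry ρ into DRM
  durations, which the driver analyses need.

Discretisation consequences, measured rather than hidden: clipping at 10
pulls the realized mean intensity ~0.2 below the latent 7.17 at default
spread; rounding and grid-snapping attenuate the realized correlation, and
the lognormal transform attenuates the raw-minute-scale r by a further
factor `σ/√(e^{σ²}−1)` (~0.89 at defaults).  Correlation-recovery tests
therefore check the pooled within-person r on the log-duration scale (where
the copula imposes ρ) with a ±0.1 band; `empirical_moments` reports both
scales.  `generate_cohort` records the realized pooled r in provenance.

What the generator does *not* emulate: activity semantics (no "working is
sadder" effects), prompt non-response/missingness, overnight carryover, and
any duration–intensity nonlinearity.  Passing tests show the pipeline
recovers planted structure under these idealised conditions; they do not
certify behaviour under real-world missingness or activity confounding.

## Post-hoc analyses

* **Driver features** — per person: Pearson r between score and duration
  (undefined-missing, never 0, when variance is zero or Q<3), sample SDs,
  and the observed diffs.
* **Max-correlation subsampling** — 100 random half-subsets (size
  ⌊Q/2⌋ ≥ 3, drawn without replacement within a subset, independently
  across subsets), keep the subset with the largest |r| ("highest
  correlation, whether positive or negative"; a signed-max flag exists).
  Ties break to the first-drawn subset.  This is deliberate selection on
  noise: with true ρ = 0 the selected |r| exceeds the full-sample |r| in
  the large majority of draws — the selection-inflation property tests pin
  this down.  The percentile curve recomputes the weighting difference *on
  the selected subset* and bins persons by the subset's |r|.
* **Drivers regression** — OLS of |diff| on z-standardized |r|,
  sd(intensity), sd(duration) (signed variant available).  Coefficients are
  comparable because standardized; "dominant driver" = largest |β|.
  Constant predictors are dropped with a warning.  R² is
  rescaling-invariant.
* **Carryover regression** — within person×method×day episode sequences,
  lag-1 pairs (never crossing a day boundary), person-mean centred,
  z-standardized: `score_t ~ score_{t−1} + duration_{t−1}`.  Person-mean
  centring carries the usual small negative dynamic-panel bias of order
  −1/T (T = episodes per person); at the study sizes used here that is
  ≲0.01 and well inside the reported SEs.  No person fixed effects beyond
  the centring; the exact published functional form is unspecified, so this
  construction is the package's own.

## Power calculations

Normal-approximation formulas for the paired comparison are primary because
they reproduce the canonical design numbers exactly
(`n(d=0.50, α=0.05, power=0.90) = 43`; `MDE(n=217) = 0.22`); the
noncentral-t solver (`method="t"`, via statsmodels) is slightly more
conservative, giving n = 44.  A published sensitivity pairing of n = 195
with d = 0.20 is internally inconsistent with any standard formula (195
gives ≈0.23, and a smaller n cannot give a smaller detectable d than 217
does); it is documented here and not reproduced.  A simulation check
confirms the paired t-test at (n=43, d=0.5) has empirical power 0.90 ± 0.02.

## Problem sizes and numerical choices

The acceptance run and tests use cohorts of 40–200 persons × 14–21 days —
large enough that Monte-Carlo bands (Fisher-z for correlations, binomial
for rates) are a few hundredths wide, chosen as the package's own
desk-scale conditions.  The TOST calibration experiment (true difference
exactly at the margin, 2000 replicates of n=200, SD 0.05) must land within
two binomial SEs of α.  Degenerate inputs are first-class: zero-variance
TOST samples decide by the constant itself; constant covariates collapse a
median split to one stratum with a warning; single-person cells are marked
not-computable rather than raising; undefined correlations are missing, not
zero.

## Known limitations

Equivalence cells are tested marginally (no cross-cell correction, matching
the analysis being reproduced).  The carryover estimate retains the small
−1/T centring bias.  The generator's copula targets the latent scale, so
raw-scale correlation targets can only be hit approximately.  Real-data
features outside the generator's scope (missingness, activity effects) are
untested by construction.
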