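# Methods

This note documents the models, conventions, and numerical choices behind
the pipeline, in the order data flows through it, and states what the
synthetic generator does and does not emulate.

## Income security and work-from-home measures

An individual is *securely employed* iff their contract is permanent or
fixed-term; casual and other insecure arrangements count as insecure.
Fixed-term work is grouped with permanent because its conditions and the
sociodemographics of its holders resemble permanent employment far more
than casual work.  Some survey conventions code the two-level variable as
0 = secure / 1 = insecure; this package returns secure = 1 everywhere and
says so in the docstrings, because the income security index is a product
of two "goods" and an inverted coding invites sign errors.

The per-occupation index is `prop_secure × earnings / max(earnings)`, where
the maximum is taken over the occupations present in the analysis sample,
not a fixed constant.  The index is therefore *sample-relative*: adding a
higher-earning occupation rescales everyone.  This is deliberate and
matches the definition of the measure; the index is exactly invariant to
multiplying all earnings by a constant.  Occupations with zero respondents
cannot contribute a proportion and are excluded with a logged warning;
zero-index occupations are retained in the table (a display layer may drop
them from log-scaled axes, but the measure itself keeps them).
Respondent-level survey weights are not applied; proportions are
unweighted, with the earnings table as the only occupation-level weight
source.

The binary work-from-home classification enters keyed to a foreign
taxonomy and is linked to 6-digit local codes by a crosswalk; 4-digit
fractions are the **unweighted mean** of the linked 6-digit binary flags.
The aggregation rule is genuinely open (an employment-weighted mean is
equally defensible and is available via the `weights=` option); the
unweighted mean was chosen as the default because the downstream quantity
is interpreted as "proportion of individuals in the group who can work
from home" and the 6-digit employment distribution is not generally
available where the crosswalk is.  Codes with neither linked entries nor a
manual override are returned in an unlinked-codes listing, never silently
dropped.

## Regional aggregation

Regional values are occupation-count weighted means.  When some counted
occupations carry no measure, weights are renormalised over the covered
occupations, and the covered fraction is reported per region.
Zero-imputing the uncovered occupations would bias regions with rare
occupations toward zero, which nothing in the data supports.  Regions with
zero covered employment are flagged and excluded from association
analyses.  The median split used for mapping assigns ties at the median to
the lower group — an arbitrary but fixed convention, reported alongside
the median value itself.

## Traffic metrics

Telemetry rows below the 50-connection privacy floor are dropped (the
provider's floor; also a variance guard against thin regions).  Rates are
bytes per 30 minutes per active connection.

Outlier censoring removes points with |x − mean| > 3 SD (sample SD,
ddof = 1) in a **single, non-iterated pass**, separately per direction,
within region × slot-of-day groups over the analysis period.  The grouping
is the main open interpretation question: the spikes such censoring targets
are network-management and infrastructure-configuration artefacts, which
are localised, so per-region grouping is the default; a pooled
(cross-region, per-slot) mode is selectable.  Groups with zero SD are
untouched, so constant series survive unchanged.  For Gaussian noise the
pass removes ≈ 0.27% of points; re-application can remove a few boundary
points when the post-censoring SD shrinks appreciably, which is why the
pass is defined as single-shot.

Metric windows are half-open on the 30-minute start label: pre-dawn
minimum [4:30, 5:30), morning daytime average [9:00, 12:00), evening
maximum [20:30, 22:00) (slots 20:30, 21:00, 21:30), overall daytime
[9:00, 17:00).  The overall daytime window is this package's resolution of
an underspecified "overall daytime average": it spans school start to the
end of typical work hours, and both it and the narrower morning average are
emitted.  Daytime metrics use weekdays only by default (home-work and
remote schooling are weekday phenomena); the pre-dawn and evening windows
keep all days.  Timestamps are local clock time with no DST adjustment —
the canonical baseline window spans an Australian DST transition, and
slot-of-day arithmetic deliberately follows the wall clock, as the
telemetry does.

Changes are wave − baseline per metric; relative changes divide by the
baseline and are missing where the baseline is zero.  Scaling all volumes
by k scales absolute changes by k and leaves relative changes unchanged.

## Inference

- **Correlations**: one censoring pass at 3 SD on both variables jointly
  (a pair is removed if either member is out), then Pearson's r on the
  survivors.  The 95% CI uses the variance-stabilising arctanh transform
  with SE 1/√(n−3) — standard, and it produces the asymmetric intervals
  typical of reported values.  Zero-variance survivor sets are reported as
  undefined, not raised.
- **t-test**: Welch's unequal-variance form by default (no variance
  homogeneity assumption is defensible across cities); pooled variance is
  an option.
- **Fisher's exact test**: the odds ratio is the cross-product *ad/bc*;
  the two-tailed p sums hypergeometric probabilities of tables no more
  probable than the observed one.  The default CI is the log-OR normal
  approximation exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)); an exact conditional
  interval is available.  Zero cells flag the result as degenerate and
  fall back to the Haldane–Anscombe +0.5 correction for the CI.
- **Moran's I**: binary rook weights, row-standardised; expectation
  −1/(n−1) under the null; inference by ≥ 999 seeded permutations with the
  pseudo p-value (1 + #extreme)/(1 + n_perm), two-sided by default.
  Isolated regions are dropped with a warning.
- **PCA**: variables z-scored (so components reflect the correlation
  matrix), constant columns excluded with a warning, and each component's
  sign fixed so its largest-magnitude loading is positive.

No multiple-testing correction is applied across the correlation battery;
the battery is reported as a family of descriptive estimates.

## The synthetic generator

The generator's job is to produce all five inputs with the statistical
structure the analysis assumes, with planted parameters that downstream
stages must recover.

- **Occupations** (default 300): 4-digit codes; lognormal weekly earnings
  (median ≈ AUD 990); a latent ability factor drives both earnings and the
  secure-employment probability; respondent counts of 12–80 with binomial
  secure counts, so the index is computed from *realised* records.  The
  binary WFH flag comes from a latent threshold model on the normal scores
  of the index, calibrated against the in-sample linearity of the index so
  the realised point-biserial correlation tracks the planted value
  (default 0.8); planted values near the attainable maximum for a binary
  variable cap at the threshold rule.
- **Regions** (default 200, grid with rook adjacency): occupation counts
  are multinomial draws (default 2,000 employed persons per region) whose
  weights tilt toward high-security occupations with a latent regional
  affluence; a smooth gradient component of that affluence induces
  positive spatial autocorrelation.  The proportion of families with
  children is generated against regional income security at a planted
  correlation (default −0.4).  The two "cities" split the grid orthogonal
  to the gradient, so they differ only stochastically.
- **Telemetry**: the diurnal profile has a pre-dawn minimum (4:30–5:30), a
  morning plateau, and an evening peak (8:30–10 p.m.); default peak scales
  are 240 MB (download) and 24 MB (upload) per connection per half hour,
  with a 1.10 weekend multiplier.  Per-region structure: a multiplicative
  usage-level factor (SD 0.12) and a children-driven download offset
  (120 MB × proportion of families with children) that are constant across
  periods — so they shape baseline levels and relative changes but cancel
  exactly from absolute changes.  During the lockdown window the daytime
  slots receive the planted effect (bytes per connection, rank-scaled by
  regional security so the effect size is interpretable in bytes
  independent of index dispersion), a per-region Gaussian disturbance, and
  i.i.d. slot noise; rates truncate at zero.  Connection counts are
  ≈ persons/2.6 with ±15% variation, floored at 50.
- **Survey**: the reference (at/below-median income) group answers "yes"
  with probability 0.20; the above-median probability is set from the
  planted odds ratio (default 2.15); default group sizes 411/464 match the
  published survey's margins.
- **Planting an end-to-end correlation**: for recovery studies, the SD of
  the per-region lockdown disturbance is solved in closed form so the
  population correlation between security and the *measured* daytime
  change equals a target, accounting for the rank-scaled effect, the slot
  noise averaged over each window's interval count, and the empirical
  security-vs-rank correlation.

What the generator does **not** emulate: individual-household
heterogeneity, data caps or plan tiers, epidemic dynamics or policy
timelines, school-holiday calendars, public holidays (the profile carries
a holiday scale but the default windows contain none), and any non-Gaussian
noise structure of real telemetry — Gaussian noise is a declared
simplification, not an inference about the data.  Consequently, passing
recovery tests demonstrates that the *pipeline* is unbiased and correctly
calibrated under its own assumptions; it does not validate those
assumptions against the restricted real data, whose headline estimates are
not reproducible at desk scale.

## Numerical design and problem sizes

Default diurnal slot means are integer multiples of 48,000 bytes, every
window length (2, 3, 6, 16 slots) divides that quantum, and the test
scenarios for the closed-form identity use a 3×3 grid so the rank scale
k/8 times a 64,000-byte effect stays integral: at zero noise every windowed
mean and every change is then exact in double precision and is asserted
with equality, not tolerance.  Determinism is byte-level: a fixed seed
reproduces identical CSVs, and all permutation and Monte-Carlo procedures
take explicit seeds.

Tests and the acceptance script run the recovery study at 200 regions with
a 14-day baseline and 7-day wave (the closed-form noise derivation accounts
for window sizes, so coverage is unaffected by the window choice), 50
replicates per planted correlation, 200 null maps for Moran calibration,
and 999 permutations for gradient detection.  The full-scale defaults
(51-day baseline, matching the canonical 2019-10-10 … 2019-11-29 window)
remain the generator's defaults.

## Known limitations

- The weighted regional mean ignores within-region covariance between
  occupation mix and traffic behaviour; like the original measures it
  assumes independent within-region distributions.
- The crosswalk aggregation's unweighted mean can misrepresent 4-digit
  groups whose 6-digit members have very unequal employment.
- Moran's I is computed on a dense weight matrix; fine for the intended
  10²–10³ regions, not for national-scale lattices.
- The Fisher CI default is an approximation; it is accurate for the table
  sizes used here but the exact conditional option should be preferred for
  very sparse tables.
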