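# Methods

This note documents the models and procedures implemented in `campusdep`,
the parameter choices behind them, what the synthetic data generator does
and does not emulate, and the numerical conventions that matter for
reproducing its output.

## Questionnaire scoring

The SDS raw score is the sum of 20 keyed item contributions; items
2, 5, 6, 11, 12, 14, 16, 17, 18 and 20 are positively worded and
reverse-keyed (`5 − score`). The standard score is `raw × 1.25`, kept as a
real number (quarter-point resolution) and never rounded before
classification. Severity bands are half-open: `< 53` none, `[53, 63)` mild,
`[63, 73)` moderate, `≥ 73` severe. The published band labels "63 to 72"
and "72 to 100" overlap at 72; we resolve 72.5 → moderate and 73 → severe,
the common convention for the Chinese norm. Factor (symptom) scores sum the
keyed contributions within four item groups — cognitive (10 items),
manifest depressed mood (6), somatic 1 (3) and diurnal variation (item 2
alone) — so the four factor scores always sum to the raw score. The
suicidal-ideation item (19) is summed positively with the cognitive group
even though fitted patterns can give it a negative loading; the keying set
is configurable for users who prefer the alternative.

Quality control, applied in order and equivalent to one intersection:

1. **Duration screen** — drop respondents strictly below the empirical 5th
   percentile of completion times. "5% of the time distribution" is read as
   the 5th percentile, computed with the linear-interpolation quantile
   (the most common default, stated here for reproducibility).
2. **Contradiction screen** — drop respondents with SDS moderate/severe but
   BDI total ≤ 9 (the classic BDI "no depression" cutoff; configurable).
3. **Breakfast screen** — drop students with zero canteen swipes in the
   breakfast window over the whole observation period (treated as living
   off campus).

## Behavioral features

Meal windows are not part of the instrument and are configurable; defaults
bracket typical campus canteen hours and the observed mean meal times
(~7.7 h breakfast, 11.75 h lunch, 17.47 h dinner): breakfast 05:00–10:00,
lunch 10:30–15:00, dinner 16:00–21:00, all half-open. Within a window, a
student's meal time on a day is their **first** canteen swipe; later swipes
in the same window are payment noise, and swipes outside every window are
ignored for meal features. Meal time statistics are decimal hours; the SD
uses the sample (n−1) denominator and both mean and SD are emitted as
missing below two records. Correlation and group tests drop missing values
pairwise.

Dormitory routine counts use half-open local-hour bins `[h, h+1)`;
direction R = entering, O = leaving. Festival days are an explicit date
list in the calendar (statutory holidays; ordinary weekends count as
nonfestival), and every (hour × direction × day-class) combination is
emitted, so bin counts sum exactly to the student's dormitory event count.

The social frequency `R_ij` counts **all** cross-pairs of canteen swipe
times within `T = 250 s` (closed window, `|Δt| ≤ T`), restricted to the
social observation window; it equals the literal double sum over both
students' swipes — the sorted/search implementation is an optimisation
verified against that definition, not a redefinition. Swipes are not
deduplicated per meal before pairing, venue sub-location is ignored, and
self-pairs are never counted. `TOP_k` sorts a student's row excluding the
diagonal, descending, zero-padded when fewer than k other students exist.

Consumption summaries are {mean, SD, min, max, total, count} of
per-calendar-month spend and {mean, SD, min, max} of per-ISO-week spend;
the exact composition of these summary sets is a package choice (the
underlying monthly/weekly feature lists were never enumerated upstream) and
is documented here rather than guessed at.

## Statistical procedures

* **Mann-Whitney U** — midranks for ties; `U` of the first (nondepressed)
  group, i.e. `R1 − n1(n1+1)/2` (the smaller `U` is also exposed);
  `z = (U − n1 n2/2)/σ` with the tie-corrected variance and **no**
  continuity correction; two-tailed normal p. This matches the "asymptotic
  significance (2-tailed)" convention of mainstream packages. The
  implementation is verified against an exact enumeration oracle for
  `n1+n2 ≤ 10` and against scipy under ties.
* **Chi-square / ASR** — Pearson chi-square with expected counts from the
  margins; adjusted standardized residual
  `(O−E)/√(E(1−p_row)(1−p_col))`; |ASR| > 2 flags driving cells.
* **Odds ratios** — `ad/bc` with Wald log-scale 95% CI (multiplier 1.96);
  an optional Haldane 0.5 correction handles zero cells and is always
  flagged by the caller.
* **Correlations** — Spearman (Pearson on midranks, t-approximation with
  n−2 df) and Pearson via scipy on pairwise-complete data; constant vectors
  yield missing. No multiple-testing adjustment is applied anywhere: the
  grids report unadjusted per-cell significance, and this is deliberate —
  downstream users should treat isolated p ≈ .04 cells accordingly.
* **Factor analysis** — eigendecomposition of the Pearson correlation
  matrix; retain eigenvalues > 1 (Kaiser) unless a count is forced; initial
  loadings are eigenvectors × √eigenvalue; Kaiser-normalised varimax
  followed by promax with κ = 4 (the standard parameterisation; κ = 1
  reproduces varimax exactly, which is tested). Factor columns are
  sign-flipped so each column's largest-magnitude loading is positive —
  rotation sign is arbitrary and determinism matters for testing. KMO uses
  the anti-image (negated scaled inverse) matrix; Bartlett's sphericity is
  `−(n−1−(2p+5)/6)·ln det R` with `p(p−1)/2` df.

The gender × severity table uses male-vs-female odds of any depression and
of mild depression; the subsidy comparison is a 2×2 chi-square of
applied-vs-not against depressed-vs-not. "Depressed" for all group
comparisons means any severity ≥ mild (configurable). Academic correlations
are restricted to first-year students, who carry most of the graded course
load. Rounding (2 d.p. for means and statistics, 3 d.p. for odds ratios and
correlations) happens only at serialization.

## Synthetic cohort generator

The generator emulates the study conditions: 466 students, 25.32% latent
depression prevalence (severity mix ≈ 16.3/6.4/2.6 within it), a semester
from 2017-09-11 to 2018-01-10 with a small fixed festival list, and a
social window opening 2017-11-20.

**Questionnaire model.** Four equicorrelated latent factors (r = 0.3),
shifted by severity (0 / 1.0 / 1.3 / 1.6), map through a planted 20×4
loading matrix — primary loadings 0.75 (0.9 for the single diurnal item),
plus secondary loadings (±0.26–0.46) through which the diurnal factor
borrows variance from the appetite, constipation, devaluation and emptiness
items. A unit-variance latent normal per item is cut at fixed thresholds
(0.2, 1.0, 1.8) to the 1–4 scale; reverse-keyed items record `5 − c`.
Those secondary loadings are what keep the fourth correlation-matrix
eigenvalue above 1 after discretisation — exactly the mechanism visible in
fitted patterns on real data, where the diurnal factor is nominally
single-item but draws on several others. The constants were calibrated once
so that the *scored* prevalence lands near the latent 25% (it comes out
≈ 26–27% with mild > moderate > severe); the score distributions of
adjacent severity groups overlap, as real SDS distributions do, so the
scored label disagrees with the latent label for roughly a quarter of
positive screens — downstream effect estimates are correspondingly diluted,
which is realistic and intentional.

**Behavior model.** Per student-day: meal attendance is Bernoulli
(breakfast 0.44, lunch 0.60, dinner 0.54, ×0.75 on festivals) with normal
meal times (means 7.7/11.75/17.47 h, SDs 0.70/0.55/0.60 h) clipped to the
window; dormitory events are Poisson per hour bin with a rate profile whose
per-semester bin totals match the observed nondepressed magnitudes
(e.g. ≈ 3 events in 8–9 h, ≈ 6–8 in 20–23 h per direction); library and
water events are homogeneous Poisson. A random friendship graph (mean
degree 3) drives co-dining: when two friends both attend a meal they
synchronise with probability 0.65, settling on the midpoint of their
intended times ± a uniform ≤ 120 s jitter — which guarantees nonzero
co-swipe counts under the 250 s window by construction.

**Planted contrasts** (latently depressed students): meals shifted +0.12 h
later and skipped 5.5 points more often, breakfast-time SD ×1.1,
20:00–24:00 dormitory rates ×1.5, 06:00–10:00 rates ×0.6, and the pair
synchronisation probability ×0.7 per depressed member. All are configurable
and a zero-effect set switches every contrast off for null experiments.
Subsidy application rates (4.9% vs 10.2%) and exam-level probabilities
(higher fail share) also differ by latent status.

**Determinism.** Three independent generator streams (questionnaire,
events, graph) spawn from the master seed, so output is byte-identical for
a fixed seed and questionnaire draws are unaffected by changes to event
generation. The CSV bundle round-trips exactly (ISO-8601 second-resolution
timestamps, 2 d.p. amounts).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: between-student heterogeneity in preferred meal
times and activity levels (every nondepressed student shares one rate
profile, so between-group tests are better powered here than they would be
on real logs); realistic friendship topology (Erdős–Rényi, no communities);
the magnitude of strongest-tie co-occurrence (synthetic TOP_1 ≈ 20–26 vs
≈ 47 observed on the real cohort — ties are thinner here); holiday travel,
attrition, dropout and term-time nonstationarity; and any consumption
structure beyond lognormal draws.

## Validation experiments and problem sizes

* **Null calibration** — 500 cohorts of 400 students over a 4-week window
  with all contrasts off; each representative feature's Mann-Whitney
  rejection rate at α = .05 must lie within 3 binomial SEs of 0.05, and
  p-values are KS-uniform. The 4-week window is a deliberate problem-size
  choice: under the null, calibration does not depend on window length.
* **Planted-effect direction** — 100 cohorts of 400 students over 6 weeks;
  the depressed group must show later mean breakfast, more 22–23 h returns
  and lower TOP_1 in ≥ 95% of cohorts (observed: 98–100%).
* **Factor recovery** — 50 cohorts of 500 respondents; the Kaiser rule must
  retain 4 factors and max-|loading| assignment must match the planted
  grouping in ≥ 90% of cohorts, with mean Tucker congruence ≥ 0.90
  (observed: ≈ 100%, ≈ 97%, ≈ 0.97). Congruence is computed after optimal
  column matching (assignment problem on absolute congruences) because
  factor order and sign are arbitrary.

## Numerical conventions and degenerate inputs

Quantiles use linear interpolation; SDs use n−1 and are missing below two
observations; correlations on constant or < 3-pair inputs are missing;
chi-square requires strictly positive margins; odds ratios require positive
cells unless Haldane-corrected; the co-swipe window is closed; hour and
meal windows are half-open; events exactly on an hour boundary belong to
the later bin; all-tied Mann-Whitney samples yield z = 0, p = 1. A cohort
whose post-QC groups fall below two members per side raises an informative
error rather than producing unstable statistics.

## Known limitations

The 121-feature count reported for the original feature set is not exactly
reconstructible from its published enumeration (the categories enumerate
118 and the social features add 5); this package emits the enumerated
features and does not chase the printed total. The group-comparison U
statistics and correlation grids of the original cohort depend on private
data and are validated here only structurally (machinery + planted-effect
properties), not numerically. BDI is used solely as a contradiction screen,
not graded for severity. No multiple-testing correction is applied, by
design, matching the reporting convention the tables follow.
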