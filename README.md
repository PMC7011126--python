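# campusdep

Digital phenotyping of depression in a college cohort from campus
information-system data: card-swipe event logs (canteen payments, dormitory
door swipes, library gates, water dispensers), questionnaire responses and
academic records. The package is aimed at researchers in psychiatric
epidemiology / computational mental health who want a tested, reusable
implementation of this analysis — and, because real student data of this
kind are private, it ships a synthetic cohort generator with the same
statistical structure so every stage can be exercised and validated.

## What it computes

**Screening.** The Zung Self-Rating Depression Scale (SDS; 20 items, 4-point
Likert, reverse-keyed items contribute `5 − score`) is scored as
`raw ∈ [20, 80]`, `standard = raw × 1.25 ∈ [25, 100]`, and classified
against the Chinese-norm cutoffs (53 mild, 63 moderate, 73 severe). Three
quality-control screens drop the fastest 5% of completions, SDS/BDI
contradictions (SDS moderate/severe with BDI total ≤ 9), and students who
never swipe for breakfast (off-campus residents).

**Behavioral features.** Per student: meal counts/mean time/SD of time per
meal window split by festival vs nonfestival days; dormitory entry/exit
counts per hour bin ("8-9 R", "22-23 O festival", …); library, consumption
and subsidy measures; and the meal-time co-occurrence **social frequency**

    R_ij = Σ_m Σ_n 1(|S_im − S_jn| ≤ T),      T = 250 s,

where `S_im` is student *i*'s m-th canteen swipe time. `TOP_1..TOP_5` — the
five largest entries of row `R_i` — summarize a student's strongest
meal-time ties.

**Statistics.** Tie-corrected asymptotic Mann-Whitney U per feature between
the depressed (any severity) and nondepressed groups; chi-square tests of
independence with adjusted standardized residuals and Wald-CI odds ratios on
the gender × severity table; Spearman/Pearson correlation grids between
factor scores and features; and principal-component factoring of the SDS
with Kaiser-normalised varimax + promax (κ = 4) rotation, retained by the
eigenvalue > 1 rule, with KMO and Bartlett sphericity diagnostics.

## Worked example

```python
from campusdep import CampusDepressionModel, CohortConfig, generate_cohort

cohort = generate_cohort(CohortConfig(seed=11))   # 466 students, one semester
results = CampusDepressionModel.from_cohort(cohort).fit()
print(results.summary())
```

prints (abridged):

```
Campus depression analysis
============================================================
Cohort after QC: 417 students (dropped: 24 fast completions, 25 SDS/BDI contradictions, 0 never at breakfast)
Depression prevalence: 25.66% (mild 16.31%, moderate 4.08%, severe 5.28%)
Gender x severity: chi2=6.7, df=3, p=0.083
Factor analysis: KMO=0.93, Bartlett chi2=4548.9 (df=190, p=0); 4 factors retained (40.07%, 12.43%, 7.59%, 6.04% variance)
Features significant at p<.05 (Mann-Whitney): 41
  Number of dinners: U=23114.5, z=6.08, p=0.000, means 61.93 vs 57.98
  20-21 O: U=10141.5, z=-6.02, p=0.000, means 7.88 vs 10.04
  22-23 R: U=10607.0, z=-5.60, p=0.000, means 6.22 vs 8.29
  ...
```

Reading: on this synthetic semester, about a quarter of students screen
positive; the depressed group shows the planted contrasts — fewer and later
meals (57.98 vs 61.93 dinners), more late-evening dormitory activity
("22-23 R" 8.29 vs 6.22 returns), weaker meal-time social ties — and the
SDS items factor into the four planted symptom groups with the adequacy
diagnostics (KMO, Bartlett) a factor analysis of a 20-item scale should
show. `results.save("report/")` writes every table (group comparison, ASR,
factor pattern, correlation grids) as CSV/JSON.

The same flows are scriptable from a shell:

```sh
campus generate --out cohort/ --seed 11
campus run --in cohort/ --out report/
```

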