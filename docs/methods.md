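# Methods

## The age-stage, two-sex life table

A cohort of `n0` eggs is followed daily until every individual dies.
Each record holds the whole-day durations of its completed stages, the
stage it died in with the days lived there, its sex (observable only at
adult emergence), and for females a daily egg-count series.

**Age convention.** Age 0 is the day of oviposition. An individual
entering a stage at age `e` with duration `d` occupies it on the
half-open day interval `[e, e+d)`; its death age is the first day it is
no longer alive, so it is alive on days `0 … death_age−1`. All ages and
durations are whole days, matching daily observation; fractional values
are rejected at parse time.

**Schedules.** `s_xj` is the daily census of stage *j* at age *x*
divided by `n0`; every entry is a multiple of `1/n0` and
`l_x = Σ_j s_xj` exactly. Because only adult females lay eggs, the
adult stage is carried as separate adult-female and adult-male columns
(the usual two-sex bookkeeping); immature stages follow the stage
scheme unchanged. `f_x` divides the cohort's eggs at age *x* by the
adult females alive then, and `m_x = Σ_j s_xj f_xj / l_x` spreads them
over survivors of both sexes, making the conservation identity
`n0 · Σ_x l_x m_x = total eggs laid` an exact integer identity — the
test suite asserts it.  `0/0` is defined as 0 so schedules extend to
the cohort's last day.

**Variable instar counts.** Cohorts reared at different temperatures
may molt through five to seven larval instars. A stage scheme carries
an order-preserving grouping map that pools supernumerary instars (e.g.
L5–L7) into one analysis stage; pooling sums durations, never changes a
death age, and when death occurs partway through a pooled run the days
completed in earlier members count toward the pooled death stage.

**Summaries.** Stage-duration means use completers only — an individual
dying inside a stage contributes to `s_xj` for the days it lived but
not to that stage's mean. SE is sample SD/√n everywhere. APOP is first
egg age minus emergence age; TPOP is first egg age; the oviposition
period defaults to the first-to-last-egg span including gap days (an
`active`-days variant is a switch). Immature mortality is the fraction
of the initial cohort dying before adulthood, reported as a percentage.

## Growth parameters

`R0 = Σ l_x m_x`, `GRR = Σ m_x`, `λ = e^r`, `T = ln(R0)/r`. The
intrinsic rate solves `Σ_x e^{−r(x+1)} l_x m_x = 1`; the `x+1` exponent
pairs with the age-0-at-oviposition convention (end-of-day census).
The left side is strictly decreasing in *r*, so the root is unique: it
is bracketed starting from ±1/day with geometric expansion and bisected
to `1e−12` (residual checked to `1e−10` in tests). `r < 0` is legitimate
(declining cohort, `R0 < 1`); `r` is undefined when `R0 = 0` and the
solver raises rather than returning NaN.

**Bootstrap.** Uncertainty is nonparametric: B resamples of `n0`
individuals with replacement, full pipeline per replicate, SE = SD of
replicate values, 95% equal-tail percentile CIs (no BCa; the default
B = 10,000 is configurable and the analysis scripts use 2,000).
Replicates whose resample contains no reproducing female leave r/λ/T
undefined; they are counted, excluded from those parameters' statistics
with a warning, and retained as zeros in R0/GRR. The per-replicate
pipeline runs on precomputed per-individual arrays (death age, egg row,
adult-female presence row); a test asserts the array path is
numerically identical to rebuilding the life table from records.

## Thermal response

Development rate is the reciprocal of mean stage duration. The model
`rate = a + b·log(T)` is ordinary least squares on per-temperature mean
rates (individual-level fitting exists but is not the default, since
per-individual rates are rarely published). The natural log is the
default base: R² is base-invariant and the intercept too (log of one
temperature unit is 0 in every base), while the slope scales by
ln(base); both facts are asserted in tests. On the published larval
means the fit gives a = −0.352, b = 0.132, R² = 0.891 — the means-based
R² can differ slightly from an individual-level fit of the same data.

## Group comparison

One-way ANOVA via the classical between/within decomposition (exposing
the pooled MSE), p from the F distribution. Pairwise comparisons are
unprotected Fisher LSD t tests with `SE = sqrt(MSE·(1/n_i + 1/n_j))` on
the within-group df — no further multiplicity correction, matching the
field's reporting convention. Letters come from the insert-and-absorb
compact-letter-display algorithm; starting from a single letter and
splitting only on significant pairs guarantees that two groups share a
letter iff their LSD comparison is non-significant (property-tested on
randomized inputs). Letters follow descending means, `a` largest.
Degenerate case: zero within-variance with unequal means is reported as
infinite F with p = 0; with equal means, F = 0 and p = 1.

## Synthetic cohorts

A `CohortSpec` holds per-stage whole-day duration distributions,
per-stage completion probabilities, the female fraction at emergence, a
pre-oviposition-delay distribution, a daily fecundity curve over
adult-female age and sex-specific adult-longevity distributions.
Simulation draws each individual's path; a stage failure kills after a
uniformly chosen 1…d days in the stage (at least one day, so every egg
is alive on its oviposition day). Daily egg counts are Poisson with the
curve's mean by default; negative-binomial (overdispersed) and
deterministic (rounded mean) variants exist — the deterministic mode
makes degenerate specs hit closed forms exactly (a pulse of M eggs at
emergence age E gives `R0 = M`, `r = ln(M)/(E+1)`).

`expected_schedules` computes the spec's *exact* expected `l_x`,
`s_xj`, `f_x`, `m_x` by convolving duration distributions under the
cumulative completion probabilities (the within-stage presence
probability at offset t is `p + (1−p)(d−t)/d` summed over durations
`d > t`); `f` and `m` are ratios of expectations, i.e. the estimators'
large-cohort limits. `true_params` feeds these to the same parameter
code, giving ground truth for recovery tests: consistency at
`n0 = 10,000` (within 1% on r), Monte-Carlo agreement of mean `l_x`
(200 cohorts, 3 SE), and bootstrap CI coverage of the true r in ≥90 of
100 replicates at `n0 = 150`, `B = 1,000`.

**Study-style specs.** `study_spec(T)` builds an illustrative spec per
rearing temperature from the published cohort means: smallest-support
two-point whole-day distributions matching each mean duration, delay
and longevity; overall immature mortality spread evenly over the
immature stages (all on the egg stage at 36 °C, where no egg hatches);
a 1:1 sex ratio; and a triangular daily-fecundity hump over the
oviposition window scaled to mean lifetime fecundity. These specs
emulate the study *design* — they make no claim to reproduce the
study's estimated growth parameters, whose raw data were not deposited,
and their two-point durations understate real between-individual
variance. Passing recovery tests therefore demonstrates estimator
correctness under the stated generative model, not fidelity of that
model to field data.

## Problem sizes and numerical choices

Tests simulate cohorts of 15–150 individuals (10,000 for the
consistency check) and use B = 1,000–2,000 bootstrap replicates; the
analysis scripts use `n0 = 150` per temperature and B = 2,000, both
chosen as typical of published cohort studies. Bisection tolerance
1e−12; Euler–Lotka residual tolerance 1e−10; all simulation and
bootstrap entry points require an explicit seed and are bit-reproducible
given one.

## Limitations

No censoring: the record format assumes every individual is followed to
death, as in the source design; individuals lost to handling cannot be
represented. The thermal model is descriptive (log-linear), not a
mechanistic or threshold/degree-day model, and is fitted on means.
Bootstrap CIs are percentile, which can undercover for strongly skewed
replicate distributions at small `n0`. The simulator draws stage
durations independently across stages and individuals; correlated
development speeds are not modelled.
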