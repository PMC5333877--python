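# agestage

Age-stage, two-sex life table analysis for insect cohort demography.

Cohort studies of ectotherm pests — here modelled on the sweet potato
leaf folder *Brachmia macroscopa* reared at constant temperatures —
follow every individual from egg to death, recording daily stage molts,
sex at emergence and each female's daily egg production. This package
turns such per-individual records into the standard age-stage, two-sex
life table quantities and their uncertainties:

* **Schedules** — the age-stage survival rate `s_xj` (probability a
  newborn is alive and in stage *j* at age *x*), age-specific survival
  `l_x = Σ_j s_xj`, age-stage fecundity `f_xj` (daily eggs per surviving
  adult female) and age-specific fecundity `m_x` (daily eggs per
  surviving individual of either sex).
* **Growth parameters** — net reproductive rate `R0 = Σ l_x m_x`, gross
  reproductive rate `GRR = Σ m_x`, the intrinsic rate of increase *r*
  solving the Euler–Lotka equation `Σ e^{−r(x+1)} l_x m_x = 1`, the
  finite rate `λ = e^r` and mean generation time `T = ln(R0)/r`, with
  standard errors and percentile confidence intervals from a
  nonparametric bootstrap over individuals.
* **Descriptive tables** — stage durations, pre-adult time, immature
  mortality, adult longevity and lifespan by sex, APOP/TPOP, oviposition
  period and lifetime fecundity, as `mean±SE letter` cells from one-way
  ANOVA with Fisher's LSD and a compact letter display.
* **Thermal response** — the log-linear development-rate regression
  `rate = a + b·ln(T)` over rearing temperatures.
* **Synthetic cohorts** — a stochastic simulator whose generating spec
  admits *exact* expected schedules and growth parameters, used
  throughout the test suite for estimator validation.

## Worked example

Simulate a 150-egg cohort in the 27 °C study configuration, estimate
its growth parameters, and compare with the simulator's exact truth:

```python
import agestage as ag

spec = ag.study_spec(27, n0=150, seed=3)     # illustrative 27 °C cohort spec
cohort = ag.simulate_cohort(spec)
assert ag.validate_cohort(cohort) == []

schedule = ag.life_schedule(cohort)
print(ag.population_params(schedule).as_dict())
# {'R0': 128.24, 'GRR': 150.28, 'r': 0.1567, 'lambda': 1.1697, 'T': 30.97}
print(ag.true_params(spec).as_dict())
# {'R0': 125.80, 'GRR': 148.58, 'r': 0.1553, 'lambda': 1.1680, 'T': 31.13}

boot = ag.bootstrap_params(cohort, B=1000, seed=5)
print(round(boot.se["r"], 4), boot.ci["r"])
# 0.0031 — the 95% CI comfortably covers the true r above
```

`R0 ≈ 128` means each newly laid egg is expected to leave ~128 eggs in
the next generation; `r ≈ 0.157`/day (`λ ≈ 1.17`/day) is the cohort's
asymptotic exponential growth rate, and a generation spans ~31 days.
The point estimates sit within about one bootstrap SE of the generating
truth.

The same computations are exposed as a CLI (`agestage simulate`,
`agestage lifetable`, `agestage thermal`, `agestage compare`) and as a
scripted analysis sequence under `analysis/` (simulate cohorts at
21–36 °C → life tables → bootstrapped parameters → thermal regression →
lettered group comparisons), which writes its tables under `results/`.

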