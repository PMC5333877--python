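"""Synthetic cohorts with analytically known life-table quantities.

A :class:`CohortSpec` is a generative description of a cohort study:
per-stage whole-day duration distributions, per-stage completion
probabilities, the female fraction among emerging adults, an adult
pre-oviposition delay, a daily fecundity curve over adult-female age and
sex-specific adult longevity distributions.  Two consumers share it:

* :func:`simulate_cohort` draws a cohort of individual records from it
  (reproducibly, given a seed), exercising the exact record format the
  rest of the package consumes;
* :func:`expected_schedules` computes the spec's *exact* expected
  ``l_x``, ``s_xj``, ``f_xj`` and ``m_x`` by convolving the stage
  duration distributions under the survival probabilities — the ground
  truth against which estimators are checked.

Timing conventions: stage durations are whole days; an individual that
fails a stage dies after a uniformly chosen number of days lived in it
(1..d, so every egg is alive on its day of oviposition); eggs are laid
once per day of adult-female age ``t`` with mean ``curve[t]`` whenever
``t`` is at least the female's pre-oviposition delay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import ConfigError
from .lifetable import LifeSchedule
from .records import FEMALE, MALE, Cohort, IndividualRecord
from .scheme import StageScheme

Pmf = dict[int, float]


def _check_pmf(pmf: Pmf, name: str, min_key: int = 1) -> None:
    if not pmf:
        raise ConfigError(f"{name}: empty distribution")
    if abs(sum(pmf.values()) - 1.0) > 1e-9:
        raise ConfigError(f"{name}: probabilities sum to {sum(pmf.values())}, not 1")
    for k, p in pmf.items():
        if int(k) != k or k < min_key:
            raise ConfigError(f"{name}: invalid support point {k!r}")
        if p < 0:
            raise ConfigError(f"{name}: negative probability at {k}")


def _sample_pmf(pmf: Pmf, rng: np.random.Generator) -> int:
    keys = list(pmf)
    return int(keys[rng.choice(len(keys), p=list(pmf.values()))])


def point_pmf(value: int) -> Pmf:
    return {int(value): 1.0}


def two_point_pmf(mean: float) -> Pmf:
    """Smallest-support whole-day distribution with the given mean."""
    lo = int(math.floor(mean))
    if lo == mean:
        return {lo: 1.0}
    w = mean - lo
    return {lo: 1.0 - w, lo + 1: w}


@dataclass
class CohortSpec:
    """Generative description of a cohort study (see module docstring)."""

    n0: int
    treatment: str
    stages: tuple[str, ...]                # immature stages, egg first
    duration_pmf: dict[str, Pmf]           # whole-day durations per stage
    survival: dict[str, float]             # P(complete the stage | entered)
    female_fraction: float
    apop_pmf: Pmf                          # adult pre-oviposition delay, days >= 0
    fecundity_curve: tuple[float, ...]     # mean eggs by adult-female age
    longevity_pmf: dict[str, Pmf]          # sex -> adult longevity, days >= 1
    fecundity_dispersion: str = "poisson"  # poisson | negbin | deterministic
    negbin_k: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n0 < 1:
            raise ConfigError(f"n0 must be positive, got {self.n0}")
        if len(self.stages) < 1:
            raise ConfigError("at least one immature stage required")
        for s in self.stages:
            if s not in self.duration_pmf:
                raise ConfigError(f"no duration distribution for stage {s!r}")
            _check_pmf(self.duration_pmf[s], f"duration of {s!r}", min_key=1)
            p = self.survival.get(s)
            if p is None or not 0.0 <= p <= 1.0:
                raise ConfigError(f"survival of {s!r} must be in [0, 1], got {p!r}")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigError("female_fraction must be in [0, 1]")
        _check_pmf(self.apop_pmf, "pre-oviposition delay", min_key=0)
        if any(v < 0 for v in self.fecundity_curve):
            raise ConfigError("fecundity curve must be non-negative")
        for sex in (FEMALE, MALE):
            _check_pmf(self.longevity_pmf[sex], f"{sex} adult longevity", min_key=1)
        if self.fecundity_dispersion not in ("poisson", "negbin", "deterministic"):
            raise ConfigError(
                f"unknown fecundity dispersion {self.fecundity_dispersion!r}"
            )

    @property
    def scheme(self) -> StageScheme:
        return StageScheme(stages=tuple([*self.stages, "adult"]))

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n0": self.n0,
            "treatment": self.treatment,
            "stages": list(self.stages),
            "duration_pmf": {s: {int(k): float(v) for k, v in p.items()}
                             for s, p in self.duration_pmf.items()},
            "survival": {s: float(v) for s, v in self.survival.items()},
            "female_fraction": self.female_fraction,
            "apop_pmf": {int(k): float(v) for k, v in self.apop_pmf.items()},
            "fecundity_curve": [float(v) for v in self.fecundity_curve],
            "longevity_pmf": {sx: {int(k): float(v) for k, v in p.items()}
                              for sx, p in self.longevity_pmf.items()},
            "fecundity_dispersion": self.fecundity_dispersion,
            "negbin_k": self.negbin_k,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        d["stages"] = tuple(d["stages"])
        d["fecundity_curve"] = tuple(d["fecundity_curve"])
        d["duration_pmf"] = {s: {int(k): v for k, v in p.items()}
                             for s, p in d["duration_pmf"].items()}
        d["apop_pmf"] = {int(k): v for k, v in d["apop_pmf"].items()}
        d["longevity_pmf"] = {sx: {int(k): v for k, v in p.items()}
                              for sx, p in d["longevity_pmf"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _draw_eggs(mean: float, spec: CohortSpec, rng: np.random.Generator) -> int:
    if mean <= 0:
        return 0
    if spec.fecundity_dispersion == "deterministic":
        return int(round(mean))
    if spec.fecundity_dispersion == "poisson":
        return int(rng.poisson(mean))
    k = spec.negbin_k
    return int(rng.negative_binomial(k, k / (k + mean)))


def simulate_cohort(spec: CohortSpec, seed: int | None = None) -> Cohort:
    """Draw a full cohort of individual records from the spec.

    Fully reproducible: the same spec and seed yield an identical
    cohort.  ``seed`` overrides the spec's own seed when given.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    scheme = spec.scheme
    records: list[IndividualRecord] = []
    curve = np.asarray(spec.fecundity_curve, dtype=float)
    for i in range(spec.n0):
        rid = f"{spec.treatment}-{i + 1:04d}"
        durations: dict[str, int] = {}
        death_stage: str | None = None
        days_in_death = 0
        for s in spec.stages:
            d = _sample_pmf(spec.duration_pmf[s], rng)
            if rng.random() < spec.survival[s]:
                durations[s] = d
            else:
                death_stage = s
                days_in_death = int(rng.integers(1, d + 1))  # dies after 1..d days
                break
        sex = "undetermined"
        fecundity: dict[int, int] = {}
        if death_stage is None:
            death_stage = scheme.adult
            sex = FEMALE if rng.random() < spec.female_fraction else MALE
            longevity = _sample_pmf(spec.longevity_pmf[sex], rng)
            days_in_death = longevity
            if sex == FEMALE:
                emergence = sum(durations.values())
                apop = _sample_pmf(spec.apop_pmf, rng)
                for t in range(apop, longevity):
                    mean = curve[t] if t < len(curve) else 0.0
                    eggs = _draw_eggs(mean, spec, rng)
                    if eggs:
                        fecundity[emergence + t] = eggs
        records.append(
            IndividualRecord(
                identifier=rid,
                treatment=spec.treatment,
                sex=sex,
                stage_durations=durations,
                death_stage=death_stage,
                days_in_death_stage=days_in_death,
                fecundity_by_age=fecundity,
            )
        )
    return Cohort(treatment=spec.treatment, records=records, scheme=scheme)


# ---------------------------------------------------------------------------
# exact expected schedules
# ---------------------------------------------------------------------------


def _convolve_pmf(a: np.ndarray, pmf: Pmf) -> np.ndarray:
    kernel = np.zeros(max(pmf) + 1)
    for k, p in pmf.items():
        kernel[k] = p
    return np.convolve(a, kernel)


def expected_schedules(spec: CohortSpec) -> LifeSchedule:
    """Exact expected s_xj, l_x, f_xj and m_x implied by the spec.

    Stage entry-age distributions are convolutions of the upstream
    duration distributions (conditional on survival); within a stage an
    individual is present at offset ``t`` with probability
    ``p + (1-p)·(d-t)/d`` summed over durations ``d > t``, the second
    term being the uniformly timed death of stage failures.  Fecundity
    combines the female fraction, the pre-oviposition delay, the
    longevity survivor function and the fecundity curve.  ``f_x`` and
    ``m_x`` are ratios of expectations (eggs over presence), matching
    the estimators' large-cohort limit.
    """
    stages = spec.stages
    max_total = sum(max(spec.duration_pmf[s]) for s in stages)
    max_long = max(max(spec.longevity_pmf[FEMALE]), max(spec.longevity_pmf[MALE]))
    A = max_total + max_long - 1
    ages = np.arange(A + 1)
    af, am = "adult female", "adult male"
    matrix_stages = tuple([*stages, af, am])
    s = np.zeros((A + 1, len(matrix_stages)))

    entry = np.zeros(A + 1)
    entry[0] = 1.0  # P(entry age of first stage = 0)
    surv_to_entry = 1.0
    for k, stage in enumerate(stages):
        pmf = spec.duration_pmf[stage]
        p = spec.survival[stage]
        dmax = max(pmf)
        # presence probability at within-stage offset t
        present = np.zeros(dmax)
        for t in range(dmax):
            present[t] = sum(
                q * (p + (1 - p) * (d - t) / d) for d, q in pmf.items() if d > t
            )
        occ = np.convolve(entry, present)[: A + 1]
        s[:, k] = surv_to_entry * occ
        entry = _convolve_pmf(entry, pmf)[: A + 1]
        surv_to_entry *= p

    # adults: longevity survivor functions by sex
    phi = spec.female_fraction
    for col, sex, frac in ((af, FEMALE, phi), (am, MALE, 1 - phi)):
        pmf = spec.longevity_pmf[sex]
        lmax = max(pmf)
        alive = np.array([sum(q for L, q in pmf.items() if L > t) for t in range(lmax)])
        occ = np.convolve(entry, alive)[: A + 1]
        s[:, matrix_stages.index(col)] = surv_to_entry * frac * occ

    # expected eggs per newborn at each age
    curve = np.asarray(spec.fecundity_curve, dtype=float)
    lf_pmf = spec.longevity_pmf[FEMALE]
    lmax = max(lf_pmf)
    apop_cdf = np.array(
        [sum(q for a0, q in spec.apop_pmf.items() if a0 <= t) for t in range(lmax)]
    )
    lay = np.zeros(lmax)
    for t in range(lmax):
        mean = curve[t] if t < len(curve) else 0.0
        if spec.fecundity_dispersion == "deterministic":
            mean = round(mean)
        alive_t = sum(q for L, q in lf_pmf.items() if L > t)
        lay[t] = mean * apop_cdf[t] * alive_t
    eggs = surv_to_entry * phi * np.convolve(entry, lay)[: A + 1]

    l = s.sum(axis=1)
    f = np.zeros_like(s)
    kf = matrix_stages.index(af)
    with np.errstate(invalid="ignore", divide="ignore"):
        f[:, kf] = np.where(s[:, kf] > 0, eggs / np.where(s[:, kf] > 0, s[:, kf], 1), 0.0)
    m = np.where(l > 0, eggs / np.where(l > 0, l, 1.0), 0.0)
    return LifeSchedule(
        ages=ages, survival=l, fecundity_matrix=f, stages=matrix_stages, fecundity=m
    )


def true_params(spec: CohortSpec):
    """Population parameters implied by the spec's expected schedules."""
    from .params import population_params

    return population_params(expected_schedules(spec))


# ---------------------------------------------------------------------------
# study-style demonstration specs
# ---------------------------------------------------------------------------

# Published cohort-mean summaries for the sweet-potato leaf folder reared at
# constant temperatures: stage durations (days), immature mortality (%),
# adult longevity by sex (days), pre-oviposition delay (days), oviposition
# period (days) and lifetime fecundity (eggs/female).  Used only to build
# illustrative specs; a spec built from means does not claim to reproduce
# the study's estimated growth parameters.
STUDY_TABLES: dict[int, dict] = {
    21: {
        "durations": {"egg": 6.35, "L1": 1.36, "L2": 2.48, "L3": 3.44, "L4": 2.83,
                      "L5": 3.35, "L6": 4.52, "L7": 5.79, "pupa": 8.15},
        "mortality_pct": 24.66,
        "longevity": {FEMALE: 25.90, MALE: 26.62},
        "apop": 2.55, "oviposition_period": 19.06, "fecundity": 376.02,
    },
    24: {
        "durations": {"egg": 5.0, "L1": 1.11, "L2": 2.05, "L3": 3.17, "L4": 2.68,
                      "L5": 3.58, "L6": 2.87, "pupa": 6.90},
        "mortality_pct": 31.43,
        "longevity": {FEMALE: 26.14, MALE: 29.68},
        "apop": 1.46, "oviposition_period": 15.40, "fecundity": 299.17,
    },
    27: {
        "durations": {"egg": 5.0, "L1": 1.85, "L2": 1.96, "L3": 2.08, "L4": 2.20,
                      "L5": 4.41, "pupa": 5.04},
        "mortality_pct": 15.33,
        "longevity": {FEMALE: 32.70, MALE: 34.17},
        "apop": 1.45, "oviposition_period": 18.31, "fecundity": 299.18,
    },
    30: {
        "durations": {"egg": 3.0, "L1": 1.28, "L2": 2.80, "L3": 1.92, "L4": 1.77,
                      "L5": 3.71, "pupa": 4.07},
        "mortality_pct": 26.00,
        "longevity": {FEMALE: 17.41, MALE: 17.98},
        "apop": 1.14, "oviposition_period": 11.94, "fecundity": 321.28,
    },
    33: {
        "durations": {"egg": 3.0, "L1": 1.10, "L2": 1.94, "L3": 1.40, "L4": 2.67,
                      "L5": 2.98, "pupa": 4.06},
        "mortality_pct": 27.52,
        "longevity": {FEMALE: 28.52, MALE: 25.29},
        "apop": 3.81, "oviposition_period": 11.22, "fecundity": 23.24,
    },
    # at 36 °C no egg hatched; represented as zero egg-stage survival
    36: {
        "durations": {"egg": 3.0, "L1": 1.1, "L2": 1.9, "L3": 1.4, "L4": 2.7,
                      "L5": 3.0, "pupa": 4.1},
        "mortality_pct": 100.0,
        "longevity": {FEMALE: 10.0, MALE: 10.0},
        "apop": 3.0, "oviposition_period": 5.0, "fecundity": 0.0,
    },
}


def study_spec(temperature: int, n0: int = 150, seed: int = 0) -> CohortSpec:
    """An illustrative spec parameterised from the study's printed means.

    Durations and delays become smallest-support whole-day distributions
    matching each mean; overall immature mortality is spread evenly
    across the immature stages (at 36 °C it all falls on the egg stage);
    the sex ratio is 1:1; daily fecundity is a triangular hump over the
    oviposition window scaled to the mean lifetime fecundity.
    """
    try:
        tab = STUDY_TABLES[temperature]
    except KeyError:
        raise ConfigError(
            f"no study table for {temperature} °C; choose from {sorted(STUDY_TABLES)}"
        )
    stages = tuple(tab["durations"])
    duration_pmf = {s: two_point_pmf(mu) for s, mu in tab["durations"].items()}
    q = tab["mortality_pct"] / 100.0
    if q >= 1.0:
        survival = {s: 1.0 for s in stages}
        survival["egg"] = 0.0
    else:
        per_stage = (1.0 - q) ** (1.0 / len(stages))
        survival = {s: per_stage for s in stages}
    apop_lo = int(math.floor(tab["apop"]))
    window = max(1, int(round(tab["oviposition_period"])))
    peak = apop_lo + max(1, window // 3)
    t_axis = np.arange(apop_lo, apop_lo + window, dtype=float)
    weights = np.minimum(
        (t_axis - apop_lo + 1) / max(peak - apop_lo + 1, 1),
        (apop_lo + window - t_axis) / max(apop_lo + window - peak, 1),
    )
    weights = np.clip(weights, 0.05, None)
    curve = np.zeros(apop_lo + window)
    if tab["fecundity"] > 0:
        curve[apop_lo:] = tab["fecundity"] * weights / weights.sum()
    return CohortSpec(
        n0=n0,
        treatment=f"{temperature}C",
        stages=stages,
        duration_pmf=duration_pmf,
        survival=survival,
        female_fraction=0.5,
        apop_pmf=two_point_pmf(tab["apop"]),
        fecundity_curve=tuple(curve),
        longevity_pmf={sx: two_point_pmf(mu) for sx, mu in tab["longevity"].items()},
        seed=seed,
    )
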