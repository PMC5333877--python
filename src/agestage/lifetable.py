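"""Age-stage, two-sex life table construction.

From a cohort of per-individual records this module builds the central
objects of the age-stage, two-sex life table:

* ``s_xj`` — the probability that a newly laid egg is alive *and* in
  stage ``j`` at age ``x`` (a daily census of the cohort divided by the
  initial cohort size ``n0``).  Because only adult females reproduce,
  the adult stage is carried as two columns, adult female and adult
  male, as is standard for two-sex life tables.
* ``l_x = Σ_j s_xj`` — age-specific survival.
* ``f_xj`` — daily eggs per surviving adult female at age ``x``
  (nonzero only in the adult-female column).
* ``m_x = Σ_j s_xj f_xj / Σ_j s_xj`` — daily eggs per surviving
  individual of either sex, so that ``n0 · Σ_x l_x m_x`` equals the
  total number of eggs the cohort laid, exactly.

It also produces the descriptive summaries usually tabulated alongside:
stage durations, immature mortality, adult longevity and lifespan, and
the reproduction summary (APOP, TPOP, oviposition period, fecundity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .records import FEMALE, MALE, Cohort, IndividualRecord
from .scheme import StageScheme


def _adult_columns(scheme: StageScheme) -> tuple[str, str]:
    return f"{scheme.adult} female", f"{scheme.adult} male"


@dataclass
class AgeStageMatrix:
    """``s_xj`` over ages 0..A and the cohort's analysis stages.

    ``stages`` are the scheme's immature stages followed by the
    adult-female and adult-male columns.  Every entry is a multiple of
    ``1/n0`` by construction.
    """

    ages: np.ndarray          # shape (A+1,)
    stages: tuple[str, ...]
    s: np.ndarray             # shape (A+1, n_stages)
    n0: int
    scheme: StageScheme

    def column(self, stage: str) -> np.ndarray:
        return self.s[:, self.stages.index(stage)]

    @property
    def adult_female_column(self) -> np.ndarray:
        return self.column(_adult_columns(self.scheme)[0])


@dataclass
class LifeSchedule:
    """Aligned per-age vectors: l_x, f_xj, m_x and net maternity l_x·m_x."""

    ages: np.ndarray
    survival: np.ndarray        # l_x
    fecundity_matrix: np.ndarray  # f_xj, same shape as s_xj
    stages: tuple[str, ...]
    fecundity: np.ndarray       # m_x

    @property
    def net_maternity(self) -> np.ndarray:
        return self.survival * self.fecundity

    @property
    def female_fecundity(self) -> np.ndarray:
        """f_x of the adult-female column (the only nonzero one)."""
        return self.fecundity_matrix.max(axis=1)


def build_age_stage_survival(cohort: Cohort) -> AgeStageMatrix:
    """Daily census of each record's stage intervals, divided by n0."""
    if not cohort.records:
        raise DataError("cannot build a life table from an empty cohort")
    scheme = cohort.scheme
    af, am = _adult_columns(scheme)
    stages = tuple([*scheme.immature_stages, af, am])
    col = {s: k for k, s in enumerate(stages)}
    A = cohort.max_death_age - 1
    counts = np.zeros((max(A, 0) + 1, len(stages)), dtype=np.int64)
    for rec in cohort.records:
        for stage, entry, exit_ in rec.stage_intervals(scheme):
            if exit_ <= entry:
                continue
            if stage == scheme.adult:
                stage = af if rec.sex == FEMALE else am
            counts[entry:exit_, col[stage]] += 1
    return AgeStageMatrix(
        ages=np.arange(counts.shape[0]),
        stages=stages,
        s=counts / cohort.n0,
        n0=cohort.n0,
        scheme=scheme,
    )


def age_specific_survival(matrix: AgeStageMatrix) -> np.ndarray:
    """l_x = Σ_j s_xj."""
    return matrix.s.sum(axis=1)


def age_stage_fecundity(cohort: Cohort, matrix: AgeStageMatrix) -> np.ndarray:
    """f_xj: eggs per surviving adult female; zero elsewhere (0/0 -> 0)."""
    af, _ = _adult_columns(cohort.scheme)
    k = matrix.stages.index(af)
    eggs = np.zeros(len(matrix.ages))
    for rec in cohort.records:
        for age, n in rec.fecundity_by_age.items():
            eggs[age] += n
    females_alive = matrix.s[:, k] * matrix.n0
    f = np.zeros_like(matrix.s)
    with np.errstate(invalid="ignore", divide="ignore"):
        fx = np.where(females_alive > 0, eggs / np.where(females_alive > 0, females_alive, 1), 0.0)
    f[:, k] = fx
    return f


def age_specific_fecundity(matrix: AgeStageMatrix, fecundity_matrix: np.ndarray) -> np.ndarray:
    """m_x = Σ_j s_xj f_xj / Σ_j s_xj, with 0 where no one is alive."""
    l = matrix.s.sum(axis=1)
    num = (matrix.s * fecundity_matrix).sum(axis=1)
    return np.where(l > 0, num / np.where(l > 0, l, 1.0), 0.0)


def life_schedule(cohort: Cohort, matrix: AgeStageMatrix | None = None) -> LifeSchedule:
    """Convenience: build the full schedule bundle from a cohort."""
    if matrix is None:
        matrix = build_age_stage_survival(cohort)
    f = age_stage_fecundity(cohort, matrix)
    return LifeSchedule(
        ages=matrix.ages,
        survival=age_specific_survival(matrix),
        fecundity_matrix=f,
        stages=matrix.stages,
        fecundity=age_specific_fecundity(matrix, f),
    )


# ---------------------------------------------------------------------------
# descriptive summaries
# ---------------------------------------------------------------------------


def mean_se(values) -> tuple[float, float, int]:
    """(mean, SE, n); SE = sample SD / sqrt(n), NaN for n < 2."""
    v = np.asarray(list(values), dtype=float)
    n = v.size
    if n == 0:
        return math.nan, math.nan, 0
    if n == 1:
        return float(v[0]), math.nan, 1
    return float(v.mean()), float(v.std(ddof=1) / math.sqrt(n)), n


@dataclass
class StageDurationSummary:
    """Mean±SE stage durations over completers, plus longevity/lifespan."""

    stage_stats: dict[str, tuple[float, float, int]]       # analysis stage -> (mean, se, n)
    preadult: tuple[float, float, int]                     # over individuals reaching adult
    adult_longevity: dict[str, tuple[float, float, int]]   # sex -> stats
    lifespan: dict[str, tuple[float, float, int]]          # sex -> stats (egg to death)
    immature_mortality_pct: float


@dataclass
class ReproductionSummary:
    """Per reproducing female: APOP, TPOP, oviposition period, fecundity."""

    apop: tuple[float, float, int]
    tpop: tuple[float, float, int]
    oviposition_period: tuple[float, float, int]
    total_fecundity: tuple[float, float, int]
    n_reproducing: int
    per_female: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return self.n_reproducing == 0


def immature_mortality(cohort: Cohort) -> float:
    """Percentage of the initial cohort dying before the adult stage."""
    deaths = sum(1 for r in cohort.records if r.death_stage != cohort.scheme.adult)
    return 100.0 * deaths / cohort.n0


def stage_duration_summary(cohort: Cohort) -> StageDurationSummary:
    """Table-style durations: completers only; death days excluded.

    An individual dying inside a stage contributed to ``s_xj`` for the
    days it lived there, but it never completed the stage, so it is left
    out of that stage's duration mean.
    """
    scheme = cohort.scheme
    per_stage: dict[str, list[int]] = {s: [] for s in scheme.immature_stages}
    preadult: list[int] = []
    longevity: dict[str, list[int]] = {FEMALE: [], MALE: []}
    lifespan: dict[str, list[int]] = {FEMALE: [], MALE: []}
    for rec in cohort.records:
        for s, d in rec.stage_durations.items():
            per_stage[s].append(d)
        if rec.reached_adult(scheme):
            preadult.append(sum(rec.stage_durations.values()))
            if rec.sex in longevity:
                longevity[rec.sex].append(rec.days_in_death_stage)
                lifespan[rec.sex].append(rec.death_age)
    return StageDurationSummary(
        stage_stats={s: mean_se(v) for s, v in per_stage.items()},
        preadult=mean_se(preadult),
        adult_longevity={sx: mean_se(v) for sx, v in longevity.items()},
        lifespan={sx: mean_se(v) for sx, v in lifespan.items()},
        immature_mortality_pct=immature_mortality(cohort),
    )


def reproduction_summary(cohort: Cohort, oviposition_mode: str = "span") -> ReproductionSummary:
    """APOP, TPOP, oviposition period and total fecundity per female.

    ``oviposition_mode`` chooses the oviposition-period convention:
    ``"span"`` (default) counts last egg day − first egg day + 1,
    including zero-egg gap days; ``"active"`` counts only days with at
    least one egg.
    """
    if oviposition_mode not in ("span", "active"):
        raise DataError(f"unknown oviposition mode {oviposition_mode!r}")
    scheme = cohort.scheme
    apop, tpop, ovip, fec = [], [], [], []
    per_female: dict[str, dict[str, float]] = {}
    for rec in cohort.records:
        if rec.sex != FEMALE or not rec.reached_adult(scheme):
            continue
        first = rec.first_egg_age
        if first is None:
            continue
        last = rec.last_egg_age
        emergence = rec.emergence_age(scheme)
        if oviposition_mode == "span":
            period = last - first + 1
        else:
            period = sum(1 for e in rec.fecundity_by_age.values() if e > 0)
        stats = {
            "apop": first - emergence,
            "tpop": first,
            "oviposition_period": period,
            "total_fecundity": rec.total_eggs,
        }
        per_female[rec.identifier] = stats
        apop.append(stats["apop"])
        tpop.append(stats["tpop"])
        ovip.append(stats["oviposition_period"])
        fec.append(stats["total_fecundity"])
    return ReproductionSummary(
        apop=mean_se(apop),
        tpop=mean_se(tpop),
        oviposition_period=mean_se(ovip),
        total_fecundity=mean_se(fec),
        n_reproducing=len(per_female),
        per_female=per_female,
    )
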