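"""Per-individual life-history records and cohorts.

Age convention: age 0 is the day of oviposition.  An individual that
enters a stage at age ``e`` and spends ``d`` whole days in it occupies
that stage on the half-open interval of days ``[e, e + d)``.  Death age
is the first day on which the individual is no longer alive, so an
individual is alive on days ``0 .. death_age - 1``.  Durations are whole
days throughout, matching a daily observation cadence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import DataError
from .scheme import StageScheme

FEMALE = "female"
MALE = "male"
UNDETERMINED = "undetermined"
SEXES = (FEMALE, MALE, UNDETERMINED)


@dataclass
class IndividualRecord:
    """One organism's complete observed life history.

    ``stage_durations`` holds whole-day durations of *completed* stages
    in developmental order; the stage in which the individual died is
    named by ``death_stage``, with ``days_in_death_stage`` days lived in
    it.  Adults are never "completed": an adult dying of old age has
    ``death_stage`` equal to the adult label and its adult longevity in
    ``days_in_death_stage``.  ``fecundity_by_age`` maps age (days since
    oviposition) to eggs laid that day; only nonzero days need storing.
    """

    identifier: str
    treatment: str
    sex: str
    stage_durations: dict[str, int]
    death_stage: str
    days_in_death_stage: int
    fecundity_by_age: dict[int, int] = field(default_factory=dict)

    @property
    def death_age(self) -> int:
        return sum(self.stage_durations.values()) + self.days_in_death_stage

    def entry_age(self, stage: str, scheme: StageScheme) -> int:
        """Age at which this individual entered ``stage`` (must have reached it)."""
        age = 0
        for s in scheme.stages:
            if s == stage:
                return age
            if s in self.stage_durations:
                age += self.stage_durations[s]
            else:
                raise DataError(
                    f"record {self.identifier!r} never reached stage {stage!r}"
                )
        raise DataError(f"unknown stage {stage!r}")

    def reached_adult(self, scheme: StageScheme) -> bool:
        return self.death_stage == scheme.adult

    def emergence_age(self, scheme: StageScheme) -> int:
        """Age at adult emergence (entry into the adult stage)."""
        return self.entry_age(scheme.adult, scheme)

    def stage_intervals(self, scheme: StageScheme) -> list[tuple[str, int, int]]:
        """(stage, entry_age, exit_age) triples; alive on [entry, exit)."""
        out: list[tuple[str, int, int]] = []
        age = 0
        for s in scheme.stages:
            if s == self.death_stage:
                out.append((s, age, age + self.days_in_death_stage))
                return out
            if s in self.stage_durations:
                d = self.stage_durations[s]
                out.append((s, age, age + d))
                age += d
            else:
                raise DataError(
                    f"record {self.identifier!r}: death stage {self.death_stage!r} "
                    "not found on its stage path"
                )
        raise DataError(
            f"record {self.identifier!r}: death stage {self.death_stage!r} "
            "is not in the scheme"
        )

    @property
    def total_eggs(self) -> int:
        return sum(self.fecundity_by_age.values())

    @property
    def first_egg_age(self) -> int | None:
        laying = [a for a, e in self.fecundity_by_age.items() if e > 0]
        return min(laying) if laying else None

    @property
    def last_egg_age(self) -> int | None:
        laying = [a for a, e in self.fecundity_by_age.items() if e > 0]
        return max(laying) if laying else None


@dataclass
class Cohort:
    """All individuals started as eggs under one treatment."""

    treatment: str
    records: list[IndividualRecord]
    scheme: StageScheme

    @property
    def n0(self) -> int:
        return len(self.records)

    @property
    def max_death_age(self) -> int:
        return max(r.death_age for r in self.records)


def validate_cohort(cohort: Cohort) -> list[str]:
    """Check every record invariant; violations are returned, not raised.

    Returns an empty list iff the cohort is internally consistent.  Each
    violation names the offending record and the rule it breaks.
    """
    scheme = cohort.scheme
    out: list[str] = []
    seen_ids: set[str] = set()
    for rec in cohort.records:
        rid = rec.identifier
        if rid in seen_ids:
            out.append(f"{rid}: duplicate identifier")
        seen_ids.add(rid)
        if rec.treatment != cohort.treatment:
            out.append(f"{rid}: treatment {rec.treatment!r} != cohort {cohort.treatment!r}")
        if rec.sex not in SEXES:
            out.append(f"{rid}: unknown sex {rec.sex!r}")
        if rec.death_stage not in scheme.stages:
            out.append(f"{rid}: death stage {rec.death_stage!r} not in scheme")
            continue
        if rec.days_in_death_stage < 0:
            out.append(f"{rid}: negative days_in_death_stage")
        # completed stages must be exactly those preceding the death stage
        path = scheme.stages[: scheme.index(rec.death_stage)]
        if tuple(rec.stage_durations) != path:
            out.append(
                f"{rid}: completed stages {tuple(rec.stage_durations)} do not match "
                f"the stages before {rec.death_stage!r} ({path})"
            )
            continue
        for s, d in rec.stage_durations.items():
            if not isinstance(d, int) or d <= 0:
                out.append(f"{rid}: stage {s!r} duration {d!r} is not a positive integer")
        died_adult = rec.death_stage == scheme.adult
        if rec.sex == UNDETERMINED and died_adult:
            out.append(f"{rid}: sex undetermined but individual reached the adult stage")
        if rec.sex != UNDETERMINED and not died_adult:
            # sex is observable only at adult emergence in this design; a
            # recorded sex on a pre-adult death is suspicious but legal in
            # principle (e.g. sexed pupae) — not flagged.
            pass
        if rec.fecundity_by_age:
            if rec.sex != FEMALE:
                out.append(f"{rid}: fecundity recorded for sex {rec.sex!r}")
            else:
                emergence = sum(rec.stage_durations.values())
                bad_age = [a for a in rec.fecundity_by_age if a < emergence]
                if bad_age:
                    out.append(
                        f"{rid}: fecundity at age(s) {sorted(bad_age)} before "
                        f"adult emergence at age {emergence}"
                    )
                dead = [a for a in rec.fecundity_by_age if a >= rec.death_age]
                if dead:
                    out.append(
                        f"{rid}: fecundity at age(s) {sorted(dead)} on or after "
                        f"death age {rec.death_age}"
                    )
            if any(e < 0 for e in rec.fecundity_by_age.values()):
                out.append(f"{rid}: negative egg count")
    return out


def apply_grouping(cohort: Cohort) -> Cohort:
    """Pool raw stages onto analysis stages, summing durations.

    Durations of raw stages mapped to the same analysis stage are summed;
    if death occurred partway through a pooled run of raw stages, the
    days already completed in earlier members of the run count toward the
    days lived in the pooled death stage.  Record count, each
    individual's death age and its fecundity series are all unchanged.
    """
    scheme = cohort.scheme
    if not scheme.grouping:
        return cohort
    gscheme = scheme.grouped()
    new_records: list[IndividualRecord] = []
    for rec in cohort.records:
        death_label = scheme.analysis_label(rec.death_stage)
        durations: dict[str, int] = {}
        for s, d in rec.stage_durations.items():
            lab = scheme.analysis_label(s)
            if lab == death_label:
                continue  # folded into days_in_death_stage below
            durations[lab] = durations.get(lab, 0) + d
        extra = sum(
            d
            for s, d in rec.stage_durations.items()
            if scheme.analysis_label(s) == death_label
        )
        new_records.append(
            replace(
                rec,
                stage_durations=durations,
                death_stage=death_label,
                days_in_death_stage=rec.days_in_death_stage + extra,
            )
        )
    return Cohort(treatment=cohort.treatment, records=new_records, scheme=gscheme)
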