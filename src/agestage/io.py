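"""Reading and writing cohort files.

A cohort is stored as two CSV tables: a rectangular individuals table
(one row per organism, one column per raw stage duration) and a long
fecundity table (identifier, age, eggs) holding each female's daily egg
counts.  Stage schemes and grouping maps travel as YAML.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .errors import DataError
from .records import Cohort, IndividualRecord
from .scheme import StageScheme

_FIXED_COLUMNS = ("identifier", "treatment", "sex", "death_stage", "days_in_death_stage")


def _fecundity_path(individuals_path: Path) -> Path:
    return individuals_path.with_name(individuals_path.stem + "_fecundity.csv")


def write_cohort(
    cohort: Cohort,
    path: str | Path,
    fecundity_path: str | Path | None = None,
) -> tuple[Path, Path]:
    """Write the individuals table to ``path`` and the egg series to a
    companion long table (default: ``<stem>_fecundity.csv`` next to it)."""
    path = Path(path)
    fec_path = Path(fecundity_path) if fecundity_path else _fecundity_path(path)
    rows = []
    fec_rows = []
    for rec in cohort.records:
        row: dict[str, object] = {
            "identifier": rec.identifier,
            "treatment": rec.treatment,
            "sex": rec.sex,
            "death_stage": rec.death_stage,
            "days_in_death_stage": rec.days_in_death_stage,
        }
        for s in cohort.scheme.stages:
            row[s] = rec.stage_durations.get(s, "")
        rows.append(row)
        for age in sorted(rec.fecundity_by_age):
            fec_rows.append(
                {"identifier": rec.identifier, "age": age, "eggs": rec.fecundity_by_age[age]}
            )
    cols = list(_FIXED_COLUMNS) + list(cohort.scheme.stages)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    pd.DataFrame(fec_rows, columns=["identifier", "age", "eggs"]).to_csv(
        fec_path, index=False
    )
    return path, fec_path


def _parse_int(value, *, row: int, col: str) -> int:
    """Whole-day parser: rejects fractional values instead of rounding."""
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise DataError(f"row {row}: column {col!r} value {value!r} is not a number")
    if f != int(f):
        raise DataError(
            f"row {row}: column {col!r} value {value!r} is not a whole number of days"
        )
    return int(f)


def read_cohort(
    path: str | Path,
    scheme: StageScheme,
    fecundity_path: str | Path | None = None,
) -> Cohort:
    """Read and validate a cohort written by :func:`write_cohort`.

    Row order is preserved.  Malformed fields raise :class:`DataError`
    naming the row and column; structural inconsistencies are reported
    by :func:`agestage.records.validate_cohort`.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    fec_path = Path(fecundity_path) if fecundity_path else _fecundity_path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _FIXED_COLUMNS if c not in df.columns]
    missing += [s for s in scheme.stages[:-1] if s not in df.columns]
    if missing:
        raise DataError(f"{path}: missing column(s) {missing}")

    fec_by_id: dict[str, dict[int, int]] = {}
    if fec_path.exists():
        fec = pd.read_csv(fec_path, dtype=str, keep_default_na=False)
        for c in ("identifier", "age", "eggs"):
            if c not in fec.columns:
                raise DataError(f"{fec_path}: missing column {c!r}")
        for i, frow in enumerate(fec.itertuples(index=False), start=2):
            age = _parse_int(frow.age, row=i, col="age")
            eggs = _parse_int(frow.eggs, row=i, col="eggs")
            fec_by_id.setdefault(str(frow.identifier), {})[age] = eggs

    records: list[IndividualRecord] = []
    treatments = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rowd = row._asdict()
        durations: dict[str, int] = {}
        for s in scheme.stages:
            raw = rowd.get(s, "")
            if raw not in ("", None):
                durations[s] = _parse_int(raw, row=i, col=s)
        rid = str(rowd["identifier"])
        rec = IndividualRecord(
            identifier=rid,
            treatment=str(rowd["treatment"]),
            sex=str(rowd["sex"]),
            stage_durations=durations,
            death_stage=str(rowd["death_stage"]),
            days_in_death_stage=_parse_int(
                rowd["days_in_death_stage"], row=i, col="days_in_death_stage"
            ),
            fecundity_by_age=fec_by_id.get(rid, {}),
        )
        if rec.fecundity_by_age and rec.sex != "female":
            raise DataError(
                f"row {i}: fecundity recorded for {rid!r} but sex is {rec.sex!r}"
            )
        treatments.add(rec.treatment)
        records.append(rec)
    if not records:
        raise DataError(f"{path}: no records")
    if len(treatments) > 1:
        raise DataError(f"{path}: multiple treatments in one cohort file: {sorted(treatments)}")
    return Cohort(treatment=treatments.pop(), records=records, scheme=scheme)


def read_scheme(path: str | Path) -> StageScheme:
    with open(path) as fh:
        return StageScheme.from_dict(yaml.safe_load(fh))


def write_scheme(scheme: StageScheme, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scheme.to_dict(), fh, sort_keys=False)
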