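"""Tabular views of life-table results, for CSV export and display."""

from __future__ import annotations

import pandas as pd

from .lifetable import (
    AgeStageMatrix,
    LifeSchedule,
    ReproductionSummary,
    StageDurationSummary,
)
from .params import BootstrapResult, PARAM_NAMES


def matrix_frame(matrix: AgeStageMatrix) -> pd.DataFrame:
    """s_xj as a tidy frame: one row per age, one column per stage."""
    df = pd.DataFrame(matrix.s, columns=list(matrix.stages))
    df.insert(0, "age", matrix.ages)
    return df


def schedule_frame(schedule: LifeSchedule) -> pd.DataFrame:
    """Per-age l_x, f_x (adult female), m_x and net maternity l_x·m_x."""
    return pd.DataFrame(
        {
            "age": schedule.ages,
            "lx": schedule.survival,
            "fx_female": schedule.female_fecundity,
            "mx": schedule.fecundity,
            "lxmx": schedule.net_maternity,
        }
    )


def _stats_row(label: str, stats: tuple[float, float, int]) -> dict:
    mean, se, n = stats
    return {"quantity": label, "mean": mean, "se": se, "n": n}


def duration_frame(summary: StageDurationSummary) -> pd.DataFrame:
    rows = [_stats_row(f"{s} period", st) for s, st in summary.stage_stats.items()]
    rows.append(_stats_row("total preadult", summary.preadult))
    for sex, st in summary.adult_longevity.items():
        rows.append(_stats_row(f"{sex} adult longevity", st))
    for sex, st in summary.lifespan.items():
        rows.append(_stats_row(f"{sex} entire lifespan", st))
    rows.append(
        {"quantity": "immature mortality (%)",
         "mean": summary.immature_mortality_pct, "se": float("nan"), "n": ""}
    )
    return pd.DataFrame(rows)


def reproduction_frame(summary: ReproductionSummary) -> pd.DataFrame:
    rows = [
        _stats_row("APOP", summary.apop),
        _stats_row("TPOP", summary.tpop),
        _stats_row("oviposition period", summary.oviposition_period),
        _stats_row("total fecundity/female", summary.total_fecundity),
    ]
    return pd.DataFrame(rows)


def params_frame(point: dict[str, float], boot: BootstrapResult | None = None) -> pd.DataFrame:
    rows = []
    for p in PARAM_NAMES:
        row: dict = {"parameter": p, "estimate": point[p]}
        if boot is not None:
            row["se"] = boot.se[p]
            row["ci_low"], row["ci_high"] = boot.ci[p]
            row["B"] = boot.B
            row["degenerate_replicates"] = boot.n_degenerate
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_text(df: pd.DataFrame, float_format: str = "%.4f") -> str:
    return df.to_string(index=False, float_format=lambda v: float_format % v) + "\n"
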