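#!/usr/bin/env python
"""Compare treatments: ANOVA + LSD letters on per-individual traits.

For each of several life-history traits (pre-adult duration, adult
longevity by sex, lifetime fecundity) this pools the per-individual
values from the simulated cohorts, runs a one-way ANOVA across
temperatures, and prints each treatment as the conventional
"mean±SE letter" cell (groups sharing a letter do not differ at the 5%
level by LSD).
"""

import argparse
import json
from pathlib import Path

from agestage import one_way_anova, read_cohort, read_scheme
from agestage.compare import format_mean_se_letter


def trait_values(cohort):
    scheme = cohort.scheme
    adults = [r for r in cohort.records if r.death_stage == scheme.adult]
    return {
        "preadult_days": [sum(r.stage_durations.values()) for r in adults],
        "female_longevity": [r.days_in_death_stage for r in adults if r.sex == "female"],
        "male_longevity": [r.days_in_death_stage for r in adults if r.sex == "male"],
        "total_fecundity": [r.total_eggs for r in adults
                            if r.sex == "female" and r.total_eggs > 0],
    }


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohorts", type=Path, default=Path("results/cohorts"))
    ap.add_argument("--out", type=Path, default=Path("results/comparison.json"))
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()

    by_trait: dict[str, dict[str, list]] = {}
    for cohort_dir in sorted(args.cohorts.iterdir()):
        if not (cohort_dir / "individuals.csv").exists():
            continue
        scheme = read_scheme(cohort_dir / "scheme.yaml")
        cohort = read_cohort(cohort_dir / "individuals.csv", scheme)
        for trait, values in trait_values(cohort).items():
            if len(values) >= 2:
                by_trait.setdefault(trait, {})[cohort.treatment] = values

    results = {}
    for trait, groups in by_trait.items():
        if len(groups) < 2:
            continue
        anova = one_way_anova(groups)
        cells = format_mean_se_letter(groups, alpha=args.alpha)
        results[trait] = {
            "F": anova.f_statistic,
            "df": [anova.df_between, anova.df_within],
            "p": anova.p_value,
            "cells": cells,
        }
        print(f"\n{trait}  (F = {anova.f_statistic:.1f}, p = {anova.p_value:.2e})")
        for g in sorted(cells):
            print(f"  {g:>5}: {cells[g]}")

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(results, indent=2) + "\n")
    print(f"\nwrote {args.out}")


if __name__ == "__main__":
    main()
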