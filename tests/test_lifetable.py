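"""Age-stage survival matrix, schedules, and cohort summaries."""

import numpy as np
import pytest

from agestage import (
    Cohort,
    StageScheme,
    age_specific_fecundity,
    age_specific_survival,
    age_stage_fecundity,
    build_age_stage_survival,
    immature_mortality,
    life_schedule,
    reproduction_summary,
    simulate_cohort,
    stage_duration_summary,
    study_spec,
)
from agestage.lifetable import mean_se

from conftest import make_record


def census_oracle(cohort):
    """Brute-force daily headcount, independent of the matrix builder:
    walk each record's cumulative durations day by day."""
    scheme = cohort.scheme
    A = max(r.death_age for r in cohort.records) - 1
    af, am = f"{scheme.adult} female", f"{scheme.adult} male"
    stages = list(scheme.immature_stages) + [af, am]
    counts = {(x, s): 0 for x in range(A + 1) for s in stages}
    for rec in cohort.records:
        for x in range(rec.death_age):
            age = 0
            stage = None
            for s, d in rec.stage_durations.items():
                if age <= x < age + d:
                    stage = s
                age += d
            if stage is None:  # in the death stage
                stage = rec.death_stage
                if stage == scheme.adult:
                    stage = af if rec.sex == "female" else am
            counts[(x, stage)] += 1
    out = np.zeros((A + 1, len(stages)))
    for (x, s), c in counts.items():
        out[x, stages.index(s)] = c
    return out / cohort.n0, tuple(stages)


class TestSurvivalMatrix:
    def test_single_individual_path(self, toy_scheme):
        rec = make_record(toy_scheme, "a", durations={"egg": 2, "L1": 1},
                          death_stage="L2", days_in_death_stage=0)
        m = build_age_stage_survival(Cohort("t", [rec], toy_scheme))
        assert m.column("egg").tolist() == [1, 1, 0]
        assert m.column("L1").tolist() == [0, 0, 1]
        assert m.s.sum() == 3  # three days alive in total

    def test_matches_brute_force_census(self, tiny_cohort, study_cohort):
        for cohort in (tiny_cohort, study_cohort):
            m = build_age_stage_survival(cohort)
            expected, stages = census_oracle(cohort)
            assert m.stages == stages
            np.testing.assert_allclose(m.s, expected)

    def test_census_on_randomized_small_cohorts(self):
        for seed in range(10):
            cohort = simulate_cohort(study_spec(30, n0=15, seed=seed))
            m = build_age_stage_survival(cohort)
            expected, _ = census_oracle(cohort)
            np.testing.assert_allclose(m.s, expected)

    def test_every_entry_is_a_multiple_of_one_over_n0(self, study_cohort):
        m = build_age_stage_survival(study_cohort)
        np.testing.assert_allclose(m.s * m.n0, np.round(m.s * m.n0))

    def test_row_sums_conserved_until_first_death(self, toy_scheme):
        recs = [
            make_record(toy_scheme, f"i{k}", sex="male",
                        durations={"egg": 2, "L1": 2, "L2": 2, "pupa": 2},
                        death_stage="adult", days_in_death_stage=4 + k)
            for k in range(5)
        ]
        m = build_age_stage_survival(Cohort("t", recs, toy_scheme))
        np.testing.assert_allclose(m.s[:12].sum(axis=1), 1.0)


class TestSchedules:
    def test_lx_is_fraction_surviving_past_each_age(self, study_cohort):
        m = build_age_stage_survival(study_cohort)
        l = age_specific_survival(m)
        deaths = np.array([r.death_age for r in study_cohort.records])
        expected = [(deaths > x).mean() for x in m.ages]
        np.testing.assert_allclose(l, expected)
        assert l[0] == 1.0
        assert np.all(np.diff(l) <= 1e-12)  # non-increasing up to float summation

    def test_female_fecundity_is_eggs_per_surviving_female(self, toy_scheme):
        recs = [
            make_record(toy_scheme, f"f{k}", sex="female",
                        durations={"egg": 1, "L1": 1, "L2": 1, "pupa": 1},
                        death_stage="adult", days_in_death_stage=10,
                        fecundity={5: eggs})
            for k, eggs in enumerate([10, 20])
        ]
        cohort = Cohort("t", recs, toy_scheme)
        m = build_age_stage_survival(cohort)
        f = age_stage_fecundity(cohort, m)
        assert f[5].max() == 15.0
        assert f[3].max() == 0.0  # no eggs, and 0/0 -> 0 after everyone dies

    def test_mx_averages_over_both_sexes(self, toy_scheme):
        recs = []
        for k, eggs in enumerate([15, 15]):
            recs.append(make_record(toy_scheme, f"f{k}", sex="female",
                                    durations={"egg": 1, "L1": 1, "L2": 1, "pupa": 1},
                                    death_stage="adult", days_in_death_stage=10,
                                    fecundity={5: eggs}))
        for k in range(2):
            recs.append(make_record(toy_scheme, f"m{k}", sex="male",
                                    durations={"egg": 1, "L1": 1, "L2": 1, "pupa": 1},
                                    death_stage="adult", days_in_death_stage=10))
        cohort = Cohort("t", recs, toy_scheme)
        m = build_age_stage_survival(cohort)
        f = age_stage_fecundity(cohort, m)
        mx = age_specific_fecundity(m, f)
        assert mx[5] == pytest.approx(7.5)

    def test_egg_conservation_identities(self, study_cohort):
        schedule = life_schedule(study_cohort)
        total_eggs = sum(r.total_eggs for r in study_cohort.records)
        # n0 · Σ l_x m_x equals total eggs laid, exactly
        assert study_cohort.n0 * schedule.net_maternity.sum() == pytest.approx(
            total_eggs, abs=1e-9
        )
        # Σ_x f_x · (#females alive at x) equals total eggs too
        m = build_age_stage_survival(study_cohort)
        females = m.adult_female_column * m.n0
        assert (schedule.female_fecundity * females).sum() == pytest.approx(
            total_eggs, abs=1e-9
        )


class TestSummaries:
    def test_mean_and_se_of_two_values(self):
        mean, se, n = mean_se([2, 4])
        assert (mean, se, n) == (3.0, 1.0, 2)

    def test_dying_individuals_excluded_from_stage_means(self, toy_scheme):
        recs = [
            make_record(toy_scheme, "a", sex="male",
                        durations={"egg": 2, "L1": 4, "L2": 2, "pupa": 2},
                        death_stage="adult", days_in_death_stage=3),
            make_record(toy_scheme, "b", durations={"egg": 2},
                        death_stage="L1", days_in_death_stage=9),
        ]
        s = stage_duration_summary(Cohort("t", recs, toy_scheme))
        mean, _, n = s.stage_stats["L1"]
        assert (mean, n) == (4.0, 1)  # the death in L1 does not count
        assert s.stage_stats["egg"][2] == 2

    def test_summary_matches_direct_arithmetic(self, study_cohort):
        s = stage_duration_summary(study_cohort)
        scheme = study_cohort.scheme
        pupal = [r.stage_durations["pupa"] for r in study_cohort.records
                 if "pupa" in r.stage_durations]
        assert s.stage_stats["pupa"][0] == pytest.approx(np.mean(pupal))
        assert s.stage_stats["pupa"][1] == pytest.approx(
            np.std(pupal, ddof=1) / np.sqrt(len(pupal))
        )
        pre = [sum(r.stage_durations.values()) for r in study_cohort.records
               if r.death_stage == scheme.adult]
        assert s.preadult[0] == pytest.approx(np.mean(pre))

    def test_immature_mortality_examples(self, toy_scheme):
        def cohort_with(n_dead, n_total):
            recs = [make_record(toy_scheme, f"d{k}", death_stage="egg",
                                days_in_death_stage=1) for k in range(n_dead)]
            recs += [make_record(toy_scheme, f"a{k}", sex="male",
                                 durations={"egg": 1, "L1": 1, "L2": 1, "pupa": 1},
                                 death_stage="adult", days_in_death_stage=2)
                     for k in range(n_total - n_dead)]
            return Cohort("t", recs, toy_scheme)

        assert immature_mortality(cohort_with(23, 150)) == pytest.approx(15.3333333)
        assert immature_mortality(cohort_with(0, 10)) == 0.0
        assert immature_mortality(cohort_with(10, 10)) == 100.0


class TestReproductionSummary:
    def _female(self, scheme, fecundity, ident="f"):
        return make_record(scheme, ident, sex="female",
                           durations={"egg": 5, "L1": 5, "L2": 5, "pupa": 5},
                           death_stage="adult", days_in_death_stage=15,
                           fecundity=fecundity)

    def test_apop_and_tpop(self, toy_scheme):
        rec = self._female(toy_scheme, {22: 3, 30: 1})  # emerges at age 20
        s = reproduction_summary(Cohort("t", [rec], toy_scheme))
        assert s.per_female["f"]["apop"] == 2
        assert s.per_female["f"]["tpop"] == 22
        assert s.per_female["f"]["total_fecundity"] == 4

    def test_oviposition_period_conventions(self, toy_scheme):
        rec = self._female(toy_scheme, {22: 1, 23: 2, 25: 1})  # gap on day 24
        span = reproduction_summary(Cohort("t", [rec], toy_scheme))
        active = reproduction_summary(Cohort("t", [rec], toy_scheme),
                                      oviposition_mode="active")
        assert span.per_female["f"]["oviposition_period"] == 4
        assert active.per_female["f"]["oviposition_period"] == 3

    def test_forced_apop_has_zero_se(self):
        spec = study_spec(27, n0=80, seed=5)
        d = spec.to_dict()
        d["apop_pmf"] = {1: 1.0}
        d["fecundity_dispersion"] = "deterministic"
        cohort = simulate_cohort(type(spec).from_dict(d))
        s = reproduction_summary(cohort)
        assert s.n_reproducing > 0
        assert s.apop[0] == 1.0
        assert s.apop[1] == 0.0

    def test_no_reproducing_females_flags_empty(self, toy_scheme):
        rec = make_record(toy_scheme, "m", sex="male",
                          durations={"egg": 1, "L1": 1, "L2": 1, "pupa": 1},
                          death_stage="adult", days_in_death_stage=2)
        assert reproduction_summary(Cohort("t", [rec], toy_scheme)).empty
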