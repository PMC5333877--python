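"""Population growth parameters: closed forms, solver, bootstrap."""

import math

import numpy as np
import pytest

from agestage import (
    Cohort,
    EstimationError,
    bootstrap_params,
    finite_rate,
    gross_reproductive_rate,
    intrinsic_rate,
    life_schedule,
    mean_generation_time,
    net_reproductive_rate,
    population_params,
    simulate_cohort,
    study_spec,
)
from agestage.lifetable import LifeSchedule
from agestage.params import CohortArrays

from conftest import make_record


def schedule_from(l, m):
    l = np.asarray(l, dtype=float)
    m = np.asarray(m, dtype=float)
    n = len(l)
    return LifeSchedule(
        ages=np.arange(n),
        survival=l,
        fecundity_matrix=np.zeros((n, 1)),
        stages=("adult female",),
        fecundity=m,
    )


class TestPointEstimates:
    def test_r0_and_grr_are_schedule_sums(self):
        s = schedule_from([1, 1, 0.5], [0, 5, 3])
        assert net_reproductive_rate(s) == pytest.approx(6.5)
        assert gross_reproductive_rate(s) == pytest.approx(8.0)

    def test_grr_bounds_r0_and_equals_it_without_mortality(self):
        with_mortality = schedule_from([1, 0.8, 0.5], [0, 2, 4])
        assert gross_reproductive_rate(with_mortality) > net_reproductive_rate(with_mortality)
        no_mortality = schedule_from([1, 1, 1], [0, 2, 4])
        assert gross_reproductive_rate(no_mortality) == pytest.approx(
            net_reproductive_rate(no_mortality)
        )

    def test_single_pulse_has_closed_form_rate(self):
        # reproduction pulse M at age x gives r = ln(M)/(x+1)
        s = schedule_from([1.0], [math.e**2])
        assert intrinsic_rate(s) == pytest.approx(2.0, abs=1e-9)
        s3 = schedule_from([1, 1, 1, 1], [0, 0, 0, 16.0])
        assert intrinsic_rate(s3) == pytest.approx(math.log(16) / 4, abs=1e-9)

    def test_two_pulse_analytic_case(self):
        # 2e^{-2r} + 4e^{-3r} = 1 at r = ln 2
        s = schedule_from([1, 1, 1], [0, 2, 4])
        assert intrinsic_rate(s) == pytest.approx(math.log(2), abs=1e-9)

    def test_negative_rate_for_declining_cohort(self):
        s = schedule_from([1, 0.5], [0, 1.0])  # R0 = 0.5 < 1
        assert intrinsic_rate(s) < 0

    def test_rate_agrees_with_fine_grid_scan(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(3, 30)
            l = np.sort(rng.random(n))[::-1]
            l[0] = 1.0
            m = rng.random(n) * rng.integers(1, 10)
            s = schedule_from(l, m)
            r = intrinsic_rate(s)
            grid = np.linspace(r - 0.01, r + 0.01, 20001)
            g = np.array([
                (np.exp(-x * (s.ages + 1)) * l * m).sum() - 1 for x in grid
            ])
            r_grid = grid[np.argmin(np.abs(g))]
            assert r == pytest.approx(r_grid, abs=1e-5)

    def test_euler_lotka_residual_below_tolerance(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(2, 25))
            l = np.minimum.accumulate(rng.random(n) + 0.01)
            m = rng.random(n) * 5
            s = schedule_from(l, m)
            r = intrinsic_rate(s)
            residual = (np.exp(-r * (s.ages + 1)) * l * m).sum() - 1
            assert abs(residual) <= 1e-10

    def test_sign_law(self):
        base_l = np.array([1, 0.9, 0.8, 0.6])
        base_m = np.array([0, 1.0, 2.0, 1.0])
        R0_base = (base_l * base_m).sum()
        for scale, sign in [(2.0, 1), (0.3, -1)]:
            s = schedule_from(base_l, scale / R0_base * base_m)
            r = intrinsic_rate(s)
            assert np.sign(r) == (1 if scale > 1 else -1) == sign
        s_unit = schedule_from(base_l, base_m / R0_base)  # R0 = 1 exactly
        assert intrinsic_rate(s_unit) == pytest.approx(0.0, abs=1e-9)

    def test_identities_lambda_and_t(self):
        s = schedule_from([1, 1, 0.9, 0.8], [0, 0, 3.0, 4.0])
        p = population_params(s)
        assert p.lambda_ == pytest.approx(math.exp(p.r), rel=1e-12)
        assert p.T == pytest.approx(math.log(p.R0) / p.r, rel=1e-12)

    def test_undefined_cases_raise(self):
        with pytest.raises(EstimationError):
            intrinsic_rate(schedule_from([1, 1], [0, 0]))
        with pytest.raises(EstimationError):
            mean_generation_time(0.0, 0.1)
        with pytest.raises(EstimationError):
            mean_generation_time(2.0, 0.0)
        assert finite_rate(0.0) == 1.0


class TestBootstrap:
    def test_requires_seed_and_replicates(self, study_cohort):
        with pytest.raises(EstimationError):
            bootstrap_params(study_cohort, B=10, seed=None)
        with pytest.raises(EstimationError):
            bootstrap_params(study_cohort, B=1, seed=3)

    def test_identical_clones_have_zero_se(self, toy_scheme):
        recs = [
            make_record(toy_scheme, f"f{k}", sex="female",
                        durations={"egg": 1, "L1": 1, "L2": 1, "pupa": 1},
                        death_stage="adult", days_in_death_stage=5,
                        fecundity={5: 8})
            for k in range(6)
        ]
        boot = bootstrap_params(Cohort("t", recs, toy_scheme), B=50, seed=1)
        for p, se in boot.se.items():
            assert se == pytest.approx(0.0, abs=1e-12), p

    def test_same_seed_is_bit_identical(self, study_cohort):
        b1 = bootstrap_params(study_cohort, B=40, seed=7)
        b2 = bootstrap_params(study_cohort, B=40, seed=7)
        for p in b1.replicates:
            np.testing.assert_array_equal(b1.replicates[p], b2.replicates[p])

    def test_independent_seeds_agree_on_ses(self, study_cohort):
        b1 = bootstrap_params(study_cohort, B=2000, seed=11)
        b2 = bootstrap_params(study_cohort, B=2000, seed=222)
        for p in b1.se:
            assert b1.se[p] == pytest.approx(b2.se[p], rel=0.15), p

    def test_degenerate_replicates_are_counted_and_warned(self, toy_scheme):
        recs = [make_record(toy_scheme, f"m{k}", sex="male",
                            durations={"egg": 1, "L1": 1, "L2": 1, "pupa": 1},
                            death_stage="adult", days_in_death_stage=5)
                for k in range(7)]
        recs.append(make_record(toy_scheme, "f", sex="female",
                                durations={"egg": 1, "L1": 1, "L2": 1, "pupa": 1},
                                death_stage="adult", days_in_death_stage=5,
                                fecundity={5: 10}))
        cohort = Cohort("t", recs, toy_scheme)
        with pytest.warns(UserWarning, match="no reproduction"):
            boot = bootstrap_params(cohort, B=200, seed=2)
        # P(resample misses the single layer) = (7/8)^8 ~ 0.34
        assert 0 < boot.n_degenerate < 200
        assert np.isnan(boot.replicates["r"]).sum() == boot.n_degenerate

    def test_fast_path_equals_record_pipeline(self, study_cohort):
        arrays = CohortArrays(study_cohort)
        fast = arrays.point_params(tol=1e-12)
        slow = population_params(life_schedule(study_cohort)).as_dict()
        for p in fast:
            assert fast[p] == pytest.approx(slow[p], abs=1e-10), p

    def test_fast_path_on_resamples_matches_rebuilt_cohort(self, toy_scheme):
        spec = study_spec(30, n0=40, seed=3)
        cohort = simulate_cohort(spec)
        arrays = CohortArrays(cohort)
        rng = np.random.default_rng(0)
        for _ in range(5):
            idx = rng.integers(0, cohort.n0, size=cohort.n0)
            resampled = Cohort(
                cohort.treatment,
                [_renamed(cohort.records[i], k) for k, i in enumerate(idx)],
                cohort.scheme,
            )
            slow = population_params(life_schedule(resampled)).as_dict()
            fast = arrays.resample_params(idx, tol=1e-12)
            for p in fast:
                assert fast[p] == pytest.approx(slow[p], abs=1e-9), p


def _renamed(rec, k):
    from dataclasses import replace

    return replace(rec, identifier=f"r{k}")
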