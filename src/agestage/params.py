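"""Population growth parameters and bootstrap uncertainty.

Point estimates from a :class:`~agestage.lifetable.LifeSchedule`:

* net reproductive rate        ``R0  = Σ_x l_x m_x``
* gross reproductive rate      ``GRR = Σ_x m_x``
* intrinsic rate of increase   ``r`` solving ``Σ_x e^{-r(x+1)} l_x m_x = 1``
* finite rate of increase      ``λ = e^r``
* mean generation time         ``T = ln(R0) / r``

The Euler–Lotka exponent uses ``x + 1`` with age 0 the day of
oviposition: a pulse of reproduction on age ``x`` is discounted one full
day more than its age, the convention used when the census is taken at
the end of each day.

Uncertainty comes from a nonparametric bootstrap over individuals: each
replicate resamples ``n0`` records with replacement and reruns the whole
pipeline (census → schedules → parameters).  Replicates in which the
resample contains no reproduction (``R0 = 0``) leave ``r``, ``λ`` and
``T`` undefined; they are counted, excluded from those parameters'
statistics, and reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import EstimationError
from .lifetable import LifeSchedule, build_age_stage_survival, life_schedule
from .records import FEMALE, Cohort

PARAM_NAMES = ("R0", "GRR", "r", "lambda", "T")
_RATE_PARAMS = ("r", "lambda", "T")


@dataclass
class PopulationParams:
    """Point estimates of the five growth parameters."""

    R0: float
    GRR: float
    r: float
    lambda_: float
    T: float

    def as_dict(self) -> dict[str, float]:
        return {"R0": self.R0, "GRR": self.GRR, "r": self.r,
                "lambda": self.lambda_, "T": self.T}


@dataclass
class BootstrapResult:
    """Replicate vectors, SEs and percentile CIs for every parameter."""

    B: int
    replicates: dict[str, np.ndarray]      # NaN marks degenerate replicates
    se: dict[str, float]
    ci: dict[str, tuple[float, float]]
    n_degenerate: int
    ci_level: float = 0.95


# ---------------------------------------------------------------------------
# point estimates
# ---------------------------------------------------------------------------


def net_reproductive_rate(schedule: LifeSchedule) -> float:
    """R0 = Σ l_x m_x — expected lifetime offspring per newborn."""
    return float(np.sum(schedule.survival * schedule.fecundity))


def gross_reproductive_rate(schedule: LifeSchedule) -> float:
    """GRR = Σ m_x — reproduction with mortality ignored."""
    return float(np.sum(schedule.fecundity))


def _euler_lotka_root(ages: np.ndarray, lm: np.ndarray, tol: float) -> float:
    """Root of g(r) = Σ e^{-r(x+1)} l_x m_x − 1 by bracketing + bisection.

    g is strictly decreasing in r wherever lm has mass, so the root is
    unique; the initial bracket [−1, 1] /day is expanded geometrically
    until it straddles the root.
    """
    w = lm > 0
    x1 = (ages[w] + 1).astype(float)
    lmw = lm[w]

    def g(r: float) -> float:
        return float(np.dot(np.exp(-r * x1), lmw)) - 1.0

    lo, hi = -1.0, 1.0
    for _ in range(200):
        if g(lo) > 0:
            break
        lo *= 2.0
    for _ in range(200):
        if g(hi) < 0:
            break
        hi *= 2.0
    if not (g(lo) > 0 > g(hi)):
        raise EstimationError("failed to bracket the Euler-Lotka root")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def intrinsic_rate(schedule: LifeSchedule, tol: float = 1e-12) -> float:
    """The unique real r satisfying Σ e^{-r(x+1)} l_x m_x = 1.

    Negative when R0 < 1 (a declining cohort); undefined when R0 = 0.
    """
    lm = schedule.net_maternity
    if float(lm.sum()) <= 0.0:
        raise EstimationError("intrinsic rate undefined: R0 = 0 (no reproduction)")
    return _euler_lotka_root(np.asarray(schedule.ages), lm, tol)


def finite_rate(r: float) -> float:
    """λ = e^r, the per-day population multiplier."""
    return math.exp(r)


def mean_generation_time(R0: float, r: float) -> float:
    """T = ln(R0)/r: days for an R0-fold increase at the stable stage
    distribution."""
    if R0 <= 0:
        raise EstimationError(f"mean generation time undefined for R0 = {R0}")
    if r == 0:
        raise EstimationError("mean generation time undefined for r = 0")
    return math.log(R0) / r


def population_params(schedule: LifeSchedule, tol: float = 1e-12) -> PopulationParams:
    """All five parameters from one schedule (R0 must be positive)."""
    R0 = net_reproductive_rate(schedule)
    GRR = gross_reproductive_rate(schedule)
    r = intrinsic_rate(schedule, tol=tol)
    return PopulationParams(R0=R0, GRR=GRR, r=r, lambda_=finite_rate(r),
                            T=mean_generation_time(R0, r))


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


class CohortArrays:
    """Per-individual arrays for fast resampled life-table pipelines.

    Stores, for each record, its death age, a per-age egg count row and
    a per-age adult-female-alive indicator row.  A resample's l_x, m_x
    and the five parameters are then row-gathers and sums — numerically
    identical to rebuilding the life table from the resampled records.
    """

    def __init__(self, cohort: Cohort):
        scheme = cohort.scheme
        n = cohort.n0
        A = cohort.max_death_age - 1
        self.n0 = n
        self.ages = np.arange(A + 1)
        self.death_age = np.array([r.death_age for r in cohort.records])
        self.eggs = np.zeros((n, A + 1))
        self.female_adult_alive = np.zeros((n, A + 1), dtype=bool)
        for i, rec in enumerate(cohort.records):
            for age, e in rec.fecundity_by_age.items():
                self.eggs[i, age] += e
            if rec.sex == FEMALE and rec.reached_adult(scheme):
                em = rec.emergence_age(scheme)
                self.female_adult_alive[i, em:rec.death_age] = True

    def resample_params(self, idx: np.ndarray, tol: float = 1e-10) -> dict[str, float]:
        """Parameters of the resample ``idx``; NaN rates if R0 = 0."""
        n = len(idx)
        death = self.death_age[idx]
        # alive at x  <=>  death age > x, so #alive(x) = n - #{death_age <= x}
        counts = np.bincount(death, minlength=len(self.ages) + 1)
        alive = n - np.cumsum(counts)[: len(self.ages)]
        eggs = self.eggs[idx].sum(axis=0)
        l = alive / n
        m = np.where(alive > 0, eggs / np.where(alive > 0, alive, 1), 0.0)
        lm = l * m
        R0 = float(lm.sum())
        GRR = float(m.sum())
        if R0 <= 0:
            return {"R0": R0, "GRR": GRR, "r": math.nan,
                    "lambda": math.nan, "T": math.nan}
        r = _euler_lotka_root(self.ages, lm, tol)
        return {"R0": R0, "GRR": GRR, "r": r, "lambda": math.exp(r),
                "T": math.log(R0) / r if r != 0 else math.nan}

    def point_params(self, tol: float = 1e-12) -> dict[str, float]:
        return self.resample_params(np.arange(self.n0), tol=tol)


def bootstrap_params(
    cohort: Cohort,
    B: int = 10_000,
    seed: int | None = None,
    tol: float = 1e-10,
    ci_level: float = 0.95,
) -> BootstrapResult:
    """Bootstrap SEs and percentile CIs for R0, GRR, r, λ and T.

    Resamples ``n0`` individuals with replacement ``B`` times and reruns
    the full estimation pipeline on each resample.  The SE of each
    parameter is the standard deviation of its replicate values; CIs are
    equal-tail percentiles.  Replicates without reproduction are
    excluded from the r/λ/T statistics (with a warning) but kept, as
    zeros, in R0 and GRR.
    """
    if B < 2:
        raise EstimationError("bootstrap needs B >= 2 replicates")
    if seed is None:
        raise EstimationError("bootstrap requires an explicit seed")
    rng = np.random.default_rng(seed)
    arrays = CohortArrays(cohort)
    reps = {p: np.empty(B) for p in PARAM_NAMES}
    for b in range(B):
        idx = rng.integers(0, arrays.n0, size=arrays.n0)
        for p, v in arrays.resample_params(idx, tol=tol).items():
            reps[p][b] = v
    n_degenerate = int(np.isnan(reps["r"]).sum())
    if n_degenerate == B:
        raise EstimationError("all bootstrap replicates were degenerate (R0 = 0)")
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate}/{B} bootstrap replicates had no reproduction; "
            "they are excluded from the r/lambda/T statistics",
            stacklevel=2,
        )
    lo_q, hi_q = 100 * (1 - ci_level) / 2, 100 * (1 + ci_level) / 2
    se: dict[str, float] = {}
    ci: dict[str, tuple[float, float]] = {}
    for p in PARAM_NAMES:
        v = reps[p][~np.isnan(reps[p])] if p in _RATE_PARAMS else reps[p]
        se[p] = float(np.std(v, ddof=1))
        ci[p] = (float(np.percentile(v, lo_q)), float(np.percentile(v, hi_q)))
    return BootstrapResult(B=B, replicates=reps, se=se, ci=ci,
                           n_degenerate=n_degenerate, ci_level=ci_level)
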