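"""Temperature dependence of development rate.

Within the favourable range, an ectotherm's development rate (the
reciprocal of its stage duration, 1/day) rises with rearing temperature.
This module fits the simple log-linear description

    rate = a + b · log(T)

by ordinary least squares on per-temperature mean rates.  R² is
invariant to the logarithm's base; the slope scales by ln(base) and the
intercept does not move (one unit of temperature has log 0 in every
base).  The natural log is the default base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import statsmodels.api as sm

from .errors import DataError


@dataclass
class ThermalFit:
    intercept: float
    slope: float
    r_squared: float
    log_base: float
    temperatures: tuple[float, ...]
    observed: tuple[float, ...]
    fitted: tuple[float, ...]

    def predict(self, temperature: float) -> float:
        return self.intercept + self.slope * math.log(temperature, self.log_base)

    def as_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "slope": self.slope,
            "r_squared": self.r_squared,
            "log_base": self.log_base,
            "temperatures": list(self.temperatures),
            "observed_rates": list(self.observed),
            "fitted_rates": list(self.fitted),
        }


def development_rates(durations: Mapping[float, float]) -> dict[float, float]:
    """Map temperature -> development rate = 1 / mean stage duration."""
    out = {}
    for temp, dur in durations.items():
        if dur <= 0:
            raise DataError(f"non-positive duration {dur} at {temp} degrees")
        out[temp] = 1.0 / dur
    return out


def fit_log_model(
    points: Mapping[float, float] | Iterable[tuple[float, float]],
    base: float = math.e,
) -> ThermalFit:
    """OLS of development rate on log(temperature).

    ``points`` maps temperature (°C) to rate (1/day), or is an iterable
    of (temperature, rate) pairs.  At least three distinct temperatures
    are required.
    """
    pairs = sorted(points.items() if isinstance(points, Mapping) else points)
    temps = np.array([t for t, _ in pairs], dtype=float)
    rates = np.array([r for _, r in pairs], dtype=float)
    if len(np.unique(temps)) < 3:
        raise DataError("need at least 3 distinct temperatures to fit")
    if np.any(temps <= 0):
        raise DataError("temperatures must be positive to take logs")
    x = np.log(temps) / math.log(base)
    if np.ptp(x) == 0:
        raise DataError("zero variance in log(temperature)")
    X = sm.add_constant(x)
    res = sm.OLS(rates, X).fit()
    fitted = res.predict(X)
    return ThermalFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        r_squared=float(res.rsquared),
        log_base=base,
        temperatures=tuple(temps),
        observed=tuple(rates),
        fitted=tuple(fitted),
    )
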