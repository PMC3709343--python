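"""Weather-dependent rate functions of the life-cycle model.

Development of eggs and of engorged adults follows a degree-day relation
(instantaneous rate ``max(T - T_X, 0) / TDD_X``); larval and pupal
development are empirical quadratics in temperature; aquatic mortality decays
exponentially with temperature towards a stage-specific floor; adult
mortality is linear in temperature with a floor.  Rainfall enters twice: a
normalized two-week rain sum inflates the aquatic carrying capacities (up to
a factor 2), and daily rainfall events gate egg hatching.

All functions accept scalars or numpy arrays and broadcast.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .params import MosquitoParams
from .weather import WeatherSeries

__all__ = [
    "HatchingMode",
    "rain_sum_normalized",
    "degree_day_rate",
    "larva_dev_rate",
    "pupa_dev_rate",
    "aquatic_mortality",
    "adult_mortality",
    "carrying_capacity",
    "egg_hatch_rate",
]

# Empirical temperature responses (degC -> day^-1), negative values clamped
# to zero because a negative transition rate would create mass from nothing.
_LARVA_COEFFS = (-0.0007, 0.0392, -0.3911)
_PUPA_COEFFS = (0.0008, -0.0051, 0.0319)

# Adult temperature-dependent mortality: max(mu_A, a + b*T).
_ADULT_MORT_INTERCEPT = 0.04417
_ADULT_MORT_SLOPE = 0.00217

#: Default end of the rain-gated "spring" hatching regime (30 June).  From
#: July onwards hatching in built-up areas is assumed to be maintained by
#: artificial flooding (garden watering), so the rain gate is dropped.
SPRING_END_DOY = 181


@dataclasses.dataclass(frozen=True)
class HatchingMode:
    """How egg hatching is gated by water availability.

    ``mode="flooding"`` (default): during spring (favourable-season start up to
    ``spring_end``) eggs hatch only on days with rainfall (P > 0 mm); for the
    rest of the favourable season the rain gate is dropped (artificial
    flooding keeps containers wet).  ``mode="rain_threshold"``: hatching
    requires daily rainfall strictly above ``threshold`` (mm) all season —
    the counterfactual used to probe the artificial-flooding assumption.
    """

    mode: str = "flooding"
    threshold: float = 0.0
    spring_end: int = SPRING_END_DOY

    def __post_init__(self) -> None:
        if self.mode not in ("flooding", "rain_threshold"):
            raise ValueError(f"unknown hatching mode {self.mode!r}")
        if self.threshold < 0:
            raise ValueError("rainfall threshold must be >= 0 mm")

    @classmethod
    def parse(cls, text: str) -> "HatchingMode":
        """Parse a CLI-style mode string: ``flooding`` or ``rain:<mm>``."""
        if text == "flooding":
            return cls()
        if text.startswith("rain:"):
            return cls(mode="rain_threshold", threshold=float(text[5:]))
        raise ValueError(f"cannot parse hatching mode {text!r}")


def rain_sum_normalized(weather: WeatherSeries) -> np.ndarray:
    """Trailing two-week rainfall sum, min-max rescaled over the whole series
    to lie in [0, 1].

    The window is trailing (days t-13 .. t), reflecting the causal effect of
    recent rain on currently available breeding water; the first 13 days,
    where no full window exists, take the first full-window value.  A series
    with constant (e.g. zero) rainfall has a degenerate min = max and maps to
    all zeros.
    """
    rain = pd.Series(weather.rainfall)
    sums = rain.rolling(window=14).sum().to_numpy()
    sums[:13] = sums[13]
    lo, hi = sums.min(), sums.max()
    if hi == lo:
        return np.zeros_like(sums)
    return (sums - lo) / (hi - lo)


def degree_day_rate(T, T_X: float, TDD_X: float):
    """Instantaneous degree-day development rate ``max(T - T_X, 0) / TDD_X``
    (day^-1).  ``TDD_X`` is the cumulative heat requirement of the stage."""
    TDD_X = np.asarray(TDD_X, dtype=float)
    if np.any(TDD_X <= 0):
        raise ValueError("TDD_X must be > 0")
    return np.maximum(np.asarray(T, dtype=float) - T_X, 0.0) / TDD_X


def larva_dev_rate(T):
    """Larva -> pupa development rate (day^-1), quadratic in temperature,
    clamped below at 0 (positive roughly for 13-43 degC, peak near 28)."""
    a, b, c = _LARVA_COEFFS
    T = np.asarray(T, dtype=float)
    return np.maximum(a * T * T + b * T + c, 0.0)


def pupa_dev_rate(T):
    """Pupa -> emerging-adult development rate (day^-1), quadratic in
    temperature, clamped below at 0."""
    a, b, c = _PUPA_COEFFS
    T = np.asarray(T, dtype=float)
    return np.maximum(a * T * T + b * T + c, 0.0)


def aquatic_mortality(T, mu_floor):
    """Larval or pupal mortality ``exp(-T/2) + mu_floor`` (day^-1): cold
    water is lethal, warm water leaves only the stage-specific floor."""
    mu_floor = np.asarray(mu_floor, dtype=float)
    if np.any(mu_floor < 0):
        raise ValueError("mortality floor must be >= 0")
    return np.exp(-np.asarray(T, dtype=float) / 2.0) + mu_floor


def adult_mortality(T, mu_A):
    """Adult mortality ``max(mu_A, 0.04417 + 0.00217 T)`` (day^-1)."""
    mu_A = np.asarray(mu_A, dtype=float)
    if np.any(mu_A < 0):
        raise ValueError("mu_A must be >= 0")
    linear = _ADULT_MORT_INTERCEPT + _ADULT_MORT_SLOPE * np.asarray(T, dtype=float)
    return np.maximum(mu_A, linear)


def carrying_capacity(kappa, P_norm, area_ha: float = 1.0):
    """Rainfall-modulated carrying capacity ``kappa * (P_norm + 1) * area``:
    recent rain doubles the available breeding water at most."""
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa <= 0):
        raise ValueError("kappa must be > 0")
    if area_ha <= 0:
        raise ValueError("area must be > 0")
    P_norm = np.asarray(P_norm, dtype=float)
    if np.any((P_norm < 0) | (P_norm > 1)):
        raise ValueError("P_norm must lie in [0, 1]")
    return kappa * (P_norm + 1.0) * area_ha


def egg_hatch_rate(T, P, day_of_year, params: MosquitoParams,
                   mode: HatchingMode | None = None, favorable=True):
    """Egg -> larva transition rate (day^-1).

    Zero during diapause (``favorable`` false).  Otherwise the rate is the
    degree-day development rate for eggs, gated by water availability
    according to *mode*: in ``flooding`` mode a rainfall event (P > 0 mm) is
    required during spring only; in ``rain_threshold`` mode rainfall strictly
    above the threshold is required throughout the season.
    """
    if mode is None:
        mode = HatchingMode()
    T = np.asarray(T, dtype=float)
    P = np.asarray(P, dtype=float)
    doy = np.asarray(day_of_year)
    rate = degree_day_rate(T, params.T_E, params.TDD_E)
    if mode.mode == "flooding":
        gate = (doy > mode.spring_end) | (P > 0.0)
    else:
        gate = P > mode.threshold
    out = np.where(gate & np.asarray(favorable, dtype=bool), rate, 0.0)
    return out if out.ndim else float(out)
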