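"""Daily weather forcing: container, CSV I/O, a Mediterranean synthetic
generator, and the day-of-year climatology used for spin-up.

The model is driven by two daily series only — mean air temperature (used
directly as a proxy for water temperature in the small urban breeding
containers the species uses) and rainfall.  The synthetic generator emulates
the climate of the French Riviera: ~750 mm annual rainfall concentrated in
autumn and winter, very dry summers, winter temperatures near 0 degC and
summer temperatures near 34 degC.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "WeatherSeries",
    "WeatherGenConfig",
    "generate_weather",
    "climatology_average_year",
    "doy365",
]

_COLUMNS = ("tmean_c", "rain_mm")

# Monthly wet-day probabilities and relative wet-day rainfall weights for the
# Mediterranean regime (dry summer, wet autumn).  The absolute rainfall scale
# is solved from these so that the expected annual total equals the target.
_WET_PROB = np.array([0.30, 0.27, 0.26, 0.27, 0.22, 0.12,
                      0.07, 0.09, 0.20, 0.32, 0.32, 0.30])
_AMOUNT_WEIGHT = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 0.8,
                           0.8, 1.2, 1.8, 2.0, 1.8, 1.2])
_DAYS_PER_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


def doy365(dates: pd.DatetimeIndex) -> np.ndarray:
    """Day-of-year on a 365-day calendar: in leap years every date from
    29 February onwards is shifted back one day, so 29 February shares the
    index of 28 February and 31 December is always day 365."""
    doy = dates.dayofyear.to_numpy().astype(np.int64)
    leap_shift = dates.is_leap_year & (doy >= 60)
    return doy - leap_shift.astype(np.int64)


class WeatherSeries:
    """A gapless daily series of mean temperature (degC) and rainfall (mm).

    Parameters
    ----------
    data : pandas.DataFrame
        Indexed by a daily ``DatetimeIndex`` with columns ``tmean_c`` and
        ``rain_mm``.  Dates must be consecutive calendar days, rainfall must
        be non-negative, and the series must span at least 15 days (the
        two-week rainfall window needs one full window plus a day).
    """

    MIN_LENGTH = 15

    def __init__(self, data: pd.DataFrame):
        data = data.copy()
        if not isinstance(data.index, pd.DatetimeIndex):
            raise TypeError("weather data must be indexed by dates")
        data.index = data.index.normalize()
        data.index.name = "date"
        missing = [c for c in _COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"weather data missing column(s): {missing}")
        data = data[list(_COLUMNS)].astype(float)
        if len(data) < self.MIN_LENGTH:
            raise ValueError(
                f"weather series must cover >= {self.MIN_LENGTH} days, "
                f"got {len(data)}"
            )
        deltas = np.diff(data.index.to_numpy()).astype("timedelta64[D]")
        if not (deltas == np.timedelta64(1, "D")).all():
            raise ValueError("weather dates must be strictly consecutive days")
        if not np.isfinite(data.to_numpy()).all():
            raise ValueError("weather series contains non-finite values")
        if (data["rain_mm"] < 0).any():
            raise ValueError("rainfall must be non-negative")
        self.data = data

    # -- accessors ---------------------------------------------------------
    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def temperature(self) -> np.ndarray:
        return self.data["tmean_c"].to_numpy()

    @property
    def rainfall(self) -> np.ndarray:
        return self.data["rain_mm"].to_numpy()

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"WeatherSeries({self.dates[0].date()} .. "
                f"{self.dates[-1].date()}, {len(self)} days)")

    def slice(self, start, end) -> "WeatherSeries":
        return WeatherSeries(self.data.loc[start:end])

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path) -> "WeatherSeries":
        df = pd.read_csv(path, parse_dates=["date"], index_col="date")
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, float_format="%.6g")


@dataclasses.dataclass
class WeatherGenConfig:
    """Knobs of the synthetic Mediterranean weather generator.

    ``annual_rainfall_mm`` is an expectation, not a per-year guarantee;
    individual years fluctuate with the Bernoulli wet-day draw and the Gamma
    amounts.  Temperature anchors are the smooth-cycle extremes; small
    autocorrelated noise is added on top and the result is clipped to
    [-5, 40] degC.
    """

    seed: int = 0
    years: int = 4
    start_year: int = 2008
    annual_rainfall_mm: float = 750.0
    winter_tmin_c: float = 0.0
    summer_tmax_c: float = 34.0
    coldest_doy: int = 15          # mid January
    noise_sd_c: float = 1.0
    noise_autocorr: float = 0.6
    gamma_shape: float = 0.9       # wet-day amount distribution

    def __post_init__(self) -> None:
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if self.annual_rainfall_mm <= 0:
            raise ValueError("annual rainfall target must be positive")
        if not 0 <= self.noise_autocorr < 1:
            raise ValueError("noise_autocorr must lie in [0, 1)")


def generate_weather(config: WeatherGenConfig | None = None, **kwargs) -> WeatherSeries:
    """Draw a reproducible multi-year daily weather series.

    Temperature is a sinusoid with its minimum in mid January and maximum in
    late July plus AR(1) noise.  Rainfall is a seasonal Bernoulli wet-day
    indicator times Gamma-distributed amounts, with dry summers and wet
    autumns; the monthly structure is scaled so the expected annual total
    matches the configured target.
    """
    if config is None:
        config = WeatherGenConfig(**kwargs)
    elif kwargs:
        config = dataclasses.replace(config, **kwargs)
    rng = np.random.default_rng(config.seed)

    start = pd.Timestamp(year=config.start_year, month=1, day=1)
    end = pd.Timestamp(year=config.start_year + config.years - 1, month=12, day=31)
    dates = pd.date_range(start, end, freq="D")
    doy = doy365(dates)

    mid = 0.5 * (config.winter_tmin_c + config.summer_tmax_c)
    amp = 0.5 * (config.summer_tmax_c - config.winter_tmin_c)
    smooth = mid - amp * np.cos(2 * np.pi * (doy - config.coldest_doy) / 365.0)
    # AR(1) noise with the stationary variance matched to noise_sd_c
    phi = config.noise_autocorr
    innov_sd = config.noise_sd_c * np.sqrt(1 - phi**2)
    eps = rng.normal(0.0, innov_sd, size=len(dates))
    noise = np.empty(len(dates))
    acc = rng.normal(0.0, config.noise_sd_c)
    for i, e in enumerate(eps):
        acc = phi * acc + e
        noise[i] = acc
    temperature = np.clip(smooth + noise, -5.0, 40.0)

    month = dates.month.to_numpy() - 1
    expected = float(np.sum(_DAYS_PER_MONTH * _WET_PROB * _AMOUNT_WEIGHT))
    base_amount = config.annual_rainfall_mm / expected
    wet = rng.random(len(dates)) < _WET_PROB[month]
    mean_amount = base_amount * _AMOUNT_WEIGHT[month]
    amounts = rng.gamma(config.gamma_shape,
                        mean_amount / config.gamma_shape, size=len(dates))
    rainfall = np.where(wet, amounts, 0.0)

    return WeatherSeries(pd.DataFrame(
        {"tmean_c": temperature, "rain_mm": rainfall}, index=dates))


def climatology_average_year(weather: WeatherSeries,
                             year: int = 2001) -> WeatherSeries:
    """Day-of-year mean temperature and rainfall across the supplied full
    calendar years — the "average year" used for simulation spin-up.

    Every year in the input must be complete (1 January through
    31 December); 29 February observations are folded onto day 59 before
    averaging.  The result is a 365-day series labelled with the (non-leap)
    calendar *year*.
    """
    dates = weather.dates
    for y in np.unique(dates.year):
        sub = dates[dates.year == y]
        expected = 366 if pd.Timestamp(year=y, month=1, day=1).is_leap_year else 365
        if len(sub) != expected:
            raise ValueError(
                f"climatology needs full calendar years; year {y} has "
                f"{len(sub)} days (expected {expected})"
            )
    df = weather.data.copy()
    df["doy"] = doy365(dates)
    clim = df.groupby("doy")[list(_COLUMNS)].mean()
    clim = clim.reindex(range(1, 366))
    if pd.Timestamp(year=year, month=1, day=1).is_leap_year:
        raise ValueError("label year for the average year must be non-leap")
    idx = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    clim.index = idx
    return WeatherSeries(clim)
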