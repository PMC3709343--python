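"""The 10-compartment life-cycle ODE system and its explicit-Euler driver.

Stages: three aquatic (E eggs, L larvae, P pupae), one emerging-adult stage
(A_em), and two parallel gonotrophic chains of adult females — nulliparous
(A1h host-seeking, A1g engorged, A1o oviposition-site-seeking) and parous
(A2h, A2g, A2o).  Only females are tracked after emergence.  Egg hatching is
switched off during the unfavourable (diapause) season; larval mortality is
density-dependent through the rainfall-modulated carrying capacity k_L, and
emergence success decreases with pupal density through k_P.

The system is non-autonomous: weather-driven rates are evaluated once per
calendar day and held constant over the sub-daily Euler steps.  The
integrator is vectorized over parameter sets, so a one-scenario simulation
and a 2,186-scenario sensitivity design share the same code path.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import forcing, outputs as _outputs
from .forcing import HatchingMode
from .params import MosquitoParams, load_params
from .weather import WeatherSeries, climatology_average_year, doy365

__all__ = [
    "STAGES",
    "SimulationConfig",
    "SimulationResults",
    "AedesPopulationModel",
    "ode_rhs",
    "euler_step",
    "eggs_laid",
    "simulate",
]

STAGES = ("E", "L", "P", "A_em", "A1h", "A1g", "A1o", "A2h", "A2g", "A2o")
ADULT_STAGES = STAGES[3:]
RATE_KEYS = ("f_E", "f_L", "f_P", "f_Ag", "m_L", "m_P", "m_A", "k_L", "k_P")


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Run-time choices of a simulation.

    ``area_ha`` is the simulated closed surface; per-hectare carrying
    capacities scale linearly with it, and it must be at least 4 ha so that
    ignoring dispersal (~100 m flight range) is defensible.  ``dt`` is the
    Euler step in days (forcing stays constant within a day).  ``spin_up``
    prepends one synthetic "average year" (day-of-year climatology of the
    supplied weather) whose trajectory is excluded from reported output.
    """

    area_ha: float = 10.0
    dt: float = 0.1
    years: int | None = None
    initial_eggs: float = 1e6
    spin_up: bool = True
    hatching: HatchingMode = dataclasses.field(default_factory=HatchingMode)

    def __post_init__(self) -> None:
        if self.area_ha < 4.0:
            raise ValueError(
                f"area_ha must be >= 4 ha (dispersal-free assumption), "
                f"got {self.area_ha}")
        if not 0 < self.dt <= 1.0:
            raise ValueError(f"dt must lie in (0, 1] day, got {self.dt}")
        if self.years is not None and self.years < 1:
            raise ValueError("years must be >= 1")
        if self.initial_eggs < 0:
            raise ValueError("initial_eggs must be >= 0")

    @property
    def steps_per_day(self) -> int:
        return max(1, int(round(1.0 / self.dt)))


# ---------------------------------------------------------------------------
# Right-hand side and stepping
# ---------------------------------------------------------------------------

def _derivative(state: np.ndarray, r: Mapping[str, Any],
                p: Mapping[str, Any]) -> np.ndarray:
    """Time derivative of the stacked state (shape (10, n)); rates in *r* and
    parameters in *p* are scalars or (n,) arrays.  ``r["f_E"]`` must already
    be zero outside the favourable season."""
    E, L, P, Aem, A1h, A1g, A1o, A2h, A2g, A2o = state
    f_E, f_L, f_P, f_Ag = r["f_E"], r["f_L"], r["f_P"], r["f_Ag"]
    m_L, m_P, m_A = r["m_L"], r["m_P"], r["m_A"]
    k_L, k_P = r["k_L"], r["k_P"]

    oviposition = p["gamma_Ao"] * (p["beta1"] * A1o + p["beta2"] * A2o)
    emergence = f_P * P * p["sigma"] * np.exp(-p["mu_em"] * (1.0 + P / k_P))

    out = np.empty_like(state)
    out[0] = oviposition - (p["mu_E"] + f_E) * E
    out[1] = f_E * E - (m_L * (1.0 + L / k_L) + f_L) * L
    out[2] = f_L * L - (m_P + f_P) * P
    out[3] = emergence - (m_A + p["gamma_Aem"]) * Aem
    out[4] = p["gamma_Aem"] * Aem - (m_A + p["mu_r"] + p["gamma_Ah"]) * A1h
    out[5] = p["gamma_Ah"] * A1h - (m_A + f_Ag) * A1g
    out[6] = f_Ag * A1g - (m_A + p["mu_r"] + p["gamma_Ao"]) * A1o
    out[7] = p["gamma_Ao"] * (A1o + A2o) - (m_A + p["mu_r"] + p["gamma_Ah"]) * A2h
    out[8] = p["gamma_Ah"] * A2h - (m_A + f_Ag) * A2g
    out[9] = f_Ag * A2g - (m_A + p["mu_r"] + p["gamma_Ao"]) * A2o
    return out


def ode_rhs(state, rates: Mapping[str, float], params: MosquitoParams,
            favorable: bool = True) -> np.ndarray:
    """Derivative of a single state vector (length 10, ordered as
    :data:`STAGES`) given the forcing rates evaluated at the current time.

    *rates* must supply f_E, f_L, f_P, f_Ag, m_L, m_P, m_A, k_L and k_P;
    f_E is overridden to 0 when *favorable* is false (egg diapause).
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (len(STAGES),):
        raise ValueError(f"state must have shape ({len(STAGES)},)")
    if (state < 0).any():
        bad = STAGES[int(np.argmin(state))]
        raise ValueError(f"negative abundance in compartment {bad}")
    missing = [k for k in RATE_KEYS if k not in rates]
    if missing:
        raise ValueError(f"rates missing {missing}")
    r = dict(rates)
    if not favorable:
        r["f_E"] = 0.0
    return _derivative(state[:, None], r, params.as_dict())[:, 0]


def euler_step(state, derivative, dt: float) -> np.ndarray:
    """One explicit-Euler step ``state + dt * derivative`` with negative
    components clamped to zero (large per-day rates can undershoot)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    new = np.asarray(state, dtype=float) + dt * np.asarray(derivative, dtype=float)
    if not np.isfinite(new).all():
        idx = np.argwhere(~np.isfinite(np.atleast_2d(new)))[0]
        bad = STAGES[int(idx[-1]) if new.ndim == 1 else int(idx[0])]
        raise FloatingPointError(f"non-finite abundance in compartment {bad}")
    return np.maximum(new, 0.0)


def eggs_laid(state, params: MosquitoParams | Mapping[str, Any]):
    """Daily oviposition flux E_l = gamma_Ao * (beta1*A1o + beta2*A2o); the
    observable compared with ovitrap collections."""
    p = params.as_dict() if isinstance(params, MosquitoParams) else params
    state = np.asarray(state, dtype=float)
    A1o = state[..., 6]
    A2o = state[..., 9]
    return p["gamma_Ao"] * (p["beta1"] * A1o + p["beta2"] * A2o)


# ---------------------------------------------------------------------------
# Forcing pre-computation and the vectorized integrator
# ---------------------------------------------------------------------------

def _broadcast_params(params, n: int) -> dict[str, np.ndarray]:
    """Parameter set(s) as a dict of (n,) float arrays."""
    if isinstance(params, MosquitoParams):
        params = params.as_dict()
    return {k: np.broadcast_to(np.asarray(v, dtype=float), (n,)).copy()
            for k, v in params.items()}


def _daily_rates(weather: WeatherSeries, p: dict[str, np.ndarray],
                 config: SimulationConfig) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Pre-evaluate all forcing rates, one row per day, one column per
    parameter scenario.  Returns (rates, favorable mask)."""
    T = weather.temperature[:, None]
    P = weather.rainfall[:, None]
    doy = doy365(weather.dates)[:, None]
    P_norm = forcing.rain_sum_normalized(weather)[:, None]
    mode = config.hatching

    favorable = (doy >= p["t_start"][None, :]) & (doy < p["t_end"][None, :])
    hatch = np.maximum(T - p["T_E"][None, :], 0.0) / p["TDD_E"][None, :]
    if mode.mode == "flooding":
        gate = (doy > mode.spring_end) | (P > 0.0)
    else:
        gate = P > mode.threshold
    rates = {
        "f_E": np.where(gate & favorable, hatch, 0.0),
        "f_L": forcing.larva_dev_rate(T),
        "f_P": forcing.pupa_dev_rate(T),
        "f_Ag": np.maximum(T - p["T_Ag"][None, :], 0.0) / p["TDD_Ag"][None, :],
        "m_L": np.exp(-T / 2.0) + p["mu_L"][None, :],
        "m_P": np.exp(-T / 2.0) + p["mu_P"][None, :],
        "m_A": np.maximum(p["mu_A"][None, :],
                          forcing.adult_mortality(T, 0.0)),
        "k_L": p["kappa_L"][None, :] * (P_norm + 1.0) * config.area_ha,
        "k_P": p["kappa_P"][None, :] * (P_norm + 1.0) * config.area_ha,
    }
    return rates, favorable


def _integrate(weather: WeatherSeries, params, config: SimulationConfig,
               n: int | None = None) -> tuple[np.ndarray, np.ndarray, dict]:
    """Run the Euler scheme over the full weather span.

    Returns ``(trajectory, favorable, p)`` where trajectory has shape
    (n_days, n_scenarios, 10) holding the state at the end of each day,
    favorable has shape (n_days, n_scenarios) and p is the broadcast
    parameter dict.
    """
    if n is None:
        if isinstance(params, MosquitoParams):
            n = 1
        else:
            n = max(np.asarray(v).size for v in dict(params).values())
    p = _broadcast_params(params, n)
    rates, favorable = _daily_rates(weather, p, config)

    n_days = len(weather)
    nsub = config.steps_per_day
    dt = 1.0 / nsub
    state = np.zeros((len(STAGES), n))
    state[0] = config.initial_eggs
    traj = np.empty((n_days, n, len(STAGES)))

    day_rates = {}
    for d in range(n_days):
        for k, v in rates.items():
            day_rates[k] = v[d]
        for _ in range(nsub):
            state += dt * _derivative(state, day_rates, p)
            np.maximum(state, 0.0, out=state)
        if not np.isfinite(state).all():
            bad = STAGES[int(np.argwhere(~np.isfinite(state))[0, 0])]
            raise FloatingPointError(
                f"non-finite abundance in compartment {bad} on "
                f"{weather.dates[d].date()}")
        traj[d] = state.T
    return traj, favorable, p


# ---------------------------------------------------------------------------
# Model / results objects
# ---------------------------------------------------------------------------

class SimulationResults:
    """Daily trajectory of all ten stages plus derived series.

    ``data`` is a date-indexed DataFrame with the ten stage columns, the
    oviposition flux ``E_l`` (eggs laid per day), total adult females
    ``A_total`` (all seven post-pupal compartments), host-seeking females
    ``A_h`` (A1h + A2h) and the boolean ``favorable`` season mask.  The
    spin-up year, if simulated, is kept in ``full_data`` but excluded from
    ``data`` and from every aggregated output.
    """

    def __init__(self, full_data: pd.DataFrame, params: MosquitoParams | None,
                 config: SimulationConfig | None, spinup_year: int | None = None):
        if full_data.empty:
            raise ValueError("empty trajectory")
        self.full_data = full_data
        self.params = params
        self.config = config
        self.spinup_year = spinup_year
        if spinup_year is not None:
            self.data = full_data[full_data.index.year != spinup_year].copy()
        else:
            self.data = full_data

    # -- constructors --------------------------------------------------------
    @classmethod
    def from_arrays(cls, dates: pd.DatetimeIndex, traj: np.ndarray,
                    favorable: np.ndarray, params: MosquitoParams,
                    config: SimulationConfig,
                    spinup_year: int | None = None) -> "SimulationResults":
        df = pd.DataFrame(traj, index=dates, columns=list(STAGES))
        df["E_l"] = eggs_laid(traj, params)
        df["A_total"] = traj[:, 3:].sum(axis=1)
        df["A_h"] = traj[:, 4] + traj[:, 7]
        df["favorable"] = favorable
        df.index.name = "date"
        return cls(df, params, config, spinup_year)

    # -- accessors ------------------------------------------------------------
    @property
    def years(self) -> list[int]:
        return sorted(set(self.data.index.year))

    def stage(self, name: str) -> pd.Series:
        return self.data[name]

    # -- aggregated outputs ----------------------------------------------------
    def annual_outputs(self) -> pd.DataFrame:
        """Adult peak (and its date), attack rate and parity rate per
        simulated year (spin-up excluded)."""
        return _outputs.annual_outputs(self)

    def validate(self, traps, accumulate: bool = False) -> float:
        """Pearson correlation between relative observed ovitrap eggs and the
        relative simulated oviposition flux at the collection dates."""
        return _outputs.validate_against_ovitraps(self, traps,
                                                  accumulate=accumulate)

    def summary(self) -> str:
        """Human-readable run summary with the per-year aggregated outputs."""
        lines = ["Aedes albopictus population simulation",
                 "=" * 44]
        if self.config is not None:
            lines.append(f"area: {self.config.area_ha} ha   dt: "
                         f"{self.config.dt} day   hatching: "
                         f"{self.config.hatching.mode}")
        lines.append(f"span: {self.data.index[0].date()} .. "
                     f"{self.data.index[-1].date()}"
                     + (f"   (spin-up year {self.spinup_year} excluded)"
                        if self.spinup_year is not None else ""))
        table = self.annual_outputs()
        with pd.option_context("display.float_format", "{:,.1f}".format):
            lines.append(table.to_string())
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot aquatic and aerial abundances over time (two stacked axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, axes = plt.subplots(2, 1, sharex=True, figsize=(10, 6))
        else:
            axes = ax
        for stage in ("E", "L", "P"):
            axes[0].plot(self.data.index, self.data[stage], label=stage)
        axes[0].set_ylabel("aquatic stages")
        axes[0].legend(loc="upper right")
        axes[1].plot(self.data.index, self.data["A_total"], label="adults")
        axes[1].plot(self.data.index, self.data["A_h"], label="host-seeking")
        axes[1].set_ylabel("adult females")
        axes[1].legend(loc="upper right")
        return axes

    def to_csv(self, path: str | Path) -> None:
        from .results_io import write_result
        write_result(self, path)


class AedesPopulationModel:
    """Weather-forced stage-structured population model of *Ae. albopictus*.

    Parameters
    ----------
    weather : WeatherSeries
        Daily forcing covering whole calendar years (1 Jan .. 31 Dec).
    params : MosquitoParams, optional
        Life-history constants (defaults are the Mediterranean set).
    config : SimulationConfig, optional
        Area, Euler step, spin-up and hatching behaviour.

    Examples
    --------
    >>> from aedespop import AedesPopulationModel, generate_weather
    >>> model = AedesPopulationModel(generate_weather(seed=1, years=4))
    >>> res = model.simulate()
    >>> res.annual_outputs()  # doctest: +SKIP
    """

    def __init__(self, weather: WeatherSeries,
                 params: MosquitoParams | None = None,
                 config: SimulationConfig | None = None):
        self.params = params if params is not None else MosquitoParams()
        self.config = config if config is not None else SimulationConfig()
        self.weather = self._check_weather(weather, self.config)

    @classmethod
    def from_csv(cls, weather_csv: str | Path,
                 params_file: str | Path | None = None,
                 **config_kwargs) -> "AedesPopulationModel":
        weather = WeatherSeries.from_csv(weather_csv)
        params = load_params(params_file)
        config = SimulationConfig(**config_kwargs) if config_kwargs else None
        return cls(weather, params, config)

    @staticmethod
    def _check_weather(weather: WeatherSeries,
                       config: SimulationConfig) -> WeatherSeries:
        d = weather.dates
        if not (d[0].month == 1 and d[0].day == 1):
            raise ValueError("weather must start on 1 January (t0)")
        if not (d[-1].month == 12 and d[-1].day == 31):
            raise ValueError("weather must cover whole calendar years")
        if config.years is not None:
            n_avail = d[-1].year - d[0].year + 1
            if config.years > n_avail:
                raise ValueError(
                    f"requested {config.years} years but weather covers "
                    f"only {n_avail}")
            if config.years < n_avail:
                last = d[0].year + config.years - 1
                weather = weather.slice(f"{d[0].year}-01-01", f"{last}-12-31")
        return weather

    def _forcing_weather(self) -> tuple[WeatherSeries, int | None]:
        """Weather actually integrated: observed years, preceded by the
        average-year spin-up when enabled."""
        if not self.config.spin_up:
            return self.weather, None
        spin_year = self.weather.dates[0].year - 1
        clim = climatology_average_year(self.weather)
        frame = clim.data.copy()
        idx = pd.date_range(f"{spin_year}-01-01", f"{spin_year}-12-31", freq="D")
        if len(idx) == 366:  # map the 365-day average year onto a leap year
            values = frame.to_numpy()
            values = np.insert(values, 59, values[58], axis=0)
            frame = pd.DataFrame(values, index=idx, columns=frame.columns)
        else:
            frame.index = idx
        combined = pd.concat([frame, self.weather.data])
        return WeatherSeries(combined), spin_year

    def simulate(self) -> SimulationResults:
        run_weather, spin_year = self._forcing_weather()
        traj, favorable, _ = _integrate(run_weather, self.params, self.config)
        return SimulationResults.from_arrays(
            run_weather.dates, traj[:, 0, :], favorable[:, 0],
            self.params, self.config, spinup_year=spin_year)


def simulate(params: MosquitoParams, weather: WeatherSeries,
             config: SimulationConfig | None = None) -> SimulationResults:
    """Functional one-shot wrapper around :class:`AedesPopulationModel`."""
    return AedesPopulationModel(weather, params, config).simulate()
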