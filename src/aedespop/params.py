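"""Life-history parameters of the *Aedes albopictus* population model.

The model has 20 constants: per-capita egg batches for nulliparous and parous
females, standard carrying capacities of the aquatic environment, the
emergence sex-ratio, six mortality rates, two degree-day pairs (threshold
temperature + cumulative heat requirement) for egg development and egg
maturation in engorged females, three gonotrophic transition rates, and the
calendar bounds of the favorable (non-diapause) season.

Dates are handled internally as day-of-year on a 365-day calendar
(29 February is folded onto 28 February); configuration files may give them
as ISO month-day strings such as ``"03-10"``.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "MosquitoParams",
    "PARAM_NAMES",
    "load_params",
    "doy_from_monthday",
    "monthday_from_doy",
    "reconstruct_standard_carrying_capacity",
    "min_simulation_area_ha",
]

#: Canonical parameter order (used by the sensitivity design).
PARAM_NAMES = (
    "beta1", "beta2", "kappa_L", "kappa_P", "sigma",
    "mu_E", "mu_L", "mu_P", "mu_em", "mu_A", "mu_r",
    "T_E", "TDD_E", "gamma_Aem", "gamma_Ah", "gamma_Ao",
    "T_Ag", "TDD_Ag", "t_start", "t_end",
)

#: Parameters that are calendar dates (perturbed in day-of-year units).
DATE_PARAMS = ("t_start", "t_end")


def doy_from_monthday(value: str | int) -> int:
    """Convert an ISO ``"MM-DD"`` string (or a plain day-of-year int) to
    day-of-year on the 365-day calendar."""
    if isinstance(value, int):
        if not 1 <= value <= 365:
            raise ValueError(f"day-of-year {value} outside [1, 365]")
        return value
    month, day = (int(x) for x in str(value).split("-"))
    return _dt.date(2001, month, day).timetuple().tm_yday  # 2001: non-leap


def monthday_from_doy(doy: int) -> str:
    d = _dt.date(2001, 1, 1) + _dt.timedelta(days=int(doy) - 1)
    return f"{d.month:02d}-{d.day:02d}"


@dataclasses.dataclass(frozen=True)
class MosquitoParams:
    """The 20 constants of the population model, with field defaults for
    *Ae. albopictus* in a Mediterranean temperate climate.

    Units: ``beta1``/``beta2`` eggs per ovipositing female; ``kappa_L``/
    ``kappa_P`` individuals per hectare; ``sigma`` dimensionless in (0, 1);
    all ``mu_*`` and ``gamma_*`` per day; ``T_E``/``T_Ag`` degrees Celsius;
    ``TDD_E``/``TDD_Ag`` degree-days; ``t_start``/``t_end`` day-of-year
    (365-day calendar).
    """

    beta1: float = 95.0        # eggs per nulliparous oviposition
    beta2: float = 75.0        # eggs per parous oviposition
    kappa_L: float = 250_000.0  # standard larval carrying capacity (ha^-1)
    kappa_P: float = 250_000.0  # standard pupal carrying capacity (ha^-1)
    sigma: float = 0.5         # female fraction at emergence
    mu_E: float = 0.05         # egg mortality (day^-1)
    mu_L: float = 0.08         # minimum larval mortality (day^-1)
    mu_P: float = 0.03         # minimum pupal mortality (day^-1)
    mu_em: float = 0.1         # mortality during emergence (day^-1)
    mu_A: float = 0.02         # minimum adult mortality (day^-1)
    mu_r: float = 0.08         # seeking-behaviour adult mortality (day^-1)
    T_E: float = 10.4          # egg development threshold (deg C)
    TDD_E: float = 110.0       # degree-days for egg development
    gamma_Aem: float = 0.4     # emerging-adult development rate (day^-1)
    gamma_Ah: float = 0.2      # host-seeking -> engorged rate (day^-1)
    gamma_Ao: float = 0.2      # oviposition -> host-seeking rate (day^-1)
    T_Ag: float = 10.0         # egg maturation threshold (deg C)
    TDD_Ag: float = 77.0       # degree-days for egg maturation
    t_start: int = 69          # favourable season start (10 March)
    t_end: int = 273           # favourable season end (30 September)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Raise ``ValueError`` naming the offending parameter and bound."""
        positive = ("beta1", "beta2", "kappa_L", "kappa_P",
                    "TDD_E", "TDD_Ag", "gamma_Aem", "gamma_Ah", "gamma_Ao")
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("mu_E", "mu_L", "mu_P", "mu_em", "mu_A", "mu_r"):
            if not getattr(self, name) >= 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        # sigma = 0 (no females) is allowed as a degenerate diagnostic case
        if not 0.0 <= self.sigma < 1.0:
            raise ValueError(f"sigma must lie in [0, 1), got {self.sigma}")
        for name in DATE_PARAMS:
            v = getattr(self, name)
            if not 1 <= int(v) <= 365:
                raise ValueError(f"{name} must be a day-of-year in [1, 365], got {v}")
        if not self.t_start < self.t_end:
            raise ValueError(
                f"t_start ({self.t_start}) must fall before t_end ({self.t_end}) "
                "within the year"
            )

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    def replace(self, **changes: Any) -> "MosquitoParams":
        for key in changes:
            if key in DATE_PARAMS:
                changes[key] = doy_from_monthday(changes[key]) \
                    if isinstance(changes[key], str) else int(round(changes[key]))
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "MosquitoParams":
        """Build from a flat mapping; omitted keys keep their defaults,
        unknown keys are an error."""
        unknown = set(mapping) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        for key, value in mapping.items():
            if key in DATE_PARAMS:
                kwargs[key] = doy_from_monthday(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "MosquitoParams":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected flat key/value pairs")
        return cls.from_mapping(data)

    def to_file(self, path: str | Path) -> None:
        data = self.as_dict()
        for name in DATE_PARAMS:
            data[name] = monthday_from_doy(int(data[name]))
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def load_params(path: str | Path | None) -> MosquitoParams:
    """Read a parameter file (flat YAML key/value), falling back to the
    default parameter set when *path* is ``None``."""
    if path is None:
        return MosquitoParams()
    return MosquitoParams.from_file(path)


def reconstruct_standard_carrying_capacity(
    density_per_cm2: float = 10.0,
    breeding_site_surface_cm2: float = 50.0,
    sites_per_household: float = 20.0,
    households_per_ha: float = 25.0,
) -> float:
    """Standard aquatic carrying capacity (individuals ha^-1) rebuilt from its
    four field ingredients: the maximal larval/pupal density observed in the
    laboratory, the water surface of a typical breeding container, the number
    of containers per household, and the housing density.

    With the default field estimates this yields 250,000 individuals ha^-1,
    the value used for both the larval and the pupal standard capacity.
    """
    return (density_per_cm2 * breeding_site_surface_cm2
            * sites_per_household * households_per_ha)


def min_simulation_area_ha(dispersal_distance_m: float = 100.0) -> float:
    """Smallest square surface (ha) over which the closed-population
    assumption is defensible: the side must exceed twice the active flight
    range, so the area is ``(2 d)^2`` expressed in hectares (4 ha for the
    ~100 m dispersal of *Ae. albopictus*)."""
    side_m = 2.0 * dispersal_distance_m
    return side_m * side_m / 10_000.0
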