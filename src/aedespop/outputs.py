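"""Aggregated epidemiological outputs and the ovitrap comparison.

Three annual summaries condense a simulated trajectory: the adult peak
(maximum total adult females within a year, and its date), the attack rate
(mean daily host-seeking females over the 21 days centred on the peak), and
the parity rate (season-total parous females over season-total females).
For comparison with surveillance data, the simulated oviposition flux E_l is
sampled at the ovitrap collection dates and both series are reduced to
relative abundances before computing a Pearson correlation.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "adult_peak",
    "attack_rate",
    "parity_rate",
    "annual_outputs",
    "relative_series",
    "OvitrapSeries",
    "validate_against_ovitraps",
]

ATTACK_HALF_WINDOW = 10  # days either side of the peak (21-day window)

_PAROUS = ("A2h", "A2g", "A2o")
_FEMALES = ("A_em", "A1h", "A1g", "A1o", "A2h", "A2g", "A2o")


def _year_frame(result, year: int) -> pd.DataFrame:
    df = result.data if hasattr(result, "data") else result
    sub = df[df.index.year == year]
    if sub.empty:
        raise ValueError(f"year {year} not covered by the simulation")
    first = pd.Timestamp(year=year, month=1, day=1)
    last = pd.Timestamp(year=year, month=12, day=31)
    if sub.index[0] != first or sub.index[-1] != last:
        raise ValueError(f"year {year} only partially covered")
    return sub


def adult_peak(result, year: int) -> tuple[float, pd.Timestamp]:
    """Maximum of the total adult-female series within *year* and its date
    (earliest date on ties)."""
    sub = _year_frame(result, year)
    adults = sub["A_total"].to_numpy()
    i = int(np.argmax(adults))  # argmax returns the first maximum
    return float(adults[i]), sub.index[i]


def attack_rate(result, year: int) -> float:
    """Mean daily host-seeking females (A_h) over the 21 days centred on the
    adult peak, truncated at the year bounds."""
    sub = _year_frame(result, year)
    _, peak_date = adult_peak(result, year)
    i = sub.index.get_loc(peak_date)
    lo = max(0, i - ATTACK_HALF_WINDOW)
    hi = min(len(sub), i + ATTACK_HALF_WINDOW + 1)
    return float(sub["A_h"].to_numpy()[lo:hi].mean())


def parity_rate(result, year: int) -> float:
    """Season-total parous females over season-total females (parous +
    nulliparous + emerging) during the favourable season of *year*; 0 when no
    females were ever present."""
    sub = _year_frame(result, year)
    fav = sub[sub["favorable"].astype(bool)]
    parous = fav[list(_PAROUS)].to_numpy().sum()
    females = fav[list(_FEMALES)].to_numpy().sum()
    if females == 0:
        return 0.0
    return float(parous / females)


def annual_outputs(result) -> pd.DataFrame:
    """Aggregated outputs per fully simulated year (spin-up excluded)."""
    df = result.data if hasattr(result, "data") else result
    rows = []
    for year in sorted(set(df.index.year)):
        peak, date = adult_peak(result, year)
        rows.append({
            "year": year,
            "adult_peak": peak,
            "peak_date": date,
            "attack_rate": attack_rate(result, year),
            "parity_rate": parity_rate(result, year),
        })
    return pd.DataFrame(rows).set_index("year")


def relative_series(values) -> np.ndarray:
    """Series rescaled by its maximum so the largest element is 1 — the
    relative-abundance reduction used before correlating simulated and
    observed egg series."""
    values = np.asarray(values, dtype=float)
    m = values.max(initial=-np.inf)
    if not m > 0:
        raise ValueError("relative_series requires a positive maximum")
    return values / m


@dataclasses.dataclass
class OvitrapSeries:
    """Mean eggs per trap per collection session at one surveillance site."""

    dates: pd.DatetimeIndex
    mean_eggs: np.ndarray
    site: str = "site"

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates).normalize()
        self.mean_eggs = np.asarray(self.mean_eggs, dtype=float)
        if len(self.dates) != len(self.mean_eggs):
            raise ValueError("dates and counts differ in length")
        if not self.dates.is_monotonic_increasing or self.dates.has_duplicates:
            raise ValueError("collection dates must be strictly increasing")
        if (self.mean_eggs < 0).any():
            raise ValueError("egg counts must be non-negative")

    def __len__(self) -> int:
        return len(self.dates)

    @classmethod
    def from_csv(cls, path: str | Path) -> list["OvitrapSeries"]:
        """Read a collection CSV (columns ``date``, ``mean_eggs_per_trap``,
        optional ``site``); returns one series per site."""
        df = pd.read_csv(path, parse_dates=["date"])
        if "mean_eggs_per_trap" not in df.columns:
            raise ValueError(f"{path}: missing column 'mean_eggs_per_trap'")
        if "site" not in df.columns:
            df["site"] = "site"
        out = []
        for site, grp in df.groupby("site", sort=False):
            grp = grp.sort_values("date")
            out.append(cls(pd.DatetimeIndex(grp["date"]),
                           grp["mean_eggs_per_trap"].to_numpy(),
                           site=str(site)))
        return out


def validate_against_ovitraps(result, traps: OvitrapSeries,
                              accumulate: bool = False) -> float:
    """Pearson (Bravais–Pearson) correlation between the relative observed
    eggs-per-trap series and the relative simulated oviposition flux sampled
    at the collection dates.

    With ``accumulate=True`` the simulated flux is summed between successive
    visits instead of sampled instantaneously (traps integrate egg laying
    between collections); the default matches sampling at collection time.
    """
    df = result.data if hasattr(result, "data") else result
    dates = traps.dates
    covered = dates[(dates >= df.index[0]) & (dates <= df.index[-1])]
    if len(covered) < 3:
        raise ValueError(
            "need at least 3 collection dates inside the simulated span, "
            f"got {len(covered)}")
    obs = traps.mean_eggs[np.isin(traps.dates, covered)]
    el = df["E_l"]
    if accumulate:
        sim = []
        prev = df.index[0]
        for d in covered:
            sim.append(el.loc[prev:d].sum())
            prev = d + pd.Timedelta(days=1)
        sim = np.asarray(sim)
    else:
        sim = el.loc[covered].to_numpy()
    if np.ptp(obs) == 0 or np.ptp(sim) == 0:
        raise ValueError("correlation undefined: zero variance in a series")
    r, _ = stats.pearsonr(relative_series(obs), relative_series(sim))
    return float(r)
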