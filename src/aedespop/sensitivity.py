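"""Global sensitivity analysis: 3-level fractional factorial design over all
20 model parameters and a linear-regression variance decomposition.

Each parameter takes three levels — nominal and nominal +/- 10% (calendar
parameters are shifted by +/- 10% of their day-of-year, rounded to whole
days).  A regular 3^(20-13) fraction (3^7 = 2187 runs) supports estimation
of all main effects and first-order interactions; the all-nominal baseline
run is removed from the design and simulated separately, leaving 2,186
scenarios.  For every aggregated output a linear model on the coded levels
(20 main effects + 190 pairwise products) is fitted; the contribution of a
term is its sequential sum of squares over the total sum of squares, the
contributions add up to the regression r^2, and terms explaining more than
1% of the variance are retained.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd

from .dynamics import AedesPopulationModel, SimulationConfig, _integrate
from .params import DATE_PARAMS, PARAM_NAMES, MosquitoParams
from .weather import WeatherSeries

__all__ = [
    "FactorialDesign",
    "SensitivityReport",
    "build_design",
    "run_design",
    "variance_decomposition",
    "FactorialSensitivity",
]

OUTPUT_NAMES = ("adult_peak", "attack_rate", "parity_rate")

# Alias matrix of the regular 3^(20-13) fraction: one GF(3)^7 column per
# factor (7 basic factors = identity block, then 13 generators).  Found by
# randomized search subject to every 4 columns being linearly independent
# over GF(3), i.e. the fraction has resolution V: main effects and two-factor
# interactions are not aliased with each other.
_ALIAS_MATRIX = np.array([
    [1, 0, 0, 0, 0, 0, 0, 1, 1, 0, 1, 1, 1, 1, 0, 1, 1, 1, 1, 1],
    [0, 1, 0, 0, 0, 0, 0, 1, 2, 1, 0, 1, 0, 0, 1, 0, 2, 0, 2, 1],
    [0, 0, 1, 0, 0, 0, 0, 2, 2, 1, 1, 0, 2, 2, 2, 0, 1, 0, 1, 0],
    [0, 0, 0, 1, 0, 0, 0, 2, 0, 2, 1, 1, 1, 2, 0, 0, 0, 1, 1, 2],
    [0, 0, 0, 0, 1, 0, 0, 0, 2, 0, 1, 0, 0, 2, 1, 1, 0, 1, 1, 2],
    [0, 0, 0, 0, 0, 1, 0, 1, 0, 2, 0, 0, 0, 1, 1, 1, 1, 2, 1, 2],
    [0, 0, 0, 0, 0, 0, 1, 2, 0, 1, 1, 1, 2, 1, 2, 1, 0, 0, 2, 0],
], dtype=np.int64)


@dataclasses.dataclass
class FactorialDesign:
    """Coded design matrix of the fractional factorial.

    ``coded`` has one row per scenario and one column per factor, entries in
    {-1, 0, +1} mapping to nominal x 0.9 / nominal / nominal x 1.1 (dates:
    nominal -/+ 10% of day-of-year).
    """

    factor_names: tuple[str, ...]
    coded: np.ndarray
    delta: float
    nominal: MosquitoParams

    @property
    def n_scenarios(self) -> int:
        return self.coded.shape[0]

    def decoded_levels(self, name: str) -> np.ndarray:
        """The three actual values factor *name* takes (low, nominal, high)."""
        base = getattr(self.nominal, name)
        if name in DATE_PARAMS:
            step = int(round(self.delta * base))
            return np.array([base - step, base, base + step], dtype=float)
        return base * np.array([1 - self.delta, 1.0, 1 + self.delta])

    def scenario_params(self) -> dict[str, np.ndarray]:
        """Per-scenario parameter values as a dict of (n_scenarios,) arrays."""
        out = {}
        for j, name in enumerate(self.factor_names):
            lo, mid, hi = self.decoded_levels(name)
            levels = np.array([lo, mid, hi])
            out[name] = levels[self.coded[:, j] + 1]
        return out


def build_design(params: MosquitoParams | None = None,
                 delta: float = 0.10,
                 factor_names: tuple[str, ...] = PARAM_NAMES) -> FactorialDesign:
    """Build the 2,186-scenario regular 3-level fraction over the 20 model
    parameters (the all-nominal baseline row is excluded; it is simulated
    separately as the reference run)."""
    if params is None:
        params = MosquitoParams()
    if len(factor_names) != _ALIAS_MATRIX.shape[1]:
        raise ValueError(
            f"the design is defined for {_ALIAS_MATRIX.shape[1]} factors, "
            f"got {len(factor_names)}")
    if not 0 < delta < 1:
        raise ValueError("delta must lie in (0, 1)")
    runs = np.array(list(itertools.product(range(3), repeat=7)), dtype=np.int64)
    levels = (runs @ _ALIAS_MATRIX) % 3
    keep = ~np.all(levels == 0, axis=1)  # drop the all-nominal baseline
    coded = np.where(levels == 2, -1, levels)[keep].astype(np.int8)
    return FactorialDesign(tuple(factor_names), coded, delta, params)


def run_design(design: FactorialDesign, weather: WeatherSeries,
               config: SimulationConfig | None = None) -> pd.DataFrame:
    """Simulate every scenario of the design and return the three aggregated
    outputs (averaged over the simulated years, spin-up excluded).

    Scenarios whose simulation produced non-finite output are flagged in the
    boolean ``failed`` column rather than dropped.
    """
    if config is None:
        config = SimulationConfig()
    model = AedesPopulationModel(weather, design.nominal, config)
    run_weather, spin_year = model._forcing_weather()
    pvecs = design.scenario_params()
    traj, favorable, _ = _integrate(run_weather, pvecs, config,
                                    n=design.n_scenarios)
    out = _batch_annual_outputs(run_weather.dates, traj, favorable,
                                exclude_year=spin_year)
    df = pd.DataFrame(out, columns=list(OUTPUT_NAMES))
    df["failed"] = ~np.isfinite(out).all(axis=1)
    return df


def _batch_annual_outputs(dates: pd.DatetimeIndex, traj: np.ndarray,
                          favorable: np.ndarray,
                          exclude_year: int | None = None) -> np.ndarray:
    """Adult peak, attack rate and parity rate per scenario, averaged over
    the reported calendar years.  Definitions mirror :mod:`aedespop.outputs`
    exactly (peak = max of the 7-compartment adult total; attack rate = mean
    host-seeking females over the 21 days around the peak, truncated at year
    bounds; parity rate over the favourable season)."""
    years = [y for y in sorted(set(dates.year)) if y != exclude_year]
    n = traj.shape[1]
    acc = np.zeros((n, 3))
    year_arr = dates.year.to_numpy()
    for year in years:
        idx = np.flatnonzero(year_arr == year)
        adults = traj[idx, :, 3:].sum(axis=2)          # (days_y, n)
        ah = traj[idx, :, 4] + traj[idx, :, 7]
        peak = adults.max(axis=0)
        peak_pos = adults.argmax(axis=0)               # first max = earliest
        attack = np.empty(n)
        for j in range(n):
            lo = max(0, peak_pos[j] - 10)
            hi = min(len(idx), peak_pos[j] + 11)
            attack[j] = ah[lo:hi, j].mean()
        fav = favorable[idx]
        parous = (traj[idx, :, 7:].sum(axis=2) * fav).sum(axis=0)
        females = (traj[idx, :, 3:].sum(axis=2) * fav).sum(axis=0)
        parity = np.divide(parous, females,
                           out=np.zeros(n), where=females > 0)
        acc += np.column_stack([peak, attack, parity])
    return acc / len(years)


@dataclasses.dataclass
class OutputDecomposition:
    """Variance decomposition of one aggregated output."""

    contributions: pd.Series   # fraction of total variance per term
    retained: list[str]        # terms with contribution > threshold
    r2: float


@dataclasses.dataclass
class SensitivityReport:
    """Per-output variance contributions of factors and interactions."""

    design: FactorialDesign
    outputs: pd.DataFrame
    decompositions: dict[str, OutputDecomposition]
    retain_threshold: float = 0.01

    def retained(self, output: str) -> list[str]:
        return self.decompositions[output].retained

    def summary(self, top: int = 10) -> str:
        lines = ["Fractional factorial sensitivity analysis",
                 "=" * 48,
                 f"scenarios: {self.design.n_scenarios}   "
                 f"delta: +/-{self.design.delta:.0%}   "
                 f"retention: > {self.retain_threshold:.0%} of variance"]
        for name, dec in self.decompositions.items():
            lines.append(f"\n{name}  (r2 = {dec.r2:.4f})")
            head = dec.contributions.sort_values(ascending=False).head(top)
            for term, frac in head.items():
                mark = "*" if term in dec.retained else " "
                lines.append(f"  {mark} {term:<20s} {frac:8.2%}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            name: {
                "r2": dec.r2,
                "retained": dec.retained,
                "contributions": {t: float(c) for t, c in
                                  dec.contributions.items() if c > 1e-6},
            }
            for name, dec in self.decompositions.items()
        }


def _model_matrix(design: FactorialDesign,
                  interactions: bool = True) -> tuple[np.ndarray, list[str]]:
    coded = design.coded.astype(float)
    names = list(design.factor_names)
    cols = [np.ones(design.n_scenarios)]
    terms = ["Intercept"]
    for j, name in enumerate(names):
        cols.append(coded[:, j])
        terms.append(name)
    if interactions:
        for i, j in itertools.combinations(range(len(names)), 2):
            cols.append(coded[:, i] * coded[:, j])
            terms.append(f"{names[i]}:{names[j]}")
    return np.column_stack(cols), terms


def variance_decomposition(design: FactorialDesign, outputs: pd.DataFrame,
                           retain_threshold: float = 0.01,
                           interactions: bool = True) -> SensitivityReport:
    """Fit, per output, a linear model on the coded main effects and all
    first-order interactions, and decompose the output variance into
    per-term contributions (sequential sums of squares over the total sum of
    squares; on this orthogonal design the decomposition is order-invariant
    and the contributions add up to r^2 exactly)."""
    if "failed" in outputs.columns:
        ok = ~outputs["failed"].to_numpy(dtype=bool)
    else:
        ok = np.isfinite(outputs.to_numpy()).all(axis=1)
    if ok.mean() < 0.95:
        raise ValueError(
            f"only {ok.mean():.0%} of scenarios produced finite outputs "
            "(need >= 95%)")
    X, terms = _model_matrix(design, interactions=interactions)
    X = X[ok]
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * len(X) * np.finfo(float).eps
    if (diag < tol).any():
        aliased = [terms[i] for i in np.flatnonzero(diag < tol)]
        raise ValueError(f"model matrix is rank-deficient; aliased terms: "
                         f"{aliased}")
    decomps = {}
    for name in OUTPUT_NAMES:
        if name not in outputs.columns:
            continue
        y = outputs[name].to_numpy(dtype=float)[ok]
        z = q.T @ y
        ss_terms = z[1:] ** 2          # sequential SS, intercept projected out
        ss_total = float(((y - y.mean()) ** 2).sum())
        if ss_total == 0:
            contrib = pd.Series(np.zeros(len(terms) - 1), index=terms[1:])
        else:
            contrib = pd.Series(ss_terms / ss_total, index=terms[1:])
        retained = list(contrib[contrib > retain_threshold]
                        .sort_values(ascending=False).index)
        decomps[name] = OutputDecomposition(contrib, retained,
                                            float(contrib.sum()))
    return SensitivityReport(design, outputs, decomps, retain_threshold)


class FactorialSensitivity:
    """Convenience driver: build the design, run all scenarios against a
    model's weather/config, and decompose the output variance.

    >>> sens = FactorialSensitivity(model, delta=0.1)   # doctest: +SKIP
    >>> report = sens.run()                             # doctest: +SKIP
    """

    def __init__(self, model: AedesPopulationModel, delta: float = 0.10,
                 retain_threshold: float = 0.01):
        self.model = model
        self.delta = delta
        self.retain_threshold = retain_threshold
        self.design = build_design(model.params, delta=delta)

    def run(self) -> SensitivityReport:
        outputs = run_design(self.design, self.model.weather,
                             self.model.config)
        return variance_decomposition(self.design, outputs,
                                      retain_threshold=self.retain_threshold)
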