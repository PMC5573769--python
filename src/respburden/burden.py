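"""Draw-level DALY accounting.

Years of life lost (YLL) multiply deaths by the remaining life expectancy
of a standard life table at the age of death; years lived with disability
(YLD) multiply the prevalence of each health state by its disability
weight and the population; DALYs are their draw-wise sum.  Uncertainty
intervals are the 25th and 975th order statistics of 1000 posterior draws
(the same order-statistic rule, scaled, for other draw counts), and a
change over time is significant when more than 95% of draw-wise
differences share a sign.  All rates are reported per 100 000 person-years.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .drawcube import DrawCube  # noqa: F401  (re-exported public surface)

__all__ = [
    "DrawCube",
    "load_lifetable",
    "load_standard_population",
    "compute_yll",
    "compute_yld",
    "compute_daly",
    "age_standardise",
    "summarise",
    "summarise_cube",
    "percent_change",
]

PER = 100_000  # reporting scale for rates


def load_lifetable(path) -> pd.Series:
    """Standard life table: remaining life expectancy by age_start.

    Validates positivity and monotone decline with age.
    """
    df = pd.read_csv(path)
    s = df.set_index("age_start")["life_expectancy"].sort_index()
    if (s <= 0).any():
        raise ValueError("life expectancy must be positive")
    if (np.diff(s.to_numpy()) > 0).any():
        raise ValueError("remaining life expectancy must not increase with age")
    return s


def load_standard_population(path) -> pd.Series:
    """Standard population weights by age_start, normalised to sum to 1."""
    df = pd.read_csv(path)
    s = df.set_index("age_start")["weight"].sort_index()
    if (s < 0).any():
        raise ValueError("standard population weights must be >= 0")
    return s / s.sum()


def compute_yll(death_draws: DrawCube, lifetable: pd.Series) -> DrawCube:
    """YLL(cell) = deaths(cell) x remaining life expectancy at that age."""
    missing = set(death_draws.keys["age_start"]) - set(lifetable.index)
    if missing:
        raise ValueError(f"life table missing ages: {sorted(missing)}")
    return death_draws.mul_series(lifetable, level="age_start")


def compute_yld(
    state_prevalence: dict[str, DrawCube],
    dw_table: dict[str, float],
    population: pd.Series,
    pop_levels=("location", "year", "sex", "age_start"),
) -> DrawCube:
    """YLD = sum over states of prevalence x disability weight x population."""
    unknown = set(state_prevalence) - set(dw_table)
    if unknown:
        raise ValueError(f"states without disability weights: {sorted(unknown)}")
    total = None
    for state, cube in state_prevalence.items():
        term = cube.mul_series(population, level=list(pop_levels)) * dw_table[state]
        total = term if total is None else total + term
    return total


def compute_daly(yll: DrawCube, yld: DrawCube) -> DrawCube:
    """DALYs are the sum of YLLs and YLDs, draw by draw."""
    return yll + yld


def age_standardise(rate_draws: DrawCube, std_pop: pd.Series) -> DrawCube:
    """Directly age-standardised rates: sum over ages of weight x rate."""
    ages_present = set(rate_draws.keys["age_start"])
    missing = set(std_pop.index) - ages_present
    if missing:
        raise ValueError(f"rate cube missing standard ages: {sorted(missing)}")
    weighted = rate_draws.mul_series(std_pop, level="age_start")
    return weighted.sum_over("age_start")


def _ui_indices(n: int) -> tuple[int, int]:
    # 25th and 975th order statistics at n = 1000; the same rule scaled
    lo = int(np.floor(0.025 * n + 0.5))
    hi = int(np.floor(0.975 * n + 0.5))
    return max(lo, 1), min(hi, n)


def summarise(draws: np.ndarray) -> tuple[float, float, float]:
    """(mean, lower, upper) of a draw vector.

    Lower/upper are the 2.5% / 97.5% order statistics (25th and 975th
    values for 1000 draws).
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("cannot summarise empty draws")
    srt = np.sort(draws)
    lo, hi = _ui_indices(draws.size)
    return float(draws.mean()), float(srt[lo - 1]), float(srt[hi - 1])


def summarise_cube(cube: DrawCube, prefix: str = "") -> pd.DataFrame:
    """Cell-wise summary table with mean/lower/upper columns."""
    srt = np.sort(cube.values, axis=1)
    lo, hi = _ui_indices(cube.n_draws)
    out = cube.keys.copy()
    out[f"{prefix}mean"] = cube.values.mean(axis=1)
    out[f"{prefix}lower"] = srt[:, lo - 1]
    out[f"{prefix}upper"] = srt[:, hi - 1]
    return out


def percent_change(
    draws_t0: np.ndarray, draws_t1: np.ndarray
) -> tuple[float, float, float, bool]:
    """Draw-wise percent change with the draw-level significance rule.

    Returns (mean change, lower, upper, significant).  The change is
    significant when strictly more than 95% of draw-wise differences are
    positive, or strictly more than 95% are negative.
    """
    v0 = np.asarray(draws_t0, dtype=float)
    v1 = np.asarray(draws_t1, dtype=float)
    if v0.shape != v1.shape:
        raise ValueError("draw vectors must be aligned")
    if np.any(v0 <= 0):
        raise ValueError("baseline draws must be > 0 for percent change")
    change = 100.0 * (v1 - v0) / v0
    mean, lower, upper = summarise(change)
    diff = v1 - v0
    share_pos = np.mean(diff > 0)
    share_neg = np.mean(diff < 0)
    significant = bool(share_pos > 0.95 or share_neg > 0.95)
    return mean, lower, upper, significant
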