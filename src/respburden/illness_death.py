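"""Illness-death (susceptible-case) compartmental model.

The two-compartment system used to force internal consistency between
incidence, remission, excess mortality and prevalence:

    dS/da = -(i + m) S + r C
    dC/da =  i S - (r + m + f) C

with S(0) = 1, C(0) = 0, where ``i`` is incidence, ``r`` remission (the cure
rate), ``f`` excess mortality among cases and ``m`` background mortality,
all per person-year.  Prevalence among survivors is p(a) = C / (S + C).

Rates are piecewise-constant between age knots; the solver marches age in
fixed substeps with classical Runge-Kutta (4th order).  The solver is
vectorised over a trailing batch axis so that many locations / posterior
draws are integrated in one pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RateSet", "PrevalenceSolution", "solve_illness_death", "solve_batch"]

DEFAULT_AGE_MAX = 96
DEFAULT_SUBSTEPS = 4


@dataclass
class RateSet:
    """Piecewise-constant rate functions on an age grid.

    ``knots`` are strictly increasing ages; each rate applies on
    ``[knots[k], knots[k+1])`` and the last value extends to the open end.
    Scalars are broadcast to all knots.
    """

    knots: np.ndarray
    i: np.ndarray
    r: np.ndarray
    f: np.ndarray
    m: np.ndarray

    def __post_init__(self):
        self.knots = np.asarray(self.knots, dtype=float)
        if self.knots.ndim != 1 or len(self.knots) < 1:
            raise ValueError("knots must be a non-empty 1-d array")
        if np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        k = len(self.knots)
        for name in ("i", "r", "f", "m"):
            v = np.broadcast_to(np.asarray(getattr(self, name), dtype=float), (k,)).copy()
            if np.any(v < 0):
                raise ValueError(f"rate '{name}' has negative values")
            setattr(self, name, v)

    def expand(self, ages: np.ndarray) -> dict[str, np.ndarray]:
        """Step-function lookup of each rate at the given ages."""
        idx = np.clip(np.searchsorted(self.knots, ages, side="right") - 1, 0, None)
        return {name: getattr(self, name)[idx] for name in ("i", "r", "f", "m")}


@dataclass
class PrevalenceSolution:
    """Solution of the illness-death system on a fine age grid."""

    ages: np.ndarray
    S: np.ndarray
    C: np.ndarray
    p: np.ndarray = field(init=False)

    def __post_init__(self):
        alive = self.S + self.C
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(alive > 0, self.C / np.where(alive > 0, alive, 1.0), 0.0)
        self.p = p
        if np.any(~np.isfinite(self.S)) or np.any(~np.isfinite(self.C)):
            raise FloatingPointError("non-finite illness-death solution")

    def p_at(self, age) -> np.ndarray | float:
        return np.interp(age, self.ages, self.p)

    def band_average(self, a0: float, a1: float) -> float:
        """Average prevalence over the age band [a0, a1)."""
        if a1 <= a0:
            return float(self.p_at(a0))
        grid = self.ages[(self.ages >= a0) & (self.ages <= a1)]
        grid = np.unique(np.concatenate([[a0], grid, [a1]]))
        vals = np.interp(grid, self.ages, self.p)
        return float(np.trapezoid(vals, grid) / (a1 - a0))


def _derivs(S, C, i, r, f, m):
    dS = -(i + m) * S + r * C
    dC = i * S - (r + m + f) * C
    return dS, dC


def solve_batch(
    i: np.ndarray,
    r: np.ndarray,
    f: np.ndarray,
    m: np.ndarray,
    n_substeps: int = DEFAULT_SUBSTEPS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate the system for a batch of rate schedules.

    Parameters
    ----------
    i, r, f, m
        Arrays of shape ``(A,)`` or ``(A, B)`` giving the rate on each
        1-year age interval ``[a, a+1)`` for ``a = 0..A-1``, batched over
        the trailing axis.
    n_substeps
        RK4 steps per year of age.

    Returns
    -------
    ages, S, C with ``ages`` of length ``A * n_substeps + 1`` (substep grid)
    and S, C of shape ``(len(ages), B)`` (or 1-d for unbatched input).
    """
    i, r, f, m = (np.atleast_2d(np.asarray(x, dtype=float).T).T for x in (i, r, f, m))
    A, B = i.shape
    for arr, name in ((r, "r"), (f, "f"), (m, "m")):
        if arr.shape != (A, B):
            raise ValueError(f"rate '{name}' shape {arr.shape} != {(A, B)}")
    if min(i.min(initial=0), r.min(initial=0), f.min(initial=0), m.min(initial=0)) < 0:
        raise ValueError("negative rate passed to solver")
    h = 1.0 / n_substeps
    n_grid = A * n_substeps + 1
    S = np.empty((n_grid, B))
    C = np.empty((n_grid, B))
    S[0] = 1.0
    C[0] = 0.0
    s = np.ones(B)
    c = np.zeros(B)
    g = 1
    for a in range(A):
        ia, ra, fa, ma = i[a], r[a], f[a], m[a]
        for _ in range(n_substeps):
            k1s, k1c = _derivs(s, c, ia, ra, fa, ma)
            k2s, k2c = _derivs(s + 0.5 * h * k1s, c + 0.5 * h * k1c, ia, ra, fa, ma)
            k3s, k3c = _derivs(s + 0.5 * h * k2s, c + 0.5 * h * k2c, ia, ra, fa, ma)
            k4s, k4c = _derivs(s + h * k3s, c + h * k3c, ia, ra, fa, ma)
            s = s + (h / 6.0) * (k1s + 2 * k2s + 2 * k3s + k4s)
            c = c + (h / 6.0) * (k1c + 2 * k2c + 2 * k3c + k4c)
            S[g] = s
            C[g] = c
            g += 1
    ages = np.linspace(0.0, A, n_grid)
    if B == 1 and np.asarray(i).ndim <= 2:
        pass  # keep 2-d; caller may squeeze
    return ages, S, C


def solve_illness_death(
    rates: RateSet,
    age_max: int = DEFAULT_AGE_MAX,
    n_substeps: int = DEFAULT_SUBSTEPS,
) -> PrevalenceSolution:
    """Solve the illness-death system for a single rate set.

    Returns the solution on the substep grid from age 0 to ``age_max`` with
    initial conditions S(0) = 1, C(0) = 0 (zero birth prevalence).
    """
    years = np.arange(age_max, dtype=float)
    ex = rates.expand(years)
    ages, S, C = solve_batch(ex["i"], ex["r"], ex["f"], ex["m"], n_substeps=n_substeps)
    return PrevalenceSolution(ages=ages, S=S[:, 0], C=C[:, 0])
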