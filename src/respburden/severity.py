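"""Severity splitting: spirometric classes to symptom-based health states.

COPD prevalence is split into GOLD spirometric classes (I: FEV1 >= 80% of
normal, II: 50-79%, III/IV combined: < 50%), whose raw modelled proportions
are scaled to sum to one.  Encounter records with combined disability
weights are decomposed into condition-specific weights (multiplicative
comorbidity model), individuals are classified into health states using
midpoint cutpoints between adjacent state disability weights, and a
GOLD-class -> health-state map is constructed in a reference population by
cumulative-quantile alignment so it can be applied to class-specific
prevalence everywhere else.  Asthma uses the same classify/apply machinery
with its own states and a single global split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GoldDistribution",
    "SeverityCutpoints",
    "GoldStateMap",
    "scale_and_apply",
    "estimate_condition_dw",
    "classify_states",
    "build_gold_state_map",
    "apply_state_map",
]

GOLD_CLASSES = ("gold_1", "gold_2", "gold_3_4")


@dataclass
class GoldDistribution:
    """Proportions of COPD cases in GOLD classes (ascending severity)."""

    gold_1: float
    gold_2: float
    gold_3_4: float

    def as_array(self) -> np.ndarray:
        return np.array([self.gold_1, self.gold_2, self.gold_3_4], dtype=float)

    def scaled(self) -> "GoldDistribution":
        arr = self.as_array()
        if np.any(arr < 0):
            raise ValueError("GOLD proportions must be >= 0")
        total = arr.sum()
        if total <= 0:
            raise ValueError("all GOLD proportions are zero")
        return GoldDistribution(*(arr / total))


@dataclass
class SeverityCutpoints:
    """Thresholds between health states: midpoints of adjacent disability
    weights.  A weight exactly at a cutpoint goes to the more severe state."""

    states: tuple
    cutpoints: np.ndarray  # len(states) - 1, strictly increasing

    def __post_init__(self):
        self.cutpoints = np.asarray(self.cutpoints, dtype=float)
        if len(self.cutpoints) != len(self.states) - 1:
            raise ValueError("need len(states) - 1 cutpoints")
        if np.any(np.diff(self.cutpoints) <= 0) or self.cutpoints[0] <= 0:
            raise ValueError("cutpoints must be strictly increasing and > 0")

    @classmethod
    def from_weights(cls, dw_by_state: dict[str, float]) -> "SeverityCutpoints":
        states = tuple(dw_by_state)
        weights = np.array([dw_by_state[s] for s in states], dtype=float)
        if weights[0] != 0.0:
            raise ValueError("first (asymptomatic) state must have weight 0")
        if np.any(np.diff(weights) <= 0):
            raise ValueError("disability weights must increase with severity")
        cut = (weights[1:] + weights[:-1]) / 2.0
        # the asymptomatic state is exactly DW = 0: any positive weight is
        # symptomatic, so the first threshold sits just above zero rather
        # than at the asymptomatic/mild midpoint
        cut[0] = np.finfo(float).tiny
        return cls(states=states, cutpoints=cut)


def scale_and_apply(props: GoldDistribution, prevalence: float) -> dict[str, float]:
    """Scale raw class proportions to sum to 1 and split overall prevalence.

    Class prevalences sum to the overall prevalence exactly.
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError(f"prevalence must lie in [0, 1], got {prevalence}")
    scaled = props.scaled().as_array()
    return dict(zip(GOLD_CLASSES, scaled * prevalence))


def estimate_condition_dw(
    records: pd.DataFrame,
    condition: str,
    conditions: list[str] | None = None,
) -> np.ndarray:
    """Marginal disability-weight distribution of one condition.

    Controls for comorbidity by regressing ln(1 - combined DW) on condition
    indicators (the multiplicative-combination model is additive on that
    scale) and attributing to each individual with the condition their
    observed log-complement minus the estimated components of their other
    conditions.  Returns the per-individual condition-specific weights.
    """
    flag = f"has_{condition}"
    if flag not in records.columns:
        raise ValueError(f"no '{flag}' column in encounter records")
    with_cond = records[records[flag] == 1]
    if len(with_cond) == 0:
        raise ValueError(f"no records with condition '{condition}'")
    if conditions is None:
        conditions = [c[4:] for c in records.columns if c.startswith("has_")]
    X = records[[f"has_{c}" for c in conditions]].to_numpy(dtype=float)
    y = np.log1p(-records["combined_dw"].to_numpy(dtype=float))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)  # no intercept: no conditions -> DW 0
    others = [j for j, c in enumerate(conditions) if c != condition]
    mask = records[flag].to_numpy() == 1
    resid = y[mask] - X[mask][:, others] @ beta[others]
    return 1.0 - np.exp(np.minimum(resid, 0.0))


def classify_states(
    individual_dws: np.ndarray, cutpoints: SeverityCutpoints
) -> dict[str, float]:
    """Exhaustive assignment of individual weights to health states.

    A weight of exactly 0 is asymptomatic; a weight exactly at a midpoint
    cutpoint is assigned to the more severe state.  Proportions sum to 1.
    """
    w = np.asarray(individual_dws, dtype=float)
    if np.any((w < 0) | (w >= 1)):
        raise ValueError("disability weights must lie in [0, 1)")
    # side="right": a weight exactly at a cutpoint lands in the more severe
    # state (deterministic, conservative tie rule)
    idx = np.searchsorted(cutpoints.cutpoints, w, side="right")
    counts = np.bincount(idx, minlength=len(cutpoints.states))
    props = counts / len(w)
    return dict(zip(cutpoints.states, props))


@dataclass
class GoldStateMap:
    """Row-stochastic map: fraction of each GOLD class in each health state."""

    classes: tuple
    states: tuple
    matrix: np.ndarray  # (n_classes, n_states)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.classes), len(self.states)):
            raise ValueError("matrix shape does not match class/state labels")
        if np.any(self.matrix < 0):
            raise ValueError("map entries must be >= 0")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("map rows must sum to 1")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "classes": list(self.classes),
                    "states": list(self.states),
                    "matrix": [[float(v) for v in row] for row in self.matrix],
                },
                fh, sort_keys=False,
            )


def build_gold_state_map(
    reference_gold: np.ndarray | GoldDistribution,
    reference_states: dict[str, float] | np.ndarray,
    classes: tuple = GOLD_CLASSES,
    states: tuple | None = None,
) -> GoldStateMap:
    """Construct the class -> state map by cumulative-quantile alignment.

    Classes and states are both ordered by severity; overlapping cumulative
    mass is allocated (a monotone coupling of the two distributions), so
    applying the map to the reference class distribution reproduces the
    reference state distribution exactly, and more severe classes receive
    stochastically more severe state splits.
    """
    if isinstance(reference_gold, GoldDistribution):
        g = reference_gold.scaled().as_array()
    else:
        g = np.asarray(reference_gold, dtype=float)
    if isinstance(reference_states, dict):
        states = tuple(reference_states)
        s = np.array([reference_states[k] for k in states], dtype=float)
    else:
        s = np.asarray(reference_states, dtype=float)
        if states is None:
            raise ValueError("state labels required with array input")
    if not np.isclose(g.sum(), 1.0) or not np.isclose(s.sum(), 1.0):
        raise ValueError("both distributions must sum to 1")
    if np.all(g == 0) or np.all(s == 0):
        raise ValueError("degenerate zero-mass distribution")
    Gc = np.concatenate([[0.0], np.cumsum(g)])
    Sc = np.concatenate([[0.0], np.cumsum(s)])
    alloc = np.zeros((len(g), len(s)))
    for a in range(len(g)):
        for b in range(len(s)):
            alloc[a, b] = max(
                0.0, min(Gc[a + 1], Sc[b + 1]) - max(Gc[a], Sc[b])
            )
    matrix = np.zeros_like(alloc)
    for a in range(len(g)):
        if g[a] > 0:
            matrix[a] = alloc[a] / g[a]
        else:
            # zero-mass class: assign to the state bin containing its
            # cumulative position (deterministic, severity-consistent)
            b = int(np.searchsorted(Sc[1:], Gc[a], side="left"))
            matrix[a, min(b, len(s) - 1)] = 1.0
    return GoldStateMap(classes=tuple(classes), states=tuple(states), matrix=matrix)


def apply_state_map(
    state_map: GoldStateMap, gold_prevalences: dict[str, float] | np.ndarray
) -> dict[str, float]:
    """Health-state prevalences = map^T . class prevalences (total preserved)."""
    if isinstance(gold_prevalences, dict):
        vec = np.array([gold_prevalences[c] for c in state_map.classes], dtype=float)
    else:
        vec = np.asarray(gold_prevalences, dtype=float)
    if vec.shape != (len(state_map.classes),):
        raise ValueError(
            f"expected {len(state_map.classes)} class prevalences, got {vec.shape}"
        )
    if np.any(vec < 0):
        raise ValueError("prevalences must be >= 0")
    out = state_map.matrix.T @ vec
    return dict(zip(state_map.states, out))
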