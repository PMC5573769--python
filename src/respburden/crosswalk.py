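"""Case-definition crosswalks.

Prevalence surveys report on many case definitions (post- vs
pre-bronchodilator GOLD spirometry, lower-limit-of-normal variants,
self-report).  Datapoints using an alternative definition are mapped onto
the reference definition by dividing by a fitted age-specific ratio curve
ratio(age) = exp(b0 + b1 * age), with delta-method propagation of the
curve's residual dispersion into the adjusted standard error.

Self-report / diagnosis-only definitions are deliberately NOT handled
here: those are adjusted inside the consistency meta-regression as
study-level multiplicative covariates (see :mod:`respburden.dismod_lite`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DefinitionRatioModel",
    "fit_exponential_ratio",
    "apply_crosswalk",
    "crosswalk_dataframe",
]

log = logging.getLogger(__name__)


@dataclass
class DefinitionRatioModel:
    """Fitted log-linear ratio of an alternative definition to the reference."""

    source_definition: str
    reference_definition: str
    b0: float
    b1: float
    residual_sd: float = 0.0
    age_min: float = 0.0
    age_max: float = 100.0

    def __post_init__(self):
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")

    def ratio(self, age) -> np.ndarray | float:
        return np.exp(self.b0 + self.b1 * np.asarray(age, dtype=float))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "DefinitionRatioModel":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def fit_exponential_ratio(
    pairs,
    source_definition: str = "alternative",
    reference_definition: str = "reference",
    weights=None,
) -> DefinitionRatioModel:
    """Least-squares fit of ln(ratio) on age.

    Parameters
    ----------
    pairs
        Sequence of ``(age_mid, ratio)`` with ratio = alternative/reference
        prevalence at that age.
    weights
        Optional inverse-variance weights for the log ratios; unweighted
        when omitted.
    """
    pairs = np.asarray(list(pairs), dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must be (age, ratio) tuples")
    ages, ratios = pairs[:, 0], pairs[:, 1]
    if np.any(ratios <= 0):
        raise ValueError("all ratios must be > 0")
    if len(np.unique(ages)) < 2:
        raise ValueError("need at least 2 distinct ages to fit a ratio curve")
    y = np.log(ratios)
    X = np.column_stack([np.ones_like(ages), ages])
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))
        Xw, yw = X * w[:, None], y * w
    else:
        Xw, yw = X, y
    coef, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = y - X @ coef
    dof = len(ages) - 2
    residual_sd = float(np.sqrt((resid**2).sum() / dof)) if dof > 0 else 0.0
    return DefinitionRatioModel(
        source_definition=source_definition,
        reference_definition=reference_definition,
        b0=float(coef[0]),
        b1=float(coef[1]),
        residual_sd=residual_sd,
        age_min=float(ages.min()),
        age_max=float(ages.max()),
    )


def apply_crosswalk(datapoint: pd.Series, model: DefinitionRatioModel) -> pd.Series:
    """Adjust one survey datapoint onto the reference definition.

    The mean is divided by the fitted ratio at the datapoint's age
    midpoint; the standard error becomes
    ``sqrt((SE/ratio)^2 + (mean/ratio)^2 * residual_sd^2)`` (delta method,
    treating the log-ratio dispersion as the curve's uncertainty).  The
    original values are retained in ``orig_*`` provenance fields.
    """
    dp = datapoint.copy()
    if dp["definition"] == model.reference_definition:
        return dp  # idempotent on reference-definition datapoints
    if dp["definition"] != model.source_definition:
        raise ValueError(
            f"datapoint definition '{dp['definition']}' does not match "
            f"model source '{model.source_definition}'"
        )
    age_mid = (dp["age_start"] + dp["age_end"]) / 2.0
    if age_mid < model.age_min or age_mid > model.age_max:
        log.debug(
            "age midpoint %.1f outside fitted range [%.1f, %.1f] for %s; "
            "extrapolating",
            age_mid, model.age_min, model.age_max, model.source_definition,
        )
    ratio = float(model.ratio(age_mid))
    mean, se = float(dp["mean"]), float(dp["standard_error"])
    dp["orig_mean"] = mean
    dp["orig_standard_error"] = se
    dp["orig_definition"] = dp["definition"]
    dp["mean"] = mean / ratio
    dp["standard_error"] = np.sqrt(
        (se / ratio) ** 2 + (mean / ratio) ** 2 * model.residual_sd**2
    )
    dp["definition"] = model.reference_definition
    return dp


def crosswalk_dataframe(
    surveys: pd.DataFrame, models: dict[str, DefinitionRatioModel]
) -> pd.DataFrame:
    """Apply per-definition ratio models to every matching row of a survey
    table; rows whose definition has no model pass through unchanged."""
    out = []
    n_extrap: dict[str, int] = {}
    for _, row in surveys.iterrows():
        model = models.get(row["definition"])
        if model is not None:
            mid = (row["age_start"] + row["age_end"]) / 2.0
            if mid < model.age_min or mid > model.age_max:
                n_extrap[model.source_definition] = (
                    n_extrap.get(model.source_definition, 0) + 1
                )
            out.append(apply_crosswalk(row, model))
        else:
            out.append(row)
    for tag, n in n_extrap.items():
        log.warning("crosswalk '%s': %d datapoints outside the fitted age "
                    "range were extrapolated", tag, n)
    return pd.DataFrame(out).reset_index(drop=True)
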