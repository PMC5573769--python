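"""Socio-demographic Index construction and expected-burden reporting.

The SDI is the geometric mean of three components rescaled to [0, 1] over
the pooled location-year window: lag-distributed income per capita (log
scale), mean years of education over age 15, and total fertility rate with
the rescaling reversed (high fertility -> low development).  Locations are
assigned to quintiles of the pooled location-year SDI distribution using
their final-year value, and the expected relationship between SDI and each
health outcome is a locally weighted (LOESS, degree 1, tricube) regression
over all location-years; observed-minus-expected deviations identify
locations doing better or worse than their development level predicts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "rescale_component",
    "compute_sdi",
    "build_sdi_table",
    "QuintileAssignment",
    "assign_quintiles",
    "ExpectedCurve",
    "fit_expected_curve",
    "observed_vs_expected",
]

QUINTILE_LABELS = ("low", "low_middle", "middle", "high_middle", "high")


def rescale_component(
    values, window_min: float, window_max: float, reverse: bool = False
) -> np.ndarray:
    """Linear map of a component onto [0, 1] over the observation window.

    ``reverse=True`` flips the direction (used for total fertility: the
    lowest fertility observed maps to 1).  Values outside the window are
    clipped.
    """
    if window_max <= window_min:
        raise ValueError("degenerate rescaling window")
    x = (np.asarray(values, dtype=float) - window_min) / (window_max - window_min)
    x = np.clip(x, 0.0, 1.0)
    return 1.0 - x if reverse else x


def compute_sdi(rescaled_income, rescaled_education, rescaled_fertility) -> np.ndarray:
    """Geometric mean of the three rescaled components."""
    comps = np.stack(
        [np.asarray(c, dtype=float) for c in
         (rescaled_income, rescaled_education, rescaled_fertility)]
    )
    if np.any((comps < 0) | (comps > 1)):
        raise ValueError("rescaled components must lie in [0, 1]")
    return np.prod(comps, axis=0) ** (1.0 / 3.0)


def build_sdi_table(components: pd.DataFrame) -> pd.DataFrame:
    """Attach rescaled components and the SDI to an (location, year) table
    with columns ldi, education, tfr.  Income is rescaled on the log scale."""
    df = components.copy()
    ln_ldi = np.log(df["ldi"])
    df["income_rescaled"] = rescale_component(ln_ldi, ln_ldi.min(), ln_ldi.max())
    df["education_rescaled"] = rescale_component(
        df["education"], df["education"].min(), df["education"].max()
    )
    df["fertility_rescaled"] = rescale_component(
        df["tfr"], df["tfr"].min(), df["tfr"].max(), reverse=True
    )
    df["sdi"] = compute_sdi(
        df["income_rescaled"], df["education_rescaled"], df["fertility_rescaled"]
    )
    return df


@dataclass
class QuintileAssignment:
    """Quintile cutoffs from the pooled distribution and per-location labels."""

    cutoffs: np.ndarray
    labels: dict[str, str]

    def label_of(self, location: str) -> str:
        return self.labels[location]


def assign_quintiles(
    sdi_table: pd.DataFrame,
    label_year: int | None = None,
    interpolation: str = "linear",
) -> QuintileAssignment:
    """Quintiles of the pooled location-year SDI distribution.

    Cutoffs sit at the pooled 20/40/60/80th percentiles (linear
    order-statistic interpolation by default); each location is labelled by
    the quintile containing its ``label_year`` (default: latest) value.
    """
    pooled = sdi_table["sdi"].to_numpy()
    if len(np.unique(pooled)) < 5:
        raise ValueError("need at least 5 distinct pooled SDI values")
    cutoffs = np.percentile(pooled, [20, 40, 60, 80], method=interpolation)
    if label_year is None:
        label_year = int(sdi_table["year"].max())
    latest = sdi_table[sdi_table["year"] == label_year]
    labels = {}
    for _, row in latest.iterrows():
        q = int(np.searchsorted(cutoffs, row["sdi"], side="right"))
        labels[row["location"]] = QUINTILE_LABELS[q]
    return QuintileAssignment(cutoffs=cutoffs, labels=labels)


@dataclass
class ExpectedCurve:
    """LOESS smoother of an outcome against SDI (degree 1, tricube)."""

    sdi: np.ndarray = field(repr=False)
    outcome: np.ndarray = field(repr=False)
    span: float = 0.6

    @property
    def sdi_range(self) -> tuple[float, float]:
        return float(self.sdi.min()), float(self.sdi.max())

    def __call__(self, at) -> np.ndarray:
        at = np.atleast_1d(np.asarray(at, dtype=float))
        est = lowess(
            self.outcome, self.sdi, frac=self.span, xvals=at, return_sorted=False
        )
        return est


def fit_expected_curve(
    records: pd.DataFrame,
    outcome_col: str,
    sdi_col: str = "sdi",
    span: float = 0.6,
) -> ExpectedCurve:
    """Fit the expected outcome-vs-SDI relationship over all location-years.

    Deterministic and invariant to row order (rows are sorted by SDI before
    fitting).
    """
    df = records[[sdi_col, outcome_col]].dropna().sort_values(sdi_col)
    if len(df) < 10:
        raise ValueError(f"need >= 10 points to fit an expected curve, got {len(df)}")
    if df[sdi_col].nunique() < 3:
        raise ValueError("SDI values do not span a range")
    return ExpectedCurve(
        sdi=df[sdi_col].to_numpy(), outcome=df[outcome_col].to_numpy(), span=span
    )


def observed_vs_expected(
    series: pd.DataFrame,
    curve: ExpectedCurve,
    outcome_col: str,
    sdi_col: str = "sdi",
) -> pd.DataFrame:
    """Deviation of observed burden from the expected curve.

    Positive deviation = worse than expected (higher burden than the SDI
    level predicts).  Values outside the fitted SDI range are flagged as
    extrapolated.
    """
    out = series.copy()
    lo, hi = curve.sdi_range
    out["expected"] = curve(out[sdi_col].to_numpy())
    out["deviation"] = out[outcome_col] - out["expected"]
    out["extrapolated"] = (out[sdi_col] < lo) | (out[sdi_col] > hi)
    return out
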