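"""Cause-of-death ensemble modelling with envelope squeezing.

An ensemble of component models — mixed-effects regressions of log death
rates or logit cause fractions on varying covariate subsets, with a random
intercept by location — is weighted by out-of-sample predictive validity
(held-out RMSE of log rates) and used to predict the aggregate
chronic-respiratory death-rate envelope everywhere, including locations
with no usable cause-of-death data.  Child causes (COPD, asthma, other
chronic respiratory) are fitted on vital-registration rows only — verbal
autopsy rows carry just the aggregate cause — and then constrained
("squeezed") to the envelope draw by draw; the same squeeze operation
constrains all causes to all-cause mortality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
import yaml

from .drawcube import DrawCube

__all__ = [
    "ComponentModel",
    "EnsembleWeights",
    "prepare_cod",
    "fit_components",
    "score_oos",
    "ensemble_predict",
    "squeeze",
]

log = logging.getLogger(__name__)

FAMILIES = ("log_rate", "logit_fraction")
_EPS_DEATHS = 0.5  # continuity correction for zero counts


def _logit(p):
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return np.log(p / (1 - p))


def _invlogit(x):
    return 1.0 / (1.0 + np.exp(-x))


def prepare_cod(cod: pd.DataFrame) -> pd.DataFrame:
    """Validate and enrich raw cause-of-death records.

    Applies the known VR completeness correction (recorded deaths divided
    by completeness) and computes death rates.  VA rows must carry only the
    aggregate chronic-respiratory cause.
    """
    df = cod.copy()
    required = {"location", "year", "sex", "age_start", "cause", "deaths",
                "person_years", "source_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cod table missing columns: {sorted(missing)}")
    if (df["deaths"] < 0).any():
        raise ValueError("negative death counts")
    if (df["person_years"] <= 0).any():
        raise ValueError("non-positive person_years")
    va_bad = df[(df["source_type"] == "VA") & (df["cause"] != "chronic_resp")]
    if len(va_bad):
        raise ValueError("VA rows must carry only the aggregate chronic_resp cause")
    comp = df["completeness"] if "completeness" in df else 1.0
    df["deaths_corrected"] = df["deaths"] / comp
    df["rate"] = df["deaths_corrected"] / df["person_years"]
    return df


def aggregate_envelope_data(cod: pd.DataFrame,
                            child_causes=("copd", "asthma", "other_resp")) -> pd.DataFrame:
    """Datapoints for the aggregate chronic-respiratory envelope: VA rows
    as recorded plus VR child rows summed per cell."""
    df = prepare_cod(cod)
    va = df[df["cause"] == "chronic_resp"].copy()
    vr = df[(df["source_type"] == "VR") & (df["cause"].isin(child_causes))]
    keys = ["location", "year", "sex", "age_start", "age_end", "source_type"]
    keys = [k for k in keys if k in vr.columns]
    agg = vr.groupby(keys, as_index=False).agg(
        deaths_corrected=("deaths_corrected", "sum"),
        person_years=("person_years", "first"),
    )
    agg["cause"] = "chronic_resp"
    agg["rate"] = agg["deaths_corrected"] / agg["person_years"]
    out = pd.concat([va, agg], ignore_index=True)
    return out


@dataclass
class ComponentModel:
    """One fitted ensemble component."""

    family: str
    covariates: tuple
    result: object = field(repr=False, default=None)
    resid_sd: float = 0.0
    re_sd: float = 0.0
    random_effects: dict = field(default_factory=dict, repr=False)
    oos_score: float | None = None

    def _formula(self) -> str:
        rhs = " + ".join(["C(age_start)"] + list(self.covariates)) or "1"
        return f"y ~ {rhs}"

    def predict_link(self, targets: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Mean and predictive sd in link space (log rate / logit fraction)."""
        mean = np.asarray(self.result.predict(exog=targets), dtype=float)
        re = targets["location"].map(self.random_effects)
        known = re.notna().to_numpy()
        mean = mean + np.where(known, re.fillna(0.0).to_numpy(), 0.0)
        sd = np.where(known, self.resid_sd,
                      np.sqrt(self.resid_sd**2 + self.re_sd**2))
        return mean, sd

    def predict_rate(self, targets: pd.DataFrame) -> np.ndarray:
        mean, _ = self.predict_link(targets)
        if self.family == "log_rate":
            return np.exp(mean)
        return _invlogit(mean) * targets["allcause_rate"].to_numpy()


def _link_observations(data: pd.DataFrame, family: str) -> pd.Series:
    if family == "log_rate":
        return np.log(
            (data["deaths_corrected"] + _EPS_DEATHS) / data["person_years"]
        )
    if family == "logit_fraction":
        frac = data["rate"] / data["allcause_rate"]
        return pd.Series(_logit(frac), index=data.index)
    raise ValueError(f"unknown family '{family}'")


def _fit_one(data: pd.DataFrame, family: str, covariates: tuple) -> ComponentModel:
    for cov in covariates:
        if cov not in data.columns:
            raise ValueError(f"covariate '{cov}' not in data")
        if np.isclose(data[cov].std(), 0.0):
            raise ValueError(f"covariate '{cov}' is constant; unidentifiable")
    df = data.copy()
    df["y"] = _link_observations(df, family)
    model = ComponentModel(family=family, covariates=tuple(covariates))
    if df["location"].nunique() > 1:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm(model._formula(), df, groups=df["location"]).fit(
                reml=True, method="bfgs", maxiter=300
            )
            model.re_sd = float(np.sqrt(max(fit.cov_re.iloc[0, 0], 0.0)))
            try:
                model.random_effects = {
                    loc: float(re.iloc[0]) for loc, re in fit.random_effects.items()
                }
            except Exception:  # RE variance collapsed to ~0: no shrinkage targets
                model.random_effects = {}
                model.re_sd = 0.0
            # guard against a diverged variance-profile optimisation: the
            # fixed part must explain the training data at least as well as
            # a plain regression would
            resid = df["y"].to_numpy() - np.asarray(fit.predict(exog=df))
            if not np.isfinite(resid).all() or np.sqrt(np.mean(resid**2)) > max(
                5.0 * np.sqrt(fit.scale), 1.0
            ):
                fit = smf.ols(model._formula(), df).fit()
                model.re_sd = 0.0
                model.random_effects = {}
    else:
        fit = smf.ols(model._formula(), df).fit()
    model.result = fit
    model.resid_sd = float(np.sqrt(fit.scale))
    return model


def fit_components(
    data: pd.DataFrame,
    covariate_pool: list[tuple],
    families=FAMILIES,
) -> list[ComponentModel]:
    """Fit one component per (family x covariate subset).

    Failed fits (rank deficiency, constant covariates, optimizer errors)
    are logged and dropped, never silently imputed; if every fit fails an
    error with the collected diagnostics is raised.
    """
    if data.empty:
        raise ValueError("no cause-of-death data supplied")
    if len(covariate_pool) < 1:
        raise ValueError("covariate_pool must contain at least one subset")
    models, failures = [], []
    for family in families:
        if family == "logit_fraction" and "allcause_rate" not in data.columns:
            failures.append((family, "*", "allcause_rate column missing"))
            continue
        for covs in covariate_pool:
            try:
                models.append(_fit_one(data, family, tuple(covs)))
            except Exception as exc:  # noqa: BLE001 - failures are reported
                failures.append((family, covs, str(exc)))
                log.warning("dropping component %s %s: %s", family, covs, exc)
    if not models:
        raise RuntimeError(f"all component fits failed: {failures}")
    return models


@dataclass
class EnsembleWeights:
    """Normalised predictive-validity weights, one per component."""

    weights: np.ndarray
    rmse: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("weights must be >= 0")
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("weights must have positive sum")
        self.weights = self.weights / total


def score_oos(
    models: list[ComponentModel],
    data: pd.DataFrame,
    holdout_frac: float = 0.2,
    reps: int = 5,
    tau: float = 1.0,
    seed: int = 0,
) -> EnsembleWeights:
    """Weight components by held-out RMSE of log death rates.

    Repeatedly holds out a fraction of location-years, refits each
    component spec on the remainder and scores its predictions; weights
    are w_k ~ exp(-RMSE_k / tau).  A component that cannot be refitted or
    evaluated on a holdout receives the worst observed score for that rep.
    """
    if len(models) == 1:
        return EnsembleWeights(weights=np.ones(1), rmse=np.zeros(1))
    rng = np.random.default_rng(seed)
    groups = data[["location", "year"]].drop_duplicates().reset_index(drop=True)
    n_hold = max(1, int(round(holdout_frac * len(groups))))
    all_rmse = np.zeros((reps, len(models)))
    for rep in range(reps):
        hold_idx = rng.choice(len(groups), size=n_hold, replace=False)
        hold = groups.iloc[hold_idx]
        mask = data.set_index(["location", "year"]).index.isin(
            pd.MultiIndex.from_frame(hold)
        )
        train, test = data[~mask], data[mask]
        obs_log_rate = np.log(
            (test["deaths_corrected"] + _EPS_DEATHS) / test["person_years"]
        ).to_numpy()
        rep_scores = np.full(len(models), np.nan)
        for k, m in enumerate(models):
            try:
                refit = _fit_one(train, m.family, m.covariates)
                pred = refit.predict_rate(test)
                rep_scores[k] = float(
                    np.sqrt(np.mean((np.log(pred + 1e-12) - obs_log_rate) ** 2))
                )
            except Exception as exc:  # noqa: BLE001
                log.warning("component %d unevaluable in rep %d: %s", k, rep, exc)
        worst = np.nanmax(rep_scores) if np.any(np.isfinite(rep_scores)) else 1.0
        rep_scores[~np.isfinite(rep_scores)] = worst
        all_rmse[rep] = rep_scores
    rmse = all_rmse.mean(axis=0)
    weights = np.exp(-(rmse - rmse.min()) / tau)
    ew = EnsembleWeights(weights=weights, rmse=rmse)
    for m, score in zip(models, rmse):
        m.oos_score = float(score)
    return ew


def ensemble_predict(
    models: list[ComponentModel],
    weights: EnsembleWeights,
    targets: pd.DataFrame,
    n_draws: int,
    seed: int = 0,
    key_cols=("location", "year", "sex", "age_start"),
) -> DrawCube:
    """Posterior draws of death rates for every target cell.

    Each draw samples a component with probability equal to its ensemble
    weight, then samples from that component's predictive distribution in
    link space.  Model-selection uncertainty thereby propagates into the
    draw distribution.
    """
    for cov in {c for m in models for c in m.covariates}:
        if cov not in targets.columns:
            raise ValueError(f"missing covariate '{cov}' in target table")
        if targets[cov].isna().any():
            bad = targets.loc[targets[cov].isna()].head(3)
            raise ValueError(f"missing covariate '{cov}' for target cells:\n{bad}")
    rng = np.random.default_rng(seed)
    n_cells = len(targets)
    link_mean = np.empty((len(models), n_cells))
    link_sd = np.empty((len(models), n_cells))
    for k, m in enumerate(models):
        link_mean[k], link_sd[k] = m.predict_link(targets)
    pick = rng.choice(len(models), size=n_draws, p=weights.weights)
    noise = rng.standard_normal((n_cells, n_draws))
    values = np.empty((n_cells, n_draws))
    for d in range(n_draws):
        k = pick[d]
        link = link_mean[k] + link_sd[k] * noise[:, d]
        if models[k].family == "log_rate":
            values[:, d] = np.exp(link)
        else:
            values[:, d] = _invlogit(link) * targets["allcause_rate"].to_numpy()
    keys = targets[list(key_cols)].reset_index(drop=True)
    return DrawCube(keys, values)


def squeeze(children: dict[str, DrawCube], envelope: DrawCube) -> dict[str, DrawCube]:
    """Constrain child-cause draws to sum to the envelope, draw by draw.

    Each child is rescaled by envelope / sum(children) per cell and draw, so
    the children sum to the envelope exactly while their ratios are
    preserved.  The same operation constrains all causes to all-cause
    mortality.
    """
    aligned = {name: envelope.align_to(cube) for name, cube in children.items()}
    total = np.zeros_like(envelope.values)
    for cube in aligned.values():
        total = total + cube.values
    bad = (total == 0) & (envelope.values > 0)
    if bad.any():
        cell, draw = np.argwhere(bad)[0]
        raise ValueError(
            "children sum to zero with positive envelope at cell "
            f"{envelope.keys.iloc[cell].to_dict()}, draw {draw}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(total > 0, envelope.values / np.where(total > 0, total, 1.0), 0.0)
    return {
        name: DrawCube(envelope.keys, cube.values * scale)
        for name, cube in aligned.items()
    }


def write_model_cards(models: list[ComponentModel], path) -> None:
    cards = [
        {
            "family": m.family,
            "covariates": list(m.covariates),
            "oos_score": m.oos_score,
            "resid_sd": m.resid_sd,
            "re_sd": m.re_sd,
        }
        for m in models
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(cards, fh, sort_keys=False)
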