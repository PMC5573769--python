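"""World configuration: dimensions, case-definition biases, risk registry.

The configuration doubles as the definition of the synthetic study
conditions: disease rate baselines, per-risk log-linear effects, case
definition biases, survey designs, and data-quality parameters
(vital-registration completeness, verbal-autopsy fraction) all live here
with defaults chosen once to be epidemiologically plausible for a world of
locations spanning the development spectrum.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = ["WorldConfig", "default_risk_registry", "DISEASES"]

DISEASES = ("copd", "asthma")

REFERENCE_DEFINITION = {"copd": "gold_postBD", "asthma": "dx_wheeze"}

# Alternative case definitions.  route = "crosswalk" definitions are adjusted
# by a fitted exponential age-ratio curve before model entry; route =
# "multiplier" definitions are adjusted inside the consistency meta-regression
# via a study-level multiplicative covariate.
DEFAULT_DEFINITIONS = {
    "copd": {
        "gold_postBD": {"b0": 0.0, "b1": 0.0, "route": "reference"},
        "gold_preBD": {"b0": 0.35, "b1": 0.004, "route": "crosswalk"},
        "lln_preBD": {"b0": 0.60, "b1": -0.012, "route": "crosswalk"},
        "lln_postBD": {"b0": 0.25, "b1": -0.010, "route": "crosswalk"},
        "self_report": {"b0": -0.45, "b1": 0.0, "route": "multiplier"},
    },
    "asthma": {
        "dx_wheeze": {"b0": 0.0, "b1": 0.0, "route": "reference"},
        "wheeze_only": {"b0": 0.40, "b1": 0.0, "route": "multiplier"},
        "dx_only": {"b0": -0.30, "b1": 0.0, "route": "multiplier"},
    },
}

# True log-linear effects of each risk exposure on incidence and on excess
# mortality (per unit of exposure as recorded in exposures.csv).
DEFAULT_RISK_EFFECTS = {
    "copd": {
        "smoking": {"incidence": 1.2, "excess_mortality": 0.3},
        "secondhand_smoke": {"incidence": 0.25, "excess_mortality": 0.0},
        "household_air_pollution": {"incidence": 0.6, "excess_mortality": 0.1},
        "ambient_pm25": {"incidence": 0.007, "excess_mortality": 0.002},
        "ozone": {"incidence": 0.004, "excess_mortality": 0.0},
        "occupational_particulates": {"incidence": 0.5, "excess_mortality": 0.0},
    },
    "asthma": {
        "smoking": {"incidence": 0.5, "excess_mortality": 0.2},
        "occupational_asthmagens": {"incidence": 0.5, "excess_mortality": 0.0},
    },
}

# Health states and disability weights (configuration fixtures; the default
# weights are placeholders on the GBD scale, not authoritative elicited
# values).
DEFAULT_DISABILITY_WEIGHTS = {
    "copd": {"asymptomatic": 0.0, "mild": 0.019, "moderate": 0.225, "severe": 0.408},
    "asthma": {
        "asymptomatic": 0.0,
        "controlled": 0.015,
        "partially_controlled": 0.036,
        "uncontrolled": 0.133,
    },
}

# True severity-state distribution among prevalent cases in the reference
# (encounter-survey) population.
DEFAULT_STATE_DISTRIBUTION = {
    "copd": {"asymptomatic": 0.35, "mild": 0.30, "moderate": 0.22, "severe": 0.13},
    "asthma": {
        "asymptomatic": 0.30,
        "controlled": 0.33,
        "partially_controlled": 0.25,
        "uncontrolled": 0.12,
    },
}

# Raw (pre-scaling) GOLD spirometric class proportions among COPD cases,
# mirroring class-proportion models fitted separately and then scaled to 1.
DEFAULT_GOLD_RAW = {"gold_1": 0.50, "gold_2": 0.42, "gold_3_4": 0.19}

# Comorbid conditions carried by encounter records besides COPD and asthma.
DEFAULT_COMORBIDITIES = {"diabetes": {"prevalence": 0.08, "dw": 0.049},
                         "low_back_pain": {"prevalence": 0.15, "dw": 0.20}}


def default_risk_registry() -> dict:
    """Risk-outcome registry: exposure type, RRs, TMREL, mediation, group.

    Categorical risks carry per-category relative risks with RR = 1 at the
    reference category; continuous risks carry a log-linear RR-per-unit slope
    and a uniform TMREL interval (sampled once per posterior draw).
    """
    return {
        "copd": {
            "smoking": {
                "type": "categorical",
                "group": "behavioural",
                "categories": {"never": 1.0, "former": 1.6, "current": 2.5},
                "reference": "never",
                "tmrel": {"kind": "none_exposed"},
                "rr_log_sd": 0.05,
            },
            "secondhand_smoke": {
                "type": "categorical",
                "group": "behavioural",
                "categories": {"unexposed": 1.0, "exposed": 1.35},
                "reference": "unexposed",
                "tmrel": {"kind": "zero"},
                "rr_log_sd": 0.05,
                "mediation": {"smoking": 0.0},
            },
            "household_air_pollution": {
                "type": "categorical",
                "group": "environmental",
                "categories": {"clean_fuel": 1.0, "solid_fuel": 2.0},
                "reference": "clean_fuel",
                "tmrel": {"kind": "none_exposed"},
                "rr_log_sd": 0.08,
                "mediation": {"ambient_pm25": 0.15},
            },
            "ambient_pm25": {
                "type": "continuous",
                "group": "environmental",
                "unit": "ug/m3",
                "rr_per_unit_log": 0.0077,  # ~8% per 10 ug/m3
                "tmrel": {"kind": "uniform", "lower": 2.4, "upper": 5.9},
                "exposure_sd_frac": 0.25,
                "rr_log_sd": 0.03,
            },
            "ozone": {
                "type": "continuous",
                "group": "environmental",
                "unit": "ppb",
                "rr_per_unit_log": 0.0058,
                "tmrel": {"kind": "uniform", "lower": 33.3, "upper": 41.9},
                "exposure_sd_frac": 0.15,
                "rr_log_sd": 0.03,
            },
            "occupational_particulates": {
                "type": "categorical",
                "group": "environmental",
                "categories": {"unexposed": 1.0, "exposed": 1.5},
                "reference": "unexposed",
                "tmrel": {"kind": "zero"},
                "rr_log_sd": 0.06,
            },
        },
        "asthma": {
            "smoking": {
                "type": "categorical",
                "group": "behavioural",
                "categories": {"never": 1.0, "former": 1.2, "current": 1.7},
                "reference": "never",
                "tmrel": {"kind": "none_exposed"},
                "rr_log_sd": 0.05,
            },
            "occupational_asthmagens": {
                "type": "categorical",
                "group": "environmental",
                "categories": {"unexposed": 1.0, "exposed": 1.6},
                "reference": "unexposed",
                "tmrel": {"kind": "zero"},
                "rr_log_sd": 0.06,
            },
        },
    }


@dataclass
class WorldConfig:
    """Dimensions and generative parameters of the synthetic world."""

    n_locations: int = 6
    years: tuple = (1990, 1995, 2000, 2005, 2010, 2015)
    age_starts: tuple = tuple(range(0, 100, 5))  # 5-year bands, terminal 95+
    sexes: tuple = ("male", "female")
    n_draws: int = 1000
    seed: int = 0
    definitions: dict = field(default_factory=lambda: _deepcopy(DEFAULT_DEFINITIONS))
    risk_effects: dict = field(default_factory=lambda: _deepcopy(DEFAULT_RISK_EFFECTS))
    disability_weights: dict = field(
        default_factory=lambda: _deepcopy(DEFAULT_DISABILITY_WEIGHTS)
    )
    state_distribution: dict = field(
        default_factory=lambda: _deepcopy(DEFAULT_STATE_DISTRIBUTION)
    )
    gold_raw: dict = field(default_factory=lambda: dict(DEFAULT_GOLD_RAW))
    comorbidities: dict = field(default_factory=lambda: _deepcopy(DEFAULT_COMORBIDITIES))
    # per-location data-quality parameters; None -> derived from development level
    va_fraction: tuple | None = None
    vr_completeness: tuple | None = None
    survey_sample_size: int = 2000
    # log-linear effect of rescaled income on excess mortality (case fatality
    # falls with wealth)
    income_emr_effect: float = -0.8
    # baseline rates: {disease: {"i0","i_slope","i_onset","f0","f_slope",
    # "f_onset","r"}}; incidence i(a)=i0*exp(i_slope*(a-onset)) above onset
    baseline_rates: dict = field(default_factory=lambda: {
        "copd": {"i0": 3e-4, "i_slope": 0.045, "i_onset": 25.0, "i_floor": 1e-5,
                 "f0": 2e-3, "f_slope": 0.045, "f_onset": 30.0, "f_floor": 5e-4,
                 "r": 0.0},
        "asthma": {"i0": 6e-3, "i_slope": -0.05, "i_onset": 0.0, "i_floor": 8e-4,
                   "f0": 4e-4, "f_slope": 0.0, "f_onset": 0.0, "f_floor": 4e-4,
                   "r": 0.035},
    })

    def __post_init__(self):
        self.validate()

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        if self.n_locations < 2:
            raise ValueError(f"n_locations must be >= 2, got {self.n_locations}")
        ages = np.asarray(self.age_starts, dtype=float)
        if np.any(np.diff(ages) <= 0):
            raise ValueError("age_starts must be strictly increasing")
        if self.n_draws < 2:
            raise ValueError(f"n_draws must be >= 2, got {self.n_draws}")
        if self.survey_sample_size <= 0:
            raise ValueError(
                f"survey_sample_size must be > 0, got {self.survey_sample_size}"
            )
        if len(self.years) < 1:
            raise ValueError("years must be non-empty")
        for vec, name in ((self.va_fraction, "va_fraction"),
                          (self.vr_completeness, "vr_completeness")):
            if vec is not None:
                arr = np.asarray(vec, dtype=float)
                if len(arr) != self.n_locations:
                    raise ValueError(f"{name} must have n_locations entries")
                if np.any((arr < 0) | (arr > 1)):
                    raise ValueError(f"{name} values must lie in [0, 1]")

    # -- derived dimension helpers ----------------------------------------

    @property
    def locations(self) -> list[str]:
        return [f"loc_{k}" for k in range(self.n_locations)]

    def development(self) -> np.ndarray:
        """Development level in [0, 1] per location (0 poorest, 1 richest)."""
        return np.linspace(0.0, 1.0, self.n_locations)

    def age_bounds(self) -> list[tuple[float, float]]:
        starts = list(self.age_starts)
        ends = starts[1:] + [starts[-1] + 5.0]
        return list(zip(map(float, starts), map(float, ends)))

    def va_fractions(self) -> np.ndarray:
        if self.va_fraction is not None:
            return np.asarray(self.va_fraction, dtype=float)
        return 0.8 * (1.0 - self.development()) ** 1.5

    def vr_completenesses(self) -> np.ndarray:
        if self.vr_completeness is not None:
            return np.asarray(self.vr_completeness, dtype=float)
        return 0.7 + 0.3 * self.development()

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["years"] = list(self.years)
        d["age_starts"] = list(self.age_starts)
        d["sexes"] = list(self.sexes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "WorldConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown WorldConfig fields: {sorted(unknown)}")
        d = dict(d)
        for key in ("years", "age_starts", "sexes", "va_fraction", "vr_completeness"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "WorldConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _deepcopy(obj):
    if isinstance(obj, dict):
        return {k: _deepcopy(v) for k, v in obj.items()}
    return obj
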