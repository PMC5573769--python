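"""Synthetic world with known ground truth.

Generates every data stream the estimation pipeline consumes — prevalence
surveys tagged by case definition, cause-of-death records from vital
registration (VR) and verbal autopsy (VA), health-service encounter records
with combined disability weights, risk-exposure tables, populations, and
socio-demographic components — from a single seeded configuration, so each
downstream stage can be tested against the truth it was generated from.

Truth construction: disease rates are piecewise-constant in 1-year ages;
incidence and excess mortality are scaled log-linearly by risk exposures
(and income, for case fatality); prevalence is the illness-death solution
of the resulting rates, so the generated world is internally consistent by
construction.  Sampling noise is binomial for surveys, Poisson for death
counts, and log-complement Gaussian for encounter disability weights; all
noise can be switched off, in which case every stream equals its
expectation exactly.

VA records carry only the aggregate chronic-respiratory cause: VA
cause-assignment cannot reliably separate COPD from asthma, so specific
causes appear only in VR rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DISEASES, REFERENCE_DEFINITION, WorldConfig, default_risk_registry
from .illness_death import solve_batch

__all__ = [
    "WorldTruth",
    "generate_world",
    "sample_surveys",
    "sample_cod",
    "sample_encounters",
    "write_world",
]

AGGREGATE_CAUSE = "chronic_resp"
CAUSES = ("copd", "asthma", "other_resp", "other")

_STREAMS = {"truth": 0, "surveys": 1, "cod": 2, "encounters": 3}


def _stream_rng(config: WorldConfig, stream: str) -> np.random.Generator:
    """One independent generator per data stream, split from the master seed."""
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS[stream]])


@dataclass
class WorldTruth:
    """Ground truth tables of the synthetic world.

    Attributes
    ----------
    cells
        One row per (location, year, sex, age band): rates i/r/f per disease,
        background mortality m, prevalence p, CSMR, population, and expected
        death counts by cause.
    exposures
        Long table (location, year, risk, category, value).
    sdi
        Per (location, year): income per capita (lag-distributed), education,
        total fertility, and the rescaled-component columns.
    """

    config: WorldConfig
    cells: pd.DataFrame
    exposures: pd.DataFrame
    sdi: pd.DataFrame
    risk_scalars: pd.DataFrame  # per (location, year, disease): combined scalar

    def reference_location(self) -> str:
        return self.config.locations[-1]


# ---------------------------------------------------------------------------
# exposure and covariate surfaces


def _exposure_table(config: WorldConfig) -> pd.DataFrame:
    dev = config.development()
    rows = []
    for loc, d in zip(config.locations, dev):
        for year in config.years:
            t = year - config.years[0]
            current = max(0.05, 0.40 - 0.20 * d - 0.003 * t)
            former = 0.05 + 0.15 * d + 0.002 * t
            shs = max(0.05, 0.50 - 0.30 * d - 0.002 * t)
            hap = 0.85 * (1.0 - d) ** 2 * (0.99 ** t)
            pm25 = 15.0 + 55.0 * np.exp(-((d - 0.55) ** 2) / 0.08) + 0.2 * t * (1 - d)
            ozone = 35.0 + 15.0 * d + 0.05 * t
            occ_part = max(0.03, 0.18 - 0.10 * d)
            occ_asth = max(0.03, 0.12 - 0.05 * d)
            rows += [
                (loc, year, "smoking", "current", current),
                (loc, year, "smoking", "former", former),
                (loc, year, "smoking", "never", 1.0 - current - former),
                (loc, year, "secondhand_smoke", "exposed", shs),
                (loc, year, "secondhand_smoke", "unexposed", 1.0 - shs),
                (loc, year, "household_air_pollution", "solid_fuel", hap),
                (loc, year, "household_air_pollution", "clean_fuel", 1.0 - hap),
                (loc, year, "ambient_pm25", "mean", pm25),
                (loc, year, "ozone", "mean", ozone),
                (loc, year, "occupational_particulates", "exposed", occ_part),
                (loc, year, "occupational_particulates", "unexposed", 1.0 - occ_part),
                (loc, year, "occupational_asthmagens", "exposed", occ_asth),
                (loc, year, "occupational_asthmagens", "unexposed", 1.0 - occ_asth),
            ]
    return pd.DataFrame(rows, columns=["location", "year", "risk", "category", "value"])


def _sdi_table(config: WorldConfig) -> pd.DataFrame:
    dev = config.development()
    rows = []
    for loc, d in zip(config.locations, dev):
        for year in config.years:
            t = year - config.years[0]
            ldi = 800.0 * np.exp(3.6 * d + 0.015 * t)
            edu = 2.0 + 12.0 * d + 0.05 * t
            tfr = max(1.2, 6.5 - 4.6 * d - 0.02 * t)
            rows.append((loc, year, ldi, edu, tfr))
    return pd.DataFrame(rows, columns=["location", "year", "ldi", "education", "tfr"])


def _exposure_scalar_inputs(exposures: pd.DataFrame) -> pd.DataFrame:
    """Per (location, year, risk) the single exposure value entering the
    log-linear rate model: exposed/current fraction for categorical risks,
    the mean for continuous ones."""
    pick = exposures[exposures["category"].isin(["current", "exposed", "solid_fuel", "mean"])]
    return pick.rename(columns={"value": "x"})[["location", "year", "risk", "x"]]


def risk_scalar_table(config: WorldConfig, exposures: pd.DataFrame) -> pd.DataFrame:
    """Combined log-linear exposure scalars per (location, year, disease)."""
    xs = _exposure_scalar_inputs(exposures)
    rows = []
    for disease in DISEASES:
        effects = config.risk_effects[disease]
        for (loc, year), grp in xs.groupby(["location", "year"], sort=False):
            lookup = dict(zip(grp["risk"], grp["x"]))
            inc = sum(eff["incidence"] * lookup[r] for r, eff in effects.items())
            emr = sum(eff["excess_mortality"] * lookup[r] for r, eff in effects.items())
            rows.append((loc, year, disease, inc, emr))
    return pd.DataFrame(
        rows, columns=["location", "year", "disease", "scalar_incidence", "scalar_emr"]
    )


# ---------------------------------------------------------------------------
# rate baselines


def _baseline_on_years(params: dict, ages: np.ndarray, which: str) -> np.ndarray:
    base = params[f"{which}0"] * np.exp(
        params[f"{which}_slope"] * (ages - params[f"{which}_onset"])
    )
    return np.where(ages >= params[f"{which}_onset"], base, params[f"{which}_floor"])


def _background_mortality(ages: np.ndarray) -> np.ndarray:
    return 3e-4 * np.exp(0.082 * ages) + 0.012 * np.exp(-ages)


def _other_resp_rate(ages: np.ndarray) -> np.ndarray:
    return 4e-5 * np.exp(0.05 * ages)


# ---------------------------------------------------------------------------
# world generation


def generate_world(config: WorldConfig) -> WorldTruth:
    """Build the ground-truth world deterministically from the config seed."""
    config.validate()
    exposures = _exposure_table(config)
    sdi = _sdi_table(config)
    scalars = risk_scalar_table(config, exposures)

    # rates are piecewise-constant within 5-year age bands (evaluated at the
    # band midpoint), expanded to the solver's 1-year grid
    age_max = int(config.age_starts[-1]) + 5
    bounds = config.age_bounds()
    band_mids = np.array([(a0 + a1) / 2 for a0, a1 in bounds])
    band_widths = np.array([int(a1 - a0) for a0, a1 in bounds])
    # ages below the first configured band take the first band's rates, so
    # the solver can always integrate from birth
    band_widths[0] += int(config.age_starts[0])
    expand = lambda band_vals: np.repeat(band_vals, band_widths)
    years_grid = expand(band_mids)  # midpoint age per 1-year interval
    m_grid = expand(_background_mortality(band_mids))

    # rescaled income in [0,1] over the whole world (drives case fatality)
    ln_ldi = np.log(sdi["ldi"])
    sdi = sdi.assign(
        ldi_rescaled=(ln_ldi - ln_ldi.min()) / (ln_ldi.max() - ln_ldi.min())
    )
    ldi_lookup = sdi.set_index(["location", "year"])["ldi_rescaled"]

    # batch of (location, year) rate schedules per disease
    groups = [(loc, yr) for loc in config.locations for yr in config.years]
    n_g = len(groups)
    sc = scalars.set_index(["location", "year", "disease"])

    per_disease = {}
    for disease in DISEASES:
        params = config.baseline_rates[disease]
        i_base = expand(_baseline_on_years(params, band_mids, "i"))
        f_base = expand(_baseline_on_years(params, band_mids, "f"))
        i_mat = np.empty((age_max, n_g))
        f_mat = np.empty((age_max, n_g))
        for g, (loc, yr) in enumerate(groups):
            row = sc.loc[(loc, yr, disease)]
            ldi = ldi_lookup.loc[(loc, yr)]
            i_mat[:, g] = i_base * np.exp(row["scalar_incidence"])
            f_mat[:, g] = f_base * np.exp(
                row["scalar_emr"] + config.income_emr_effect * ldi
            )
        r_mat = np.full((age_max, n_g), params["r"])
        m_mat = np.tile(m_grid[:, None], (1, n_g))
        ages_fine, S, C = solve_batch(i_mat, r_mat, f_mat, m_mat)
        alive = S + C
        p_fine = np.where(alive > 0, C / np.where(alive > 0, alive, 1.0), 0.0)
        per_disease[disease] = {
            "i": i_mat, "r": r_mat, "f": f_mat,
            "ages_fine": ages_fine, "p_fine": p_fine,
        }

    # population structure
    dev = config.development()
    growth = {loc: 0.003 + 0.012 * (1 - d) for loc, d in zip(config.locations, dev)}
    lam = {loc: 0.015 + 0.035 * (1 - d) for loc, d in zip(config.locations, dev)}
    base_total = {loc: (2.0 + 8.0 * k) * 1e6 for k, loc in enumerate(config.locations)}

    rows = []
    for g, (loc, yr) in enumerate(groups):
        t = yr - config.years[0]
        total = base_total[loc] * (1.0 + growth[loc]) ** t
        mids = np.array([(a0 + a1) / 2 for a0, a1 in bounds])
        shape = np.exp(-lam[loc] * mids)
        shape /= shape.sum()
        for sex in config.sexes:
            for (a0, a1), w in zip(bounds, shape):
                sel = slice(int(a0), int(a1))
                fine_sel = None
                cell = {
                    "location": loc, "year": yr, "sex": sex,
                    "age_start": a0, "age_end": a1,
                    "pop": total * w / len(config.sexes),
                    "m": float(m_grid[sel][0]),
                    "other_resp_rate": float(_other_resp_rate((a0 + a1) / 2)),
                }
                for disease in DISEASES:
                    dd = per_disease[disease]
                    fine = dd["ages_fine"]
                    if fine_sel is None:
                        fine_sel = (fine >= a0) & (fine <= a1)
                    # band prevalence = integral mean over [a0, a1]
                    p_band = float(
                        np.trapezoid(dd["p_fine"][fine_sel, g],
                                     fine[fine_sel]) / (a1 - a0)
                    )
                    f_band = float(dd["f"][sel, g][0])
                    pf_band = p_band * f_band
                    cell[f"i_{disease}"] = float(dd["i"][sel, g][0])
                    cell[f"r_{disease}"] = float(dd["r"][sel, g][0])
                    cell[f"f_{disease}"] = f_band
                    cell[f"p_{disease}"] = p_band
                    cell[f"csmr_{disease}"] = pf_band
                rows.append(cell)
    cells = pd.DataFrame(rows)
    for disease in DISEASES:
        cells[f"deaths_{disease}"] = cells[f"csmr_{disease}"] * cells["pop"]
    cells["deaths_other_resp"] = cells["other_resp_rate"] * cells["pop"]
    cells["deaths_other"] = cells["m"] * cells["pop"]
    cells["deaths_all"] = cells[[f"deaths_{c}" for c in CAUSES]].sum(axis=1)

    return WorldTruth(config=config, cells=cells, exposures=exposures, sdi=sdi,
                      risk_scalars=scalars)


# ---------------------------------------------------------------------------
# data streams


def definition_ratio(config: WorldConfig, disease: str, definition: str,
                     age_mid) -> np.ndarray:
    spec = config.definitions[disease][definition]
    return np.exp(spec["b0"] + spec["b1"] * np.asarray(age_mid, dtype=float))


def sample_surveys(
    world: WorldTruth,
    definitions: dict | None = None,
    noise: bool = True,
    rng: np.random.Generator | None = None,
    include_remission: bool = True,
) -> pd.DataFrame:
    """Draw prevalence survey datapoints for every configured definition.

    A datapoint's expectation is true prevalence times the definition's
    age-ratio bias; sampling is binomial at the design's effective sample
    size.  With ``noise=False`` the recorded mean equals the expectation.
    For diseases with a non-zero cure rate a sparse set of remission
    datapoints (reference definition, Gaussian noise at 10% relative SE)
    is also emitted, mirroring the handful of remission studies available
    for asthma.
    """
    config = world.config
    if definitions is None:
        definitions = {d: list(config.definitions[d]) for d in DISEASES}
    for disease, tags in definitions.items():
        for tag in tags:
            if tag not in config.definitions[disease]:
                raise ValueError(f"unknown case definition '{tag}' for {disease}")
    if rng is None:
        rng = _stream_rng(config, "surveys")
    n = config.survey_sample_size
    out = []
    for disease, tags in definitions.items():
        p_true = world.cells[["location", "year", "sex", "age_start", "age_end",
                              f"p_{disease}"]].copy()
        age_mid = (p_true["age_start"] + p_true["age_end"]) / 2
        for tag in tags:
            expect = np.clip(
                p_true[f"p_{disease}"].to_numpy()
                * definition_ratio(config, disease, tag, age_mid),
                0.0, 0.995,
            )
            if noise:
                mean = rng.binomial(n, expect) / n
            else:
                mean = expect
            phat = np.clip(mean, 0.5 / n, 1 - 0.5 / n)
            se = np.sqrt(phat * (1 - phat) / n)
            df = p_true[["location", "year", "sex", "age_start", "age_end"]].copy()
            df["measure"] = "prevalence"
            df["disease"] = disease
            df["definition"] = tag
            df["mean"] = mean
            df["standard_error"] = se
            df["sample_size"] = n
            out.append(df)
        if include_remission and config.baseline_rates[disease]["r"] > 0:
            rem = world.cells[
                (world.cells["sex"] == config.sexes[0])
                & (world.cells["age_start"] % 10 == 0)
            ][["location", "year", "sex", "age_start", "age_end", f"r_{disease}"]]
            r_true = rem[f"r_{disease}"].to_numpy()
            se_r = np.maximum(0.1 * r_true, 1e-4)
            mean_r = r_true + (rng.normal(0, se_r) if noise else 0.0)
            df = rem[["location", "year", "sex", "age_start", "age_end"]].copy()
            df["measure"] = "remission"
            df["disease"] = disease
            df["definition"] = REFERENCE_DEFINITION[disease]
            df["mean"] = np.maximum(mean_r, 0.0)
            df["standard_error"] = se_r
            df["sample_size"] = np.nan
            out.append(df)
    return pd.concat(out, ignore_index=True)


def sample_cod(
    world: WorldTruth,
    noise: bool = True,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw cause-of-death records.

    Each location's deaths are split between a VR stream (cause detail,
    thinned by VR completeness) and a VA stream (aggregate
    chronic-respiratory cause only).  Counts are Poisson around their
    expectations when ``noise`` is on.
    """
    config = world.config
    if rng is None:
        rng = _stream_rng(config, "cod")
    va_frac = dict(zip(config.locations, config.va_fractions()))
    vr_comp = dict(zip(config.locations, config.vr_completenesses()))
    cells = world.cells
    rows = []
    for _, cell in cells.iterrows():
        loc = cell["location"]
        va, comp = va_frac[loc], vr_comp[loc]
        py_vr = cell["pop"] * (1.0 - va)
        py_va = cell["pop"] * va
        base = dict(location=loc, year=cell["year"], sex=cell["sex"],
                    age_start=cell["age_start"], age_end=cell["age_end"])
        if py_vr > 0:
            for cause in CAUSES:
                expect = cell[f"deaths_{cause}"] * (1.0 - va) * comp
                deaths = rng.poisson(expect) if noise else expect
                rows.append({**base, "cause": cause, "deaths": deaths,
                             "person_years": py_vr, "source_type": "VR",
                             "completeness": comp})
        if py_va > 0:
            expect = (cell["deaths_copd"] + cell["deaths_asthma"]
                      + cell["deaths_other_resp"]) * va
            deaths = rng.poisson(expect) if noise else expect
            rows.append({**base, "cause": AGGREGATE_CAUSE, "deaths": deaths,
                         "person_years": py_va, "source_type": "VA",
                         "completeness": 1.0})
    return pd.DataFrame(rows)


def sample_encounters(
    world: WorldTruth,
    n_individuals: int,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw individual encounter records from the reference location.

    Each record carries condition flags and a combined disability weight
    1 - prod(1 - dw_c) over the individual's conditions; optional Gaussian
    noise is added on the ln(1 - DW) scale.
    """
    if n_individuals <= 0:
        raise ValueError(f"n_individuals must be > 0, got {n_individuals}")
    config = world.config
    if rng is None:
        rng = _stream_rng(config, "encounters")
    loc = world.reference_location()
    year = min(config.years, key=lambda y: abs(y - 2005))
    ref = world.cells[(world.cells["location"] == loc)
                      & (world.cells["year"] == year)
                      & (world.cells["sex"] == config.sexes[0])]
    weights = ref["pop"].to_numpy()
    weights = weights / weights.sum()
    band_idx = rng.choice(len(ref), size=n_individuals, p=weights)
    age_start = ref["age_start"].to_numpy()[band_idx]
    ages = age_start + rng.uniform(0, 5, size=n_individuals)

    conditions = list(DISEASES) + list(config.comorbidities)
    flags = {}
    dws = np.zeros((n_individuals, len(conditions)))
    for j, cond in enumerate(conditions):
        if cond in DISEASES:
            prev = ref[f"p_{cond}"].to_numpy()[band_idx]
            has = rng.random(n_individuals) < prev
            states = list(config.state_distribution[cond])
            probs = np.array([config.state_distribution[cond][s] for s in states])
            state_draw = rng.choice(len(states), size=n_individuals, p=probs / probs.sum())
            w = np.array([config.disability_weights[cond][s] for s in states])[state_draw]
            dws[:, j] = np.where(has, w, 0.0)
        else:
            spec = config.comorbidities[cond]
            has = rng.random(n_individuals) < spec["prevalence"]
            dws[:, j] = np.where(has, spec["dw"], 0.0)
        flags[f"has_{cond}"] = has.astype(int)

    log_comp = np.log1p(-dws).sum(axis=1)
    if noise_sd > 0:
        log_comp = log_comp + rng.normal(0, noise_sd, size=n_individuals)
        log_comp = np.minimum(log_comp, 0.0)
    combined = 1.0 - np.exp(log_comp)
    df = pd.DataFrame({"age": ages, **flags, "combined_dw": combined})
    df.insert(0, "individual", np.arange(n_individuals))
    return df


# ---------------------------------------------------------------------------
# CSV export


def write_world(world: WorldTruth, outdir, noise: bool = True,
                n_encounters: int = 20000, encounter_noise_sd: float = 0.02) -> dict:
    """Write every data stream and the truth tables as CSV files."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = world.config
    files = {}

    surveys = sample_surveys(world, noise=noise)
    cod = sample_cod(world, noise=noise)
    encounters = sample_encounters(
        world, n_encounters, noise_sd=encounter_noise_sd if noise else 0.0
    )
    pop = world.cells[["location", "year", "sex", "age_start", "age_end", "pop"]]

    tables = {
        "surveys.csv": surveys,
        "cod.csv": cod,
        "encounters.csv": encounters,
        "exposures.csv": world.exposures,
        "population.csv": pop,
        "sdi_components.csv": world.sdi,
        "world_truth.csv": world.cells,
        "risk_scalars.csv": world.risk_scalars,
    }
    for name, df in tables.items():
        path = outdir / name
        df.to_csv(path, index=False, float_format="%.10g")
        files[name] = path
    config.to_yaml(outdir / "world_config.yaml")
    files["world_config.yaml"] = outdir / "world_config.yaml"
    import yaml as _yaml

    with open(outdir / "risk_registry.yaml", "w") as fh:
        _yaml.safe_dump(default_risk_registry(), fh, sort_keys=True)
    files["risk_registry.yaml"] = outdir / "risk_registry.yaml"
    return files
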