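"""End-to-end pipeline: synthetic world through burden tables.

Stages (each a function reading its inputs from, and writing its outputs
to, a working directory):

1.  simulate   — generate the synthetic world and all data-stream CSVs
2.  crosswalk  — fit ratio curves, adjust alternative-definition surveys
3.  cod        — cause-of-death ensemble, envelope + all-cause squeezes
4.  nonfatal   — illness-death consistency fits, prevalence/incidence draws
5.  severity   — encounter-based state splits and GOLD -> state mapping
6.  risk       — PAF draws per risk, mediation, multiplicative combination
7.  burden     — YLL/YLD/DALY draws, summary tables, attribution by quintile
8.  sdi        — SDI construction, quintiles, expected curves, deviations

``run_pipeline`` chains them and writes a provenance manifest (seed,
version, config hash).  All randomness derives from the config seed, so a
rerun with the same seed reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
import logging
import pathlib

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .burden import (
    DrawCube,
    PER,
    age_standardise,
    compute_daly,
    compute_yld,
    compute_yll,
    load_lifetable,
    load_standard_population,
    percent_change,
    summarise,
    summarise_cube,
)
from .config import DISEASES, REFERENCE_DEFINITION, WorldConfig, default_risk_registry
from .codem_lite import (
    aggregate_envelope_data,
    ensemble_predict,
    fit_components,
    prepare_cod,
    score_oos,
    squeeze,
    write_model_cards,
    EnsembleWeights,
)
from .cra import (
    TMRELSpec,
    combine_pafs,
    decompose_groups,
    mediation_adjust,
    paf_categorical_draws,
    paf_loglinear_lognormal_draws,
)
from .crosswalk import crosswalk_dataframe, fit_exponential_ratio
from .dismod_lite import DismodConfig, derive_emr_datapoints, fit_consistent, predict
from .published import data_path
from .sdi_report import (
    assign_quintiles,
    build_sdi_table,
    fit_expected_curve,
    observed_vs_expected,
)
from .severity import (
    GoldDistribution,
    SeverityCutpoints,
    apply_state_map,
    build_gold_state_map,
    classify_states,
    estimate_condition_dw,
    scale_and_apply,
)
from .synthworld import CAUSES, generate_world, write_world

log = logging.getLogger(__name__)

FLOAT_FMT = "%.12g"
CHRONIC_CHILDREN = ("copd", "asthma", "other_resp")


def _require(outdir: pathlib.Path, *names) -> list[pathlib.Path]:
    paths = []
    for name in names:
        p = outdir / name
        if not p.exists():
            raise FileNotFoundError(f"pipeline input missing: {p}")
        paths.append(p)
    return paths


def _stage_seed(config: WorldConfig, k: int) -> int:
    return (config.seed * 1_000_003 + k) % (2**31 - 1)


def _load_config(outdir: pathlib.Path) -> WorldConfig:
    (p,) = _require(outdir, "world_config.yaml")
    return WorldConfig.from_yaml(p)


def _write_cube(cube: DrawCube, path: pathlib.Path) -> None:
    cube.to_long().to_csv(path, index=False, float_format=FLOAT_FMT)


def _read_cube(path: pathlib.Path, key_cols) -> DrawCube:
    df = pd.read_csv(path)
    return DrawCube.from_long(df, key_cols=key_cols)


# ---------------------------------------------------------------------------
# stage 1: simulate


def stage_simulate(config: WorldConfig, outdir, noise: bool = True):
    outdir = pathlib.Path(outdir)
    world = generate_world(config)
    write_world(world, outdir, noise=noise)
    return world


# ---------------------------------------------------------------------------
# stage 2: crosswalk


def _ratio_pairs(surveys: pd.DataFrame, disease: str, definition: str,
                 reference: str, min_ref: float = 0.01) -> list[tuple]:
    """Age-specific alternative/reference prevalence ratios from cells
    observed under both definitions."""
    sub = surveys[surveys["disease"] == disease]
    keys = ["location", "year", "sex", "age_start", "age_end"]
    ref = sub[sub["definition"] == reference][keys + ["mean"]]
    alt = sub[sub["definition"] == definition][keys + ["mean"]]
    merged = ref.merge(alt, on=keys, suffixes=("_ref", "_alt"))
    merged = merged[merged["mean_ref"] >= min_ref]
    merged = merged[merged["mean_alt"] > 0]
    age_mid = (merged["age_start"] + merged["age_end"]) / 2
    return list(zip(age_mid, merged["mean_alt"] / merged["mean_ref"]))


def stage_crosswalk(outdir):
    outdir = pathlib.Path(outdir)
    (surveys_path,) = _require(outdir, "surveys.csv")
    config = _load_config(outdir)
    surveys = pd.read_csv(surveys_path)
    models = {}
    cards = {}
    for disease in DISEASES:
        reference = REFERENCE_DEFINITION[disease]
        for tag, spec in config.definitions[disease].items():
            if spec["route"] != "crosswalk":
                continue
            pairs = _ratio_pairs(surveys, disease, tag, reference)
            if len(pairs) < 2:
                log.warning("too few ratio pairs for %s; skipping crosswalk", tag)
                continue
            model = fit_exponential_ratio(
                pairs, source_definition=tag, reference_definition=reference
            )
            models[tag] = model
            cards[tag] = {
                "b0": model.b0, "b1": model.b1,
                "residual_sd": model.residual_sd,
                "n_pairs": len(pairs),
                "reference": reference,
            }
    prev = surveys[surveys["measure"] == "prevalence"]
    other = surveys[surveys["measure"] != "prevalence"]
    adjusted = crosswalk_dataframe(prev, models)
    adjusted = pd.concat([adjusted, other], ignore_index=True)
    adjusted.to_csv(outdir / "surveys_adjusted.csv", index=False,
                    float_format=FLOAT_FMT)
    with open(outdir / "crosswalk_models.yaml", "w") as fh:
        yaml.safe_dump(cards, fh, sort_keys=True)
    return models


# ---------------------------------------------------------------------------
# stage 3: cause of death


def _covariate_table(outdir: pathlib.Path) -> pd.DataFrame:
    _require(outdir, "exposures.csv", "sdi_components.csv")
    exposures = pd.read_csv(outdir / "exposures.csv")
    sdi = build_sdi_table(pd.read_csv(outdir / "sdi_components.csv"))
    pick = exposures[exposures["category"].isin(
        ["current", "solid_fuel", "mean"])]
    wide = pick.pivot_table(index=["location", "year"], columns="risk",
                            values="value").reset_index()
    cov = wide.merge(sdi[["location", "year", "ldi", "income_rescaled", "sdi"]],
                     on=["location", "year"])
    cov["ln_ldi"] = np.log(cov["ldi"])
    return cov


def stage_cod(outdir, n_draws: int | None = None):
    outdir = pathlib.Path(outdir)
    _require(outdir, "cod.csv", "world_truth.csv")
    config = _load_config(outdir)
    if n_draws is None:
        n_draws = config.n_draws
    seed = _stage_seed(config, 3)
    cod = pd.read_csv(outdir / "cod.csv")
    cov = _covariate_table(outdir)

    # all-cause mortality and person-years are demographic inputs
    truth = pd.read_csv(outdir / "world_truth.csv")
    targets = truth[["location", "year", "sex", "age_start", "age_end", "pop"]].copy()
    targets["allcause_rate"] = truth["deaths_all"] / truth["pop"]
    targets = targets.merge(cov, on=["location", "year"])

    env_data = aggregate_envelope_data(cod).merge(cov, on=["location", "year"])
    pool = [(), ("smoking",), ("smoking", "household_air_pollution"),
            ("ambient_pm25", "ln_ldi")]
    models = fit_components(env_data, pool)
    weights = score_oos(models, env_data, seed=seed)
    envelope = ensemble_predict(models, weights, targets, n_draws, seed=seed + 1)
    write_model_cards(models, outdir / "cod_model_cards.yaml")

    # child causes: VR rows only (VA cannot separate specific causes)
    vr = prepare_cod(cod)
    vr = vr[vr["source_type"] == "VR"].merge(cov, on=["location", "year"])
    children = {}
    for k, cause in enumerate(CHRONIC_CHILDREN):
        sub = vr[vr["cause"] == cause]
        cmodels = fit_components(sub, [("smoking", "ln_ldi")],
                                 families=("log_rate",))
        cw = EnsembleWeights(weights=np.ones(len(cmodels)),
                             rmse=np.zeros(len(cmodels)))
        children[cause] = ensemble_predict(cmodels, cw, targets, n_draws,
                                           seed=seed + 2 + k)
    squeezed = squeeze(children, envelope)

    # constrain everything to all-cause mortality
    other_sub = vr[vr["cause"] == "other"]
    omods = fit_components(other_sub, [("ln_ldi",)], families=("log_rate",))
    ow = EnsembleWeights(weights=np.ones(len(omods)), rmse=np.zeros(len(omods)))
    other_cube = ensemble_predict(omods, ow, targets, n_draws, seed=seed + 9)
    allcause = DrawCube.from_scalar(
        envelope.keys, 0.0, n_draws
    )
    allcause.values[:] = targets["allcause_rate"].to_numpy()[:, None]
    final = squeeze({**squeezed, "other": other_cube}, allcause)

    for cause in CAUSES:
        _write_cube(final[cause], outdir / f"death_rate_draws_{cause}.csv")
    return final


# ---------------------------------------------------------------------------
# stage 4: non-fatal (consistency fits)


def _background_mortality_by_group(truth: pd.DataFrame, groups: pd.DataFrame,
                                   age_max: int) -> np.ndarray:
    """Background (all-other-cause) mortality per 1-year age per group."""
    rate = truth.assign(m_rate=truth["deaths_other"] / truth["pop"])
    pooled = rate.groupby(["location", "year", "age_start"])["m_rate"].mean()
    years = np.arange(age_max)
    m = np.empty((age_max, len(groups)))
    for g, row in enumerate(groups.itertuples(index=False)):
        series = pooled.loc[(row.location, row.year)]
        band = np.clip((years // 5) * 5, series.index.min(), series.index.max())
        m[:, g] = series.reindex(band).to_numpy()
    return m


def _csmr_datapoints(outdir: pathlib.Path, disease: str, truth: pd.DataFrame,
                     n_for_se: int = 100) -> pd.DataFrame:
    cube = _read_cube(outdir / f"death_rate_draws_{disease}.csv",
                      key_cols=["location", "year", "sex", "age_start"])
    summ = summarise_cube(cube)
    summ["sd"] = cube.values.std(axis=1, ddof=1)
    pooled = summ.groupby(["location", "year", "age_start"], as_index=False).agg(
        mean=("mean", "mean"), sd=("sd", "mean")
    )
    pooled["sex"] = "both"
    pooled["age_end"] = pooled["age_start"] + 5.0
    pooled["measure"] = "csmr"
    pooled["standard_error"] = np.maximum(pooled["sd"], 1e-8)
    pooled["definition"] = REFERENCE_DEFINITION[disease]
    return pooled[["measure", "location", "year", "sex", "age_start", "age_end",
                   "mean", "standard_error", "definition"]]


def stage_nonfatal(outdir, n_draws: int | None = None):
    outdir = pathlib.Path(outdir)
    _require(outdir, "surveys_adjusted.csv", "world_truth.csv", "risk_scalars.csv")
    config = _load_config(outdir)
    if n_draws is None:
        n_draws = config.n_draws
    truth = pd.read_csv(outdir / "world_truth.csv")
    surveys = pd.read_csv(outdir / "surveys_adjusted.csv")
    scalars = pd.read_csv(outdir / "risk_scalars.csv")
    sdi = build_sdi_table(pd.read_csv(outdir / "sdi_components.csv"))
    age_bounds = _load_config(outdir).age_bounds()
    age_max = int(config.age_starts[-1]) + 5

    results = {}
    for disease in DISEASES:
        reference = REFERENCE_DEFINITION[disease]
        multiplier_tags = tuple(
            t for t, s in config.definitions[disease].items()
            if s["route"] == "multiplier"
        )
        sub = surveys[surveys["disease"] == disease]
        prev = sub[(sub["measure"] == "prevalence")
                   & (sub["definition"].isin((reference,) + multiplier_tags))]
        rem = sub[sub["measure"] == "remission"]
        dps = [prev, rem]

        csmr = _csmr_datapoints(outdir, disease, truth)
        ref_prev = prev[prev["definition"] == reference].groupby(
            ["location", "year", "age_start", "age_end"], as_index=False
        ).agg(mean=("mean", "mean"), standard_error=("standard_error", "mean"))
        ref_prev["sex"] = "both"
        emr = derive_emr_datapoints(csmr, ref_prev)
        dps.append(emr)

        cols = ["measure", "location", "year", "sex", "age_start", "age_end",
                "mean", "standard_error", "definition"]
        datapoints = pd.concat([d[cols] for d in dps], ignore_index=True)

        cov = scalars[scalars["disease"] == disease].rename(
            columns={"scalar_incidence": "risk_scalar"}
        ).merge(sdi[["location", "year", "income_rescaled"]],
                on=["location", "year"])
        cov = cov.rename(columns={"income_rescaled": "ldi"})

        groups = datapoints[["location", "year"]].drop_duplicates().reset_index(drop=True)
        m_bg = _background_mortality_by_group(truth, groups, age_max)

        dconfig = DismodConfig(
            age_max=age_max,
            remission=("fit" if config.baseline_rates[disease]["r"] > 0 else "zero"),
            study_covariates=multiplier_tags,
        )
        fit = fit_consistent(
            datapoints, cov[["location", "year", "risk_scalar", "ldi"]],
            m_bg, config=dconfig, n_draws=n_draws,
            seed=_stage_seed(config, 4),
        )
        fit.to_yaml(outdir / f"dismod_fit_{disease}.yaml")

        table = cov[["location", "year", "risk_scalar", "ldi"]].drop_duplicates(
        ).sort_values(["location", "year"]).reset_index(drop=True)
        gm = _background_mortality_by_group(truth, table[["location", "year"]],
                                            age_max)
        cubes = predict(fit, table, age_bounds, m_background=gm)
        _write_cube(cubes["prevalence"], outdir / f"prevalence_draws_{disease}.csv")
        _write_cube(cubes["incidence"], outdir / f"incidence_draws_{disease}.csv")
        results[disease] = fit
    return results


# ---------------------------------------------------------------------------
# stage 5: severity


def stage_severity(outdir):
    outdir = pathlib.Path(outdir)
    _require(outdir, "encounters.csv")
    config = _load_config(outdir)
    encounters = pd.read_csv(outdir / "encounters.csv")
    splits = {}
    for disease in DISEASES:
        dws = estimate_condition_dw(encounters, disease)
        cutpoints = SeverityCutpoints.from_weights(config.disability_weights[disease])
        splits[disease] = classify_states(dws, cutpoints)
    gold = GoldDistribution(**config.gold_raw)
    state_map = build_gold_state_map(gold.scaled(), splits["copd"])
    state_map.to_yaml(outdir / "gold_state_map.yaml")

    # split a unit of COPD prevalence: GOLD classes -> states via the map
    class_split = scale_and_apply(gold, 1.0)
    copd_states = apply_state_map(state_map, class_split)
    out = {
        "copd": {k: float(v) for k, v in copd_states.items()},
        "asthma": {k: float(v) for k, v in splits["asthma"].items()},
        "copd_encounter_split": {k: float(v) for k, v in splits["copd"].items()},
        "gold_classes": {k: float(v) for k, v in class_split.items()},
    }
    with open(outdir / "severity_splits.yaml", "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)
    return out


# ---------------------------------------------------------------------------
# stage 6: comparative risk assessment


def _exposure_lookup(exposures: pd.DataFrame):
    return exposures.set_index(["location", "year", "risk", "category"])["value"]


def stage_risk(outdir, n_draws: int | None = None):
    outdir = pathlib.Path(outdir)
    _require(outdir, "exposures.csv")
    config = _load_config(outdir)
    if n_draws is None:
        n_draws = config.n_draws
    rng = np.random.default_rng(_stage_seed(config, 6))
    exposures = pd.read_csv(outdir / "exposures.csv")
    lookup = _exposure_lookup(exposures)
    registry = default_risk_registry()
    cells = exposures[["location", "year"]].drop_duplicates().reset_index(drop=True)

    frames = []
    for disease, risks in registry.items():
        per_risk = {}
        for risk, spec in risks.items():
            rr_shift = rng.normal(0.0, spec.get("rr_log_sd", 0.0), size=n_draws)
            if spec["type"] == "categorical":
                cats = list(spec["categories"])
                frac = np.array([
                    [float(lookup.loc[(row.location, row.year, risk, cat)])
                     for cat in cats]
                    for row in cells.itertuples(index=False)
                ])
                base = np.array([spec["categories"][c] for c in cats])
                rr_draws = np.exp(np.log(base)[None, :] + rr_shift[:, None])
                rr_draws[:, cats.index(spec["reference"])] = 1.0
                values = paf_categorical_draws(frac, rr_draws)
            else:
                tmrel_draws = TMRELSpec(**spec["tmrel"]).sample(rng, n_draws)
                beta_draws = spec["rr_per_unit_log"] * np.exp(rr_shift)
                mus = np.array([
                    float(lookup.loc[(row.location, row.year, risk, "mean")])
                    for row in cells.itertuples(index=False)
                ])
                values = paf_loglinear_lognormal_draws(
                    mus, spec.get("exposure_sd_frac", 0.2),
                    beta_draws, tmrel_draws,
                )
            per_risk[risk] = np.clip(values, 0.0, 0.999)

        # mediation, then multiplicative combination per group and overall
        adjusted = {}
        for risk, vals in per_risk.items():
            mfs = list(registry[disease][risk].get("mediation", {}).values())
            adjusted[risk] = mediation_adjust(vals, mfs)
        groups = {"behavioural": [], "environmental": []}
        for risk, spec in risks.items():
            groups[spec["group"]].append(adjusted[risk])
        combos = {
            "all": combine_pafs(np.stack(list(adjusted.values()))),
            "behavioural": combine_pafs(np.stack(groups["behavioural"]))
            if groups["behavioural"] else np.zeros((len(cells), n_draws)),
            "environmental": combine_pafs(np.stack(groups["environmental"]))
            if groups["environmental"] else np.zeros((len(cells), n_draws)),
        }
        for risk, vals in adjusted.items():
            df = cells.copy()
            df["disease"], df["risk"] = disease, risk
            frames.append((df, vals))
        for name, vals in combos.items():
            df = cells.copy()
            df["disease"], df["risk"] = disease, f"_{name}"
            frames.append((df, vals))

    long = []
    for keys, vals in frames:
        cube = DrawCube(keys, vals)
        long.append(cube.to_long())
    pd.concat(long, ignore_index=True).to_csv(
        outdir / "paf_draws.csv", index=False, float_format=FLOAT_FMT
    )
    return frames


# ---------------------------------------------------------------------------
# stage 7: burden accounting


def _cell_paf(paf: pd.DataFrame, disease: str, which: str,
              keys: pd.DataFrame, n_draws: int) -> DrawCube:
    sub = paf[(paf["disease"] == disease) & (paf["risk"] == which)]
    cube = DrawCube.from_long(sub, key_cols=["location", "year"])
    idx = pd.MultiIndex.from_frame(cube.keys)
    pos = idx.get_indexer(pd.MultiIndex.from_frame(keys[["location", "year"]]))
    if (pos < 0).any():
        raise ValueError("PAF draws missing for some cells")
    return DrawCube(keys, cube.values[pos][:, :n_draws])


def stage_burden(outdir, n_draws: int | None = None):
    outdir = pathlib.Path(outdir)
    _require(outdir, "population.csv", "severity_splits.yaml", "paf_draws.csv")
    config = _load_config(outdir)
    pop = pd.read_csv(outdir / "population.csv")
    pop_series = pop.set_index(["location", "year", "sex", "age_start"])["pop"]
    lifetable = load_lifetable(data_path("standard_lifetable.csv"))
    std_pop = load_standard_population(data_path("standard_population.csv"))
    with open(outdir / "severity_splits.yaml") as fh:
        splits = yaml.safe_load(fh)
    paf = pd.read_csv(outdir / "paf_draws.csv")
    sdi = build_sdi_table(pd.read_csv(outdir / "sdi_components.csv"))
    quintiles = assign_quintiles(sdi)

    summary_rows = []
    attribution_rows = []
    results = {}
    for disease in DISEASES:
        deaths_rate = _read_cube(outdir / f"death_rate_draws_{disease}.csv",
                                 key_cols=["location", "year", "sex", "age_start"])
        n_draws_eff = deaths_rate.n_draws if n_draws is None else n_draws
        prev = _read_cube(outdir / f"prevalence_draws_{disease}.csv",
                          key_cols=["location", "year", "age_start"])
        # broadcast sex onto prevalence (fits pool sexes)
        sex_frames = []
        for sex in config.sexes:
            k = prev.keys[["location", "year", "age_start"]].copy()
            k.insert(2, "sex", sex)
            sex_frames.append(DrawCube(k, prev.values))
        prev_sex = DrawCube(
            pd.concat([c.keys for c in sex_frames], ignore_index=True),
            np.vstack([c.values for c in sex_frames]),
        )

        deaths = deaths_rate.mul_series(
            pop_series, level=["location", "year", "sex", "age_start"]
        )
        yll = compute_yll(deaths, lifetable)
        state_prev = {
            state: prev_sex * share
            for state, share in splits[disease].items()
        }
        yld = compute_yld(state_prev, config.disability_weights[disease],
                          pop_series)
        yld = yll.align_to(yld)
        daly = compute_daly(yll, yld)
        prev_count = prev_sex.mul_series(
            pop_series, level=["location", "year", "sex", "age_start"]
        )

        # attribution: PAF draws broadcast to cells, applied to DALYs
        paf_all = _cell_paf(paf, disease, "_all", daly.keys, daly.n_draws)
        paf_beh = _cell_paf(paf, disease, "_behavioural", daly.keys, daly.n_draws)
        paf_env = _cell_paf(paf, disease, "_environmental", daly.keys, daly.n_draws)

        results[disease] = {
            "deaths": deaths, "yll": yll, "yld": yld, "daly": daly,
            "prevalence_count": prev_count,
            "paf_all": paf_all,
        }

        strata: dict[str, list | None] = {"global": None}
        for loc, label in quintiles.labels.items():
            strata.setdefault(label, []).append(loc)
        year_last = int(max(config.years))
        year_first = int(min(config.years))
        for stratum, locs in strata.items():
            def _tot(cube: DrawCube, year: int) -> np.ndarray:
                sel = cube.select(year=year) if locs is None else \
                    cube.select(year=year, location=locs)
                return sel.total()
            row = {"cause": disease, "stratum": stratum}
            for qty, cube in (("deaths", deaths), ("prevalence", prev_count),
                              ("yll", yll), ("yld", yld), ("daly", daly)):
                mean, lo, hi = summarise(_tot(cube, year_last) / 1e3)
                row[f"{qty}_thousands"] = mean
                row[f"{qty}_lower"] = lo
                row[f"{qty}_upper"] = hi
            ch_mean, ch_lo, ch_hi, sig = percent_change(
                _tot(daly, year_first), _tot(daly, year_last)
            )
            row["daly_pct_change"] = ch_mean
            row["daly_pct_change_lower"] = ch_lo
            row["daly_pct_change_upper"] = ch_hi
            row["daly_change_significant"] = sig
            summary_rows.append(row)

            if stratum != "global":
                # DALY-weighted group PAFs, then exclusive decomposition
                daly_s = daly.select(year=year_last, location=locs)
                w = daly_s.values
                def _wp(cube):
                    v = cube.select(year=year_last, location=locs).values
                    return float((v * w).sum() / w.sum())
                pb, pe, pa = _wp(paf_beh), _wp(paf_env), _wp(paf_all)
                pa = min(max(pa, max(pb, pe)), pb + pe)
                env_only, joint, beh_only, unattributed = decompose_groups(pb, pe, pa)
                attribution_rows.append({
                    "cause": disease, "stratum": stratum,
                    "env_only_pct": 100 * env_only, "joint_pct": 100 * joint,
                    "beh_only_pct": 100 * beh_only,
                    "unattributed_pct": 100 * unattributed,
                })

        # age-standardised DALY rates per location-year (per 100 000)
        pop_lookup = pop_series.reindex(
            pd.MultiIndex.from_frame(
                daly.keys[["location", "year", "sex", "age_start"]])
        ).to_numpy()
        rate = DrawCube(daly.keys, daly.values / pop_lookup[:, None] * PER)
        both_sex = rate.sum_over("sex") * 0.5  # mean rate across sexes
        asdr = age_standardise(both_sex, std_pop)
        asdr_summary = summarise_cube(asdr, prefix="asdr_")
        asdr_summary["cause"] = disease
        results[disease]["asdr"] = asdr_summary

    table = pd.DataFrame(summary_rows)
    table.to_csv(outdir / "burden_summary.csv", index=False, float_format=FLOAT_FMT)
    pd.DataFrame(attribution_rows).to_csv(
        outdir / "attribution_by_quintile.csv", index=False, float_format=FLOAT_FMT
    )
    asdr_all = pd.concat([results[d]["asdr"] for d in DISEASES], ignore_index=True)
    asdr_all.to_csv(outdir / "asdr.csv", index=False, float_format=FLOAT_FMT)
    return results


# ---------------------------------------------------------------------------
# stage 8: SDI reporting


def stage_sdi(outdir):
    outdir = pathlib.Path(outdir)
    _require(outdir, "sdi_components.csv", "asdr.csv")
    sdi = build_sdi_table(pd.read_csv(outdir / "sdi_components.csv"))
    quintiles = assign_quintiles(sdi)
    sdi["quintile"] = sdi["location"].map(quintiles.labels)
    sdi.to_csv(outdir / "sdi.csv", index=False, float_format=FLOAT_FMT)

    asdr = pd.read_csv(outdir / "asdr.csv")
    merged = asdr.merge(sdi[["location", "year", "sdi"]], on=["location", "year"])
    rows = []
    for disease, sub in merged.groupby("cause"):
        curve = fit_expected_curve(sub, outcome_col="asdr_mean")
        dev = observed_vs_expected(sub, curve, outcome_col="asdr_mean")
        dev["cause"] = disease
        rows.append(dev)
    out = pd.concat(rows, ignore_index=True)
    out.to_csv(outdir / "observed_vs_expected.csv", index=False,
               float_format=FLOAT_FMT)
    return out


# ---------------------------------------------------------------------------
# orchestration


STAGES = ("simulate", "crosswalk", "cod", "nonfatal", "severity", "risk",
          "burden", "sdi")


def run_pipeline(config: WorldConfig, outdir, n_draws: int | None = None,
                 noise: bool = True) -> dict:
    """Run every stage in order and write a provenance manifest."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if n_draws is None:
        n_draws = config.n_draws
    results = {}
    stage_fns = {
        "simulate": lambda: stage_simulate(config, outdir, noise=noise),
        "crosswalk": lambda: stage_crosswalk(outdir),
        "cod": lambda: stage_cod(outdir, n_draws=n_draws),
        "nonfatal": lambda: stage_nonfatal(outdir, n_draws=n_draws),
        "severity": lambda: stage_severity(outdir),
        "risk": lambda: stage_risk(outdir, n_draws=n_draws),
        "burden": lambda: stage_burden(outdir, n_draws=n_draws),
        "sdi": lambda: stage_sdi(outdir),
    }
    for stage in STAGES:
        log.info("pipeline stage: %s", stage)
        try:
            results[stage] = stage_fns[stage]()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "n_draws": n_draws,
        "version": __version__,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "stages": list(STAGES),
    }
    with open(outdir / "provenance.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    results["manifest"] = manifest
    return results
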