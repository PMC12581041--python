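"""End-to-end orchestration of the undiagnosed-fraction analysis.

One condition's run is: case definitions -> weighted logistic fit with
stepwise-AIC interaction selection (undiagnosed model) -> prevalence model
(signs-or-diagnosis on the full survey) -> segment predictions ->
population-weighted national estimate. ``run_all`` chains every stage over
the configured conditions on synthetic fixtures, adds the microsimulation,
the Moran permutation test on the 2011->2019 change, and the sensitivity
layers, and writes a manifest recording inputs, seeds and output hashes.

All randomness flows from one root seed through named substreams
(``derive_seed``), so a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .calibration import calibrated_config
from .case_definitions import DEFAULT_RULES, ConditionRule, build_condition_dataset, disease_indicator
from .design import ModelSpec
from .levels import CONDITIONS
from .microsim import aggregate_areas, change_map
from .modelling import FittedModel, fit_weighted_logistic, hosmer_lemeshow, stepwise_aic
from .predict import SegmentPredictions, national_estimate, predict_segments
from .sensitivity import ppv_adjusted_fraction, qof_compare
from .spatial import SpatialWeights, permutation_test
from .synthetic_data import attach_area_truth, generate_adjacency, generate_population, generate_qof_table, generate_survey

logger = logging.getLogger(__name__)


def derive_seed(root_seed: int, name: str) -> int:
    """Stable, named 31-bit substream seed from one root seed."""
    digest = hashlib.sha256(f"{root_seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineOptions:
    """Model/microsim options shared across conditions."""

    stepwise: bool = True
    prevalence_stepwise: bool = False  # prevalence model: main effects + year by default
    year_droppable: bool = False
    n_sim: int = 10_000
    n_replicates: int = 200
    alpha: float = 0.05
    years_of_interest: tuple[int, int] = (2011, 2019)
    n_perm: int = 9_999


@dataclass
class ConditionResult:
    condition: str
    dataset_n: int
    model_undiag: FittedModel
    selection_path: list
    model_disease: FittedModel
    hl: tuple[float, int, float]
    predictions: SegmentPredictions
    national: dict


def fit_condition_models(
    survey: pd.DataFrame,
    rule: ConditionRule,
    options: PipelineOptions,
):
    """Case definition plus the undiagnosed and prevalence model fits."""
    dataset = build_condition_dataset(survey, rule)
    full = ModelSpec(interactions=ModelSpec().candidates)
    if options.stepwise:
        model_undiag, path = stepwise_aic(
            dataset.data, "undiagnosed", full, year_droppable=options.year_droppable
        )
    else:
        model_undiag = fit_weighted_logistic(dataset.data, "undiagnosed", ModelSpec())
        path = []

    prevalence = disease_indicator(survey, rule)
    if options.prevalence_stepwise:
        model_disease, _ = stepwise_aic(prevalence, "disease", full)
    else:
        model_disease = fit_weighted_logistic(prevalence, "disease", ModelSpec())
    return dataset, model_undiag, path, model_disease


def run_condition(
    survey: pd.DataFrame,
    rule: ConditionRule,
    population: pd.DataFrame,
    options: PipelineOptions | None = None,
    seed: int = 0,
    years=None,
) -> ConditionResult:
    """Case definitions through national estimates for one condition."""
    options = options or PipelineOptions()
    years = list(options.years_of_interest) if years is None else [int(y) for y in years]
    dataset, model_undiag, path, model_disease = fit_condition_models(survey, rule, options)
    n_rows = len(dataset.data)

    p_hat = model_undiag.predict(dataset.data)
    hl = hosmer_lemeshow(p_hat, dataset.data["undiagnosed"].to_numpy(), dataset.data["weight"].to_numpy())

    preds = predict_segments(
        model_undiag,
        model_disease,
        years=years,
        condition=rule.condition,
        n_sim=options.n_sim,
        alpha=options.alpha,
        seed=derive_seed(seed, f"predict:{rule.condition}"),
    )
    national = {}
    if model_undiag.spec.include_year:
        for year in years:
            national[year] = national_estimate(preds, population, [year])
    else:
        national["pooled"] = national_estimate(preds, population, years)
    return ConditionResult(
        condition=rule.condition,
        dataset_n=n_rows,
        model_undiag=model_undiag,
        selection_path=path,
        model_disease=model_disease,
        hl=hl,
        predictions=preds,
        national=national,
    )


def recovery_run(
    condition: str,
    seed: int,
    n_survey: int | None = None,
    options: PipelineOptions | None = None,
):
    """Calibrated-generator recovery run for one condition.

    Generates the synthetic survey and population at the study's sample
    sizes, runs case definitions, model selection and segment prediction, and
    returns ``(result, truth, population)``. For hypertension — whose
    calibrated truth carries no time trend — the year trend joins the
    droppable set and the national summary pools 2011-2019; the other
    conditions report the 2011 and 2019 national estimates.
    """
    from .levels import YEARS

    cfg = calibrated_config(condition, seed=seed, n_survey=n_survey)
    survey, truth = generate_survey(cfg, condition)
    population = generate_population(cfg)
    rule = DEFAULT_RULES[condition]
    if options is None:
        options = PipelineOptions(year_droppable=(condition == "hypertension"))
    years = YEARS if condition == "hypertension" else options.years_of_interest
    result = run_condition(survey, rule, population, options, seed=seed, years=years)
    if condition == "hypertension" and "pooled" not in result.national:
        result.national["pooled"] = national_estimate(result.predictions, population, years)
    return result, truth, population


# ---------------------------------------------------------------------------
# full-run orchestration


@dataclass
class PipelineConfig:
    """Configuration for a full synthetic end-to-end run."""

    out_dir: str = "results/pipeline"
    seed: int = 0
    conditions: tuple[str, ...] = CONDITIONS
    n_survey: dict = field(default_factory=dict)  # per-condition override
    mcs_threshold: float | None = None  # alternative depression threshold
    qof_noise_sd: float = 0.01
    include_qof: bool = True
    ppv: float = 0.48
    options: PipelineOptions = field(default_factory=PipelineOptions)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        opts = PipelineOptions(**raw.pop("options", {}))
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known, options=opts) if "options" not in known else cls(**known)
        cfg.conditions = tuple(cfg.conditions)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Execute the full analysis on calibrated synthetic fixtures.

    Stages: simulate -> case definitions -> fits -> predictions -> national
    estimates -> microsimulation (anchor years) -> Moran test on the change
    -> QOF comparison and PPV adjustment. Any stage failure raises with the
    stage name. Returns the manifest (also written to ``out_dir``).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}, "skipped": []}
    stage = "setup"
    try:
        year_a, year_b = config.options.years_of_interest
        results: dict[str, ConditionResult] = {}
        for condition in config.conditions:
            stage = f"simulate:{condition}"
            t0 = time.perf_counter()
            gen = calibrated_config(
                condition,
                seed=derive_seed(config.seed, f"generate:{condition}"),
                n_survey=config.n_survey.get(condition),
            )
            survey, truth = generate_survey(gen, condition)
            population = generate_population(gen)
            truth = attach_area_truth(truth, gen, population, (year_a, year_b))
            survey_path = out_dir / f"survey_{condition}.csv"
            survey.to_csv(survey_path, index=False)
            truth.to_json(out_dir / f"truth_{condition}.json")
            logger.info("%s: %.1fs", stage, time.perf_counter() - t0)

            stage = f"fit:{condition}"
            t0 = time.perf_counter()
            rule = DEFAULT_RULES[condition]
            opts = config.options
            if condition == "hypertension":
                opts = PipelineOptions(**{**opts.__dict__, "year_droppable": True})
            res = run_condition(survey, rule, population, opts, seed=config.seed)
            results[condition] = res
            res.predictions.frame.to_csv(out_dir / f"segment_predictions_{condition}.csv", index=False)
            res.model_undiag.params.rename("coefficient").to_csv(out_dir / f"coefficients_{condition}.csv")
            (out_dir / f"diagnostics_{condition}.json").write_text(
                json.dumps(
                    {
                        "hosmer_lemeshow": {"statistic": res.hl[0], "df": res.hl[1], "p": res.hl[2]},
                        "selection_path": [
                            {"action": s.action, "term": s.term, "aic": s.aic} for s in res.selection_path
                        ],
                        "national": {str(k): v for k, v in res.national.items()},
                        "truth_national": {str(k): v for k, v in truth.national_fraction.items()},
                    },
                    indent=1,
                )
            )
            logger.info("%s: %.1fs", stage, time.perf_counter() - t0)

            stage = f"microsim:{condition}"
            areas = {}
            for year in (year_a, year_b):
                areas[year] = aggregate_areas(
                    population,
                    res.predictions,
                    year,
                    n_replicates=config.options.n_replicates,
                    seed=derive_seed(config.seed, f"microsim:{condition}:{year}"),
                )
                areas[year].to_csv(out_dir / f"areas_{condition}_{year}.csv", index=False)

            stage = f"moran:{condition}"
            change = change_map(areas[year_a], areas[year_b])
            adjacency = generate_adjacency(gen)
            weights = SpatialWeights.from_adjacency(adjacency)
            ordered = change.set_index("ccg_id").loc[weights.area_ids, "change"]
            moran = permutation_test(
                ordered.to_numpy(),
                weights,
                n_perm=config.options.n_perm,
                seed=derive_seed(config.seed, f"moran:{condition}"),
            )
            (out_dir / f"moran_{condition}.json").write_text(json.dumps(moran, indent=1))

            stage = f"sensitivity:{condition}"
            sens: dict = {}
            if config.include_qof:
                qof = generate_qof_table(
                    truth, config.qof_noise_sd, seed=derive_seed(config.seed, f"qof:{condition}")
                )
                seg_prev = res.predictions.for_year(year_b)
                pop_cells = population.merge(
                    seg_prev[[*("age_group", "sex", "imd_quintile", "region"), "p_disease"]],
                    on=["age_group", "sex", "imd_quintile", "region"],
                )
                pop_cells["e_dis"] = pop_cells["count"] * pop_cells["p_disease"]
                total = (
                    pop_cells.groupby("ccg_id")
                    .apply(lambda g: g["e_dis"].sum() / g["count"].sum(), include_groups=False)
                    .rename("total_prevalence")
                    .reset_index()
                )
                comparison = qof_compare(total, qof)
                comparison.to_csv(out_dir / f"qof_compare_{condition}.csv", index=False)
                sens["qof_mean_undiag"] = float(comparison["undiagnosed_fraction"].mean())
            else:
                manifest["skipped"].append(f"qof:{condition}")
                logger.info("qof comparison skipped for %s (no qof input)", condition)
            if condition == "depression":
                key = year_b if year_b in res.national else "pooled"
                sens["ppv_adjusted"] = ppv_adjusted_fraction(
                    res.national[key]["estimate"], config.ppv
                )
            (out_dir / f"sensitivity_{condition}.json").write_text(json.dumps(sens, indent=1))

            manifest["stages"][condition] = {
                "n_disease_rows": res.dataset_n,
                "selected_interactions": [list(t) for t in res.model_undiag.spec.interactions],
                "national": {
                    str(k): {kk: vv for kk, vv in v.items() if kk != "years"}
                    for k, v in res.national.items()
                },
                "moran_p": moran["p_value"],
            }

        if config.mcs_threshold is not None and "depression" in results:
            stage = "sensitivity:mcs-threshold"
            gen = calibrated_config(
                "depression",
                seed=derive_seed(config.seed, "generate:depression"),
                n_survey=config.n_survey.get("depression"),
            )
            survey, _ = generate_survey(gen, "depression")
            population = generate_population(gen)
            alt_rule = DEFAULT_RULES["depression"].with_threshold(config.mcs_threshold)
            alt = run_condition(survey, alt_rule, population, config.options, seed=config.seed)
            alt.predictions.frame.to_csv(out_dir / "segment_predictions_depression_alt.csv", index=False)
            manifest["stages"]["depression_alt_threshold"] = {
                "threshold": config.mcs_threshold,
                "national": {
                    str(k): {kk: vv for kk, vv in v.items() if kk != "years"}
                    for k, v in alt.national.items()
                },
            }
    except Exception as err:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    for path in sorted(out_dir.glob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][path.name] = _sha256(path)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
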