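"""Sensitivity analyses: QOF-style comparison, PPV adjustment, lower MCS cut.

Three probes of the main results:
1. per-CCG undiagnosed fraction implied by comparing survey-modelled total
   prevalence with the QOF-like diagnosed prevalence registers;
2. the depression estimate discounted for the SF-12 MCS screening
   instrument's positive predictive value (0.48);
3. a full depression re-run with a stricter (lower) MCS threshold of 38.

Requires analysis/02_fit_models.py to have run.
"""

import json
from pathlib import Path

import pandas as pd

from underdx import (
    CONDITIONS,
    DEFAULT_RULES,
    PipelineOptions,
    qof_compare,
    run_condition,
    ppv_adjusted_fraction,
    threshold_sensitivity_run,
)

DATA = Path("scratch/data")
MODELS = Path("results/models")
OUT = Path("results/sensitivity")

PPV_MCS = 0.48
ALT_MCS_THRESHOLD = 38.0


def survey_total_prevalence(condition: str, population: pd.DataFrame, year: int) -> pd.DataFrame:
    """Model-based total prevalence per CCG from the segment predictions."""
    preds = pd.read_csv(MODELS / f"segment_predictions_{condition}.csv")
    preds = preds[preds["year"] == year]
    keys = ["age_group", "sex", "imd_quintile", "region"]
    cells = population.merge(preds[keys + ["p_disease"]], on=keys)
    cells["expected"] = cells["count"] * cells["p_disease"]
    by_area = cells.groupby("ccg_id")[["count", "expected"]].sum()
    return (by_area["expected"] / by_area["count"]).rename("total_prevalence").reset_index()


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    population = pd.read_csv(DATA / "population.csv")

    print("QOF-style comparison (2019):")
    for condition in CONDITIONS:
        total = survey_total_prevalence(condition, population, 2019)
        qof = pd.read_csv(DATA / f"qof_{condition}.csv")
        out = qof_compare(total, qof)
        out.to_csv(OUT / f"qof_compare_{condition}.csv", index=False)
        print(
            f"  {condition}: mean CCG undiagnosed fraction "
            f"{out['undiagnosed_fraction'].mean():.1%} "
            f"(IQR {out['undiagnosed_fraction'].quantile(0.25):.1%}-"
            f"{out['undiagnosed_fraction'].quantile(0.75):.1%})"
        )

    national = pd.read_csv(Path("results") / "national_estimates.csv")
    mask = (national["condition"] == "depression") & (national["year"].astype(str) == "2019")
    dep_2019 = float(national.loc[mask, "estimate"].iloc[0])
    adjusted = ppv_adjusted_fraction(dep_2019, PPV_MCS)
    print(
        f"\nPPV adjustment: depression 2019 raw {dep_2019:.1%} -> "
        f"{adjusted:.1%} at PPV {PPV_MCS:.0%}"
    )

    print(f"\nAlternative MCS threshold ({ALT_MCS_THRESHOLD:g} instead of 42):")
    survey = pd.read_csv(DATA / "survey_depression.csv")
    alt = threshold_sensitivity_run(
        run_condition,
        DEFAULT_RULES["depression"],
        ALT_MCS_THRESHOLD,
        survey=survey,
        population=population,
        options=PipelineOptions(),
        seed=1,
    )
    alt.predictions.frame.to_csv(OUT / "segment_predictions_depression_alt.csv", index=False)
    summary = {"threshold": ALT_MCS_THRESHOLD, "n_disease_rows": alt.dataset_n, "national": {}}
    for year in (2011, 2019):
        est = alt.national[year]
        summary["national"][year] = est
        print(f"  national {year}: {est['estimate']:.1%} [{est['lo']:.1%}, {est['hi']:.1%}]")
    (OUT / "depression_alt_threshold.json").write_text(json.dumps(summary, indent=1))
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
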