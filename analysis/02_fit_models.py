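"""Fit the undiagnosed-fraction and prevalence models and summarise them.

For each condition: apply the case definition, fit the survey-weighted
logistic model for P(undiagnosed | disease) with stepwise-AIC interaction
selection (year trend droppable for hypertension), fit the prevalence model
P(disease), run the Hosmer-Lemeshow diagnostic, tabulate mean adjusted
predictions by age group, sex and deprivation quintile for 2011 and 2019,
predict all 540 segments, and compute the national population-weighted
estimates.

Requires analysis/01_simulate.py to have run.
"""

import json
from pathlib import Path

import pandas as pd

from underdx import (
    CONDITIONS,
    DEFAULT_RULES,
    PipelineOptions,
    mean_adjusted_prediction,
    national_estimate,
    run_condition,
)
from underdx.levels import AGE_GROUPS, IMD_QUINTILES, SEXES, YEARS

DATA = Path("scratch/data")
OUT = Path("results/models")


def adjusted_prediction_table(result, dataset):
    """Mean adjusted predictions by focal level, the figure-style summary."""
    rows = []
    focals = (
        [("age_group", a) for a in AGE_GROUPS]
        + [("sex", s) for s in SEXES]
        + [("imd_quintile", q) for q in IMD_QUINTILES]
    )
    for year in (2011, 2019):
        for var, level in focals:
            point, lo, hi = mean_adjusted_prediction(
                result.model_undiag, dataset, {var: level, "year": year}, n_sim=2000, seed=1
            )
            rows.append((year, var, level, point, lo, hi))
    return pd.DataFrame(rows, columns=["year", "variable", "level", "p_undiag", "lo", "hi"])


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    population = pd.read_csv(DATA / "population.csv")
    national_rows = []

    for condition in CONDITIONS:
        survey = pd.read_csv(DATA / f"survey_{condition}.csv")
        truth = json.loads((DATA / f"truth_{condition}.json").read_text())
        options = PipelineOptions(year_droppable=(condition == "hypertension"))
        years = YEARS if condition == "hypertension" else (2011, 2019)
        res = run_condition(
            survey, DEFAULT_RULES[condition], population, options, seed=1, years=years
        )

        res.model_undiag.params.rename("coefficient").to_csv(OUT / f"coefficients_{condition}.csv")
        anchor = res.predictions.frame[res.predictions.frame["year"].isin((2011, 2019))]
        anchor.to_csv(OUT / f"segment_predictions_{condition}.csv", index=False)

        from underdx import build_condition_dataset

        dataset = build_condition_dataset(survey, DEFAULT_RULES[condition]).data
        adjusted_prediction_table(res, dataset).to_csv(
            OUT / f"adjusted_predictions_{condition}.csv", index=False
        )

        stat, df, p = res.hl
        selected = [f"{a}:{b}" for a, b in res.model_undiag.spec.interactions]
        print(f"\n{condition}: {res.dataset_n:,} disease rows")
        print(f"  selected interactions: {selected or 'none'}"
              + ("" if res.model_undiag.spec.include_year else " (year trend dropped)"))
        print(f"  Hosmer-Lemeshow: chi2={stat:.2f}, df={df}, p={p:.3f}")

        if "pooled" in res.national:
            natl = {"pooled": res.national["pooled"]}
        else:
            natl = {y: res.national[y] for y in (2011, 2019)}
        for key, est in natl.items():
            true = (
                truth["pooled_fraction"]
                if key == "pooled"
                else truth["national_fraction"][str(key)]
            )
            print(
                f"  national {key}: {est['estimate']:.1%} "
                f"[{est['lo']:.1%}, {est['hi']:.1%}] (truth {true:.0%})"
            )
            national_rows.append(
                (condition, key, est["estimate"], est["lo"], est["hi"], true)
            )

    pd.DataFrame(
        national_rows, columns=["condition", "year", "estimate", "lo", "hi", "truth"]
    ).to_csv(Path("results") / "national_estimates.csv", index=False)
    print("\nwrote results/models/ and results/national_estimates.csv")


if __name__ == "__main__":
    main()
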