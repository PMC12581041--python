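"""Generate the calibrated synthetic study inputs.

Writes, per condition, an HSE-like survey (UKHLS-like panel for depression),
plus one shared small-area population table (LSOA -> CCG -> region), a
QOF-like diagnosed-prevalence table and the CCG adjacency list, all with
their ground-truth records. The generator truths are calibrated to the
published national undiagnosed fractions: diabetes 26% (2011) -> 22% (2019),
hypertension 23% (flat), depression 68% (2011) -> 64% (2019).

Run from the repository root:  python analysis/01_simulate.py [--seed 1]
"""

import argparse
from pathlib import Path

from underdx import (
    CONDITIONS,
    attach_area_truth,
    calibrated_config,
    derive_seed,
    generate_adjacency,
    generate_population,
    generate_qof_table,
    generate_survey,
)

OUT = Path("scratch/data")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    OUT.mkdir(parents=True, exist_ok=True)

    for condition in CONDITIONS:
        cfg = calibrated_config(condition, seed=derive_seed(args.seed, f"sim:{condition}"))
        survey, truth = generate_survey(cfg, condition)
        population = generate_population(cfg)
        truth = attach_area_truth(truth, cfg, population, (2011, 2019))
        qof = generate_qof_table(truth, noise_sd=0.01, seed=derive_seed(args.seed, f"qof:{condition}"))

        survey.to_csv(OUT / f"survey_{condition}.csv", index=False)
        truth.to_json(OUT / f"truth_{condition}.json")
        qof.to_csv(OUT / f"qof_{condition}.csv", index=False)
        if condition == CONDITIONS[0]:
            population.to_csv(OUT / "population.csv", index=False)
            generate_adjacency(cfg).to_csv(OUT / "adjacency.csv", index=False)

        kind = "person-waves" if condition == "depression" else "respondents"
        print(
            f"{condition}: {len(survey):,} {kind}, truth "
            + ", ".join(f"{y}={truth.national_fraction[y]:.0%}" for y in (2011, 2019))
        )
    print(f"wrote fixtures to {OUT}/ (regenerate any time; not tracked)")


if __name__ == "__main__":
    main()
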