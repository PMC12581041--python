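"""Project the fitted probabilities onto the small-area population.

Binomial microsimulation of disease and undiagnosed counts per LSOA cell,
aggregated to the 191 CCG-like planning areas for 2011 and 2019 with
Monte-Carlo intervals over 200 replicate draws, plus the 2011 -> 2019
change in the proportion undiagnosed per area.

Requires analysis/02_fit_models.py to have run.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from underdx import CONDITIONS, aggregate_areas, change_map, derive_seed
from underdx.predict import SegmentPredictions

DATA = Path("scratch/data")
MODELS = Path("results/models")
OUT = Path("results/areas")


def load_predictions(condition: str) -> SegmentPredictions:
    frame = pd.read_csv(MODELS / f"segment_predictions_{condition}.csv")
    empty = np.zeros((1, len(frame)), dtype=np.float32)
    return SegmentPredictions(condition, frame, empty, empty, alpha=0.05)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    population = pd.read_csv(DATA / "population.csv")

    for condition in CONDITIONS:
        preds = load_predictions(condition)
        estimates = {}
        for year in (2011, 2019):
            estimates[year] = aggregate_areas(
                population, preds, year,
                n_replicates=200, seed=derive_seed(1, f"microsim:{condition}:{year}"),
            )
            estimates[year].to_csv(OUT / f"areas_{condition}_{year}.csv", index=False)
        change = change_map(estimates[2011], estimates[2019])
        change.to_csv(OUT / f"change_{condition}.csv", index=False)
        print(
            f"{condition}: mean CCG proportion undiagnosed "
            f"2011={estimates[2011]['prop_undiag'].mean():.1%}, "
            f"2019={estimates[2019]['prop_undiag'].mean():.1%}, "
            f"mean change={change['change'].mean():+.1%} "
            f"(range {change['change'].min():+.1%} to {change['change'].max():+.1%})"
        )
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
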