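"""Test whether the 2011 -> 2019 change in underdiagnosis is spatially clustered.

Global Moran's I with row-standardised adjacency weights and a 9 999-draw
permutation test, per condition, on the per-CCG change in the proportion
undiagnosed from the microsimulation.

Requires analysis/03_microsim.py to have run.
"""

import json
from pathlib import Path

import pandas as pd

from underdx import CONDITIONS, SpatialWeights, derive_seed, permutation_test

AREAS = Path("results/areas")
DATA = Path("scratch/data")


def main() -> None:
    adjacency = pd.read_csv(DATA / "adjacency.csv")
    weights = SpatialWeights.from_adjacency(adjacency)
    results = {}
    for condition in CONDITIONS:
        change = pd.read_csv(AREAS / f"change_{condition}.csv").set_index("ccg_id")
        values = change.loc[weights.area_ids, "change"].to_numpy()
        out = permutation_test(
            values, weights, n_perm=9_999, seed=derive_seed(1, f"moran:{condition}")
        )
        results[condition] = out
        print(
            f"{condition}: I={out['I']:+.3f} (E[I]={out['expected_I']:+.4f}), "
            f"p={out['p_value']:.4f}"
        )
    Path("results/moran.json").write_text(json.dumps(results, indent=1))
    print("wrote results/moran.json")


if __name__ == "__main__":
    main()
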