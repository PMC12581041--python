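"""Fixed factor level tables shared by every stage of the analysis.

All categorical encodings in the package are anchored to these tables rather
than inferred per-dataset, so that design matrices, segment predictions and
microsimulation merges always agree on levels and reference categories.

The population is segmented by six age bands, two sexes, five deprivation
(IMD) quintiles and nine English regions: 6 x 2 x 5 x 9 = 540 segments.
Calendar years span 2011-2019 and enter models as a linear trend centred at
2011 (so the intercept refers to 2011).
"""

from __future__ import annotations

import itertools

import pandas as pd

AGE_GROUPS: tuple[str, ...] = ("18-29", "30-49", "50-59", "60-69", "70-79", "80+")
SEXES: tuple[str, ...] = ("female", "male")
IMD_QUINTILES: tuple[int, ...] = (1, 2, 3, 4, 5)  # 1 = least deprived
REGIONS: tuple[str, ...] = (
    "East Midlands",
    "East of England",
    "London",
    "North East",
    "North West",
    "South East",
    "South West",
    "West Midlands",
    "Yorkshire and the Humber",
)
YEARS: tuple[int, ...] = tuple(range(2011, 2020))
YEAR_REF: int = 2011

#: factor name -> ordered level tuple; first level is the reference category.
FACTORS: dict[str, tuple] = {
    "age_group": AGE_GROUPS,
    "sex": SEXES,
    "imd_quintile": IMD_QUINTILES,
    "region": REGIONS,
}

SEGMENT_VARS: tuple[str, ...] = ("age_group", "sex", "imd_quintile", "region")
N_SEGMENTS: int = 6 * 2 * 5 * 9

CONDITIONS: tuple[str, ...] = ("diabetes", "hypertension", "depression")


def segment_frame() -> pd.DataFrame:
    """All 540 segments in deterministic order (age, sex, IMD, region)."""
    rows = itertools.product(AGE_GROUPS, SEXES, IMD_QUINTILES, REGIONS)
    return pd.DataFrame(rows, columns=list(SEGMENT_VARS))


def validate_levels(df: pd.DataFrame) -> None:
    """Raise ``ValueError`` if any segment column holds an unknown level."""
    for var, levels in FACTORS.items():
        if var not in df.columns:
            raise ValueError(f"missing segment column {var!r}")
        bad = set(df[var].unique()) - set(levels)
        if bad:
            raise ValueError(f"unknown {var} level(s): {sorted(map(str, bad))}")
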