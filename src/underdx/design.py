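"""Design-matrix construction with fixed reference levels.

Columns are named so that a coefficient map (``{"intercept": -1.2,
"age_group[30-49]": 0.4, "sex[male]:year": -0.02, ...}``) and a fitted
coefficient vector share one vocabulary: ``var[level]`` is a dummy for a
non-reference factor level, ``year`` is the calendar year centred at 2011,
and ``a:b`` is the elementwise product of the two parent columns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .levels import FACTORS, YEAR_REF, validate_levels

#: interaction candidates in canonical order: all two-way interactions among
#: age group, sex, deprivation quintile, region and the linear year trend.
INTERACTION_VARS: tuple[str, ...] = ("age_group", "sex", "imd_quintile", "region", "year")
CANDIDATE_INTERACTIONS: tuple[tuple[str, str], ...] = tuple(
    itertools.combinations(INTERACTION_VARS, 2)
)


@dataclass(frozen=True)
class ModelSpec:
    """Model structure: fixed main effects, optional year trend, interactions.

    Main effects for the four segment factors are always retained; stepwise
    selection operates on ``interactions`` (a subset of ``candidates``).
    ``include_year`` drops the linear year trend entirely (used when the
    selection loop is allowed to remove it and does so).
    """

    interactions: tuple[tuple[str, str], ...] = ()
    include_year: bool = True
    candidates: tuple[tuple[str, str], ...] = CANDIDATE_INTERACTIONS

    def __post_init__(self) -> None:
        for pair in self.interactions:
            if pair not in self.candidates:
                raise ValueError(f"interaction {pair} not in candidate set")
        if not self.include_year:
            for pair in self.interactions:
                if "year" in pair:
                    raise ValueError("year interaction selected but year trend excluded")

    def with_interactions(self, interactions) -> "ModelSpec":
        return ModelSpec(tuple(interactions), self.include_year, self.candidates)


def _factor_columns(var: str) -> list[str]:
    if var == "year":
        return ["year"]
    levels = FACTORS[var]
    return [f"{var}[{lv}]" for lv in levels[1:]]


def spec_columns(spec: ModelSpec) -> list[str]:
    """Deterministic column order: intercept, main effects, year, interactions."""
    cols = ["intercept"]
    for var in FACTORS:
        cols.extend(_factor_columns(var))
    if spec.include_year:
        cols.append("year")
    for a, b in spec.interactions:
        for ca in _factor_columns(a):
            for cb in _factor_columns(b):
                cols.append(f"{ca}:{cb}")
    return cols


def _base_column(df: pd.DataFrame, name: str) -> np.ndarray:
    if name == "intercept":
        return np.ones(len(df))
    if name == "year":
        return df["year"].to_numpy(dtype=float) - YEAR_REF
    var, level = name[:-1].split("[", 1)
    levels = FACTORS[var]
    # levels may be ints (IMD quintile); compare on string form
    target = next(lv for lv in levels if str(lv) == level)
    return (df[var].to_numpy() == target).astype(float)


def column_values(df: pd.DataFrame, name: str) -> np.ndarray:
    """Evaluate one named design column (products for interaction columns)."""
    parts = name.split(":")
    out = _base_column(df, parts[0])
    for part in parts[1:]:
        out = out * _base_column(df, part)
    return out


def build_design(df: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Build the dense design matrix for ``spec`` over rows of ``df``.

    Requires the fixed level tables to cover every value present (unseen
    levels raise), and a ``year`` column when the spec uses the year trend.
    """
    validate_levels(df)
    cols = spec_columns(spec)
    X = np.empty((len(df), len(cols)))
    for j, name in enumerate(cols):
        X[:, j] = column_values(df, name)
    return X, cols


def linear_predictor(df: pd.DataFrame, coefs: dict[str, float]) -> np.ndarray:
    """Evaluate eta = sum_k coef_k * column_k(df) for a named coefficient map."""
    eta = np.zeros(len(df))
    for name, value in coefs.items():
        eta += value * column_values(df, name)
    return eta


def n_columns_closed_form(spec: ModelSpec) -> int:
    """Closed-form column count (used as an independent combinatorial check)."""
    size = {var: len(lv) - 1 for var, lv in FACTORS.items()}
    size["year"] = 1
    n = 1 + sum(size[v] for v in FACTORS) + (1 if spec.include_year else 0)
    n += sum(size[a] * size[b] for a, b in spec.interactions)
    return n
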