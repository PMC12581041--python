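"""Screening-threshold case definitions.

Converts raw survey records into per-condition analysis datasets. A person
has *clinical signs* when the survey measurement crosses the condition's
screening threshold (SBP strictly above 140 mm Hg for hypertension, HbA1c at
or above 48 mmol/mol for diabetes, SF-12 MCS at or below 42 for depression);
they are *diagnosed* when they self-report having been told they have the
condition (for depression, ever-reported across waves). The analysis dataset
keeps only people with disease — clinical signs or a diagnosis — and the
modelled outcome is ``undiagnosed = signs and not diagnosed``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .levels import CONDITIONS, SEGMENT_VARS

logger = logging.getLogger(__name__)

DIRECTIONS = ("above-strict", "at-or-above", "at-or-below")


@dataclass(frozen=True)
class ConditionRule:
    """Threshold rule for clinical signs plus the diagnosed-case convention."""

    condition: str
    signs_variable: str  # "sbp" (mm Hg) | "hba1c" (mmol/mol) | "mcs" (score)
    signs_threshold: float
    signs_direction: str  # one of DIRECTIONS
    diagnosed_rule: str = "point-in-time"  # or "ever-report"

    def __post_init__(self) -> None:
        if self.signs_direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.signs_direction!r}")
        if self.diagnosed_rule not in ("point-in-time", "ever-report"):
            raise ValueError(f"unknown diagnosed rule {self.diagnosed_rule!r}")
        if not math.isfinite(self.signs_threshold):
            raise ValueError("signs_threshold must be finite")

    def with_threshold(self, threshold: float) -> "ConditionRule":
        return replace(self, signs_threshold=float(threshold))


DEFAULT_RULES: dict[str, ConditionRule] = {
    "hypertension": ConditionRule("hypertension", "sbp", 140.0, "above-strict"),
    "diabetes": ConditionRule("diabetes", "hba1c", 48.0, "at-or-above"),
    "depression": ConditionRule("depression", "mcs", 42.0, "at-or-below", "ever-report"),
}


def classify_clinical_signs(measurement, rule: ConditionRule) -> np.ndarray:
    """Boolean signs flag per measurement, honouring threshold strictness.

    Missing (NaN) measurements raise: callers must handle missingness
    explicitly (see :func:`build_condition_dataset`) rather than treat it as
    signs-absent.
    """
    x = np.asarray(measurement, dtype=float)
    if np.isnan(x).any():
        raise ValueError("missing measurement passed to classify_clinical_signs")
    if rule.signs_direction == "above-strict":
        return x > rule.signs_threshold
    if rule.signs_direction == "at-or-above":
        return x >= rule.signs_threshold
    return x <= rule.signs_threshold


def derive_ever_diagnosed(person_waves: pd.DataFrame) -> pd.Series:
    """Carry a self-reported diagnosis forward across a person's waves.

    Expects columns ``person_id``, ``year`` and ``self_report``, sorted by
    year within person (unsorted input is rejected). Returns a boolean Series
    aligned to the input rows that is monotone non-decreasing within person:
    true from the first reporting wave onward.
    """
    years = person_waves.groupby("person_id", sort=False)["year"]
    if not years.apply(lambda s: s.is_monotonic_increasing).all():
        raise ValueError("waves must be sorted ascending by year within person")
    flag = person_waves.groupby("person_id", sort=False)["self_report"].cummax()
    return flag.astype(bool)


@dataclass
class ConditionDataset:
    """Rows restricted to people with disease, with the undiagnosed outcome."""

    condition: str
    data: pd.DataFrame  # includes segment fields, year, weight, undiagnosed
    n_input: int
    n_excluded_no_disease: int
    n_excluded_missing: int

    def __post_init__(self) -> None:
        d = self.data
        if not ((d["signs"] | d["diagnosed"]).all()):
            raise AssertionError("dataset contains a row with neither signs nor diagnosis")
        if not (d["undiagnosed"] == (d["signs"] & ~d["diagnosed"])).all():
            raise AssertionError("outcome must equal signs AND NOT diagnosed")


def build_condition_dataset(records: pd.DataFrame, rule: ConditionRule) -> ConditionDataset:
    """Apply the case definition to raw survey records.

    Rows with a missing measurement and no diagnosis are dropped with a
    logged count (their disease status is unknowable); rows with neither
    signs nor a diagnosis are excluded as disease-free. Raises if the
    resulting dataset is empty.
    """
    if rule.condition not in CONDITIONS:
        raise ValueError(f"unknown condition {rule.condition!r}")
    df = records.copy()
    n_input = len(df)

    if rule.diagnosed_rule == "ever-report":
        df = df.sort_values(["person_id", "year"], kind="stable").reset_index(drop=True)
        df["diagnosed"] = derive_ever_diagnosed(df)
    else:
        df["diagnosed"] = df["self_report"].astype(bool)

    missing = df["measurement"].isna()
    n_missing_dropped = int((missing & ~df["diagnosed"]).sum())
    if n_missing_dropped:
        logger.info(
            "%s: dropping %d rows with missing measurement and no diagnosis",
            rule.condition,
            n_missing_dropped,
        )
    df = df[~missing | df["diagnosed"]].copy()
    df["signs"] = False
    ok = ~df["measurement"].isna()
    df.loc[ok, "signs"] = classify_clinical_signs(df.loc[ok, "measurement"], rule)

    with_disease = df["signs"] | df["diagnosed"]
    n_no_disease = int((~with_disease).sum())
    out = df[with_disease].copy()
    out["undiagnosed"] = (out["signs"] & ~out["diagnosed"]).astype(int)
    if out.empty:
        raise ValueError(f"no rows with disease for condition {rule.condition!r}")
    keep = ["person_id", "year", *SEGMENT_VARS, "weight", "signs", "diagnosed", "undiagnosed"]
    return ConditionDataset(
        condition=rule.condition,
        data=out[keep].reset_index(drop=True),
        n_input=n_input,
        n_excluded_no_disease=n_no_disease,
        n_excluded_missing=n_missing_dropped,
    )


def disease_indicator(records: pd.DataFrame, rule: ConditionRule) -> pd.DataFrame:
    """Full-survey table with a binary ``disease`` column (signs or diagnosis).

    This is the outcome for the prevalence model used to weight segments in
    the national estimate and to drive the microsimulation. Rows with missing
    measurements and no diagnosis are dropped as in the main case definition.
    """
    df = records.copy()
    if rule.diagnosed_rule == "ever-report":
        df = df.sort_values(["person_id", "year"], kind="stable").reset_index(drop=True)
        df["diagnosed"] = derive_ever_diagnosed(df)
    else:
        df["diagnosed"] = df["self_report"].astype(bool)
    df = df[~df["measurement"].isna() | df["diagnosed"]].copy()
    df["signs"] = False
    ok = ~df["measurement"].isna()
    df.loc[ok, "signs"] = classify_clinical_signs(df.loc[ok, "measurement"], rule)
    df["disease"] = (df["signs"] | df["diagnosed"]).astype(int)
    keep = ["person_id", "year", *SEGMENT_VARS, "weight", "disease"]
    return df[keep].reset_index(drop=True)
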