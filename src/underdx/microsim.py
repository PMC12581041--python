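"""Binomial microsimulation onto the nested synthetic population.

Segment-level probabilities are projected onto LSOA x age x sex population
cells: the number with disease in a cell is Binomial(count, P(disease)) and
the number undiagnosed is Binomial(n_disease, P(undiagnosed | disease)) —
distributionally identical to flagging every individual with independent
Bernoulli draws, but desk-scale. Cell draws aggregate to CCG estimates;
replicate draws give a Monte-Carlo interval per area.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .levels import SEGMENT_VARS
from .predict import SegmentPredictions


def _cell_probabilities(
    cells: pd.DataFrame, predictions: SegmentPredictions, year: int
) -> pd.DataFrame:
    preds = predictions.for_year(year)[[*SEGMENT_VARS, "p_disease", "p_undiag"]]
    merged = cells.merge(preds, on=list(SEGMENT_VARS), how="left", validate="many_to_one")
    if merged["p_disease"].isna().any():
        missing = merged.loc[merged["p_disease"].isna(), list(SEGMENT_VARS)].drop_duplicates()
        raise ValueError(f"no prediction for segment(s):\n{missing.to_string(index=False)}")
    return merged


def simulate_flags(
    cells: pd.DataFrame,
    predictions: SegmentPredictions,
    year: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """One realisation of per-cell disease and undiagnosed counts."""
    merged = _cell_probabilities(cells, predictions, year)
    n = merged["count"].to_numpy(dtype=np.int64)
    n_dis = rng.binomial(n, merged["p_disease"].to_numpy())
    n_und = rng.binomial(n_dis, merged["p_undiag"].to_numpy())
    out = merged[["lsoa_id", "ccg_id", *SEGMENT_VARS, "count"]].copy()
    out["n_disease"] = n_dis
    out["n_undiagnosed"] = n_und
    return out


def aggregate_areas(
    cells: pd.DataFrame,
    predictions: SegmentPredictions,
    year: int,
    n_replicates: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """CCG-level undiagnosed proportions with Monte-Carlo intervals.

    Repeats the binomial draw ``n_replicates`` times; per CCG reports the
    mean disease and undiagnosed counts, the mean of the per-replicate
    proportions and their percentile interval. A CCG with zero drawn disease
    count in a replicate contributes no proportion for that replicate and is
    flagged (``any_zero_disease``). Count conservation from cells to areas to
    the national total holds exactly within every replicate.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    if (cells["count"] == 0).all():
        import warnings

        warnings.warn("population counts are all zero; microsim estimates are empty")
    merged = _cell_probabilities(cells, predictions, year)
    n = merged["count"].to_numpy(dtype=np.int64)
    p_dis = merged["p_disease"].to_numpy()
    p_und = merged["p_undiag"].to_numpy()
    codes, ccg_ids = pd.factorize(merged["ccg_id"], sort=True)
    n_areas = len(ccg_ids)

    rng = np.random.default_rng(seed)
    dis_reps = np.empty((n_replicates, n_areas))
    und_reps = np.empty((n_replicates, n_areas))
    for r in range(n_replicates):
        n_dis = rng.binomial(n, p_dis)
        n_und = rng.binomial(n_dis, p_und)
        dis_reps[r] = np.bincount(codes, weights=n_dis, minlength=n_areas)
        und_reps[r] = np.bincount(codes, weights=n_und, minlength=n_areas)

    with np.errstate(invalid="ignore"):
        props = np.where(dis_reps > 0, und_reps / np.where(dis_reps > 0, dis_reps, 1), np.nan)
    lo_q, hi_q = 100 * alpha / 2, 100 * (1 - alpha / 2)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN areas stay NaN
        prop_mean = np.nanmean(props, axis=0)
        lo = np.nanpercentile(props, lo_q, axis=0)
        hi = np.nanpercentile(props, hi_q, axis=0)
    out = pd.DataFrame(
        {
            "ccg_id": ccg_ids,
            "condition": predictions.condition,
            "year": year,
            "n_disease": dis_reps.mean(axis=0),
            "n_undiag": und_reps.mean(axis=0),
            "prop_undiag": prop_mean,
            "lo": lo,
            "hi": hi,
            "any_zero_disease": (dis_reps == 0).any(axis=0),
        }
    )
    return out


def change_map(estimates_a: pd.DataFrame, estimates_b: pd.DataFrame) -> pd.DataFrame:
    """Per-area difference in proportion undiagnosed, year b minus year a."""
    a = estimates_a.set_index("ccg_id")["prop_undiag"]
    b = estimates_b.set_index("ccg_id")["prop_undiag"]
    if set(a.index) != set(b.index):
        raise ValueError("area sets differ between the two years")
    b = b.reindex(a.index)
    return pd.DataFrame({"ccg_id": a.index, "change": (b - a).to_numpy()}).reset_index(drop=True)
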