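"""Segment-level adjusted predictions and national summaries.

For each of the 540 population segments and each requested year, the fitted
prevalence model gives P(disease) and the undiagnosed model gives
P(undiagnosed | disease). Uncertainty comes from parametric simulation: draw
coefficient vectors from N(beta_hat, cov), push each through the inverse
logit, and take percentile bounds — the same draws propagate through the
national population-weighted summary so its interval reflects both models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import build_design
from .levels import SEGMENT_VARS, YEARS, segment_frame
from .modelling import FittedModel


def segment_year_frame(years) -> pd.DataFrame:
    frames = []
    for year in years:
        seg = segment_frame().copy()
        seg["year"] = int(year)
        frames.append(seg)
    return pd.concat(frames, ignore_index=True)


@dataclass
class SegmentPredictions:
    """Point predictions per segment-year plus paired coefficient-draw surfaces.

    ``frame`` has one row per (year, segment) with point estimates and
    percentile CIs; ``draws_disease`` and ``draws_undiag`` are (n_sim, rows)
    float32 arrays of simulated probabilities aligned to ``frame`` rows, kept
    so downstream weighted summaries can propagate the same uncertainty.
    """

    condition: str
    frame: pd.DataFrame
    draws_disease: np.ndarray
    draws_undiag: np.ndarray
    alpha: float

    def for_year(self, year: int) -> pd.DataFrame:
        out = self.frame[self.frame["year"] == year]
        if out.empty:
            raise ValueError(f"no predictions for year {year}")
        return out.reset_index(drop=True)


def _prob_draws(model: FittedModel, grid: pd.DataFrame, n_sim: int, rng) -> np.ndarray:
    X, _ = build_design(grid, model.spec)
    betas = model.simulate_coefs(n_sim, rng)
    return expit(betas @ X.T).astype(np.float32)


def predict_segments(
    model_undiag: FittedModel,
    model_disease: FittedModel,
    years=YEARS,
    condition: str = "",
    n_sim: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> SegmentPredictions:
    """Predict both probabilities for every segment-year with percentile CIs.

    Years outside the fitted 2011-2019 window are allowed but flagged in the
    output (``extrapolated`` column).
    """
    years = [int(y) for y in years]
    grid = segment_year_frame(years)
    rng = np.random.default_rng(seed)

    p_dis = model_disease.predict(grid)
    p_und = model_undiag.predict(grid)
    draws_dis = _prob_draws(model_disease, grid, n_sim, rng)
    draws_und = _prob_draws(model_undiag, grid, n_sim, rng)

    lo_q, hi_q = 100 * alpha / 2, 100 * (1 - alpha / 2)
    frame = grid.copy()
    frame.insert(0, "condition", condition)
    frame["p_disease"] = p_dis
    frame["p_disease_lo"], frame["p_disease_hi"] = np.percentile(draws_dis, [lo_q, hi_q], axis=0)
    frame["p_undiag"] = p_und
    frame["p_undiag_lo"], frame["p_undiag_hi"] = np.percentile(draws_und, [lo_q, hi_q], axis=0)
    frame["extrapolated"] = ~frame["year"].isin(YEARS)
    return SegmentPredictions(condition, frame, draws_dis, draws_und, alpha)


def mean_adjusted_prediction(
    model: FittedModel,
    dataset: pd.DataFrame,
    at: dict[str, object],
    weights: str = "weight",
    n_sim: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Weighted mean adjusted prediction at counterfactual level(s) ``at``.

    Every row of ``dataset`` has the focal variable(s) set to the given
    level(s); the model predicts each row and the survey-weighted mean is
    returned with a percentile CI from coefficient simulation.
    """
    from .levels import FACTORS

    cf = dataset.copy()
    for var, level in at.items():
        if var == "year":
            cf[var] = level
        elif var in FACTORS:
            if level not in FACTORS[var]:
                raise ValueError(f"invalid level {level!r} for {var}")
            cf[var] = level
        else:
            raise ValueError(f"unknown variable {var!r}")
    w = cf[weights].to_numpy(dtype=float)
    w = w / w.sum()

    X, _ = build_design(cf, model.spec)
    point = float(w @ expit(X @ model.params.to_numpy()))
    rng = np.random.default_rng(seed)
    betas = model.simulate_coefs(n_sim, rng)
    sims = expit(betas @ X.T) @ w
    lo, hi = np.percentile(sims, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return point, float(lo), float(hi)


def _segment_population(population: pd.DataFrame) -> pd.DataFrame:
    return population.groupby(list(SEGMENT_VARS), as_index=False, observed=True)["count"].sum()


def national_estimate(
    predictions: SegmentPredictions,
    population: pd.DataFrame,
    years,
) -> dict[str, float]:
    """National proportion undiagnosed, weighting segments by population x P(disease).

    With single ``years=[y]`` this is the year-y national estimate; with
    several years the numerator and denominator pool over years (used when
    the model carries no time trend). The CI propagates the paired
    coefficient draws stored in ``predictions`` through the same weighting.
    Raises if the population table misses any segment.
    """
    years = [int(y) for y in np.atleast_1d(years)]
    seg_pop = _segment_population(population)
    if len(seg_pop) < len(segment_frame()):
        raise ValueError("population table does not cover all 540 segments")

    num = den = 0.0
    num_d = den_d = 0.0
    for year in years:
        mask = (predictions.frame["year"] == year).to_numpy()
        if not mask.any():
            raise ValueError(f"no predictions for year {year}")
        sub = predictions.frame.loc[mask]
        merged = sub.merge(seg_pop, on=list(SEGMENT_VARS), how="left", validate="one_to_one")
        if merged["count"].isna().any():
            raise ValueError("population table missing segments")
        pop = merged["count"].to_numpy(dtype=float)
        num += float(np.sum(pop * merged["p_disease"] * merged["p_undiag"]))
        den += float(np.sum(pop * merged["p_disease"]))
        d_dis = predictions.draws_disease[:, mask].astype(np.float64)
        d_und = predictions.draws_undiag[:, mask].astype(np.float64)
        num_d = num_d + (d_dis * d_und) @ pop
        den_d = den_d + d_dis @ pop
    if den == 0:
        raise ValueError("zero disease-weighted population")
    sims = num_d / den_d
    a = predictions.alpha
    lo, hi = np.percentile(sims, [100 * a / 2, 100 * (1 - a / 2)])
    return {
        "estimate": num / den,
        "lo": float(lo),
        "hi": float(hi),
        "years": years,
        "condition": predictions.condition,
    }
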