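"""Segment predictions, mean adjusted predictions, national estimates."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from underdx import (
    FittedModel,
    ModelSpec,
    build_design,
    mean_adjusted_prediction,
    national_estimate,
    predict_segments,
    segment_frame,
)
from underdx.design import spec_columns
from underdx.predict import segment_year_frame


def _manual_model(coef_map, spec=None, var=1e-12):
    """A FittedModel built by hand (no fitting) with the given coefficients."""
    spec = spec or ModelSpec()
    cols = spec_columns(spec)
    params = pd.Series([coef_map.get(c, 0.0) for c in cols], index=cols)
    cov = pd.DataFrame(np.eye(len(cols)) * var, index=cols, columns=cols)
    return FittedModel(
        spec=spec, params=params, cov=cov, llf=0.0, aic=0.0,
        n_obs=1000, rank=len(cols), converged=True, n_iter=1,
    )


def _flat_population(count=100):
    pop = segment_frame().copy()
    pop["lsoa_id"] = "L1"
    pop["ccg_id"] = "C1"
    pop["count"] = count
    return pop


def test_exactly_540_segment_rows_per_year():
    m = _manual_model({"intercept": 0.3})
    preds = predict_segments(m, m, years=(2011, 2019), condition="diabetes", n_sim=50)
    for year in (2011, 2019):
        assert len(preds.for_year(year)) == 540
    assert len(preds.frame) == 1080
    assert not preds.frame[["age_group", "sex", "imd_quintile", "region", "year"]].duplicated().any()


def test_zero_coefficients_predict_one_half():
    m = _manual_model({})
    preds = predict_segments(m, m, years=(2015,), n_sim=50)
    np.testing.assert_allclose(preds.frame["p_undiag"], 0.5)
    np.testing.assert_allclose(preds.frame["p_disease"], 0.5)


def test_near_zero_covariance_gives_tiny_ci():
    m = _manual_model({"intercept": -0.7}, var=1e-16)
    preds = predict_segments(m, m, years=(2015,), n_sim=10_000)
    widths = preds.frame["p_undiag_hi"] - preds.frame["p_undiag_lo"]
    assert (widths < 1e-3).all()
    assert (preds.frame["p_undiag_lo"] <= preds.frame["p_undiag"]).all()
    assert (preds.frame["p_undiag"] <= preds.frame["p_undiag_hi"]).all()


def test_extrapolated_year_is_flagged():
    m = _manual_model({})
    preds = predict_segments(m, m, years=(2019, 2025), n_sim=10)
    assert not preds.for_year(2019)["extrapolated"].any()
    assert preds.for_year(2025)["extrapolated"].all()


def test_predictions_invariant_to_reference_level_choice():
    """Refitting with the sex labels swapped (so the other level is the
    reference) yields identical predicted probabilities row for row."""
    from underdx import fit_weighted_logistic

    rng = np.random.default_rng(4)
    df = segment_frame().sample(3000, replace=True, random_state=2).reset_index(drop=True)
    df["year"] = rng.choice(range(2011, 2020), size=len(df))
    df["weight"] = 1.0
    eta = -0.5 + 0.7 * (df["sex"] == "male") - 0.03 * (df["year"] - 2011)
    df["undiagnosed"] = rng.binomial(1, expit(eta))

    swap = {"male": "female", "female": "male"}
    df_swapped = df.assign(sex=df["sex"].map(swap))

    fit_a = fit_weighted_logistic(df, "undiagnosed", ModelSpec())
    fit_b = fit_weighted_logistic(df_swapped, "undiagnosed", ModelSpec())
    grid = segment_year_frame([2015])
    grid_swapped = grid.assign(sex=grid["sex"].map(swap))
    np.testing.assert_allclose(fit_a.predict(grid), fit_b.predict(grid_swapped), atol=1e-8)


def test_mean_adjusted_prediction_intercept_only_equals_overall():
    m = _manual_model({"intercept": 0.8})
    df = segment_frame().head(50).copy()
    df["year"] = 2013
    df["weight"] = np.linspace(0.5, 2.0, 50)
    point, lo, hi = mean_adjusted_prediction(m, df, {"sex": "male"}, n_sim=100)
    assert point == pytest.approx(expit(0.8), abs=1e-12)


def test_mean_adjusted_prediction_equals_per_row_counterfactual_oracle():
    """Matches the explicit row-by-row counterfactual average to 1e-10."""
    rng = np.random.default_rng(8)
    spec = ModelSpec(interactions=(("sex", "year"), ("age_group", "sex")))
    coef = {
        "intercept": -0.9,
        "sex[male]": 0.5,
        "year": -0.04,
        "sex[male]:year": 0.03,
        "age_group[80+]:sex[male]": 0.7,
    }
    m = _manual_model(coef, spec)
    df = segment_frame().sample(50, random_state=1).reset_index(drop=True)
    df["year"] = rng.choice(range(2011, 2020), size=50)
    df["weight"] = rng.lognormal(0, 0.5, 50)

    point, _, _ = mean_adjusted_prediction(m, df, {"sex": "male"}, n_sim=10)

    # oracle: set the level row by row, predict each row alone, weight-average
    total, wsum = 0.0, 0.0
    for _, row in df.iterrows():
        r = row.to_frame().T
        r["sex"] = "male"
        r = r.astype(df.dtypes)
        X, _ = build_design(r, spec)
        total += row["weight"] * expit(X @ m.params.to_numpy())[0]
        wsum += row["weight"]
    assert point == pytest.approx(total / wsum, abs=1e-10)


def test_mean_adjusted_prediction_saturates_with_huge_coefficient():
    m = _manual_model({"intercept": 0.0, "sex[male]": 20.0})
    df = segment_frame().head(40).copy()
    df["year"] = 2012
    df["weight"] = 1.0
    point, _, _ = mean_adjusted_prediction(m, df, {"sex": "male"}, n_sim=10)
    assert point >= 0.999


def test_mean_adjusted_prediction_rejects_invalid_level():
    m = _manual_model({})
    df = segment_frame().head(5).copy()
    df["year"] = 2012
    df["weight"] = 1.0
    with pytest.raises(ValueError, match="invalid level"):
        mean_adjusted_prediction(m, df, {"sex": "other"}, n_sim=10)


def test_national_estimate_constant_field_and_scale_invariance():
    m_und = _manual_model({"intercept": np.log(0.3 / 0.7)})  # p_undiag = 0.3
    m_dis = _manual_model({"intercept": -1.0, "sex[male]": 0.8})
    preds = predict_segments(m_und, m_dis, years=(2015,), n_sim=50)

    pop = _flat_population(100)
    est = national_estimate(preds, pop, [2015])
    assert est["estimate"] == pytest.approx(0.3, abs=1e-9)

    pop2 = pop.copy()
    pop2["count"] *= 2
    est2 = national_estimate(preds, pop2, [2015])
    assert est2["estimate"] == pytest.approx(est["estimate"], abs=1e-12)


def test_national_estimate_requires_full_population_coverage():
    m = _manual_model({})
    preds = predict_segments(m, m, years=(2015,), n_sim=10)
    pop = _flat_population().iloc[:-5]  # drop some segments
    with pytest.raises(ValueError, match="segment"):
        national_estimate(preds, pop, [2015])
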