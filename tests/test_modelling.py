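"""Weighted logistic fit, stepwise-AIC selection, Hosmer-Lemeshow diagnostics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from underdx import (
    GeneratorConfig,
    ModelSpec,
    SeparationError,
    fit_logit,
    fit_weighted_logistic,
    generate_survey,
    hosmer_lemeshow,
    stepwise_aic,
)
from underdx.design import linear_predictor
from underdx.synthetic_data import _draw_segments, _substream


def test_weighted_2x2_matches_closed_form_to_1e8():
    """Coefficients from a weighted 2x2 table equal the closed-form weighted
    log-odds and log-odds-ratio."""
    w11, w10, w01, w00 = 3.2, 1.7, 2.4, 5.1  # (x, y) cell weights
    X = np.array([[1, 1], [1, 1], [1, 0], [1, 0]], dtype=float)
    y = np.array([1.0, 0.0, 1.0, 0.0])
    w = np.array([w11, w10, w01, w00])
    fit = fit_logit(X, y, w, columns=["intercept", "x"])
    intercept = np.log(w01 / w00)
    slope = np.log((w11 / w10) / (w01 / w00))
    assert fit.params["intercept"] == pytest.approx(intercept, abs=1e-8)
    assert fit.params["x"] == pytest.approx(slope, abs=1e-8)


def test_equal_weights_match_unweighted_mle_and_statsmodels():
    rng = np.random.default_rng(0)
    n = 2000
    X = np.column_stack([np.ones(n), rng.normal(size=n), rng.binomial(1, 0.4, n)])
    y = rng.binomial(1, expit(X @ np.array([-0.5, 0.8, -0.6]))).astype(float)
    ours = fit_logit(X, y, np.full(n, 7.3))  # constant weights, arbitrary scale
    ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    np.testing.assert_allclose(ours.params.to_numpy(), ref.params, atol=1e-8)
    np.testing.assert_allclose(ours.cov.to_numpy(), ref.cov_params(), rtol=1e-6)
    assert ours.llf == pytest.approx(ref.llf, abs=1e-6)
    assert ours.aic == pytest.approx(ref.aic, abs=1e-5)


def test_weighted_fit_matches_statsmodels_freq_weights():
    rng = np.random.default_rng(1)
    n = 3000
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = rng.binomial(1, expit(-0.3 + 0.5 * X[:, 1])).astype(float)
    w = rng.lognormal(0, 0.4, n)
    w = w / w.mean()
    ours = fit_logit(X, y, w)
    ref = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w).fit()
    np.testing.assert_allclose(ours.params.to_numpy(), ref.params, atol=1e-8)
    assert ours.llf == pytest.approx(ref.llf, abs=1e-6)


def test_aic_identity_holds():
    rng = np.random.default_rng(2)
    n = 500
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = rng.binomial(1, 0.4, n).astype(float)
    fit = fit_logit(X, y)
    assert fit.aic == pytest.approx(-2 * fit.llf + 2 * fit.rank, abs=1e-10)


def test_constant_outcome_raises_separation_error():
    X = np.column_stack([np.ones(50), np.arange(50.0)])
    with pytest.raises(SeparationError):
        fit_logit(X, np.ones(50))


def test_separated_covariate_raises_separation_error():
    x = np.concatenate([np.zeros(30), np.ones(30)])
    y = x.copy()  # perfectly separated
    X = np.column_stack([np.ones(60), x])
    with pytest.raises(SeparationError):
        fit_logit(X, y)


def _undiag_frame(n, coefs, seed):
    """Disease-rows-only frame drawn directly from the undiagnosed model."""
    rng = _substream(seed, "direct")
    cfg = GeneratorConfig(n_survey=10, seed=seed)
    df = _draw_segments(rng, cfg, n)
    df["year"] = rng.choice(np.arange(2011, 2020), size=n)
    df["weight"] = 1.0
    df["undiagnosed"] = (rng.random(n) < expit(linear_predictor(df, coefs))).astype(int)
    return df


def test_stepwise_fixed_point_and_monotone_path():
    df = _undiag_frame(4000, {"intercept": -0.4}, seed=3)
    start = ModelSpec()  # no interactions; nothing should be added on null data...
    fit, path = stepwise_aic(df, "undiagnosed", start)
    aics = [p.aic for p in path]
    assert all(b < a for a, b in zip(aics, aics[1:]))  # strictly decreasing
    # starting from the selected model is a fixed point
    fit2, path2 = stepwise_aic(df, "undiagnosed", fit.spec)
    assert fit2.spec.interactions == fit.spec.interactions
    assert len(path2) == 1


def test_stepwise_recovers_planted_age_sex_interaction():
    """A large planted age x sex effect is selected in >=95% of 20 replicates
    (n = 50 000, candidates restricted to non-region interactions)."""
    candidates = tuple(
        p for p in ModelSpec().candidates if "region" not in p
    )
    coefs = {
        "intercept": -0.5,
        "sex[male]": 0.3,
        "age_group[80+]": 0.3,
        "age_group[80+]:sex[male]": 1.2,
        "age_group[70-79]:sex[male]": 0.9,
    }
    hits = 0
    for rep in range(20):
        df = _undiag_frame(50_000, coefs, seed=100 + rep)
        start = ModelSpec(interactions=candidates, candidates=candidates)
        fit, path = stepwise_aic(df, "undiagnosed", start)
        aics = [p.aic for p in path]
        assert all(b < a for a, b in zip(aics, aics[1:]))
        if ("age_group", "sex") in fit.spec.interactions:
            hits += 1
    assert hits >= 19


def test_coefficient_ci_coverage_near_nominal():
    """Wald-type coverage of the true slope across 200 replicates in [0.90, 0.98]."""
    rng = np.random.default_rng(42)
    n, beta1 = 1500, 0.6
    covered = 0
    for _ in range(200):
        x = rng.normal(size=n)
        y = rng.binomial(1, expit(-0.2 + beta1 * x)).astype(float)
        fit = fit_logit(np.column_stack([np.ones(n), x]), y)
        se = np.sqrt(fit.cov.iloc[1, 1])
        b = fit.params.iloc[1]
        covered += (b - 1.96 * se) <= beta1 <= (b + 1.96 * se)
    assert 0.90 <= covered / 200 <= 0.98


def test_hosmer_lemeshow_perfect_fit_is_zero():
    # grouped data where observed equals expected exactly in every group
    p = np.repeat([0.2, 0.4, 0.6, 0.8], 10)
    y = np.concatenate(
        [[1] * round(q * 10) + [0] * (10 - round(q * 10)) for q in (0.2, 0.4, 0.6, 0.8)]
    ).astype(float)
    stat, df, pval = hosmer_lemeshow(p, y, n_groups=4)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert pval == pytest.approx(1.0)
    assert df == 2


def test_hosmer_lemeshow_nonnegative_and_group_reduction():
    rng = np.random.default_rng(5)
    p = np.repeat([0.3, 0.7], 50)  # only two distinct predictions
    y = rng.binomial(1, p).astype(float)
    stat, df, pval = hosmer_lemeshow(p, y, n_groups=10)
    assert stat >= 0.0
    assert df == 0 or df >= 0  # groups reduced to the 2 distinct values
    with pytest.raises(ValueError):
        hosmer_lemeshow(p, y, n_groups=1)


def test_hosmer_lemeshow_null_calibration():
    """Under a correctly specified model the HL test rejects at ~alpha."""
    rng = np.random.default_rng(7)
    n, reps, alpha = 400, 500, 0.05
    rejections = 0
    for _ in range(reps):
        x = rng.normal(size=n)
        y = rng.binomial(1, expit(-0.3 + 0.7 * x)).astype(float)
        fit = fit_logit(np.column_stack([np.ones(n), x]), y)
        p_hat = expit(np.column_stack([np.ones(n), x]) @ fit.params.to_numpy())
        _, _, pval = hosmer_lemeshow(p_hat, y)
        rejections += pval < alpha
    assert 0.02 <= rejections / reps <= 0.09
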