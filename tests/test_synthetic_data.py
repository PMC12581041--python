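"""Generator contracts: determinism, calibration, geography, conservation."""

import numpy as np
import pandas as pd
import pytest

from underdx import (
    GeneratorConfig,
    attach_area_truth,
    generate_adjacency,
    generate_population,
    generate_qof_table,
    generate_survey,
    segment_frame,
)
from underdx.levels import SEGMENT_VARS


def test_same_config_and_seed_gives_byte_identical_tables(small_config):
    a, _ = generate_survey(small_config, "diabetes")
    b, _ = generate_survey(small_config, "diabetes")
    assert a.to_csv(index=False) == b.to_csv(index=False)
    pa = generate_population(small_config)
    pb = generate_population(small_config)
    assert pa.to_csv(index=False) == pb.to_csv(index=False)


def test_invalid_condition_and_sizes_rejected(small_config):
    with pytest.raises(ValueError, match="condition"):
        generate_survey(small_config, "gout")
    with pytest.raises(ValueError):
        GeneratorConfig(n_survey=0)
    with pytest.raises(ValueError):
        generate_population(GeneratorConfig(n_survey=10, lsoas_per_ccg=0))


def test_intercept_only_undiagnosed_share_is_half_within_3_binomial_se():
    """With logit^-1(0) = 0.5 truth and perfect screening, the empirical
    undiagnosed share among disease rows is 0.5 up to binomial noise."""
    cfg = GeneratorConfig(
        n_survey=20_000,
        disease_coefs={"intercept": 0.0},
        undiag_coefs={"intercept": 0.0},
        seed=7,
    )
    survey, truth = generate_survey(cfg, "diabetes")
    assert truth.national_fraction[2019] == pytest.approx(0.5)
    disease = survey["self_report"] | (survey["measurement"] >= 48.0)
    undiag = (~survey["self_report"]) & (survey["measurement"] >= 48.0)
    share = undiag.sum() / disease.sum()
    se = np.sqrt(0.25 / disease.sum())
    assert abs(share - 0.5) < 3 * se


def test_perfect_specificity_keeps_nondiseased_below_threshold():
    cfg = GeneratorConfig(
        n_survey=5_000,
        disease_coefs={"intercept": -40.0},  # nobody diseased
        undiag_coefs={"intercept": 0.0},
        screening_specificity=1.0,
        seed=3,
    )
    survey, _ = generate_survey(cfg, "diabetes")
    assert not survey["self_report"].any()
    assert (survey["measurement"] < 48.0).all()


def test_segment_closure_only_legal_combinations(small_survey):
    survey, _ = small_survey
    legal = segment_frame()
    merged = survey[list(SEGMENT_VARS)].drop_duplicates().merge(legal, how="left", indicator=True)
    assert (merged["_merge"] == "both").all()


def test_calibration_per_segment_cell():
    """Empirical P(undiagnosed | disease) converges to the logistic truth in
    a large single-segment cell (within 3 binomial SEs)."""
    cfg = GeneratorConfig(
        n_survey=40_000,
        disease_coefs={"intercept": 0.5},
        undiag_coefs={"intercept": -0.6, "sex[male]": 0.4},
        seed=11,
    )
    survey, _ = generate_survey(cfg, "hypertension")
    from scipy.special import expit

    for sex, eta in (("female", -0.6), ("male", -0.2)):
        sub = survey[survey["sex"] == sex]
        disease = sub["self_report"] | (sub["measurement"] > 140.0)
        undiag = (~sub["self_report"]) & (sub["measurement"] > 140.0)
        n = disease.sum()
        p = expit(eta)
        assert n > 5_000
        assert abs(undiag.sum() / n - p) < 3 * np.sqrt(p * (1 - p) / n)


def test_depression_panel_reports_carry_forward_and_calibrate():
    cfg = GeneratorConfig(
        n_survey=30_000,
        disease_coefs={"intercept": 0.0},
        undiag_coefs={"intercept": 0.3, "year": -0.05},
        seed=5,
    )
    survey, truth = generate_survey(cfg, "depression")
    # once reported, reported at every later wave
    monotone = survey.groupby("person_id")["self_report"].apply(
        lambda s: (s.astype(int).diff().fillna(0) >= 0).all()
    )
    assert monotone.all()
    # per-year marginal matches the logistic truth among disease rows
    from scipy.special import expit

    for year in (2011, 2019):
        rows = survey[survey["year"] == year]
        disease = rows["self_report"] | (rows["measurement"] <= 42.0)
        undiag = (~rows["self_report"]) & (rows["measurement"] <= 42.0)
        n = disease.sum()
        p = expit(0.3 - 0.05 * (year - 2011))
        assert abs(undiag.sum() / n - p) < 3 * np.sqrt(p * (1 - p) / n)
        assert truth.national_fraction[year] == pytest.approx(p)


def test_population_geography_and_conservation(small_population):
    pop = small_population
    assert pop["ccg_id"].nunique() == 191
    assert (pop["count"] >= 0).all()
    # each LSOA maps to exactly one (imd, ccg, region)
    per_lsoa = pop.groupby("lsoa_id")[["ccg_id", "region", "imd_quintile"]].nunique()
    assert (per_lsoa == 1).all().all()
    assert pop["count"].sum() == pop.attrs["national_total"]


def test_zero_population_mean_gives_all_zero_counts():
    cfg = GeneratorConfig(n_survey=10, lsoas_per_ccg=1, pop_cell_mean=0.0, seed=1)
    pop = generate_population(cfg)
    assert (pop["count"] == 0).all()


def test_qof_table_noise_and_determinism(small_config, small_population):
    _, truth = generate_survey(small_config, "diabetes")
    truth = attach_area_truth(truth, small_config, small_population, (2019,))
    exact = generate_qof_table(truth, noise_sd=0.0, seed=1)
    expected = truth.area_table.drop_duplicates("ccg_id", keep="last")
    np.testing.assert_allclose(
        exact["diagnosed_prevalence"].to_numpy(),
        expected["diagnosed_prevalence"].to_numpy(),
    )
    noisy1 = generate_qof_table(truth, noise_sd=0.5, seed=9)
    noisy2 = generate_qof_table(truth, noise_sd=0.5, seed=9)
    pd.testing.assert_frame_equal(noisy1, noisy2)
    assert noisy1["diagnosed_prevalence"].between(0, 1).all()
    with pytest.raises(ValueError):
        generate_qof_table(truth, noise_sd=-0.1, seed=1)


def test_adjacency_symmetric_connected_min_degree():
    cfg = GeneratorConfig(n_survey=10, n_ccgs=2, seed=1)
    adj = generate_adjacency(cfg)
    assert len(adj) == 1 and set(adj.iloc[0]) == {"CCG001", "CCG002"}

    cfg = GeneratorConfig(n_survey=10, n_ccgs=25, seed=1)
    adj = generate_adjacency(cfg)
    n = 25
    w = np.zeros((n, n))
    idx = {f"CCG{str(i+1).zfill(3)}": i for i in range(n)}
    for a, b in zip(adj["area_a"], adj["area_b"]):
        w[idx[a], idx[b]] = w[idx[b], idx[a]] = 1
    np.testing.assert_array_equal(w, w.T)
    assert np.all(np.diag(w) == 0)
    assert (w.sum(axis=1) >= 2).all()
    # connectivity: powers of (I + W) must fill in
    reach = np.eye(n) + w
    for _ in range(n):
        reach = np.minimum(reach @ reach, 1)
    assert (reach > 0).all()

    with pytest.raises(ValueError):
        generate_adjacency(GeneratorConfig(n_survey=10, n_ccgs=1, seed=1))
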