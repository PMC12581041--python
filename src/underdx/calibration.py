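"""Truth-calibrated generator configurations.

For recovery runs, the generator's undiagnosed-model intercept and year slope
are solved (2-d Newton via ``scipy.optimize.fsolve``) so that the
population-weighted true undiagnosed fraction

    f(y) = sum_s P_s p_dis(s, y) p_und(s, y) / sum_s P_s p_dis(s, y)

equals a stated national figure in the anchor years (or pooled over years
when the truth carries no time trend). Segment-level effects in both
coefficient maps are fixed, field-realistic choices; only the intercept and
slope are solved, so the target fractions are exact properties of the truth,
not of any fitted model.

The default targets are the published national undiagnosed percentages the
study conditions are anchored to: diabetes 26% (2011) falling to 22% (2019),
hypertension 23% with no time trend, depression 68% (2011) falling to 64%
(2019).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq, fsolve
from scipy.special import expit, logit

from .design import linear_predictor
from .levels import YEARS, segment_frame
from .synthetic_data import GeneratorConfig, default_segment_probs

#: national undiagnosed fractions used as calibration anchors.
PUBLISHED_FRACTIONS: dict[str, dict] = {
    "diabetes": {2011: 0.26, 2019: 0.22},
    "hypertension": {"pooled": 0.23},
    "depression": {2011: 0.68, 2019: 0.64},
}

# Disease (signs-or-diagnosis) prevalence structure per condition: strong age
# gradients for the cardiometabolic conditions, a mild deprivation gradient
# throughout, no year trend for depression (the panel generator treats latent
# depression as persistent within a person, so its prevalence model must be
# time-constant for the carry-forward construction to stay calibrated).
DISEASE_COEFS: dict[str, dict[str, float]] = {
    "diabetes": {
        "intercept": -4.2,
        "age_group[30-49]": 1.0,
        "age_group[50-59]": 1.8,
        "age_group[60-69]": 2.3,
        "age_group[70-79]": 2.7,
        "age_group[80+]": 2.9,
        "sex[male]": 0.3,
        "imd_quintile[2]": 0.15,
        "imd_quintile[3]": 0.30,
        "imd_quintile[4]": 0.45,
        "imd_quintile[5]": 0.60,
        "year": 0.02,
    },
    "hypertension": {
        "intercept": -2.4,
        "age_group[30-49]": 0.8,
        "age_group[50-59]": 1.6,
        "age_group[60-69]": 2.2,
        "age_group[70-79]": 2.7,
        "age_group[80+]": 3.1,
        "sex[male]": 0.4,
        "imd_quintile[2]": 0.05,
        "imd_quintile[3]": 0.10,
        "imd_quintile[4]": 0.15,
        "imd_quintile[5]": 0.20,
    },
    "depression": {
        "intercept": -1.3,
        "age_group[30-49]": -0.2,
        "age_group[50-59]": -0.1,
        "age_group[60-69]": -0.3,
        "age_group[70-79]": -0.4,
        "age_group[80+]": -0.2,
        "sex[male]": -0.3,
        "imd_quintile[2]": 0.15,
        "imd_quintile[3]": 0.30,
        "imd_quintile[4]": 0.45,
        "imd_quintile[5]": 0.60,
    },
}

# Segment effects of the undiagnosed model, before the solved intercept/slope:
# hypertension underdiagnosis higher for men and lower in deprived areas;
# depression the reverse, with a U-shaped age pattern; diabetes close to flat.
UNDIAG_SEGMENT_EFFECTS: dict[str, dict[str, float]] = {
    "diabetes": {
        "sex[male]": 0.10,
        "age_group[30-49]": -0.10,
        "imd_quintile[2]": -0.05,
        "imd_quintile[3]": -0.10,
        "imd_quintile[4]": -0.15,
        "imd_quintile[5]": -0.20,
    },
    "hypertension": {
        "sex[male]": 0.30,
        "age_group[50-59]": -0.10,
        "age_group[60-69]": -0.30,
        "age_group[70-79]": -0.50,
        "age_group[80+]": -0.60,
        "imd_quintile[2]": -0.10,
        "imd_quintile[3]": -0.20,
        "imd_quintile[4]": -0.30,
        "imd_quintile[5]": -0.40,
    },
    "depression": {
        "sex[male]": 0.30,
        "age_group[30-49]": -0.40,
        "age_group[50-59]": -0.45,
        "age_group[60-69]": -0.40,
        "age_group[70-79]": -0.20,
        "age_group[80+]": 0.10,
        "imd_quintile[2]": 0.10,
        "imd_quintile[3]": 0.20,
        "imd_quintile[4]": 0.30,
        "imd_quintile[5]": 0.40,
    },
}


def _weighted_fraction(disease_coefs, undiag_coefs, segment_probs, years) -> float:
    num = den = 0.0
    for year in years:
        seg = segment_frame().copy()
        seg["year"] = year
        p_dis = expit(linear_predictor(seg, disease_coefs))
        p_und = expit(linear_predictor(seg, undiag_coefs))
        num += float(np.sum(segment_probs * p_dis * p_und))
        den += float(np.sum(segment_probs * p_dis))
    return num / den


def solve_undiag_coefs(
    condition: str,
    targets: dict | None = None,
    segment_probs: np.ndarray | None = None,
    years=YEARS,
) -> dict[str, float]:
    """Solve intercept (and year slope) so the truth hits the target fractions."""
    targets = PUBLISHED_FRACTIONS[condition] if targets is None else targets
    probs = default_segment_probs() if segment_probs is None else segment_probs
    dis = DISEASE_COEFS[condition]
    base = dict(UNDIAG_SEGMENT_EFFECTS[condition])

    if "pooled" in targets:
        target = targets["pooled"]

        def g(b0):
            return _weighted_fraction(dis, {**base, "intercept": b0}, probs, years) - target

        b0 = brentq(g, -10.0, 10.0, xtol=1e-12)
        return {**base, "intercept": float(b0)}

    anchor_years = sorted(targets)
    y0, y1 = anchor_years[0], anchor_years[-1]

    def equations(x):
        coefs = {**base, "intercept": x[0], "year": x[1]}
        return [
            _weighted_fraction(dis, coefs, probs, [y0]) - targets[y0],
            _weighted_fraction(dis, coefs, probs, [y1]) - targets[y1],
        ]

    start = [logit(targets[y0]), (logit(targets[y1]) - logit(targets[y0])) / (y1 - y0)]
    sol = fsolve(equations, start, xtol=1e-13)
    resid = equations(sol)
    if max(abs(r) for r in resid) > 1e-9:
        raise RuntimeError(f"calibration failed for {condition}: residuals {resid}")
    return {**base, "intercept": float(sol[0]), "year": float(sol[1])}


def calibrated_config(
    condition: str,
    seed: int,
    n_survey: int | None = None,
    targets: dict | None = None,
) -> GeneratorConfig:
    """Generator configuration whose national truth equals the target figures.

    Sample sizes default to the surveys being emulated: 35 000 respondents
    for the HSE-like cross-sections, 50 000 persons for the UKHLS-like panel.
    """
    if n_survey is None:
        n_survey = 50_000 if condition == "depression" else 35_000
    undiag = solve_undiag_coefs(condition, targets=targets)
    return GeneratorConfig(
        n_survey=n_survey,
        disease_coefs=dict(DISEASE_COEFS[condition]),
        undiag_coefs=undiag,
        seed=seed,
    )
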