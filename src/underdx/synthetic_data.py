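"""Synthetic survey, population, QOF-style and adjacency fixtures.

Emulates the structure of the real inputs — an HSE-like cross-sectional
biomarker survey, a UKHLS-like longitudinal panel with "ever diagnosed"
carry-forward, ONS-like small-area population counts nested LSOA -> CCG ->
region, and a QOF-like table of diagnosed prevalence per planning area —
with known logistic ground truth so the whole pipeline can be checked by
parameter recovery.

The latent-status model: a person in segment s (age x sex x IMD x region) in
year t has the condition with probability expit(eta_disease(s, t)) and, given
the condition, is undiagnosed with probability expit(eta_undiag(s, t)), both
linear predictors given as named coefficient maps. Clinical measurements are
drawn on the signs side of the screening threshold with probability
``screening_sensitivity`` for cases (``1 - screening_specificity`` for
non-cases), uniformly within the implied side; the defaults of 1.0 make the
latent status coincide with "would screen positive or be diagnosed", which is
the operational estimand of the analysis.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import linear_predictor
from .levels import CONDITIONS, N_SEGMENTS, REGIONS, SEGMENT_VARS, YEARS, segment_frame

# measurement support per condition: (low, threshold, high); the screening
# rules are SBP > 140 (strict), HbA1c >= 48, MCS <= 42.
_MEASUREMENT_RANGES = {
    "hypertension": (90.0, 140.0, 220.0),  # signs side is (140, 220]
    "diabetes": (25.0, 48.0, 120.0),  # signs side is [48, 120]
    "depression": (10.0, 42.0, 70.0),  # signs side is [10, 42]
}


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child stream of a single root seed."""
    digest = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(digest,)))


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic survey + population fixture."""

    n_survey: int = 35_000
    years: tuple[int, ...] = YEARS
    segment_probs: np.ndarray | None = None  # over segment_frame() order; None = default mix
    disease_coefs: dict[str, float] = field(default_factory=lambda: {"intercept": -2.0})
    undiag_coefs: dict[str, float] = field(default_factory=lambda: {"intercept": -1.0})
    screening_sensitivity: float = 1.0
    screening_specificity: float = 1.0
    weight_dispersion: float = 0.3
    n_regions: int = 9
    n_ccgs: int = 191
    lsoas_per_ccg: int = 8
    pop_cell_mean: float = 2000.0
    retention: float = 0.78  # per-wave stay probability for the longitudinal panel
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_survey <= 0:
            raise ValueError("n_survey must be positive")
        if len(self.years) == 0:
            raise ValueError("years must be non-empty")
        if self.n_regions != len(REGIONS):
            raise ValueError(f"n_regions must be {len(REGIONS)} (fixed level table)")
        if self.n_ccgs < 1:
            raise ValueError("n_ccgs must be at least 1")
        for name in ("screening_sensitivity", "screening_specificity", "retention"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.segment_probs is not None:
            p = np.asarray(self.segment_probs, dtype=float)
            if p.shape != (N_SEGMENTS,):
                raise ValueError(f"segment_probs must have length {N_SEGMENTS}")
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("segment_probs must be nonnegative and sum to 1")
            object.__setattr__(self, "segment_probs", p)

    def resolved_segment_probs(self) -> np.ndarray:
        if self.segment_probs is not None:
            return self.segment_probs
        return default_segment_probs()


_AGE_SHARES = {  # adult population mix, chosen once for the default fixture
    "18-29": 0.20,
    "30-49": 0.33,
    "50-59": 0.16,
    "60-69": 0.14,
    "70-79": 0.11,
    "80+": 0.06,
}


def default_segment_probs() -> np.ndarray:
    seg = segment_frame()
    p = seg["age_group"].map(_AGE_SHARES).to_numpy()
    p = p / p.sum()
    return p


@dataclass
class TruthRecord:
    """Ground truth carried alongside a generated fixture.

    ``national_fraction[year]`` is the population-weighted true undiagnosed
    fraction sum_s P_s p_dis(s,y) p_und(s,y) / sum_s P_s p_dis(s,y); the
    pooled fraction averages numerator and denominator over years. Area-level
    expectations are attached by :func:`attach_area_truth` once a population
    table exists.
    """

    condition: str
    disease_coefs: dict[str, float]
    undiag_coefs: dict[str, float]
    years: tuple[int, ...]
    national_fraction: dict[int, float]
    pooled_fraction: float
    area_table: pd.DataFrame | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "condition": self.condition,
            "disease_coefs": self.disease_coefs,
            "undiag_coefs": self.undiag_coefs,
            "years": list(self.years),
            "national_fraction": {str(k): v for k, v in self.national_fraction.items()},
            "pooled_fraction": self.pooled_fraction,
        }
        if self.area_table is not None:
            payload["area_table"] = self.area_table.to_dict(orient="list")
        Path(path).write_text(json.dumps(payload, indent=1))


def segment_probabilities(config: GeneratorConfig, condition: str, year: int) -> pd.DataFrame:
    """True per-segment P(disease) and P(undiagnosed | disease) for one year."""
    seg = segment_frame().copy()
    seg["year"] = year
    seg["p_disease"] = expit(linear_predictor(seg, config.disease_coefs))
    seg["p_undiag"] = expit(linear_predictor(seg, config.undiag_coefs))
    return seg


def _national_truth(config: GeneratorConfig) -> tuple[dict[int, float], float]:
    probs = config.resolved_segment_probs()
    national = {}
    num_pool = den_pool = 0.0
    for year in config.years:
        seg = segment_probabilities(config, "", year)
        num = float(np.sum(probs * seg["p_disease"] * seg["p_undiag"]))
        den = float(np.sum(probs * seg["p_disease"]))
        national[year] = num / den
        num_pool += num
        den_pool += den
    return national, num_pool / den_pool


def _truth(config: GeneratorConfig, condition: str) -> TruthRecord:
    national, pooled = _national_truth(config)
    return TruthRecord(
        condition=condition,
        disease_coefs=dict(config.disease_coefs),
        undiag_coefs=dict(config.undiag_coefs),
        years=tuple(config.years),
        national_fraction=national,
        pooled_fraction=pooled,
    )


def _draw_measurement(rng, signs: np.ndarray, condition: str) -> np.ndarray:
    lo, thr, hi = _MEASUREMENT_RANGES[condition]
    u = rng.random(len(signs))
    if condition == "hypertension":  # signs strictly above threshold
        return np.where(signs, thr + u * (hi - thr), lo + u * (thr - lo))
    if condition == "diabetes":  # signs at or above threshold
        return np.where(signs, thr + u * (hi - thr), lo + u * (thr - lo) * (1 - 1e-9))
    # depression: signs at or below threshold
    return np.where(signs, lo + u * (thr - lo), thr + (u * (hi - thr)) * (1 - 1e-9) + 1e-9)


def _draw_weights(rng, n: int, dispersion: float) -> np.ndarray:
    w = rng.lognormal(mean=0.0, sigma=dispersion, size=n)
    return w / w.mean()


def generate_survey(config: GeneratorConfig, condition: str) -> tuple[pd.DataFrame, TruthRecord]:
    """Generate one survey table plus its ground truth.

    Diabetes and hypertension yield a cross-sectional table (one row per
    person, HSE-like); depression yields a longitudinal panel (one row per
    person-wave, UKHLS-like) in which the self-report flag follows the
    ever-diagnosed convention: once reported, reported at every later wave.
    Columns: person_id, year, age_group, sex, region, imd_quintile, weight,
    measurement, self_report.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    if condition == "depression":
        return _generate_panel(config, condition)
    return _generate_cross_sectional(config, condition)


def _draw_segments(rng, config: GeneratorConfig, n: int) -> pd.DataFrame:
    seg = segment_frame()
    idx = rng.choice(N_SEGMENTS, size=n, p=config.resolved_segment_probs())
    return seg.iloc[idx].reset_index(drop=True)


def _generate_cross_sectional(config, condition):
    rng = _substream(config.seed, f"survey:{condition}")
    n = config.n_survey
    df = _draw_segments(rng, config, n)
    df["year"] = rng.choice(np.asarray(config.years), size=n)
    df["person_id"] = np.arange(n)
    df["weight"] = _draw_weights(rng, n, config.weight_dispersion)

    p_dis = expit(linear_predictor(df, config.disease_coefs))
    disease = rng.random(n) < p_dis
    p_und = expit(linear_predictor(df, config.undiag_coefs))
    undiag = disease & (rng.random(n) < p_und)
    df["self_report"] = disease & ~undiag

    signs = np.where(
        disease,
        rng.random(n) < config.screening_sensitivity,
        rng.random(n) < 1.0 - config.screening_specificity,
    )
    df["measurement"] = _draw_measurement(rng, signs, condition)
    cols = ["person_id", "year", *SEGMENT_VARS, "weight", "measurement", "self_report"]
    return df[cols], _truth(config, condition)


def _generate_panel(config, condition):
    rng = _substream(config.seed, f"survey:{condition}")
    n = config.n_survey  # persons
    persons = _draw_segments(rng, config, n)
    years = np.asarray(sorted(config.years))
    entry = rng.choice(years, size=n)
    # geometric stay: person observed from entry until dropout or final year
    stay = rng.geometric(1.0 - config.retention, size=n) if config.retention < 1 else None
    last = years[-1] if stay is None else np.minimum(entry + stay - 1, years[-1])

    # persistent latent disease per person, drawn at entry
    persons["year"] = entry
    p_dis = expit(linear_predictor(persons, config.disease_coefs))
    disease = rng.random(n) < p_dis
    # a single uniform per person defines the diagnosis time: undiagnosed at
    # year t iff u < P(undiagnosed | disease, segment, t); with a
    # non-increasing truth this reproduces the per-year marginal exactly and
    # makes the report flag monotone (ever-diagnosed carry-forward).
    u_diag = rng.random(n)
    sens_draw = rng.random  # per-wave screening draws below

    n_waves = (last - entry + 1).astype(int)
    person_idx = np.repeat(np.arange(n), n_waves)
    wave_year = np.concatenate([np.arange(e, l + 1) for e, l in zip(entry, last)])

    df = persons.iloc[person_idx][list(SEGMENT_VARS)].reset_index(drop=True)
    df["person_id"] = person_idx
    df["year"] = wave_year
    m = len(df)

    dis_rows = disease[person_idx]
    p_und_rows = expit(linear_predictor(df, config.undiag_coefs))
    undiag_rows = dis_rows & (u_diag[person_idx] < p_und_rows)
    raw_report = dis_rows & ~undiag_rows
    # enforce carry-forward even if a non-monotone truth was supplied
    rep = pd.Series(raw_report).groupby(person_idx).cummax().to_numpy()
    df["self_report"] = rep

    signs = np.where(
        dis_rows,
        sens_draw(m) < config.screening_sensitivity,
        sens_draw(m) < 1.0 - config.screening_specificity,
    )
    df["measurement"] = _draw_measurement(rng, signs, condition)
    df["weight"] = _draw_weights(rng, m, config.weight_dispersion)
    df = df.sort_values(["person_id", "year"], kind="stable").reset_index(drop=True)
    cols = ["person_id", "year", *SEGMENT_VARS, "weight", "measurement", "self_report"]
    return df[cols], _truth(config, condition)


# ---------------------------------------------------------------------------
# population, QOF and adjacency fixtures


def generate_population(config: GeneratorConfig) -> pd.DataFrame:
    """LSOA x age group x sex population counts nested in CCGs and regions.

    CCGs are assigned to regions in contiguous blocks; each CCG holds
    ``lsoas_per_ccg`` LSOAs cycling through the five IMD quintiles so every
    (region, IMD) combination is populated. The national total
    ``n_ccgs * lsoas_per_ccg * 12 * pop_cell_mean`` is allocated to segments
    by a multinomial draw on ``segment_probs`` and spread uniformly across
    the LSOAs sharing each segment's (region, IMD).
    """
    if config.lsoas_per_ccg < 1:
        raise ValueError("lsoas_per_ccg must be at least 1")
    rng = _substream(config.seed, "population")
    n_ccgs, per = config.n_ccgs, config.lsoas_per_ccg

    ccg_ids = [f"CCG{str(i + 1).zfill(3)}" for i in range(n_ccgs)]
    ccg_region = [REGIONS[i * len(REGIONS) // n_ccgs] for i in range(n_ccgs)]
    lsoa = pd.DataFrame(
        {
            "lsoa_id": [f"LSOA{str(i + 1).zfill(5)}" for i in range(n_ccgs * per)],
            "ccg_id": np.repeat(ccg_ids, per),
            "region": np.repeat(ccg_region, per),
            "imd_quintile": [(i % 5) + 1 for i in range(n_ccgs * per)],
        }
    )

    seg = segment_frame()
    total = int(round(n_ccgs * per * 12 * config.pop_cell_mean))
    if total == 0:
        seg_counts = np.zeros(N_SEGMENTS, dtype=int)
    else:
        seg_counts = rng.multinomial(total, config.resolved_segment_probs())

    # LSOAs eligible for each (region, imd); spread each segment's count
    groups = {k: v.to_numpy() for k, v in lsoa.groupby(["region", "imd_quintile"]).groups.items()}
    records = []
    for (row, count) in zip(seg.itertuples(index=False), seg_counts):
        members = groups[(row.region, row.imd_quintile)]
        if count > 0:
            alloc = rng.multinomial(count, np.full(len(members), 1.0 / len(members)))
        else:
            alloc = np.zeros(len(members), dtype=int)
        for pos, c in zip(members, alloc):
            records.append((pos, row.age_group, row.sex, int(c)))
    alloc_df = pd.DataFrame(records, columns=["_pos", "age_group", "sex", "count"])
    out = alloc_df.merge(lsoa.reset_index().rename(columns={"index": "_pos"}), on="_pos")
    out = out[["lsoa_id", "ccg_id", "region", "imd_quintile", "age_group", "sex", "count"]]
    out = out.sort_values(["lsoa_id", "age_group", "sex"], kind="stable").reset_index(drop=True)
    out.attrs["national_total"] = total
    return out


def attach_area_truth(
    truth: TruthRecord, config: GeneratorConfig, population: pd.DataFrame, years: tuple[int, ...]
) -> TruthRecord:
    """Compute per-CCG expected undiagnosed proportion and diagnosed prevalence."""
    tables = []
    for year in years:
        seg = segment_probabilities(config, truth.condition, year)
        merged = population.merge(seg, on=list(SEGMENT_VARS), how="left")
        merged["e_dis"] = merged["count"] * merged["p_disease"]
        merged["e_und"] = merged["e_dis"] * merged["p_undiag"]
        g = merged.groupby("ccg_id").agg(
            pop=("count", "sum"), e_dis=("e_dis", "sum"), e_und=("e_und", "sum")
        )
        tables.append(
            pd.DataFrame(
                {
                    "ccg_id": g.index,
                    "year": year,
                    "expected_prop_undiag": g["e_und"] / g["e_dis"],
                    "diagnosed_prevalence": (g["e_dis"] - g["e_und"]) / g["pop"],
                }
            ).reset_index(drop=True)
        )
    return replace(truth, area_table=pd.concat(tables, ignore_index=True))


def generate_qof_table(truth: TruthRecord, noise_sd: float, seed: int) -> pd.DataFrame:
    """QOF-like diagnosed prevalence per CCG: area truth plus truncated noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if truth.area_table is None:
        raise ValueError("truth has no area table; call attach_area_truth first")
    rng = _substream(seed, "qof")
    base = truth.area_table.drop_duplicates("ccg_id", keep="last")
    prev = base["diagnosed_prevalence"].to_numpy()
    noisy = np.clip(prev + rng.normal(0.0, noise_sd, len(prev)) if noise_sd > 0 else prev, 0.0, 1.0)
    return pd.DataFrame(
        {"ccg_id": base["ccg_id"].to_numpy(), "condition": truth.condition, "diagnosed_prevalence": noisy}
    )


def generate_adjacency(config: GeneratorConfig) -> pd.DataFrame:
    """Symmetric, connected ring-plus-chords adjacency over the CCGs.

    Each area links to its two ring neighbours plus a chord to the area
    halfway around the ring, so every area has degree >= 2 (degree >= 3 for
    n >= 5) and the graph is connected.
    """
    n = config.n_ccgs
    if n < 2:
        raise ValueError("need at least 2 areas for an adjacency structure")
    ids = [f"CCG{str(i + 1).zfill(3)}" for i in range(n)]
    pairs = set()
    for i in range(n):
        pairs.add(tuple(sorted((i, (i + 1) % n))))
        pairs.add(tuple(sorted((i, (i + n // 2) % n))))
    pairs = sorted(p for p in pairs if p[0] != p[1])
    return pd.DataFrame([(ids[a], ids[b]) for a, b in pairs], columns=["area_a", "area_b"])
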