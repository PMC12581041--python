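"""Sensitivity layers: QOF-style comparison, PPV adjustment, alternative threshold.

Three checks on the main survey-based estimates:

* comparing survey-estimated total prevalence against an external diagnosed
  prevalence per area (QOF-like registers) gives an alternative undiagnosed
  fraction (total - diagnosed) / total;
* a screening instrument with positive predictive value below one inflates
  the apparent undiagnosed share; ``ppv_adjusted_fraction`` discounts the
  screen-positive-only group accordingly;
* re-running the whole pipeline under a lower (more severe) MCS threshold
  for depression probes the dependence on the case definition.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def undiagnosed_from_prevalence(total_prevalence, diagnosed_prevalence):
    """Undiagnosed fraction implied by total vs diagnosed prevalence.

    Elementwise ``(total - diagnosed) / total``; values where diagnosed
    exceeds total are clamped to 0 with a warning, and a zero total yields
    NaN (flagged) rather than a division error. Inputs must lie in [0, 1].
    """
    t = np.asarray(total_prevalence, dtype=float)
    d = np.asarray(diagnosed_prevalence, dtype=float)
    for name, x in (("total", t), ("diagnosed", d)):
        if np.any((x < 0) | (x > 1)):
            raise ValueError(f"{name} prevalence must be in [0, 1]")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(t > 0, (t - d) / np.where(t > 0, t, 1.0), np.nan)
    n_neg = int(np.sum(frac < 0))
    if n_neg:
        warnings.warn(
            f"diagnosed prevalence exceeds total in {n_neg} area(s); clamping to 0"
        )
        frac = np.clip(frac, 0.0, None)
    return frac if frac.ndim else float(frac)


def ppv_adjusted_fraction(raw_fraction: float, ppv: float) -> float:
    """Discount the undiagnosed share for screening false positives.

    Among apparent cases, a share U = ``raw_fraction`` is screen-positive
    without a diagnosis and D = 1 - U self-reports a diagnosis (taken at face
    value). If only ``ppv`` of the screen-positives truly have the condition,
    the adjusted undiagnosed fraction is ppv*U / (ppv*U + D).
    """
    for name, x in (("raw_fraction", raw_fraction), ("ppv", ppv)):
        if not 0.0 <= x <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    u, d = raw_fraction, 1.0 - raw_fraction
    denom = ppv * u + d
    if denom == 0.0:
        raise ZeroDivisionError("ppv * raw + (1 - raw) is zero; adjustment undefined")
    return ppv * u / denom


def qof_compare(total_prevalence: pd.DataFrame, qof: pd.DataFrame) -> pd.DataFrame:
    """Join survey-based total prevalence with QOF-like diagnosed prevalence.

    ``total_prevalence`` needs columns ``ccg_id``, ``total_prevalence``; the
    QOF table needs ``ccg_id``, ``diagnosed_prevalence``. Returns one row per
    area with the implied undiagnosed fraction.
    """
    merged = total_prevalence.merge(qof[["ccg_id", "diagnosed_prevalence"]], on="ccg_id")
    merged["undiagnosed_fraction"] = undiagnosed_from_prevalence(
        merged["total_prevalence"].to_numpy(), merged["diagnosed_prevalence"].to_numpy()
    )
    return merged


def threshold_sensitivity_run(run_condition, base_rule, alternative_threshold: float, **kwargs):
    """Re-run a condition pipeline under an alternative signs threshold.

    ``run_condition`` is the pipeline entry point (dependency-injected to
    keep this module import-light); the rule's threshold is overridden and
    everything downstream re-executed. A threshold at least as permissive as
    the primary one is allowed but warned about.
    """
    if alternative_threshold >= base_rule.signs_threshold:
        warnings.warn(
            "alternative threshold is not stricter than the primary one; "
            "running anyway"
        )
    rule = base_rule.with_threshold(alternative_threshold)
    return run_condition(rule=rule, **kwargs)
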