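"""Global Moran's I and its permutation test.

Used to ask whether the 2011->2019 change in the proportion undiagnosed is
spatially clustered across planning areas. Weights default to row-standardised
binary adjacency; significance comes from random relabelling of the values
over areas (plus-one permutation p-value, so p >= 1/(n_perm + 1)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SpatialWeights:
    """Dense spatial weight matrix over ordered area ids."""

    area_ids: list
    matrix: np.ndarray  # (n, n), zero diagonal
    row_standardised: bool

    def __post_init__(self) -> None:
        w = self.matrix
        n = len(self.area_ids)
        if w.shape != (n, n):
            raise ValueError("weight matrix shape does not match area ids")
        if np.any(np.diag(w) != 0):
            raise ValueError("self-weights must be zero")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if self.row_standardised:
            sums = w.sum(axis=1)
            nz = sums > 0
            if not np.allclose(sums[nz], 1.0, atol=1e-9):
                raise ValueError("row-standardised rows must sum to 1")

    @classmethod
    def from_adjacency(cls, adjacency: pd.DataFrame, row_standardise: bool = True):
        """Build from an edge list with columns ``area_a``, ``area_b``."""
        ids = sorted(set(adjacency["area_a"]) | set(adjacency["area_b"]))
        index = {a: i for i, a in enumerate(ids)}
        w = np.zeros((len(ids), len(ids)))
        for a, b in zip(adjacency["area_a"], adjacency["area_b"]):
            if a == b:
                continue
            w[index[a], index[b]] = 1.0
            w[index[b], index[a]] = 1.0
        if row_standardise:
            sums = w.sum(axis=1, keepdims=True)
            w = np.divide(w, sums, out=np.zeros_like(w), where=sums > 0)
        return cls(ids, w, row_standardise)


def _check(values: np.ndarray, weights: SpatialWeights) -> np.ndarray:
    z = np.asarray(values, dtype=float)
    if len(z) != len(weights.area_ids):
        raise ValueError("values length does not match number of areas")
    if len(z) < 2:
        raise ValueError("Moran's I needs at least 2 areas")
    if np.isclose(z.var(), 0.0):
        raise ValueError("values have zero variance; Moran's I is undefined")
    return z - z.mean()


def _moran_from_centred(z: np.ndarray, w: np.ndarray, s0: float) -> float:
    return float(len(z) / s0 * (z @ w @ z) / (z @ z))


def morans_i(values, weights: SpatialWeights) -> float:
    """I = (n / S0) * (sum_ij w_ij z_i z_j) / (sum_i z_i^2), z centred."""
    z = _check(values, weights)
    return _moran_from_centred(z, weights.matrix, weights.matrix.sum())


def expected_i(n: int) -> float:
    """Expectation of I under the spatial-randomness null: -1/(n-1)."""
    return -1.0 / (n - 1)


def permutation_test(
    values,
    weights: SpatialWeights,
    n_perm: int = 9_999,
    alternative: str = "two-sided",
    seed: int = 0,
) -> dict[str, float]:
    """Permutation test of Moran's I by random relabelling of areas.

    Two-sided p = (1 + #{|I_perm| >= |I_obs|}) / (n_perm + 1); ``greater`` and
    ``less`` use the corresponding one-sided exceedances.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    z = _check(values, weights)
    w, s0 = weights.matrix, weights.matrix.sum()
    i_obs = _moran_from_centred(z, w, s0)
    rng = np.random.default_rng(seed)
    zz = z @ z  # invariant under permutation
    sims = np.empty(n_perm)
    for k in range(n_perm):
        zp = rng.permutation(z)
        sims[k] = len(z) / s0 * (zp @ w @ zp) / zz
    if alternative == "two-sided":
        exceed = np.abs(sims) >= abs(i_obs) - 1e-15
    elif alternative == "greater":
        exceed = sims >= i_obs - 1e-15
    else:
        exceed = sims <= i_obs + 1e-15
    p = (1 + int(exceed.sum())) / (n_perm + 1)
    return {
        "I": i_obs,
        "expected_I": expected_i(len(z)),
        "p_value": p,
        "n_perm": n_perm,
        "perm_mean": float(sims.mean()),
    }
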