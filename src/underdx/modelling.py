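"""Survey-weighted logistic regression with stepwise-AIC interaction selection.

The undiagnosed-fraction model regresses, among people with disease (clinical
signs or a diagnosis), the indicator of having no diagnosis on age group, sex,
deprivation quintile, region and a linear year trend, with two-way
interactions chosen by bidirectional stepwise search on the Akaike
information criterion.

Fitting maximises the weighted log-pseudo-likelihood

    l(b) = sum_i w_i [ y_i log p_i + (1 - y_i) log(1 - p_i) ],
    p_i = expit(x_i' b),

by Newton iteration (iteratively reweighted least squares), with survey
weights normalised to mean one beforehand so the AIC behaves like a
sample-size-n quantity. The coefficient covariance is the inverse of the
weighted information matrix at the optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.special import expit
from scipy.stats import chi2

from .design import ModelSpec, build_design

logger = logging.getLogger(__name__)

_EPS = 1e-12


class SeparationError(RuntimeError):
    """Raised when the likelihood has no finite maximiser (complete separation)."""


class FitError(RuntimeError):
    """Raised when the Newton iteration fails to converge."""


@dataclass
class FittedModel:
    """A fitted weighted logistic model.

    ``params``/``cov`` are indexed by design column names. ``llf`` is the
    weighted log-pseudo-likelihood at the optimum and ``aic = -2 llf + 2 k``
    with ``k`` the rank of the information matrix.
    """

    spec: ModelSpec
    params: pd.Series
    cov: pd.DataFrame
    llf: float
    aic: float
    n_obs: int
    rank: int
    converged: bool
    n_iter: int

    @property
    def column_names(self) -> list[str]:
        return list(self.params.index)

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        X, _ = build_design(df, self.spec)
        return expit(X @ self.params.to_numpy())

    def simulate_coefs(self, n_sim: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n_sim`` coefficient vectors from N(params, cov)."""
        cov = self.cov.to_numpy()
        # symmetrise and clip tiny negative eigenvalues from finite arithmetic
        cov = (cov + cov.T) / 2.0
        vals, vecs = np.linalg.eigh(cov)
        root = vecs * np.sqrt(np.clip(vals, 0.0, None))
        z = rng.standard_normal((n_sim, len(vals)))
        return self.params.to_numpy() + z @ root.T


def weighted_loglik(y: np.ndarray, p: np.ndarray, w: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(np.sum(w * (y * np.log(p) + (1.0 - y) * np.log1p(-p))))


def _irls(X, y, w, start=None, tol=1e-10, max_iter=100):
    n, k = X.shape
    beta = np.zeros(k) if start is None else np.asarray(start, dtype=float).copy()
    ll = weighted_loglik(y, expit(X @ beta), w)
    rank = k
    for it in range(1, max_iter + 1):
        p = expit(X @ beta)
        s = w * p * (1.0 - p)
        grad = X.T @ (w * (y - p))
        H = (X * s[:, None]).T @ X
        try:
            step = cho_solve(cho_factor(H), grad)
        except (LinAlgError, np.linalg.LinAlgError):
            # aliased columns: fall back to minimum-norm Newton step
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
            rank = np.linalg.matrix_rank(H)
        # step-halving keeps the weighted log-likelihood non-decreasing
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = weighted_loglik(y, expit(X @ cand), w)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        beta = beta + scale * step
        ll = ll_new
        if np.max(np.abs(scale * step)) < tol:
            return beta, ll, H, rank, True, it
    return beta, ll, H, rank, False, max_iter


def fit_logit(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    columns: list[str] | None = None,
    spec: ModelSpec | None = None,
    start: np.ndarray | None = None,
) -> FittedModel:
    """Weighted logistic fit on a raw design matrix (lower-level entry point).

    ``fit_weighted_logistic`` builds the design from a spec and delegates
    here. Weights are normalised to mean one; separation and non-convergence
    raise as documented there.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    w = w / w.mean()
    if y.min() == y.max():
        raise SeparationError("outcome is constant; model is degenerate")
    if X.shape[0] <= X.shape[1]:
        raise ValueError(f"{X.shape[0]} rows cannot support {X.shape[1]} coefficients")
    cols = columns if columns is not None else [f"x{j}" for j in range(X.shape[1])]

    beta, ll, H, rank, converged, n_iter = _irls(X, y, w, start=start)
    if np.max(np.abs(beta)) > 30.0:
        raise SeparationError(
            "diverging coefficients indicate (quasi-)complete separation "
            f"(max |beta| = {np.max(np.abs(beta)):.1f})"
        )
    if not converged:
        raise FitError(f"IRLS did not converge in {n_iter} iterations")
    try:
        cov = cho_solve(cho_factor(H), np.eye(len(cols)))
    except (LinAlgError, np.linalg.LinAlgError):
        cov = np.linalg.pinv(H)
    return FittedModel(
        spec=spec,
        params=pd.Series(beta, index=cols),
        cov=pd.DataFrame(cov, index=cols, columns=cols),
        llf=ll,
        aic=-2.0 * ll + 2.0 * rank,
        n_obs=len(y),
        rank=rank,
        converged=converged,
        n_iter=n_iter,
    )


def fit_weighted_logistic(
    df: pd.DataFrame,
    outcome: str,
    spec: ModelSpec,
    weights: str | np.ndarray = "weight",
    start: pd.Series | None = None,
) -> FittedModel:
    """Fit the weighted logistic model defined by ``spec`` on ``df``.

    ``outcome`` must be a binary column; weights must be strictly positive and
    are normalised to mean one. Complete separation (and an all-0/all-1
    outcome) raises :class:`SeparationError`; non-convergence raises
    :class:`FitError`.
    """
    y = df[outcome].to_numpy(dtype=float)
    w = df[weights].to_numpy(dtype=float) if isinstance(weights, str) else np.asarray(weights, float)
    X, cols = build_design(df, spec)
    start_vec = None
    if start is not None:
        start_vec = np.array([start.get(c, 0.0) for c in cols])
    return fit_logit(X, y, w, columns=cols, spec=spec, start=start_vec)


@dataclass
class StepRecord:
    action: str  # "start", "drop", "add"
    term: str
    aic: float


def _term_label(term) -> str:
    return "year" if term == "year" else f"{term[0]}:{term[1]}"


def stepwise_aic(
    df: pd.DataFrame,
    outcome: str,
    spec: ModelSpec,
    weights: str | np.ndarray = "weight",
    year_droppable: bool = False,
) -> tuple[FittedModel, list[StepRecord]]:
    """Bidirectional stepwise selection over two-way interactions by AIC.

    Starts from ``spec`` (conventionally the full candidate model), at each
    step evaluating every single-term drop from and add to the current
    interaction set, accepting the move with the lowest AIC if it improves on
    the current one; ties break toward the smaller model. Main effects are
    never dropped; the linear year trend joins the droppable set only when
    ``year_droppable`` is true and no selected interaction involves year.
    Returns the final fit and the selection path (monotone decreasing AIC).
    """

    def _fit(cur_spec, warm):
        try:
            return fit_weighted_logistic(df, outcome, cur_spec, weights, start=warm)
        except (SeparationError, FitError) as err:
            logger.warning("stepwise: skipping %s (%s)", cur_spec.interactions, err)
            return None

    current = _fit(spec, None)
    if current is None:
        # full starting model is unstable (sparse cells); restart from main
        # effects only and let the add-steps recover whatever fits
        logger.warning("stepwise: starting model failed; restarting from main effects")
        current = _fit(spec.with_interactions(()), None)
        if current is None:
            raise FitError("the starting model failed to fit")
    path = [StepRecord("start", "", current.aic)]

    while True:
        moves: list[tuple[str, object, ModelSpec]] = []
        selected = list(current.spec.interactions)
        for term in selected:
            rest = tuple(t for t in selected if t != term)
            moves.append(("drop", term, current.spec.with_interactions(rest)))
        for term in current.spec.candidates:
            if term not in selected and (current.spec.include_year or "year" not in term):
                moves.append(("add", term, current.spec.with_interactions((*selected, term))))
        if year_droppable:
            year_in_use = any("year" in t for t in selected)
            if current.spec.include_year and not year_in_use:
                moves.append(
                    ("drop", "year", ModelSpec(tuple(selected), False, current.spec.candidates))
                )
            elif not current.spec.include_year:
                moves.append(
                    ("add", "year", ModelSpec(tuple(selected), True, current.spec.candidates))
                )

        best = None
        for action, term, cand_spec in moves:
            fit = _fit(cand_spec, current.params)
            if fit is None:
                continue
            key = (fit.aic, fit.rank)  # ties toward the smaller model
            if fit.aic < current.aic - 1e-9 and (best is None or key < (best[0].aic, best[0].rank)):
                best = (fit, action, term)
        if best is None:
            return current, path
        current, action, term = best
        path.append(StepRecord(action, _term_label(term), current.aic))


def hosmer_lemeshow(
    p_hat: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    n_groups: int = 10,
) -> tuple[float, int, float]:
    """Hosmer-Lemeshow goodness-of-fit test on (weighted) deciles of risk.

    Rows are sorted by predicted probability and cut into ``n_groups`` groups
    of equal total weight; the statistic sums (O - E)^2 / (E (1 - E/n)) over
    groups and is referred to chi-square with ``n_groups - 2`` df. When there
    are fewer distinct predictions than groups, the group count is reduced
    with a warning. Returns ``(statistic, df, p_value)``.
    """
    if n_groups < 2:
        raise ValueError("n_groups must be at least 2")
    p_hat = np.asarray(p_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(p_hat) if weights is None else np.asarray(weights, dtype=float)

    n_distinct = len(np.unique(p_hat))
    if n_distinct < n_groups:
        logger.warning(
            "hosmer_lemeshow: only %d distinct predictions; reducing groups from %d",
            n_distinct,
            n_groups,
        )
        n_groups = max(2, n_distinct)

    order = np.argsort(p_hat, kind="stable")
    p_s, y_s, w_s = p_hat[order], y[order], w[order]
    cum_w = np.cumsum(w_s)
    edges = cum_w[-1] * np.arange(1, n_groups) / n_groups
    group = np.searchsorted(cum_w - 1e-12 * cum_w[-1], edges).tolist()
    bounds = [0, *group, len(p_s)]

    stat = 0.0
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi <= lo:
            continue
        n_g = w_s[lo:hi].sum()
        obs = (w_s[lo:hi] * y_s[lo:hi]).sum()
        exp = (w_s[lo:hi] * p_s[lo:hi]).sum()
        denom = exp * (1.0 - exp / n_g)
        if denom <= 0:
            continue
        stat += (obs - exp) ** 2 / denom
    df = n_groups - 2
    return float(stat), df, float(chi2.sf(stat, df))
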