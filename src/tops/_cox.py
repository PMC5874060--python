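"""Newton-Raphson solver for the Cox proportional-hazards partial likelihood.

Breslow handling of tied event times, optional ridge penalty for numerical
stability on small or near-degenerate risk sets.  Vectorized so that a fit on
a few thousand subjects with a handful of covariates costs milliseconds; the
tree construction performs hundreds of such fits per split search.
"""

from __future__ import annotations

import numpy as np


class CoxConvergenceError(RuntimeError):
    """Raised when the Newton iteration fails to converge."""


def _risk_set_sums(Xs: np.ndarray, w: np.ndarray, group_end: np.ndarray):
    """Cumulative risk-set sums S0, S1, S2 for rows sorted by descending time.

    ``group_end[i]`` is the index of the last row sharing row i's time, so the
    risk set {j : t_j >= t_i} includes all tied rows.
    """
    S0 = np.cumsum(w)[group_end]
    S1 = np.cumsum(w[:, None] * Xs, axis=0)[group_end]
    outer = Xs[:, :, None] * Xs[:, None, :]
    S2 = np.cumsum(w[:, None, None] * outer, axis=0)[group_end]
    return S0, S1, S2


def fit_cox(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    ridge: float = 1e-4,
    tol: float = 1e-8,
    max_iter: int = 60,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit Cox regression; return (beta, event_times, baseline_cumhaz).

    ``baseline_cumhaz[k]`` is the Breslow cumulative baseline hazard at
    ``event_times[k]`` (distinct event times, ascending), evaluated at
    covariate value 0 — callers standardize X, so "0" is the training mean.
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    n, d = X.shape
    if event.sum() == 0:
        raise CoxConvergenceError("no events in training subset")

    order = np.argsort(-time, kind="stable")
    Xs, ts, es = X[order], time[order], event[order]

    # index of the last row of each tied-time group (descending order)
    _, inv = np.unique(-ts, return_inverse=True)
    group_end = np.zeros(inv.max() + 1, dtype=np.int64)
    np.maximum.at(group_end, inv, np.arange(n))
    group_end = group_end[inv]

    beta = np.zeros(d)
    eye = np.eye(d)
    converged = False
    for _ in range(max_iter):
        eta = Xs @ beta
        eta -= eta.max()  # rescale; partial likelihood is shift-invariant
        w = np.exp(eta)
        S0, S1, S2 = _risk_set_sums(Xs, w, group_end)
        xbar = S1 / S0[:, None]
        score = (es[:, None] * (Xs - xbar)).sum(axis=0) - ridge * beta
        info = (
            es[:, None, None]
            * (S2 / S0[:, None, None] - xbar[:, :, None] * xbar[:, None, :])
        ).sum(axis=0) + ridge * eye
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate
            raise CoxConvergenceError(f"singular information matrix: {exc}") from exc
        if not np.all(np.isfinite(step)):
            raise CoxConvergenceError("non-finite Newton step")
        # dampen very large steps (separation / monotone likelihood)
        norm = np.abs(step).max()
        if norm > 10.0:
            step *= 10.0 / norm
        beta = beta + step
        if norm < tol:
            converged = True
            break
    if not converged and np.abs(step).max() > 1e-4:
        raise CoxConvergenceError("Newton iteration did not converge")

    # Breslow baseline cumulative hazard at beta (covariates already centered)
    eta = Xs @ beta
    w = np.exp(eta - eta.max())
    S0 = np.cumsum(w)[group_end] * np.exp(eta.max())
    ev = es > 0
    ev_times = ts[ev]
    increments = 1.0 / S0[ev]
    # rows are in descending time: reverse to ascending, merge ties
    ev_times = ev_times[::-1]
    increments = increments[::-1]
    uniq_times, start = np.unique(ev_times, return_index=True)
    summed = np.add.reduceat(increments, start)
    cumhaz = np.cumsum(summed)
    return beta, uniq_times, cumhaz


def baseline_survival_at(
    event_times: np.ndarray, cumhaz: np.ndarray, horizon: float
) -> float:
    """Breslow baseline survival S0(horizon) = exp(-H0(horizon))."""
    idx = np.searchsorted(event_times, horizon, side="right")
    h0 = cumhaz[idx - 1] if idx > 0 else 0.0
    return float(np.exp(-h0))
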