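"""The base class R of learners: Cox regression, a linear probability model
("linear perceptron"), and logistic regression.

All three share one contract: fit on a subject subset, then score any
subject with a horizon mortality risk in [0, 1].

* COX fits a proportional-hazards model on (followup_time, event) — censored
  subjects participate natively — and converts to horizon risk through the
  Breslow baseline survival: risk = 1 - S0(h)^exp(eta).
* LINEAR fits ordinary least squares on the 0/1 horizon labels and clips the
  output to [0, 1].
* LOGISTIC fits a near-unregularized L2 logistic model (inverse strength
  1e4) so that near-separable small clusters still converge.

Binary learners train only on horizon-included subjects (the censoring
discard rule defines the binary view); Cox uses every subject of the subset.
Continuous covariates are standardized on the training subset inside the
learner; the transform is reused at scoring time.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from ._cox import CoxConvergenceError, baseline_survival_at, fit_cox
from .cohort import HorizonTask

_LOGISTIC_C = 1e4


class LearnerKind(IntEnum):
    """The base class R, in canonical (tie-breaking) order."""

    COX = 0
    LINEAR = 1
    LOGISTIC = 2


@dataclass
class FittedModel:
    """A fitted base learner mapping encoded covariates to horizon risk."""

    kind: LearnerKind
    columns: list[str]
    coef: np.ndarray
    intercept: float
    center: np.ndarray
    scale: np.ndarray
    baseline_survival: float | None = None  # S0(horizon), COX only
    training_node_id: int | None = None

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.center) / self.scale
        return Z @ self.coef + self.intercept

    def predict_risk_array(self, X: np.ndarray) -> np.ndarray:
        eta = self.linear_predictor(X)
        if self.kind == LearnerKind.COX:
            risk = 1.0 - self.baseline_survival ** np.exp(eta)
        elif self.kind == LearnerKind.LINEAR:
            risk = eta
        else:
            risk = 1.0 / (1.0 + np.exp(-eta))
        return np.clip(risk, 0.0, 1.0)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind.name,
            "columns": list(self.columns),
            "coef": [float(v) for v in self.coef],
            "intercept": float(self.intercept),
            "center": [float(v) for v in self.center],
            "scale": [float(v) for v in self.scale],
            "baseline_survival": None
            if self.baseline_survival is None
            else float(self.baseline_survival),
            "training_node_id": self.training_node_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        return cls(
            kind=LearnerKind[d["kind"]],
            columns=list(d["columns"]),
            coef=np.asarray(d["coef"], dtype=float),
            intercept=float(d["intercept"]),
            center=np.asarray(d["center"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            baseline_survival=d.get("baseline_survival"),
            training_node_id=d.get("training_node_id"),
        )


def _standardizer(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column center/scale; binary {0,1} columns are left untouched."""
    d = X.shape[1]
    center = np.zeros(d)
    scale = np.ones(d)
    for j in range(d):
        col = X[:, j]
        uniq = np.unique(col)
        if np.all(np.isin(uniq, (0.0, 1.0))):
            continue
        center[j] = col.mean()
        sd = col.std()
        scale[j] = sd if sd > 0 else 1.0
    return center, scale


def fit_learner_arrays(
    kind: LearnerKind,
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    label: np.ndarray,
    included: np.ndarray,
    rows: np.ndarray,
    horizon: float,
    columns: list[str],
    training_node_id: int | None = None,
) -> FittedModel:
    """Low-level fit on positional ``rows``; the tree's inner loop calls this."""
    rows = np.asarray(rows)
    if len(rows) == 0:
        raise ValueError("empty training subset")
    if kind == LearnerKind.COX:
        sub = rows
    else:
        sub = rows[included[rows]]
        if len(sub) == 0 or len(np.unique(label[sub])) < 2:
            raise ValueError(
                f"degenerate labels for {kind.name} on node {training_node_id}"
            )
    Xs = X[sub]
    center, scale = _standardizer(Xs)
    Z = (Xs - center) / scale

    if kind == LearnerKind.COX:
        try:
            beta, ev_times, cumhaz = fit_cox(Z, time[sub], event[sub])
        except CoxConvergenceError as exc:
            raise RuntimeError(
                f"COX failed to converge on node {training_node_id}: {exc}"
            ) from exc
        s0 = baseline_survival_at(ev_times, cumhaz, horizon)
        return FittedModel(kind, columns, beta, 0.0, center, scale,
                           baseline_survival=s0, training_node_id=training_node_id)

    y = label[sub].astype(float)
    if kind == LearnerKind.LINEAR:
        A = np.column_stack([np.ones(len(Z)), Z])
        theta, *_ = np.linalg.lstsq(A, y, rcond=None)
        return FittedModel(kind, columns, theta[1:], float(theta[0]), center, scale,
                           training_node_id=training_node_id)

    clf = LogisticRegression(C=_LOGISTIC_C, solver="lbfgs", max_iter=2000)
    clf.fit(Z, y.astype(int))
    # class order is [0, 1]; coef_ is oriented toward class 1 (death)
    return FittedModel(kind, columns, clf.coef_[0].copy(), float(clf.intercept_[0]),
                       center, scale, training_node_id=training_node_id)


def fit_base_learner(
    kind: LearnerKind,
    matrix: pd.DataFrame,
    table: pd.DataFrame,
    task: HorizonTask,
    subset=None,
    training_node_id: int | None = None,
) -> FittedModel:
    """Fit one base learner on a subject subset (positional indices)."""
    rows = np.arange(len(matrix)) if subset is None else np.asarray(subset)
    return fit_learner_arrays(
        kind,
        matrix.to_numpy(dtype=float),
        table["time"].to_numpy(dtype=float),
        table["event"].to_numpy(dtype=float),
        task.label.astype(float),
        task.included,
        rows,
        task.horizon,
        list(matrix.columns),
        training_node_id,
    )


def predict_risk(
    model: FittedModel, matrix: pd.DataFrame, subset=None
) -> np.ndarray:
    """Score subjects with a fitted model; deterministic, output in [0, 1]."""
    missing = [c for c in model.columns if c not in matrix.columns]
    extra = [c for c in matrix.columns if c not in model.columns]
    if missing or extra:
        raise ValueError(
            f"feature columns do not match the model (missing={missing}, extra={extra})"
        )
    X = matrix[model.columns].to_numpy(dtype=float)
    if subset is not None:
        X = X[np.asarray(subset)]
    return model.predict_risk_array(X)
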