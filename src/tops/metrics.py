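"""Evaluation metrics: AUC, Harrell's C-index, calibration, and operating
points at fixed specificity/sensitivity, plus the k-fold CV harness.

One AUC implementation (tie-aware Mann-Whitney) serves both evaluation and
the tree's split search.  The C-index follows Harrell's convention: a pair
(i, j) is comparable when times[i] < times[j] and subject i died (censored
subjects participate only as the longer-time member), or when both died at
the same time (credited 1/2); score ties earn 1/2 credit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata


def auc(scores, labels) -> float:
    """Tie-aware Mann-Whitney AUC: P(score+ > score-) + 1/2 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def concordance_index(scores, times, events) -> float:
    """Harrell's C over comparable pairs, vectorized O(n^2)."""
    s = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    n = len(s)
    num = 0.0
    den = 0.0
    ev = e == 1
    # pairs with strictly smaller event time
    for i in np.flatnonzero(ev):
        later = t > t[i]
        m = int(later.sum())
        if m:
            den += m
            num += (s[i] > s[later]).sum() + 0.5 * (s[i] == s[later]).sum()
        # tied event times, both events: 1/2 credit, count each unordered pair once
        tied = ev & (t == t[i])
        k = int(tied[i + 1:].sum()) if i + 1 < n else 0
        den += k
        num += 0.5 * k
    if den == 0:
        raise ValueError("C-index undefined: no comparable pairs")
    return float(num / den)


@dataclass
class CalibrationReport:
    """Binned predicted-vs-observed calibration with 95% CIs and rho.

    ``rho`` is the root-mean-square distance of the (mean predicted risk,
    observed event rate) points from the identity line.
    """

    bins: list[dict] = field(default_factory=list)
    rho: float = float("nan")

    @property
    def n(self) -> int:
        return int(sum(b["count"] for b in self.bins))


def calibration(scores, labels, n_bins: int = 10) -> CalibrationReport:
    """Equal-frequency (quantile) calibration bins; duplicate bin edges are
    merged rather than errored."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    edges = np.unique(np.quantile(s, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 2:  # all scores identical: one bin
        assign = np.zeros(len(s), dtype=int)
        n_eff = 1
    else:
        assign = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, len(edges) - 2)
        n_eff = len(edges) - 1
    bins = []
    errors = []
    for b in range(n_eff):
        mask = assign == b
        if not mask.any():
            continue
        p_hat = float(y[mask].mean())
        count = int(mask.sum())
        half = 1.96 * np.sqrt(p_hat * (1 - p_hat) / count)
        bins.append(
            {
                "mean_predicted": float(s[mask].mean()),
                "observed_rate": p_hat,
                "ci_lower": max(0.0, p_hat - half),
                "ci_upper": min(1.0, p_hat + half),
                "count": count,
            }
        )
        errors.append(bins[-1]["mean_predicted"] - p_hat)
    rho = float(np.sqrt(np.mean(np.square(errors))))
    return CalibrationReport(bins=bins, rho=rho)


@dataclass
class OperatingPoint:
    sensitivity: float
    specificity: float
    threshold: float
    true_positives: int
    true_negatives: int


def sensitivity_at_specificity(scores, labels, target_specificity: float) -> OperatingPoint:
    """Smallest score cutoff (predict death when score >= cutoff) whose
    specificity reaches the target; returns sensitivity there plus raw
    correct-positive / correct-negative counts."""
    return _operating_point(scores, labels, target_specificity, fix="specificity")


def specificity_at_sensitivity(scores, labels, target_sensitivity: float) -> OperatingPoint:
    """Largest cutoff whose sensitivity reaches the target (mirror contract)."""
    return _operating_point(scores, labels, target_sensitivity, fix="sensitivity")


def _operating_point(scores, labels, target: float, fix: str) -> OperatingPoint:
    if not 0.0 < target < 1.0:
        raise ValueError("target must lie in (0, 1)")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    cutoffs = np.unique(s)
    cutoffs = np.append(cutoffs, np.inf)  # predict-nobody fallback
    best = None
    for c in cutoffs if fix == "specificity" else cutoffs[::-1]:
        pred = s >= c
        tp = int((pred & (y == 1)).sum())
        tn = int((~pred & (y == 0)).sum())
        sens = tp / n_pos
        spec = tn / n_neg
        if fix == "specificity" and spec >= target:
            best = OperatingPoint(sens, spec, float(c), tp, tn)
            break
        if fix == "sensitivity" and sens >= target:
            best = OperatingPoint(sens, spec, float(c), tp, tn)
            break
    assert best is not None  # spec>=target always holds at +inf; sens at -inf
    return best


# ---------------------------------------------------------------------------
# cross-validation harness
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    """Mean +/- std of each metric across folds, Tables-style."""

    horizons: list[float]
    folds: int
    per_fold: dict = field(default_factory=dict)  # metric name -> list of values
    mean: dict = field(default_factory=dict)
    std: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.mean:
            rows.append(
                {
                    "metric": name,
                    "mean": self.mean[name],
                    "std": self.std[name],
                    "display": f"{self.mean[name]:.3f} ± {self.std[name]:.3f}",
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "horizons": self.horizons,
            "folds": self.folds,
            "per_fold": self.per_fold,
            "mean": self.mean,
            "std": self.std,
        }


def aggregate_folds(per_fold: dict[str, list[float]]) -> tuple[dict, dict]:
    mean = {k: float(np.mean(v)) for k, v in per_fold.items()}
    std = {k: float(np.std(v)) for k, v in per_fold.items()}
    return mean, std


def cross_validate(
    table: pd.DataFrame,
    horizons,
    k: int = 5,
    seed: int = 0,
    encoder_params: dict | None = None,
    build_params: dict | None = None,
    date_column: str | None = None,
    train_range: tuple | None = None,
    test_range: tuple | None = None,
) -> CVReport:
    """k-fold CV of the full ToPs pipeline (encode -> build per horizon ->
    AUC with the censoring discard rule, C-index on all held-out subjects).

    Era mode: passing ``date_column`` with ``train_range`` / ``test_range``
    replaces the fold loop by a single train-on-one-era, test-on-another
    evaluation (fold count 1, std 0).
    """
    from .cohort import CohortEncoder, make_horizon_labels
    from .tree import ToPsRiskPredictor

    horizons = list(horizons)
    encoder_params = encoder_params or {}
    build_params = build_params or {}

    if (train_range is not None) != (test_range is not None):
        raise ValueError("era mode needs both train_range and test_range")
    if train_range is not None:
        if date_column is None or date_column not in table.columns:
            raise ValueError(
                "era filtering requires an explicit date column present in the data"
            )
        dates = pd.to_datetime(table[date_column])
        tr = (dates >= pd.Timestamp(train_range[0])) & (dates <= pd.Timestamp(train_range[1]))
        te = (dates >= pd.Timestamp(test_range[0])) & (dates <= pd.Timestamp(test_range[1]))
        splits = [(np.flatnonzero(tr.to_numpy()), np.flatnonzero(te.to_numpy()))]
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(table))
        folds = np.array_split(perm, k)
        splits = [
            (np.concatenate([folds[j] for j in range(k) if j != i]), folds[i])
            for i in range(k)
        ]

    drop = [date_column] if date_column and date_column in table.columns else []
    per_fold: dict[str, list[float]] = {}
    for fold_i, (train_rows, test_rows) in enumerate(splits):
        train = table.iloc[train_rows].drop(columns=drop)
        test = table.iloc[test_rows].drop(columns=drop)
        if len(train) < 4 * max(1, int(build_params.get("min_child_training_size", 50))):
            raise ValueError(f"fold {fold_i} too small to build a tree")
        enc = CohortEncoder(**encoder_params).fit(train)
        Xtr, Xte = enc.transform(train), enc.transform(test)
        cindices = []
        for h in horizons:
            model = ToPsRiskPredictor(horizon=h, random_state=seed, **build_params)
            model.fit(Xtr, train)
            scores = model.predict(Xte)
            task = make_horizon_labels(test, h)
            inc = task.included
            per_fold.setdefault(f"auc_{int(h)}d", []).append(
                auc(scores[inc], task.label[inc])
            )
            ci = concordance_index(
                scores, test["time"].to_numpy(), test["event"].to_numpy()
            )
            per_fold.setdefault(f"cindex_{int(h)}d", []).append(ci)
            cindices.append(ci)
        per_fold.setdefault("cindex_mean", []).append(float(np.mean(cindices)))

    mean, std = aggregate_folds(per_fold)
    return CVReport(
        horizons=horizons, folds=len(splits), per_fold=per_fold, mean=mean, std=std
    )
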