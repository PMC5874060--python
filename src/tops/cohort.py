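"""Cohort ingestion, encoding, imputation and horizon labeling.

A cohort is a pandas DataFrame with one row per subject, reserved numeric
columns ``time`` (follow-up, days) and ``event`` (1 = death observed,
0 = right-censored), and arbitrary mixed-type covariate columns.  Missing
covariate values are NaN (empty string / ``NA`` in CSV input).

Fixed-horizon mortality prediction casts survival as binary classification:
a subject censored before the horizon contributes no label and is excluded
from binary training and AUC evaluation (the censoring discard rule); a
subject observed past the horizon is a confirmed survivor even if censored
later.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.model_selection import train_test_split

RESERVED_COLUMNS = ("time", "event")

#: kind labels used in FeatureSchema
BINARY, CATEGORICAL, CONTINUOUS = "binary", "categorical", "continuous"


def validate_cohort(table: pd.DataFrame) -> None:
    """Check the cohort invariants; raise ValueError on violation."""
    if len(table) == 0:
        raise ValueError("empty cohort")
    for col in RESERVED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"cohort is missing required column '{col}'")
    time = pd.to_numeric(table["time"], errors="coerce")
    if time.isna().any() or (time < 0).any():
        raise ValueError("column 'time' must be numeric and non-negative")
    event = table["event"]
    if not event.isin([0, 1]).all():
        raise ValueError("column 'event' must contain only 0/1")
    if table.index.duplicated().any():
        raise ValueError("subject ids (index) must be unique")


def load_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV (empty string or 'NA' = missing) and validate it."""
    table = pd.read_csv(path, na_values=["NA", ""])
    validate_cohort(table)
    return table


def covariate_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in RESERVED_COLUMNS]


# ---------------------------------------------------------------------------
# schema inference and encoding
# ---------------------------------------------------------------------------

@dataclass
class FeatureSchema:
    """Per-covariate kind, observed categories and missing fraction."""

    kinds: dict[str, str]
    categories: dict[str, list] = field(default_factory=dict)
    missing_fraction: dict[str, float] = field(default_factory=dict)


def infer_schema(
    table: pd.DataFrame, overrides: dict[str, str] | None = None
) -> FeatureSchema:
    """Infer feature kinds: <=2 distinct non-missing values -> binary,
    non-numeric -> categorical, otherwise continuous."""
    overrides = overrides or {}
    kinds: dict[str, str] = {}
    categories: dict[str, list] = {}
    missing: dict[str, float] = {}
    n = len(table)
    for col in covariate_columns(table):
        series = table[col]
        missing[col] = float(series.isna().sum()) / n
        observed = series.dropna()
        distinct = sorted(observed.unique(), key=str)
        kind = overrides.get(col)
        if kind is None:
            if len(distinct) <= 2:
                kind = BINARY
            elif not pd.api.types.is_numeric_dtype(observed):
                kind = CATEGORICAL
            else:
                kind = CONTINUOUS
        if kind not in (BINARY, CATEGORICAL, CONTINUOUS):
            raise ValueError(f"unknown feature kind '{kind}' for '{col}'")
        kinds[col] = kind
        if kind in (BINARY, CATEGORICAL):
            categories[col] = distinct
    return FeatureSchema(kinds=kinds, categories=categories, missing_fraction=missing)


def filter_features_by_missingness(
    table: pd.DataFrame, max_fraction: float = 0.10
) -> tuple[pd.DataFrame, list[tuple[str, float]]]:
    """Drop covariates with missing fraction strictly greater than the cap.

    Returns the filtered table and a report of dropped (name, fraction)
    pairs for logging.  A feature at exactly the cap is retained.
    """
    if not 0.0 <= max_fraction <= 1.0:
        raise ValueError("max_fraction must lie in [0, 1]")
    validate_cohort(table)
    n = len(table)
    dropped: list[tuple[str, float]] = []
    keep = list(RESERVED_COLUMNS)
    for col in covariate_columns(table):
        frac = float(table[col].isna().sum()) / n
        if frac > max_fraction:
            dropped.append((col, frac))
        else:
            keep.append(col)
    ordered = [c for c in table.columns if c in keep]
    return table[ordered], dropped


def encode_features(
    table: pd.DataFrame, schema: FeatureSchema
) -> tuple[pd.DataFrame, dict[str, tuple[str, object]]]:
    """Encode covariates numerically; missing entries stay NaN.

    binary -> one {0,1} column; categorical with k levels -> k one-vs-rest
    indicator columns (``feat=level``); continuous -> passthrough.  Returns
    (matrix, provenance) where provenance maps each encoded column to its
    (source feature, category label or None for identity).
    """
    columns: dict[str, np.ndarray] = {}
    provenance: dict[str, tuple[str, object]] = {}
    for col in covariate_columns(table):
        kind = schema.kinds.get(col)
        if kind is None:
            continue  # dropped by the missingness filter
        series = table[col]
        if kind == CONTINUOUS:
            columns[col] = pd.to_numeric(series, errors="raise").to_numpy(dtype=float)
            provenance[col] = (col, None)
            continue
        cats = schema.categories[col]
        observed = series.dropna()
        unseen = set(observed.unique()) - set(cats)
        if unseen:
            raise ValueError(
                f"unseen category for feature '{col}': {sorted(unseen, key=str)!r}"
            )
        if kind == BINARY:
            if set(cats) <= {0, 1}:
                columns[col] = series.to_numpy(dtype=float)
                provenance[col] = (col, None)
            else:
                level = cats[-1]  # indicator of the last observed level
                vals = np.where(series.isna(), np.nan, (series == level).astype(float))
                columns[f"{col}={level}"] = vals
                provenance[f"{col}={level}"] = (col, level)
        else:  # one-vs-rest indicators, "A / not-A"
            for level in cats:
                name = f"{col}={level}"
                vals = np.where(series.isna(), np.nan, (series == level).astype(float))
                columns[name] = vals
                provenance[name] = (col, level)
    matrix = pd.DataFrame(columns, index=table.index)
    return matrix, provenance


def decode_features(
    matrix: pd.DataFrame,
    provenance: dict[str, tuple[str, object]],
    schema: FeatureSchema,
) -> pd.DataFrame:
    """Invert :func:`encode_features` for observed entries."""
    out: dict[str, pd.Series] = {}
    by_source: dict[str, list[str]] = {}
    for enc, (src, _) in provenance.items():
        by_source.setdefault(src, []).append(enc)
    for src, encs in by_source.items():
        if len(encs) == 1 and provenance[encs[0]][1] is None:
            out[src] = matrix[encs[0]]  # continuous or numeric 0/1 passthrough
        elif len(encs) == 1:
            # two-level feature as a single indicator of cats[-1]
            cats = schema.categories[src]
            col = matrix[encs[0]]
            vals = col.map({1.0: cats[-1], 0.0: cats[0]})
            vals[col.isna()] = np.nan
            out[src] = vals
        else:
            block = matrix[encs]
            labels = [provenance[e][1] for e in encs]
            idx = block.to_numpy().argmax(axis=1)
            vals = pd.Series([labels[i] for i in idx], index=matrix.index)
            vals[block.isna().any(axis=1)] = np.nan
            out[src] = vals
    return pd.DataFrame(out, index=matrix.index)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def impute(
    matrix: pd.DataFrame,
    strategy: str = "mean_mode",
    fill_values: pd.Series | None = None,
    fit_index=None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Single-pass deterministic imputation.

    Continuous columns are filled with the column mean of observed values,
    binary/indicator columns with the column mode (ties -> 0).  Fill values
    are computed on ``fit_index`` (default: all rows) and can be reused on
    held-out data by passing ``fill_values`` back in.  Returns the filled
    matrix and the fill values.  The ``strategy`` enum is a hook for richer
    imputers; only ``mean_mode`` ships.
    """
    if strategy != "mean_mode":
        raise ValueError(f"unknown imputation strategy '{strategy}'")
    if fill_values is None:
        sub = matrix if fit_index is None else matrix.loc[fit_index]
        fills = {}
        for col in matrix.columns:
            observed = sub[col].dropna()
            if len(observed) == 0:
                raise ValueError(
                    f"column '{col}' entirely missing on the fitting subset "
                    "(should have been dropped by the missingness filter)"
                )
            vals = observed.to_numpy(dtype=float)
            if set(np.unique(vals)) <= {0.0, 1.0}:
                fills[col] = float(vals.mean() > 0.5)  # mode, ties -> 0
            else:
                fills[col] = float(vals.mean())
        fill_values = pd.Series(fills)
    filled = matrix.fillna(fill_values)
    return filled, fill_values


class CohortEncoder(BaseEstimator, TransformerMixin):
    """Missingness filter + numeric encoding + mean/mode imputation.

    Fit on the development cohort; transform reuses the schema, encoding map
    and fill values on held-out data, erroring on unseen categories.

    Parameters
    ----------
    max_missing_fraction : float, default 0.10
        Covariates missing in strictly more than this fraction of fitting
        subjects are dropped.
    kind_overrides : dict, optional
        Per-feature kind override ('binary' | 'categorical' | 'continuous').
    impute_strategy : str, default 'mean_mode'
    """

    def __init__(self, max_missing_fraction: float = 0.10,
                 kind_overrides: dict | None = None,
                 impute_strategy: str = "mean_mode"):
        self.max_missing_fraction = max_missing_fraction
        self.kind_overrides = kind_overrides
        self.impute_strategy = impute_strategy

    def fit(self, table: pd.DataFrame, y=None):
        filtered, dropped = filter_features_by_missingness(
            table, self.max_missing_fraction
        )
        self.dropped_features_ = dropped
        self.schema_ = infer_schema(filtered, self.kind_overrides)
        matrix, provenance = encode_features(filtered, self.schema_)
        _, self.fill_values_ = impute(matrix, self.impute_strategy)
        self.provenance_ = provenance
        self.columns_ = list(matrix.columns)
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "schema_"):
            raise RuntimeError("CohortEncoder is not fitted")
        matrix, _ = encode_features(table, self.schema_)
        matrix = matrix.reindex(columns=self.columns_)
        filled, _ = impute(matrix, self.impute_strategy, self.fill_values_)
        return filled


# ---------------------------------------------------------------------------
# horizon labeling
# ---------------------------------------------------------------------------

@dataclass
class HorizonTask:
    """Binary mortality task at a fixed horizon (days).

    ``label[i] = 1`` iff subject i died within the horizon; ``included[i]``
    is False exactly for subjects censored before the horizon, which carry
    no binary label.
    """

    horizon: float
    label: np.ndarray
    included: np.ndarray

    @property
    def n(self) -> int:
        return len(self.label)


def make_horizon_labels(table: pd.DataFrame, horizon: float) -> HorizonTask:
    """Apply the censoring discard rule at ``horizon`` (days)."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    validate_cohort(table)
    time = table["time"].to_numpy(dtype=float)
    event = table["event"].to_numpy(dtype=int)
    label = ((event == 1) & (time <= horizon)).astype(np.int8)
    included = ~((event == 0) & (time < horizon))
    return HorizonTask(horizon=float(horizon), label=label, included=included)


def relevance_scores(
    matrix: pd.DataFrame, task: HorizonTask, subset=None
) -> pd.Series:
    """|Pearson correlation| between each encoded column and the binary
    label over included subjects of ``subset`` (positional indices).
    Constant columns score 0."""
    pos = np.arange(task.n) if subset is None else np.asarray(subset)
    pos = pos[task.included[pos]]
    if len(pos) == 0:
        raise ValueError("no labeled subjects in cluster")
    y = task.label[pos].astype(float)
    X = matrix.to_numpy(dtype=float)[pos]
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    sy = np.sqrt((yc ** 2).sum())
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, np.abs(Xc.T @ yc) / np.where(denom > 0, denom, 1.0), 0.0)
    return pd.Series(r, index=matrix.columns)


def split_development(
    task: HorizonTask, validation_fraction: float = 0.2, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/validation partition of the included subjects.

    Returns disjoint positional index arrays covering every included
    subject; deterministic given ``seed``.
    """
    if not 0.0 < validation_fraction < 1.0:
        raise ValueError("validation_fraction must lie in (0, 1)")
    pos = np.flatnonzero(task.included)
    y = task.label[pos]
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("need at least 2 included subjects per class")
    train, val = train_test_split(
        pos, test_size=validation_fraction, stratify=y, random_state=seed
    )
    return np.sort(train), np.sort(val)
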