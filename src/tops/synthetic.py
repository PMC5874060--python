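"""Synthetic heterogeneous survival cohorts with closed-form oracle risks.

Emulates the statistical structure of a transplant-registry cohort at desk
scale: subpopulations (clusters) defined by covariate thresholds, each with
its own proportional-hazards coefficient vector and baseline rate, plus
independent uniform right censoring.  Because event times come from a known
parametric family, the true risk P(T <= h | x) is available in closed form
for every subject and horizon, which makes discrimination and calibration
testable without external data.

Times are in days; baseline rates are events per year (365 days).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.0

#: conventional horizons: 3 months, 1 year, 3 years, 10 years
DEFAULT_HORIZONS = (91.0, 365.0, 1095.0, 3650.0)


@dataclass
class SyntheticConfig:
    """Generator parameters.

    ``planted_splits`` is an ordered list of (feature, threshold) pairs;
    subject cluster id is the little-endian bit pattern of the indicators
    1{x_feature >= threshold}, giving up to 2^k clusters.  ``betas`` has one
    row per cluster (columns follow continuous then binary features);
    ``baseline_rates`` is per-cluster, events/year.  ``censoring_max`` is
    the upper bound (days) of the uniform censoring time; ``inf`` disables
    censoring.
    """

    n: int
    d_continuous: int = 4
    d_binary: int = 2
    planted_splits: list[tuple[str, float]] = field(default_factory=list)
    betas: np.ndarray | None = None
    baseline_rates: np.ndarray | None = None
    time_family: str = "exponential"
    weibull_shape: float = 1.0
    censoring_max: float = 3650.0
    seed: int = 0

    @property
    def feature_names(self) -> list[str]:
        return [f"x{i + 1}" for i in range(self.d_continuous)] + [
            f"b{i + 1}" for i in range(self.d_binary)
        ]

    @property
    def n_clusters(self) -> int:
        return 2 ** len(self.planted_splits)

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.time_family not in ("exponential", "weibull"):
            raise ValueError(f"unknown time family '{self.time_family}'")
        if self.weibull_shape <= 0:
            raise ValueError("weibull shape must be positive")
        d = self.d_continuous + self.d_binary
        if self.betas is None:
            self.betas = np.zeros((self.n_clusters, d))
        self.betas = np.atleast_2d(np.asarray(self.betas, dtype=float))
        if self.betas.shape != (self.n_clusters, d):
            raise ValueError(
                f"betas must have shape ({self.n_clusters}, {d}), "
                f"got {self.betas.shape}"
            )
        if self.baseline_rates is None:
            self.baseline_rates = np.full(self.n_clusters, 0.25)
        self.baseline_rates = np.asarray(self.baseline_rates, dtype=float)
        if self.baseline_rates.shape != (self.n_clusters,):
            raise ValueError("baseline_rates must have one entry per cluster")
        if (self.baseline_rates <= 0).any():
            raise ValueError("baseline rates must be positive")
        names = self.feature_names
        for f, _ in self.planted_splits:
            if f not in names:
                raise ValueError(f"planted split on unknown feature '{f}'")


@dataclass
class SyntheticCohort:
    """Generated cohort with planted truth."""

    cohort: pd.DataFrame  # covariates + time + event
    true_cluster: np.ndarray
    config: SyntheticConfig

    def oracle_risk(self, horizon: float) -> np.ndarray:
        """True P(T <= horizon | x) for every subject."""
        X = self.covariates().to_numpy(dtype=float)
        return _risk(self.config, X, self.true_cluster, horizon)

    def covariates(self) -> pd.DataFrame:
        return self.cohort[self.config.feature_names]

    def truth_frame(self, horizons=DEFAULT_HORIZONS) -> pd.DataFrame:
        out = pd.DataFrame({"true_cluster": self.true_cluster})
        for h in horizons:
            out[f"oracle_risk_{int(h)}d"] = self.oracle_risk(h)
        return out


def _cluster_ids(config: SyntheticConfig, X: np.ndarray) -> np.ndarray:
    names = config.feature_names
    ids = np.zeros(len(X), dtype=int)
    for bit, (feat, thr) in enumerate(config.planted_splits):
        ids += (X[:, names.index(feat)] >= thr).astype(int) << bit
    return ids


def _cumhaz_scale(config: SyntheticConfig, X: np.ndarray,
                  cluster: np.ndarray) -> np.ndarray:
    """lambda_k * exp(beta_k . x) per subject (per-year hazard scale)."""
    eta = np.einsum("ij,ij->i", config.betas[cluster], X)
    return config.baseline_rates[cluster] * np.exp(eta)


def _risk(config: SyntheticConfig, X: np.ndarray, cluster: np.ndarray,
          horizon: float) -> np.ndarray:
    """Closed-form P(T <= h | x): 1 - exp(-scale * (h/365)^shape)."""
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    shape = config.weibull_shape if config.time_family == "weibull" else 1.0
    scale = _cumhaz_scale(config, X, cluster)
    return 1.0 - np.exp(-scale * (horizon / DAYS_PER_YEAR) ** shape)


def oracle_risk(config: SyntheticConfig, x, horizon: float) -> float:
    """True risk for a single feature vector (array, Series or dict)."""
    if isinstance(x, dict):
        x = np.array([x[f] for f in config.feature_names], dtype=float)
    elif isinstance(x, pd.Series):
        x = x[config.feature_names].to_numpy(dtype=float)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    cluster = _cluster_ids(config, x)
    return float(_risk(config, x, cluster, horizon)[0])


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Sample a cohort: x ~ N(0,1) / Bernoulli(0.5), event time from the
    cluster's proportional-hazards family, censoring ~ U(0, censoring_max)."""
    rng = np.random.default_rng(config.seed)
    Xc = rng.standard_normal((config.n, config.d_continuous))
    Xb = rng.binomial(1, 0.5, size=(config.n, config.d_binary)).astype(float)
    X = np.column_stack([Xc, Xb]) if config.d_binary else Xc
    cluster = _cluster_ids(config, X)
    scale = _cumhaz_scale(config, X, cluster)
    # inverse-CDF sampling: T = 365 * (E / scale)^(1/shape), E ~ Exp(1)
    shape = config.weibull_shape if config.time_family == "weibull" else 1.0
    E = rng.exponential(1.0, size=config.n)
    T = DAYS_PER_YEAR * (E / scale) ** (1.0 / shape)
    if np.isfinite(config.censoring_max):
        U = rng.uniform(0.0, config.censoring_max, size=config.n)
    else:
        U = np.full(config.n, np.inf)
    time = np.minimum(T, U)
    event = (T <= U).astype(int)
    cohort = pd.DataFrame(X, columns=config.feature_names)
    cohort["time"] = time
    cohort["event"] = event
    return SyntheticCohort(cohort=cohort, true_cluster=cluster, config=config)


# ---------------------------------------------------------------------------
# named study scenarios
# ---------------------------------------------------------------------------

def scenario_homogeneous(n: int = 4000, seed: int = 0) -> SyntheticConfig:
    """One global risk model, nothing to discover: the stopping rule should
    block splits and the tree should match a global learner."""
    return SyntheticConfig(
        n=n,
        planted_splits=[],
        betas=np.array([[0.9, -0.6, 0.4, 0.0, 0.5, 0.0]]),
        baseline_rates=np.array([0.25]),
        seed=seed,
    )


def scenario_single_split(n: int = 4000, seed: int = 0) -> SyntheticConfig:
    """Two regimes separated at x1 = 0 with distinct risk models (and zero
    direct effect of x1), so the first discovered split should recover the
    planted feature and threshold."""
    return SyntheticConfig(
        n=n,
        planted_splits=[("x1", 0.0)],
        betas=np.array(
            [
                [0.0, 1.3, 0.0, 0.0, 0.6, 0.0],   # x1 < 0
                [0.0, -1.3, 0.9, 0.0, 0.0, 0.7],  # x1 >= 0
            ]
        ),
        baseline_rates=np.array([0.25, 0.25]),
        seed=seed,
    )


def scenario_four_cluster(n: int = 8000, seed: int = 0) -> SyntheticConfig:
    """Two nested thresholds (x1 = 0, then x2 = 0) defining four clusters
    with sign-flipped coefficient vectors: globally the covariate effects
    cancel, so a single model has almost no discriminative power while the
    cluster-specific truth is strongly predictive — the heterogeneity the
    tree construction exists to exploit."""
    return SyntheticConfig(
        n=n,
        planted_splits=[("x1", 0.0), ("x2", 0.0)],
        betas=np.array(
            [
                [0.0, 0.0, 1.5, -1.0, 0.6, 0.0],   # x1 < 0, x2 < 0
                [0.0, 0.0, -1.5, 1.0, 0.0, 0.6],   # x1 >= 0, x2 < 0
                [0.0, 0.0, 1.0, 1.5, -0.6, 0.0],   # x1 < 0, x2 >= 0
                [0.0, 0.0, -1.0, -1.5, 0.0, -0.6],  # x1 >= 0, x2 >= 0
            ]
        ),
        baseline_rates=np.array([0.25, 0.25, 0.25, 0.25]),
        seed=seed,
    )


SCENARIOS = {
    "homogeneous": scenario_homogeneous,
    "single-split": scenario_single_split,
    "four-cluster": scenario_four_cluster,
}
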