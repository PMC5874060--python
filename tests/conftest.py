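import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from tops import ToPsRiskPredictor, auc, make_horizon_labels
from tops.learners import LearnerKind, fit_base_learner
from tops.synthetic import (
    generate_cohort,
    scenario_four_cluster,
    scenario_homogeneous,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

HORIZON = 1095.0


def dev_test_split(synthetic_cohort, n_test, seed):
    """Deterministic development / held-out split of a generated cohort."""
    df = synthetic_cohort.cohort
    X = synthetic_cohort.covariates()
    perm = np.random.default_rng(seed).permutation(len(df))
    dev, test = perm[n_test:], perm[:n_test]
    return (
        X.iloc[dev].reset_index(drop=True),
        df.iloc[dev].reset_index(drop=True),
        X.iloc[test].reset_index(drop=True),
        df.iloc[test].reset_index(drop=True),
        test,
    )


def _heldout_auc(scores, table):
    task = make_horizon_labels(table, HORIZON)
    inc = task.included
    return auc(scores[inc], task.label[inc]), task


@pytest.fixture(scope="session")
def four_cluster_runs():
    """ToPs vs globally trained base learners on the planted 4-cluster
    cohort (n = 8000, 10 seeds, 75/25 development/held-out)."""
    runs = []
    for seed in range(10):
        sc = generate_cohort(scenario_four_cluster(8000, seed=seed))
        Xd, dd, Xt, dt, _ = dev_test_split(sc, 2000, seed)
        model = ToPsRiskPredictor(horizon=HORIZON, random_state=seed).fit(Xd, dd)
        scores = model.predict(Xt)
        tops_auc, task = _heldout_auc(scores, dt)
        dev_task = make_horizon_labels(dd, HORIZON)
        global_aucs = {}
        for kind in LearnerKind:
            gm = fit_base_learner(kind, Xd, dd, dev_task)
            ga, _ = _heldout_auc(gm.predict_risk_array(Xt.to_numpy(float)), dt)
            global_aucs[kind.name] = ga
        runs.append(
            {
                "seed": seed,
                "model": model,
                "tops_auc": tops_auc,
                "best_global_auc": max(global_aucs.values()),
                "global_aucs": global_aucs,
                "test_scores": scores,
                "test_task": task,
            }
        )
    return runs


@pytest.fixture(scope="session")
def homogeneous_run():
    """ToPs vs global logistic on a cohort with nothing to discover."""
    sc = generate_cohort(scenario_homogeneous(4000, seed=0))
    Xd, dd, Xt, dt, _ = dev_test_split(sc, 1000, 0)
    model = ToPsRiskPredictor(horizon=HORIZON, random_state=0).fit(Xd, dd)
    tops_auc, _ = _heldout_auc(model.predict(Xt), dt)
    dev_task = make_horizon_labels(dd, HORIZON)
    gl = fit_base_learner(LearnerKind.LOGISTIC, Xd, dd, dev_task)
    logistic_auc, _ = _heldout_auc(gl.predict_risk_array(Xt.to_numpy(float)), dt)
    return {"model": model, "tops_auc": tops_auc, "global_logistic_auc": logistic_auc}


@pytest.fixture
def mixed_cohort():
    """Small mixed-type cohort with missing values for preprocessing tests."""
    rng = np.random.default_rng(7)
    n = 50
    df = pd.DataFrame(
        {
            "age": rng.normal(50, 10, n),
            "sex": rng.choice(["Male", "Female"], n),
            "blood": rng.choice(["A", "B", "AB", "O"], n),
            "flag": rng.integers(0, 2, n).astype(float),
            "lab": rng.normal(0, 1, n),
            "time": rng.uniform(10, 4000, n),
            "event": rng.integers(0, 2, n),
        }
    )
    df.loc[: int(0.12 * n) - 1, "lab"] = np.nan  # 12% missing -> dropped
    df.loc[:4, "age"] = np.nan  # 10% missing -> retained
    return df
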