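"""Trees of Predictors (ToPs): recursive discovery of predictive clusters.

The tree partitions feature space into clusters (nodes); each node carries
its own fitted base learner.  A split of a terminal cluster C into
C- = {x : x_i < tau} and C+ = {x : x_i >= tau} is chosen by searching
*jointly* over the split feature i, the threshold tau (per-node empirical
quantiles of the training members), the learner for each side, and the
training set for each side — any node weakly preceding the child, i.e. the
nodes on C's root-path plus the prospective child itself.  A candidate is
scored by the AUC of the combined scorer (left model on C-'s validation
members, right model on C+'s) over all validation members of C, and is
accepted only when it beats the incumbent node model by more than epsilon
AND does not decrease the overall validation AUC of the working tree
predictor.  Construction stops when no terminal node admits an improving
split.

Prediction for a feature vector x walks the unique root-to-terminal path Pi
containing x and returns the convex combination
H(x) = sum_{C in Pi} w(C, Pi) * h_C(x), with per-terminal weights fitted by
non-negative least squares on validation labels and normalized onto the
simplex, so H(x) is always in [0, 1].
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator
from sklearn.isotonic import IsotonicRegression

from .cohort import HorizonTask, make_horizon_labels, split_development
from .learners import FittedModel, LearnerKind, fit_learner_arrays
from .metrics import auc

__all__ = [
    "SplitRule",
    "Node",
    "BuildConfig",
    "ToPsRiskPredictor",
    "build_tops",
    "search_best_split",
    "fit_path_weights",
    "solve_path_weights",
    "predict_tops",
    "survival_curve",
    "SurvivalCurve",
    "describe_tree",
]


@dataclass
class SplitRule:
    """Axis-aligned half-open split: left = {x_feature < threshold},
    right = {x_feature >= threshold}."""

    feature: str
    threshold: float


@dataclass
class Node:
    node_id: int
    parent_id: int | None
    depth: int
    constraints: list[tuple[str, str, float]]  # (feature, '<' | '>=', threshold)
    model: FittedModel | None = None
    training_node_id: int | None = None
    split: SplitRule | None = None
    child_ids: list[int] = field(default_factory=list)
    n_train: int = 0
    n_val: int = 0
    top_features: list[str] = field(default_factory=list)
    # transient (not serialized)
    train_rows: np.ndarray | None = None
    val_rows: np.ndarray | None = None

    @property
    def is_terminal(self) -> bool:
        return self.split is None


@dataclass
class BuildConfig:
    """Tunable construction parameters (the method itself fixes none)."""

    learner_set: tuple[LearnerKind, ...] = (
        LearnerKind.COX,
        LearnerKind.LINEAR,
        LearnerKind.LOGISTIC,
    )
    validation_fraction: float = 0.2
    quantile_count: int = 10
    min_child_training_size: int = 50
    min_child_validation_per_class: int = 5
    improvement_epsilon: float = 1e-4
    max_depth: int = 10
    max_splits: int | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in (0, 1)")
        if min(self.quantile_count, self.min_child_training_size,
               self.min_child_validation_per_class, self.max_depth) <= 0:
            raise ValueError("size parameters must be positive")
        if self.improvement_epsilon < 0:
            raise ValueError("improvement_epsilon must be >= 0")
        self.learner_set = tuple(
            LearnerKind(k) if not isinstance(k, LearnerKind) else k
            for k in self.learner_set
        )


@dataclass
class SplitCandidate:
    """Winner of the joint grid search at one terminal node."""

    feature: str
    feature_index: int
    threshold: float
    auc: float
    incumbent_auc: float
    side_kind: tuple[LearnerKind, LearnerKind]
    side_training_node: tuple[int | None, int | None]  # None = the child itself
    side_model: tuple[FittedModel, FittedModel]
    side_train_rows: tuple[np.ndarray, np.ndarray]
    side_val_rows: tuple[np.ndarray, np.ndarray]
    side_val_scores: tuple[np.ndarray, np.ndarray]


class _TreeBuilder:
    """Stateful recursive construction over positional arrays."""

    def __init__(self, X: np.ndarray, columns: list[str], time: np.ndarray,
                 event: np.ndarray, task: HorizonTask, config: BuildConfig):
        self.X = X
        self.columns = columns
        self.time = time
        self.event = event
        self.task = task
        self.config = config
        self.nodes: dict[int, Node] = {}
        self.build_log: list[dict] = []
        self._next_id = 0
        self._model_cache: dict[tuple[int, LearnerKind], FittedModel | None] = {}

        inc = np.flatnonzero(task.included)
        if len(inc) < 2 * config.min_child_training_size:
            raise ValueError(
                "too few included subjects for the configured size floors"
            )
        train_inc, val = split_development(
            task, config.validation_fraction, config.seed
        )
        excluded = np.flatnonzero(~task.included)
        # censored-before-horizon subjects carry no binary label; they join
        # the training side where Cox can still use them
        self.train_rows = np.sort(np.concatenate([train_inc, excluded]))
        self.val_rows = val
        self.val_labels = task.label[val].astype(int)
        self.overall_scores = np.zeros(len(val))

    # -- model fitting with cache -------------------------------------------

    def _fit_cached(self, node_id: int, kind: LearnerKind) -> FittedModel | None:
        key = (node_id, kind)
        if key not in self._model_cache:
            try:
                self._model_cache[key] = fit_learner_arrays(
                    kind, self.X, self.time, self.event,
                    self.task.label.astype(float), self.task.included,
                    self.nodes[node_id].train_rows, self.task.horizon,
                    self.columns, training_node_id=node_id,
                )
            except (ValueError, RuntimeError):
                self._model_cache[key] = None
        return self._model_cache[key]

    def _fit_fresh(self, kind: LearnerKind, rows: np.ndarray) -> FittedModel | None:
        try:
            return fit_learner_arrays(
                kind, self.X, self.time, self.event,
                self.task.label.astype(float), self.task.included,
                rows, self.task.horizon, self.columns, training_node_id=None,
            )
        except (ValueError, RuntimeError):
            return None

    def _new_node(self, parent: Node | None, constraints) -> Node:
        node = Node(
            node_id=self._next_id,
            parent_id=None if parent is None else parent.node_id,
            depth=0 if parent is None else parent.depth + 1,
            constraints=list(constraints),
        )
        self._next_id += 1
        self.nodes[node.node_id] = node
        return node

    def _annotate(self, node: Node) -> None:
        node.n_train = len(node.train_rows)
        node.n_val = len(node.val_rows)
        dev = np.concatenate([node.train_rows, node.val_rows])
        dev = dev[self.task.included[dev]]
        if len(dev) >= 2 and len(np.unique(self.task.label[dev])) == 2:
            y = self.task.label[dev].astype(float)
            Xc = self.X[dev] - self.X[dev].mean(axis=0)
            yc = y - y.mean()
            sx = np.sqrt((Xc ** 2).sum(axis=0))
            sy = np.sqrt((yc ** 2).sum())
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.where(sx > 0, np.abs(Xc.T @ yc) / np.where(sx > 0, sx * sy, 1.0), 0.0)
            node.top_features = [self.columns[j] for j in np.argsort(-r)[:3]]

    def _path(self, node: Node) -> list[Node]:
        path = [node]
        while path[0].parent_id is not None:
            path.insert(0, self.nodes[path[0].parent_id])
        return path

    # -- construction -------------------------------------------------------

    def build(self) -> None:
        cfg = self.config
        root = self._new_node(None, [])
        root.train_rows = self.train_rows
        root.val_rows = self.val_rows
        self._annotate(root)

        # Stage 0: train every learner in R globally, keep the best on the
        # validation part (ties broken by canonical learner order)
        best = None
        for kind in cfg.learner_set:
            model = self._fit_cached(root.node_id, kind)
            if model is None:
                continue
            scores = model.predict_risk_array(self.X[self.val_rows])
            a = auc(scores, self.val_labels)
            if best is None or a > best[0]:
                best = (a, kind, model, scores)
        if best is None:
            raise ValueError("no base learner could be fitted on the root")
        root_auc, _, root.model, self.overall_scores = best
        root.training_node_id = root.node_id
        self.build_log.append(
            {
                "stage": 0,
                "node_id": root.node_id,
                "action": "root",
                "learner": root.model.kind.name,
                "overall_validation_auc": root_auc,
            }
        )

        queue = deque([root.node_id])
        stage = 0
        n_splits = 0
        while queue:
            if cfg.max_splits is not None and n_splits >= cfg.max_splits:
                break
            node = self.nodes[queue.popleft()]
            if node.depth >= cfg.max_depth:
                continue
            cand = self.search_node(node)
            if cand is None:
                continue
            # global guard: the working tree predictor (each validation
            # subject scored by its terminal node's model) must not get worse
            new_scores = self.overall_scores.copy()
            val_pos = {r: i for i, r in enumerate(self.val_rows)}
            for side in (0, 1):
                idx = np.fromiter(
                    (val_pos[r] for r in cand.side_val_rows[side]), dtype=int,
                    count=len(cand.side_val_rows[side]),
                )
                new_scores[idx] = cand.side_val_scores[side]
            new_overall = auc(new_scores, self.val_labels)
            old_overall = auc(self.overall_scores, self.val_labels)
            if new_overall < old_overall:
                continue  # node closed
            stage += 1
            n_splits += 1
            self.overall_scores = new_scores
            self._accept(node, cand, stage, new_overall)
            for cid in node.child_ids:
                queue.append(cid)

    def _accept(self, node: Node, cand: SplitCandidate, stage: int,
                overall: float) -> None:
        node.split = SplitRule(cand.feature, float(cand.threshold))
        ops = ("<", ">=")
        for side in (0, 1):
            child = self._new_node(
                node, node.constraints + [(cand.feature, ops[side], float(cand.threshold))]
            )
            child.train_rows = cand.side_train_rows[side]
            child.val_rows = cand.side_val_rows[side]
            model = cand.side_model[side]
            tn = cand.side_training_node[side]
            if tn is None:  # trained on the prospective child itself
                model = FittedModel(**{**model.__dict__})
                model.training_node_id = child.node_id
                self._model_cache[(child.node_id, model.kind)] = model
            child.model = model
            child.training_node_id = model.training_node_id
            node.child_ids.append(child.node_id)
            self._annotate(child)
        self.build_log.append(
            {
                "stage": stage,
                "node_id": node.node_id,
                "action": "split",
                "feature": cand.feature,
                "threshold": float(cand.threshold),
                "learner_left": cand.side_kind[0].name,
                "learner_right": cand.side_kind[1].name,
                "training_node_left": self.nodes[node.child_ids[0]].training_node_id,
                "training_node_right": self.nodes[node.child_ids[1]].training_node_id,
                "node_auc_before": cand.incumbent_auc,
                "node_auc_after": cand.auc,
                "overall_validation_auc": overall,
            }
        )

    # -- split search -------------------------------------------------------

    def search_node(self, node: Node) -> SplitCandidate | None:
        """Argmax over the joint (feature, threshold, learners, training
        sets) grid, or None when nothing admissible improves by > epsilon."""
        cfg = self.config
        rows_tr, rows_val = node.train_rows, node.val_rows
        if len(rows_tr) < 2 * cfg.min_child_training_size:
            return None
        y_val = self.task.label[rows_val].astype(int)
        if len(np.unique(y_val)) < 2:
            return None
        incumbent = auc(node.model.predict_risk_array(self.X[rows_val]), y_val)

        path = self._path(node)
        # path-node models scored once on this node's validation members
        path_opts: list[tuple[LearnerKind, int, int, np.ndarray]] = []
        for A in path:
            for kind in cfg.learner_set:
                model = self._fit_cached(A.node_id, kind)
                if model is not None:
                    path_opts.append(
                        (kind, A.depth, A.node_id,
                         model.predict_risk_array(self.X[rows_val]))
                    )

        best_key = None
        best: SplitCandidate | None = None
        child_depth = node.depth + 1
        Xtr = self.X[rows_tr]
        Xval = self.X[rows_val]
        for j in range(self.X.shape[1]):
            qs = np.quantile(
                Xtr[:, j], np.arange(1, cfg.quantile_count) / cfg.quantile_count
            )
            for tau in np.unique(qs):
                left_tr_mask = Xtr[:, j] < tau
                n_left, n_right = int(left_tr_mask.sum()), int((~left_tr_mask).sum())
                if min(n_left, n_right) < cfg.min_child_training_size:
                    continue
                left_val_mask = Xval[:, j] < tau
                ok = True
                for mask in (left_val_mask, ~left_val_mask):
                    counts = np.bincount(y_val[mask], minlength=2)
                    if counts.min() < cfg.min_child_validation_per_class:
                        ok = False
                        break
                if not ok:
                    continue
                side_masks = (left_val_mask, ~left_val_mask)
                side_tr = (rows_tr[left_tr_mask], rows_tr[~left_tr_mask])
                # candidate scorers per side: path nodes + the child itself
                side_opts: list[list] = []
                for s in (0, 1):
                    opts = [
                        (kind, depth, nid, sc[side_masks[s]], None)
                        for kind, depth, nid, sc in path_opts
                    ]
                    for kind in cfg.learner_set:
                        m = self._fit_fresh(kind, side_tr[s])
                        if m is not None:
                            opts.append(
                                (kind, child_depth, None,
                                 m.predict_risk_array(Xval[side_masks[s]]), m)
                            )
                    side_opts.append(opts)
                if not side_opts[0] or not side_opts[1]:
                    continue
                y_cat = np.concatenate([y_val[side_masks[0]], y_val[side_masks[1]]])
                for kl, dl, nl, sl, ml in side_opts[0]:
                    for kr, dr, nr_, sr, mr in side_opts[1]:
                        a = auc(np.concatenate([sl, sr]), y_cat)
                        key = (-a, j, tau, int(kl), int(kr), dl, dr)
                        if best_key is None or key < best_key:
                            best_key = key
                            best = SplitCandidate(
                                feature=self.columns[j],
                                feature_index=j,
                                threshold=float(tau),
                                auc=a,
                                incumbent_auc=incumbent,
                                side_kind=(kl, kr),
                                side_training_node=(nl, nr_),
                                side_model=(
                                    ml if nl is None else self._model_cache[(nl, kl)],
                                    mr if nr_ is None else self._model_cache[(nr_, kr)],
                                ),
                                side_train_rows=side_tr,
                                side_val_rows=(
                                    rows_val[side_masks[0]], rows_val[side_masks[1]]
                                ),
                                side_val_scores=(sl, sr),
                            )
        if best is None or best.auc <= incumbent + cfg.improvement_epsilon:
            return None
        return best


# ---------------------------------------------------------------------------
# path weights
# ---------------------------------------------------------------------------

def solve_path_weights(score_matrix: np.ndarray, labels: np.ndarray,
                       min_members: int = 10) -> np.ndarray:
    """Convex weights over path models: NNLS of labels on per-model score
    columns, normalized to the simplex.  Falls back to uniform weights when
    fewer than ``min_members`` validation members are available, when every
    score column is identical (collinear degeneracy), or when the NNLS
    solution is all-zero."""
    S = np.asarray(score_matrix, dtype=float)
    n, p = S.shape
    uniform = np.full(p, 1.0 / p)
    if n < min_members:
        return uniform
    if p == 1:
        return np.array([1.0])
    if np.max(np.abs(S - S[:, [0]])) < 1e-12:
        return uniform
    w, _ = nnls(S, np.asarray(labels, dtype=float))
    total = w.sum()
    if total <= 0:
        return uniform
    return w / total


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class ToPsRiskPredictor(BaseEstimator):
    """Trees-of-Predictors risk model for mortality within a fixed horizon.

    Parameters mirror :class:`BuildConfig`; ``fit`` expects an encoded,
    fully numeric feature DataFrame plus a frame (or mapping) carrying
    ``time`` (days) and ``event`` (0/1) columns.  ``predict`` returns the
    path-weighted mortality risk in [0, 1] (higher = more likely to die
    within the horizon).
    """

    def __init__(self, horizon: float = 1095.0, learner_set=None,
                 validation_fraction: float = 0.2, quantile_count: int = 10,
                 min_child_training_size: int = 50,
                 min_child_validation_per_class: int = 5,
                 improvement_epsilon: float = 1e-4, max_depth: int = 10,
                 max_splits: int | None = None, random_state: int = 0):
        self.horizon = horizon
        self.learner_set = learner_set
        self.validation_fraction = validation_fraction
        self.quantile_count = quantile_count
        self.min_child_training_size = min_child_training_size
        self.min_child_validation_per_class = min_child_validation_per_class
        self.improvement_epsilon = improvement_epsilon
        self.max_depth = max_depth
        self.max_splits = max_splits
        self.random_state = random_state

    def _config(self) -> BuildConfig:
        learners = self.learner_set
        if learners is None:
            learners = (LearnerKind.COX, LearnerKind.LINEAR, LearnerKind.LOGISTIC)
        return BuildConfig(
            learner_set=tuple(learners),
            validation_fraction=self.validation_fraction,
            quantile_count=self.quantile_count,
            min_child_training_size=self.min_child_training_size,
            min_child_validation_per_class=self.min_child_validation_per_class,
            improvement_epsilon=self.improvement_epsilon,
            max_depth=self.max_depth,
            max_splits=self.max_splits,
            seed=self.random_state,
        )

    def fit(self, X: pd.DataFrame, y) -> "ToPsRiskPredictor":
        X = pd.DataFrame(X)
        if X.isna().any().any():
            raise ValueError("feature matrix contains missing values; impute first")
        time, event = _extract_survival(y, len(X))
        frame = pd.DataFrame({"time": time, "event": event})
        task = make_horizon_labels(frame, self.horizon)
        config = self._config()
        builder = _TreeBuilder(
            X.to_numpy(dtype=float), list(map(str, X.columns)),
            time, event.astype(float), task, config,
        )
        builder.build()
        self.columns_ = list(map(str, X.columns))
        self.nodes_ = builder.nodes
        self.root_id_ = 0
        self.build_log_ = builder.build_log
        self.path_weights_ = {}
        self._builder = builder
        self._fit_weights(builder)
        return self

    def _fit_weights(self, builder: _TreeBuilder) -> None:
        for node in self.nodes_.values():
            if not node.is_terminal:
                continue
            path = builder._path(node)
            S = np.column_stack(
                [p.model.predict_risk_array(builder.X[node.val_rows]) for p in path]
            )
            y = builder.task.label[node.val_rows].astype(float)
            self.path_weights_[node.node_id] = solve_path_weights(S, y)

    # -- prediction ---------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "nodes_"):
            raise RuntimeError("ToPsRiskPredictor is not fitted")

    def _terminal_assignment(self, X: np.ndarray) -> dict[int, np.ndarray]:
        """Map terminal node id -> positional rows landing there."""
        col_index = {c: j for j, c in enumerate(self.columns_)}
        out: dict[int, np.ndarray] = {}
        stack = [(self.root_id_, np.arange(len(X)))]
        while stack:
            nid, rows = stack.pop()
            node = self.nodes_[nid]
            if node.is_terminal:
                out[nid] = rows
                continue
            j = col_index[node.split.feature]
            left = X[rows, j] < node.split.threshold
            stack.append((node.child_ids[0], rows[left]))
            stack.append((node.child_ids[1], rows[~left]))
        return out

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        X = pd.DataFrame(X)
        missing = [c for c in self.columns_ if c not in X.columns]
        if missing:
            raise ValueError(f"feature matrix is missing columns {missing}")
        Xv = X[self.columns_].to_numpy(dtype=float)
        out = np.empty(len(Xv))
        for tid, rows in self._terminal_assignment(Xv).items():
            if len(rows) == 0:
                continue
            path = self._path_ids(tid)
            w = self.path_weights_[tid]
            acc = np.zeros(len(rows))
            for wi, nid in zip(w, path):
                acc += wi * self.nodes_[nid].model.predict_risk_array(Xv[rows])
            out[rows] = np.clip(acc, 0.0, 1.0)
        return out

    def _path_ids(self, node_id: int) -> list[int]:
        path = [node_id]
        while self.nodes_[path[0]].parent_id is not None:
            path.insert(0, self.nodes_[path[0]].parent_id)
        return path

    # -- introspection and serialization ------------------------------------

    def describe(self) -> dict:
        self._check_fitted()
        nodes = []
        for node in sorted(self.nodes_.values(), key=lambda n: n.node_id):
            rec = {
                "node_id": node.node_id,
                "parent_id": node.parent_id,
                "depth": node.depth,
                "constraints": [
                    f"{f} {op} {thr:g}" for f, op, thr in node.constraints
                ],
                "n_train": node.n_train,
                "n_val": node.n_val,
                "learner": node.model.kind.name,
                "training_node_id": node.training_node_id,
                "top_relevant_features": list(node.top_features),
                "terminal": node.is_terminal,
            }
            if node.split is not None:
                rec["split"] = {
                    "feature": node.split.feature,
                    "threshold": node.split.threshold,
                }
                rec["child_ids"] = list(node.child_ids)
            if node.is_terminal:
                rec["path_weights"] = [
                    float(v) for v in self.path_weights_[node.node_id]
                ]
            nodes.append(rec)
        return {
            "horizon": float(self.horizon),
            "n_nodes": len(nodes),
            "nodes": nodes,
            "build_log": self.build_log_,
        }

    def to_dot(self) -> str:
        self._check_fitted()
        lines = ["digraph tops {", "  node [shape=box];"]
        for node in sorted(self.nodes_.values(), key=lambda n: n.node_id):
            parts = [f"node {node.node_id}", node.model.kind.name,
                     f"n={node.n_train}+{node.n_val}"]
            if node.top_features:
                parts.append("top: " + ", ".join(node.top_features))
            style = ', style=filled, fillcolor="gray90"' if node.is_terminal else ""
            lines.append(
                f'  n{node.node_id} [label="' + "\\n".join(parts) + f'"{style}];'
            )
            if node.split is not None:
                l, r = node.child_ids
                f_, t_ = node.split.feature, node.split.threshold
                lines.append(f'  n{node.node_id} -> n{l} [label="{f_} < {t_:g}"];')
                lines.append(f'  n{node.node_id} -> n{r} [label="{f_} >= {t_:g}"];')
        lines.append("}")
        return "\n".join(lines)

    def to_json(self) -> str:
        self._check_fitted()
        nodes = []
        for node in sorted(self.nodes_.values(), key=lambda n: n.node_id):
            nodes.append(
                {
                    "node_id": node.node_id,
                    "parent_id": node.parent_id,
                    "depth": node.depth,
                    "constraints": [list(c) for c in node.constraints],
                    "split": None if node.split is None else asdict(node.split),
                    "child_ids": list(node.child_ids),
                    "n_train": node.n_train,
                    "n_val": node.n_val,
                    "training_node_id": node.training_node_id,
                    "top_features": list(node.top_features),
                    "model": node.model.to_dict(),
                }
            )
        payload = {
            "format": "tops-tree/1",
            "horizon": float(self.horizon),
            "columns": self.columns_,
            "config": {
                "learner_set": [k.name for k in self._config().learner_set],
                "validation_fraction": self.validation_fraction,
                "quantile_count": self.quantile_count,
                "min_child_training_size": self.min_child_training_size,
                "min_child_validation_per_class": self.min_child_validation_per_class,
                "improvement_epsilon": self.improvement_epsilon,
                "max_depth": self.max_depth,
                "seed": self.random_state,
            },
            "nodes": nodes,
            "path_weights": {
                str(k): [float(v) for v in w] for k, w in sorted(self.path_weights_.items())
            },
            "build_log": self.build_log_,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ToPsRiskPredictor":
        payload = json.loads(text)
        if payload.get("format") != "tops-tree/1":
            raise ValueError("not a serialized ToPs tree")
        cfg = payload["config"]
        est = cls(
            horizon=payload["horizon"],
            learner_set=tuple(LearnerKind[k] for k in cfg["learner_set"]),
            validation_fraction=cfg["validation_fraction"],
            quantile_count=cfg["quantile_count"],
            min_child_training_size=cfg["min_child_training_size"],
            min_child_validation_per_class=cfg["min_child_validation_per_class"],
            improvement_epsilon=cfg["improvement_epsilon"],
            max_depth=cfg["max_depth"],
            random_state=cfg["seed"],
        )
        est.columns_ = list(payload["columns"])
        est.nodes_ = {}
        for nd in payload["nodes"]:
            node = Node(
                node_id=nd["node_id"],
                parent_id=nd["parent_id"],
                depth=nd["depth"],
                constraints=[tuple(c) for c in nd["constraints"]],
                model=FittedModel.from_dict(nd["model"]),
                training_node_id=nd["training_node_id"],
                split=None if nd["split"] is None else SplitRule(**nd["split"]),
                child_ids=list(nd["child_ids"]),
                n_train=nd["n_train"],
                n_val=nd["n_val"],
                top_features=list(nd["top_features"]),
            )
            est.nodes_[node.node_id] = node
        est.root_id_ = 0
        est.path_weights_ = {
            int(k): np.asarray(v, dtype=float)
            for k, v in payload["path_weights"].items()
        }
        est.build_log_ = payload["build_log"]
        return est


def _extract_survival(y, n: int) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(y, pd.DataFrame):
        time = y["time"].to_numpy(dtype=float)
        event = y["event"].to_numpy(dtype=float)
    elif isinstance(y, dict):
        time = np.asarray(y["time"], dtype=float)
        event = np.asarray(y["event"], dtype=float)
    elif isinstance(y, np.ndarray) and y.dtype.names:
        time = y["time"].astype(float)
        event = y["event"].astype(float)
    else:
        time, event = y
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=float)
    if len(time) != n:
        raise ValueError("survival outcome length does not match X")
    return time, event


# ---------------------------------------------------------------------------
# functional wrappers over the estimator
# ---------------------------------------------------------------------------

def build_tops(matrix: pd.DataFrame, table: pd.DataFrame, task: HorizonTask,
               config: BuildConfig | None = None) -> ToPsRiskPredictor:
    """Build a tree of predictors for ``task.horizon`` (functional wrapper
    over :class:`ToPsRiskPredictor`)."""
    config = config or BuildConfig()
    est = ToPsRiskPredictor(
        horizon=task.horizon,
        learner_set=config.learner_set,
        validation_fraction=config.validation_fraction,
        quantile_count=config.quantile_count,
        min_child_training_size=config.min_child_training_size,
        min_child_validation_per_class=config.min_child_validation_per_class,
        improvement_epsilon=config.improvement_epsilon,
        max_depth=config.max_depth,
        max_splits=config.max_splits,
        random_state=config.seed,
    )
    return est.fit(matrix, table)


def search_best_split(tree: ToPsRiskPredictor, node_id: int) -> SplitCandidate | None:
    """Re-run the joint grid search at a terminal node of a freshly fitted
    tree (requires the in-memory builder; not available on deserialized
    trees)."""
    builder = getattr(tree, "_builder", None)
    if builder is None:
        raise RuntimeError("search_best_split needs a tree fitted in this session")
    node = tree.nodes_[node_id]
    if not node.is_terminal:
        raise ValueError("node is not terminal")
    return builder.search_node(node)


def fit_path_weights(tree: ToPsRiskPredictor) -> ToPsRiskPredictor:
    """Recompute every terminal path-weight vector on the validation set."""
    builder = getattr(tree, "_builder", None)
    if builder is None:
        raise RuntimeError("fit_path_weights needs a tree fitted in this session")
    tree._fit_weights(builder)
    return tree


def predict_tops(tree: ToPsRiskPredictor, x) -> float:
    """Path-weighted risk for a single feature vector (Series/dict/1-row)."""
    if isinstance(x, (pd.Series, dict)):
        x = pd.DataFrame([x])
    return float(tree.predict(x)[0])


# ---------------------------------------------------------------------------
# survival curve across horizons
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    """Piecewise-linear survival function through per-horizon predictions.

    Anchored at S(0) = 1; the per-horizon survival sequence is made
    non-increasing by pool-adjacent-violators before interpolation; constant
    beyond the last horizon.
    """

    horizons: np.ndarray
    survival: np.ndarray

    def __call__(self, t):
        return np.interp(t, self.horizons, self.survival)


def survival_curve(trees: dict[float, ToPsRiskPredictor], x) -> SurvivalCurve:
    """Survival function for one subject from fixed-horizon trees."""
    if len(trees) < 2:
        raise ValueError("need >= 2 horizons")
    hs = np.array(sorted(trees), dtype=float)
    if isinstance(x, (pd.Series, dict)):
        x = pd.DataFrame([x])
    risks = np.array([float(trees[h].predict(x)[0]) for h in hs])
    surv = 1.0 - risks
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=False)
    surv = iso.fit_transform(hs, surv)
    return SurvivalCurve(
        horizons=np.concatenate([[0.0], hs]),
        survival=np.concatenate([[1.0], surv]),
    )


def describe_tree(tree: ToPsRiskPredictor) -> dict:
    """Structured, serializable summary (see :meth:`ToPsRiskPredictor.describe`)."""
    return tree.describe()
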