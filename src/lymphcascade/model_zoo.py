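"""Six model families per task, evaluation grids, and best-family selection.

Linear/kernel/network families (LR, SVM, MLP) consume the paired one-hot
encoding; tree families (DT, RF, GBM) consume three-level categorical codes.
The family used system-wide is chosen by the summed one-vs-rest AUC over all
tasks and all declared validation cohorts, ties broken by a fixed family
order.  Every fit derives its seed deterministically from the pipeline seed,
the task id and the family, so reruns are bit-reproducible.
"""

from __future__ import annotations

import enum
import json
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier
from xgboost import XGBClassifier

from .marker_data import Cohort, DesignMatrix, encode
from .metrics import auc_ovr_macro
from .task_hierarchy import TaskSpec, class_label_map, default_hierarchy

__all__ = [
    "ModelFamily",
    "TrainedTaskModel",
    "SelectionReport",
    "DEFAULT_HYPERPARAMS",
    "derive_seed",
    "train_task_model",
    "predict_scores",
    "predict_labels",
    "select_best_family",
    "reference_auc",
    "task_labels",
]


class ModelFamily(enum.Enum):
    LR = "LR"
    SVM = "SVM"
    MLP = "MLP"
    DT = "DT"
    RF = "RF"
    GBM = "GBM"

    @property
    def encoding_kind(self) -> str:
        return ("onehot_pair" if self in (ModelFamily.LR, ModelFamily.SVM,
                                          ModelFamily.MLP)
                else "categorical3")

    @property
    def order(self) -> int:
        """Fixed tie-break order: LR < SVM < MLP < DT < RF < GBM."""
        return list(ModelFamily).index(self)


#: Conventional defaults; every entry is overridable through ``hyperparams``.
DEFAULT_HYPERPARAMS: dict[ModelFamily, dict] = {
    ModelFamily.LR: {"C": 1.0, "max_iter": 1000},
    ModelFamily.SVM: {"kernel": "rbf", "C": 1.0},
    ModelFamily.MLP: {"hidden_layer_sizes": (32,), "early_stopping": False,
                      "max_iter": 500},
    ModelFamily.DT: {"criterion": "gini"},
    ModelFamily.RF: {"n_estimators": 500},
    ModelFamily.GBM: {"n_estimators": 300, "max_depth": 4,
                      "learning_rate": 0.1},
}


def derive_seed(base_seed: int, *parts: str) -> int:
    """Deterministic per-task/per-family seed below 2**31."""
    h = zlib.crc32(":".join(parts).encode("utf-8"))
    return (int(base_seed) * 2654435761 + h) % (2**31 - 1)


@dataclass
class TrainedTaskModel:
    """A fitted model for one task on one marker panel."""

    task_id: str
    family: ModelFamily
    panel: tuple[str, ...]
    encoding_kind: str
    class_labels: tuple[str, ...]
    estimator: object
    seed: int
    train_auc: float

    @property
    def fitted_parameters(self) -> dict:
        """Serializable parameter blob; for LR the coefficient matrix itself."""
        out: dict = {"family": self.family.value, "panel": list(self.panel),
                     "class_labels": list(self.class_labels),
                     "seed": self.seed}
        if self.family is ModelFamily.LR:
            out["feature_names"] = self.feature_names
            out["coef"] = np.asarray(self.estimator.coef_).tolist()
            out["intercept"] = np.asarray(self.estimator.intercept_).tolist()
        return out

    @property
    def feature_names(self) -> list[str]:
        if self.encoding_kind == "onehot_pair":
            return [f"{m}::{s}" for m in self.panel for s in ("pos", "neg")]
        return list(self.panel)

    def to_json(self) -> str:
        return json.dumps(self.fitted_parameters, sort_keys=True)


@dataclass
class SelectionReport:
    """AUC grid over (family x task x validation cohort) and the chosen family."""

    grid: dict[tuple[ModelFamily, str, str], float]
    family_sums: dict[ModelFamily, float]
    family_means: dict[ModelFamily, float]
    chosen_family: ModelFamily

    def to_dict(self) -> dict:
        return {
            "chosen_family": self.chosen_family.value,
            "family_sum_auc": {f.value: s for f, s in self.family_sums.items()},
            "family_mean_auc": {f.value: m for f, m in self.family_means.items()},
            "grid": [
                {"family": f.value, "task_id": t, "cohort_id": c, "auc": a}
                for (f, t, c), a in sorted(
                    self.grid.items(),
                    key=lambda kv: (kv[0][0].order, kv[0][1], kv[0][2]))
            ],
        }


def _make_estimator(family: ModelFamily, seed: int, hyperparams: Mapping | None):
    params = dict(DEFAULT_HYPERPARAMS[family])
    if hyperparams:
        params.update(hyperparams)
    if family is ModelFamily.LR:
        # L2 penalty (sklearn default), single multinomial model per task
        return LogisticRegression(solver="lbfgs", **params)
    if family is ModelFamily.SVM:
        # decision-value ranking; no Platt scaling
        return SVC(decision_function_shape="ovr", random_state=seed, **params)
    if family is ModelFamily.MLP:
        return MLPClassifier(random_state=seed, **params)
    if family is ModelFamily.DT:
        return DecisionTreeClassifier(random_state=seed, **params)
    if family is ModelFamily.RF:
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family is ModelFamily.GBM:
        return XGBClassifier(random_state=seed, n_jobs=1, verbosity=0,
                             **params)
    raise ValueError(f"unknown family {family!r}")


def task_labels(cohort: Cohort, task: TaskSpec, tree=None) -> list[str]:
    """Class label of each case for *task*, derived from its leaf label."""
    tree = tree if tree is not None else default_hierarchy()
    leaf_to_class = class_label_map(tree, task.task_id)
    out = []
    for r in cohort:
        if r.subtype_label is None:
            raise ValueError(f"case {r.case_id!r} has no subtype label")
        if r.subtype_label not in leaf_to_class:
            raise ValueError(f"case {r.case_id!r}: leaf {r.subtype_label!r} "
                             f"unreachable from task {task.task_id!r}")
        out.append(leaf_to_class[r.subtype_label])
    return out


def task_training_frame(cohort: Cohort, task: TaskSpec,
                        tree=None) -> tuple[Cohort, list[str]]:
    """Restrict a cohort to a task: cases under the task's subtree that meet
    its minimum-required markers, with their class labels at that task."""
    from .marker_data import filter_eligible
    tree = tree if tree is not None else default_hierarchy()
    leaf_to_class = class_label_map(tree, task.task_id)
    in_scope = Cohort(cohort.cohort_id,
                      [r for r in cohort if r.subtype_label in leaf_to_class])
    eligible = filter_eligible(in_scope, task)
    return eligible, [leaf_to_class[r.subtype_label] for r in eligible]


def train_task_model(train: Cohort, task: TaskSpec, family: ModelFamily,
                     panel: Sequence[str], seed: int, *,
                     hyperparams: Mapping | None = None,
                     labels: Sequence[str] | None = None,
                     class_labels: Sequence[str] | None = None,
                     tree=None) -> TrainedTaskModel:
    """Fit one family on one task.

    ``train`` must already be eligibility-filtered for the task.  ``labels``
    defaults to class labels derived from each case's leaf via the hierarchy.
    ``class_labels`` defaults to the task's declared classes, and a declared
    class absent from the training labels is an error; pass the observed
    subset explicitly to train on fewer classes.
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    panel = tuple(panel)
    extra = set(panel) - set(task.full_panel)
    if extra:
        raise ValueError(f"{task.task_id}: markers outside the task's full "
                         f"panel: {sorted(extra)}")
    y = list(labels) if labels is not None else task_labels(train, task, tree)
    if len(y) != len(train):
        raise ValueError("labels length must match cohort size")
    classes = tuple(class_labels) if class_labels is not None \
        else task.class_labels
    observed = set(y)
    missing = [c for c in classes if c not in observed]
    if missing:
        raise ValueError(f"{task.task_id}: class(es) absent from training "
                         f"data: {missing}")
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train")

    dm = encode(train, panel, family.encoding_kind)
    if np.all(dm.X == dm.X[0:1, :]):
        raise ValueError("degenerate all-constant design matrix")
    class_index = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([class_index[c] for c in y])

    fit_seed = derive_seed(seed, task.task_id, family.value)
    est = _make_estimator(family, fit_seed, hyperparams)
    est.fit(dm.X, y_idx)

    model = TrainedTaskModel(
        task_id=task.task_id, family=family, panel=panel,
        encoding_kind=family.encoding_kind, class_labels=classes,
        estimator=est, seed=fit_seed, train_auc=float("nan"))
    scores = predict_scores(model, train)
    model.train_auc = auc_ovr_macro(scores, y, classes)
    return model


def predict_scores(model: TrainedTaskModel, cohort: Cohort) -> np.ndarray:
    """Per-class score matrix, columns in ``model.class_labels`` order.

    Probabilistic families return rows summing to 1; the SVM returns
    one-vs-rest decision values (rank-valid for ROC analysis).  Unknown
    markers encode exactly as at training time, so an all-unknown case scores
    as the intercept-only prediction.
    """
    dm = encode(cohort, model.panel, model.encoding_kind)
    est = model.estimator
    k = len(model.class_labels)
    if model.family is ModelFamily.SVM:
        d = est.decision_function(dm.X)
        if d.ndim == 1:  # binary: single margin for the second class
            return np.column_stack([-d, d])
        return np.asarray(d, dtype=float)
    proba = est.predict_proba(dm.X)
    # estimator classes_ are indices into model.class_labels
    out = np.zeros((len(cohort), k))
    for col, cls_idx in enumerate(np.asarray(est.classes_, dtype=int)):
        out[:, cls_idx] = proba[:, col]
    return out


def predict_labels(model: TrainedTaskModel, cohort: Cohort) -> list[str]:
    """Argmax class per case; ties go to the first class in task order."""
    scores = predict_scores(model, cohort)
    # np.argmax takes the first maximum, matching the declared tie rule
    idx = np.argmax(scores, axis=1)
    return [model.class_labels[i] for i in idx]


def select_best_family(
        grid: Mapping[tuple[ModelFamily, str, str], float]) -> SelectionReport:
    """Pick the family maximizing the summed AUC over tasks and cohorts.

    The grid must be complete over the cross product of the families, tasks
    and cohorts it mentions; missing cells are an error.  Exact ties resolve
    to the lower-ordered family (LR < SVM < MLP < DT < RF < GBM).
    """
    if not grid:
        raise ValueError("empty grid")
    families = sorted({f for f, _, _ in grid}, key=lambda f: f.order)
    tasks = sorted({t for _, t, _ in grid})
    cohorts = sorted({c for _, _, c in grid})
    missing = [(f.value, t, c) for f in families for t in tasks for c in cohorts
               if (f, t, c) not in grid]
    if missing:
        raise ValueError(f"incomplete selection grid; missing cells: {missing}")
    sums = {f: float(sum(grid[(f, t, c)] for t in tasks for c in cohorts))
            for f in families}
    means = {f: sums[f] / (len(tasks) * len(cohorts)) for f in families}
    chosen = max(families, key=lambda f: (sums[f], -f.order))
    return SelectionReport(dict(grid), sums, means, chosen)


def reference_auc(full_model: TrainedTaskModel) -> float:
    """Train-set macro one-vs-rest AUC of a full-panel model.

    This is the yardstick the panel simplification must retain a fraction of
    (99%, or 95% for the B-subtype task).
    """
    return full_model.train_auc
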