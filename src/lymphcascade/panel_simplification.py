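"""Greedy panel simplification with cross-level marker reuse.

The core cost-saving device of the system: for each task, markers are ranked
by logistic-regression coefficient magnitude on the full candidate panel
(importance of a marker = max |coefficient| over its two one-hot features and
over classes).  Markers already stained by ancestor tasks enter the panel
first as a block ("utilize all tested markers before adding new ones"); if
that block already retains the required fraction of the full model's train
AUC the task needs no new stains, otherwise the remaining markers are
appended one at a time in descending importance, refitting after each, until
the train AUC reaches the retention threshold (99% of the reference AUC, 95%
for the harder B-subtype task).  If the threshold is never met the task falls
back to its full panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cascade import CascadeSystem
from .marker_data import Cohort, filter_eligible
from .model_zoo import (ModelFamily, TrainedTaskModel, derive_seed,
                        train_task_model)
from .task_hierarchy import HierarchyNode, TaskSpec, class_label_map

__all__ = [
    "ImportanceRanking",
    "SimplifiedPanel",
    "marker_importance",
    "simplify_panel",
    "build_simplified_system",
]


@dataclass(frozen=True)
class ImportanceRanking:
    """Markers of one task's full panel in descending importance order."""

    task_id: str
    entries: tuple[tuple[str, float], ...]  # (marker, importance >= 0)

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(m for m, _ in self.entries)

    def to_dict(self) -> dict:
        return {"task_id": self.task_id,
                "ranking": [{"marker": m, "importance": v}
                            for m, v in self.entries],
                "importance_rule": "max |LR coefficient| over classes and "
                                   "over the marker's two one-hot features"}


@dataclass
class SimplifiedPanel:
    """Ordered inherited + added markers with the achieved and reference AUC."""

    task_id: str
    inherited_markers: tuple[str, ...]
    added_markers: tuple[str, ...]
    achieved_train_auc: float
    reference_auc: float
    retention_threshold: float  # fraction of reference_auc to retain
    satisfied: bool
    trace: list[dict] = field(default_factory=list)  # AUC after each refit

    @property
    def panel(self) -> tuple[str, ...]:
        return self.inherited_markers + self.added_markers

    def to_dict(self) -> dict:
        return {
            "task_id": self.task_id,
            "inherited_markers": list(self.inherited_markers),
            "added_markers": list(self.added_markers),
            "panel": list(self.panel),
            "achieved_train_auc": self.achieved_train_auc,
            "reference_auc": self.reference_auc,
            "retention_threshold": self.retention_threshold,
            "satisfied": self.satisfied,
        }


def marker_importance(model: TrainedTaskModel) -> ImportanceRanking:
    """Rank a full-panel LR model's markers by coefficient magnitude.

    importance(m) = max over classes and over m's two one-hot features of
    the absolute coefficient.  Ordering is descending; exact ties keep the
    full-panel order.
    """
    if model.family is not ModelFamily.LR:
        raise ValueError("importance ranking is defined for LR models only")
    if model.encoding_kind != "onehot_pair":
        raise ValueError("importance ranking requires the onehot_pair encoding")
    coef = np.abs(np.atleast_2d(np.asarray(model.estimator.coef_)))
    if coef.shape[1] != 2 * len(model.panel):
        raise ValueError("coefficient matrix does not match the panel")
    per_marker = [float(coef[:, 2 * j:2 * j + 2].max())
                  for j in range(len(model.panel))]
    order = sorted(range(len(model.panel)),
                   key=lambda j: (-per_marker[j], j))
    entries = tuple((model.panel[j], per_marker[j]) for j in order)
    return ImportanceRanking(model.task_id, entries)


def simplify_panel(task: TaskSpec, train: Cohort,
                   ancestor_panels: Sequence[Sequence[str]],
                   reference: float, ranking: ImportanceRanking, seed: int, *,
                   hyperparams: Mapping | None = None,
                   labels: Sequence[str] | None = None,
                   class_labels: Sequence[str] | None = None,
                   tree: HierarchyNode | None = None) -> SimplifiedPanel:
    """Grow the smallest panel retaining the task's reference AUC fraction.

    ``ancestor_panels`` are the *simplified* panels of the tasks above this
    one; their union, intersected with the task's full panel and kept in
    full-panel order, forms the inherited block.  The threshold comparison is
    a plain ``achieved >= retention * reference`` at full float precision.
    """
    if len(train) == 0:
        raise ValueError("empty training cohort")
    inherited_pool = set().union(*map(set, ancestor_panels)) if ancestor_panels else set()
    inherited = tuple(m for m in task.full_panel if m in inherited_pool)
    candidates = [m for m in ranking.markers if m not in inherited]
    if not inherited and not candidates:
        raise ValueError("nothing to select: no inherited markers and empty ranking")
    threshold = task.auc_retention * reference

    def fit(panel: Sequence[str]) -> float:
        model = train_task_model(
            train, task, ModelFamily.LR, panel, seed,
            hyperparams=hyperparams, labels=labels,
            class_labels=class_labels, tree=tree)
        return model.train_auc

    trace: list[dict] = []
    added: list[str] = []

    def record(auc: float) -> None:
        trace.append({"n_markers": len(inherited) + len(added),
                      "added": list(added), "train_auc": auc})

    achieved = -np.inf
    if inherited:
        achieved = fit(inherited)
        record(achieved)
        if achieved >= threshold:
            return SimplifiedPanel(task.task_id, inherited, (), achieved,
                                   reference, task.auc_retention, True, trace)
    for marker in candidates:
        added.append(marker)
        achieved = fit(tuple(inherited) + tuple(added))
        record(achieved)
        if achieved >= threshold:
            return SimplifiedPanel(task.task_id, inherited, tuple(added),
                                   achieved, reference, task.auc_retention,
                                   True, trace)
    warnings.warn(f"{task.task_id}: retention threshold "
                  f"{task.auc_retention:.2f} x {reference:.4f} never met; "
                  "falling back to the full panel", stacklevel=2)
    full = tuple(task.full_panel)
    achieved = fit(full)
    return SimplifiedPanel(task.task_id, inherited,
                           tuple(m for m in full if m not in inherited),
                           achieved, reference, task.auc_retention, False,
                           trace)


def build_simplified_system(train: Cohort, tree: HierarchyNode,
                            family: ModelFamily = ModelFamily.LR,
                            seed: int = 0, *,
                            hyperparams: Mapping | None = None
                            ) -> CascadeSystem:
    """Build the whole simplified cascade from a labeled training cohort.

    Tasks are visited root-to-leaf; each task is eligibility-filtered, a
    full-panel model fit (its train AUC is the reference), markers ranked,
    the panel simplified with the ancestors' already-simplified panels, and a
    final model fit on the simplified panel.  Coefficient-based importance is
    defined for LR, the family the original selection stage chose; other
    families are rejected.
    """
    if family is not ModelFamily.LR:
        raise ValueError("the simplification pipeline is defined for the LR "
                         "family (coefficient-based importance)")
    panels: dict[str, SimplifiedPanel] = {}
    models: dict[str, TrainedTaskModel] = {}
    full_models: dict[str, TrainedTaskModel] = {}
    rankings: dict[str, ImportanceRanking] = {}

    def visit(node: HierarchyNode, ancestors: list[str]) -> None:
        if node.is_leaf:
            return
        task = node.task
        leaf_to_class = class_label_map(tree, task.task_id)
        # a task sees only cases whose true subtype lies under its node
        in_scope = Cohort(train.cohort_id,
                          [r for r in train if r.subtype_label in leaf_to_class])
        eligible = filter_eligible(in_scope, task)
        labels = [leaf_to_class[r.subtype_label] for r in eligible]
        observed = set(labels)
        present = tuple(c for c in task.class_labels if c in observed)
        if len(present) < 2:
            raise ValueError(f"{task.task_id}: fewer than 2 classes present "
                             "after eligibility filtering")
        full = train_task_model(
            eligible, task, family, task.full_panel, seed,
            hyperparams=hyperparams, labels=labels, class_labels=present,
            tree=tree)
        ranking = marker_importance(full)
        ancestor_panels = [panels[a].panel for a in ancestors]
        simplified = simplify_panel(
            task, eligible, ancestor_panels, full.train_auc, ranking,
            seed, hyperparams=hyperparams, labels=labels,
            class_labels=present, tree=tree)
        model = train_task_model(
            eligible, task, family, simplified.panel, seed,
            hyperparams=hyperparams, labels=labels, class_labels=present,
            tree=tree)
        full_models[task.task_id] = full
        rankings[task.task_id] = ranking
        panels[task.task_id] = simplified
        models[task.task_id] = model
        for label in task.class_labels:
            visit(node.children[label], ancestors + [task.task_id])

    visit(tree, [])
    return CascadeSystem(
        tree=tree, panels=panels, models=models,
        metadata={"seed": int(seed), "family": family.value,
                  "reference_aucs": {t: m.train_auc
                                     for t, m in full_models.items()},
                  "rankings": {t: r.to_dict() for t, r in rankings.items()}})
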