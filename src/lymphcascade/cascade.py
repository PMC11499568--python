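"""Sequential hierarchical inference and the marker-cost report.

A built system routes each case from the root task downward: the task's
simplified-panel model scores the case, the argmax class picks the child, and
the walk stops at a leaf.  Cost accounting compares, per hierarchy level, the
cumulative number of distinct markers the system needs on the root-to-leaf
path against the number actually measured in the clinic, with a
record-weighted overall mean; routing for cost purposes follows the *true*
subtype (the panel a case would need given its diagnosis), while predicted
routing drives the classification metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd

from .marker_data import CaseRecord, Cohort, filter_eligible
from .metrics import MetricSet, auc_ovr_macro, classification_metrics, panel_size_test
from .model_zoo import TrainedTaskModel, predict_scores
from .task_hierarchy import HierarchyNode, class_label_map, route_to_leaf

if TYPE_CHECKING:  # circular at runtime: panel_simplification imports us
    from .panel_simplification import SimplifiedPanel

__all__ = [
    "CascadeSystem",
    "CasePrediction",
    "CostReport",
    "LevelCost",
    "predict_case",
    "cumulative_panel_size",
    "cost_report",
    "evaluate_system",
]


@dataclass
class CascadeSystem:
    """The decision tree plus, per task, a simplified panel and (optionally) a model."""

    tree: HierarchyNode
    panels: dict[str, "SimplifiedPanel"]
    models: dict[str, TrainedTaskModel] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        task_ids = {n.task.task_id for n in self.tree.iter_task_nodes()}
        missing = task_ids - set(self.panels)
        if missing:
            raise ValueError(f"no simplified panel for task(s): {sorted(missing)}")
        for t, m in self.models.items():
            if tuple(m.panel) != tuple(self.panels[t].panel):
                raise ValueError(f"{t}: model panel differs from simplified panel")

    @classmethod
    def from_panels(cls, tree: HierarchyNode,
                    panels: Mapping[str, Sequence[str]] |
                    Mapping[str, "SimplifiedPanel"],
                    metadata: dict | None = None) -> "CascadeSystem":
        """Panel-only system (no fitted models); supports routing and cost ops.

        ``panels`` may map task ids to bare marker lists; these are wrapped
        into :class:`SimplifiedPanel` records with no recorded AUCs.
        """
        from .panel_simplification import SimplifiedPanel
        wrapped: dict[str, SimplifiedPanel] = {}
        for t, p in panels.items():
            if isinstance(p, SimplifiedPanel):
                wrapped[t] = p
            else:
                wrapped[t] = SimplifiedPanel(
                    task_id=t, inherited_markers=(), added_markers=tuple(p),
                    achieved_train_auc=float("nan"),
                    reference_auc=float("nan"),
                    retention_threshold=float("nan"), satisfied=True)
        return cls(tree=tree, panels=wrapped, metadata=metadata or {})

    def panels_json(self) -> str:
        return json.dumps({t: p.to_dict() for t, p in sorted(self.panels.items())},
                          sort_keys=True, indent=2, allow_nan=True)


@dataclass
class CasePrediction:
    """Decision trace of one case through the cascade."""

    case_id: str
    decisions: tuple[tuple[str, str, tuple[float, ...]], ...]  # (task, class, scores)
    leaf_label: str
    markers_consulted: frozenset[str]
    low_information: bool  # no panel marker of any visited task was known

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "decisions": [{"task_id": t, "predicted_class": c,
                           "scores": list(s)} for t, c, s in self.decisions],
            "leaf_label": self.leaf_label,
            "markers_consulted": sorted(self.markers_consulted),
            "low_information": self.low_information,
        }


def predict_case(system: CascadeSystem, case: CaseRecord) -> CasePrediction:
    """Route one case root-to-leaf through the fitted cascade.

    Ties at a task resolve to the first class in the task's declared order
    (argmax convention).  Unknown markers are allowed; a case with no known
    marker in any consulted panel is flagged ``low_information`` and is
    effectively predicted from the intercepts.
    """
    node = system.tree
    decisions: list[tuple[str, str, tuple[float, ...]]] = []
    consulted: set[str] = set()
    any_known = False
    single = Cohort("single", [case])
    while not node.is_leaf:
        task_id = node.task.task_id
        model = system.models.get(task_id)
        if model is None:
            raise ValueError(f"no fitted model for task {task_id!r}")
        consulted.update(model.panel)
        if case.known_markers() & set(model.panel):
            any_known = True
        scores = predict_scores(model, single)[0]
        chosen = model.class_labels[int(np.argmax(scores))]
        decisions.append((task_id, chosen, tuple(float(s) for s in scores)))
        node = node.children[chosen]
    return CasePrediction(
        case_id=case.case_id, decisions=tuple(decisions),
        leaf_label=node.leaf_label, markers_consulted=frozenset(consulted),
        low_information=not any_known)


def cumulative_panel_size(system: CascadeSystem, leaf_label: str) -> int:
    """Number of distinct markers on the root-to-leaf path's simplified panels."""
    path = route_to_leaf(system.tree, leaf_label)
    union: set[str] = set()
    for task_id in path.task_ids:
        union.update(system.panels[task_id].panel)
    return len(union)


# ---------------------------------------------------------------------------
# cost report
# ---------------------------------------------------------------------------

@dataclass
class LevelCost:
    """One hierarchy level of the cost table (its terminal leaves)."""

    task_id: str
    display_name: str
    leaves: tuple[str, ...]
    n_records: int
    clinical_mean: float | None
    cumulative_required: int
    saving_pct: float | None
    p_value: float | None


@dataclass
class CostReport:
    """Per-level and record-weighted overall marker-cost comparison.

    Savings are computed from means rounded to two decimals — the convention
    of the printed clinical report this table mirrors — as
    ``(clinical - required) / clinical * 100`` (signed; negative when the
    system needs more markers than the clinic measured).
    """

    levels: list[LevelCost]
    n_records: int
    weighted_required_mean: float
    clinical_mean: float | None
    overall_saving_pct: float | None
    overall_p_value: float | None

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "task": lv.display_name,
            "final_leaves": ", ".join(lv.leaves),
            "n_records": lv.n_records,
            "clinical_mean_markers": lv.clinical_mean,
            "cumulative_required_markers": lv.cumulative_required,
            "saving_pct": lv.saving_pct,
            "p_value": lv.p_value,
        } for lv in self.levels]
        rows.append({
            "task": "Average number of markers to reach the final leaves",
            "final_leaves": "",
            "n_records": self.n_records,
            "clinical_mean_markers": self.clinical_mean,
            "cumulative_required_markers": self.weighted_required_mean,
            "saving_pct": self.overall_saving_pct,
            "p_value": self.overall_p_value,
        })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        df = self.to_frame()
        return {"rows": df.to_dict(orient="records")}


def _saving_pct(clinical_mean: float | None, required_mean: float) -> float | None:
    if clinical_mean is None:
        return None
    c = round(float(clinical_mean), 2)
    r = round(float(required_mean), 2)
    if c == 0:
        return None
    return (c - r) / c * 100.0


def terminal_leaves_by_level(tree: HierarchyNode) -> list[tuple[str, str, tuple[str, ...]]]:
    """Per task node (preorder): its id, display name, and direct leaf children."""
    out = []
    for node in tree.iter_task_nodes():
        leaves = tuple(label for label in node.task.class_labels
                       if node.children[label].is_leaf)
        out.append((node.task.task_id, node.task.display_name, leaves))
    return out


def cost_report(system: CascadeSystem, leaf_counts: Mapping[str, int],
                clinical_means: Mapping[str, float] | None = None,
                per_case_clinical: Mapping[str, Sequence[float]] | None = None
                ) -> CostReport:
    """Cost table: per level and overall, system markers vs clinical markers.

    Parameters
    ----------
    leaf_counts
        Record count per terminal leaf (true-subtype routing).
    clinical_means
        Mean clinically-tested marker count per level, keyed by task id.
        Derived from ``per_case_clinical`` when omitted.
    per_case_clinical
        Raw per-case clinical counts per level (task id -> counts); enables
        the Mann-Whitney/Welch p-values.
    """
    levels_spec = terminal_leaves_by_level(system.tree)
    known_leaves = set(system.tree.leaves())
    unknown = set(leaf_counts) - known_leaves
    if unknown:
        raise KeyError(f"unknown leaves in leaf_counts: {sorted(unknown)}")

    levels: list[LevelCost] = []
    tot_records = 0
    req_weighted = 0.0
    clin_weighted = 0.0
    have_clinical = True
    all_required: list[float] = []
    all_clinical: list[float] = []
    for task_id, display, leaves in levels_spec:
        n = int(sum(leaf_counts.get(l, 0) for l in leaves))
        if not leaves or n == 0:
            continue
        cums = {cumulative_panel_size(system, l) for l in leaves}
        if len(cums) != 1:
            raise ValueError(f"{task_id}: terminal leaves disagree on "
                             f"cumulative panel size: {sorted(cums)}")
        cum = cums.pop()
        raw = list(per_case_clinical.get(task_id, [])) if per_case_clinical else []
        if clinical_means is not None and task_id in clinical_means:
            cmean = float(clinical_means[task_id])
        elif raw:
            cmean = float(np.mean(raw))
        else:
            cmean = None
        p = panel_size_test([cum] * n, raw) if raw else None
        levels.append(LevelCost(task_id, display, leaves, n, cmean, cum,
                                _saving_pct(cmean, cum), p))
        tot_records += n
        req_weighted += n * cum
        if cmean is None:
            have_clinical = False
        else:
            clin_weighted += n * cmean
        all_required.extend([float(cum)] * n)
        all_clinical.extend(raw)
    if tot_records == 0:
        raise ValueError("zero total records across terminal leaves")

    weighted_required = req_weighted / tot_records
    overall_clin = clin_weighted / tot_records if have_clinical else None
    overall_p = (panel_size_test(all_required, all_clinical)
                 if all_clinical else None)
    return CostReport(
        levels=levels, n_records=tot_records,
        weighted_required_mean=weighted_required,
        clinical_mean=overall_clin,
        overall_saving_pct=_saving_pct(overall_clin, weighted_required),
        overall_p_value=overall_p)


def leaf_counts_from_cohort(cohort: Cohort) -> dict[str, int]:
    """Record count per true subtype leaf (cost-accounting convention)."""
    counts: dict[str, int] = {}
    for r in cohort:
        if r.subtype_label is not None:
            counts[r.subtype_label] = counts.get(r.subtype_label, 0) + 1
    return counts


def clinical_counts_by_level(system: CascadeSystem,
                             cohort: Cohort) -> dict[str, list[float]]:
    """Group per-case clinical tested counts by the level their true leaf ends at."""
    level_of_leaf: dict[str, str] = {}
    for task_id, _, leaves in terminal_leaves_by_level(system.tree):
        for l in leaves:
            level_of_leaf[l] = task_id
    out: dict[str, list[float]] = {}
    for r in cohort:
        if r.subtype_label is None or r.clinical_tested_count is None:
            continue
        task_id = level_of_leaf.get(r.subtype_label)
        if task_id is not None:
            out.setdefault(task_id, []).append(float(r.clinical_tested_count))
    return out


def evaluate_system(system: CascadeSystem, cohort: Cohort,
                    cohort_label: str | None = None) -> pd.DataFrame:
    """Per-task metric table on one validation cohort (tidy, one row per task).

    Each task is evaluated on its eligibility-filtered sub-cohort with the
    case's true class at that task; AUC is macro one-vs-rest over classes
    present.
    """
    rows = []
    for node in system.tree.iter_task_nodes():
        task = node.task
        model = system.models.get(task.task_id)
        if model is None:
            raise ValueError(f"no fitted model for task {task.task_id!r}")
        eligible = filter_eligible(cohort, task)
        leaf_to_class = class_label_map(system.tree, task.task_id)
        labeled = [r for r in eligible if r.subtype_label in leaf_to_class]
        sub = Cohort(cohort.cohort_id, labeled)
        if len(sub) == 0:
            continue
        truth = [leaf_to_class[r.subtype_label] for r in sub]
        scores = predict_scores(model, sub)
        preds = [model.class_labels[i] for i in np.argmax(scores, axis=1)]
        try:
            auc = auc_ovr_macro(scores, truth, model.class_labels)
        except ValueError:
            auc = float("nan")
        ms: MetricSet = classification_metrics(
            preds, truth, class_labels=model.class_labels, auc=auc)
        row = {"task_id": task.task_id, "task": task.display_name,
               "cohort": cohort_label or cohort.cohort_id,
               "simplified_panel": ", ".join(model.panel),
               "n": len(sub), **ms.to_dict()}
        rows.append(row)
    return pd.DataFrame(rows)
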