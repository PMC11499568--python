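"""The five classification tasks, the WHO-aligned decision tree, and the Hans rule.

The classifier mimics a pathologist's stepwise differential diagnosis: Hodgkin
vs non-Hodgkin lymphoma at the root, then NHL lineage (B / T / NK), then
lineage-specific subtyping, and finally cell-of-origin (GCB vs non-GCB) for
DLBCL.  Task definitions (class labels, minimum-required marker expressions,
candidate panels, AUC-retention thresholds) are data, shipped as a packaged
YAML config so alternate taxonomies can be declared without code changes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import yaml

from .marker_data import (CaseRecord, Expression, MarkerStatus,
                          normalize_marker, parse_expression,
                          expression_from_dict)

__all__ = [
    "TaskSpec",
    "HierarchyNode",
    "RoutePath",
    "TASK_IDS",
    "LEAF_LABELS",
    "default_tasks",
    "default_hierarchy",
    "load_hierarchy",
    "route_to_leaf",
    "class_label_map",
    "hans_classify",
    "distinct_markers",
]

TASK_IDS = ("t_hl_nhl", "t_nhl_sub", "t_b_sub", "t_t_sub", "t_dlbcl_coo")

#: Terminal diagnoses of the default tree (Hodgkin lymphoma; NK-cell NHL;
#: the B-cell subtypes; DLBCL cell-of-origin classes; the T-cell subtypes).
LEAF_LABELS = ("HL", "NK-NHL", "FL", "MZL", "MCL", "BL", "SLL", "PMLBCL",
               "B-LBL/ALL", "Others", "GCB", "non-GCB",
               "ALCL", "AITL", "TLBL", "PTCL-U")

# copy-pasted labels often carry Unicode hyphens; fold to ASCII
_HYPHENS = re.compile(r"[‐‑‒–—−]")


def normalize_label(label: str) -> str:
    return _HYPHENS.sub("-", label.strip())


@dataclass(frozen=True)
class TaskSpec:
    """One classification task of the hierarchy."""

    task_id: str
    display_name: str
    class_labels: tuple[str, ...]
    min_required_expr: Expression
    full_panel: tuple[str, ...]
    auc_retention: float

    def __post_init__(self) -> None:
        if not 0.0 < self.auc_retention <= 1.0:
            raise ValueError("auc_retention must lie in (0, 1]")
        if len(set(self.full_panel)) != len(self.full_panel):
            raise ValueError(f"{self.task_id}: duplicate markers in full panel")


@dataclass
class HierarchyNode:
    """Either an internal task node (children keyed by class label) or a leaf."""

    task: TaskSpec | None = None
    children: dict[str, "HierarchyNode"] = field(default_factory=dict)
    leaf_label: str | None = None

    @property
    def is_leaf(self) -> bool:
        return self.leaf_label is not None

    def __post_init__(self) -> None:
        if self.is_leaf == (self.task is not None):
            raise ValueError("node must be exactly one of task node / leaf")
        if self.task is not None:
            missing = set(self.task.class_labels) - set(self.children)
            if missing:
                raise ValueError(
                    f"{self.task.task_id}: classes without children: {missing}")

    def iter_task_nodes(self) -> Iterator["HierarchyNode"]:
        """Preorder over task nodes, children visited in class-label order."""
        if self.is_leaf:
            return
        yield self
        for label in self.task.class_labels:
            yield from self.children[label].iter_task_nodes()

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.leaf_label]
        out: list[str] = []
        for label in self.task.class_labels:
            out.extend(self.children[label].leaves())
        return out

    def find_task(self, task_id: str) -> "HierarchyNode":
        for node in self.iter_task_nodes():
            if node.task.task_id == task_id:
                return node
        raise KeyError(f"no task {task_id!r} in hierarchy")


@dataclass(frozen=True)
class RoutePath:
    """Root-to-leaf path: the tasks visited and the class chosen at each."""

    steps: tuple[tuple[str, str], ...]  # (task_id, chosen class label)
    leaf_label: str

    @property
    def task_ids(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.steps)


# ---------------------------------------------------------------------------
# config loading
# ---------------------------------------------------------------------------

def _task_from_config(obj: Mapping) -> TaskSpec:
    raw = obj["min_required"]
    expr = (parse_expression(raw) if isinstance(raw, str)
            else expression_from_dict(raw))
    return TaskSpec(
        task_id=str(obj["task_id"]),
        display_name=str(obj["display_name"]),
        class_labels=tuple(normalize_label(str(c)) for c in obj["class_labels"]),
        min_required_expr=expr,
        full_panel=tuple(normalize_marker(m) for m in obj["full_panel"]),
        auc_retention=float(obj["auc_retention"]),
    )


def _node_from_config(obj: Mapping, tasks: Mapping[str, TaskSpec],
                      seen: set[str]) -> HierarchyNode:
    if "leaf" in obj:
        return HierarchyNode(leaf_label=normalize_label(str(obj["leaf"])))
    task_id = str(obj["task"])
    if task_id in seen:
        raise ValueError(f"task {task_id!r} appears more than once in tree")
    seen.add(task_id)
    task = tasks[task_id]
    children = {normalize_label(str(k)): _node_from_config(v, tasks, seen)
                for k, v in obj["children"].items()}
    return HierarchyNode(task=task, children=children)


def _load_config(config: Mapping) -> tuple[dict[str, TaskSpec], HierarchyNode]:
    tasks = {t["task_id"]: _task_from_config(t) for t in config["tasks"]}
    root = _node_from_config(config["hierarchy"], tasks, set())
    return tasks, root


def _default_config() -> Mapping:
    text = (resources.files("lymphcascade") / "data" / "default_tasks.yaml") \
        .read_text(encoding="utf-8")
    return yaml.safe_load(text)


def default_tasks() -> dict[str, TaskSpec]:
    """The five packaged task specifications, keyed by task id."""
    tasks, _ = _load_config(_default_config())
    return tasks


def default_hierarchy() -> HierarchyNode:
    """The packaged five-step decision tree (root: HL vs NHL)."""
    _, root = _load_config(_default_config())
    return root


def load_hierarchy(path: str | Path) -> tuple[dict[str, TaskSpec], HierarchyNode]:
    """Load a custom task/hierarchy config (same YAML schema as the default)."""
    config = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return _load_config(config)


# ---------------------------------------------------------------------------
# routing
# ---------------------------------------------------------------------------

def route_to_leaf(tree: HierarchyNode, leaf_label: str) -> RoutePath:
    """Unique root-to-leaf path whose decisions are the edge class labels."""
    leaf_label = normalize_label(leaf_label)

    def walk(node: HierarchyNode, steps: list[tuple[str, str]]) -> RoutePath | None:
        if node.is_leaf:
            return RoutePath(tuple(steps), leaf_label) \
                if node.leaf_label == leaf_label else None
        for label in node.task.class_labels:
            found = walk(node.children[label],
                         steps + [(node.task.task_id, label)])
            if found is not None:
                return found
        return None

    path = walk(tree, [])
    if path is None:
        raise KeyError(f"unknown leaf label {leaf_label!r}; "
                       f"leaves: {sorted(tree.leaves())}")
    return path


def class_label_map(tree: HierarchyNode, task_id: str) -> dict[str, str]:
    """Map each leaf reachable from *task* to its class label at that task."""
    node = tree.find_task(task_id)
    out: dict[str, str] = {}
    for label in node.task.class_labels:
        for leaf in node.children[label].leaves():
            out[leaf] = label
    return out


def distinct_markers(tasks: Mapping[str, TaskSpec] | None = None) -> set[str]:
    """Union of all candidate panels (32 markers for the default tasks)."""
    tasks = tasks if tasks is not None else default_tasks()
    out: set[str] = set()
    for t in tasks.values():
        out.update(t.full_panel)
    return out


# ---------------------------------------------------------------------------
# Hans cell-of-origin comparator
# ---------------------------------------------------------------------------

def hans_classify(cd10: MarkerStatus, bcl6: MarkerStatus,
                  mum1: MarkerStatus) -> str:
    """Hans immunohistochemical cell-of-origin rule for DLBCL.

    CD10 positive -> GCB; otherwise Bcl-6 negative -> non-GCB; otherwise
    MUM-1 positive -> non-GCB, MUM-1 negative -> GCB.  If a status consulted
    by the active branch is unknown the call is ``"indeterminate"``.
    """
    if cd10 is MarkerStatus.POSITIVE:
        return "GCB"
    if cd10 is MarkerStatus.UNKNOWN:
        return "indeterminate"
    if bcl6 is MarkerStatus.NEGATIVE:
        return "non-GCB"
    if bcl6 is MarkerStatus.UNKNOWN:
        return "indeterminate"
    if mum1 is MarkerStatus.POSITIVE:
        return "non-GCB"
    if mum1 is MarkerStatus.UNKNOWN:
        return "indeterminate"
    return "GCB"


def hans_classify_record(record: CaseRecord) -> str:
    """Apply the Hans rule to a case's CD10 / Bcl-6 / MUM-1 statuses."""
    return hans_classify(record.status("CD10"), record.status("Bcl-6"),
                         record.status("MUM-1"))
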