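"""lymphcascade: hierarchical lymphoma classification from tri-state IHC markers.

A five-step cascade (HL vs NHL, NHL lineage, B subtypes, T subtypes, DLBCL
cell of origin) trained on tri-state immunomarker tables, with greedy
coefficient-ranked panel simplification that reuses markers stained at upper
levels, and marker-cost accounting against clinical practice.
"""

from __future__ import annotations

import json
from importlib import resources

from .marker_data import (CANONICAL_MARKERS, CaseRecord, Cohort, DesignMatrix,
                          Dialect, DEFAULT_DIALECT, MarkerStatus,
                          encode_categorical, encode_onehot, filter_eligible,
                          normalize_marker, parse_expression, read_cohort,
                          write_cohort)
from .task_hierarchy import (LEAF_LABELS, TASK_IDS, HierarchyNode, RoutePath,
                             TaskSpec, class_label_map, default_hierarchy,
                             default_tasks, distinct_markers, hans_classify,
                             route_to_leaf)
from .model_zoo import (DEFAULT_HYPERPARAMS, ModelFamily, SelectionReport,
                        TrainedTaskModel, predict_labels, predict_scores,
                        reference_auc, select_best_family, train_task_model)
from .metrics import (MetricSet, auc_ovr_macro, classification_metrics,
                      marker_expression_test, panel_size_test)
from .panel_simplification import (ImportanceRanking, SimplifiedPanel,
                                   build_simplified_system, marker_importance,
                                   simplify_panel)
from .cascade import (CascadeSystem, CasePrediction, CostReport,
                      clinical_counts_by_level, cost_report,
                      cumulative_panel_size, evaluate_system,
                      leaf_counts_from_cohort, predict_case)
from .synthetic_cohort import (GeneratorConfig, TruthRecord, default_config,
                               generate_cohort)

__version__ = "0.1.0"


def reference_study() -> dict:
    """The packaged published-value fixture (simplified panels, leaf counts,
    clinical marker means) used to reproduce the panel-reuse arithmetic and
    the cost comparison without patient-level data."""
    text = (resources.files("lymphcascade") / "data" / "reference_study.json") \
        .read_text(encoding="utf-8")
    return json.loads(text)
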