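"""Importance ranking and the greedy AUC-retention panel search."""

import warnings

import numpy as np
import pytest

import lymphcascade as lc
from lymphcascade.marker_data import parse_expression
from lymphcascade.model_zoo import ModelFamily, TrainedTaskModel, train_task_model
from lymphcascade.panel_simplification import (ImportanceRanking,
                                               build_simplified_system,
                                               marker_importance,
                                               simplify_panel)
from lymphcascade.task_hierarchy import TaskSpec


def _lr_stub(panel, coef):
    """TrainedTaskModel wrapper around a bare coefficient matrix."""

    class _Est:
        pass

    est = _Est()
    est.coef_ = np.asarray(coef, dtype=float)
    return TrainedTaskModel(
        task_id="t_hl_nhl", family=ModelFamily.LR, panel=tuple(panel),
        encoding_kind="onehot_pair", class_labels=("A", "B"),
        estimator=est, seed=0, train_auc=1.0)


class TestImportance:
    def test_max_abs_over_pair(self):
        model = _lr_stub(["CD30"], [[2.1, -0.3]])
        ranking = marker_importance(model)
        assert ranking.entries == (("CD30", 2.1),)

    def test_max_over_classes_and_features(self):
        model = _lr_stub(["CD30", "CD5"],
                         [[0.2, -0.1, 1.5, 0.4],
                          [-3.0, 0.0, 0.3, -0.2]])
        ranking = marker_importance(model)
        assert ranking.entries == (("CD30", 3.0), ("CD5", 1.5))

    def test_all_zero_ties_keep_panel_order(self):
        model = _lr_stub(["CD5", "CD30", "LCA"], [[0.0] * 6])
        ranking = marker_importance(model)
        assert ranking.markers == ("CD5", "CD30", "LCA")
        assert all(v == 0.0 for _, v in ranking.entries)

    def test_non_lr_model_rejected(self):
        model = _lr_stub(["CD30"], [[1.0, 0.0]])
        model.family = ModelFamily.RF
        with pytest.raises(ValueError, match="LR"):
            marker_importance(model)


def _toy_task(markers, retention=0.99):
    return TaskSpec("toy", "toy task", ("A", "B"),
                    parse_expression(" OR ".join(markers)), tuple(markers),
                    retention)


def _toy_cohort(markers, informative, n=3000, seed=0, missingness=0.1):
    pos = {leaf: {m: 0.5 for m in markers} for leaf in ("A", "B")}
    for m in informative:
        pos["A"][m], pos["B"][m] = 0.9, 0.1
    config = lc.GeneratorConfig(
        n=n, seed=seed, leaf_prevalence={"A": 0.5, "B": 0.5}, positivity=pos,
        missingness={m: missingness for m in markers},
        clinical_count_model={"kind": "fixed", "value": len(markers)})
    cohort, _ = lc.generate_cohort(config)
    return cohort, [r.subtype_label for r in cohort]


MARKERS = ["CD30", "CD5", "CD10", "CD20", "CD56", "TIA1", "TdT", "CD23"]


class TestSimplifyPanel:
    def test_zero_reference_returns_inherited_only(self):
        task = _toy_task(MARKERS)
        cohort, labels = _toy_cohort(MARKERS, ["CD30"], n=300)
        ranking = ImportanceRanking("toy", tuple((m, 1.0) for m in MARKERS))
        sp = simplify_panel(task, cohort, [["CD5", "CD20"]], reference=0.0,
                            ranking=ranking, seed=0, labels=labels,
                            class_labels=("A", "B"))
        assert sp.inherited_markers == ("CD5", "CD20")
        assert sp.added_markers == ()
        assert sp.satisfied

    def test_inherited_ordered_by_full_panel(self):
        task = _toy_task(MARKERS)
        cohort, labels = _toy_cohort(MARKERS, ["CD30"], n=300)
        ranking = ImportanceRanking("toy", tuple((m, 1.0) for m in MARKERS))
        sp = simplify_panel(task, cohort, [["CD20"], ["CD5", "Ki67"]],
                            reference=0.0, ranking=ranking, seed=0,
                            labels=labels, class_labels=("A", "B"))
        # Ki67 is outside the task panel; CD5 precedes CD20 in panel order
        assert sp.inherited_markers == ("CD5", "CD20")

    def test_empty_train_rejected(self):
        task = _toy_task(MARKERS)
        ranking = ImportanceRanking("toy", tuple((m, 1.0) for m in MARKERS))
        with pytest.raises(ValueError, match="empty"):
            simplify_panel(task, lc.Cohort("e", []), [], 0.9, ranking, 0)

    def test_stopping_panel_is_minimal_among_evaluated_prefixes(self):
        task = _toy_task(MARKERS)
        cohort, labels = _toy_cohort(MARKERS, ["CD30", "CD5"], n=4000, seed=3)
        full = train_task_model(cohort, task, ModelFamily.LR, MARKERS, 3,
                                labels=labels, class_labels=("A", "B"))
        ranking = marker_importance(full)
        sp = simplify_panel(task, cohort, [], full.train_auc, ranking, 3,
                            labels=labels, class_labels=("A", "B"))
        assert sp.satisfied
        threshold = sp.retention_threshold * sp.reference_auc
        assert sp.achieved_train_auc >= threshold

        def refit_auc(panel):
            m = train_task_model(cohort, task, ModelFamily.LR, panel, 3,
                                 labels=labels, class_labels=("A", "B"))
            return m.train_auc

        # replay every evaluated proper prefix: all must fail the threshold
        sequence = list(sp.panel)
        start = len(sp.inherited_markers) or 1
        for k in range(start, len(sequence)):
            assert refit_auc(sequence[:k]) < threshold

    def test_unmet_threshold_falls_back_to_full_panel(self):
        # pure-noise markers cannot retain an inflated reference AUC
        task = _toy_task(MARKERS[:4])
        cohort, labels = _toy_cohort(MARKERS[:4], [], n=400, seed=5)
        ranking = ImportanceRanking("toy",
                                    tuple((m, 1.0) for m in MARKERS[:4]))
        with pytest.warns(UserWarning, match="never met"):
            sp = simplify_panel(task, cohort, [], reference=1.5,
                                ranking=ranking, seed=5, labels=labels,
                                class_labels=("A", "B"))
        assert not sp.satisfied
        assert set(sp.panel) == set(MARKERS[:4])

    def test_deterministic_for_fixed_inputs(self):
        task = _toy_task(MARKERS)
        cohort, labels = _toy_cohort(MARKERS, ["CD30", "CD5"], n=1500, seed=7)
        full = train_task_model(cohort, task, ModelFamily.LR, MARKERS, 7,
                                labels=labels, class_labels=("A", "B"))
        ranking = marker_importance(full)
        args = dict(labels=labels, class_labels=("A", "B"))
        sp1 = simplify_panel(task, cohort, [], full.train_auc, ranking, 7, **args)
        sp2 = simplify_panel(task, cohort, [], full.train_auc, ranking, 7, **args)
        assert sp1.to_dict() == sp2.to_dict()

    def test_recovers_informative_markers_single_seed(self):
        cohort, labels = _toy_cohort(MARKERS + ["ALK", "Ki67"],
                                     ["CD30", "CD5"], n=5000, seed=11)
        task = _toy_task(MARKERS + ["ALK", "Ki67"])
        full = train_task_model(cohort, task, ModelFamily.LR,
                                task.full_panel, 11, labels=labels,
                                class_labels=("A", "B"))
        ranking = marker_importance(full)
        sp = simplify_panel(task, cohort, [], full.train_auc, ranking, 11,
                            labels=labels, class_labels=("A", "B"))
        selected = set(sp.panel)
        assert {"CD30", "CD5"} <= selected
        assert len(selected - {"CD30", "CD5"}) <= 1


class TestBuildSystem:
    def test_ancestor_panels_propagate(self, trained_system):
        coo = trained_system.panels["t_dlbcl_coo"]
        upstream = set().union(
            *(trained_system.panels[t].panel
              for t in ("t_hl_nhl", "t_nhl_sub", "t_b_sub")))
        expected_inherited = tuple(
            m for m in ("CD10", "MUM-1", "Bcl-6") if m in upstream)
        assert coo.inherited_markers == expected_inherited

    def test_threshold_contract_holds_for_every_task(self, trained_system,
                                                     tasks):
        for task_id, sp in trained_system.panels.items():
            if sp.satisfied:
                assert sp.achieved_train_auc >= \
                    sp.retention_threshold * sp.reference_auc
            else:
                assert set(sp.panel) == set(tasks[task_id].full_panel)

    def test_panels_subset_of_full_panels(self, trained_system, tasks):
        for task_id, sp in trained_system.panels.items():
            assert set(sp.panel) <= set(tasks[task_id].full_panel)
            assert len(sp.panel) == len(set(sp.panel))

    def test_non_lr_family_rejected(self, synthetic_split, tree):
        train, _ = synthetic_split
        with pytest.raises(ValueError, match="LR"):
            build_simplified_system(train, tree, ModelFamily.RF, seed=0)

    def test_single_task_tree_has_no_inheritance(self, synthetic_split):
        from lymphcascade.task_hierarchy import HierarchyNode, default_tasks
        train, _ = synthetic_split
        task = default_tasks()["t_hl_nhl"]
        # degenerate tree: the root task only, every class a leaf
        tree = HierarchyNode(task=task, children={
            "HL": HierarchyNode(leaf_label="HL"),
            "NHL": HierarchyNode(leaf_label="NK-NHL"),
        })
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            system = build_simplified_system(train, tree, seed=0)
        assert system.panels["t_hl_nhl"].inherited_markers == ()
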