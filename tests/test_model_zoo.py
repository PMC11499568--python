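"""Model families: training contracts, determinism, scoring, family selection."""

import numpy as np
import pytest

import lymphcascade as lc
from lymphcascade.marker_data import CaseRecord, Cohort, MarkerStatus
from lymphcascade.model_zoo import (ModelFamily, predict_scores,
                                    reference_auc, select_best_family,
                                    task_training_frame, train_task_model)

P, N, U = MarkerStatus.POSITIVE, MarkerStatus.NEGATIVE, MarkerStatus.UNKNOWN


def _separable_cohort(n=40):
    """CD30-positive cases are HL, CD30-negative are NHL leaves."""
    records = []
    for i in range(n):
        if i % 2 == 0:
            records.append(CaseRecord(f"h{i}", {"CD30": P, "CD20": N},
                                      subtype_label="HL"))
        else:
            records.append(CaseRecord(f"n{i}", {"CD30": N, "CD20": P},
                                      subtype_label="FL"))
    return Cohort("toy", records)


@pytest.fixture(scope="module")
def noisy_binary():
    """One informative marker (CD30) among noise, 2 classes, n=2000."""
    markers = ["CD30", "CD5", "CD10", "CD20", "CD56", "TIA1"]
    pos = {leaf: {m: 0.5 for m in markers} for leaf in ("HL", "FL")}
    pos["HL"]["CD30"], pos["FL"]["CD30"] = 0.9, 0.1
    config = lc.GeneratorConfig(
        n=2000, seed=17, leaf_prevalence={"HL": 0.5, "FL": 0.5},
        positivity=pos, missingness={},
        clinical_count_model={"kind": "fixed", "value": 6})
    cohort, _ = lc.generate_cohort(config)
    return cohort, markers


class TestTraining:
    def test_separable_toy_reaches_auc_one(self, tasks):
        model = train_task_model(_separable_cohort(), tasks["t_hl_nhl"],
                                 ModelFamily.LR, ["CD30", "CD20"], seed=0)
        assert model.train_auc == pytest.approx(1.0)
        assert reference_auc(model) == model.train_auc

    def test_absent_class_named_in_error(self, tasks):
        cohort = Cohort("c", [CaseRecord(f"h{i}", {"CD30": P},
                                         subtype_label="HL")
                              for i in range(4)])
        with pytest.raises(ValueError, match="NHL"):
            train_task_model(cohort, tasks["t_hl_nhl"], ModelFamily.LR,
                             ["CD30"], seed=0)

    def test_constant_design_rejected(self, tasks):
        cohort = Cohort("c", [
            CaseRecord("a", {"CD30": U}, subtype_label="HL"),
            CaseRecord("b", {"CD30": U}, subtype_label="FL"),
        ])
        with pytest.raises(ValueError, match="constant"):
            train_task_model(cohort, tasks["t_hl_nhl"], ModelFamily.LR,
                             ["CD30"], seed=0)

    def test_panel_outside_task_rejected(self, tasks):
        with pytest.raises(ValueError, match="full panel"):
            train_task_model(_separable_cohort(), tasks["t_hl_nhl"],
                             ModelFamily.LR, ["CXCL-13"], seed=0)

    def test_lr_coefficient_vector_shape(self, tasks, noisy_binary):
        cohort, markers = noisy_binary
        model = train_task_model(
            cohort, tasks["t_nhl_sub"], ModelFamily.LR, markers, seed=1,
            labels=[r.subtype_label for r in cohort],
            class_labels=("HL", "FL"))
        assert np.asarray(model.estimator.coef_).shape[1] == 2 * len(markers)

    def test_informative_marker_gets_largest_coefficient(self, tasks,
                                                         noisy_binary):
        cohort, markers = noisy_binary
        model = train_task_model(
            cohort, tasks["t_nhl_sub"], ModelFamily.LR, markers, seed=1,
            labels=[r.subtype_label for r in cohort],
            class_labels=("HL", "FL"))
        coef = np.abs(np.asarray(model.estimator.coef_)).max(axis=0)
        per_marker = coef.reshape(-1, 2).max(axis=1)
        assert markers[int(np.argmax(per_marker))] == "CD30"

    @pytest.mark.parametrize("family", list(ModelFamily))
    def test_retrain_same_seed_reproduces_predictions(self, tasks, family):
        cohort, markers = _make_small_task_cohort()
        kwargs = dict(labels=[r.subtype_label for r in cohort],
                      class_labels=("HL", "FL"))
        m1 = train_task_model(cohort, tasks["t_hl_nhl"], family, markers,
                             seed=5, **kwargs)
        m2 = train_task_model(cohort, tasks["t_hl_nhl"], family, markers,
                             seed=5, **kwargs)
        np.testing.assert_array_equal(predict_scores(m1, cohort),
                                      predict_scores(m2, cohort))


def _make_small_task_cohort(n=200):
    markers = ["CD30", "CD5", "CD20"]
    pos = {"HL": {"CD30": 0.9, "CD5": 0.3, "CD20": 0.2},
           "FL": {"CD30": 0.1, "CD5": 0.3, "CD20": 0.9}}
    config = lc.GeneratorConfig(
        n=n, seed=23, leaf_prevalence={"HL": 0.5, "FL": 0.5},
        positivity=pos, missingness={m: 0.1 for m in markers},
        clinical_count_model={"kind": "fixed", "value": 3})
    cohort, _ = lc.generate_cohort(config)
    return cohort, markers


@pytest.fixture(scope="module")
def lr_model(tasks):
    cohort, markers = _make_small_task_cohort()
    return cohort, train_task_model(
        cohort, tasks["t_hl_nhl"], ModelFamily.LR, markers, seed=2,
        labels=[r.subtype_label for r in cohort],
        class_labels=("HL", "FL"))


class TestScoring:
    def test_probabilistic_rows_sum_to_one(self, lr_model):
        cohort, model = lr_model
        scores = predict_scores(model, cohort)
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-9)

    def test_all_unknown_case_scores_as_intercept(self, lr_model):
        _, model = lr_model
        blank = Cohort("b", [CaseRecord("x", {})])
        got = predict_scores(model, blank)[0]
        z = np.asarray(model.estimator.intercept_, dtype=float)
        if z.size == 1:  # sklearn binary parameterization: P(c1) = sigmoid(z)
            p1 = 1.0 / (1.0 + np.exp(-z[0]))
            expected = np.array([1.0 - p1, p1])
        else:
            expected = np.exp(z) / np.exp(z).sum()
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_duplicated_case_scores_identically(self, lr_model):
        cohort, model = lr_model
        rec = cohort.records[0]
        twin = CaseRecord("twin", dict(rec.markers))
        pair = Cohort("p", [rec, twin])
        scores = predict_scores(model, pair)
        np.testing.assert_array_equal(scores[0], scores[1])


class TestSelection:
    @staticmethod
    def _grid(values):
        fams = [ModelFamily.LR, ModelFamily.DT]
        return {(f, t, c): values[f] for f in fams
                for t in ("t_hl_nhl", "t_nhl_sub")
                for c in ("v1", "v2")}

    def test_dominant_family_chosen(self):
        report = select_best_family(self._grid({ModelFamily.LR: 0.8,
                                                ModelFamily.DT: 0.9}))
        assert report.chosen_family is ModelFamily.DT
        assert report.family_sums[ModelFamily.DT] == pytest.approx(3.6)
        assert report.family_means[ModelFamily.DT] == pytest.approx(0.9)

    def test_exact_tie_goes_to_lower_ordered_family(self):
        report = select_best_family(self._grid({ModelFamily.LR: 0.85,
                                                ModelFamily.DT: 0.85}))
        assert report.chosen_family is ModelFamily.LR

    def test_incomplete_grid_lists_missing_cells(self):
        grid = self._grid({ModelFamily.LR: 0.8, ModelFamily.DT: 0.9})
        del grid[(ModelFamily.DT, "t_nhl_sub", "v2")]
        with pytest.raises(ValueError, match="t_nhl_sub"):
            select_best_family(grid)


class TestFamilyComparison:
    def test_lr_competitive_on_conditionally_independent_markers(self, tasks,
                                                                 tree):
        """Markers independent given the class make the true posterior
        logistic in the one-hot features, so LR should be within 0.02 AUC of
        every other family out of sample."""
        train, _ = lc.generate_cohort(lc.default_config(5000, 31),
                                      cohort_tag="train")
        val, _ = lc.generate_cohort(lc.default_config(3000, 32),
                                    case_prefix="V")
        task = tasks["t_hl_nhl"]
        tr, tr_labels = task_training_frame(train, task, tree)
        va, va_labels = task_training_frame(val, task, tree)
        aucs = {}
        for family in ModelFamily:
            model = train_task_model(tr, task, family, task.full_panel,
                                     seed=31, labels=tr_labels,
                                     class_labels=("HL", "NHL"))
            scores = predict_scores(model, va)
            aucs[family] = lc.auc_ovr_macro(scores, va_labels, ("HL", "NHL"))
        for family, auc in aucs.items():
            assert aucs[ModelFamily.LR] >= auc - 0.02, (family, aucs)
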