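"""Decision-tree training, clinical metrics and the evaluation protocols."""

import numpy as np
import pytest

import regularogram as rg
from regularogram.detector import (TreeModel, _one_tailed_p, cross_database,
                                   cross_validate, evaluate, patient_to_self,
                                   train_tree)

XOR = (np.array([[0, 0, 0], [0, 1, 0], [1, 0, 0], [1, 1, 0]], dtype=float),
       np.array(["AF", "non-AF", "non-AF", "AF"]))


class TestTrainTree:
    def test_one_threshold_separable_set(self):
        X = np.array([[0.1, 0.9, 0.5], [0.12, 0.95, 0.5],
                      [0.01, 0.9, 0.8], [0.02, 0.92, 0.8]])
        y = np.array(["AF", "AF", "non-AF", "non-AF"])
        model = train_tree(X, y, max_splits=30)
        assert model.n_internal_nodes == 1
        assert model.predict(X) == list(y)

    def test_xor_needs_more_than_one_split(self):
        X, y = XOR
        capped = train_tree(X, y, max_splits=1)
        acc = evaluate(capped.predict(X), y).accuracy
        assert acc <= 0.75  # no single axis threshold separates XOR
        full = train_tree(X, y, max_splits=3)
        assert full.n_internal_nodes >= 3
        assert evaluate(full.predict(X), y).accuracy == 1.0

    def test_split_cap_honored_on_noisy_input(self):
        rng = np.random.default_rng(0)
        X = rng.random((500, 3))
        y = np.where(rng.random(500) < 0.5, "AF", "non-AF")  # unlearnable
        model = train_tree(X, y, max_splits=30)
        assert model.n_internal_nodes <= 30

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            train_tree(np.zeros((4, 3)), np.array(["AF"] * 4))

    def test_deterministic_on_identical_input(self):
        rng = np.random.default_rng(5)
        X = rng.random((200, 3))
        y = np.where(X[:, 0] + 0.1 * rng.random(200) > 0.5, "AF", "non-AF")
        a, b = train_tree(X, y, 10), train_tree(X, y, 10)
        assert a.to_json() == b.to_json()

    def test_json_round_trip_preserves_predictions(self, tmp_path):
        X, y = XOR
        model = train_tree(X, y, max_splits=5)
        p = tmp_path / "model.json"
        model.to_json(p)
        back = TreeModel.from_json(p)
        assert back.predict(X) == model.predict(X)
        assert back.max_splits == model.max_splits

    def test_arity_mismatch_rejected(self):
        X, y = XOR
        model = train_tree(X, y, max_splits=3)
        with pytest.raises(ValueError, match="arity"):
            model.predict(np.zeros((2, 2)))

    def test_out_of_range_points_routed_by_thresholds(self):
        X = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        y = np.array(["non-AF", "AF"])
        model = train_tree(X, y, max_splits=1)
        assert model.predict([[100.0, 0, 0], [-100.0, 0, 0]]) == ["AF", "non-AF"]


class TestEvaluate:
    def test_worked_confusion_table(self):
        pred = ["AF"] * 11 + ["non-AF"] * 9
        true = ["AF"] * 9 + ["non-AF"] * 2 + ["AF"] * 1 + ["non-AF"] * 8
        rep = evaluate(pred, true)
        assert (rep.tp, rep.fp, rep.tn, rep.fn) == (9, 2, 8, 1)
        assert rep.sensitivity == pytest.approx(0.900)
        assert rep.specificity == pytest.approx(0.800)
        assert rep.ppv == pytest.approx(0.818, abs=5e-4)
        assert rep.npv == pytest.approx(0.889, abs=5e-4)
        assert rep.accuracy == pytest.approx(0.850)
        assert rep.f1 == pytest.approx(0.857, abs=5e-4)

    def test_enumerated_tables_match_formulas_exactly(self):
        # integer-exact over a grid of confusion tables
        for tp in range(0, 6):
            for fp in range(0, 4):
                for tn in range(0, 4):
                    for fn in range(0, 4):
                        total = tp + fp + tn + fn
                        if total == 0:
                            continue
                        pred = ["AF"] * (tp + fp) + ["non-AF"] * (tn + fn)
                        true = (["AF"] * tp + ["non-AF"] * fp
                                + ["non-AF"] * tn + ["AF"] * fn)
                        r = evaluate(pred, true)
                        assert r.sensitivity == (tp / (tp + fn) if tp + fn else None)
                        assert r.specificity == (tn / (tn + fp) if tn + fp else None)
                        assert r.ppv == (tp / (tp + fp) if tp + fp else None)
                        assert r.npv == (tn / (tn + fn) if tn + fn else None)
                        assert r.accuracy == (tp + tn) / total
                        assert r.f1 == (2 * tp / (2 * tp + fp + fn)
                                        if 2 * tp + fp + fn else None)

    def test_perfect_prediction(self):
        rep = evaluate(["AF", "non-AF"], ["AF", "non-AF"])
        assert (rep.sensitivity, rep.specificity, rep.ppv, rep.npv,
                rep.accuracy, rep.f1) == (1, 1, 1, 1, 1, 1)

    def test_all_negative_reports_only_sp_and_acc(self):
        rep = evaluate(["non-AF"] * 10, ["non-AF"] * 10)
        assert rep.sensitivity is None and rep.ppv is None and rep.f1 is None
        assert rep.specificity == rep.accuracy == 1.0

    def test_accuracy_identity_with_prevalence(self):
        rng = np.random.default_rng(2)
        pred = np.where(rng.random(200) < 0.4, "AF", "non-AF")
        true = np.where(rng.random(200) < 0.3, "AF", "non-AF")
        r = evaluate(pred, true)
        p, n = r.tp + r.fn, r.tn + r.fp
        assert r.accuracy == pytest.approx(
            (r.sensitivity * p + r.specificity * n) / (p + n), abs=1e-15)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate(["AF"], ["AF", "AF"])


@pytest.fixture(scope="module")
def small_dataset():
    cohort = rg.gen_cohort(8, (0.3, 0.7), seed=31, other_rhythms=False,
                           beats_per_record=2500)
    return [(rec.rr, rec.segments) for rec in cohort]


class TestCrossValidate:
    def test_identical_fold_accuracies_give_half_p(self):
        a = np.array([0.9, 0.95, 0.92])
        assert _one_tailed_p(a, a.copy()) == pytest.approx(0.5)

    def test_best_cell_is_argmax_of_grid(self, small_dataset):
        res = cross_validate(small_dataset, orders=[1, 2],
                             window_lengths=[70, 150], folds=4, seed=0)
        assert res.best == max(res.grid, key=res.grid.get)
        assert all(0 < p <= 1 for p in res.p_values.values())
        assert res.best not in res.p_values

    def test_record_level_folds_partition_records(self, small_dataset):
        res = cross_validate(small_dataset, orders=[1], window_lengths=[150],
                             folds=4, seed=0)
        fold_of = res.fold_assignment
        assert len(fold_of) == len(small_dataset)
        assert set(fold_of) == set(range(4))  # every fold non-empty

    def test_too_few_records_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            cross_validate(small_dataset[:3], orders=[1], window_lengths=[150],
                           folds=5, seed=0)


class TestPatientToSelf:
    def test_single_class_record_skipped_with_note(self, mixed_cohort_indices):
        nsr_only = [[r for r in mixed_cohort_indices[0] if r.label == "non-AF"]]
        with pytest.warns(UserWarning, match="skipped"):
            accs, skipped = patient_to_self(nsr_only, split_caps=(2,), seed=0)
        assert len(skipped) == 1
        assert np.isnan(accs[2])

    def test_table1_cap_list_accepted(self, mixed_cohort_indices):
        caps = (2, 3, 4, 10, 20, 30, 50, 100)
        accs, _ = patient_to_self(mixed_cohort_indices[:4], split_caps=caps, seed=0)
        assert set(accs) == set(caps)
        assert all(0 <= a <= 1 for a in accs.values() if not np.isnan(a))


class TestCrossDatabase:
    def test_record_id_overlap_rejected(self, mixed_cohort_indices):
        with pytest.raises(ValueError, match="shared"):
            cross_database(("A", mixed_cohort_indices[:5]),
                           {"B": mixed_cohort_indices[4:6]})

    def test_train_set_metrics_flagged_optimistic(self, mixed_cohort_indices):
        res = cross_database(("A", mixed_cohort_indices[:6]),
                             {"B": mixed_cohort_indices[6:12]})
        assert res.optimistic == ("A",)
        assert res.train_report.accuracy >= res.test_reports["B"].accuracy - 1e-9

    def test_nsr_only_test_set_reports_only_sp_and_acc(self, mixed_cohort_indices):
        nsr_records = [[r for r in recs if r.label == "non-AF"]
                       for recs in mixed_cohort_indices[6:10]]
        res = cross_database(("A", mixed_cohort_indices[:6]), {"NSR": nsr_records})
        rep = res.test_reports["NSR"]
        assert rep.tp == 0 and rep.fn == 0
        assert rep.sensitivity is None  # no positive windows to be sensitive to
        assert rep.specificity is not None and rep.accuracy is not None
        if rep.fp == 0:  # all-negative prediction too: PPV and F1 also absent
            assert rep.ppv is None and rep.f1 is None
            assert rep.specificity == rep.accuracy
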