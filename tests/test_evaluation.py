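import numpy as np
import pytest

from oracles import concordance_auc, trapezoid_roc_auc
from scribepd.evaluation import (
    CVReport,
    FoldPlan,
    SVMGrid,
    binary_metrics,
    compare_pipelines,
    make_folds,
    run_svm_cv,
    select_gmm_M,
)


def _labels(n_pd, n_hc):
    ids = [f"PD{i}" for i in range(n_pd)] + [f"HC{i}" for i in range(n_hc)]
    y = np.array([1] * n_pd + [0] * n_hc)
    return ids, y


SMALL_GRID = SVMGrid(c_values=(0.1, 1.0, 10.0), gamma_values=(0.01,),
                     kernels=("linear",))


class TestMakeFolds:
    def test_study_sized_plan_is_balanced(self):
        plan = make_folds(_labels(51, 53), seed=0)
        sizes = sorted(np.bincount(plan.assignments).tolist())
        assert sizes == [20, 21, 21, 21, 21]
        for f in range(5):
            in_fold = plan.labels[plan.assignments == f]
            assert in_fold.sum() in (10, 11)          # PD per fold
            assert (in_fold == 0).sum() in (10, 11)   # HC per fold

    def test_same_seed_same_plan(self):
        a = make_folds(_labels(20, 20), seed=7)
        b = make_folds(_labels(20, 20), seed=7)
        assert np.array_equal(a.assignments, b.assignments)
        assert a.hash == b.hash

    def test_too_few_subjects_in_a_class(self):
        with pytest.raises(ValueError, match="PD"):
            make_folds(_labels(4, 20), seed=0)

    def test_folds_partition_subjects(self):
        plan = make_folds(_labels(13, 17), seed=1)
        seen = np.concatenate([te for _, te in plan.folds()])
        assert sorted(seen.tolist()) == list(range(30))


class TestMetrics:
    def test_confusion_arithmetic(self):
        m = binary_metrics(tp=3, fn=1, tn=3, fp=1)
        assert m == {"accuracy": 0.75, "sensitivity": 0.75,
                     "specificity": 0.75, "f1": 0.75}

    def test_degenerate_denominators_give_zero(self):
        m = binary_metrics(tp=0, fn=0, tn=4, fp=0)
        assert m["sensitivity"] == 0.0 and m["specificity"] == 1.0


class TestRunSVMCV:
    def test_well_separated_clouds_are_perfectly_classified(self):
        rng = np.random.default_rng(0)
        n = 40
        X = np.vstack([rng.normal(0, 1, size=(n // 2, 4)),
                       rng.normal(10, 1, size=(n // 2, 4))])
        ids, y = _labels(n // 2, n // 2)
        plan = make_folds((ids, y), seed=0)
        rep = run_svm_cv(X, y, plan, seed=0)
        assert rep.accuracy == 1.0
        assert rep.auc == 1.0

    def test_label_shuffling_gives_chance_accuracy(self):
        """Permutation null: accuracy concentrates around 50%."""
        rng = np.random.default_rng(123)
        n, reps = 40, 30
        X = rng.normal(size=(n, 6))
        ids, y = _labels(n // 2, n // 2)
        accs = []
        for _ in range(reps):
            y_perm = rng.permutation(y)
            plan = make_folds((ids, y_perm), seed=int(rng.integers(1 << 16)))
            rep = run_svm_cv(X, y_perm, plan, grid=SMALL_GRID, seed=0)
            accs.append(rep.accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_non_finite_features_error_names_subject(self):
        ids, y = _labels(10, 10)
        plan = make_folds((ids, y), seed=0)
        X = np.zeros((20, 3))
        X[4, 1] = np.inf
        with pytest.raises(ValueError, match="PD4"):
            run_svm_cv(X, y, plan)

    def test_roc_is_monotone_and_auc_matches_concordance(self):
        rng = np.random.default_rng(5)
        n = 30
        X = rng.normal(size=(n, 3)) + 0.8 * np.array([1] * 15 + [0] * 15)[:, None]
        ids, y = _labels(15, 15)
        plan = make_folds((ids, y), seed=2)
        rep = run_svm_cv(X, y, plan, grid=SMALL_GRID, seed=0)
        fpr, tpr, _ = rep.roc()
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)
        oracle = concordance_auc(rep.true_labels, rep.scores)
        assert rep.auc == pytest.approx(oracle, abs=1e-9)
        assert trapezoid_roc_auc(fpr, tpr) == pytest.approx(oracle, abs=1e-9)

    def test_report_json_is_deterministic(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(20, 3))
        ids, y = _labels(10, 10)
        plan = make_folds((ids, y), seed=3)
        a = run_svm_cv(X, y, plan, grid=SMALL_GRID, seed=1).to_json()
        b = run_svm_cv(X, y, plan, grid=SMALL_GRID, seed=1).to_json()
        assert a == b


class TestSelectGmmM:
    def test_single_candidate_is_chosen(self):
        rng = np.random.default_rng(1)
        ids, y = _labels(10, 10)
        plan = make_folds((ids, y), seed=0)
        X = rng.normal(size=(20, 4)) + y[:, None]
        chosen, report, table = select_gmm_M({4: X}, y, plan, grid=SMALL_GRID)
        assert chosen == 4
        assert report.chosen_M == 4
        assert list(table["M"]) == [4]

    def test_tie_selects_smaller_m(self):
        rng = np.random.default_rng(2)
        ids, y = _labels(10, 10)
        plan = make_folds((ids, y), seed=0)
        X = rng.normal(size=(20, 4)) + 3 * y[:, None]
        chosen, _, table = select_gmm_M({2: X, 6: X.copy()}, y, plan,
                                        grid=SMALL_GRID)
        accs = table.set_index("M")["train_accuracy"]
        assert accs[2] == accs[6]
        assert chosen == 2

    def test_invalid_m_keys_rejected(self):
        ids, y = _labels(10, 10)
        plan = make_folds((ids, y), seed=0)
        with pytest.raises(ValueError, match="invalid M"):
            select_gmm_M({3: np.zeros((20, 2))}, y, plan)

    def test_empty_map_rejected(self):
        ids, y = _labels(10, 10)
        plan = make_folds((ids, y), seed=0)
        with pytest.raises(ValueError, match="empty"):
            select_gmm_M({}, y, plan)


class TestComparePipelines:
    def _report(self, seed, plan_seed=0):
        rng = np.random.default_rng(seed)
        ids, y = _labels(10, 10)
        plan = make_folds((ids, y), seed=plan_seed)
        X = rng.normal(size=(20, 3)) + 2 * y[:, None]
        return run_svm_cv(X, y, plan, grid=SMALL_GRID, seed=0)

    def test_identical_reports_have_zero_accuracy_difference(self):
        rep = self._report(0)
        out = compare_pipelines({"a": rep, "b": rep})
        assert out["accuracy_differences_pct"]["a - b"] == 0.0
        assert set(out["table"].index) == {"a", "b"}

    def test_mismatched_fold_plans_rejected(self):
        a = self._report(0, plan_seed=0)
        b = self._report(0, plan_seed=1)
        with pytest.raises(ValueError, match="different fold plans"):
            compare_pipelines({"a": a, "b": b})

    def test_metric_table_is_on_percent_scale(self):
        rep = self._report(3)
        out = compare_pipelines({"a": rep})
        acc = out["table"].loc["a", "accuracy_pct"]
        assert 0.0 <= acc <= 100.0
        assert acc == pytest.approx(100.0 * rep.accuracy)
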