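"""Splits, evaluation metrics, grid search and the iterated optimiser."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_two_class_table
from dermfocus.training import (
    HyperParamGrid,
    NoModelRetainedError,
    SearchConfig,
    evaluate,
    f1_from_precision_recall,
    grid_search_cv,
    optimize_model,
    random_split,
    subject_wise_split,
    youden,
)


def _subject_table(n_subjects=14, per_subject=4, seed=0):
    r = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for i in range(per_subject):
            focused = i % 2 == 0
            rows.append(
                {
                    "subject_id": f"s{s:02d}",
                    "label": "focused" if focused else "non_focused",
                    # cleanly separated focus evidence with per-subject offsets
                    "A": r.normal(3.0 if focused else 0.0, 0.3) + 0.1 * s,
                    "B": r.normal(),
                }
            )
    return pd.DataFrame(rows)


class TestSplits:
    def test_subject_wise_no_overlap(self):
        df = _subject_table()
        tr, te = subject_wise_split(df, 9, 5, seed=1)
        assert set(tr.subject_id).isdisjoint(te.subject_id)
        assert tr.subject_id.nunique() == 9 and te.subject_id.nunique() == 5

    def test_subject_wise_no_overlap_many_seeds(self):
        df = _subject_table()
        for seed in range(200):
            tr, te = subject_wise_split(df, 9, 5, seed=seed)
            assert set(tr.subject_id).isdisjoint(te.subject_id)

    def test_subject_wise_deterministic_and_errors(self):
        df = _subject_table()
        a = subject_wise_split(df, 9, 5, seed=7)[0]
        b = subject_wise_split(df, 9, 5, seed=7)[0]
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError):
            subject_wise_split(_subject_table(n_subjects=2), 9, 5)

    def test_random_split_stratified(self):
        df = make_two_class_table(n_per_class=50)
        tr, te = random_split(df, 0.7, seed=0)
        assert len(tr) == 70 and len(te) == 30
        assert abs(tr.label.value_counts()["pos"] - 35) <= 1

    def test_random_split_errors_and_determinism(self):
        df = make_two_class_table(n_per_class=50)
        with pytest.raises(ValueError):
            random_split(df, 1.0)
        pd.testing.assert_frame_equal(
            random_split(df, 0.7, seed=3)[0], random_split(df, 0.7, seed=3)[0]
        )


class TestEvaluationMetrics:
    @pytest.mark.parametrize(
        "precision,recall,f1",
        [(100.0, 96.96, 98.5), (72.8, 80.5, 76.5), (80.7, 91.1, 85.6)],
    )
    def test_f1_worked_examples(self, precision, recall, f1):
        assert f1_from_precision_recall(precision, recall) == pytest.approx(f1, abs=0.05)

    @pytest.mark.parametrize(
        "recall,specificity,expected",
        [(100.0, 100.0, 100.0), (85.4, 82.4, 67.8), (80.5, 75.8, 56.3)],
    )
    def test_youden_worked_examples(self, recall, specificity, expected):
        assert youden(recall, specificity) == pytest.approx(expected, abs=1e-9)

    def test_report_self_consistency(self, rng):
        y_true = rng.choice(["pos", "neg"], size=200)
        y_pred = rng.choice(["pos", "neg"], size=200)
        rep = evaluate(y_true, y_pred, positive_label="pos")
        (tn, fp), (fn, tp) = rep.confusion
        assert rep.accuracy == pytest.approx(100 * (tp + tn) / 200, abs=0.05)
        assert rep.recall == pytest.approx(100 * tp / (tp + fn), abs=0.05)
        assert rep.precision == pytest.approx(100 * tp / (tp + fp), abs=0.05)
        assert rep.specificity == pytest.approx(100 * tn / (tn + fp), abs=0.05)
        assert rep.f1 == pytest.approx(
            f1_from_precision_recall(rep.precision, rep.recall), abs=0.05
        )
        assert rep.youden == pytest.approx(rep.recall + rep.specificity - 100, abs=0.05)

    def test_single_class_set_warns_with_sentinels(self):
        with pytest.warns(UserWarning):
            rep = evaluate(["pos", "pos"], ["pos", "neg"], positive_label="pos")
        assert np.isnan(rep.specificity)


class TestGridSearch:
    def test_grid_enumerates_36_combinations(self):
        grid = HyperParamGrid()
        assert grid.n_combinations() == 36

    def test_separable_data_reaches_perfect_cv_score(self):
        df = make_two_class_table(n_per_class=30)
        best, score, search = grid_search_cv(
            df[["A", "B"]].to_numpy(), df["label"], positive_label="pos",
            folds=5, seed=0,
        )
        assert score == pytest.approx(1.0)
        assert len(search.cv_results_["params"]) == 36

    def test_same_seed_same_winner(self):
        df = make_two_class_table(n_per_class=30, seed=5)
        X, y = df[["A", "B"]].to_numpy(), df["label"]
        r1 = grid_search_cv(X, y, "pos", folds=5, seed=11)
        r2 = grid_search_cv(X, y, "pos", folds=5, seed=11)
        assert r1[0].get_params() == r2[0].get_params()
        assert r1[1] == r2[1]

    def test_infeasible_folds_rejected(self):
        df = make_two_class_table(n_per_class=4)
        with pytest.raises(ValueError):
            grid_search_cv(df[["A", "B"]].to_numpy(), df["label"], "pos", folds=10)


class TestOptimizeModel:
    def _tables(self):
        df = _subject_table()
        return subject_wise_split(df, 9, 5, seed=0)

    def test_retains_model_on_separable_data(self):
        tr, te = self._tables()
        cfg = SearchConfig(n_iterations=30, cv_folds=5, objective="youden", rng_seed=3)
        model, history = optimize_model(tr, te, "preview_focus", cfg)
        assert model.task == "preview_focus"
        assert len(history) >= 1
        rep_recall = history.iloc[-1]["test_recall"]
        assert rep_recall > 85.0

    def test_history_strictly_improving(self):
        tr, te = self._tables()
        cfg = SearchConfig(n_iterations=30, cv_folds=5, objective="youden", rng_seed=3)
        _, history = optimize_model(tr, te, "preview_focus", cfg)
        obj = history["cv_objective"].to_numpy()
        assert np.all(np.diff(obj) > 0)

    def test_unattainable_recall_floor(self):
        tr, te = self._tables()
        cfg = SearchConfig(
            n_iterations=5, cv_folds=5, objective="youden", recall_floor=1.01, rng_seed=0
        )
        with pytest.raises(NoModelRetainedError):
            optimize_model(tr, te, "preview_focus", cfg)

    def test_parameter_recovery_on_threshold_rule(self):
        # one informative feature with a known class gap: the learned stump
        # must pick it and place its threshold inside the gap
        df = make_two_class_table(
            n_per_class=40, gap=(1.0, 2.0), seed=2, label_names=("focused", "non_focused")
        )
        tr, te = random_split(df, 0.7, seed=0)
        cfg = SearchConfig(
            n_iterations=10, cv_folds=5, objective="youden", rng_seed=1,
            feature_pair_search=True,
        )
        grid = HyperParamGrid(max_depth=(1,), min_samples_split=(2,))
        model, _ = optimize_model(tr, te, "preview_focus", cfg, grid=grid)
        root = model.nodes[0]
        assert root["feature"] == "A"
        assert 1.0 < root["threshold"] < 2.0
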