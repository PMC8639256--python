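import numpy as np
import pandas as pd
import pytest

from copsway.classify import (
    ConfusionCounts,
    evaluate_repeated,
    metrics,
    train_tree,
)
from copsway.features import level_codes


def make_table(n_fall, n_nonfall, effect=3.0, scale=1.0, seed=0, level=0,
               conditions=("CR", "OR", "CF", "OF"), trials=3):
    """Feature table whose level-`level` codes carry a group shift."""
    rng = np.random.default_rng(seed)
    rows = []
    for group, count in (("fall", n_fall), ("nonfall", n_nonfall)):
        for i in range(count):
            sid = f"{group[0]}{i}"
            for cond in conditions:
                for trial in range(1, trials + 1):
                    row = dict(subject_id=sid, group=group, condition=cond,
                               trial=trial)
                    for code in level_codes(level):
                        shift = effect if group == "fall" else 0.0
                        row[code] = shift + scale * rng.normal()
                    rows.append(row)
    return pd.DataFrame(rows)


class TestMetrics:
    def test_perfect_classification(self):
        assert metrics(ConfusionCounts(tp=29, tn=47, fp=0, fn=0)) == (100, 100, 100)

    def test_mixed_counts_arithmetic(self):
        acc, sen, spe = metrics(ConfusionCounts(tp=20, fn=9, tn=40, fp=7))
        assert acc == pytest.approx(78.94736842105263)
        assert sen == pytest.approx(68.96551724137931)
        assert spe == pytest.approx(85.1063829787234)

    def test_empty_positive_class_undefined_sensitivity(self):
        acc, sen, spe = metrics(ConfusionCounts(tp=0, fn=0, tn=5, fp=0))
        assert sen is None and acc == 100 and spe == 100

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(0, 0, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 2)


class TestTrainTree:
    def test_single_threshold_separates_1d_clusters(self):
        X = pd.DataFrame({"x.0.1": [1, 2, 3, 10, 11, 12]})
        y = ["nonfall"] * 3 + ["fall"] * 3
        model = train_tree(X, y, min_samples_leaf=1)
        assert (model.predict(X) == y).all()
        thresh = model.tree.tree_.threshold[0]
        assert 3 < thresh < 10

    def test_xor_needs_depth_two(self):
        X = pd.DataFrame({"x.0.1": [0, 0, 1, 1], "y.0.1": [0, 1, 0, 1]})
        y = ["nonfall", "fall", "fall", "nonfall"]
        model = train_tree(X, y, min_samples_leaf=1)
        assert (model.predict(X) == y).all()
        assert model.tree.get_depth() == 2

    def test_identical_rows_predict_majority(self):
        X = pd.DataFrame({"x.0.1": [1.0] * 5})
        y = ["fall", "fall", "fall", "nonfall", "nonfall"]
        model = train_tree(X, y, min_samples_leaf=1)
        assert model.tree.get_n_leaves() == 1
        assert (model.predict(X) == "fall").all()

    def test_single_class_warns_and_predicts_it(self):
        X = pd.DataFrame({"x.0.1": [1.0, 2.0, 3.0]})
        with pytest.warns(RuntimeWarning, match="single-class"):
            model = train_tree(X, ["fall"] * 3)
        assert (model.predict(X) == "fall").all()

    def test_median_imputation_of_missing_values(self):
        X = pd.DataFrame(
            {
                "x.0.1": [1, 2, 3, 10, 11, np.nan],
                "x.0.2": [0.0, 0.1, -0.1, 0.05, 0.0, 12.0],
            }
        )
        y = ["nonfall"] * 3 + ["fall"] * 3
        model = train_tree(X, y, min_samples_leaf=1)
        assert np.allclose(model.medians, np.nanmedian(X.to_numpy(), axis=0))
        assert len(model.predict(X)) == 6

    def test_all_missing_row_rejected(self):
        X = pd.DataFrame({"x.0.1": [1.0, np.nan], "x.0.2": [2.0, np.nan]})
        with pytest.raises(ValueError, match="missing"):
            train_tree(X, ["fall", "nonfall"])


class TestEvaluateRepeated:
    def test_separable_features_classify_perfectly(self):
        table = make_table(6, 8, effect=10.0, scale=0.1)
        report = evaluate_repeated(table, level=0, repeats=20, seed=3)
        s = report.summary("test")
        assert s["accuracy"]["mean"] == 100.0
        assert s["accuracy"]["sd"] == 0.0

    def test_permutation_null_near_majority_rate(self):
        table = make_table(6, 8, effect=0.0)
        rng = np.random.default_rng(0)
        table["group"] = rng.permutation(table["group"].to_numpy())
        majority = table.group.value_counts(normalize=True).max() * 100
        report = evaluate_repeated(table, level=0, repeats=20, seed=1)
        assert abs(report.summary("test")["accuracy"]["mean"] - majority) <= 10.0

    def test_single_repeat_sd_zero_and_flagged(self):
        table = make_table(4, 4)
        report = evaluate_repeated(table, level=0, repeats=1, seed=0)
        assert report.single_repeat
        assert report.summary("test")["accuracy"]["sd"] == 0.0

    def test_seeded_determinism(self):
        table = make_table(5, 6, effect=1.0)
        r1 = evaluate_repeated(table, level=0, repeats=10, seed=42)
        r2 = evaluate_repeated(table, level=0, repeats=10, seed=42)
        pd.testing.assert_frame_equal(r1.rows, r2.rows)

    def test_condition_view_filters_records(self):
        table = make_table(5, 6, effect=1.0)
        r = evaluate_repeated(table, level=0, condition="OR", repeats=2, seed=0)
        row = r.rows.iloc[0:2]
        total = int(row[["tp", "fp", "fn", "tn"]].sum(axis=1).sum())
        assert total == 11 * 3  # one condition: subjects x trials

    def test_undersized_class_rejected(self):
        table = make_table(2, 6)
        sub = table[table.condition == "OR"]
        first_fall = sub[sub.group == "fall"].index[:1]
        sub = sub[(sub.group == "nonfall") | sub.index.isin(first_fall)]
        with pytest.raises(ValueError, match="2 records"):
            evaluate_repeated(sub, level=0)

    def test_all_missing_level_rows_dropped_with_warning(self):
        table = make_table(5, 6, effect=2.0)
        for code in level_codes(0):
            table.loc[table.index[:2], code] = np.nan
        with pytest.warns(RuntimeWarning, match="dropping"):
            report = evaluate_repeated(table, level=0, repeats=2, seed=0)
        totals = report.rows[["tp", "fp", "fn", "tn"]].sum(axis=1)
        counts = totals.groupby(report.rows.partition).first()
        assert counts.sum() == len(table) - 2

    def test_group_by_subject_keeps_subjects_in_one_partition(self):
        table = make_table(5, 6, effect=1.0)
        report = evaluate_repeated(
            table, level=0, repeats=3, seed=9, group_by_subject=True
        )
        assert report.n_repeats == 3  # smoke: splits are valid and disjoint

    def test_training_accuracy_dominates_testing(self, small_table):
        report = evaluate_repeated(small_table, level=5, repeats=20, seed=11)
        rows = report.rows.pivot_table(
            index="repeat", columns="partition", values="accuracy"
        )
        assert (rows["train"] >= rows["test"]).sum() >= 15
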