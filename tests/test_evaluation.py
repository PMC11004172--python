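"""Splitting, one-vs-rest confusion metrics and report consistency."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from leukoflow.errors import (
    DegenerateCounts,
    LeakageError,
    StratificationError,
    UnknownLabel,
)
from leukoflow.evaluation import (
    FoldSplit,
    confusion_counts,
    evaluate_predictions,
    metrics_from_counts,
    percent,
    report_from_predictions,
    split_cohort,
)
from leukoflow.vocab import DIAGNOSES

CLINICAL_COUNTS = {"Normal": 64, "AML": 41, "B-ALL": 43, "Complex": 60, "Other": 33}


def _manifest(counts):
    rows = []
    for diag, n in counts.items():
        for j in range(n):
            rows.append({"sample_id": f"{diag}-{j}", "diagnosis": diag})
    return pd.DataFrame(rows)


class TestSplitCohort:
    def test_clinical_cohort_gives_185_train_56_test(self):
        manifest = _manifest(CLINICAL_COUNTS)
        split = split_cohort(manifest, test_fraction=56 / 241, seed=0)
        assert len(split.test_ids) == 56
        assert len(split.train_ids) == 185

    def test_kfold_of_ten_gives_folds_of_two(self):
        manifest = _manifest({"Normal": 10})
        split = split_cohort(manifest, test_fraction=0.0, stratify=False, k=5)
        sizes = sorted(len(split.fold_ids(f)) for f in range(5))
        assert sizes == [2] * 5

    def test_same_seed_identical_assignments(self):
        manifest = _manifest(CLINICAL_COUNTS)
        s1 = split_cohort(manifest, seed=3)
        s2 = split_cohort(manifest, seed=3)
        assert s1.assignments == s2.assignments
        assert s1.test_ids == s2.test_ids

    def test_folds_partition_training_set(self):
        manifest = _manifest(CLINICAL_COUNTS)
        split = split_cohort(manifest, seed=1)
        all_fold_ids = [s for f in range(split.k) for s in split.fold_ids(f)]
        assert sorted(all_fold_ids) == sorted(split.train_ids)  # exactly once
        assert not set(all_fold_ids) & set(split.test_ids)

    def test_stratified_fold_sizes_balanced(self):
        manifest = _manifest(CLINICAL_COUNTS)
        split = split_cohort(manifest, seed=2)
        diag_of = dict(zip(manifest.sample_id, manifest.diagnosis))
        for diag in DIAGNOSES:
            per_fold = [
                sum(1 for s in split.fold_ids(f) if diag_of[s] == diag)
                for f in range(split.k)
            ]
            assert max(per_fold) - min(per_fold) <= 1

    def test_small_stratum_raises(self):
        manifest = _manifest({"Normal": 5, "AML": 3})
        with pytest.raises(StratificationError):
            split_cohort(manifest, seed=0)  # AML stratum < k after test split

    def test_duplicate_ids_raise(self):
        manifest = _manifest({"Normal": 10, "AML": 10})
        manifest.loc[1, "sample_id"] = manifest.loc[0, "sample_id"]
        with pytest.raises(LeakageError):
            split_cohort(manifest, seed=0)


class TestConfusionCounts:
    def test_clinical_example(self):
        # 56-sample test set: 10 true AML, 8 caught, 3 false alarms among 46
        y_true = np.array(["AML"] * 10 + ["Normal"] * 46)
        y_pred = np.array(
            ["AML"] * 8 + ["Normal"] * 2 + ["AML"] * 3 + ["Normal"] * 43
        )
        assert confusion_counts(y_true, y_pred, "AML") == (8, 3, 2, 43)

    def test_perfect_prediction(self):
        y = np.array(["AML", "Normal", "B-ALL", "AML"])
        tp, fp, fn, tn = confusion_counts(y, y, "AML")
        assert (fp, fn) == (0, 0)
        assert tp == 2 and tn == 2

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        y_true = rng.choice(DIAGNOSES, 60)
        y_pred = rng.choice(DIAGNOSES, 60)
        for target in DIAGNOSES:
            tp = fp = fn = tn = 0
            for a, b in zip(y_true, y_pred):  # double-loop oracle
                if a == target and b == target:
                    tp += 1
                elif a != target and b == target:
                    fp += 1
                elif a == target and b != target:
                    fn += 1
                else:
                    tn += 1
            assert confusion_counts(y_true, y_pred, target) == (tp, fp, fn, tn)

    def test_unknown_label_raises(self):
        with pytest.raises(UnknownLabel):
            confusion_counts(np.array(["CML"]), np.array(["AML"]), "AML")


class TestMetricsFromCounts:
    def test_aml_worked_example(self):
        m = metrics_from_counts(8, 3, 2, 43)
        assert percent(m["accuracy"]) == "91.1%"
        assert percent(m["sensitivity"]) == "80.0%"
        assert percent(m["specificity"]) == "93.5%"
        assert percent(m["f1"]) == "76.2%"

    def test_ball_worked_example(self):
        m = metrics_from_counts(10, 0, 1, 45)
        assert percent(m["specificity"]) == "100.0%"
        assert percent(m["f1"]) == "95.2%"

    def test_degenerate_no_positives(self):
        m = metrics_from_counts(0, 0, 0, 10)
        assert m["sensitivity"] is None
        assert m["specificity"] == 1.0
        assert m["f1"] is None

    def test_all_zero_raises(self):
        with pytest.raises(DegenerateCounts):
            metrics_from_counts(0, 0, 0, 0)

    def test_negative_raises(self):
        with pytest.raises(DegenerateCounts):
            metrics_from_counts(-1, 0, 0, 10)

    @settings(deadline=None, max_examples=50)
    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50),
        fn=st.integers(0, 50), tn=st.integers(0, 50),
    )
    def test_f1_is_harmonic_mean_and_bounded(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        m = metrics_from_counts(tp, fp, fn, tn)
        for key in ("accuracy", "sensitivity", "specificity", "f1"):
            if m[key] is not None:
                assert 0.0 <= m[key] <= 1.0
        if tp + fp > 0 and tp + fn > 0 and tp > 0:
            precision = tp / (tp + fp)
            recall = tp / (tp + fn)
            harmonic = 2 * precision * recall / (precision + recall)
            assert m["f1"] == pytest.approx(harmonic)

    def test_percent_rounds_half_up(self):
        assert percent(0.5454545) == "54.5%"
        assert percent(0.76185) == "76.2%"  # 76.185 -> 76.2
        assert percent(0.11115, 2) == "11.12%"  # half-up at the boundary
        assert percent(None) == "n/a"


class TestReport:
    def test_perfect_predictions_all_f1_100(self):
        y = np.array([d for d in DIAGNOSES for _ in range(4)])
        report = report_from_predictions(y, y)
        assert all(r["f1"] == 1.0 for r in report.rows)
        assert report.confusion.trace() == 20

    def test_counts_consistent_on_56_sample_test(self, rng):
        y_true = rng.choice(DIAGNOSES, 56)
        y_pred = rng.choice(DIAGNOSES, 56)
        report = report_from_predictions(y_true, y_pred)
        for r in report.rows:
            assert r["tp"] + r["fp"] + r["fn"] + r["tn"] == 56
            assert r["tp"] + r["fn"] == r["support"]
        assert report.confusion.sum() == 56
        # row sums = true-class counts
        for i, d in enumerate(DIAGNOSES):
            assert report.confusion[i].sum() == (y_true == d).sum()

    def test_report_rows_match_metrics_from_counts(self, rng):
        y_true = rng.choice(DIAGNOSES, 80)
        y_pred = rng.choice(DIAGNOSES, 80)
        report = report_from_predictions(y_true, y_pred)
        for r in report.rows:
            m = metrics_from_counts(r["tp"], r["fp"], r["fn"], r["tn"])
            for key, val in m.items():
                assert r[key] == val

    def test_rows_in_clinical_order(self, rng):
        y = rng.choice(DIAGNOSES, 30)
        report = report_from_predictions(y, y)
        assert [r["class"] for r in report.rows] == list(DIAGNOSES)

    def test_leakage_hard_fails(self):
        manifest = _manifest({"Normal": 10, "AML": 10})
        split = split_cohort(manifest, seed=0)
        test_manifest = manifest[manifest.sample_id.isin(split.test_ids)]
        leaky = FoldSplit(
            k=5,
            assignments={s: 0 for s in manifest.sample_id},  # test ids inside
            test_ids=split.test_ids,
            seed=0,
        )
        with pytest.raises(LeakageError):
            evaluate_predictions(
                leaky, test_manifest, test_manifest.diagnosis.to_numpy()
            )

    def test_csv_and_json_outputs(self, tmp_path, rng):
        y = rng.choice(DIAGNOSES, 25)
        report = report_from_predictions(y, y)
        path = report.to_csv(tmp_path / "r.csv")
        df = pd.read_csv(path)
        assert len(df) == 5
        assert "sensitivity_fraction" in df.columns
        assert "100.0%" in df["f1"].values
        assert '"n_test": 25' in report.to_json()
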