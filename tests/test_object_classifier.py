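"""Hold-out splitting, morphology-forest training, confusion matrices."""

import numpy as np
import pandas as pd
import pytest

from plateseg.containers import MorphClass
from plateseg.object_classifier import (DEFAULT_ABLATION_ARMS, ConfusionMatrix,
                                        classify, confusion_matrix,
                                        feature_ablation, overall_accuracy,
                                        split_train_validation,
                                        train_object_classifier)
from plateseg.pixel_classifier import ForestParams
from plateseg.synthetic import sample_platelet_records


@pytest.fixture(scope="module")
def records():
    return sample_platelet_records(60, rng_seed=3)


class TestSplit:
    def test_eighty_twenty_arithmetic(self, records):
        train, val = split_train_validation(records.head(100), 0.2, rng_seed=0,
                                            stratified=False)
        assert len(train) == 80 and len(val) == 20
        assert len(set(train.index) & set(val.index)) == 0

    def test_stratified_rounding_rule(self):
        rows = ([{"true_class": 0, "x": i} for i in range(60)]
                + [{"true_class": 1, "x": i} for i in range(30)]
                + [{"true_class": 2, "x": i} for i in range(10)])
        df = pd.DataFrame(rows)
        _, val = split_train_validation(df, 0.2, rng_seed=1)
        counts = val.true_class.value_counts()
        assert counts[0] == 12 and counts[1] == 6 and counts[2] == 2

    def test_deterministic(self, records):
        a = split_train_validation(records, 0.2, rng_seed=5)
        b = split_train_validation(records, 0.2, rng_seed=5)
        assert a[0].index.tolist() == b[0].index.tolist()
        assert a[1].index.tolist() == b[1].index.tolist()

    def test_tiny_class_rejected(self):
        df = pd.DataFrame([{"true_class": 0, "x": 1},
                           {"true_class": 0, "x": 2},
                           {"true_class": 1, "x": 3}])
        with pytest.raises(ValueError, match="PARTIAL"):
            split_train_validation(df, 0.2)


class TestTrainClassify:
    def test_single_feature_classifier_is_valid(self, records):
        clf = train_object_classifier(records, features=("area_um2",),
                                      rng_seed=0)
        pred = classify(clf, records)
        assert pred.predicted_class.isin([0, 1, 2]).all()

    def test_training_accuracy_perfect_on_separable_classes(self, records):
        clf = train_object_classifier(records, rng_seed=0)
        pred = classify(clf, records)
        assert (pred.predicted_class == pred.true_class).mean() == 1.0

    def test_unknown_feature_rejected(self, records):
        with pytest.raises(ValueError, match="unknown"):
            train_object_classifier(records, features=("no_such_feature",))

    def test_classify_empty_records(self, records):
        clf = train_object_classifier(records, rng_seed=0)
        out = classify(clf, records.iloc[0:0])
        assert len(out) == 0 and "predicted_class" in out.columns

    def test_missing_feature_column_rejected(self, records):
        clf = train_object_classifier(records, rng_seed=0)
        with pytest.raises(ValueError, match="lack"):
            classify(clf, records.drop(columns=["circularity"]))

    def test_seeded_determinism(self, records):
        a = classify(train_object_classifier(records, rng_seed=4), records)
        b = classify(train_object_classifier(records, rng_seed=4), records)
        assert a.predicted_class.tolist() == b.predicted_class.tolist()

    def test_holdout_accuracy_on_separable_scene_records(self, records):
        train, val = split_train_validation(records, 0.2, rng_seed=2)
        clf = train_object_classifier(train, rng_seed=2)
        pred = classify(clf, val)
        acc = (pred.predicted_class == pred.true_class).mean()
        assert acc >= 0.9


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = [0, 0, 1, 2, 2, 2]
        cm = confusion_matrix(y, y)
        assert np.array_equal(cm.counts, np.diag([2, 1, 3]))
        assert overall_accuracy(cm) == 1.0

    def test_single_predicted_class_single_column(self):
        cm = confusion_matrix([0, 1, 2, 1], [1, 1, 1, 1])
        assert cm.counts[:, [0, 2]].sum() == 0
        assert cm.counts[:, 1].sum() == 4

    def test_accuracy_is_trace_over_total(self):
        cm = ConfusionMatrix(tuple(MorphClass),
                             np.array([[8, 2, 0], [3, 7, 0], [0, 0, 0]]))
        assert overall_accuracy(cm) == pytest.approx(15 / 20)

    def test_row_sums_equal_true_counts(self, records):
        train, val = split_train_validation(records, 0.2, rng_seed=0)
        pred = classify(train_object_classifier(train, rng_seed=0), val)
        cm = confusion_matrix(pred.true_class, pred.predicted_class)
        for i, cls in enumerate(cm.classes):
            assert cm.counts[i].sum() == int((val.true_class == int(cls)).sum())
        assert cm.counts.sum() == len(val)
        direct = (pred.true_class == pred.predicted_class).mean()
        assert overall_accuracy(cm) == pytest.approx(direct)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_matrix([0, 1], [0])


class TestAblation:
    def test_default_arms_and_ordering(self, records):
        table = feature_ablation(records, rng_seed=0)
        assert len(table) == 4
        accs = dict(zip(table.features, table.accuracy))
        full = accs["+".join(DEFAULT_ABLATION_ARMS[3])]
        both = accs["area_um2+circularity"]
        single = max(accs["area_um2"], accs["circularity"])
        assert full >= both - 1e-12 >= single - 1e-12

    def test_duplicate_subsets_identical_rows(self, records):
        table = feature_ablation(records,
                                 subsets=[("area_um2",), ("area_um2",)],
                                 rng_seed=1)
        assert table.accuracy[0] == table.accuracy[1]

    def test_unknown_subset_rejected(self, records):
        with pytest.raises(ValueError, match="unknown"):
            feature_ablation(records, subsets=[("bogus",)])
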