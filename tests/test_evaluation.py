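"""Confusion matrices, accuracies, critical errors and re-sampling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ergopose import (
    ConfusionMatrix,
    EmptyInputError,
    LabelledSample,
    accuracy,
    confusion_matrix,
    critical_errors,
    overall_accuracy,
    read_labelled_csv,
    resample_eval,
    summarize_accuracies,
    to_binary,
    write_labelled_csv,
)

P = "neck_lateral_bend"


def samples_from_pairs(pairs, parameter=P):
    return [
        LabelledSample(frame=i, truth={parameter: g}, pred={parameter: p})
        for i, (g, p) in enumerate(pairs)
    ]


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        cm = confusion_matrix(samples_from_pairs([(z, z) for z in (0, 1, 2, 3)] * 3), P)
        assert np.all(cm.counts == np.diag(np.diag(cm.counts)))
        assert cm.total == 12

    def test_misclassification_placement(self):
        cm = confusion_matrix(samples_from_pairs([(0, 2)]), P)
        assert cm.counts[0][2] == 1
        assert cm.total == 1

    def test_total_conservation_and_invalid_exclusion(self):
        pairs = [(0, 0), (1, 2), (3, 3)]
        samples = samples_from_pairs(pairs) + [
            LabelledSample(frame=99, truth={P: 2}, pred={P: None})
        ]
        cm = confusion_matrix(samples, P)
        assert cm.total == 3
        assert cm.n_invalid == 1

    def test_no_valid_samples_raises(self):
        samples = [LabelledSample(frame=0, truth={P: 1}, pred={P: None})]
        with pytest.raises(EmptyInputError):
            confusion_matrix(samples, P)


class TestAccuracy:
    def test_diagonal_matrix_perfect(self):
        cm = confusion_matrix(samples_from_pairs([(z, z) for z in range(4)]), P)
        scores, overall = accuracy(cm)
        assert overall == 1.0
        assert all(s.accuracy == 1.0 for s in scores)

    def test_two_class_hand_example(self):
        """counts [[3,1],[0,6]]: overall 0.9 and both one-vs-rest accuracies 0.9."""
        cm = ConfusionMatrix(parameter=P, counts=np.array([[3, 1], [0, 6]]))
        scores, overall = accuracy(cm)
        assert overall == pytest.approx(0.9)
        assert scores[0].accuracy == pytest.approx(0.9)
        assert scores[1].accuracy == pytest.approx(0.9)

    @settings(max_examples=50, deadline=None)
    @given(counts=st.lists(st.integers(0, 20), min_size=16, max_size=16))
    def test_partition_identity(self, counts):
        """TP+TN+FP+FN = TOTAL for every class; row/column sums partition TOTAL."""
        arr = np.array(counts).reshape(4, 4)
        if arr.sum() == 0:
            return
        cm = ConfusionMatrix(parameter=P, counts=arr)
        scores, overall = accuracy(cm)
        total = cm.total
        for s in scores:
            assert s.tp + s.tn + s.fp + s.fn == total
        assert sum(s.tp + s.fn for s in scores) == total
        assert sum(s.tp + s.fp for s in scores) == total
        assert overall == pytest.approx(1 - (total - np.trace(arr)) / total)


class TestBinaryCollapse:
    def test_within_class_merge_fixes_adjacent_error(self):
        (s,) = to_binary(samples_from_pairs([(1, 0)]))
        assert s.truth[P] == s.pred[P] == 0

    def test_critical_error_persists(self):
        (s,) = to_binary(samples_from_pairs([(2, 0)]))
        assert s.truth[P] == 1 and s.pred[P] == 0

    zone_pair = st.tuples(st.integers(0, 3), st.integers(0, 3))

    @settings(max_examples=100, deadline=None)
    @given(pairs=st.lists(zone_pair, min_size=1, max_size=40))
    def test_merging_never_lowers_accuracy(self, pairs):
        samples = samples_from_pairs(pairs)
        acc4 = overall_accuracy(samples, P)
        acc2 = overall_accuracy(to_binary(samples), P)
        assert acc2 >= acc4


class TestCriticalErrors:
    def test_direction_matters(self):
        assert critical_errors(samples_from_pairs([(3, 1)]), P) == 1
        assert critical_errors(samples_from_pairs([(1, 3)]), P) == 0

    def test_perfect_predictions_zero(self):
        assert critical_errors(samples_from_pairs([(z, z) for z in range(4)]), P) == 0

    def test_count(self):
        pairs = [(2, 0), (2, 1), (3, 0), (3, 3), (0, 2), (1, 1)]
        assert critical_errors(samples_from_pairs(pairs), P) == 3


class TestSummarize:
    def test_all_equal_list_has_zero_std(self):
        rows, _, _ = summarize_accuracies([1.0] * 15)
        assert rows.std == 0.0
        assert rows.min == rows.max == rows.mean == 1.0

    def test_improve_definition(self):
        four, two, improve = summarize_accuracies([0.8, 0.8], [0.9, 0.9])
        assert improve == pytest.approx(100 * (0.9 - 0.8) / 0.8)

    def test_empty_list_raises(self):
        with pytest.raises(EmptyInputError):
            summarize_accuracies([])

    @settings(max_examples=50, deadline=None)
    @given(vals=st.lists(st.floats(0, 1, width=64), min_size=1, max_size=15))
    def test_matches_two_pass_oracle(self, vals):
        """MEAN/STD agree with a naive two-pass implementation to 1e-12."""
        rows, _, _ = summarize_accuracies(vals)
        mean = sum(vals) / len(vals)
        std = math.sqrt(sum((v - mean) ** 2 for v in vals) / len(vals))
        assert rows.mean == pytest.approx(mean, abs=1e-12)
        assert rows.std == pytest.approx(std, abs=1e-12)
        assert rows.min == min(vals) and rows.max == max(vals)


class TestResample:
    def make_samples(self, n=60, seed=7):
        rng = np.random.default_rng(seed)
        pairs = [(int(g), int(p)) for g, p in rng.integers(0, 4, size=(n, 2))]
        return samples_from_pairs(pairs)

    def test_fraction_one_has_zero_variance(self):
        samples = self.make_samples()
        summ = resample_eval(samples, n_subsets=8, fraction=1.0, seed=0, parameters=[P])
        assert summ[P].four_class.std == 0.0
        assert summ[P].four_class.mean == pytest.approx(overall_accuracy(samples, P))

    def test_deterministic_given_seed(self):
        samples = self.make_samples()
        a = resample_eval(samples, n_subsets=15, fraction=0.5, seed=42, parameters=[P])
        b = resample_eval(samples, n_subsets=15, fraction=0.5, seed=42, parameters=[P])
        assert a[P].four_class.values == b[P].four_class.values
        assert a[P].two_class.values == b[P].two_class.values

    def test_subset_count_and_bounds(self):
        summ = resample_eval(self.make_samples(), n_subsets=15, fraction=0.5, seed=1, parameters=[P])
        assert len(summ[P].four_class.values) == 15
        assert summ[P].four_class.min <= summ[P].four_class.mean <= summ[P].four_class.max
        assert summ[P].two_class.mean >= summ[P].four_class.mean  # class-merging property

    def test_too_few_samples(self):
        with pytest.raises(EmptyInputError):
            resample_eval(samples_from_pairs([]), n_subsets=3, fraction=0.5, parameters=[P])


class TestLabelledCsv:
    def test_round_trip_with_invalid_cells(self, tmp_path):
        samples = [
            LabelledSample(frame=0, truth={P: 2}, pred={P: 1}),
            LabelledSample(frame=1, truth={P: 3}, pred={P: None}),
        ]
        path = tmp_path / "labels.csv"
        write_labelled_csv(samples, path, parameters=[P])
        back = read_labelled_csv(path, parameters=[P])
        assert [(s.truth[P], s.pred[P]) for s in back] == [(2, 1), (3, None)]

    def test_out_of_range_zone_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(f"frame,{P}_truth,{P}_pred\n0,5,1\n")
        with pytest.raises(ValueError, match="row 2"):
            read_labelled_csv(path, parameters=[P])
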