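import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from mangresil.accuracy import (
    ConfusionMatrix,
    accuracy_report,
    build_confusion,
    class_accuracies,
    disagreement,
    overall_accuracy,
    qadi,
    qadi_confidence,
)

matrices = hnp.arrays(
    dtype=np.int64,
    shape=st.integers(2, 5).map(lambda k: (k, k)),
    elements=st.integers(0, 50),
).filter(lambda m: m.sum() > 0)


def cm_of(counts):
    counts = np.asarray(counts)
    return ConfusionMatrix(counts, tuple(f"c{i}" for i in range(counts.shape[0])))


class TestBuildConfusion:
    def test_perfect_agreement_is_diagonal(self):
        labels = [1, 1, 1, 2, 2, 2, 2, 1, 2, 1]
        cm = build_confusion(labels, labels, {1: "a", 2: "b"})
        assert cm.trace == 10 and cm.N == 10
        assert np.array_equal(cm.counts, np.diag(np.diag(cm.counts)))

    def test_direct_counts(self):
        # three mangrove/mangrove pairs plus one point mapped mangrove but water on the ground
        ref = ["m", "m", "m", "w"]
        pred = ["m", "m", "m", "m"]
        legend = {0: "m", 1: "w"}
        code = {"m": 0, "w": 1}
        cm = build_confusion([code[r] for r in ref], [code[p] for p in pred], legend)
        assert cm.counts[0, 0] == 3 and cm.counts[0, 1] == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_confusion([], [], {1: "a"})

    def test_unknown_label_named(self):
        with pytest.raises(ValueError, match="9"):
            build_confusion([1, 9], [1, 1], {1: "a"})


class TestPublishedMatrices:
    """Statistics recomputed from the two published 4-class error matrices."""

    def test_first_epoch_overall_and_class_accuracies(self, table3):
        assert table3.trace == 1698 and table3.N == 1705
        assert round(overall_accuracy(table3), 1) == 99.6
        acc = class_accuracies(table3)
        assert acc.loc["mangrove", "producers_accuracy"] == pytest.approx(100 * 647 / 649)
        assert round(acc.loc["mangrove", "producers_accuracy"], 1) == 99.7
        assert acc.loc["bare_builtup", "users_accuracy"] == pytest.approx(81.25)

    def test_first_epoch_column_totals_recomputed_from_cells(self, table3):
        # the published other-vegetation column total is a typo; cells are authoritative
        assert table3.column_totals.tolist() == [81, 649, 26, 949]

    def test_second_epoch_overall_and_class_accuracies(self, table4):
        assert table4.trace == 1691 and table4.N == 1705
        assert overall_accuracy(table4) == pytest.approx(100 * 1691 / 1705)
        acc = class_accuracies(table4)
        assert round(acc.loc["mangrove", "users_accuracy"], 1) == 99.2
        assert round(acc.loc["mangrove", "producers_accuracy"], 1) == 98.6

    def test_second_epoch_disagreement_decomposition(self, table4):
        Q, A, D = disagreement(table4)
        assert (Q, A, D) == (5.0, 9.0, 14.0)
        value, label = qadi(table4)
        assert value == pytest.approx(np.hypot(9 / 1705, 5 / 1705))
        assert "Very high confidence" in label


class TestDisagreement:
    def test_perfect_matrix_zero_everywhere(self):
        cm = cm_of(np.diag([5, 7]))
        assert disagreement(cm) == (0.0, 0.0, 0.0)
        assert qadi(cm)[0] == 0.0

    def test_pure_quantity_case(self):
        Q, A, D = disagreement(cm_of([[2, 0], [2, 0]]))
        assert (Q, A, D) == (2.0, 0.0, 2.0)

    def test_half_n_quantity_reaches_qadi_half(self):
        value, label = qadi(cm_of([[5, 5], [0, 0]]))
        assert value == pytest.approx(0.5)
        assert "Very low confidence" in label

    @given(matrices)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_quantity_plus_allocation_is_total(self, counts):
        cm = cm_of(counts)
        Q, A, D = disagreement(cm)
        assert Q + A == pytest.approx(cm.N - cm.trace)
        assert Q >= 0 and A >= 0

    @given(matrices)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_qadi_bounds_and_diagonal_equivalence(self, counts):
        cm = cm_of(counts)
        Q, A, D = disagreement(cm)
        value, _ = qadi(cm)
        assert max(A, Q) / cm.N - 1e-12 <= value <= (A + Q) / cm.N + 1e-12
        is_diagonal = np.array_equal(counts, np.diag(np.diag(counts)))
        assert (value == 0) == is_diagonal
        assert (overall_accuracy(cm) == 100.0) == is_diagonal

    @given(matrices, st.randoms(use_true_random=False))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_qadi_invariant_to_class_relabelling(self, counts, rnd):
        k = counts.shape[0]
        perm = list(range(k))
        rnd.shuffle(perm)
        permuted = counts[np.ix_(perm, perm)]
        assert qadi(cm_of(permuted))[0] == pytest.approx(qadi(cm_of(counts))[0])


class TestConfidenceScale:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.0, "Very high confidence"),
            (0.069, "Very high confidence"),
            (0.07, "High confidence"),
            (0.12, "Moderate confidence"),
            (0.20, "Low confidence"),
            (0.30, "Very low confidence"),
            (1.0, "Very low confidence"),
        ],
    )
    def test_scale_bins(self, value, expected):
        assert expected in qadi_confidence(value)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            qadi_confidence(-0.01)


def test_report_bundles_consistent_fields(table4):
    report = accuracy_report(table4)
    assert report.total_disagreement == report.N - table4.trace
    assert report.quantity_disagreement + report.allocation_disagreement == (
        report.total_disagreement
    )
    d = report.to_dict()
    assert d["overall_accuracy_pct"] == 99.2 and d["qadi"] == 0.00604
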