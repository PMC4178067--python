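"""The cell kernel: assignment, labelling, classification, accuracy."""

import numpy as np
import pytest

from mvgmdr import (
    HIGH,
    LOW,
    UNASSIGNED,
    ClassificationModel,
    GenotypeMatrix,
    accuracy_report,
    assign_cells,
    build_cell_table,
    classify,
)
from mvgmdr.core import cell_key, metric_value
from mvgmdr.errors import EmptyTableError, GmdrError


def _geno(values):
    values = np.asarray(values)
    return GenotypeMatrix(values,
                          [f"L{j}" for j in range(values.shape[1])],
                          [f"S{i}" for i in range(values.shape[0])])


def test_assign_cells_indicator_semantics():
    G = _geno([[0, 2, 1], [1, 1, 0], [2, -1, 0]])
    cells = assign_cells(G, (0, 1))
    assert cells[0] == 2          # codes (0,2) -> base-3 index 2
    assert cell_key(cells[0], 2) == (0, 2)
    assert cells[1] == 4          # codes (1,1)
    assert cells[2] == UNASSIGNED  # missing at locus 1


def test_assign_cells_partition_property():
    rng = np.random.default_rng(0)
    G = _geno(rng.integers(0, 3, size=(50, 4)))
    cells = assign_cells(G, (1, 3))
    # every individual occupies exactly one of the 9 cells
    assert np.all(cells >= 0) and np.all(cells < 9)
    assert np.bincount(cells, minlength=9).sum() == 50


def test_assign_cells_errors():
    G = _geno([[0, 1]])
    with pytest.raises(GmdrError):
        assign_cells(G, ())
    with pytest.raises(GmdrError):
        assign_cells(G, (0, 0))


def test_build_cell_table_labels():
    cells = np.array([0, 0, 5])
    scores = np.array([1.0, -0.5, -2.0])
    tab = build_cell_table(cells, scores, 0.0, m=2)
    assert tab.score_means[0] == pytest.approx(0.25)
    assert tab.labels[0] == HIGH
    assert tab.labels[5] == LOW
    assert tab.labels[1] == UNASSIGNED  # empty cell
    assert tab.counts.sum() == 3


def test_cell_mean_exactly_zero_is_high():
    tab = build_cell_table(np.array([0, 0]), np.array([1.0, -1.0]), 0.0, m=1)
    assert tab.labels[0] == HIGH  # "not less than" the threshold


def test_build_cell_table_empty_error():
    with pytest.raises(EmptyTableError):
        build_cell_table(np.array([-1, -1]), np.array([1.0, 2.0]), 0.0, m=1)


def test_classify_policies():
    model = ClassificationModel(subset=(0,), high_cells=frozenset({0}),
                                seen_cells=frozenset({0, 1}), unseen_cell_policy="low")
    cells = np.array([0, 1, 2, UNASSIGNED])
    groups = classify(model, cells)
    assert groups.tolist() == [HIGH, LOW, LOW, UNASSIGNED]
    excl = ClassificationModel(subset=(0,), high_cells=frozenset({0}),
                               seen_cells=frozenset({0, 1}), unseen_cell_policy="exclude")
    assert classify(excl, cells).tolist() == [HIGH, LOW, UNASSIGNED, UNASSIGNED]


def test_accuracy_report_hand_values():
    # TP=3, FN=2 (high values), FP=1, TN=2 (low values), unit-magnitude scores
    scores = np.array([1, 1, 1, 1, 1, -1, -1, -1], dtype=float)
    groups = np.array([HIGH, HIGH, HIGH, LOW, LOW, HIGH, LOW, LOW])
    rep = accuracy_report(scores, groups)
    assert (rep.tp, rep.fn, rep.fp, rep.tn) == (3, 2, 1, 2)
    assert rep.accuracy == pytest.approx(0.625)
    assert rep.balanced_accuracy == pytest.approx((3 / 5 + 2 / 3) / 2)
    assert rep.weighted_accuracy == pytest.approx(0.625)  # unit masses coincide
    assert rep.n_classified == 8


def test_accuracy_perfect_separation():
    scores = np.array([2.0, 1.0, -1.0, -3.0])
    groups = np.array([HIGH, HIGH, LOW, LOW])
    rep = accuracy_report(scores, groups)
    assert rep.accuracy == 1.0
    assert rep.balanced_accuracy == 1.0
    assert rep.weighted_accuracy == 1.0
    assert rep.score_difference == pytest.approx(1.5 - (-2.0))


def test_accuracy_random_is_half():
    rng = np.random.default_rng(99)
    n = 100_000
    scores = rng.normal(size=n)
    groups = rng.integers(0, 2, size=n).astype(np.int8)
    rep = accuracy_report(scores, groups)
    assert rep.accuracy == pytest.approx(0.5, abs=0.01)
    assert rep.weighted_accuracy == pytest.approx(0.5, abs=0.01)


def test_unclassified_excluded_from_denominators():
    scores = np.array([1.0, -1.0, 5.0])
    groups = np.array([HIGH, LOW, UNASSIGNED])
    rep = accuracy_report(scores, groups)
    assert rep.n_classified == 2
    assert rep.accuracy == 1.0


def _brute_force_metrics(scores, cells, n_cells, threshold=0.0):
    """Independent loop-based oracle for table building and accuracy."""
    members = {c: [] for c in range(n_cells)}
    for s, c in zip(scores, cells):
        if c >= 0:
            members[c].append(s)
    high_cells = {c for c, v in members.items() if v and np.mean(v) >= threshold}
    correct = wrong = 0
    wcorrect = wwrong = 0.0
    for s, c in zip(scores, cells):
        if c < 0:
            continue
        predicted_high = c in high_cells
        value_high = s >= threshold
        if predicted_high == value_high:
            correct += 1
            wcorrect += abs(s - threshold)
        else:
            wrong += 1
            wwrong += abs(s - threshold)
    return correct / (correct + wrong), wcorrect / (wcorrect + wwrong)


@pytest.mark.parametrize("m", [1, 2, 3, 4])
def test_kernel_matches_brute_force_oracle(m):
    rng = np.random.default_rng(m)
    G = _geno(rng.integers(0, 3, size=(300, 5)))
    scores = rng.normal(size=300)
    subset = tuple(range(m))
    cells = assign_cells(G, subset)
    tab = build_cell_table(cells, scores, 0.0, m=m)
    model = ClassificationModel.from_table(subset, tab)
    rep = accuracy_report(scores, classify(model, cells))
    acc, wacc = _brute_force_metrics(scores, cells, 3**m)
    assert rep.accuracy == pytest.approx(acc, abs=1e-12)
    assert rep.weighted_accuracy == pytest.approx(wacc, abs=1e-12)


def test_label_symmetry_under_score_negation():
    # negating scores flips every label; accuracy is unchanged
    rng = np.random.default_rng(4)
    G = _geno(rng.integers(0, 3, size=(400, 4)))
    scores = rng.normal(size=400) + 0.2
    cells = assign_cells(G, (0, 2))
    tab = build_cell_table(cells, scores, 0.0, m=2)
    rep = accuracy_report(scores, classify(ClassificationModel.from_table((0, 2), tab), cells))
    tab_neg = build_cell_table(cells, -scores, 0.0, m=2)
    rep_neg = accuracy_report(
        -scores, classify(ClassificationModel.from_table((0, 2), tab_neg), cells))
    # ties (mean exactly at the boundary) are measure-zero for continuous scores
    assert rep_neg.accuracy == pytest.approx(rep.accuracy, abs=1e-12)
    assert rep_neg.weighted_accuracy == pytest.approx(rep.weighted_accuracy, abs=1e-12)


def test_sum_and_mean_labeling_agree_at_zero_threshold():
    rng = np.random.default_rng(8)
    cells = rng.integers(0, 9, size=200)
    scores = rng.normal(size=200)
    tab = build_cell_table(cells, scores, 0.0, m=2)
    occ = tab.counts > 0
    assert np.array_equal(tab.labels[occ] == HIGH, tab.score_sums[occ] >= 0)


def test_metric_value_dispatch():
    scores = np.array([1.0, -1.0])
    groups = np.array([HIGH, LOW])
    rep = accuracy_report(scores, groups)
    assert metric_value(rep, "plain") == rep.accuracy
    assert metric_value(rep, "weighted") == rep.weighted_accuracy
    assert metric_value(rep, "balanced") == rep.balanced_accuracy
    assert metric_value(rep, "score_difference") == rep.score_difference
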