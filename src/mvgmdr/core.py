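"""The dimensionality-reduction kernel.

A subset of m attributes (loci, or pre-discretized environmental factors)
spans a 3^m-cell contingency table.  Each individual with complete genotypes
on the subset occupies exactly one cell; a cell is labelled *high-valued* when
the mean score of its members is not less than the threshold T (0 by
default), *low-valued* otherwise, and *empty* when unoccupied.  Pooling high
cells against low cells yields a one-dimensional classification attribute
whose fit is measured by classification accuracy: an individual's own value
is "high" iff its score >= T, and accuracy is the proportion of high-valued
individuals in the high group plus low-valued individuals in the low group.
Balanced accuracy and a quantitative score-difference criterion are available
as alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import GenotypeMatrix
from .errors import EmptyTableError, GmdrError

#: group / label codes
HIGH, LOW, UNASSIGNED = 1, 0, -1


def _check_subset(subset, n_loci: int):
    subset = tuple(int(i) for i in subset)
    if len(subset) == 0:
        raise GmdrError("factor subset must contain at least one attribute")
    if len(set(subset)) != len(subset):
        raise GmdrError(f"factor subset {subset} has repeated attributes")
    if any(i < 0 or i >= n_loci for i in subset):
        raise GmdrError(f"factor subset {subset} out of range for {n_loci} loci")
    return tuple(sorted(subset))


def assign_cells(G: GenotypeMatrix, subset) -> np.ndarray:
    """Map each individual to a cell index in the m-way table (or -1).

    Cells are numbered by the base-3 expansion of the genotype codes along
    the (ascending) subset; individuals missing any subset locus are
    unassigned (-1).
    """
    subset = _check_subset(subset, G.n_loci)
    codes = G.values[:, subset].astype(np.int64)
    valid = (codes >= 0).all(axis=1)
    weights = 3 ** np.arange(len(subset) - 1, -1, -1, dtype=np.int64)
    cells = codes @ weights
    cells[~valid] = UNASSIGNED
    return cells


def cell_key(index: int, m: int) -> tuple[int, ...]:
    """Base-3 digits of a cell index: the m-tuple of genotype codes."""
    digits = []
    for _ in range(m):
        digits.append(index % 3)
        index //= 3
    return tuple(reversed(digits))


@dataclass
class CellTable:
    """Per-cell occupancy, score sums/means and high/low/empty labels."""

    m: int
    threshold: float
    counts: np.ndarray      # (3^m,) int
    score_sums: np.ndarray  # (3^m,) float
    labels: np.ndarray      # (3^m,) int8: HIGH / LOW / UNASSIGNED(empty)

    @property
    def n_cells(self) -> int:
        return 3 ** self.m

    @property
    def score_means(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.counts > 0, self.score_sums / self.counts, np.nan)

    @property
    def high_cells(self) -> frozenset[int]:
        return frozenset(np.flatnonzero(self.labels == HIGH).tolist())

    @property
    def seen_cells(self) -> frozenset[int]:
        return frozenset(np.flatnonzero(self.counts > 0).tolist())

    def to_records(self):
        """Cell-level records (key, count, score_sum, label) for export."""
        names = {HIGH: "high", LOW: "low", UNASSIGNED: "empty"}
        return [
            {
                "cell": cell_key(c, self.m),
                "count": int(self.counts[c]),
                "score_sum": float(self.score_sums[c]),
                "label": names[int(self.labels[c])],
            }
            for c in range(self.n_cells)
        ]


def build_cell_table(cells: np.ndarray, scores: np.ndarray, threshold: float = 0.0,
                     m: int | None = None) -> CellTable:
    """Tabulate counts and score sums per cell and label high/low cells.

    A non-empty cell is high-valued iff its mean member score is not less
    than ``threshold`` (with T=0 this is the sign of the score sum); empty
    cells are labelled ``UNASSIGNED`` and never join either pooled group.
    """
    cells = np.asarray(cells)
    scores = np.asarray(scores, dtype=float)
    if cells.shape != scores.shape:
        raise GmdrError("cells and scores are not aligned")
    assigned = cells >= 0
    if not assigned.any():
        raise EmptyTableError("no individual could be assigned to any cell")
    if m is None:
        m = int(np.ceil(np.log(max(int(cells[assigned].max()), 1) + 1) / np.log(3))) or 1
    n_cells = 3 ** m
    counts = np.bincount(cells[assigned], minlength=n_cells)
    sums = np.bincount(cells[assigned], weights=scores[assigned], minlength=n_cells)
    labels = np.full(n_cells, UNASSIGNED, dtype=np.int8)
    occ = counts > 0
    labels[occ] = np.where(sums[occ] >= threshold * counts[occ], HIGH, LOW)
    return CellTable(m=m, threshold=float(threshold), counts=counts,
                     score_sums=sums, labels=labels)


@dataclass(frozen=True)
class ClassificationModel:
    """A trained high/low pooling over the cells of one factor subset."""

    subset: tuple[int, ...]
    high_cells: frozenset[int]
    seen_cells: frozenset[int]
    unseen_cell_policy: str = "low"

    @classmethod
    def from_table(cls, subset, table: CellTable,
                   unseen_cell_policy: str = "low") -> "ClassificationModel":
        return cls(tuple(sorted(int(i) for i in subset)), table.high_cells,
                   table.seen_cells, unseen_cell_policy)


def classify(model: ClassificationModel, cells: np.ndarray) -> np.ndarray:
    """Group individuals as HIGH / LOW / UNASSIGNED under a trained model.

    Individuals in cells that were empty during training follow the model's
    ``unseen_cell_policy``: ``low`` assigns them to the low group,
    ``exclude`` leaves them unclassified.
    """
    cells = np.asarray(cells)
    groups = np.full(cells.shape, UNASSIGNED, dtype=np.int8)
    assigned = cells >= 0
    if model.high_cells:
        high = np.isin(cells, list(model.high_cells))
        groups[assigned & high] = HIGH
    seen = np.isin(cells, list(model.seen_cells)) if model.seen_cells else np.zeros_like(assigned)
    groups[assigned & seen & (groups != HIGH)] = LOW
    unseen = assigned & ~seen
    if model.unseen_cell_policy == "low":
        groups[unseen] = LOW
    return groups


@dataclass
class AccuracyReport:
    """Confusion counts and the four classification criteria.

    ``tp``..``fn`` are individual counts; ``weighted_accuracy`` re-weights the
    same confusion by each individual's score mass |score - T|, so that
    individuals barely on either side of the boundary count less.  For scores
    of unit magnitude the two accuracies coincide.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    balanced_accuracy: float
    weighted_accuracy: float
    score_difference: float
    n_classified: int


def accuracy_report(scores: np.ndarray, groups: np.ndarray,
                    threshold: float = 0.0) -> AccuracyReport:
    """Score a high/low grouping against the individuals' own values.

    An individual's value is "high" iff its score >= ``threshold`` (the same
    boundary convention as cell labelling).  Unclassified individuals are
    excluded from every denominator.  Balanced-accuracy arms with an empty
    denominator contribute 0.5; the score difference is the mean score of the
    high group minus that of the low group (NaN if either group is empty).
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    mask = groups != UNASSIGNED
    if not mask.any():
        raise GmdrError("no classified individuals to score")
    s, g = scores[mask], groups[mask]
    value_high = s >= threshold
    in_high = g == HIGH
    tp = int(np.sum(value_high & in_high))
    fn = int(np.sum(value_high & ~in_high))
    fp = int(np.sum(~value_high & in_high))
    tn = int(np.sum(~value_high & ~in_high))
    n = tp + tn + fp + fn
    acc = (tp + tn) / n
    sens = tp / (tp + fn) if (tp + fn) > 0 else 0.5
    spec = tn / (tn + fp) if (tn + fp) > 0 else 0.5
    mass = np.abs(s - threshold)
    correct_mass = float(mass[value_high == in_high].sum())
    total_mass = float(mass.sum())
    wacc = correct_mass / total_mass if total_mass > 0 else float("nan")
    if in_high.any() and (~in_high).any():
        diff = float(s[in_high].mean() - s[~in_high].mean())
    else:
        diff = float("nan")
    return AccuracyReport(tp=tp, tn=tn, fp=fp, fn=fn, accuracy=acc,
                          balanced_accuracy=(sens + spec) / 2.0,
                          weighted_accuracy=wacc,
                          score_difference=diff, n_classified=n)


def metric_value(report: AccuracyReport, metric: str) -> float:
    """Extract one selection criterion from an :class:`AccuracyReport`."""
    return {
        "weighted": report.weighted_accuracy,
        "plain": report.accuracy,
        "balanced": report.balanced_accuracy,
        "score_difference": report.score_difference,
    }[metric]
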