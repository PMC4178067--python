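"""k-fold cross-validated exhaustive search over factor subsets.

For every subset of m loci the data are split into k folds; on each fold's
training part the cell table is built and labelled, the within-fold best
subset maximizes the training criterion, and the held-out part yields the
testing accuracy.  The final model at each size is the modal per-fold winner
(ties broken by higher mean testing accuracy, then lexicographically);
cross-validation consistency (CVC) counts the folds that picked it and the
reported testing accuracy (TA) is its mean held-out accuracy across folds.

The search kernel is vectorized: all C(L, m) subsets of one size are scored
per fold with a handful of ``bincount`` calls over base-3 cell indices, which
keeps full permutation tests and Monte Carlo studies tractable on one CPU.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from math import comb

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .core import (
    ClassificationModel,
    accuracy_report,
    assign_cells,
    build_cell_table,
    classify,
    metric_value,
)
from .datamodel import GenotypeMatrix, RunConfig
from .errors import FoldError, GmdrError

# cap on the per-chunk (rows x subsets) workspace of the vectorized kernel
_CHUNK_ELEMENTS = 20_000_000


def kfold_split(n: int, k: int, seed: int, strata=None) -> np.ndarray:
    """Balanced random fold assignment (0..k-1 per individual), reproducible.

    With ``strata`` (any label array, e.g. the sign of the score) the split
    is stratified so each fold carries a proportional share of every stratum;
    if a stratum is smaller than k the split falls back to a plain shuffle.
    """
    if k > n:
        raise GmdrError(f"cannot split {n} individuals into {k} folds")
    if k < 2:
        raise GmdrError("need at least 2 folds")
    rs = int(seed) % (2**32)
    folds = np.empty(n, dtype=np.int32)
    if strata is not None:
        strata = np.asarray(strata)
        if np.bincount(np.unique(strata, return_inverse=True)[1]).min() < k:
            strata = None
    if strata is None:
        splitter = KFold(n_splits=k, shuffle=True, random_state=rs).split(np.zeros(n))
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs).split(
            np.zeros(n), strata)
    for f, (_, test_idx) in enumerate(splitter):
        folds[test_idx] = f
    return folds


@dataclass
class CVResult:
    """Search outcome for one model size."""

    size: int
    n_subsets: int
    final_subset: tuple[int, ...]
    final_locus_ids: tuple[str, ...]
    cvc: int
    mean_test_accuracy: float
    mean_train_accuracy: float
    winner_mean_test_accuracy: float
    fold_winners: list[tuple[int, ...]] = field(repr=False)
    fold_train_accuracy: np.ndarray = field(repr=False)
    fold_test_accuracy: np.ndarray = field(repr=False)


def cross_validation_consistency(per_fold_best) -> int:
    """Number of folds whose winner equals the modal winner."""
    winners = [tuple(w) for w in per_fold_best]
    if not winners:
        raise GmdrError("no per-fold winners supplied")
    return Counter(winners).most_common(1)[0][1]


def _tabulate(flat: np.ndarray, rows: np.ndarray, weight_arrays, S: int, ncells: int):
    """Per-(subset, cell) occupancy count plus one table per weight array."""
    nbins = S * ncells
    fl = flat[rows].ravel()
    out = [np.bincount(fl, minlength=nbins + 1)[:nbins].reshape(S, ncells)]
    for w in weight_arrays:
        out.append(np.bincount(fl, weights=np.repeat(w[rows], S),
                               minlength=nbins + 1)[:nbins].reshape(S, ncells))
    return out


def _balanced(counts, nh, label):
    pos = nh.sum(axis=1)
    neg = counts.sum(axis=1) - pos
    tp = (nh * label).sum(axis=1)
    tn = ((counts - nh) * ~label).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(pos > 0, tp / pos, 0.5)
        spec = np.where(neg > 0, tn / neg, 0.5)
    return (sens + spec) / 2.0


def _ratio(correct, denom):
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, correct / denom, np.nan)


class _SizeKernel:
    """Vectorized evaluation of every subset of one size on one fold split.

    Centred scores ``sT = score - T`` drive everything: a training cell is
    high-valued iff its ``sT`` sum is >= 0 (the mean >= T rule), an
    individual's value is high iff ``sT >= 0``, and the weighted criterion
    uses each individual's |sT| mass.
    """

    def __init__(self, scores: np.ndarray, config: RunConfig):
        self.metric = config.accuracy_metric
        self.policy = config.unseen_cell_policy
        self.sT = scores - config.threshold
        self.high = (self.sT >= 0).astype(float)
        if self.metric == "weighted":
            pos = np.clip(self.sT, 0.0, None)
            self.weights = [self.sT, pos, np.abs(self.sT)]
        else:
            self.weights = [self.sT, self.high]

    def fold(self, flat, train_rows, test_rows, S, ncells):
        """(selection metric, train accuracy, test accuracy) per subset."""
        tabs_tr = _tabulate(flat, train_rows, self.weights, S, ncells)
        counts_tr, sums_tr = tabs_tr[0], tabs_tr[1]
        occ = counts_tr > 0
        label = occ & (sums_tr >= 0)
        tabs_te = _tabulate(flat, test_rows, self.weights, S, ncells)
        if self.policy == "exclude":
            tabs_te = [t * occ for t in tabs_te]
        if self.metric == "weighted":
            pos_tr, abs_tr = tabs_tr[2], tabs_tr[3]
            acc = _ratio(np.where(label, pos_tr, abs_tr - pos_tr).sum(axis=1),
                         abs_tr.sum(axis=1))
            pos_te, abs_te = tabs_te[2], tabs_te[3]
            test = _ratio(np.where(label, pos_te, abs_te - pos_te).sum(axis=1),
                          abs_te.sum(axis=1))
            sel = acc
        else:
            nh_tr = tabs_tr[2]
            counts_te, nh_te = tabs_te[0], tabs_te[2]
            plain_tr = _ratio(np.where(label, nh_tr, counts_tr - nh_tr).sum(axis=1),
                              counts_tr.sum(axis=1))
            plain_te = _ratio(np.where(label, nh_te, counts_te - nh_te).sum(axis=1),
                              counts_te.sum(axis=1))
            if self.metric == "plain":
                sel = acc = plain_tr
                test = plain_te
            elif self.metric == "balanced":
                sel = acc = _balanced(counts_tr, nh_tr, label)
                test = _balanced(counts_te, nh_te, label)
            else:  # score_difference selects; accuracies stay count-based
                n_high = (counts_tr * label).sum(axis=1).astype(float)
                s_high = (sums_tr * label).sum(axis=1)
                denom = counts_tr.sum(axis=1).astype(float)
                n_low = denom - n_high
                s_low = sums_tr.sum(axis=1) - s_high
                with np.errstate(invalid="ignore", divide="ignore"):
                    sel = np.where((n_high > 0) & (n_low > 0),
                                   s_high / n_high - s_low / n_low, -np.inf)
                acc = plain_tr
                test = plain_te
        sel = np.where(np.isnan(sel), -np.inf, sel)
        return sel, acc, test


def _subset_cells(values: np.ndarray, subsets: np.ndarray, ncells: int) -> np.ndarray:
    """Flattened (subset-offset) cell index per individual; invalid -> S*ncells."""
    n = values.shape[0]
    S, m = subsets.shape
    cols = values[:, subsets.ravel()].reshape(n, S, m)
    valid = (cols >= 0).all(axis=2)
    w3 = 3 ** np.arange(m - 1, -1, -1, dtype=np.int64)
    flat = cols.astype(np.int64) @ w3 + np.arange(S, dtype=np.int64) * ncells
    flat[~valid] = S * ncells
    return flat


def _search_one_size(G: GenotypeMatrix, kernel: _SizeKernel, m: int, folds: np.ndarray,
                     config: RunConfig) -> CVResult:
    n, L = G.values.shape
    k = int(folds.max()) + 1
    S = comb(L, m)
    ncells = 3 ** m
    train_sel = np.empty((k, S))
    train_acc = np.empty((k, S))
    test_acc = np.empty((k, S))
    chunk = max(1, min(S, _CHUNK_ELEMENTS // max(1, n * m)))
    combos = itertools.combinations(range(L), m)
    fold_rows = [(np.flatnonzero(folds != f), np.flatnonzero(folds == f)) for f in range(k)]
    start = 0
    while start < S:
        sub = np.array(list(itertools.islice(combos, chunk)), dtype=np.int64)
        sc = sub.shape[0]
        flat = _subset_cells(G.values, sub, ncells)
        sl = slice(start, start + sc)
        for f, (tr, te) in enumerate(fold_rows):
            sel, acc, ta = kernel.fold(flat, tr, te, sc, ncells)
            train_sel[f, sl] = sel
            train_acc[f, sl] = acc
            test_acc[f, sl] = ta
        start += sc
    if not np.isfinite(train_sel).any(axis=1).all():
        raise FoldError(f"a fold has no assignable training individual at size {m}")

    winners = np.argmax(train_sel, axis=1)  # ties -> lowest index = lexicographic
    counts = Counter(winners.tolist())
    top = max(counts.values())
    with np.errstate(invalid="ignore"):
        mean_ta = np.nanmean(test_acc, axis=0)
    candidates = sorted((idx for idx, c in counts.items() if c == top),
                        key=lambda idx: (-mean_ta[idx], idx))
    final = int(candidates[0])
    subsets_of = _nth_combinations(L, m, sorted(set(winners.tolist()) | {final}))
    final_subset = subsets_of[final]
    return CVResult(
        size=m,
        n_subsets=S,
        final_subset=final_subset,
        final_locus_ids=tuple(G.locus_ids[i] for i in final_subset),
        cvc=int(np.sum(winners == final)),
        mean_test_accuracy=float(np.nanmean(test_acc[:, final])),
        mean_train_accuracy=float(np.nanmean(train_acc[:, final])),
        winner_mean_test_accuracy=float(np.nanmean(test_acc[np.arange(k), winners])),
        fold_winners=[subsets_of[int(w)] for w in winners],
        fold_train_accuracy=train_acc[:, final].copy(),
        fold_test_accuracy=test_acc[:, final].copy(),
    )


def _nth_combinations(L: int, m: int, wanted) -> dict[int, tuple[int, ...]]:
    """Map lexicographic combination ranks to their index tuples."""
    wanted = sorted(set(int(w) for w in wanted))
    out = {}
    it = enumerate(itertools.combinations(range(L), m))
    for target in wanted:
        for rank, combo in it:
            if rank == target:
                out[target] = combo
                break
    return out


def evaluate_subset(subset, folds: np.ndarray, G: GenotypeMatrix, scores,
                    config: RunConfig | None = None):
    """Reference per-fold evaluation of a single subset via the cell kernel.

    Returns ``(train_acc, test_acc)`` arrays of length k holding the
    configured accuracy metric.  Deliberately routed through
    :mod:`mvgmdr.core` object by object, independent of the vectorized
    search path, so the two can check each other.
    """
    config = config or RunConfig()
    metric = config.accuracy_metric if config.accuracy_metric != "score_difference" else "plain"
    scores = np.asarray(scores, dtype=float)
    folds = np.asarray(folds)
    cells = assign_cells(G, subset)
    k = int(folds.max()) + 1
    train_acc = np.empty(k)
    test_acc = np.empty(k)
    for f in range(k):
        tr = folds != f
        te = ~tr
        if not (cells[tr] >= 0).any():
            raise FoldError(f"fold {f}: no assignable training individuals")
        table = build_cell_table(cells[tr], scores[tr], config.threshold, m=len(subset))
        model = ClassificationModel.from_table(subset, table, config.unseen_cell_policy)
        train_acc[f] = metric_value(
            accuracy_report(scores[tr], classify(model, cells[tr]), config.threshold), metric)
        try:
            test_acc[f] = metric_value(
                accuracy_report(scores[te], classify(model, cells[te]), config.threshold),
                metric)
        except GmdrError:
            test_acc[f] = np.nan
    return train_acc, test_acc


def exhaustive_search(G: GenotypeMatrix, scores, sizes, folds: np.ndarray,
                      config: RunConfig | None = None) -> list[CVResult]:
    """Evaluate every C(L, m) subset at each requested size; one CVResult per size."""
    config = config or RunConfig()
    sizes = [int(m) for m in np.atleast_1d(sizes)]
    if not sizes:
        raise GmdrError("no model sizes requested")
    if max(sizes) > G.n_loci:
        raise GmdrError(f"model size {max(sizes)} exceeds {G.n_loci} loci")
    if min(sizes) < 1:
        raise GmdrError("model sizes must be >= 1")
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != G.n_samples:
        raise GmdrError("scores are not aligned to the genotype matrix")
    folds = np.asarray(folds)
    kernel = _SizeKernel(scores, config)
    return [_search_one_size(G, kernel, m, folds, config) for m in sizes]


def run_search(G: GenotypeMatrix, scores, sizes, config: RunConfig | None = None,
               seed: int | None = None) -> list[CVResult]:
    """Fold assignment + exhaustive search in one call.

    Folds are stratified on the sign of the score (``score >= T``) when
    ``config.stratify_folds`` is set; ``seed`` defaults to ``config.seed``.
    """
    config = config or RunConfig()
    seed = config.seed if seed is None else int(seed)
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != G.n_samples:
        raise GmdrError("scores are not aligned to the genotype matrix")
    strata = (scores >= config.threshold) if config.stratify_folds else None
    folds = kfold_split(G.n_samples, config.cv_folds, seed, strata=strata)
    return exhaustive_search(G, scores, sizes, folds, config)


def select_best_size(results: list[CVResult]) -> CVResult:
    """Across sizes, prefer the highest CVC, then the highest testing accuracy."""
    if not results:
        raise GmdrError("no results to select from")
    return max(results, key=lambda r: (r.cvc, r.mean_test_accuracy))
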