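"""Cross-validated exhaustive search: folds, winners, CVC, consistency."""

import numpy as np
import pytest

from mvgmdr import (
    RunConfig,
    cross_validation_consistency,
    evaluate_subset,
    exhaustive_search,
    kfold_split,
    run_search,
    select_best_size,
)
from mvgmdr.datamodel import GenotypeMatrix
from mvgmdr.errors import GmdrError
from mvgmdr.null_models import null_scores


def _geno(values):
    values = np.asarray(values)
    return GenotypeMatrix(values,
                          [f"L{j}" for j in range(values.shape[1])],
                          [f"S{i}" for i in range(values.shape[0])])


def test_kfold_sizes_and_determinism():
    folds = kfold_split(1000, 10, seed=5)
    assert np.bincount(folds).tolist() == [100] * 10
    assert np.array_equal(folds, kfold_split(1000, 10, seed=5))
    assert not np.array_equal(folds, kfold_split(1000, 10, seed=6))
    singles = kfold_split(10, 10, seed=1)
    assert sorted(singles.tolist()) == list(range(10))


def test_kfold_stratified_balances_strata():
    strata = np.repeat([0, 1], [800, 200])
    folds = kfold_split(1000, 10, seed=2, strata=strata)
    for f in range(10):
        assert np.sum((folds == f) & (strata == 1)) == 20


def test_kfold_k_greater_than_n_errors():
    with pytest.raises(GmdrError):
        kfold_split(5, 10, seed=0)


def test_exhaustive_search_counts_subsets(null_dataset, config):
    G, Y, _ = null_dataset
    _, _, s = null_scores(Y, config=config)
    res = run_search(G, s, [2], config, seed=0)[0]
    assert res.n_subsets == 45  # C(10, 2)


def test_strong_signal_recovers_causal_pair(strong_digenic, config):
    G, Y, truth = strong_digenic
    _, _, s = null_scores(Y, config=config)
    res = run_search(G, s, [2], config, seed=3)[0]
    assert res.final_subset == tuple(truth["causal_loci"])
    assert res.cvc == 10
    assert res.mean_test_accuracy > 0.75


def test_null_scores_give_half_testing_accuracy(null_dataset, config):
    G, Y, _ = null_dataset
    _, _, s = null_scores(Y, config=config)
    rng = np.random.default_rng(17)
    res = run_search(G, rng.permutation(s), [2], config, seed=17)[0]
    assert res.winner_mean_test_accuracy == pytest.approx(0.5, abs=0.05)


def test_engine_matches_reference_recomputation(strong_digenic):
    """Fold-level accuracies from the vectorized path equal a from-scratch
    object-by-object recomputation of the same subset (both metrics)."""
    G, Y, _ = strong_digenic
    for metric in ("weighted", "plain"):
        cfg = RunConfig(accuracy_metric=metric, stratify_folds=False)
        _, _, s = null_scores(Y, config=cfg)
        folds = kfold_split(G.n_samples, 10, seed=4)
        res = exhaustive_search(G, s, [2], folds, cfg)[0]
        tr, te = evaluate_subset(res.final_subset, folds, G, s, cfg)
        assert res.fold_train_accuracy == pytest.approx(tr, abs=1e-12)
        assert res.fold_test_accuracy == pytest.approx(te, abs=1e-12)


def test_constant_scores_degenerate_case():
    # every cell mean equals T=0 boundary -> all cells high; with plain
    # accuracy every individual is "high" and classified high: accuracy 1
    rng = np.random.default_rng(2)
    G = _geno(rng.integers(0, 3, size=(100, 3)))
    s = np.zeros(100)
    cfg = RunConfig(accuracy_metric="plain", stratify_folds=False, cv_folds=5)
    folds = kfold_split(100, 5, seed=0)
    tr, te = evaluate_subset((0, 1), folds, G, s, cfg)
    assert tr == pytest.approx(np.ones(5))
    assert te == pytest.approx(np.ones(5))


def test_search_invariant_to_locus_order(strong_digenic, config):
    G, Y, _ = strong_digenic
    _, _, s = null_scores(Y, config=config)
    perm = np.array([3, 0, 5, 1, 4, 2])
    Gp = _geno(G.values[:, perm])
    folds = kfold_split(G.n_samples, 10, seed=9)
    res = exhaustive_search(G, s, [2], folds, config)[0]
    res_p = exhaustive_search(Gp, s, [2], folds, config)[0]
    mapped = tuple(sorted(int(np.flatnonzero(perm == i)[0]) for i in res.final_subset))
    assert res_p.final_subset == mapped
    assert res_p.mean_test_accuracy == pytest.approx(res.mean_test_accuracy, abs=1e-12)


def test_cross_validation_consistency_counts():
    assert cross_validation_consistency([(0, 1)] * 10) == 10
    winners = [(0, 1)] * 6 + [(2, 3)] * 4
    assert cross_validation_consistency(winners) == 6
    assert cross_validation_consistency([(i,) for i in range(10)]) == 1


def test_missing_genotypes_excluded_per_subset():
    values = np.array([[0, 1], [1, -1], [2, 2], [0, 0], [1, 1], [2, 0]] * 5)
    G = _geno(values)
    rng = np.random.default_rng(0)
    s = rng.normal(size=30)
    cfg = RunConfig(cv_folds=3, stratify_folds=False)
    folds = kfold_split(30, 3, seed=1)
    res = exhaustive_search(G, s, [2], folds, cfg)[0]
    assert np.isfinite(res.mean_test_accuracy)


def test_select_best_size_prefers_cvc_then_ta(strong_digenic, config):
    G, Y, _ = strong_digenic
    _, _, s = null_scores(Y, config=config)
    results = run_search(G, s, [1, 2, 3], config, seed=5)
    best = select_best_size(results)
    ranked = sorted(results, key=lambda r: (r.cvc, r.mean_test_accuracy), reverse=True)
    assert best is ranked[0]


def test_search_validates_arguments(null_dataset, config):
    G, Y, _ = null_dataset
    _, _, s = null_scores(Y, config=config)
    with pytest.raises(GmdrError):
        run_search(G, s, [], config)
    with pytest.raises(GmdrError):
        run_search(G, s, [11], config)
    with pytest.raises(GmdrError):
        run_search(G, s[:-1], [2], config)
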