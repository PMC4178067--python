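"""Significance assessment for a selected model's testing accuracy.

Under the null of no genotype-phenotype association the testing accuracy of
a cross-validated model fluctuates around 0.5, so three complementary tests
are offered: an exact one-sided sign test on the per-fold testing accuracies,
an empirical p-value against a permutation null built by shuffling the score
vector against the genotype rows (which preserves the genotype structure
while destroying the association), and a normal (Z) approximation to that
permutation null.  A Bonferroni helper adjusts for the number of candidate
models examined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import GenotypeMatrix, RunConfig, child_seed
from .errors import DegenerateNullError, GmdrError
from .search import run_search


@dataclass
class NullDistribution:
    """Sorted testing accuracies from B permutation replicates."""

    values: np.ndarray
    B: int
    mean: float
    sd: float

    @classmethod
    def from_values(cls, values) -> "NullDistribution":
        values = np.sort(np.asarray(values, dtype=float))
        if values.size < 1:
            raise GmdrError("a null distribution needs at least one replicate")
        sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
        return cls(values=values, B=int(values.size), mean=float(values.mean()), sd=sd)

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.values, q))


def sign_test(fold_TAs) -> float:
    """One-sided exact binomial test that per-fold TAs exceed 0.5.

    Folds with TA exactly 0.5 are dropped from the trial count; if every fold
    ties at 0.5 the test is uninformative and p = 1 with a warning.
    """
    tas = np.asarray(fold_TAs, dtype=float)
    tas = tas[np.isfinite(tas)]
    trials = int(np.sum(tas != 0.5))
    wins = int(np.sum(tas > 0.5))
    if trials == 0:
        warnings.warn("all folds tied at TA = 0.5; sign test is uninformative")
        return 1.0
    return float(stats.binom.sf(wins - 1, trials, 0.5))


def model_ta(result, statistic: str = "winner") -> float:
    """The testing-accuracy statistic of one size's search outcome.

    ``winner`` (default) is the mean held-out accuracy of the per-fold
    winning subsets; ``final`` is the mean held-out accuracy of the final
    (modal) subset across folds.
    """
    if statistic == "winner":
        return result.winner_mean_test_accuracy
    if statistic == "final":
        return result.mean_test_accuracy
    raise GmdrError(f"unknown TA statistic {statistic!r}")


def permutation_null(G: GenotypeMatrix, scores, size: int, k: int, B: int, seed: int,
                     config: RunConfig | None = None,
                     statistic: str = "winner") -> NullDistribution:
    """Permutation null of the selected-model TA at one model size.

    Each of the B replicates permutes the aggregated score vector against the
    genotype rows (the null-model fit stays fixed), re-runs the k-fold
    cross-validated exhaustive search at ``size``, and records the selected
    model's testing accuracy (see :func:`model_ta` for the statistic choice).
    """
    if B < 1:
        raise GmdrError("need at least one permutation replicate")
    config = (config or RunConfig())
    if config.cv_folds != k:
        config = RunConfig(**{**config.__dict__, "cv_folds": int(k)})
    scores = np.asarray(scores, dtype=float)
    tas = np.empty(B)
    for b in range(B):
        rng = np.random.default_rng(child_seed(seed, 7001, b))
        perm = rng.permutation(scores)
        res = run_search(G, perm, [size], config, seed=child_seed(seed, 7002, b))
        tas[b] = model_ta(res[0], statistic)
    return NullDistribution.from_values(tas)


def empirical_pvalue(TA_obs: float, null: NullDistribution) -> float:
    """Add-one permutation p-value: (r + 1) / (B + 1) with r = #{null >= TA}."""
    r = int(np.sum(null.values >= TA_obs))
    return (r + 1) / (null.B + 1)


def z_pvalue(TA_obs: float, null: NullDistribution) -> float:
    """Upper-tail normal approximation to the permutation p-value."""
    if null.sd == 0.0:
        raise DegenerateNullError("null distribution has zero spread")
    if null.B < 30:
        warnings.warn(f"normal approximation with only B={null.B} replicates is crude")
    return float(stats.norm.sf((TA_obs - null.mean) / null.sd))


def bonferroni(p: float, M: int) -> float:
    """Bonferroni adjustment over M examined models: min(1, p * M)."""
    if M < 1:
        raise GmdrError("number of tests must be >= 1")
    return min(1.0, float(p) * int(M))
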