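"""Monte Carlo orchestration: Type I error, per-size CVC/TA tables, power.

All experiments share one pattern: simulate a scenario replicate, fit the
null model, aggregate score residuals, run the cross-validated exhaustive
search, and record the final model and its testing accuracy.  Significance
cutoffs come from a single permutation-based null TA distribution per
scenario: a rejection at level alpha means the replicate's final-model TA
has an add-one empirical p-value <= alpha against that distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import PhenotypeSet, RunConfig, child_seed
from .errors import GmdrError
from .null_models import null_scores
from .search import run_search
from .significance import NullDistribution, empirical_pvalue, model_ta, permutation_null
from .simulate import SimulationConfig, simulate_dataset

log = logging.getLogger(__name__)


@dataclass
class ExperimentSpec:
    """A simulation scenario plus the Monte Carlo scales to run it at."""

    sim: SimulationConfig
    replicates: int = 200
    permutations: int = 1000
    alphas: tuple[float, ...] = (0.05, 0.01)
    sizes: tuple[int, ...] = (2,)
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise GmdrError("need at least one replicate")
        if self.permutations < 1:
            raise GmdrError("need at least one permutation")
        self.sizes = tuple(int(m) for m in self.sizes)
        self.alphas = tuple(float(a) for a in self.alphas)


def compute_scores(Y: PhenotypeSet, config: RunConfig, analysis: str = "multivariate"):
    """Aggregated null-model score vector for one analysis arm.

    ``analysis`` is ``multivariate`` (joint GEE score over all traits) or
    ``trait_<j>`` (univariate fit of trait j alone, 1-based).
    """
    if analysis == "multivariate":
        sub = Y
    elif analysis.startswith("trait_"):
        j = int(analysis.split("_", 1)[1]) - 1
        if not 0 <= j < Y.n_traits:
            raise GmdrError(f"no trait {j + 1} in a {Y.n_traits}-trait phenotype set")
        sub = PhenotypeSet(Y.values[:, [j]], [Y.trait_ids[j]], [Y.trait_kinds[j]])
    else:
        raise GmdrError(f"unknown analysis arm {analysis!r}")
    return null_scores(sub, None, config)[2]


@dataclass
class ReplicateStudy:
    """Raw per-replicate records plus the across-replicate summary."""

    details: pd.DataFrame
    summary: pd.DataFrame
    failures: list[tuple[int, str]] = field(default_factory=list)


def run_replicates(spec: ExperimentSpec, config: RunConfig | None = None,
                   analyses: tuple[str, ...] | None = None) -> ReplicateStudy:
    """Simulate R replicates and summarize CVC / TA per analysis arm and size.

    The summary reports the across-replicate mean, SD and SEM (SD / sqrt(R))
    of CVC and TA, and the fraction of replicates whose final model at each
    size is exactly the causal subset.  Replicate failures are recorded and
    skipped, never fatal.
    """
    config = config or RunConfig()
    if analyses is None:
        analyses = ("multivariate",) + tuple(
            f"trait_{j + 1}" for j in range(spec.sim.n_traits)
        ) if spec.sim.n_traits > 1 else ("multivariate",)
    rows, failures = [], []
    causal = None
    for r in range(spec.replicates):
        try:
            G, Y, truth = simulate_dataset(spec.sim, child_seed(spec.seed, 1, r))
            causal = tuple(truth["causal_loci"])
            for arm in analyses:
                s = compute_scores(Y, config, arm)
                for res in run_search(G, s, spec.sizes, config,
                                      seed=child_seed(spec.seed, 2, r)):
                    rows.append({
                        "replicate": r,
                        "analysis": arm,
                        "size": res.size,
                        "cvc": res.cvc,
                        "ta": res.mean_test_accuracy,
                        "train": res.mean_train_accuracy,
                        "winner_ta": res.winner_mean_test_accuracy,
                        "true_model": res.final_subset == causal,
                    })
        except GmdrError as exc:
            failures.append((r, str(exc)))
            log.warning("replicate %d failed: %s", r, exc)
    details = pd.DataFrame(rows)
    if details.empty:
        raise GmdrError("every replicate failed")
    grp = details.groupby(["analysis", "size"])
    summary = grp.agg(
        replicates=("replicate", "count"),
        cvc_mean=("cvc", "mean"),
        cvc_sd=("cvc", "std"),
        ta_mean=("ta", "mean"),
        ta_sd=("ta", "std"),
        winner_ta_mean=("winner_ta", "mean"),
        true_model_rate=("true_model", "mean"),
    ).reset_index()
    summary["cvc_sem"] = summary["cvc_sd"] / np.sqrt(summary["replicates"])
    summary["ta_sem"] = summary["ta_sd"] / np.sqrt(summary["replicates"])
    summary.attrs["incomplete"] = bool(failures)
    return ReplicateStudy(details=details, summary=summary, failures=failures)


@dataclass
class ScenarioNull:
    """Per-scenario permutation null and the replicate-level search outcomes."""

    null: NullDistribution
    tas: np.ndarray
    true_model: np.ndarray
    size: int


def _single_size(spec: ExperimentSpec) -> int:
    if len(spec.sizes) != 1:
        raise GmdrError("Type I / power experiments run one model size at a time")
    return spec.sizes[0]


def scenario_null_study(spec: ExperimentSpec, config: RunConfig | None = None,
                        analysis: str = "multivariate",
                        pool_datasets: int = 1) -> ScenarioNull:
    """Build the scenario's permutation null and run its R search replicates.

    The null TA distribution comes from one simulated dataset of the scenario
    whose score vector is permuted B times (``pool_datasets`` > 1 pools the
    permutation TAs of several independent datasets for a smoother null);
    the replicates then record each selected model's TA (per-fold-winner
    mean, the reported statistic) and whether the final model equals the
    causal subset.
    """
    config = config or RunConfig()
    m = _single_size(spec)
    if pool_datasets < 1:
        raise GmdrError("need at least one null dataset")
    values = []
    for d in range(pool_datasets):
        key3 = (3,) if d == 0 else (3, d)
        key4 = (4,) if d == 0 else (4, d)
        G0, Y0, _ = simulate_dataset(spec.sim, child_seed(spec.seed, *key3))
        s0 = compute_scores(Y0, config, analysis)
        nd = permutation_null(G0, s0, m, config.cv_folds, spec.permutations,
                              child_seed(spec.seed, *key4), config)
        values.append(nd.values)
    null = NullDistribution.from_values(np.concatenate(values))
    tas = np.empty(spec.replicates)
    hit = np.zeros(spec.replicates, dtype=bool)
    for r in range(spec.replicates):
        G, Y, truth = simulate_dataset(spec.sim, child_seed(spec.seed, 1, r))
        s = compute_scores(Y, config, analysis)
        res = run_search(G, s, [m], config, seed=child_seed(spec.seed, 2, r))[0]
        tas[r] = model_ta(res, "winner")
        hit[r] = res.final_subset == tuple(truth["causal_loci"])
    return ScenarioNull(null=null, tas=tas, true_model=hit, size=m)


def rejection_rate(study: ScenarioNull, alpha: float) -> float:
    """Fraction of replicates whose TA clears the permutation cutoff at alpha."""
    ps = np.array([empirical_pvalue(ta, study.null) for ta in study.tas])
    return float(np.mean(ps <= alpha))


def type_i_error(spec: ExperimentSpec, alpha: float, config: RunConfig | None = None,
                 study: ScenarioNull | None = None) -> float:
    """Empirical Type I error of the search at one size under a null scenario."""
    if any(h > 0 for h in spec.sim.h2):
        raise GmdrError("a Type I error scenario requires h2 = 0 for every trait")
    if study is None:
        study = scenario_null_study(spec, config)
    return rejection_rate(study, alpha)


@dataclass
class PowerResult:
    """Power at one level: strict requires the causal subset to be selected."""

    strict: float
    lenient: float
    alpha: float


def power(spec: ExperimentSpec, alpha: float, config: RunConfig | None = None,
          analysis: str = "multivariate", study: ScenarioNull | None = None) -> PowerResult:
    """Proportion of replicates with a significant (true) model at level alpha.

    Strict mode counts a success only when the final model at the true size
    is exactly the causal subset and its TA clears the cutoff; lenient mode
    drops the subset-identity requirement.
    """
    if all(h == 0 for h in spec.sim.h2):
        raise GmdrError("a power scenario requires h2 > 0")
    if study is None:
        study = scenario_null_study(spec, config, analysis)
    ps = np.array([empirical_pvalue(ta, study.null) for ta in study.tas])
    sig = ps <= alpha
    return PowerResult(strict=float(np.mean(sig & study.true_model)),
                       lenient=float(np.mean(sig)), alpha=float(alpha))


def qq_typeI(study: ScenarioNull, levels) -> pd.DataFrame:
    """Paired (alpha, rejection rate) table for a Q-Q check against the diagonal."""
    levels = sorted(float(a) for a in np.atleast_1d(levels))
    rates = [rejection_rate(study, a) for a in levels]
    return pd.DataFrame({"alpha": levels, "rate": rates})
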