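"""Core in-memory containers shared by every mvgmdr module.

Genotypes are held additively coded (0/1/2 copies of the coded allele) with a
``MISSING`` sentinel of -1; phenotypes are an n x J numeric matrix of one or
more continuous or 0/1 binary traits whose rows are aligned to the genotype
sample order; covariates are a plain numeric design block.  ``RunConfig``
gathers the knobs that govern an analysis run (null-model family, working
correlation, cell threshold, cross-validation folds, aggregation, seed) and is
the single source from which all child seeds flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml

from .errors import FormatError

#: Sentinel for a missing genotype call.
MISSING = -1

_FAMILIES = ("gaussian", "binomial", "quasi")
_LINKS = ("identity", "logit", "log")
_VARIANCES = ("constant", "binomial", "mu")
_CORSTRS = ("independence", "exchangeable", "unstructured")
_METRICS = ("weighted", "plain", "balanced", "score_difference")
_AGGREGATIONS = ("sum", "mean")
_UNSEEN = ("low", "exclude")


def _check_unique(ids, what):
    if len(set(ids)) != len(ids):
        raise FormatError(f"duplicate {what} identifiers")


@dataclass
class GenotypeMatrix:
    """n x L additive genotype codes: the attribute space for cell building.

    ``values[i, l]`` counts copies of the coded allele at locus ``l`` for
    sample ``i`` (0, 1 or 2), or :data:`MISSING` for a failed call.
    """

    values: np.ndarray
    locus_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2 or self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise FormatError("genotype matrix must be 2-D with n >= 1 and L >= 1")
        self.locus_ids = [str(x) for x in self.locus_ids]
        self.sample_ids = [str(x) for x in self.sample_ids]
        if len(self.locus_ids) != self.values.shape[1]:
            raise FormatError("locus_ids length does not match number of columns")
        if len(self.sample_ids) != self.values.shape[0]:
            raise FormatError("sample_ids length does not match number of rows")
        _check_unique(self.locus_ids, "locus")
        _check_unique(self.sample_ids, "sample")
        bad = ~np.isin(self.values, (0, 1, 2, MISSING))
        if bad.any():
            i, l = np.argwhere(bad)[0]
            raise FormatError(
                f"genotype code {self.values[i, l]} at sample "
                f"{self.sample_ids[i]!r}, locus {self.locus_ids[l]!r} is not 0/1/2/missing"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]


@dataclass
class PhenotypeSet:
    """n x J trait matrix (continuous or 0/1 binary), row-aligned to genotypes."""

    values: np.ndarray
    trait_ids: list[str]
    trait_kinds: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise FormatError("phenotype matrix must be 2-D with J >= 1")
        self.trait_ids = [str(x) for x in self.trait_ids]
        if len(self.trait_ids) != self.values.shape[1]:
            raise FormatError("trait_ids length does not match number of traits")
        _check_unique(self.trait_ids, "trait")
        if self.trait_kinds is None:
            self.trait_kinds = [
                "binary" if np.isin(col[np.isfinite(col)], (0.0, 1.0)).all() else "continuous"
                for col in self.values.T
            ]
        if len(self.trait_kinds) != self.values.shape[1]:
            raise FormatError("trait_kinds length does not match number of traits")
        for kind, col, tid in zip(self.trait_kinds, self.values.T, self.trait_ids):
            if kind not in ("continuous", "binary"):
                raise FormatError(f"unknown trait kind {kind!r}")
            if kind == "binary" and not np.isin(col, (0.0, 1.0)).all():
                raise FormatError(f"binary trait {tid!r} has values outside {{0,1}}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]


@dataclass
class CovariateMatrix:
    """n x c numeric covariate block (c may be zero)."""

    values: np.ndarray
    covariate_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        self.covariate_ids = [str(x) for x in self.covariate_ids]
        if len(self.covariate_ids) != self.values.shape[1]:
            raise FormatError("covariate_ids length does not match number of columns")
        _check_unique(self.covariate_ids, "covariate")
        if not np.isfinite(self.values).all():
            raise FormatError("covariate matrix contains missing/non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.values.shape[1]

    @classmethod
    def empty(cls, n: int) -> "CovariateMatrix":
        return cls(np.empty((n, 0)), [])


@dataclass
class RunConfig:
    """Analysis configuration; every stochastic step derives from ``seed``.

    Parameters
    ----------
    family:
        Null-model response family: ``gaussian`` (identity link),
        ``binomial`` (logit link) or ``quasi`` (link + variance function only).
    link, variance_function:
        Only consulted for ``family='quasi'``; defaulted from the family
        otherwise.
    working_correlation:
        GEE working correlation. ``None`` resolves to ``exchangeable`` for
        multivariate phenotypes and ``independence`` for a single trait, in
        which case the fit coincides with the ordinary GLM.
    threshold:
        Cell-labelling threshold T: a cell is high-valued when its mean score
        is >= T (default 0).
    cv_folds:
        Number of cross-validation folds k (default 10).
    accuracy_metric:
        ``weighted`` (default) score-magnitude-weighted classification
        accuracy — each individual contributes its |score - T| mass, which
        reduces to the plain proportion for unit-magnitude (case/control)
        scores; ``plain`` count-based accuracy; ``balanced`` accuracy; or the
        quantitative ``score_difference`` between pooled groups.
    aggregation:
        Per-individual aggregation of trait-wise score residuals: ``sum``
        (default) or ``mean``.
    unseen_cell_policy:
        Grouping of test individuals whose cell was empty during training:
        ``low`` (default, conservative) or ``exclude``.
    stratify_folds:
        Stratify the k-fold split on the sign of the score, balancing
        high/low-valued individuals across folds.
    """

    family: str = "gaussian"
    link: str | None = None
    variance_function: str | None = None
    working_correlation: str | None = None
    threshold: float = 0.0
    cv_folds: int = 10
    accuracy_metric: str = "weighted"
    aggregation: str = "sum"
    unseen_cell_policy: str = "low"
    stratify_folds: bool = True
    max_iter: int = 100
    tol: float = 1e-8
    seed: int = 0

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise FormatError(f"family must be one of {_FAMILIES}, got {self.family!r}")
        if self.link is not None and self.link not in _LINKS:
            raise FormatError(f"link must be one of {_LINKS}, got {self.link!r}")
        if self.variance_function is not None and self.variance_function not in _VARIANCES:
            raise FormatError(
                f"variance_function must be one of {_VARIANCES}, got {self.variance_function!r}"
            )
        if self.working_correlation is not None and self.working_correlation not in _CORSTRS:
            raise FormatError(
                f"working_correlation must be one of {_CORSTRS}, got {self.working_correlation!r}"
            )
        if self.accuracy_metric not in _METRICS:
            raise FormatError(f"accuracy_metric must be one of {_METRICS}")
        if self.aggregation not in _AGGREGATIONS:
            raise FormatError(f"aggregation must be one of {_AGGREGATIONS}")
        if self.unseen_cell_policy not in _UNSEEN:
            raise FormatError(f"unseen_cell_policy must be one of {_UNSEEN}")
        if not np.isfinite(self.threshold):
            raise FormatError("threshold must be finite")
        if self.cv_folds < 2:
            raise FormatError("cv_folds must be >= 2")

    def resolve_link(self) -> str:
        if self.link is not None:
            return self.link
        return {"gaussian": "identity", "binomial": "logit", "quasi": "identity"}[self.family]

    def resolve_variance(self) -> str:
        if self.variance_function is not None:
            return self.variance_function
        return {"gaussian": "constant", "binomial": "binomial", "quasi": "constant"}[self.family]

    def resolve_corstr(self, n_traits: int) -> str:
        if self.working_correlation is not None:
            return self.working_correlation
        return "exchangeable" if n_traits > 1 else "independence"

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=int(seed))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise FormatError(f"config file {path} must hold a mapping")
        return cls(**data)


def child_rng(seed: int, *key: int) -> np.random.Generator:
    """Named, replayable child generator: same ``(seed, key)`` -> same stream."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def child_seed(seed: int, *key: int) -> int:
    """A 31-bit integer seed derived deterministically from ``(seed, key)``."""
    return int(np.random.SeedSequence([int(seed), *map(int, key)]).generate_state(1)[0] % (2**31))
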