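"""Synthetic genotypes and correlated traits under epistatic penetrance models.

Loci are unlinked biallelic markers under Hardy-Weinberg and linkage
equilibrium: the additive code at each locus is Binomial(2, p) in the coded
allele frequency p.  The interaction models partition the multilocus
genotypes at the m causal loci into a high-valued and a low-valued class by
the total coded-allele count: the digenic *antidiagonal* model takes AAbb,
AaBb and aaBB (count = 2 over 2 loci) as high-valued, and the k-uppercase
models take exactly k coded alleles over k loci.  Under HWE/LE the count is
Binomial(2m, p), so the high-class frequency f has the closed form
``P(count = m)``; the single-locus marginal effects of these models are near
zero, which is what makes them a pure-interaction benchmark.

The shared (pleiotropic) genetic value is a mean-zero two-point effect with
variance equal to the target genetic variance: ``a_high = sigma_g *
sqrt((1-f)/f)`` in the high class and ``a_low = -sigma_g * sqrt(f/(1-f))``
otherwise.  Each trait is the sum of its population mean, this common
genetic value and a Gaussian residual; residual vectors are multivariate
normal with per-trait variance ``1 - h2`` and correlation rho, so the total
variance per trait is normalized to 1 and h2 is exactly the fraction of
variance the interaction explains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datamodel import GenotypeMatrix, PhenotypeSet, child_rng
from .errors import DegenerateModelError, GmdrError


@dataclass(frozen=True)
class EpistasisModel:
    """A high/low penetrance class on the total coded-allele count.

    ``name`` is ``antidiagonal`` (m = 2) or ``k_uppercase``; in both cases a
    multilocus genotype is high-valued iff its total coded-allele count over
    the m causal loci equals m.
    """

    name: str
    m: int

    def __post_init__(self):
        if self.name not in ("antidiagonal", "k_uppercase"):
            raise GmdrError(f"unknown epistasis model {self.name!r}")
        if self.name == "antidiagonal" and self.m != 2:
            raise GmdrError("the antidiagonal model is digenic (m = 2)")
        if self.m < 1:
            raise GmdrError("need at least one causal locus")

    @classmethod
    def antidiagonal(cls) -> "EpistasisModel":
        return cls("antidiagonal", 2)

    @classmethod
    def k_uppercase(cls, m: int) -> "EpistasisModel":
        return cls("k_uppercase", m)

    @classmethod
    def by_order(cls, m: int) -> "EpistasisModel":
        """Digenic -> antidiagonal; higher orders -> k-uppercase."""
        return cls.antidiagonal() if m == 2 else cls.k_uppercase(m)

    def is_high(self, codes: np.ndarray) -> np.ndarray:
        """High-valued indicator for an (n, m) block of causal-locus codes."""
        codes = np.atleast_2d(codes)
        if codes.shape[1] != self.m:
            raise GmdrError(f"expected {self.m} causal-locus columns, got {codes.shape[1]}")
        if (codes < 0).any():
            raise GmdrError("causal-locus codes must be complete (no missing)")
        return codes.sum(axis=1) == self.m


@dataclass
class SimulationConfig:
    """Full specification of one synthetic scenario.

    Defaults are the benchmark conditions: n = 1000 individuals, 10 unlinked
    loci with coded-allele frequency 0.3, a digenic antidiagonal interaction
    explaining h2 = 5% of each of two unit-variance traits, residual
    correlation 0.  The causal loci are the first m columns; the remaining
    loci carry no effect and act purely as search noise.
    """

    n: int = 1000
    L: int = 10
    maf: float = 0.3
    model: EpistasisModel = field(default_factory=EpistasisModel.antidiagonal)
    h2: tuple[float, ...] = (0.05, 0.05)
    rho: float = 0.0
    means: tuple[float, ...] | None = None
    causal_loci: tuple[int, ...] | None = None

    def __post_init__(self):
        if not 0.0 < self.maf < 1.0:
            raise GmdrError("coded-allele frequency must lie in (0, 1)")
        self.h2 = tuple(float(h) for h in np.atleast_1d(self.h2))
        if any(not 0.0 <= h < 1.0 for h in self.h2):
            raise GmdrError("heritability must lie in [0, 1)")
        if not -1.0 < self.rho < 1.0:
            raise GmdrError("residual correlation must lie in (-1, 1)")
        if self.model.m > self.L:
            raise GmdrError("more causal loci than loci")
        if self.causal_loci is None:
            self.causal_loci = tuple(range(self.model.m))
        self.causal_loci = tuple(int(i) for i in self.causal_loci)
        if len(self.causal_loci) != self.model.m:
            raise GmdrError("causal_loci length must equal the model order")
        if any(i < 0 or i >= self.L for i in self.causal_loci):
            raise GmdrError("causal locus index out of range")
        if self.means is None:
            self.means = tuple(0.0 for _ in self.h2)
        self.means = tuple(float(x) for x in self.means)
        if len(self.means) != len(self.h2):
            raise GmdrError("means and h2 must have one entry per trait")

    @property
    def n_traits(self) -> int:
        return len(self.h2)


def simulate_genotypes(n: int, L: int, p: float, seed: int) -> GenotypeMatrix:
    """Unlinked HWE loci: additive codes drawn Binomial(2, p) per locus."""
    if not 0.0 < p < 1.0:
        raise GmdrError("coded-allele frequency must lie in (0, 1)")
    rng = child_rng(seed, 11)
    values = rng.binomial(2, p, size=(n, L)).astype(np.int8)
    return GenotypeMatrix(
        values,
        locus_ids=[f"L{j}" for j in range(L)],
        sample_ids=[f"S{i}" for i in range(n)],
    )


def high_group_frequency(model: EpistasisModel, p: float) -> float:
    """Closed-form frequency of the high-valued multilocus class.

    Under HWE/LE the total coded-allele count over the m causal loci is
    Binomial(2m, p); the high class collects count = m exactly.
    """
    return float(stats.binom.pmf(model.m, 2 * model.m, p))


def genetic_values(model: EpistasisModel, p: float, var_g: float):
    """Two-point genetic effect with mean zero and variance ``var_g``.

    Returns ``(a_high, a_low, f)`` satisfying ``f*a_high + (1-f)*a_low = 0``
    and ``f*a_high^2 + (1-f)*a_low^2 = var_g`` identically.
    """
    f = high_group_frequency(model, p)
    if not 0.0 < f < 1.0:
        raise DegenerateModelError(f"high-group frequency {f} admits no two-point effect")
    sigma_g = float(np.sqrt(var_g))
    a_high = sigma_g * np.sqrt((1.0 - f) / f)
    a_low = -sigma_g * np.sqrt(f / (1.0 - f))
    return float(a_high), float(a_low), f


def simulate_traits(G: GenotypeMatrix, config: SimulationConfig, seed: int) -> PhenotypeSet:
    """Traits = mean + shared two-point genetic value + correlated residual.

    All traits receive the identical genetic value (equal pleiotropic
    control); residuals are multivariate normal with variances ``1 - h2_j``
    and common correlation rho, so each trait has total variance ~1.
    """
    J = config.n_traits
    codes = G.values[:, list(config.causal_loci)]
    high = config.model.is_high(codes)
    g = np.zeros((G.n_samples, J))
    for j, h2 in enumerate(config.h2):
        if h2 > 0:
            a_high, a_low, _ = genetic_values(config.model, config.maf, h2)
            g[:, j] = np.where(high, a_high, a_low)
    sd = np.sqrt([1.0 - h for h in config.h2])
    cov = np.outer(sd, sd) * config.rho
    np.fill_diagonal(cov, sd**2)
    rng = child_rng(seed, 13)
    e = rng.multivariate_normal(np.zeros(J), cov, size=G.n_samples, method="cholesky")
    values = np.asarray(config.means) + g + e
    return PhenotypeSet(values, trait_ids=[f"T{j + 1}" for j in range(J)],
                        trait_kinds=["continuous"] * J)


def simulate_dataset(config: SimulationConfig, seed: int):
    """One full scenario draw: ``(G, Y, truth)``.

    ``truth`` records the causal loci, the high-class frequency f and the
    two-point effects per trait, for downstream power accounting.
    """
    G = simulate_genotypes(config.n, config.L, config.maf, seed)
    Y = simulate_traits(G, config, seed)
    effects = {}
    for j, h2 in enumerate(config.h2):
        if h2 > 0:
            a_high, a_low, f = genetic_values(config.model, config.maf, h2)
            effects[f"T{j + 1}"] = {"a_high": a_high, "a_low": a_low}
    truth = {
        "model": config.model.name,
        "causal_loci": list(config.causal_loci),
        "causal_locus_ids": [G.locus_ids[i] for i in config.causal_loci],
        "f": high_group_frequency(config.model, config.maf),
        "h2": list(config.h2),
        "rho": config.rho,
        "effects": effects,
    }
    return G, Y, truth
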