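"""Population statistics for imputed nsSNP profiles.

Carrier counting of gene-level allele combinations in a genotype panel,
the Jeffreys-prior probability estimate (x + 1/2)/(n + 1), product-rule
profile probabilities accumulated in log space, parametric-bootstrap 90%
confidence intervals, and cross-population likelihood ratios.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .imputation import SubjectProfile
from .io_formats import PopulationPanel

logger = logging.getLogger(__name__)

__all__ = [
    "GeneProbability",
    "ProfileProbabilityResult",
    "count_combination",
    "jeffreys_probability",
    "profile_probability",
    "bootstrap_ci",
    "likelihood_ratio",
    "profile_result",
]


@dataclass(frozen=True)
class GeneProbability:
    """Jeffreys estimate for one gene's detected allele combination."""

    gene: str
    combination: tuple[tuple[str, str], ...]
    x: int
    n: int

    def __post_init__(self) -> None:
        if not 0 <= self.x <= self.n or self.n < 1:
            raise ValueError(f"invalid counts x={self.x}, n={self.n}")

    @property
    def p_hat(self) -> float:
        return jeffreys_probability(self.x, self.n)


@dataclass(frozen=True)
class ProfileProbabilityResult:
    subject_id: str
    population_id: str
    gene_probabilities: tuple[GeneProbability, ...]
    overall: float
    log10_overall: float
    ci90: tuple[float, float]
    bootstrap_reps: int
    seed: int


def count_combination(
    panel: PopulationPanel,
    gene: str,
    combination: set[tuple[str, str]] | Sequence[tuple[str, str]],
) -> tuple[int, int]:
    """Carrier count of an allele combination within one gene.

    x = individuals whose diploid genotypes contain every allele of the
    combination (heterozygous or homozygous both qualify); n =
    individuals with complete (non-missing) calls at all the
    combination's loci. Loci absent from the panel are dropped with a
    warning; an empty combination is an error.
    """
    combo = sorted(set(combination))
    if not combo:
        raise ValueError(f"empty allele combination for gene {gene}")
    present = [(rs, nuc) for rs, nuc in combo if rs in panel.loci]
    for rs, _ in set(combo) - set(present):
        logger.warning(
            "%s: locus %s not in panel %s; dropped from combination",
            gene, rs, panel.population_id,
        )
    if not present:
        raise ValueError(
            f"no combination loci for gene {gene} present in panel "
            f"{panel.population_id}"
        )
    loci = {rs for rs, _ in present}
    x = n = 0
    for individual in panel.individuals:
        calls = {rs: panel.genotype(individual, rs) for rs in loci}
        if any(c is None or c.missing for c in calls.values()):
            continue
        n += 1
        if all(calls[rs].carries(nuc) for rs, nuc in present):
            x += 1
    return x, n


def jeffreys_probability(x: int, n: int) -> float:
    """Posterior mean (x + 1/2)/(n + 1) of a binomial proportion under
    the Jeffreys Beta(1/2, 1/2) prior; strictly inside (0, 1)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError(f"x={x} outside [0, {n}]")
    return (x + 0.5) / (n + 1)


def profile_probability(gene_probabilities: Sequence[float]) -> float:
    """Product-rule profile probability, accumulated in log space.

    Independence between genes is assumed. An empty profile yields the
    vacuous product 1.0 (with a warning).
    """
    if len(gene_probabilities) == 0:
        logger.warning("empty profile: vacuous product probability 1.0")
        return 1.0
    return float(np.exp(np.sum(np.log(np.asarray(gene_probabilities, dtype=float)))))


def bootstrap_ci(
    gene_counts: Sequence[tuple[int, int]],
    B: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Parametric-bootstrap 90% CI for the product-rule probability.

    Per replicate, x* ~ Binomial(n, (x + 1/2)/(n + 1)) independently for
    each gene; the replicate statistic is the product of the re-estimated
    (x* + 1/2)/(n + 1); the CI is the empirical 5th and 95th percentile
    (linear interpolation) over B replicates. Deterministic given seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ns = np.array([n for _, n in gene_counts], dtype=float)
    ps = np.array([jeffreys_probability(x, n) for x, n in gene_counts])
    draws = rng.binomial(ns.astype(int), ps, size=(B, len(gene_counts)))
    log_products = np.sum(np.log((draws + 0.5) / (ns + 1.0)), axis=1)
    lo, hi = np.percentile(np.exp(log_products), [5.0, 95.0])
    return float(lo), float(hi)


def likelihood_ratio(
    result_pop1: ProfileProbabilityResult, result_pop2: ProfileProbabilityResult
) -> tuple[float, float]:
    """Ratio of one subject's profile probabilities under two population
    panels, computed in log space; returns (ratio, log10 ratio)."""
    if result_pop1.subject_id != result_pop2.subject_id:
        raise ValueError("likelihood ratio requires the same subject")
    genes1 = tuple(g.gene for g in result_pop1.gene_probabilities)
    genes2 = tuple(g.gene for g in result_pop2.gene_probabilities)
    if genes1 != genes2:
        raise ValueError(
            f"gene-set mismatch between populations: {genes1} vs {genes2}"
        )
    log10_lr = result_pop1.log10_overall - result_pop2.log10_overall
    return 10.0 ** log10_lr, log10_lr


def profile_result(
    profile: SubjectProfile,
    panel: PopulationPanel,
    B: int = 10_000,
    seed: int = 0,
) -> ProfileProbabilityResult:
    """End-to-end: count each gene's combination in the panel, apply the
    Jeffreys estimator and product rule, and bootstrap the 90% CI."""
    gene_probs = []
    for gene in sorted(profile.gene_profiles):
        combo = profile.gene_profiles[gene]
        x, n = count_combination(panel, gene, combo)
        gene_probs.append(
            GeneProbability(gene=gene, combination=tuple(sorted(combo)), x=x, n=n)
        )
    log10_overall = float(
        sum(math.log10(g.p_hat) for g in gene_probs)
    )
    overall = profile_probability([g.p_hat for g in gene_probs])
    counts = [(g.x, g.n) for g in gene_probs]
    ci = bootstrap_ci(counts, B=B, seed=seed) if counts else (1.0, 1.0)
    return ProfileProbabilityResult(
        subject_id=profile.subject_id,
        population_id=panel.population_id,
        gene_probabilities=tuple(gene_probs),
        overall=overall,
        log10_overall=log10_overall,
        ci90=ci,
        bootstrap_reps=B,
        seed=seed if isinstance(seed, int) else -1,
    )
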