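"""Bayesian hybrid-category classification (Gibbs sampling front end)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .._errors import ValidationError
from ..genotype_core.model import GenotypeMatrix
from .categories import GenotypeFrequencyClass, category_matrix, default_categories

logger = logging.getLogger(__name__)

PRIOR_KINDS = {"uniform": 1.0, "jeffreys": 0.5}

#: the four prior combinations (pi_prior, theta_prior) explored per analysis
PRIOR_COMBINATIONS: tuple[tuple[str, str], ...] = (
    ("uniform", "uniform"),
    ("uniform", "jeffreys"),
    ("jeffreys", "uniform"),
    ("jeffreys", "jeffreys"),
)


@dataclass
class ClassifierConfig:
    categories: list[GenotypeFrequencyClass] = field(default_factory=default_categories)
    pi_prior: str = "uniform"
    theta_prior: str = "uniform"
    burn_in: int = 100_000
    sweeps: int = 500_000
    known_assignments: Mapping[str, str] | None = None
    seed: int = 0
    chains: int = 1
    estimator: str = "visit"  # or "rao-blackwell"
    assignment_threshold: float = 0.5
    hybrid_sum_threshold: float = 0.7

    def __post_init__(self) -> None:
        if self.pi_prior not in PRIOR_KINDS or self.theta_prior not in PRIOR_KINDS:
            raise ValidationError(f"priors must be one of {sorted(PRIOR_KINDS)}")
        if self.burn_in <= 0 or self.sweeps <= 0:
            raise ValidationError("burn_in and sweeps must be positive")
        if not (0.0 < self.assignment_threshold < 1.0
                and 0.0 < self.hybrid_sum_threshold < 1.0):
            raise ValidationError("thresholds must lie in (0, 1)")
        if not self.categories:
            raise ValidationError("category list must not be empty")
        if self.estimator not in ("visit", "rao-blackwell"):
            raise ValidationError("estimator must be 'visit' or 'rao-blackwell'")

    @property
    def category_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.categories)


#: reduced run lengths used by the test suite / desk-scale evaluations
REDUCED_BURN_IN = 5_000
REDUCED_SWEEPS = 20_000


@dataclass
class CategoryPosterior:
    individual_id: str
    categories: tuple[str, ...]
    q: np.ndarray
    assigned_category: str | None = None
    hybrid_sum: float = 0.0
    hybrid_detected: bool = False

    def q_of(self, name: str) -> float:
        return float(self.q[self.categories.index(name)])


def genotype_likelihood(call: int, p: float, q: float,
                        g: tuple[float, float, float]) -> float:
    """P(call | wolf allele1 freq p, dog allele1 freq q, origin profile g).

    hom1: g_WW p^2 + g_WD p q + g_DD q^2; het and hom2 analogous; a missing
    call has likelihood 1.
    """
    if not (0.0 <= p <= 1.0 and 0.0 <= q <= 1.0):
        raise ValidationError("allele frequencies must be in [0, 1]")
    g_ww, g_wd, g_dd = g
    if call == 0:
        return g_ww * p * p + g_wd * p * q + g_dd * q * q
    if call == 1:
        return (g_ww * 2 * p * (1 - p) + g_wd * (p * (1 - q) + q * (1 - p))
                + g_dd * 2 * q * (1 - q))
    if call == 2:
        return g_ww * (1 - p) ** 2 + g_wd * (1 - p) * (1 - q) + g_dd * (1 - q) ** 2
    return 1.0


def decide(post: CategoryPosterior, config: ClassifierConfig) -> CategoryPosterior:
    """Apply the assignment (max q >= threshold) and hybrid-sum decisions."""
    parental = {"W", "D"}
    hybrid_idx = [k for k, name in enumerate(post.categories) if name not in parental]
    post.hybrid_sum = float(post.q[hybrid_idx].sum())
    best = int(np.argmax(post.q))
    post.assigned_category = (
        post.categories[best] if post.q[best] >= config.assignment_threshold else None
    )
    post.hybrid_detected = post.hybrid_sum > config.hybrid_sum_threshold
    return post


@dataclass
class ClassifierResult:
    posteriors: list[CategoryPosterior]
    config: ClassifierConfig
    theta_mean: np.ndarray  # (2, n_loci) posterior-mean allele1 frequencies
    per_chain_q: np.ndarray  # (chains, n, C)
    seeds: list[int]

    def as_frame(self):
        import pandas as pd

        names = self.config.category_names
        rows = []
        for p in self.posteriors:
            row = {"individual": p.individual_id}
            row.update({f"q_{n}": p.q[k] for k, n in enumerate(names)})
            row["assigned_category"] = p.assigned_category or "unassigned"
            row["hybrid_sum"] = p.hybrid_sum
            row["hybrid_detected"] = p.hybrid_detected
            rows.append(row)
        return pd.DataFrame(rows)


def classify(matrix: GenotypeMatrix, config: ClassifierConfig) -> ClassifierResult:
    """Run the Gibbs classifier on every individual of `matrix`.

    Individuals listed in ``config.known_assignments`` are clamped to their
    category (the z-option): they contribute to allele-frequency estimation
    but their own category is never resampled, and they are excluded from
    the mixing-proportion counts.
    """
    from ._kernel import run_classifier

    if matrix.n_individuals < 2:
        raise ValidationError("classification needs at least 2 individuals")
    names = config.category_names
    g = category_matrix(config.categories)
    clamped = np.full(matrix.n_individuals, -1, dtype=np.int64)
    if config.known_assignments:
        index = {n: k for k, n in enumerate(names)}
        by_id = {ind.id: i for i, ind in enumerate(matrix.individuals)}
        for ind_id, cat in config.known_assignments.items():
            if ind_id not in by_id:
                raise ValidationError(f"known assignment for unknown individual {ind_id!r}")
            if cat not in index:
                raise ValidationError(f"known assignment to unknown category {cat!r}")
            clamped[by_id[ind_id]] = index[cat]

    pooled = np.clip(np.nan_to_num(matrix.allele1_frequency(), nan=0.5), 0.02, 0.98)
    theta_init = np.vstack([pooled, pooled])

    ss = np.random.SeedSequence((config.seed, 0xC1A))
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config.chains)]
    per_chain = np.empty((config.chains, matrix.n_individuals, len(names)))
    theta_acc = np.zeros_like(theta_init)
    for c, chain_seed in enumerate(seeds):
        visit, rb, theta_mean = run_classifier(
            matrix.calls, g, clamped,
            PRIOR_KINDS[config.pi_prior], PRIOR_KINDS[config.theta_prior],
            config.burn_in, config.sweeps, chain_seed, theta_init,
        )
        per_chain[c] = visit if config.estimator == "visit" else rb
        theta_acc += theta_mean
    q = per_chain.mean(axis=0)

    posteriors = []
    for i, ind in enumerate(matrix.individuals):
        post = CategoryPosterior(individual_id=ind.id, categories=names, q=q[i])
        posteriors.append(decide(post, config))
    return ClassifierResult(posteriors=posteriors, config=config,
                            theta_mean=theta_acc / config.chains,
                            per_chain_q=per_chain, seeds=seeds)
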