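"""Admixture inference front end: multi-run protocol and label alignment."""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .._errors import ValidationError
from ..genotype_core.model import GenotypeMatrix

logger = logging.getLogger(__name__)

#: reduced run lengths used by the test suite / desk-scale evaluations
REDUCED_BURN_IN = 2_000
REDUCED_SWEEPS = 10_000


@dataclass
class AdmixtureConfig:
    K: int = 2
    frequency_model: str = "correlated"  # or "independent"
    alpha_init: float = 1.0
    burn_in: int = 50_000
    sweeps: int = 500_000
    runs: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValidationError(f"K must be >= 1, got {self.K}")
        if self.runs < 1:
            raise ValidationError(f"runs must be >= 1, got {self.runs}")
        if self.frequency_model not in ("correlated", "independent"):
            raise ValidationError("frequency_model must be 'correlated' or 'independent'")
        if self.burn_in <= 0 or self.sweeps <= 0:
            raise ValidationError("burn_in and sweeps must be positive")


@dataclass
class AdmixtureResult:
    q: np.ndarray  # individuals x K ancestry proportions
    lnP: float  # estimated log probability of the data
    K: int
    seed: int
    alpha: float = float("nan")
    aligned: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.lnP):
            raise ValidationError("lnP must be finite")


def run_admixture(matrix: GenotypeMatrix, config: AdmixtureConfig) -> list[AdmixtureResult]:
    """Run `config.runs` independent chains; seeds are derived from config.seed."""
    from ._kernel import run_admixture_chain

    if matrix.n_individuals < 1 or matrix.n_loci < 1:
        raise ValidationError("matrix must contain at least one individual and one locus")
    ss = np.random.SeedSequence((config.seed, config.K, 0xAD))
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config.runs)]
    results = []
    for run_seed in seeds:
        q, lnP, alpha = run_admixture_chain(
            matrix.calls, config.K, config.frequency_model == "correlated",
            config.alpha_init, config.burn_in, config.sweeps, run_seed,
        )
        results.append(AdmixtureResult(q=q, lnP=float(lnP), K=config.K,
                                       seed=run_seed, alpha=float(alpha)))
    return results


def _column_score(a: np.ndarray, b: np.ndarray) -> float:
    """Correlation of two q columns; falls back to a dot product when flat."""
    if a.std() == 0.0 or b.std() == 0.0:
        return float(a @ b)
    return float(np.corrcoef(a, b)[0, 1])


def align_and_average(results: list[AdmixtureResult]) -> AdmixtureResult:
    """Permute cluster labels per run to best match the first run, then average.

    The permutation maximising the summed column-wise q-correlation with the
    reference run is found by exact search (K! is small for K <= 6).
    """
    if not results:
        raise ValidationError("need at least one run")
    K = results[0].K
    if any(r.K != K for r in results):
        raise ValidationError("all runs must share the same K")
    ref = results[0].q
    acc = ref.copy()
    for r in results[1:]:
        best_perm, best_score = None, -np.inf
        for perm in itertools.permutations(range(K)):
            score = sum(_column_score(ref[:, k], r.q[:, perm[k]]) for k in range(K))
            if score > best_score:
                best_perm, best_score = perm, score
        acc += r.q[:, list(best_perm)]
    mean_q = acc / len(results)
    return AdmixtureResult(q=mean_q, lnP=float(np.mean([r.lnP for r in results])),
                           K=K, seed=results[0].seed, aligned=True)
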