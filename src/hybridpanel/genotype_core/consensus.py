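"""Replicate-consensus genotyping and success-rate based filtering.

Consensus rule: per locus, a call is accepted only if it is observed at
least twice across replicates and is the single most commonly observed
non-missing call; everything else (including ties between calls each seen
at least twice) is recorded as missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .._errors import EmptyPanelError, ValidationError
from .model import CALL_DTYPE, MISSING, GenotypeMatrix, ReplicateSet


def consensus_genotype(reps: ReplicateSet) -> np.ndarray:
    """Collapse a ReplicateSet into a single per-locus call vector."""
    stack = np.vstack(reps.replicates)  # (n_reps, n_loci)
    n_reps, n_loci = stack.shape
    out = np.full(n_loci, MISSING, dtype=CALL_DTYPE)
    if n_reps == 1:
        return out  # a single observation can never reach two
    for j in range(n_loci):
        col = stack[:, j]
        col = col[col != MISSING]
        if col.size == 0:
            continue
        values, counts = np.unique(col, return_counts=True)
        top = counts.max()
        if top >= 2 and (counts == top).sum() == 1:
            out[j] = values[np.argmax(counts)]
    return out


def genotyping_success_rate(calls: np.ndarray) -> float:
    """Fraction of scored (non-missing) loci in a call vector."""
    calls = np.asarray(calls)
    if calls.size == 0:
        raise ValidationError("empty call vector")
    return float((calls != MISSING).sum() / calls.size)


@dataclass
class RemovalReport:
    """Audit trail of filter_samples_and_loci."""

    removed_loci: dict[str, float] = field(default_factory=dict)
    removed_samples: dict[str, float] = field(default_factory=dict)
    kept_by_override: dict[str, float] = field(default_factory=dict)
    locus_min: float = 0.0
    sample_min: float = 0.0


def filter_samples_and_loci(
    matrix: GenotypeMatrix,
    sample_min: float = 0.8,
    locus_min: float = 0.7,
    keep_samples: Sequence[str] = (),
) -> tuple[GenotypeMatrix, RemovalReport]:
    """Drop low-success loci, then low-success samples.

    Loci with per-locus success rate < `locus_min` are removed first; sample
    success is then recomputed over the retained loci and samples below
    `sample_min` are removed, except ids listed in `keep_samples`, which are
    retained and flagged in the report.  Because removing samples can in turn
    depress locus rates, the locus->sample pass repeats until stable, which
    makes the operation idempotent.
    """
    for name, thr in (("sample_min", sample_min), ("locus_min", locus_min)):
        if not 0.0 <= thr <= 1.0:
            raise ValidationError(f"{name} must be in [0, 1], got {thr}")
    report = RemovalReport(locus_min=locus_min, sample_min=sample_min)
    keep_set = set(keep_samples)
    current = matrix
    while True:
        scored = current.calls != MISSING
        locus_rate = scored.mean(axis=0) if current.n_individuals else np.ones(current.n_loci)
        keep_loci = locus_rate >= locus_min
        for j in np.flatnonzero(~keep_loci):
            report.removed_loci[current.loci[j].id] = float(locus_rate[j])
        if current.n_loci and not keep_loci.any():
            raise EmptyPanelError(
                f"all loci fell below the locus success threshold {locus_min}"
            )

        scored = scored[:, keep_loci]
        sample_rate = scored.mean(axis=1) if keep_loci.any() else np.ones(current.n_individuals)
        keep_ind = np.ones(current.n_individuals, dtype=bool)
        report.kept_by_override = {}
        for i, ind in enumerate(current.individuals):
            if sample_rate[i] < sample_min:
                if ind.id in keep_set:
                    report.kept_by_override[ind.id] = float(sample_rate[i])
                else:
                    keep_ind[i] = False
                    report.removed_samples[ind.id] = float(sample_rate[i])
        changed = (~keep_loci).any() or (~keep_ind).any()
        current = current.subset(individuals=keep_ind, loci=keep_loci)
        if not changed:
            return current, report
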