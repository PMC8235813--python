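"""Relatedness-based subsampling for balanced admixture runs.

Relatedness is measured as allele-sharing similarity: one minus half the
absolute dosage difference, averaged over loci scored in both individuals.
The most-related individual (highest mean similarity to the rest of its
group) is removed iteratively until the target size is reached.
"""

from __future__ import annotations

import logging

import numpy as np

from ..genotype_core.model import GenotypeMatrix

logger = logging.getLogger(__name__)


def allele_sharing_matrix(matrix: GenotypeMatrix) -> np.ndarray:
    """Pairwise allele-sharing similarity in [0, 1]; NaN when no shared loci."""
    dose = matrix.dosage(missing=np.nan)
    n = matrix.n_individuals
    out = np.full((n, n), np.nan)
    for i in range(n):
        out[i, i] = 1.0
        for j in range(i + 1, n):
            both = ~np.isnan(dose[i]) & ~np.isnan(dose[j])
            if not both.any():
                continue
            share = 1.0 - np.abs(dose[i, both] - dose[j, both]) / 2.0
            out[i, j] = out[j, i] = float(share.mean())
    return out


def subsample_by_relatedness(matrix: GenotypeMatrix, group: str, target_n: int) -> list[str]:
    """Ids retained after trimming `group` down to `target_n` individuals.

    Ties in mean relatedness are broken by individual id, making the result
    deterministic.  A group already at or below `target_n` is returned
    unchanged (with a warning when strictly smaller).
    """
    mask = matrix.group_mask(group)
    sub = matrix.subset(individuals=mask)
    ids = sub.individual_ids
    if len(ids) < target_n:
        logger.warning("group %r has %d < target %d individuals; returned unchanged",
                       group, len(ids), target_n)
        return ids
    sim = allele_sharing_matrix(sub)
    active = list(range(len(ids)))
    while len(active) > target_n:
        means = []
        for i in active:
            others = [j for j in active if j != i]
            vals = sim[i, others]
            means.append(float(np.nanmean(vals)) if np.isfinite(vals).any() else -np.inf)
        worst = max(zip(means, (ids[i] for i in active), active))
        active.remove(worst[2])
    return [ids[i] for i in active]
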