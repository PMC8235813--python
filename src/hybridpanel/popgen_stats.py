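"""Population-genetic summaries: Weir-Cockerham F_ST, permutation p-values
and genotype PCA.

F_ST follows the 1984 variance-components estimator: per locus the three
components (a: among populations, b: among individuals within populations,
c: within individuals) are computed from genotype counts, using observed
heterozygosity, and the multilocus estimate is the ratio of summed
components -- not the mean of per-locus ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._errors import ValidationError
from .genotype_core.model import HET, MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Weir-Cockerham theta


def _wc_components_masks(calls: np.ndarray, masks: list[np.ndarray]) -> np.ndarray:
    """Per-locus (a, b, c) variance components; NaN rows for skipped loci.

    Vectorised over loci; `masks` are two boolean individual selectors.
    """
    r = 2
    n_loci = calls.shape[1]
    n_i = np.empty((r, n_loci))
    p_i = np.empty((r, n_loci))
    h_i = np.empty((r, n_loci))
    for k, m in enumerate(masks):
        sub = calls[m]
        obs = sub != MISSING
        n = obs.sum(axis=0)
        dose2 = np.where(obs, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            n_i[k] = n
            p_i[k] = 1.0 - dose2 / (2.0 * np.maximum(n, 1))  # allele1 frequency
            h_i[k] = ((sub == HET) & obs).sum(axis=0) / np.maximum(n, 1)
    ok = (n_i >= 2).all(axis=0)
    n_sum = n_i.sum(axis=0)
    nbar = n_sum / r
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (n_sum - (n_i**2).sum(axis=0) / n_sum) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / n_sum
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / n_sum
        a = (nbar / n_c) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    out = np.stack([a, b, c], axis=1)
    out[~ok] = np.nan
    return out


@dataclass
class FstResult:
    groups: tuple[str, str]
    per_locus: np.ndarray
    multilocus: float
    p_value: float | None = None
    replicates: int = 0
    skipped_loci: list[str] = field(default_factory=list)


def _wc_from_masks(calls, masks) -> tuple[np.ndarray, float, np.ndarray]:
    comp = _wc_components_masks(calls, masks)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = comp[:, 0] / comp.sum(axis=1)
    ok = ~np.isnan(comp[:, 0])
    denom = comp[ok].sum()
    multilocus = float(comp[ok, 0].sum() / denom) if ok.any() and denom != 0 else float("nan")
    return per_locus, multilocus, ok


def wc_fst(matrix: GenotypeMatrix, groups: tuple[str, str]) -> FstResult:
    """Weir-Cockerham theta between two group labels of `matrix`."""
    masks = [matrix.group_mask(g) for g in groups]
    for g, m in zip(groups, masks):
        if m.sum() < 2:
            raise ValidationError(f"group {g!r} needs at least 2 individuals")
    per_locus, multilocus, ok = _wc_from_masks(matrix.calls, masks)
    if (~ok).any():
        logger.debug("wc_fst: skipped %d loci with <2 genotyped individuals in a group",
                     int((~ok).sum()))
    skipped = [matrix.loci[l].id for l in np.flatnonzero(~ok)]
    return FstResult(groups=groups, per_locus=per_locus, multilocus=multilocus,
                     skipped_loci=skipped)


def fst_pvalue(
    matrix: GenotypeMatrix,
    groups: tuple[str, str],
    replicates: int = 1000,
    seed: int = 0,
) -> FstResult:
    """Permutation p-value for the multilocus theta between two groups.

    Group labels are permuted over the pooled individuals `replicates` times;
    p = (#{permuted theta >= observed} + 1) / (replicates + 1).
    """
    if replicates < 1:
        raise ValidationError(f"replicates must be >= 1, got {replicates}")
    observed = wc_fst(matrix, groups)
    mask = matrix.group_mask(groups[0]) | matrix.group_mask(groups[1])
    calls = matrix.calls[mask]
    labels = np.array(matrix.groups, dtype=object)[mask]
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(replicates):
        perm = rng.permutation(labels)
        masks = [perm == g for g in groups]
        _, theta, _ = _wc_from_masks(calls, masks)
        if theta >= observed.multilocus:
            hits += 1
    observed.p_value = (hits + 1) / (replicates + 1)
    observed.replicates = replicates
    return observed


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PcaResult:
    coordinates: np.ndarray  # individuals x components
    explained: np.ndarray  # variance fractions, non-increasing
    loadings: np.ndarray  # loci x components (dropped loci get zero rows)
    dropped_loci: list[str] = field(default_factory=list)


def genotype_pca(matrix: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """PCA of the allele2 dosage matrix with smartpca-style normalization.

    Dosages are mean-centred per locus and scaled by sqrt(p(1-p)) with p the
    shrinkage-adjusted allele frequency (1 + sum g) / (2 + 2n); missing calls
    are imputed to the locus mean.  Monomorphic loci are dropped.
    """
    if matrix.n_individuals < 2:
        raise ValidationError("PCA needs at least 2 individuals")
    dose = matrix.dosage(missing=np.nan)
    n_obs = (~np.isnan(dose)).sum(axis=0)
    col_sum = np.nansum(dose, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = col_sum / n_obs
    keep = (n_obs > 0) & (np.nanstd(dose, axis=0) > 0)
    dropped = [matrix.loci[j].id for j in np.flatnonzero(~keep)]
    if dropped:
        logger.info("PCA: dropping %d monomorphic/empty loci", len(dropped))
    X = dose[:, keep]
    mean_k = mean[keep]
    inds = np.where(np.isnan(X))
    X[inds] = mean_k[inds[1]]
    p_hat = (1.0 + col_sum[keep]) / (2.0 + 2.0 * n_obs[keep])
    X = (X - mean_k) / np.sqrt(p_hat * (1.0 - p_hat))

    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    positive = S > 1e-9 * (S[0] if S.size else 1.0)
    U, S, Vt = U[:, positive], S[positive], Vt[positive]
    k = min(n_components, S.size)
    coords = U[:, :k] * S[:k]
    explained = (S**2 / (S**2).sum())[:k] if S.size else np.empty(0)
    loadings = np.zeros((matrix.n_loci, k))
    loadings[np.flatnonzero(keep), :] = Vt[:k].T
    return PcaResult(coordinates=coords, explained=explained, loadings=loadings,
                     dropped_loci=dropped)


# ---------------------------------------------------------------------------
# parametric theta (used for generator calibration)


def parametric_fst(p1: np.ndarray | float, p2: np.ndarray | float) -> np.ndarray | float:
    """Large-sample limit of Weir-Cockerham theta for two HWE populations.

    With d = p1 - p2 and pbar the midpoint frequency, the estimator converges
    to 2 d^2 / (4 pbar (1 - pbar) + d^2), i.e. the between-minus-within over
    between heterozygosity ratio; identical fixed frequencies give 0.
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    d2 = (p1 - p2) ** 2
    pbar = (p1 + p2) / 2.0
    denom = 4.0 * pbar * (1.0 - pbar) + d2
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom > 0, 2.0 * d2 / np.where(denom > 0, denom, 1.0), 0.0)
    return float(theta) if theta.ndim == 0 else theta
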