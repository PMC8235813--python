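"""Ancestry-informative-marker panel design.

Pipeline stages (each also usable standalone): pooled-MAF filter, greedy LD
pruning on composite genotype r-squared, proximity exclusion against an
annotation track, and top-N selection by between-group F_ST.  Every stage
can append to an audit trail so the final panel ships with stage-by-stage
kept/removed counts.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._errors import GenotypeParseError, SelectionError, ValidationError
from .genotype_core.model import MISSING, GenotypeMatrix, Locus
from .popgen_stats import wc_fst

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PanelCandidate:
    """A locus with its selection statistics."""

    locus: Locus
    maf: float
    fst: float
    r2_partners: frozenset[str] = frozenset()
    distance_to_nearest_variant: int | None = None

    def __post_init__(self) -> None:
        if self.maf > 0.5 + 1e-12:
            raise ValidationError(f"locus {self.locus.id}: MAF {self.maf} > 0.5")


@dataclass
class AuditRow:
    stage: str
    n_in: int
    n_kept: int
    n_removed: int
    reason: str


Audit = list


def audit_to_frame(audit: Sequence[AuditRow]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in audit])


def _record(audit, stage: str, n_in: int, n_kept: int, reason: str) -> None:
    if audit is not None:
        audit.append(AuditRow(stage=stage, n_in=n_in, n_kept=n_kept,
                              n_removed=n_in - n_kept, reason=reason))


def build_candidates(
    matrix: GenotypeMatrix, groups: tuple[str, str] = ("wolf", "dog")
) -> list[PanelCandidate]:
    """Compute pooled MAF and between-group F_ST for every locus."""
    mask = matrix.group_mask(groups[0]) | matrix.group_mask(groups[1])
    pooled = matrix.subset(individuals=mask)
    freq1 = pooled.allele1_frequency()
    maf = np.minimum(freq1, 1.0 - freq1)
    fst = wc_fst(matrix, groups).per_locus
    return [
        PanelCandidate(locus=loc, maf=float(maf[j]), fst=float(fst[j]))
        for j, loc in enumerate(matrix.loci)
    ]


# ---------------------------------------------------------------------------
# stages


def maf_filter(
    candidates: Sequence[PanelCandidate], threshold: float = 0.1, audit: Audit | None = None
) -> list[PanelCandidate]:
    """Keep candidates with pooled MAF strictly greater than `threshold`."""
    if not 0.0 < threshold <= 0.5:
        raise ValidationError(f"threshold must be in (0, 0.5], got {threshold}")
    kept = [c for c in candidates if c.maf > threshold]
    _record(audit, "maf_filter", len(candidates), len(kept), f"MAF <= {threshold}")
    return kept


def composite_r2(matrix: GenotypeMatrix) -> np.ndarray:
    """Pairwise composite (Burrows) genotype r-squared from dosages.

    Uses pairwise-complete observations; pairs involving a monomorphic locus
    get r^2 = 0 (undefined correlation, treated as unlinked).
    """
    dose = matrix.dosage(missing=np.nan)
    n_loci = matrix.n_loci
    if not np.isnan(dose).any():  # fast path: one corrcoef call
        sd = dose.std(axis=0)
        poly = sd > 0
        out = np.zeros((n_loci, n_loci))
        if poly.any():
            r = np.corrcoef(dose[:, poly].T)
            out[np.ix_(poly, poly)] = r * r
        np.fill_diagonal(out, 1.0)
        return out
    out = np.zeros((n_loci, n_loci))
    for j in range(n_loci):
        out[j, j] = 1.0
        for k in range(j + 1, n_loci):
            both = ~np.isnan(dose[:, j]) & ~np.isnan(dose[:, k])
            x, y = dose[both, j], dose[both, k]
            if x.size < 2 or x.std() == 0 or y.std() == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            out[j, k] = out[k, j] = r * r
    return out


def ld_prune(
    matrix: GenotypeMatrix,
    r2_threshold: float = 0.2,
    ranking: Sequence[float] | None = None,
    audit: Audit | None = None,
) -> list[str]:
    """Greedy LD pruning: accept loci in descending `ranking` order iff their
    composite r^2 with every already-accepted locus is below `r2_threshold`.

    Ties in the ranking are broken by (chromosome, position).  Returns the
    retained locus ids in panel order.
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ValidationError(f"r2_threshold must be in (0, 1], got {r2_threshold}")
    n = matrix.n_loci
    score = np.zeros(n) if ranking is None else np.asarray(ranking, float)
    if score.shape != (n,):
        raise ValidationError("ranking length must match the number of loci")
    monomorphic = [matrix.loci[j].id
                   for j in range(n) if len(set(matrix.calls[:, j][matrix.calls[:, j] != MISSING])) <= 1]
    if monomorphic:
        logger.info("ld_prune: %d monomorphic loci, r^2 with them treated as 0", len(monomorphic))
    r2 = composite_r2(matrix)
    order = sorted(range(n),
                   key=lambda j: (-score[j], matrix.loci[j].chromosome, matrix.loci[j].position))
    accepted: list[int] = []
    for j in order:
        if all(r2[j, k] < r2_threshold for k in accepted):
            accepted.append(j)
    accepted_ids = {matrix.loci[j].id for j in accepted}
    kept = [loc.id for loc in matrix.loci if loc.id in accepted_ids]
    _record(audit, "ld_prune", n, len(kept), f"r^2 >= {r2_threshold} with a higher-ranked locus")
    return kept


def read_annotation(path: str | os.PathLike, format: str | None = None) -> dict[str, np.ndarray]:
    """Read an annotation track (BED or VCF) into per-chromosome 1-based positions."""
    fmt = format
    if fmt is None:
        fmt = "vcf" if str(path).endswith(".vcf") else "bed"
    points: dict[str, list[int]] = {}
    if fmt == "bed":
        try:
            df = pd.read_csv(path, sep="\t", header=None, comment="#",
                             usecols=[0, 1], names=["chrom", "start"])
        except Exception as exc:
            raise GenotypeParseError(f"{path}: not parseable as BED: {exc}") from exc
        for chrom, start in zip(df["chrom"].astype(str), df["start"].astype(int)):
            points.setdefault(chrom, []).append(start + 1)  # 0-based half-open -> 1-based point
    elif fmt == "vcf":
        from cyvcf2 import VCF

        for var in VCF(str(path)):
            points.setdefault(var.CHROM, []).append(var.POS)
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    return {c: np.unique(np.array(p, dtype=np.int64)) for c, p in points.items()}


def proximity_filter(
    candidates: Sequence[PanelCandidate],
    annotation: dict[str, np.ndarray] | str | os.PathLike,
    min_distance: int = 100,
    audit: Audit | None = None,
) -> list[PanelCandidate]:
    """Exclude candidates closer than `min_distance` bp to another annotated
    polymorphic site on the same chromosome (distance == min_distance keeps).

    A candidate's own annotation record (distance 0) is ignored; candidates on
    chromosomes absent from the annotation are kept and logged as unchecked.
    """
    if isinstance(annotation, (str, os.PathLike)):
        annotation = read_annotation(annotation)
    kept: list[PanelCandidate] = []
    unchecked = 0
    for c in candidates:
        sites = annotation.get(c.locus.chromosome)
        if sites is None or sites.size == 0:
            unchecked += 1
            kept.append(replace(c, distance_to_nearest_variant=None))
            continue
        dist = np.abs(sites - c.locus.position)
        dist = dist[dist > 0]  # the candidate's own record
        nearest = int(dist.min()) if dist.size else None
        c = replace(c, distance_to_nearest_variant=nearest)
        if nearest is None or nearest >= min_distance:
            kept.append(c)
    if unchecked:
        logger.warning("proximity_filter: %d candidates on unannotated chromosomes kept unchecked",
                       unchecked)
    _record(audit, "proximity_filter", len(candidates), len(kept),
            f"another variant < {min_distance} bp away")
    return kept


def select_top(
    candidates: Sequence[PanelCandidate], n: int, audit: Audit | None = None
) -> list[PanelCandidate]:
    """Pick the `n` candidates with the highest F_ST (ties by chrom, position)."""
    if n > len(candidates):
        raise SelectionError(
            f"requested {n} loci but only {len(candidates)} candidates remain "
            f"(short by {n - len(candidates)})"
        )
    ranked = sorted(candidates,
                    key=lambda c: (-c.fst, c.locus.chromosome, c.locus.position))
    kept = ranked[:n]
    _record(audit, "select_top", len(candidates), len(kept), f"rank by F_ST, keep top {n}")
    return kept


def select_panel(
    matrix: GenotypeMatrix,
    groups: tuple[str, str] = ("wolf", "dog"),
    maf_threshold: float = 0.1,
    r2_threshold: float = 0.2,
    annotation: dict[str, np.ndarray] | None = None,
    min_distance: int = 100,
    n_final: int = 96,
) -> tuple[list[PanelCandidate], list[AuditRow]]:
    """Run the full selection pipeline: MAF -> LD prune -> proximity -> top-N."""
    audit: list[AuditRow] = []
    cands = build_candidates(matrix, groups)
    _record(audit, "input", len(cands), len(cands), "candidate loci")
    cands = maf_filter(cands, maf_threshold, audit=audit)
    keep_ids = set(c.locus.id for c in cands)
    sub = matrix.subset(loci=[j for j, l in enumerate(matrix.loci) if l.id in keep_ids])
    kept_ids = set(ld_prune(sub, r2_threshold,
                            ranking=[c.fst for c in cands], audit=audit))
    cands = [c for c in cands if c.locus.id in kept_ids]
    if annotation is not None:
        cands = proximity_filter(cands, annotation, min_distance, audit=audit)
    return select_top(cands, min(n_final, len(cands)), audit=audit), audit
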