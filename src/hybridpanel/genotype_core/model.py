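"""Core data model: loci, individuals, diploid biallelic genotype matrices.

Calls are stored as a dense ``int8`` array with the encoding

* ``0`` — homozygous for ``allele1`` (``HOM1``)
* ``1`` — heterozygous (``HET``)
* ``2`` — homozygous for ``allele2`` (``HOM2``)
* ``-1`` — missing (``MISSING``)

so that a non-missing call equals the dosage of ``allele2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .._errors import ValidationError

HOM1: int = 0
HET: int = 1
HOM2: int = 2
MISSING: int = -1

CALL_DTYPE = np.int8


@dataclass(frozen=True)
class Locus:
    """A biallelic SNP with its two declared alleles."""

    id: str
    chromosome: str
    position: int
    allele1: str
    allele2: str

    def __post_init__(self) -> None:
        if self.allele1 == self.allele2:
            raise ValidationError(f"locus {self.id}: allele1 == allele2 ({self.allele1!r})")
        if self.position < 1:
            raise ValidationError(f"locus {self.id}: position must be >= 1, got {self.position}")
        if len(self.allele1) != 1 or len(self.allele2) != 1:
            raise ValidationError(f"locus {self.id}: alleles must be single characters")


@dataclass(frozen=True)
class Individual:
    """A sample row: stable id, group label (population) and sample type."""

    id: str
    group: str = "unknown"
    sample_type: str = "tissue"


@dataclass
class GenotypeMatrix:
    """Individuals x loci diploid biallelic calls."""

    loci: list[Locus]
    individuals: list[Individual]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=CALL_DTYPE)
        if self.calls.shape != (len(self.individuals), len(self.loci)):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        bad = ~np.isin(self.calls, (HOM1, HET, HOM2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"invalid call code {self.calls[i, j]} for individual "
                f"{self.individuals[i].id!r} at locus {self.loci[j].id!r}"
            )
        ids = [loc.id for loc in self.loci]
        if len(set(ids)) != len(ids):
            dup = sorted({x for x in ids if ids.count(x) > 1})
            raise ValidationError(f"duplicate locus ids: {dup}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [loc.id for loc in self.loci]

    @property
    def individual_ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    @property
    def groups(self) -> list[str]:
        return [ind.group for ind in self.individuals]

    # -- views ----------------------------------------------------------
    def dosage(self, missing: float = np.nan) -> np.ndarray:
        """Dosage of allele2 per call as float; missing replaced by `missing`."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = missing
        return d

    def group_mask(self, group: str | Iterable[str]) -> np.ndarray:
        wanted = {group} if isinstance(group, str) else set(group)
        return np.array([ind.group in wanted for ind in self.individuals], dtype=bool)

    def subset(
        self,
        individuals: Sequence[int] | np.ndarray | None = None,
        loci: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        ind_idx = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        if ind_idx.dtype == bool:
            ind_idx = np.flatnonzero(ind_idx)
        loc_idx = np.arange(self.n_loci) if loci is None else np.asarray(loci)
        if loc_idx.dtype == bool:
            loc_idx = np.flatnonzero(loc_idx)
        return GenotypeMatrix(
            loci=[self.loci[j] for j in loc_idx],
            individuals=[self.individuals[i] for i in ind_idx],
            calls=self.calls[np.ix_(ind_idx, loc_idx)].copy(),
        )

    def select_group(self, group: str | Iterable[str]) -> "GenotypeMatrix":
        return self.subset(individuals=self.group_mask(group))

    def relabel(self, group: str) -> "GenotypeMatrix":
        return GenotypeMatrix(
            loci=list(self.loci),
            individuals=[replace(ind, group=group) for ind in self.individuals],
            calls=self.calls.copy(),
        )

    def allele1_frequency(self) -> np.ndarray:
        """Per-locus frequency of allele1 among non-missing calls (NaN if none)."""
        obs = self.calls != MISSING
        n = obs.sum(axis=0)
        dose2 = np.where(obs, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, 1.0 - dose2 / (2.0 * n), np.nan)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.loci == other.loci
            and self.individuals == other.individuals
            and np.array_equal(self.calls, other.calls)
        )


def concatenate(matrices: Sequence[GenotypeMatrix]) -> GenotypeMatrix:
    """Stack matrices with identical panels along the individual axis."""
    if not matrices:
        raise ValidationError("cannot concatenate zero matrices")
    panel = matrices[0].loci
    for m in matrices[1:]:
        if m.loci != panel:
            raise ValidationError("cannot concatenate matrices with different panels")
    return GenotypeMatrix(
        loci=list(panel),
        individuals=[ind for m in matrices for ind in m.individuals],
        calls=np.vstack([m.calls for m in matrices]),
    )


@dataclass
class ReplicateSet:
    """Repeated genotypings of one individual (possibly several sample types)."""

    individual_id: str
    replicates: list[np.ndarray]
    sample_ids: list[str] = field(default_factory=list)
    sample_types: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValidationError(f"individual {self.individual_id!r}: at least one replicate required")
        self.replicates = [np.asarray(r, dtype=CALL_DTYPE) for r in self.replicates]
        n = self.replicates[0].shape[0]
        for k, r in enumerate(self.replicates):
            if r.shape != (n,):
                raise ValidationError(
                    f"individual {self.individual_id!r}: replicate {k} length "
                    f"{r.shape} != panel length {n}"
                )
        if not self.sample_ids:
            self.sample_ids = [f"{self.individual_id}_r{k+1}" for k in range(len(self.replicates))]
        if not self.sample_types:
            self.sample_types = ["unknown"] * len(self.replicates)


@dataclass
class ConcordanceReport:
    """Tallies and rates from reference-vs-test genotype comparisons.

    Rates are percentages; ``None`` when the denominator is zero (undefined,
    deliberately distinct from a true 0%).
    """

    false_allele_count: int = 0
    hom_reference_count: int = 0
    missing_allele_count: int = 0
    het_reference_count: int = 0
    per_sample_missing: list[float] = field(default_factory=list)

    @property
    def false_allele_rate(self) -> float | None:
        if self.hom_reference_count == 0:
            return None
        return 100.0 * self.false_allele_count / self.hom_reference_count

    @property
    def missing_allele_rate(self) -> float | None:
        if self.het_reference_count == 0:
            return None
        return 100.0 * self.missing_allele_count / self.het_reference_count

    @property
    def missing_data_rate(self) -> float | None:
        if not self.per_sample_missing:
            return None
        return 100.0 * float(np.mean(self.per_sample_missing))
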