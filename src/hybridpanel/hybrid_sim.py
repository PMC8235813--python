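"""Pedigree-based simulation of hybrid genotype classes from parental
allele-frequency pools.

Each of the ten categories (two parentals, F1, F2 and first- to
third-generation backcrosses in both directions) is described by a binary
pedigree tree whose leaves are the parental pools W and D.  An individual
is simulated by recursive gamete sampling: a leaf contributes one allele
drawn from its pool's per-locus frequency, an internal node first simulates
its own two-gamete genotype and then passes on one of the two alleles
uniformly at random.  Loci are treated as unlinked (the panel is LD-pruned).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from ._errors import ValidationError
from .genotype_core.model import CALL_DTYPE, GenotypeMatrix, Individual, Locus

Pedigree = Union[str, tuple]  # "W" | "D" | (father_tree, mother_tree)

_F1: Pedigree = ("W", "D")
_BC1W: Pedigree = (_F1, "W")
_BC2W: Pedigree = (_BC1W, "W")
_BC3W: Pedigree = (_BC2W, "W")
_BC1D: Pedigree = (_F1, "D")
_BC2D: Pedigree = (_BC1D, "D")
_BC3D: Pedigree = (_BC2D, "D")

PEDIGREES: dict[str, Pedigree] = {
    "W": "W",
    "D": "D",
    "F1": _F1,
    "F2": (_F1, _F1),
    "BC1w": _BC1W,
    "BC2w": _BC2W,
    "BC3w": _BC3W,
    "BC1d": _BC1D,
    "BC2d": _BC2D,
    "BC3d": _BC3D,
}

HYBRID_CLASS_NAMES = tuple(PEDIGREES)  # parentals first, then hybrid categories
HYBRID_CATEGORY_NAMES = tuple(n for n in PEDIGREES if n not in ("W", "D"))


@dataclass(frozen=True)
class HybridClass:
    name: str
    pedigree: Pedigree

    def __post_init__(self) -> None:
        expected = PEDIGREES.get(self.name)
        if expected is not None and expected != self.pedigree:
            raise ValidationError(
                f"pedigree for {self.name!r} does not match its standard definition"
            )


def get_class(name: str) -> HybridClass:
    try:
        return HybridClass(name=name, pedigree=PEDIGREES[name])
    except KeyError:
        raise ValidationError(
            f"unknown hybrid class {name!r}; expected one of {HYBRID_CLASS_NAMES}"
        ) from None


# ---------------------------------------------------------------------------
# parental pools


def estimate_pool_frequencies(
    parental: GenotypeMatrix, exclude_sample_types: Sequence[str] = ("scat",)
) -> np.ndarray:
    """Per-locus allele1 frequency of a parental pool.

    Sample types in `exclude_sample_types` (scat by default, to mirror the
    contamination-risk exclusion) are dropped before counting; missing calls
    are excluded from the denominator.
    """
    keep = [i for i, ind in enumerate(parental.individuals)
            if ind.sample_type not in set(exclude_sample_types)]
    if len(keep) < 2:
        raise ValidationError("parental pool needs at least 2 usable individuals")
    sub = parental.subset(individuals=keep)
    freq = sub.allele1_frequency()
    empty = np.isnan(freq)
    if empty.any():
        bad = sub.loci[int(np.argmax(empty))].id
        raise ValidationError(f"locus {bad!r}: no non-missing genotype in the parental pool")
    return freq


# ---------------------------------------------------------------------------
# simulation


def _gamete(tree: Pedigree, q_wolf: np.ndarray, q_dog: np.ndarray,
            n: int, rng: np.random.Generator) -> np.ndarray:
    """One gamete per (individual, locus): 0/1 indicator of carrying allele2."""
    if tree == "W":
        return (rng.random((n, q_wolf.size)) < 1.0 - q_wolf).astype(np.int8)
    if tree == "D":
        return (rng.random((n, q_dog.size)) < 1.0 - q_dog).astype(np.int8)
    father, mother = tree
    own = _gamete(father, q_wolf, q_dog, n, rng), _gamete(mother, q_wolf, q_dog, n, rng)
    pick = rng.random((n, q_wolf.size)) < 0.5
    return np.where(pick, own[0], own[1])


def simulate_class(
    cls: HybridClass | str,
    wolf_freqs: np.ndarray,
    dog_freqs: np.ndarray,
    n: int,
    seed: int,
    loci: Sequence[Locus] | None = None,
    group: str | None = None,
) -> GenotypeMatrix:
    """Simulate `n` individuals of a hybrid class.

    `wolf_freqs` / `dog_freqs` are per-locus allele1 frequencies of the two
    parental pools.  The class name is recorded as the group label unless
    `group` overrides it.
    """
    if isinstance(cls, str):
        cls = get_class(cls)
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    wolf_freqs = np.asarray(wolf_freqs, float)
    dog_freqs = np.asarray(dog_freqs, float)
    if wolf_freqs.shape != dog_freqs.shape:
        raise ValidationError("parental frequency vectors differ in length")
    rng = np.random.default_rng(seed)
    if cls.pedigree in ("W", "D"):
        father = mother = cls.pedigree  # parental class: two pool gametes
    else:
        father, mother = cls.pedigree
    calls = (
        _gamete(father, wolf_freqs, dog_freqs, n, rng)
        + _gamete(mother, wolf_freqs, dog_freqs, n, rng)
    ).astype(CALL_DTYPE)
    if loci is None:
        loci = [Locus(id=f"L{j + 1:04d}", chromosome="0", position=j + 1,
                      allele1="A", allele2="B") for j in range(wolf_freqs.size)]
    group = group or cls.name
    individuals = [Individual(id=f"{cls.name}_{i + 1:04d}", group=group,
                              sample_type="simulated") for i in range(n)]
    return GenotypeMatrix(loci=list(loci), individuals=individuals, calls=calls)


# ---------------------------------------------------------------------------
# expected gene-copy origin profiles


def _wolf_share(tree: Pedigree) -> float:
    if tree == "W":
        return 1.0
    if tree == "D":
        return 0.0
    return (_wolf_share(tree[0]) + _wolf_share(tree[1])) / 2.0


def expected_origin_profile(cls: HybridClass | str) -> tuple[float, float, float]:
    """Expected per-locus proportions (g_WW, g_WD, g_DD) of gene-copy origins."""
    if isinstance(cls, str):
        cls = get_class(cls)
    if cls.pedigree in ("W", "D"):
        w = _wolf_share(cls.pedigree)
        return (w, 0.0, 1.0 - w)
    w_f = _wolf_share(cls.pedigree[0])
    w_m = _wolf_share(cls.pedigree[1])
    g_ww = w_f * w_m
    g_dd = (1.0 - w_f) * (1.0 - w_m)
    return (g_ww, 1.0 - g_ww - g_dd, g_dd)
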