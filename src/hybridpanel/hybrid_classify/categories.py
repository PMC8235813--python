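"""Genotype-frequency classes for the hybrid-category classifier.

Each category is a triple (g_WW, g_WD, g_DD): the expected per-locus
proportions of gene-copy pairs with both copies of wolf origin, one of
each, or both of dog origin.  The default ten categories are the two
parentals, F1, F2 and first- to third-generation backcrosses both ways,
derived from their pedigrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._errors import ValidationError
from ..hybrid_sim import HYBRID_CLASS_NAMES, expected_origin_profile

PARENTAL_NAMES = ("W", "D")


@dataclass(frozen=True)
class GenotypeFrequencyClass:
    name: str
    g: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(x < 0 for x in self.g):
            raise ValidationError(f"category {self.name!r}: negative origin proportion")
        if abs(sum(self.g) - 1.0) > 1e-9:
            raise ValidationError(f"category {self.name!r}: origin proportions must sum to 1")


def default_categories() -> list[GenotypeFrequencyClass]:
    """The ten standard categories, parentals first."""
    return [
        GenotypeFrequencyClass(name=name, g=expected_origin_profile(name))
        for name in HYBRID_CLASS_NAMES
    ]


def category_matrix(categories: list[GenotypeFrequencyClass]) -> np.ndarray:
    return np.array([c.g for c in categories], dtype=float)


def mirror_category(name: str) -> str:
    """Swap the species roles of a category name (W<->D, BCkw<->BCkd)."""
    table = {"W": "D", "D": "W"}
    if name in table:
        return table[name]
    if name.endswith("w"):
        return name[:-1] + "d"
    if name.endswith("d"):
        return name[:-1] + "w"
    return name
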