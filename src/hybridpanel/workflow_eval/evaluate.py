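"""Accuracy tables and assignment-distribution summaries for simulated
hybrid classes."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .._errors import ValidationError
from ..hybrid_classify.sampler import CategoryPosterior, ClassifierConfig

logger = logging.getLogger(__name__)


@dataclass
class ClassAccuracy:
    name: str
    n: int
    correct_pct: tuple[float, float]  # min-max over prior combinations
    hybrid_pct: tuple[float, float]


@dataclass
class AccuracyTable:
    classes: list[ClassAccuracy] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        def fmt(rng):
            lo, hi = rng
            return f"{lo:g}" if lo == hi else f"{lo:g}-{hi:g}"

        return pd.DataFrame(
            [
                {
                    "class": c.name,
                    "n": c.n,
                    "correct_pct_min": c.correct_pct[0],
                    "correct_pct_max": c.correct_pct[1],
                    "correct_pct": fmt(c.correct_pct),
                    "hybrid_pct_min": c.hybrid_pct[0],
                    "hybrid_pct_max": c.hybrid_pct[1],
                    "hybrid_pct": fmt(c.hybrid_pct),
                }
                for c in self.classes
            ]
        )

    def by_class(self) -> dict[str, ClassAccuracy]:
        return {c.name: c for c in self.classes}


def _percentages(
    by_class: Mapping[str, Sequence[CategoryPosterior]], config: ClassifierConfig
) -> dict[str, tuple[int, float, float]]:
    out = {}
    for cls, posts in by_class.items():
        if not posts:
            logger.warning("class %r has no individuals; omitted from the table", cls)
            continue
        n = len(posts)
        correct = sum(p.q_of(cls) >= config.assignment_threshold for p in posts)
        hybrid = sum(p.hybrid_sum > config.hybrid_sum_threshold for p in posts)
        out[cls] = (n, 100.0 * correct / n, 100.0 * hybrid / n)
    return out


def evaluate_accuracy(
    posteriors_by_run: Mapping[str, Mapping[str, Sequence[CategoryPosterior]]]
    | Mapping[str, Sequence[CategoryPosterior]],
    config: ClassifierConfig,
) -> AccuracyTable:
    """Percent correctly assigned and percent hybrid-detected per true class.

    `posteriors_by_run` maps run labels (e.g. prior combinations) to
    {true class -> posteriors}; a single {true class -> posteriors} mapping
    is also accepted.  Denominators are always the full class size; ranges
    are min-max over runs.
    """
    first = next(iter(posteriors_by_run.values()), None)
    if first is None:
        raise ValidationError("no posteriors supplied")
    if not isinstance(first, Mapping):
        posteriors_by_run = {"run": posteriors_by_run}  # type: ignore[assignment]

    per_run = [_percentages(by_class, config) for by_class in posteriors_by_run.values()]
    classes: list[ClassAccuracy] = []
    for cls in per_run[0]:
        stats = [r[cls] for r in per_run if cls in r]
        ns = {s[0] for s in stats}
        if len(ns) != 1:
            raise ValidationError(f"class {cls!r}: inconsistent n across runs: {ns}")
        classes.append(
            ClassAccuracy(
                name=cls,
                n=ns.pop(),
                correct_pct=(min(s[1] for s in stats), max(s[1] for s in stats)),
                hybrid_pct=(min(s[2] for s in stats), max(s[2] for s in stats)),
            )
        )
    return AccuracyTable(classes=classes)


@dataclass
class AssignmentDistribution:
    """Five-number summaries of admixture q per class plus range overlaps."""

    classes: list[str]
    summary: dict[str, tuple[float, float, float, float, float]]  # min,Q1,med,Q3,max

    def overlap(self, a: str, b: str) -> bool:
        lo_a, hi_a = self.summary[a][0], self.summary[a][4]
        lo_b, hi_b = self.summary[b][0], self.summary[b][4]
        return lo_a <= hi_b and lo_b <= hi_a

    def overlap_matrix(self) -> pd.DataFrame:
        data = [[self.overlap(a, b) for b in self.classes] for a in self.classes]
        return pd.DataFrame(data, index=self.classes, columns=self.classes)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"class": c, "min": s[0], "q1": s[1], "median": s[2], "q3": s[3], "max": s[4]}
                for c, s in self.summary.items()
            ]
        )


def summarize_q_distributions(
    q_by_class: Mapping[str, Sequence[float] | np.ndarray],
) -> AssignmentDistribution:
    """Five-number summary of ancestry proportions per class."""
    summary = {}
    for cls, values in q_by_class.items():
        values = np.asarray(values, float)
        if values.size == 0:
            raise ValidationError(f"class {cls!r} has no q values")
        summary[cls] = tuple(np.quantile(values, [0.0, 0.25, 0.5, 0.75, 1.0]))
    return AssignmentDistribution(classes=list(summary), summary=summary)
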