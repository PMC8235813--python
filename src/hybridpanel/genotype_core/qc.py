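"""Concordance metrics between reference (tissue) and test (non-invasive)
genotypes: false-allele and missing-allele tallies and aggregate rates.

An allele is "false" when the test genotype carries an allele copy absent
from a homozygous reference genotype (a het test call counts one such copy,
the opposite homozygote counts two).  An allele is "missing" when a
heterozygous reference genotype is observed as either homozygote in the
test.  Denominators are counts of homozygous / heterozygous reference
genotypes among loci where both calls are scored; rates are percentages of
these counts.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .._errors import ValidationError
from .model import HET, MISSING, ConcordanceReport


def concordance(reference: np.ndarray, test: np.ndarray) -> ConcordanceReport:
    """Compare one test call vector against its reference; return increments."""
    reference = np.asarray(reference)
    test = np.asarray(test)
    if reference.shape != test.shape:
        raise ValidationError(
            f"reference and test lengths differ: {reference.shape} vs {test.shape}"
        )
    rep = ConcordanceReport()
    both = (reference != MISSING) & (test != MISSING)

    ref_hom = both & (reference != HET)
    rep.hom_reference_count = int(ref_hom.sum())
    # novel allele copies: |dosage difference| from the homozygous reference
    rep.false_allele_count = int(
        np.abs(test[ref_hom].astype(int) - reference[ref_hom].astype(int)).sum()
    )

    ref_het = both & (reference == HET)
    rep.het_reference_count = int(ref_het.sum())
    rep.missing_allele_count = int((test[ref_het] != HET).sum())

    rep.per_sample_missing = [float((test == MISSING).sum() / test.size)]
    return rep


def aggregate_concordance(increments: Iterable[ConcordanceReport]) -> ConcordanceReport:
    """Sum per-pair increments into a study-level report."""
    total = ConcordanceReport()
    for inc in increments:
        total.false_allele_count += inc.false_allele_count
        total.hom_reference_count += inc.hom_reference_count
        total.missing_allele_count += inc.missing_allele_count
        total.het_reference_count += inc.het_reference_count
        total.per_sample_missing.extend(inc.per_sample_missing)
    return total
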