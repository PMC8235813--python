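"""Readers and writers for genotype matrices.

Three dialects are supported:

``tabular``
    The package's own plain-text format: a header row with ``id  group
    sample_type`` followed by locus ids (tab-separated); one row per sample
    with two-character genotype strings (``--`` = missing).
``ped-map``
    PLINK text PED/MAP pair (space-delimited, ``0 0`` = missing alleles).
    The family-id column carries the group label and the phenotype column
    the sample type, so that a write/read cycle is lossless.
``vcf``
    Minimal VCF v4.2, GT field only, 1-based positions, ``./.`` = missing.
    Group and sample-type are preserved in ``##SAMPLE`` header lines.

Because tabular and PED files do not declare which allele is "allele1", a
panel definition (list of :class:`Locus` or a panel TSV path) may be passed
to pin the allele order; otherwise alleles are inferred from the data in
order of first appearance.
"""

from __future__ import annotations

import os
import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .._errors import GenotypeParseError, ValidationError
from .model import CALL_DTYPE, HET, HOM1, HOM2, MISSING, GenotypeMatrix, Individual, Locus

FORMATS = ("tabular", "ped-map", "vcf")

# ---------------------------------------------------------------------------
# panel definition TSV


def read_panel(path: str | os.PathLike) -> list[Locus]:
    """Read a panel definition TSV (id, chromosome, position, allele1, allele2)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "chromosome": str})
    required = {"id", "chromosome", "position", "allele1", "allele2"}
    missing = required - set(df.columns)
    if missing:
        raise GenotypeParseError(f"panel file {path}: missing columns {sorted(missing)}")
    return [
        Locus(
            id=row.id,
            chromosome=row.chromosome,
            position=int(row.position),
            allele1=str(row.allele1),
            allele2=str(row.allele2),
        )
        for row in df.itertuples()
    ]


def write_panel(loci: Sequence[Locus], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "id": [l.id for l in loci],
            "chromosome": [l.chromosome for l in loci],
            "position": [l.position for l in loci],
            "allele1": [l.allele1 for l in loci],
            "allele2": [l.allele2 for l in loci],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# shared helpers


def _resolve_panel(panel, locus_ids: Sequence[str]) -> list[Locus] | None:
    if panel is None:
        return None
    if isinstance(panel, (str, os.PathLike)):
        panel = read_panel(panel)
    by_id = {l.id: l for l in panel}
    try:
        return [by_id[i] for i in locus_ids]
    except KeyError as exc:
        raise ValidationError(f"locus {exc.args[0]!r} not present in the panel definition") from exc


def _calls_from_allele_pairs(
    pairs: np.ndarray,
    locus_ids: Sequence[str],
    individual_ids: Sequence[str],
    panel: list[Locus] | None,
    missing_tokens: frozenset[str],
    default_chrom: str = "0",
) -> tuple[list[Locus], np.ndarray]:
    """Map an (n, L, 2) array of allele characters onto call codes.

    If `panel` is None, alleles are inferred per locus in order of first
    appearance (a monomorphic locus gets a placeholder second allele).
    """
    n, n_loci, _ = pairs.shape
    loci: list[Locus] = []
    calls = np.full((n, n_loci), MISSING, dtype=CALL_DTYPE)
    for j in range(n_loci):
        col = pairs[:, j, :]
        if panel is None:
            seen: list[str] = []
            for a in col.ravel():
                if a not in missing_tokens and a not in seen:
                    seen.append(a)
            if len(seen) > 2:
                raise ValidationError(
                    f"locus {locus_ids[j]!r}: more than two alleles observed ({seen})"
                )
            a1 = seen[0] if seen else "A"
            a2 = seen[1] if len(seen) > 1 else ("B" if a1 != "B" else "A")
            locus = Locus(id=str(locus_ids[j]), chromosome=default_chrom, position=j + 1,
                          allele1=a1, allele2=a2)
        else:
            locus = panel[j]
        loci.append(locus)
        valid = {locus.allele1, locus.allele2}
        for i in range(n):
            a, b = col[i]
            if a in missing_tokens or b in missing_tokens:
                continue
            if a not in valid or b not in valid:
                if panel is None:
                    continue  # inference saw <=2 alleles, unreachable
                raise ValidationError(
                    f"allele outside declared pair at locus {locus.id!r} for "
                    f"individual {individual_ids[i]!r}: {a}{b}"
                )
            calls[i, j] = (a == locus.allele2) + (b == locus.allele2)
    return loci, calls


def _genotype_string(call: int, locus: Locus, missing: str) -> str:
    if call == MISSING:
        return missing
    if call == HOM1:
        return locus.allele1 + locus.allele1
    if call == HET:
        return locus.allele1 + locus.allele2
    return locus.allele2 + locus.allele2


# ---------------------------------------------------------------------------
# tabular dialect


def _read_tabular(path, panel) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise GenotypeParseError(f"{path}: not parseable as tabular genotypes: {exc}") from exc
    fixed = ["id", "group", "sample_type"]
    if list(df.columns[:3]) != fixed:
        raise GenotypeParseError(
            f"{path}: tabular header must start with {fixed}, got {list(df.columns[:3])}"
        )
    locus_ids = list(df.columns[3:])
    individuals = [
        Individual(id=row.id, group=row.group, sample_type=row.sample_type)
        for row in df[fixed].itertuples()
    ]
    geno = df[locus_ids].to_numpy(dtype=object) if locus_ids else np.empty((len(df), 0), object)
    pairs = np.full((len(df), len(locus_ids), 2), "-", dtype=object)
    for i in range(len(df)):
        for j in range(len(locus_ids)):
            g = geno[i, j]
            if not isinstance(g, str) or len(g) != 2:
                raise GenotypeParseError(
                    f"{path}: line {i + 2}: malformed genotype {g!r} at locus {locus_ids[j]!r}"
                )
            pairs[i, j] = (g[0], g[1])
    loci, calls = _calls_from_allele_pairs(
        pairs, locus_ids, [ind.id for ind in individuals],
        _resolve_panel(panel, locus_ids), frozenset("-"),
    )
    return GenotypeMatrix(loci=loci, individuals=individuals, calls=calls)


def _write_tabular(matrix: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(["id", "group", "sample_type"] + matrix.locus_ids) + "\n")
        for i, ind in enumerate(matrix.individuals):
            row = [ind.id, ind.group, ind.sample_type] + [
                _genotype_string(int(matrix.calls[i, j]), loc, "--")
                for j, loc in enumerate(matrix.loci)
            ]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# PLINK PED/MAP


def _ped_map_paths(path) -> tuple[Path, Path]:
    p = Path(path)
    if p.suffix in {".ped", ".map"}:
        p = p.with_suffix("")
    return p.with_suffix(".ped"), p.with_suffix(".map")


def _read_ped_map(path, panel) -> GenotypeMatrix:
    ped_path, map_path = _ped_map_paths(path)
    map_rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise GenotypeParseError(f"{map_path}: line {lineno}: expected 4 fields")
            map_rows.append(parts)
    locus_ids = [r[1] for r in map_rows]

    individuals, rows = [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * len(locus_ids):
                raise GenotypeParseError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * len(locus_ids)} fields, "
                    f"got {len(parts)}"
                )
            individuals.append(
                Individual(id=parts[1], group=parts[0], sample_type=parts[5])
            )
            rows.append(parts[6:])
    pairs = np.array(rows, dtype=object).reshape(len(rows), len(locus_ids), 2)
    resolved = _resolve_panel(panel, locus_ids)
    loci, calls = _calls_from_allele_pairs(
        pairs, locus_ids, [ind.id for ind in individuals], resolved, frozenset("0"),
    )
    if resolved is None:
        # adopt chromosome/position from the MAP file
        loci = [
            Locus(id=l.id, chromosome=r[0], position=max(int(r[3]), 1),
                  allele1=l.allele1, allele2=l.allele2)
            for l, r in zip(loci, map_rows)
        ]
    return GenotypeMatrix(loci=loci, individuals=individuals, calls=calls)


def _write_ped_map(matrix: GenotypeMatrix, path) -> None:
    ped_path, map_path = _ped_map_paths(path)
    with open(map_path, "w") as fh:
        for loc in matrix.loci:
            fh.write(f"{loc.chromosome} {loc.id} 0 {loc.position}\n")
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(matrix.individuals):
            fields = [ind.group, ind.id, "0", "0", "0", ind.sample_type]
            for j, loc in enumerate(matrix.loci):
                g = _genotype_string(int(matrix.calls[i, j]), loc, "00")
                fields.extend([g[0], g[1]])
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# VCF v4.2 (GT only)

_SAMPLE_META = re.compile(r"^##SAMPLE=<ID=([^,>]+),Group=([^,>]+),Type=([^,>]+)>")


def _read_vcf(path, panel) -> GenotypeMatrix:
    from cyvcf2 import VCF  # deferred: htslib import is comparatively heavy

    vcf = VCF(str(path))
    meta: dict[str, tuple[str, str]] = {}
    for line in vcf.raw_header.splitlines():
        m = _SAMPLE_META.match(line)
        if m:
            meta[m.group(1)] = (m.group(2), m.group(3))
    individuals = [
        Individual(id=s, group=meta.get(s, ("unknown", "tissue"))[0],
                   sample_type=meta.get(s, ("unknown", "tissue"))[1])
        for s in vcf.samples
    ]
    loci: list[Locus] = []
    columns: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValidationError(
                f"locus {var.ID or f'{var.CHROM}:{var.POS}'!r}: site is not biallelic "
                f"(ALT={var.ALT})"
            )
        loci.append(
            Locus(id=var.ID or f"{var.CHROM}:{var.POS}", chromosome=var.CHROM,
                  position=var.POS, allele1=var.REF, allele2=var.ALT[0])
        )
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        col = np.array([{0: HOM1, 1: HET, 3: HOM2}.get(t, MISSING) for t in var.gt_types],
                       dtype=CALL_DTYPE)
        columns.append(col)
    calls = (
        np.column_stack(columns) if columns
        else np.empty((len(individuals), 0), dtype=CALL_DTYPE)
    )
    out = GenotypeMatrix(loci=loci, individuals=individuals, calls=calls)
    if panel is not None:
        resolved = _resolve_panel(panel, out.locus_ids)
        for got, want in zip(out.loci, resolved):
            if (got.allele1, got.allele2) != (want.allele1, want.allele2):
                raise ValidationError(
                    f"locus {got.id!r}: VCF REF/ALT {got.allele1}/{got.allele2} disagree "
                    f"with panel alleles {want.allele1}/{want.allele2}"
                )
        out.loci = resolved
    return out


_VCF_GT = {HOM1: "0/0", HET: "0/1", HOM2: "1/1", MISSING: "./."}


def _write_vcf(matrix: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(l.chromosome for l in matrix.loci):
            fh.write(f"##contig=<ID={chrom}>\n")
        for ind in matrix.individuals:
            fh.write(f"##SAMPLE=<ID={ind.id},Group={ind.group},Type={ind.sample_type}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        header += matrix.individual_ids
        fh.write("\t".join(header) + "\n")
        # records are emitted in panel order so that a write/read cycle is the
        # identity; callers wanting coordinate-sorted VCF should sort the panel
        for j in range(matrix.n_loci):
            loc = matrix.loci[j]
            row = [loc.chromosome, str(loc.position), loc.id, loc.allele1, loc.allele2,
                   ".", "PASS", ".", "GT"]
            row += [_VCF_GT[int(c)] for c in matrix.calls[:, j]]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# public API

_READERS = {"tabular": _read_tabular, "ped-map": _read_ped_map, "vcf": _read_vcf}
_WRITERS = {"tabular": _write_tabular, "ped-map": _write_ped_map, "vcf": _write_vcf}


def read_genotypes(path: str | os.PathLike, format: str = "tabular", panel=None) -> GenotypeMatrix:
    """Read a genotype matrix.

    Parameters
    ----------
    path
        Input file (for ``ped-map``, either of the pair or the common prefix).
    format
        One of ``tabular``, ``ped-map``, ``vcf``.
    panel
        Optional panel definition (list of :class:`Locus` or path to a panel
        TSV) declaring allele order per locus.
    """
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    return _READERS[format](path, panel)


def write_genotypes(matrix: GenotypeMatrix, path: str | os.PathLike, format: str = "tabular") -> None:
    """Write `matrix` to `path` in the given dialect (inverse of read_genotypes)."""
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    _WRITERS[format](matrix, path)
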