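"""Variant catalogs: parsing, region classification, and summaries.

A catalog is a table of single-nucleotide variants annotated against one
gene.  Each record carries either a resolved region class (intronic, UTR,
coding synonymous / non-synonymous) or a genomic position from which the
class can be derived given a :class:`GeneAnnotation` and the coding
sequence.  Non-synonymous records additionally carry a protein-change
token such as ``A147T`` (one-letter reference amino acid, 1-based residue
position, one-letter alternative).

All coordinates are 1-based and intervals are closed on both ends,
matching the residue numbering conventions of the structural literature.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .errors import (
    AnnotationGapError,
    ConfigurationError,
    InputError,
    ParseError,
)

REGION_CLASSES = (
    "intronic",
    "utr",
    "coding_synonymous",
    "coding_nonsynonymous",
)

_AA1 = set("ACDEFGHIKLMNPQRSTVWY")
_TOKEN_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (half-up), as tables print."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _check_intervals(name: str, intervals: Sequence[tuple[int, int]]) -> None:
    prev_end = 0
    for start, end in intervals:
        if start > end:
            raise InputError(f"{name}: inverted interval ({start}, {end})")
        if start <= prev_end:
            raise InputError(f"{name}: intervals overlap or are unsorted at {start}")
        prev_end = end


@dataclass(frozen=True)
class GeneAnnotation:
    """Exon/intron/UTR structure of one transcript on the plus strand."""

    transcript_id: str
    protein_length: int
    cds_intervals: tuple[tuple[int, int], ...]
    utr5_intervals: tuple[tuple[int, int], ...] = ()
    utr3_intervals: tuple[tuple[int, int], ...] = ()
    intron_intervals: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        for name in ("cds_intervals", "utr5_intervals", "utr3_intervals", "intron_intervals"):
            _check_intervals(name, getattr(self, name))
        cds_len = self.cds_length
        if cds_len % 3 != 0:
            raise InputError(f"CDS length {cds_len} not divisible by 3")
        if self.protein_length != cds_len // 3 - 1:
            raise InputError(
                f"protein_length {self.protein_length} inconsistent with CDS "
                f"length {cds_len} (expected {cds_len // 3 - 1}, stop excluded)"
            )

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.cds_intervals)

    def cds_offset(self, position: int) -> int | None:
        """0-based offset of a genomic position within the spliced CDS."""
        offset = 0
        for start, end in self.cds_intervals:
            if start <= position <= end:
                return offset + position - start
            offset += end - start + 1
        return None


@dataclass
class VariantRecord:
    """One catalog entry; at least one of position / region_class is set."""

    id: str = "n/a"
    position: int | None = None
    region_class: str | None = None
    protein_change: str | None = None
    maf: float | None = None
    ref_base: str | None = None
    alt_base: str | None = None

    def __post_init__(self) -> None:
        if self.position is None and self.region_class is None:
            raise InputError(
                f"variant {self.id!r}: neither position nor region_class given"
            )
        if self.region_class is not None and self.region_class not in REGION_CLASSES:
            raise InputError(
                f"variant {self.id!r}: unknown region class {self.region_class!r}"
            )
        if self.maf is not None and not 0.0 <= self.maf <= 1.0:
            raise InputError(f"variant {self.id!r}: MAF {self.maf} outside [0, 1]")


@dataclass(frozen=True)
class ProteinVariant:
    """A parsed amino-acid substitution."""

    ref_aa: str
    position: int
    alt_aa: str
    source_id: str = "n/a"

    @property
    def token(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass
class DistributionSummary:
    """Per-class counts with one-decimal percentages of the total."""

    counts: dict[str, int]
    percentages: dict[str, float]
    total: int

    def to_tsv(self) -> str:
        lines = ["class\tcount\tpercent"]
        for cls in REGION_CLASSES:
            if cls in self.counts:
                lines.append(f"{cls}\t{self.counts[cls]}\t{self.percentages[cls]}")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {"total": self.total, "counts": self.counts, "percentages": self.percentages},
            indent=2,
        )


@dataclass
class LoadResult:
    """Parsed records plus an audit trail of rejected rows."""

    records: list[VariantRecord]
    rejects: list[dict] = field(default_factory=list)


DEFAULT_DIALECT: Mapping[str, str] = {
    "id": "id",
    "position": "position",
    "region_class": "region_class",
    "protein_change": "protein_change",
    "maf": "maf",
    "ref_base": "ref_base",
    "alt_base": "alt_base",
}


def load_variant_table(path: str | Path, dialect: Mapping[str, str] | None = None) -> LoadResult:
    """Read a TSV variant table; malformed rows go to the rejects list.

    ``dialect`` maps canonical field names to the file's column names.
    Only ``id`` plus one of ``position`` / ``region_class`` must resolve;
    all other fields are optional.
    """
    colmap = dict(DEFAULT_DIALECT)
    if dialect:
        colmap.update(dialect)
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise InputError(f"{path}: empty file")
        header = set(reader.fieldnames)
        if colmap["position"] not in header and colmap["region_class"] not in header:
            raise ConfigurationError(
                f"{path}: neither {colmap['position']!r} nor "
                f"{colmap['region_class']!r} column present"
            )
        result = LoadResult(records=[])
        for i, row in enumerate(reader, start=2):
            try:
                result.records.append(_record_from_row(row, colmap))
            except (InputError, ValueError) as exc:
                result.rejects.append({"line": i, "reason": str(exc), "row": dict(row)})
    if not result.records and not result.rejects:
        raise InputError(f"{path}: no data rows")
    return result


def _record_from_row(row: Mapping[str, str], colmap: Mapping[str, str]) -> VariantRecord:
    def get(key: str) -> str | None:
        value = row.get(colmap[key])
        if value is None or value.strip() == "":
            return None
        return value.strip()

    pos = get("position")
    maf = get("maf")
    return VariantRecord(
        id=get("id") or "n/a",
        position=int(pos) if pos is not None else None,
        region_class=get("region_class"),
        protein_change=get("protein_change"),
        maf=float(maf) if maf is not None else None,
        ref_base=get("ref_base"),
        alt_base=get("alt_base"),
    )


def classify_region(
    variant: VariantRecord,
    annotation: GeneAnnotation,
    cds_sequence: str,
) -> str:
    """Resolve a positioned variant to its region class.

    Coding positions are split into synonymous / non-synonymous by
    translating the reference and alternative codon; this requires the
    record to carry ``ref_base`` and ``alt_base``.
    """
    if variant.position is None:
        raise InputError(f"variant {variant.id!r} carries no genomic position")
    pos = variant.position
    for start, end in annotation.intron_intervals:
        if start <= pos <= end:
            return "intronic"
    for intervals in (annotation.utr5_intervals, annotation.utr3_intervals):
        for start, end in intervals:
            if start <= pos <= end:
                return "utr"
    offset = annotation.cds_offset(pos)
    if offset is None:
        raise AnnotationGapError(
            f"position {pos} outside all annotated intervals of "
            f"{annotation.transcript_id}"
        )
    if variant.alt_base is None:
        raise InputError(
            f"variant {variant.id!r} in CDS but lacks an alternative allele"
        )
    codon_start = offset - offset % 3
    ref_codon = cds_sequence[codon_start : codon_start + 3].upper()
    if variant.ref_base is not None and ref_codon[offset % 3] != variant.ref_base.upper():
        raise InputError(
            f"variant {variant.id!r}: reference allele {variant.ref_base!r} "
            f"disagrees with CDS base {ref_codon[offset % 3]!r} at offset {offset}"
        )
    alt_codon = (
        ref_codon[: offset % 3] + variant.alt_base.upper() + ref_codon[offset % 3 + 1 :]
    )
    same = str(Seq(ref_codon).translate()) == str(Seq(alt_codon).translate())
    return "coding_synonymous" if same else "coding_nonsynonymous"


def summarize_distribution(variants: Iterable[VariantRecord]) -> DistributionSummary:
    """Count class-resolved records and compute one-decimal percentages.

    The 5' and 3' UTR classes are pooled under ``utr``.
    """
    counts = {cls: 0 for cls in REGION_CLASSES}
    total = 0
    for v in variants:
        if v.region_class is None:
            raise InputError(f"variant {v.id!r} has no resolved region class")
        counts[v.region_class] += 1
        total += 1
    if total == 0:
        raise InputError("empty variant list")
    percentages = {
        cls: round_half_up(100.0 * n / total, 1) for cls, n in counts.items()
    }
    return DistributionSummary(counts=counts, percentages=percentages, total=total)


def map_protein_variants(variants: Iterable[VariantRecord]) -> list[ProteinVariant]:
    """Parse ``<refAA><position><altAA>`` tokens of non-synonymous records."""
    out: list[ProteinVariant] = []
    for v in variants:
        if v.protein_change is None:
            continue
        out.append(parse_protein_token(v.protein_change, source_id=v.id))
    return out


def parse_protein_token(token: str, source_id: str = "n/a") -> ProteinVariant:
    m = _TOKEN_RE.match(token.strip())
    if not m:
        raise ParseError(f"malformed protein-change token {token!r}")
    ref_aa, pos_s, alt_aa = m.group(1).upper(), m.group(2), m.group(3).upper()
    position = int(pos_s)
    if ref_aa not in _AA1 or alt_aa not in _AA1:
        raise ParseError(f"unknown amino-acid letter in token {token!r}")
    if position < 1:
        raise ParseError(f"non-positive residue position in token {token!r}")
    if ref_aa == alt_aa:
        raise ParseError(f"token {token!r} is not a substitution")
    return ProteinVariant(ref_aa=ref_aa, position=position, alt_aa=alt_aa, source_id=source_id)


def multiallelic_residues(
    pvs: Iterable[ProteinVariant],
) -> dict[int, list[ProteinVariant]]:
    """Residue positions carrying two or more distinct substitutions."""
    by_pos: dict[int, list[ProteinVariant]] = {}
    for pv in pvs:
        by_pos.setdefault(pv.position, []).append(pv)
    return {
        pos: sorted(entries, key=lambda p: p.alt_aa)
        for pos, entries in sorted(by_pos.items())
        if len({p.alt_aa for p in entries}) >= 2
    }


@dataclass
class MafPartition:
    """Three-way split of a catalog by minor allele frequency."""

    retained: list[VariantRecord]
    rare: list[VariantRecord]
    unknown: list[VariantRecord]


def filter_by_maf(variants: Iterable[VariantRecord], min_maf: float) -> MafPartition:
    """Partition records: retained (maf >= min_maf), rare, or unknown maf."""
    if not 0.0 <= min_maf <= 1.0:
        raise InputError(f"min_maf {min_maf} outside [0, 1]")
    part = MafPartition(retained=[], rare=[], unknown=[])
    for v in variants:
        if v.maf is None:
            part.unknown.append(v)
        elif v.maf >= min_maf:
            part.retained.append(v)
        else:
            part.rare.append(v)
    return part
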