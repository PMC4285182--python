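"""Readers and writers for the tabular and genomic formats the pipeline touches.

Internal coordinates are 1-based and inclusive on both ends, matching how
breakpoints are reported in the genetics literature (an interval
[32106204, 32167777] spans 61,574 bp).  BED input/output converts between
that convention and BED's 0-based half-open one at the boundary; GFF3 is
already 1-based inclusive and is used as-is.  Chromosome names are
normalized to ``chrN`` form on input.
"""
from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from ._util import chrom_sort_key

SEXES = frozenset({"female", "male", "unknown"})
GROUPS = frozenset({"case", "fertile_control", "cohort"})
SUBTYPES = frozenset({"primary_rm", "secondary_rm", "none"})
CNV_TYPES = frozenset({"deletion", "duplication"})

CNV_CALL_COLUMNS = (
    "sample_id",
    "caller_id",
    "chrom",
    "start",
    "end",
    "cnv_type",
    "copy_number",
    "confidence",
)
SAMPLE_SHEET_COLUMNS = ("sample_id", "sex", "group", "subtype", "country")


class ParseError(ValueError):
    """A line of an input file could not be parsed."""


class ValidationError(ValueError):
    """A parsed record violates a domain invariant."""


def normalize_chrom(chrom: str) -> str:
    """Normalize mixed dialects ('5', 'Chr5', 'chr5') to 'chr5'."""
    body = chrom.strip()
    if body.lower().startswith("chr"):
        body = body[3:]
    if not body:
        raise ValidationError(f"empty chromosome name: {chrom!r}")
    return "chr" + body


@dataclass(frozen=True)
class Sample:
    """One study subject from the sample sheet."""

    sample_id: str
    sex: str
    group: str
    subtype: str = "none"
    country: str = ""

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r} for {self.sample_id}")
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r} for {self.sample_id}")
        if self.subtype not in SUBTYPES:
            raise ValidationError(
                f"unknown subtype {self.subtype!r} for {self.sample_id}"
            )
        if self.subtype != "none" and self.group != "case":
            raise ValidationError(
                f"sample {self.sample_id}: subtype {self.subtype!r} is only valid "
                f"for group 'case', got group {self.group!r}"
            )


@dataclass(frozen=True)
class CnvCall:
    """One caller's CNV interval for one sample (1-based inclusive)."""

    sample_id: str
    caller_id: str
    chrom: str
    start: int
    end: int
    cnv_type: str
    copy_number: int | None = None
    confidence: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start > self.end:
            raise ValidationError(
                f"call {self.sample_id} {self.chrom}:{self.start}-{self.end}: "
                "end < start"
            )
        if self.start < 1:
            raise ValidationError(f"start must be >= 1, got {self.start}")
        if self.cnv_type not in CNV_TYPES:
            raise ValidationError(f"unknown cnv_type {self.cnv_type!r}")
        if self.copy_number is not None:
            if self.copy_number < 0:
                raise ValidationError("copy_number must be >= 0")
            if self.copy_number == 2:
                raise ValidationError(
                    f"call {self.sample_id} {self.chrom}:{self.start}-{self.end}: "
                    "copy_number 2 is not a variant"
                )
            implied = "deletion" if self.copy_number < 2 else "duplication"
            if implied != self.cnv_type:
                raise ValidationError(
                    f"copy_number {self.copy_number} inconsistent with "
                    f"cnv_type {self.cnv_type!r}"
                )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval (1-based inclusive)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start > self.end:
            raise ValidationError(f"gene {self.gene_id}: end < start")
        if self.start < 1:
            raise ValidationError(f"gene {self.gene_id}: coordinate underflow")
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")


# ---------------------------------------------------------------------------
# CNV call tables


def _parse_optional_int(token: str) -> int | None:
    return None if token in ("", ".", "NA") else int(token)


def _parse_optional_float(token: str) -> float | None:
    return None if token in ("", ".", "NA") else float(token)


_RAWCNV_INTERVAL = re.compile(r"^(\S+?):(\d+)-(\d+)$")
_RAWCNV_CN = re.compile(r"\bcn=(\d+)\b")


def _parse_rawcnv_line(line: str, lineno: int) -> CnvCall:
    """Parse a PennCNV 'rawcnv'-style line.

    Expected shape: ``chr5:32106204-32167777 numsnp=30 cn=3 SAMPLE ...`` —
    an interval token, key=value tokens (``cn=`` mandatory), and the sample
    identifier as the first bare token.  The CNV type is inferred from the
    copy number.
    """
    tokens = line.split()
    m = _RAWCNV_INTERVAL.match(tokens[0])
    if m is None:
        raise ParseError(f"line {lineno}: bad interval token {tokens[0]!r}")
    cn_match = _RAWCNV_CN.search(line)
    if cn_match is None:
        raise ParseError(f"line {lineno}: missing cn= field")
    cn = int(cn_match.group(1))
    sample_id = next((t for t in tokens[1:] if "=" not in t), None)
    if sample_id is None:
        raise ParseError(f"line {lineno}: missing sample identifier")
    if cn == 2:
        raise ValidationError(f"line {lineno}: cn=2 is not a variant call")
    cnv_type = "deletion" if cn < 2 else "duplication"
    return CnvCall(
        sample_id=sample_id,
        caller_id="penncnv",
        chrom=m.group(1),
        start=int(m.group(2)),
        end=int(m.group(3)),
        cnv_type=cnv_type,
        copy_number=cn,
    )


def read_cnv_calls(path: str | Path, dialect: str = "tsv") -> list[CnvCall]:
    """Read per-sample, per-caller CNV calls.

    ``dialect='tsv'`` expects a header with columns
    ``sample_id caller_id chrom start end cnv_type copy_number confidence``;
    ``dialect='penncnv_rawcnv'`` accepts PennCNV raw output lines.  Records
    are returned sorted by (sample_id, chrom, start).
    """
    if dialect not in {"tsv", "penncnv_rawcnv"}:
        raise ValueError(f"unsupported dialect {dialect!r}")
    path = Path(path)
    calls: list[CnvCall] = []
    with path.open() as fh:
        if dialect == "penncnv_rawcnv":
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                calls.append(_parse_rawcnv_line(line, lineno))
        else:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader, None)
            if header is None:
                return []
            if tuple(h.strip() for h in header[:6]) != CNV_CALL_COLUMNS[:6]:
                raise ParseError(
                    f"line 1: expected header starting with "
                    f"{CNV_CALL_COLUMNS[:6]}, got {tuple(header[:6])}"
                )
            for lineno, row in enumerate(reader, start=2):
                if not row or (len(row) == 1 and not row[0].strip()):
                    continue
                if len(row) < 6:
                    raise ParseError(f"line {lineno}: expected >=6 fields, got {len(row)}")
                try:
                    calls.append(
                        CnvCall(
                            sample_id=row[0],
                            caller_id=row[1],
                            chrom=row[2],
                            start=int(row[3]),
                            end=int(row[4]),
                            cnv_type=row[5],
                            copy_number=_parse_optional_int(row[6]) if len(row) > 6 else None,
                            confidence=_parse_optional_float(row[7]) if len(row) > 7 else None,
                        )
                    )
                except ValidationError:
                    raise
                except ValueError as exc:
                    raise ParseError(f"line {lineno}: {exc}") from exc
    calls.sort(key=lambda c: (c.sample_id, chrom_sort_key(c.chrom), c.start))
    return calls


def write_cnv_calls(calls: Iterable[CnvCall], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CNV_CALL_COLUMNS)
        for c in calls:
            writer.writerow(
                [
                    c.sample_id,
                    c.caller_id,
                    c.chrom,
                    c.start,
                    c.end,
                    c.cnv_type,
                    "" if c.copy_number is None else c.copy_number,
                    "" if c.confidence is None else repr(c.confidence),
                ]
            )


# ---------------------------------------------------------------------------
# Sample sheets


def read_sample_sheet(path: str | Path) -> list[Sample]:
    """Read the sample sheet; duplicate sample ids are rejected."""
    samples: list[Sample] = []
    seen: set[str] = set()
    with Path(path).open() as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(h.strip() for h in header) != SAMPLE_SHEET_COLUMNS:
            raise ParseError(
                f"expected header {SAMPLE_SHEET_COLUMNS}, got "
                f"{None if header is None else tuple(header)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 5:
                raise ParseError(f"line {lineno}: expected 5 fields, got {len(row)}")
            sample = Sample(*[t.strip() for t in row[:5]])
            if sample.sample_id in seen:
                raise ValidationError(
                    f"line {lineno}: duplicate sample_id {sample.sample_id!r}"
                )
            seen.add(sample.sample_id)
            samples.append(sample)
    return samples


def write_sample_sheet(samples: Iterable[Sample], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SAMPLE_SHEET_COLUMNS)
        for s in samples:
            writer.writerow([s.sample_id, s.sex, s.group, s.subtype, s.country])


def group_sizes(samples: Sequence[Sample]) -> dict[str, int]:
    """Recruitment count per study group."""
    counts: dict[str, int] = {}
    for s in samples:
        counts[s.group] = counts.get(s.group, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Gene annotation (BED6 / GFF3)

_GFF_ID = re.compile(r"(?:^|;)\s*ID=([^;]+)")
_GFF_NAME = re.compile(r"(?:^|;)\s*Name=([^;]+)")


def read_gene_annotation(
    path: str | Path,
    format: str = "bed",
    feature_types: Sequence[str] = ("gene",),
) -> list[GeneAnnotation]:
    """Read gene intervals from BED6 or GFF3.

    BED half-open 0-based coordinates are converted to 1-based inclusive;
    GFF3 coordinates are used as-is.  For GFF3 only records whose feature
    type is in ``feature_types`` are kept.
    """
    if format not in {"bed", "gff3"}:
        raise ValueError(f"unsupported format {format!r}")
    genes: list[GeneAnnotation] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if format == "bed":
                    if len(fields) < 4:
                        raise ParseError(
                            f"line {lineno}: BED needs >=4 columns, got {len(fields)}"
                        )
                    chrom, start0, end0, name = fields[:4]
                    strand = fields[5] if len(fields) >= 6 else "."
                    start0, end0 = int(start0), int(end0)
                    if start0 < 0 or end0 <= start0:
                        raise ValidationError(
                            f"line {lineno}: bad BED interval [{start0}, {end0})"
                        )
                    genes.append(
                        GeneAnnotation(name, chrom, start0 + 1, end0, strand)
                    )
                else:
                    if len(fields) < 9:
                        raise ParseError(
                            f"line {lineno}: GFF3 needs 9 columns, got {len(fields)}"
                        )
                    chrom, _source, ftype, start, end, _score, strand, _frame, attrs = (
                        fields[:9]
                    )
                    if ftype not in feature_types:
                        continue
                    m = _GFF_ID.search(attrs) or _GFF_NAME.search(attrs)
                    gene_id = m.group(1) if m else attrs
                    gene_id = re.sub(r"^gene:", "", gene_id)
                    genes.append(
                        GeneAnnotation(
                            gene_id,
                            chrom,
                            int(start),
                            int(end),
                            strand if strand in {"+", "-"} else ".",
                        )
                    )
            except ValueError as exc:
                if isinstance(exc, (ParseError, ValidationError)):
                    raise
                raise ParseError(f"line {lineno}: {exc}") from exc
    return genes


def write_gene_annotation(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    """Write genes as BED6 (converting back to 0-based half-open)."""
    with Path(path).open("w", newline="") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n"
            )
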