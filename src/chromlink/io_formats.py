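"""Table and locus-string input/output with one internal coordinate convention.

All coordinates held in memory are 0-based half-open (BED convention).
Display strings — browser-style locus strings such as ``chr13:21045571-21046978``
— are 1-based inclusive, and :func:`parse_locus` / :func:`format_locus` are an
exact inverse pair between the two conventions.

Three table kinds flow through the pipeline:

* gene tables (BED-like TSV or GTF-lite) → :class:`GeneRecord`
* peak tables (signed, mark-labelled, lncRNA-attributed) → :class:`Peak`
* contact tables (lncRNA-attributed, with experiment provenance) → :class:`Contact`

Readers are faithful: duplicate rows are kept, record order is file order.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "GenomicInterval",
    "GeneRecord",
    "Peak",
    "Contact",
    "LocusParseError",
    "TableFormatError",
    "DEFAULT_MARKS",
    "parse_locus",
    "format_locus",
    "read_gene_table",
    "read_peak_table",
    "read_contact_table",
    "write_gene_table",
    "write_peak_table",
    "write_contact_table",
]

#: Default histone-mark vocabulary: the eight marks that appear in the peak
#: database's published examples plus two common marks filling the remaining
#: slots of its ten-mark catalogue.  Override via the ``marks`` argument of
#: :func:`read_peak_table` or :class:`~chromlink.synthetic.SyntheticConfig`.
DEFAULT_MARKS: tuple[str, ...] = (
    "H3K27ac",
    "H3K27me3",
    "H3K36me3",
    "H3K4me1",
    "H3K4me2",
    "H3K4me3",
    "H3K79me2",
    "H3K9me3",
    "H3K9ac",
    "H4K20me1",
)


class LocusParseError(ValueError):
    """Raised for a malformed or inverted locus string."""


class TableFormatError(ValueError):
    """Raised for a malformed table row; message carries the 1-based line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome-anchored coordinate range, 0-based half-open.

    Invariants: ``0 <= start < end`` and ``chrom`` non-empty.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 base (same chromosome)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GeneRecord:
    """One gene of one annotation version.

    ``gene_id`` is a versioned Ensembl-style identifier (``ENSG....11``);
    text after the last ``.`` is the version suffix, stripped for
    version-insensitive ID comparison.  ``source_tag`` marks which of the
    two annotations the record came from ("A" or "B").
    """

    interval: GenomicInterval
    gene_id: str
    gene_name: str
    strand: str = "."
    source_tag: str = "A"

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def unversioned_id(self) -> str:
        return strip_version(self.gene_id)


def strip_version(gene_id: str) -> str:
    """Drop the version suffix (text after the last '.') of a gene identifier."""
    head, sep, _ = gene_id.rpartition(".")
    return head if sep else gene_id


@dataclass(frozen=True)
class Peak:
    """A signed histone-modification peak attributed to one lncRNA.

    ``sign`` is "+" when the mark's signal correlates positively with the
    lncRNA's expression and "-" when negatively.
    """

    interval: GenomicInterval
    mark: str
    sign: str
    peak_id: str
    lncrna_id: str
    associated_gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sign not in {"+", "-"}:
            raise ValueError(f"peak sign must be '+' or '-', got {self.sign!r}")


@dataclass(frozen=True)
class Contact:
    """An experimentally detected RNA-chromatin contact of one lncRNA."""

    interval: GenomicInterval
    lncrna_id: str
    experiment_id: str


_LOCUS_RE = re.compile(r"^([^:\s]+):(\d+)-(\d+)$")


def parse_locus(text: str) -> GenomicInterval:
    """Parse a browser-style locus string into an internal interval.

    The display form is 1-based inclusive (``chrX:23456-24253566``); the
    returned interval is 0-based half-open.  Thousands separators (commas)
    are tolerated and stripped.

    Raises
    ------
    LocusParseError
        If the string is malformed or the first coordinate exceeds the second.
    """
    cleaned = text.strip().replace(",", "")
    m = _LOCUS_RE.match(cleaned)
    if m is None:
        raise LocusParseError(f"malformed locus string: {text!r}")
    chrom, first, second = m.group(1), int(m.group(2)), int(m.group(3))
    if first < 1 or first > second:
        raise LocusParseError(
            f"locus {text!r}: coordinates must satisfy 1 <= first <= second"
        )
    return GenomicInterval(chrom, first - 1, second)


def format_locus(iv: GenomicInterval) -> str:
    """Render an internal interval in 1-based inclusive display form."""
    return f"{iv.chrom}:{iv.start + 1}-{iv.end}"


# -- sign normalisation: tables in the wild carry either the ASCII hyphen or
#    the Unicode minus; internally the sign is always ASCII.
_SIGN_MAP = {"+": "+", "-": "-", "−": "-", "–": "-"}


def _normalize_sign(raw: str, lineno: int) -> str:
    sign = _SIGN_MAP.get(raw.strip())
    if sign is None:
        raise TableFormatError(f"line {lineno}: invalid sign {raw!r} (expected '+' or '-')")
    return sign


def _rows(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) for non-comment, non-blank lines."""
    with open(path, newline="") as handle:
        for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or (row[0].startswith("#")):
                continue
            if len(row) == 1 and not row[0].strip():
                continue
            yield lineno, row


def _parse_coord(raw: str, lineno: int, what: str) -> int:
    try:
        return int(raw)
    except ValueError:
        raise TableFormatError(f"line {lineno}: cannot parse {what} {raw!r}") from None


_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gene_table(
    path: str | Path,
    dialect: str = "bed_tsv",
    source_tag: str = "A",
) -> list[GeneRecord]:
    """Read a gene annotation table.

    Parameters
    ----------
    dialect
        ``"bed_tsv"`` — columns chrom, start, end, gene_id, gene_name
        [, strand]; coordinates taken as 0-based half-open as-is.
        ``"gtf_lite"`` — nine GTF columns, ``feature == "gene"`` rows only,
        ``gene_id``/``gene_name`` read from the attribute column; coordinates
        converted from 1-based inclusive to half-open.
    source_tag
        Annotation label ("A" or "B") stamped on every record.
    """
    if dialect not in {"bed_tsv", "gtf_lite"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    records: list[GeneRecord] = []
    for lineno, row in _rows(path):
        if dialect == "bed_tsv":
            if len(row) < 5:
                raise TableFormatError(
                    f"line {lineno}: expected >= 5 columns "
                    "(chrom, start, end, gene_id, gene_name[, strand]), got "
                    f"{len(row)}"
                )
            chrom = row[0]
            start = _parse_coord(row[1], lineno, "start")
            end = _parse_coord(row[2], lineno, "end")
            gene_id, gene_name = row[3], row[4]
            strand = row[5] if len(row) > 5 and row[5] else "."
        else:
            if len(row) < 9:
                raise TableFormatError(
                    f"line {lineno}: expected 9 GTF columns, got {len(row)}"
                )
            if row[2] != "gene":
                continue
            chrom = row[0]
            start = _parse_coord(row[3], lineno, "start") - 1  # 1-based -> half-open
            end = _parse_coord(row[4], lineno, "end")
            strand = row[6] if row[6] in {"+", "-"} else "."
            attrs = dict(_GTF_ATTR_RE.findall(row[8]))
            if "gene_id" not in attrs:
                raise TableFormatError(f"line {lineno}: missing gene_id attribute")
            gene_id = attrs["gene_id"]
            gene_name = attrs.get("gene_name", gene_id)
        try:
            iv = GenomicInterval(chrom, start, end)
        except ValueError as exc:
            raise TableFormatError(f"line {lineno}: {exc}") from None
        records.append(GeneRecord(iv, gene_id, gene_name, strand, source_tag))
    return records


def read_peak_table(
    path: str | Path,
    marks: Optional[Sequence[str]] = DEFAULT_MARKS,
) -> list[Peak]:
    """Read a peak table: chrom, start, end, mark, sign, peak_id, lncrna_id
    [, associated_gene].

    ``marks=None`` disables mark-vocabulary validation.  Duplicate rows are
    kept — the reader is faithful, deduplication is an analysis decision.
    """
    mark_set = set(marks) if marks is not None else None
    peaks: list[Peak] = []
    for lineno, row in _rows(path):
        if len(row) < 7:
            raise TableFormatError(
                f"line {lineno}: expected >= 7 columns "
                "(chrom, start, end, mark, sign, peak_id, lncrna_id"
                "[, associated_gene]), got "
                f"{len(row)}"
            )
        chrom = row[0]
        start = _parse_coord(row[1], lineno, "start")
        end = _parse_coord(row[2], lineno, "end")
        mark = row[3]
        if mark_set is not None and mark not in mark_set:
            raise TableFormatError(
                f"line {lineno}: unknown histone mark {mark!r}"
            )
        sign = _normalize_sign(row[4], lineno)
        gene = row[7] if len(row) > 7 and row[7] not in {"", "."} else None
        try:
            iv = GenomicInterval(chrom, start, end)
        except ValueError as exc:
            raise TableFormatError(f"line {lineno}: {exc}") from None
        peaks.append(Peak(iv, mark, sign, row[5], row[6], gene))
    return peaks


def read_contact_table(path: str | Path) -> list[Contact]:
    """Read a contact table: chrom, start, end, lncrna_id, experiment_id."""
    contacts: list[Contact] = []
    for lineno, row in _rows(path):
        if len(row) < 5:
            raise TableFormatError(
                f"line {lineno}: expected >= 5 columns "
                "(chrom, start, end, lncrna_id, experiment_id), got "
                f"{len(row)}"
            )
        chrom = row[0]
        start = _parse_coord(row[1], lineno, "start")
        end = _parse_coord(row[2], lineno, "end")
        try:
            iv = GenomicInterval(chrom, start, end)
        except ValueError as exc:
            raise TableFormatError(f"line {lineno}: {exc}") from None
        contacts.append(Contact(iv, row[3], row[4]))
    return contacts


def write_gene_table(records: Iterable[GeneRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        out = csv.writer(handle, delimiter="\t", lineterminator="\n")
        for r in records:
            out.writerow(
                [r.interval.chrom, r.interval.start, r.interval.end,
                 r.gene_id, r.gene_name, r.strand]
            )


def write_peak_table(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        out = csv.writer(handle, delimiter="\t", lineterminator="\n")
        for p in peaks:
            out.writerow(
                [p.interval.chrom, p.interval.start, p.interval.end,
                 p.mark, p.sign, p.peak_id, p.lncrna_id,
                 p.associated_gene if p.associated_gene is not None else "."]
            )


def write_contact_table(contacts: Iterable[Contact], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        out = csv.writer(handle, delimiter="\t", lineterminator="\n")
        for c in contacts:
            out.writerow(
                [c.interval.chrom, c.interval.start, c.interval.end,
                 c.lncrna_id, c.experiment_id]
            )
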