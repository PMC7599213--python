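"""On-disk formats and coordinate conventions.

Every interval in this package, in memory and on disk, is 0-based
half-open (BED-compatible).  FASTA case is load-bearing: lowercase means
"masked", ``N`` means "undetermined".  Alignments are exchanged as
PAF-style tab-separated lines with a ``cg:Z:`` cigar tag; query
coordinates are always on the forward strand of the query, regardless of
alignment strand.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

FASTA_WIDTH = 60
TABLE_MAGIC = "#nuiforge-table"
TABLE_VERSION = "v1"

_VALID_BASES = set("ACGTNacgtn")
# IUPAC ambiguity letters tolerated on ingest; anything else is an error.
_IUPAC_AMBIG = set("RYSWKMBDHVryswkmbdhv")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement, preserving case; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# sequences


@dataclass
class GenomeSequence:
    """A named sequence over {A,C,G,T,N} with lowercase = masked."""

    name: str
    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"empty sequence for record {self.name!r}")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def length(self) -> int:
        return len(self.bases)

    def masked_positions(self) -> set[int]:
        return {i for i, b in enumerate(self.bases) if b.islower()}


def _sanitize_bases(name: str, raw: str) -> tuple[str, int]:
    """Replace IUPAC ambiguity letters with N/n; reject anything else."""
    converted = 0
    if set(raw) <= _VALID_BASES:
        return raw, 0
    out = []
    for ch in raw:
        if ch in _VALID_BASES:
            out.append(ch)
        elif ch in _IUPAC_AMBIG:
            out.append("n" if ch.islower() else "N")
            converted += 1
        else:
            raise ValueError(f"record {name!r}: non-sequence character {ch!r}")
    return "".join(out), converted


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a FASTA file, preserving case and record order.

    IUPAC ambiguity letters are converted to N (count logged); any other
    character is an error, as are duplicate record names and empty files.
    """
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    total_converted = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record name {rec.id!r} in {path}")
        seen.add(rec.id)
        bases, n_conv = _sanitize_bases(rec.id, str(rec.seq))
        total_converted += n_conv
        records.append(GenomeSequence(name=rec.id, bases=bases))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if total_converted:
        logger.warning(
            "converted %d ambiguous IUPAC letters to N while reading %s",
            total_converted,
            path,
        )
    return records


def write_fasta(records: Iterable[GenomeSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.bases), FASTA_WIDTH):
                fh.write(rec.bases[i : i + FASTA_WIDTH] + "\n")


# ---------------------------------------------------------------------------
# alignments

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

# ops that consume query / reference, after =/X are folded into M
_Q_CONSUMING = {"M", "I"}
_R_CONSUMING = {"M", "D"}


@dataclass
class AlignmentBlock:
    """One pairwise alignment record (PAF dialect).

    Query coordinates are forward-strand regardless of ``strand``; for a
    ``-`` alignment the cigar walks the reverse complement of the query
    segment against the forward reference.
    """

    query_name: str
    query_length: int
    query_start: int
    query_end: int
    strand: str
    ref_name: str
    ref_length: int
    ref_start: int
    ref_end: int
    mapq: int
    is_primary: bool
    cigar: list[tuple[int, str]]

    def validate(self) -> None:
        if not (0 <= self.query_start < self.query_end <= self.query_length):
            raise ValueError(
                f"bad query interval {self.query_start}-{self.query_end} "
                f"(length {self.query_length}) for {self.query_name}"
            )
        if not (0 <= self.ref_start < self.ref_end <= self.ref_length):
            raise ValueError(
                f"bad reference interval {self.ref_start}-{self.ref_end} "
                f"(length {self.ref_length}) for {self.ref_name}"
            )
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        qlen = sum(n for n, op in self.cigar if op in _Q_CONSUMING)
        rlen = sum(n for n, op in self.cigar if op in _R_CONSUMING)
        if qlen != self.query_end - self.query_start:
            raise ValueError(
                f"cigar consumes {qlen} query bases but span is "
                f"{self.query_end - self.query_start} ({self.query_name})"
            )
        if rlen != self.ref_end - self.ref_start:
            raise ValueError(
                f"cigar consumes {rlen} reference bases but span is "
                f"{self.ref_end - self.ref_start} ({self.query_name})"
            )

    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for n, op in self.cigar)

    def to_paf_line(self) -> str:
        n_match = sum(n for n, op in self.cigar if op == "M")
        aln_len = sum(n for n, _ in self.cigar)
        tp = "P" if self.is_primary else "S"
        fields = [
            self.query_name,
            str(self.query_length),
            str(self.query_start),
            str(self.query_end),
            self.strand,
            self.ref_name,
            str(self.ref_length),
            str(self.ref_start),
            str(self.ref_end),
            str(n_match),
            str(aln_len),
            str(self.mapq),
            f"tp:A:{tp}",
            f"cg:Z:{self.cigar_string()}",
        ]
        return "\t".join(fields)


def parse_cigar(text: str) -> list[tuple[int, str]]:
    ops: list[tuple[int, str]] = []
    pos = 0
    for m in _CIGAR_RE.finditer(text):
        if m.start() != pos:
            raise ValueError(f"malformed cigar {text!r}")
        n, op = int(m.group(1)), m.group(2)
        if op in "=X":
            op = "M"
        if op not in "MID":
            raise ValueError(f"unsupported cigar op {op!r} in {text!r}")
        if ops and ops[-1][1] == op:
            ops[-1] = (ops[-1][0] + n, op)
        else:
            ops.append((n, op))
        pos = m.end()
    if pos != len(text) or not ops:
        raise ValueError(f"malformed cigar {text!r}")
    return ops


def parse_alignment(line: str) -> AlignmentBlock:
    """Parse one PAF line with a cg:Z: cigar tag into an AlignmentBlock."""
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise ValueError(f"alignment line has {len(fields)} fields, need >= 12")
    cigar = None
    is_primary = True
    for tag in fields[12:]:
        if tag.startswith("cg:Z:"):
            cigar = parse_cigar(tag[5:])
        elif tag.startswith("tp:A:"):
            is_primary = tag[5:] == "P"
    if cigar is None:
        raise ValueError("alignment line lacks a cg:Z: cigar tag")
    block = AlignmentBlock(
        query_name=fields[0],
        query_length=int(fields[1]),
        query_start=int(fields[2]),
        query_end=int(fields[3]),
        strand=fields[4],
        ref_name=fields[5],
        ref_length=int(fields[6]),
        ref_start=int(fields[7]),
        ref_end=int(fields[8]),
        mapq=int(fields[11]),
        is_primary=is_primary,
        cigar=cigar,
    )
    block.validate()
    return block


def read_alignments(path: str | Path) -> list[AlignmentBlock]:
    blocks = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                blocks.append(parse_alignment(line))
            except ValueError as exc:
                raise ValueError(f"{path}:{i}: {exc}") from exc
    return blocks


def write_alignments(blocks: Iterable[AlignmentBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(b.to_paf_line() + "\n")


# ---------------------------------------------------------------------------
# BED tracks


@dataclass
class BedRecord:
    chrom: str
    start: int
    end: int
    name: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"bad BED interval {self.chrom}:{self.start}-{self.end}")


def read_bed(path: str | Path) -> list[BedRecord]:
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{i}: BED line has fewer than 3 columns")
            name = parts[3] if len(parts) > 3 else "."
            records.append(BedRecord(parts[0], int(parts[1]), int(parts[2]), name))
    return records


def write_bed(records: Iterable[BedRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\n")


class IntervalSet:
    """Per-chromosome merged interval set with half-open overlap queries."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            by_chrom.setdefault(chrom, []).append((start, end))
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for chrom, ivs in by_chrom.items():
            merged: list[list[int]] = []
            for s, e in sorted(ivs):
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[chrom] = [s for s, _ in merged]
            self._ends[chrom] = [e for _, e in merged]

    @classmethod
    def from_bed(cls, records: Iterable[BedRecord]) -> "IntervalSet":
        return cls((r.chrom, r.start, r.end) for r in records)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) shares >= 1 base with any stored interval."""
        starts = self._starts.get(chrom)
        if not starts:
            return False
        i = bisect_right(starts, start)
        # interval starting at or before `start`
        if i > 0 and self._ends[chrom][i - 1] > start:
            return True
        # next interval, starting inside [start, end)
        return i < len(starts) and starts[i] < end


# ---------------------------------------------------------------------------
# versioned TSV tables

_NONE = "."


def _encode(value, ftype) -> str:
    if value is None:
        return _NONE
    if ftype is bool:
        return "true" if value else "false"
    if ftype is float:
        return repr(float(value))
    return str(value)


def _decode(text: str, ftype):
    if text == _NONE and ftype is not str:
        return None
    if ftype is bool:
        if text not in ("true", "false"):
            raise ValueError(f"bad boolean {text!r}")
        return text == "true"
    return ftype(text)


def _field_types(record_type) -> list[tuple[str, type]]:
    out = []
    for f in dataclasses.fields(record_type):
        t = f.type
        if isinstance(t, str):
            # resolve the common annotations used by our records
            t = {"str": str, "int": int, "float": float, "bool": bool,
                 "Optional[str]": str, "str | None": str}.get(t, str)
        out.append((f.name, t))
    return out


def write_table(records: Sequence, path: str | Path, record_type=None) -> None:
    """Write dataclass records as a versioned TSV; round-trips bit-exact."""
    if record_type is None:
        if not records:
            raise ValueError("record_type required for empty record lists")
        record_type = type(records[0])
    fields = _field_types(record_type)
    with open(path, "w") as fh:
        fh.write(
            f"{TABLE_MAGIC}\t{TABLE_VERSION}\t{record_type.__name__}"
            "\tcoords=0-based-half-open\n"
        )
        fh.write("\t".join(name for name, _ in fields) + "\n")
        for rec in records:
            fh.write(
                "\t".join(
                    _encode(getattr(rec, name), t) for name, t in fields
                )
                + "\n"
            )


def read_table(path: str | Path, record_type) -> list:
    fields = _field_types(record_type)
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3 or header[0] != TABLE_MAGIC:
            raise ValueError(f"{path}: not a nuiforge table")
        if header[1] != TABLE_VERSION:
            raise ValueError(f"{path}: unknown table version {header[1]!r}")
        if header[2] != record_type.__name__:
            raise ValueError(
                f"{path}: table holds {header[2]}, expected {record_type.__name__}"
            )
        columns = fh.readline().rstrip("\n").split("\t")
        if columns != [name for name, _ in fields]:
            raise ValueError(f"{path}: column header mismatch")
        for i, line in enumerate(fh, 3):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(fields):
                raise ValueError(
                    f"{path}:{i}: expected {len(fields)} columns, got {len(parts)}"
                )
            kwargs = {
                name: _decode(text, t)
                for (name, t), text in zip(fields, parts)
            }
            records.append(record_type(**kwargs))
    return records
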