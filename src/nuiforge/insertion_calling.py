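"""Per-sample insertion calling from assembly-to-reference alignments.

Two call paths: insertion runs inside a single alignment's cigar, and
gaps between adjacent alignments of the same query.  Insert size is
the query gap size minus the reference gap size; calls below the size
floor (default 10 bp) are not emitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .formats import AlignmentBlock, GenomeSequence, IntervalSet, revcomp

logger = logging.getLogger(__name__)

DEFAULT_MIN_SIZE = 10
DEFAULT_MIN_ANCHOR_LEN = 1000
DEFAULT_MAX_REF_GAP = 10000
DEFAULT_MIN_MAPQ = 20


@dataclass
class InsertionCall:
    """One per-sample insertion with reference footprint and query provenance.

    ``sequence`` holds the inserted bases in reference-forward orientation;
    its length equals the query gap, so
    ``insert_size == len(sequence) - (ref_end - ref_start)``.
    """

    sample_id: str
    haplotype_id: str
    chrom: str
    ref_start: int
    ref_end: int
    query_name: str
    query_start: int
    query_end: int
    strand: str
    sequence: str

    @property
    def insert_size(self) -> int:
        return len(self.sequence) - (self.ref_end - self.ref_start)

    @property
    def footprint(self) -> tuple[int, int]:
        """Reference footprint, zero-length footprints expanded to 1 bp."""
        if self.ref_end == self.ref_start:
            return self.ref_start, self.ref_start + 1
        return self.ref_start, self.ref_end

    def validate(self, min_size: int = DEFAULT_MIN_SIZE) -> None:
        if self.ref_end < self.ref_start:
            raise ValueError("negative reference footprint")
        if len(self.sequence) != self.query_end - self.query_start:
            raise ValueError("sequence length does not match query gap")
        if self.insert_size < min_size:
            raise ValueError(f"insert size {self.insert_size} below {min_size}")


def _assembly_index(assembly) -> dict[str, GenomeSequence]:
    if isinstance(assembly, dict):
        return assembly
    if isinstance(assembly, GenomeSequence):
        return {assembly.name: assembly}
    return {rec.name: rec for rec in assembly}


def call_within_alignment(
    block: AlignmentBlock,
    assembly,
    sample_id: str,
    haplotype_id: str = "1",
    min_size: int = DEFAULT_MIN_SIZE,
) -> list[InsertionCall]:
    """Emit one call per insertion cigar run of length >= min_size.

    The reference footprint of a within-alignment insertion is zero-length
    (the gap point).  For a ``-`` strand block the cigar walks the reverse
    complement of the query segment, so forward-query coordinates run
    backwards from ``query_end``.
    """
    if not block.is_primary:
        return []
    seqs = _assembly_index(assembly)
    if block.query_name not in seqs:
        raise KeyError(f"query {block.query_name!r} not found in assembly")
    qseq = seqs[block.query_name].bases
    calls = []
    rpos = block.ref_start
    c = 0  # offset walked within the (strand-oriented) query segment
    for length, op in block.cigar:
        if op == "M":
            rpos += length
            c += length
        elif op == "D":
            rpos += length
        else:  # I
            if length >= min_size:
                if block.strand == "+":
                    qs = block.query_start + c
                    qe = qs + length
                    seq = qseq[qs:qe]
                else:
                    qe = block.query_end - c
                    qs = qe - length
                    seq = revcomp(qseq[qs:qe])
                calls.append(
                    InsertionCall(
                        sample_id=sample_id,
                        haplotype_id=haplotype_id,
                        chrom=block.ref_name,
                        ref_start=rpos,
                        ref_end=rpos,
                        query_name=block.query_name,
                        query_start=qs,
                        query_end=qe,
                        strand=block.strand,
                        sequence=seq,
                    )
                )
            c += length
    return calls


def call_between_alignments(
    blocks: list[AlignmentBlock],
    assembly,
    sample_id: str,
    haplotype_id: str = "1",
    min_size: int = DEFAULT_MIN_SIZE,
    min_anchor_len: int = DEFAULT_MIN_ANCHOR_LEN,
    max_ref_gap: int = DEFAULT_MAX_REF_GAP,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> list[InsertionCall]:
    """Call insertions from the gap between adjacent alignments of a query.

    For each adjacent pair (sorted by forward query coordinate) on the same
    chromosome and strand, with both anchors >= min_anchor_len and
    mapq >= min_mapq, a call is emitted iff 0 <= r_gap <= max_ref_gap and
    q_gap - r_gap >= min_size.  Anchor-overlapping pairs (negative gaps)
    are skipped and logged.
    """
    seqs = _assembly_index(assembly)
    by_query: dict[str, list[AlignmentBlock]] = {}
    for b in blocks:
        if b.is_primary:
            by_query.setdefault(b.query_name, []).append(b)
    calls = []
    for qname, qblocks in sorted(by_query.items()):
        if qname not in seqs:
            raise KeyError(f"query {qname!r} not found in assembly")
        qseq = seqs[qname].bases
        qblocks = sorted(qblocks, key=lambda b: (b.query_start, b.query_end))
        for a, b in zip(qblocks, qblocks[1:]):
            if a.ref_name != b.ref_name or a.strand != b.strand:
                continue
            if min(a.mapq, b.mapq) < min_mapq:
                continue
            if (
                a.query_end - a.query_start < min_anchor_len
                or b.query_end - b.query_start < min_anchor_len
            ):
                continue
            q_gap = b.query_start - a.query_end
            if a.strand == "+":
                r_gap = b.ref_start - a.ref_end
                ref_lo = a.ref_end
            else:
                # forward-query order runs against the reference for '-'
                r_gap = a.ref_start - b.ref_end
                ref_lo = b.ref_end
            if q_gap < 0 or r_gap < 0:
                logger.info(
                    "skipping overlapping anchors on %s (q_gap=%d, r_gap=%d)",
                    qname,
                    q_gap,
                    r_gap,
                )
                continue
            if r_gap > max_ref_gap or q_gap - r_gap < min_size:
                continue
            gap_seq = qseq[a.query_end : b.query_start]
            if a.strand == "-":
                gap_seq = revcomp(gap_seq)
            calls.append(
                InsertionCall(
                    sample_id=sample_id,
                    haplotype_id=haplotype_id,
                    chrom=a.ref_name,
                    ref_start=ref_lo,
                    ref_end=ref_lo + r_gap,
                    query_name=qname,
                    query_start=a.query_end,
                    query_end=b.query_start,
                    strand=a.strand,
                    sequence=gap_seq,
                )
            )
    return calls


def call_sample(
    blocks: list[AlignmentBlock],
    assembly,
    sample_id: str,
    haplotype_id: str = "1",
    min_size: int = DEFAULT_MIN_SIZE,
    min_anchor_len: int = DEFAULT_MIN_ANCHOR_LEN,
    max_ref_gap: int = DEFAULT_MAX_REF_GAP,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> list[InsertionCall]:
    """Union of within- and between-alignment calls for one sample."""
    calls = []
    for block in blocks:
        if block.is_primary:
            calls.extend(
                call_within_alignment(
                    block, assembly, sample_id, haplotype_id, min_size
                )
            )
    calls.extend(
        call_between_alignments(
            blocks,
            assembly,
            sample_id,
            haplotype_id,
            min_size,
            min_anchor_len,
            max_ref_gap,
            min_mapq,
        )
    )
    calls.sort(key=lambda c: (c.chrom, c.ref_start, c.ref_end, c.query_name))
    return calls


def apply_region_exclusions(
    calls: list[InsertionCall],
    blacklist: IntervalSet | None = None,
    segdups: IntervalSet | None = None,
    core_chroms: set[str] | None = None,
) -> list[InsertionCall]:
    """Drop calls on non-core contigs or overlapping an exclusion track.

    Zero-length footprints are expanded to 1 bp before the overlap test.
    """
    kept = []
    for call in calls:
        if core_chroms is not None and call.chrom not in core_chroms:
            continue
        s, e = call.footprint
        if blacklist is not None and blacklist.overlaps(call.chrom, s, e):
            continue
        if segdups is not None and segdups.overlaps(call.chrom, s, e):
            continue
        kept.append(call)
    return kept
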