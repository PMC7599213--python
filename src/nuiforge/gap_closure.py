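"""Reference N-gap closure from assembly scaffolds.

Gaps can be closed either by insertion-style calls whose footprints span
the gap, or by realigning 10 kb reference flanks to the assemblies and
extracting the scaffold sequence between the inner anchor ends.  A gap
is "closed" when the fill has no N, "minimized" when residual N remains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .formats import AlignmentBlock, BedRecord, GenomeSequence, revcomp
from .hdr_build import GapFill
from .insertion_calling import InsertionCall

logger = logging.getLogger(__name__)

DEFAULT_EXCLUDED_GAP_TYPES = frozenset({"short_arm", "telomere", "heterochromatin"})
DEFAULT_FLANK_LEN = 10000
DEFAULT_MIN_MAPQ = 30

STATUS_OPEN = "open"
STATUS_CLOSED = "closed"
STATUS_MINIMIZED = "minimized"


@dataclass
class GapRecord:
    chrom: str
    start: int
    end: int
    gap_type: str
    closure_status: str = STATUS_OPEN
    fill: str = "."  # '.' when open
    source_scaffold: str = "."

    @property
    def gap_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def validate(self) -> None:
        if self.closure_status == STATUS_CLOSED and "N" in self.fill.upper():
            raise ValueError("closed gap fill contains N")
        if self.closure_status == STATUS_MINIMIZED and "N" not in self.fill.upper():
            raise ValueError("minimized gap fill contains no N")


def _status_for_fill(fill: str) -> str:
    return STATUS_MINIMIZED if "N" in fill.upper() else STATUS_CLOSED


def load_gap_track(
    records: list[BedRecord] | str,
    excluded_types: frozenset[str] = DEFAULT_EXCLUDED_GAP_TYPES,
) -> list[GapRecord]:
    """Build open gap records from a BED-like track (type in column 4),
    dropping excluded gap types."""
    if isinstance(records, str):
        from .formats import read_bed

        records = read_bed(records)
    gaps = []
    for r in records:
        if r.name in excluded_types:
            continue
        gaps.append(GapRecord(chrom=r.chrom, start=r.start, end=r.end, gap_type=r.name))
    return gaps


def close_gaps_from_calls(
    calls: list[InsertionCall], gaps: list[GapRecord]
) -> list[GapRecord]:
    """Use calls whose footprints span a whole gap to supply its fill.

    The candidate fill is the call sequence with the footprint bases
    outside the gap trimmed off each end; among multiple candidates the
    fill with the fewest N wins (tie: alphabetical sample id).
    """
    out = []
    for gap in gaps:
        candidates: list[tuple[int, str, str, str]] = []
        for call in calls:
            if call.chrom != gap.chrom:
                continue
            if call.ref_start <= gap.start and call.ref_end >= gap.end:
                left_trim = gap.start - call.ref_start
                right_trim = call.ref_end - gap.end
                fill = call.sequence[left_trim : len(call.sequence) - right_trim]
                if not fill:
                    continue
                candidates.append(
                    (fill.upper().count("N"), call.sample_id, fill, call.query_name)
                )
        if candidates:
            n_count, sample, fill, scaffold = min(candidates)
            out.append(
                GapRecord(
                    chrom=gap.chrom,
                    start=gap.start,
                    end=gap.end,
                    gap_type=gap.gap_type,
                    closure_status=_status_for_fill(fill),
                    fill=fill,
                    source_scaffold=scaffold,
                )
            )
        else:
            out.append(gap)
    return out


def flank_query_names(gap: GapRecord) -> tuple[str, str]:
    """Query names used for the upstream/downstream flank alignments."""
    return f"{gap.gap_id}:L", f"{gap.gap_id}:R"


def extract_flanks(
    gap: GapRecord, ref: dict[str, GenomeSequence], flank_len: int = DEFAULT_FLANK_LEN
) -> list[GenomeSequence]:
    """The two reference flanks around a gap, as alignment queries."""
    chrom_seq = ref[gap.chrom].bases
    lname, rname = flank_query_names(gap)
    left = chrom_seq[max(0, gap.start - flank_len) : gap.start]
    right = chrom_seq[gap.end : gap.end + flank_len]
    return [GenomeSequence(lname, left), GenomeSequence(rname, right)]


def _best_primary(blocks: list[AlignmentBlock], min_mapq: int):
    primaries = [b for b in blocks if b.is_primary and b.mapq >= min_mapq]
    if not primaries:
        return None
    return max(primaries, key=lambda b: b.ref_end - b.ref_start)


def close_gap_by_flanks(
    gap: GapRecord,
    flank_alignments: list[AlignmentBlock],
    scaffolds: dict[str, GenomeSequence],
    scaffold_sample: dict[str, str] | None = None,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> GapRecord:
    """Close one gap from flank-to-assembly alignments.

    Requires primary alignments of both flanks with mapq >= 30 to the
    same scaffold in a consistent orientation, with the inner anchor ends
    ordered; the fill is the scaffold substring between the inner anchor
    ends (reverse-complemented for '-' orientation).  When several
    samples close the gap the fill with the fewest N wins (tie:
    alphabetical sample id).
    """
    lname, rname = flank_query_names(gap)
    per_scaffold: dict[str, dict[str, list[AlignmentBlock]]] = {}
    for b in flank_alignments:
        if b.query_name == lname:
            per_scaffold.setdefault(b.ref_name, {}).setdefault("L", []).append(b)
        elif b.query_name == rname:
            per_scaffold.setdefault(b.ref_name, {}).setdefault("R", []).append(b)
    candidates: list[tuple[int, str, str, str]] = []
    for scaf_name, sides in per_scaffold.items():
        left = _best_primary(sides.get("L", []), min_mapq)
        right = _best_primary(sides.get("R", []), min_mapq)
        if left is None or right is None:
            logger.info("gap %s: flank anchors missing on %s", gap.gap_id, scaf_name)
            continue
        if left.strand != right.strand:
            logger.info("gap %s: inconsistent orientation on %s", gap.gap_id, scaf_name)
            continue
        if scaf_name not in scaffolds:
            continue
        scaf = scaffolds[scaf_name].bases
        if left.strand == "+":
            # inner anchor ends: end of the left flank, start of the right
            inner_l = left.ref_end + (left.query_length - left.query_end)
            inner_r = right.ref_start - right.query_start
            if inner_l > inner_r:
                logger.info("gap %s: anchors out of order on %s", gap.gap_id, scaf_name)
                continue
            fill = scaf[inner_l:inner_r]
        else:
            inner_l = left.ref_start - (left.query_length - left.query_end)
            inner_r = right.ref_end + right.query_start
            if inner_r > inner_l:
                logger.info("gap %s: anchors out of order on %s", gap.gap_id, scaf_name)
                continue
            fill = revcomp(scaf[inner_r:inner_l])
        if not fill:
            continue
        sample = (scaffold_sample or {}).get(scaf_name, scaf_name)
        candidates.append((fill.upper().count("N"), sample, fill, scaf_name))
    if not candidates:
        return gap
    _, _, fill, scaf_name = min(candidates)
    return GapRecord(
        chrom=gap.chrom,
        start=gap.start,
        end=gap.end,
        gap_type=gap.gap_type,
        closure_status=_status_for_fill(fill),
        fill=fill,
        source_scaffold=scaf_name,
    )


def gap_records_to_fills(gaps: list[GapRecord]) -> list[GapFill]:
    """Convert non-open gap records into HDR gap-fill events."""
    fills = []
    for g in gaps:
        if g.closure_status == STATUS_OPEN:
            continue
        fills.append(
            GapFill(
                chrom=g.chrom,
                start=g.start,
                end=g.end,
                sequence=g.fill,
                source=g.source_scaffold,
                status=g.closure_status,
            )
        )
    return fills
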