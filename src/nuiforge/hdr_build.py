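"""Linear integration of representative insertions and gap fills.

Events (pure insertions with zero-length footprints, or replacements
with positive footprints) are spliced into the reference chromosomes to
produce an augmented FASTA plus a bidirectional interval mapping table.
Per chromosome, augmented length = reference length + sum over events of
(sequence length - footprint length).
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field

from .clustering import RepresentativeNUI
from .formats import GenomeSequence

logger = logging.getLogger(__name__)

SEG_COLLINEAR = "collinear"
SEG_INSERTED = "inserted"
SEG_REPLACED = "replaced"


@dataclass
class GapFill:
    """An assembly-derived sequence replacing a reference interval."""

    chrom: str
    start: int
    end: int
    sequence: str
    source: str
    status: str = "closed"  # closed | minimized
    n_gaps: int = 1  # reference gaps spanned (dedup criterion)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("gap fill sequence must be non-empty")
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"bad fill interval {self.chrom}:{self.start}-{self.end}")


@dataclass
class MappingInterval:
    chrom: str
    segment_type: str  # collinear | inserted | replaced
    ref_start: int
    ref_end: int  # == ref_start for inserted segments
    hdr_start: int
    hdr_end: int
    event_id: str = "."


@dataclass
class HDREvent:
    event_id: str
    chrom: str
    ref_start: int
    ref_end: int
    sequence: str
    ref_bases: str  # footprint bases being replaced ("" for pure insertion)
    source: str = "."


@dataclass
class HDRBuild:
    sequences: list[GenomeSequence]
    mapping: list[MappingInterval]
    events: list[HDREvent]

    def sequence_by_name(self, name: str) -> GenomeSequence:
        for s in self.sequences:
            if s.name == name:
                return s
        raise KeyError(name)


def dedupe_gapfills(fills: list[GapFill]) -> list[GapFill]:
    """Among fills with overlapping reference intervals keep the one
    spanning the most gaps (tie: longest fill sequence)."""
    ordered = sorted(
        fills, key=lambda f: (f.chrom, f.start, f.end, f.source)
    )
    groups: list[list[GapFill]] = []
    cur: list[GapFill] = []
    cur_chrom, cur_end = None, -1
    for f in ordered:
        if cur and f.chrom == cur_chrom and f.start < cur_end:
            cur.append(f)
            cur_end = max(cur_end, f.end)
        else:
            if cur:
                groups.append(cur)
            cur = [f]
            cur_chrom, cur_end = f.chrom, f.end
    if cur:
        groups.append(cur)
    kept = []
    for group in groups:
        winner = max(group, key=lambda f: (f.n_gaps, len(f.sequence)))
        for f in group:
            if f is not winner:
                logger.info(
                    "dropping redundant gap fill %s:%d-%d from %s",
                    f.chrom,
                    f.start,
                    f.end,
                    f.source,
                )
        kept.append(winner)
    kept.sort(key=lambda f: (f.chrom, f.start))
    return kept


def drop_conflicting_nuis(
    nuis: list[RepresentativeNUI], fills: list[GapFill]
) -> list[RepresentativeNUI]:
    """Drop NUIs whose (expanded) footprints intersect a retained fill."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for f in fills:
        by_chrom.setdefault(f.chrom, []).append((f.start, f.end))
    kept = []
    for nui in nuis:
        s, e = nui.footprint
        if any(
            s < fe and fs < e for fs, fe in by_chrom.get(nui.chrom, [])
        ):
            continue
        kept.append(nui)
    return kept


def _as_events(
    nuis: list[RepresentativeNUI], fills: list[GapFill], ref_by_name
) -> list[HDREvent]:
    events = []
    for nui in nuis:
        ref_bases = ref_by_name[nui.chrom].bases[nui.ref_start : nui.ref_end]
        events.append(
            HDREvent(
                event_id=nui.nui_id,
                chrom=nui.chrom,
                ref_start=nui.ref_start,
                ref_end=nui.ref_end,
                sequence=nui.sequence,
                ref_bases=ref_bases,
                source=f"{nui.sample_id}/{nui.haplotype_id}",
            )
        )
    for f in fills:
        events.append(
            HDREvent(
                event_id=f"fill:{f.chrom}:{f.start}-{f.end}",
                chrom=f.chrom,
                ref_start=f.start,
                ref_end=f.end,
                sequence=f.sequence,
                ref_bases=ref_by_name[f.chrom].bases[f.start : f.end],
                source=f.source,
            )
        )
    return events


def integrate(
    ref: list[GenomeSequence],
    nuis: list[RepresentativeNUI],
    fills: list[GapFill] | None = None,
    name_suffix: str = "",
) -> HDRBuild:
    """Splice events into the reference, emitting sequences + mapping.

    Events must be pairwise non-overlapping (conflicts were resolved
    upstream); any overlap is a hard error listing the offenders.  A
    zero-footprint event yields an ``inserted`` segment, a positive
    footprint (or a gap fill) a ``replaced`` segment; ``collinear``
    segments tile the remainder.
    """
    ref_by_name = {r.name: r for r in ref}
    events = _as_events(nuis, fills or [], ref_by_name)
    by_chrom: dict[str, list[HDREvent]] = {}
    for ev in events:
        if ev.chrom not in ref_by_name:
            raise KeyError(f"event chromosome {ev.chrom!r} not in reference")
        by_chrom.setdefault(ev.chrom, []).append(ev)

    out_seqs: list[GenomeSequence] = []
    mapping: list[MappingInterval] = []
    all_events: list[HDREvent] = []
    for chrom_seq in ref:
        chrom = chrom_seq.name
        chrom_events = sorted(
            by_chrom.get(chrom, []), key=lambda e: (e.ref_start, e.ref_end)
        )
        # overlap check on raw footprints; two pure insertions at the same
        # point also conflict (no defined order)
        for a, b in zip(chrom_events, chrom_events[1:]):
            if b.ref_start < a.ref_end or (
                a.ref_start == a.ref_end == b.ref_start == b.ref_end
            ):
                raise ValueError(
                    f"overlapping events on {chrom}: {a.event_id} and {b.event_id}"
                )
        parts: list[str] = []
        pos = 0  # reference cursor
        hdr_pos = 0
        out_name = chrom + name_suffix
        for ev in chrom_events:
            if ev.ref_start > pos:
                seg_len = ev.ref_start - pos
                parts.append(chrom_seq.bases[pos : ev.ref_start])
                mapping.append(
                    MappingInterval(
                        out_name,
                        SEG_COLLINEAR,
                        pos,
                        ev.ref_start,
                        hdr_pos,
                        hdr_pos + seg_len,
                    )
                )
                hdr_pos += seg_len
                pos = ev.ref_start
            seg_type = SEG_INSERTED if ev.ref_start == ev.ref_end else SEG_REPLACED
            parts.append(ev.sequence)
            mapping.append(
                MappingInterval(
                    out_name,
                    seg_type,
                    ev.ref_start,
                    ev.ref_end,
                    hdr_pos,
                    hdr_pos + len(ev.sequence),
                    ev.event_id,
                )
            )
            hdr_pos += len(ev.sequence)
            pos = ev.ref_end
            all_events.append(ev)
        if pos < len(chrom_seq.bases):
            seg_len = len(chrom_seq.bases) - pos
            parts.append(chrom_seq.bases[pos:])
            mapping.append(
                MappingInterval(
                    out_name,
                    SEG_COLLINEAR,
                    pos,
                    len(chrom_seq.bases),
                    hdr_pos,
                    hdr_pos + seg_len,
                )
            )
            hdr_pos += seg_len
        out_seqs.append(GenomeSequence(out_name, "".join(parts)))
    return HDRBuild(sequences=out_seqs, mapping=mapping, events=all_events)


def liftover(
    mapping: list[MappingInterval],
    chrom: str,
    pos: int,
    direction: str = "ref2hdr",
) -> tuple[int | None, str | None]:
    """Translate one coordinate through the mapping table.

    Returns (position, None) on success, (None, reason) when the position
    falls in non-transferable sequence: "replaced" for reference bases
    substituted away (ref2hdr), "non-reference" for inserted/replacement
    bases (hdr2ref).
    """
    if direction not in ("ref2hdr", "hdr2ref"):
        raise ValueError(f"bad direction {direction!r}")
    segs = [m for m in mapping if m.chrom == chrom]
    if not segs:
        raise KeyError(f"unknown chromosome {chrom!r}")
    if direction == "ref2hdr":
        # inserted segments are zero-length on the reference side; skip them
        usable = [m for m in segs if m.segment_type != SEG_INSERTED]
        usable.sort(key=lambda m: m.ref_start)
        starts = [m.ref_start for m in usable]
        i = bisect_right(starts, pos) - 1
        if i < 0 or pos >= usable[i].ref_end:
            raise ValueError(f"position {pos} outside reference {chrom}")
        seg = usable[i]
        if seg.segment_type == SEG_REPLACED:
            return None, "replaced"
        return seg.hdr_start + (pos - seg.ref_start), None
    usable = sorted(segs, key=lambda m: m.hdr_start)
    starts = [m.hdr_start for m in usable]
    i = bisect_right(starts, pos) - 1
    if i < 0 or pos >= usable[i].hdr_end:
        raise ValueError(f"position {pos} outside augmented {chrom}")
    seg = usable[i]
    if seg.segment_type != SEG_COLLINEAR:
        return None, "non-reference"
    return seg.ref_start + (pos - seg.hdr_start), None


def extract_event_sequences(build: HDRBuild) -> dict[str, str]:
    """Slice each event's augmented interval out of the augmented FASTA."""
    seq_by_name = {s.name: s.bases for s in build.sequences}
    out = {}
    for m in build.mapping:
        if m.segment_type == SEG_COLLINEAR:
            continue
        out[m.event_id] = seq_by_name[m.chrom][m.hdr_start : m.hdr_end]
    return out


def reconstruct_reference(build: HDRBuild, name_suffix: str = "") -> list[GenomeSequence]:
    """Invert the build: delete inserted segments, restore replaced
    footprints.  Reproduces the input reference byte-identically."""
    events_by_id = {e.event_id: e for e in build.events}
    out = []
    for seq in build.sequences:
        parts = []
        for m in sorted(
            (m for m in build.mapping if m.chrom == seq.name),
            key=lambda m: m.hdr_start,
        ):
            if m.segment_type == SEG_COLLINEAR:
                parts.append(seq.bases[m.hdr_start : m.hdr_end])
            elif m.segment_type == SEG_REPLACED:
                parts.append(events_by_id[m.event_id].ref_bases)
        name = seq.name
        if name_suffix and name.endswith(name_suffix):
            name = name[: -len(name_suffix)]
        out.append(GenomeSequence(name, "".join(parts)))
    return out
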