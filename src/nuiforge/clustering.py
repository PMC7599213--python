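"""Component building, multiple alignment, scoring, and representative choice.

Calls whose reference footprints overlap by >= 1 bp form a component.
Within a component each member is padded with reference context, soft
masked, multiple-aligned (center-star progressive alignment), and scored
against the column consensus; members are then grouped into clusters at
80% pairwise identity to the highest-scoring unassigned member, and each
cluster's top member may become a representative if its footprint does
not collide with an already accepted one.

Global scoring scheme (per insert-segment column of the scored row):
match +2 unmasked / +0.2 masked, mismatch -1, N -0.5, gap 0.
Pairwise identity scheme: match +1, mismatch -4, N 0, gap open -4.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .align import Alignment, PairwiseScheme, global_align
from .formats import GenomeSequence
from .insertion_calling import InsertionCall

DEFAULT_MIN_SUPPORT = 2
IDENTITY_THRESHOLD = 0.8
PAD_CONTEXT = 50
PAD_SIZE_TRIGGER = 50  # pad only when some member's insert exceeds this


@dataclass
class GlobalScoreScheme:
    """Consensus-match scoring over insert-segment columns."""

    match_unmasked: float = 2.0
    match_masked: float = 0.2
    mismatch: float = -1.0
    undetermined: float = -0.5
    gap: float = 0.0


# ---------------------------------------------------------------------------
# components


@dataclass
class Component:
    id: str
    members: list[InsertionCall]
    chrom: str
    start: int  # min footprint start over members
    end: int  # max footprint end over members

    @property
    def n_distinct_samples(self) -> int:
        return len({m.sample_id for m in self.members})


def build_components(calls: list[InsertionCall]) -> list[Component]:
    """Partition calls by transitive >=1 bp footprint overlap.

    Zero-length footprints are expanded to 1 bp, so two pure insertion
    points at the same coordinate share a base and group together.
    """
    ordered = sorted(calls, key=lambda c: (c.chrom, c.footprint))
    components: list[Component] = []
    current: list[InsertionCall] = []
    cur_chrom, cur_end = None, -1
    for call in ordered:
        s, e = call.footprint
        if current and call.chrom == cur_chrom and s < cur_end:
            current.append(call)
            cur_end = max(cur_end, e)
        else:
            if current:
                components.append(_finish_component(current))
            current = [call]
            cur_chrom, cur_end = call.chrom, e
    if current:
        components.append(_finish_component(current))
    return components


def _finish_component(members: list[InsertionCall]) -> Component:
    start = min(m.footprint[0] for m in members)
    end = max(m.footprint[1] for m in members)
    chrom = members[0].chrom
    members = sorted(
        members, key=lambda m: (m.sample_id, m.haplotype_id, m.ref_start)
    )
    return Component(
        id=f"{chrom}:{start}", members=members, chrom=chrom, start=start, end=end
    )


def drop_singletons(
    components: list[Component], min_support: int = DEFAULT_MIN_SUPPORT
) -> list[Component]:
    """Remove components carried by fewer than min_support distinct samples."""
    return [c for c in components if c.n_distinct_samples >= min_support]


# ---------------------------------------------------------------------------
# padding and masking


@dataclass
class PaddedSeq:
    member: InsertionCall
    text: str
    insert_start: int  # insert-segment span within text
    insert_end: int

    @property
    def insert_segment(self) -> str:
        return self.text[self.insert_start : self.insert_end]


def pad_component(component: Component, ref) -> list[PaddedSeq]:
    """Attach reference context to each member's inserted sequence.

    Context (50 bp beyond the component's min start / max end, clipped at
    chromosome bounds) is added only when at least one member's insert is
    longer than 50 bp; short components align better unpadded.
    """
    refs = (
        ref
        if isinstance(ref, dict)
        else {r.name: r for r in ([ref] if isinstance(ref, GenomeSequence) else ref)}
    )
    use_padding = any(m.insert_size > PAD_SIZE_TRIGGER for m in component.members)
    padded = []
    for m in component.members:
        if not use_padding:
            padded.append(PaddedSeq(m, m.sequence, 0, len(m.sequence)))
            continue
        chrom_seq = refs[component.chrom].bases
        # raw (unexpanded) footprint bounds the replaced reference bases
        lo = max(0, min(component.start, m.ref_start) - PAD_CONTEXT)
        hi = min(len(chrom_seq), max(component.end, m.ref_end) + PAD_CONTEXT)
        left = chrom_seq[lo : m.ref_start]
        right = chrom_seq[m.ref_end : hi]
        text = left + m.sequence + right
        padded.append(
            PaddedSeq(m, text, len(left), len(left) + len(m.sequence))
        )
    return padded


def _tandem_mask(text: str, max_period: int = 100, min_identity: float = 0.8,
                 min_len: int = 20) -> np.ndarray:
    """Boolean mask of tandem arrays: period <= max_period, adjacent-copy
    identity >= min_identity, total array length >= min_len."""
    n = len(text)
    mask = np.zeros(n, dtype=bool)
    if n < 2:
        return mask
    arr = np.frombuffer(text.upper().encode(), dtype=np.uint8)
    is_n = arr == ord("N")
    for p in range(1, min(max_period, n // 2) + 1):
        m = (arr[:-p] == arr[p:]) & ~is_n[:-p] & ~is_n[p:]
        if not m.any():
            continue
        # maximal runs of matches, greedily merged while identity holds
        idx = np.flatnonzero(m)
        run_start = idx[0]
        prev = idx[0]
        segs: list[tuple[int, int]] = []
        # collect consecutive-true runs first
        for i in idx[1:]:
            if i == prev + 1:
                prev = i
            else:
                segs.append((run_start, prev - run_start + 1))
                run_start, prev = i, i
        segs.append((run_start, prev - run_start + 1))
        # merge runs while overall identity stays above threshold
        cur_start, cur_matches = segs[0][0], segs[0][1]
        cur_end = segs[0][0] + segs[0][1]
        for s, length in segs[1:]:
            span = s + length - cur_start
            matches = cur_matches + length
            if matches / span >= min_identity:
                cur_matches, cur_end = matches, s + length
            else:
                _emit_tandem(mask, cur_start, cur_end, cur_matches, p,
                             min_identity, min_len)
                cur_start, cur_matches, cur_end = s, length, s + length
        _emit_tandem(mask, cur_start, cur_end, cur_matches, p,
                     min_identity, min_len)
    mask &= ~is_n
    return mask


def _emit_tandem(mask, start, end, matches, period, min_identity, min_len):
    span = end - start
    if (
        span >= period
        and span + period >= min_len
        and matches / span >= min_identity
    ):
        mask[start : end + period] = True


def _entropy_mask(text: str, window: int = 64, step: int = 16,
                  threshold: float = 2.0) -> np.ndarray:
    """Boolean mask of low-triplet-entropy windows."""
    n = len(text)
    mask = np.zeros(n, dtype=bool)
    if n < window // 2:
        return mask
    s = text.upper()
    w = min(window, n)
    starts = list(range(0, n - w + 1, step))
    if starts[-1] != n - w:
        starts.append(n - w)
    for a in starts:
        counts: Counter = Counter()
        valid = 0
        for i in range(a, a + w - 2):
            tri = s[i : i + 3]
            if "N" in tri:
                continue
            counts[tri] += 1
            valid += 1
        if valid < (w - 2) // 2:
            continue
        ent = -sum(
            (c / valid) * math.log2(c / valid) for c in counts.values()
        )
        if ent < threshold:
            mask[a : a + w] = True
    mask &= np.frombuffer(s.encode(), dtype=np.uint8) != ord("N")
    return mask


def soft_mask(
    text: str,
    mode: str = "both",
    external_intervals: list[tuple[int, int]] | None = None,
) -> str:
    """Lowercase low-complexity / tandem positions; letters never change.

    ``external_intervals`` (half-open spans) override the built-in
    detectors when supplied.  N positions are never case-changed.
    """
    n = len(text)
    if external_intervals is not None:
        mask = np.zeros(n, dtype=bool)
        for s, e in external_intervals:
            mask[max(0, s) : min(n, e)] = True
        mask &= np.frombuffer(text.upper().encode(), dtype=np.uint8) != ord("N")
    else:
        mask = np.zeros(n, dtype=bool)
        if mode in ("tandem", "both"):
            mask |= _tandem_mask(text)
        if mode in ("entropy", "both"):
            mask |= _entropy_mask(text)
    if not mask.any():
        return text
    chars = list(text)
    for i in np.flatnonzero(mask):
        chars[i] = chars[i].lower()
    return "".join(chars)


def mask_fraction(text: str, mode: str) -> float:
    """Fraction of non-N bases flagged by the requested detector(s)."""
    n_resolved = sum(1 for c in text.upper() if c != "N")
    if n_resolved == 0:
        return 0.0
    if mode == "tandem":
        mask = _tandem_mask(text)
    elif mode == "entropy":
        mask = _entropy_mask(text)
    else:
        mask = _tandem_mask(text) | _entropy_mask(text)
    return float(mask.sum()) / n_resolved


# ---------------------------------------------------------------------------
# multiple alignment


@dataclass
class Msa:
    rows: list[str]  # equal-length gapped strings, input order preserved
    insert_cols: list[set[int]]  # per row: columns of insert-segment chars

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("MSA rows have unequal lengths")


def align_component(
    padded: list[PaddedSeq], scheme: PairwiseScheme | None = None
) -> Msa:
    """Center-star progressive alignment of the padded member texts.

    The center is the member with the greatest summed pairwise alignment
    score to all others (tie: first in input order); every other member
    is aligned to the center and the pairwise gaps are merged.
    Deterministic for a fixed input order.
    """
    scheme = scheme or PairwiseScheme()
    k = len(padded)
    if k == 0:
        raise ValueError("empty component")
    texts = [p.text for p in padded]
    if k == 1:
        return Msa([texts[0]], [set(range(padded[0].insert_start, padded[0].insert_end))])

    alignments: dict[tuple[int, int], Alignment] = {}
    totals = [0.0] * k
    for i in range(k):
        for j in range(i + 1, k):
            al = global_align(texts[i], texts[j], scheme)
            alignments[(i, j)] = al
            totals[i] += al.score
            totals[j] += al.score
    center = max(range(k), key=lambda i: (totals[i], -i))
    ctext = texts[center]
    L = len(ctext)

    # per row: gaps[b] = chars inserted before center base b (b in 0..L),
    # and matched[b] = row char aligned to center base b ('-' possible)
    row_gaps: list[list[str]] = []
    row_matched: list[list[str]] = []
    for j in range(k):
        if j == center:
            row_gaps.append([""] * (L + 1))
            row_matched.append(list(ctext))
            continue
        if (center, j) in alignments:
            al = alignments[(center, j)]
            ca, ra = al.aligned_a, al.aligned_b
        else:
            al = alignments[(j, center)]
            ca, ra = al.aligned_b, al.aligned_a
        gaps = [""] * (L + 1)
        matched = []
        b = 0
        for cc, rc in zip(ca, ra):
            if cc == "-":
                gaps[b] += rc
            else:
                matched.append(rc)
                b += 1
        row_gaps.append(gaps)
        row_matched.append(matched)

    slot = [max(len(g[b]) for g in row_gaps) for b in range(L + 1)]
    rows = []
    col_of: list[dict[int, int]] = []  # per row: original char index -> column
    for j in range(k):
        out = []
        mapping: dict[int, int] = {}
        pos = 0  # original char index in row j
        col = 0
        for b in range(L + 1):
            g = row_gaps[j][b]
            for ch in g:
                mapping[pos] = col
                out.append(ch)
                pos += 1
                col += 1
            pad = slot[b] - len(g)
            out.append("-" * pad)
            col += pad
            if b < L:
                ch = row_matched[j][b]
                out.append(ch)
                if ch != "-":
                    mapping[pos] = col
                    pos += 1
                col += 1
        rows.append("".join(out))
        col_of.append(mapping)

    insert_cols = []
    for j, p in enumerate(padded):
        insert_cols.append(
            {col_of[j][i] for i in range(p.insert_start, p.insert_end)}
        )
    return Msa(rows, insert_cols)


# ---------------------------------------------------------------------------
# scoring


def harmonize_column_masking(msa: Msa) -> Msa:
    """Lowercase a whole column when any row carries a masked base there.

    Members of a component are observations of one locus; per-member mask
    detection can disagree (an N run destroys the motif that triggered the
    detector on a sibling copy), which would let an N-gapped copy outscore
    a fully resolved one.  Column-consistent masking restores the ordering
    guarantee of the N penalty.  N and gap characters are untouched.
    """
    n_cols = len(msa.rows[0]) if msa.rows else 0
    masked_cols = [
        any(r[j].islower() and r[j] != "n" for r in msa.rows)
        for j in range(n_cols)
    ]
    rows = []
    for r in msa.rows:
        rows.append(
            "".join(
                c.lower() if masked_cols[j] and c.upper() != "N" and c != "-" else c
                for j, c in enumerate(r)
            )
        )
    return Msa(rows, [set(s) for s in msa.insert_cols])


def _column_consensus(msa: Msa, col: int) -> str | None:
    """Most frequent determined non-gap symbol (case-insensitive;
    tie -> lexicographically smallest).  N never forms the consensus:
    an undetermined base is penalized, not matchable."""
    counts: Counter = Counter()
    for row in msa.rows:
        ch = row[col]
        if ch != "-" and ch.upper() != "N":
            counts[ch.upper()] += 1
    if not counts:
        return None
    top = max(counts.values())
    return min(sym for sym, c in counts.items() if c == top)


def global_score(
    msa: Msa, row: int, scheme: GlobalScoreScheme | None = None
) -> float:
    """Consensus-match score of one row over its insert-segment columns."""
    scheme = scheme or GlobalScoreScheme()
    text = msa.rows[row]
    score = 0.0
    for col in msa.insert_cols[row]:
        ch = text[col]
        if ch == "-":
            score += scheme.gap
            continue
        up = ch.upper()
        if up == "N":
            score += scheme.undetermined
            continue
        cons = _column_consensus(msa, col)
        if up == cons:
            score += scheme.match_masked if ch.islower() else scheme.match_unmasked
        else:
            score += scheme.mismatch
    return score


_MATCH_TIEBREAK = 1 << 20  # scheme inflation factor; see pairwise_identity


def pairwise_identity(
    a: str, b: str, scheme: PairwiseScheme | None = None
) -> float:
    """Identity of two insert segments: matched columns of the optimal
    global alignment divided by the shorter segment's length.

    Ties between equally scoring alignments are resolved toward the one
    with the most matched columns, by scaling all scheme constants by a
    large factor and granting each true match a +1 bonus.  This makes the
    identity a well-defined function of the two sequences.
    """
    if not a or not b:
        raise ValueError("insert segments must be non-empty")
    scheme = scheme or PairwiseScheme()
    B = _MATCH_TIEBREAK
    inflated = PairwiseScheme(
        match=scheme.match * B + 1,
        mismatch=scheme.mismatch * B,
        n_score=scheme.n_score * B,
        gap_open=scheme.gap_open * B,
        gap_extend=scheme.gap_extend * B,
    )
    al = global_align(a, b, inflated)
    return al.matched_columns() / min(len(a), len(b))


# ---------------------------------------------------------------------------
# clustering and representative choice


@dataclass
class Cluster:
    id: str
    top: InsertionCall
    top_score: float
    members: list[InsertionCall]
    identities: list[float]  # identity of each member to the top

    @property
    def n_distinct_samples(self) -> int:
        return len({m.sample_id for m in self.members})


def _score_order(padded: list[PaddedSeq], scores: list[float]) -> list[int]:
    return sorted(
        range(len(padded)),
        key=lambda i: (
            -scores[i],
            padded[i].member.sample_id,
            padded[i].member.haplotype_id,
        ),
    )


def cluster_component(
    padded: list[PaddedSeq],
    scores: list[float],
    component_id: str = "c",
    scheme: PairwiseScheme | None = None,
    min_identity: float = IDENTITY_THRESHOLD,
) -> list[Cluster]:
    """Recursive clustering: the highest-scoring unassigned member founds a
    cluster and every unassigned member with identity >= 0.8 (inclusive)
    to the founder joins it; repeat until all members are assigned."""
    scheme = scheme or PairwiseScheme()
    order = _score_order(padded, scores)
    unassigned = list(order)
    clusters: list[Cluster] = []
    while unassigned:
        founder = unassigned[0]
        members = [founder]
        identities = [1.0]
        rest = []
        fseg = padded[founder].insert_segment
        for i in unassigned[1:]:
            ident = pairwise_identity(fseg, padded[i].insert_segment, scheme)
            if ident >= min_identity:
                members.append(i)
                identities.append(ident)
            else:
                rest.append(i)
        clusters.append(
            Cluster(
                id=f"{component_id}#{len(clusters)}",
                top=padded[founder].member,
                top_score=scores[founder],
                members=[padded[i].member for i in members],
                identities=identities,
            )
        )
        unassigned = rest
    return clusters


@dataclass
class RepresentativeNUI:
    """The top-scoring member chosen to stand for a cluster."""

    nui_id: str
    chrom: str
    ref_start: int
    ref_end: int
    sequence: str
    sample_id: str
    haplotype_id: str
    support_samples: int
    global_score: float
    component_id: str
    cluster_id: str
    repeat_class: str = "."
    genic_class: str = "."
    regulatory: bool = False
    filter_status: str = "pass"

    @property
    def insert_size(self) -> int:
        return len(self.sequence) - (self.ref_end - self.ref_start)

    @property
    def footprint(self) -> tuple[int, int]:
        if self.ref_end == self.ref_start:
            return self.ref_start, self.ref_start + 1
        return self.ref_start, self.ref_end


def pick_representatives(
    clusters: list[Cluster],
    component: Component,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> list[RepresentativeNUI]:
    """Visit clusters by descending top score; a cluster's top becomes a
    representative iff its footprint overlaps no already accepted
    representative of the component and the cluster is supported by at
    least ``min_support`` distinct samples."""
    ordered = sorted(
        clusters,
        key=lambda c: (-c.top_score, c.top.sample_id, c.top.haplotype_id),
    )
    reps: list[RepresentativeNUI] = []
    accepted: list[tuple[int, int]] = []
    for cluster in ordered:
        if cluster.n_distinct_samples < min_support:
            continue
        top = cluster.top
        s, e = top.footprint
        if any(s < ae and as_ < e for as_, ae in accepted):
            continue
        accepted.append((s, e))
        reps.append(
            RepresentativeNUI(
                nui_id=f"{component.chrom}:{top.ref_start}-{top.ref_end}:{cluster.id}",
                chrom=top.chrom,
                ref_start=top.ref_start,
                ref_end=top.ref_end,
                sequence=top.sequence,
                sample_id=top.sample_id,
                haplotype_id=top.haplotype_id,
                support_samples=cluster.n_distinct_samples,
                global_score=cluster.top_score,
                component_id=component.id,
                cluster_id=cluster.id,
            )
        )
    reps.sort(key=lambda r: (r.chrom, r.ref_start, r.ref_end))
    return reps


def select_representatives(
    calls: list[InsertionCall],
    ref,
    min_support: int = DEFAULT_MIN_SUPPORT,
    global_scheme: GlobalScoreScheme | None = None,
    pairwise_scheme: PairwiseScheme | None = None,
    mask_mode: str = "both",
) -> list[RepresentativeNUI]:
    """Full clustering stage: calls -> representative NUIs."""
    refs = (
        ref
        if isinstance(ref, dict)
        else {r.name: r for r in ([ref] if isinstance(ref, GenomeSequence) else ref)}
    )
    reps: list[RepresentativeNUI] = []
    components = drop_singletons(build_components(calls), min_support)
    for comp in components:
        padded = pad_component(comp, refs)
        masked = [
            PaddedSeq(p.member, soft_mask(p.text, mask_mode), p.insert_start, p.insert_end)
            for p in padded
        ]
        msa = harmonize_column_masking(align_component(masked, pairwise_scheme))
        scores = [global_score(msa, r, global_scheme) for r in range(len(masked))]
        clusters = cluster_component(masked, scores, comp.id, pairwise_scheme)
        reps.extend(pick_representatives(clusters, comp, min_support))
    reps.sort(key=lambda r: (r.chrom, r.ref_start, r.ref_end))
    return reps
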