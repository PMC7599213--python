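"""Sequence-content, window, and breakpoint-consistency filters.

Order matters and is fixed: sequence rules, then the 200 bp window rule,
then the 50 bp window rule, then breakpoint consistency.  Each removal
carries a rule id so removal counts reconcile with input minus output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .clustering import Cluster, RepresentativeNUI, mask_fraction

# rule ids
RULE_TANDEM = "tandem_gt80_lt100_unmasked"
RULE_LOWCOMPLEX = "lowcomplex_gt80_lt100_unmasked"
RULE_N10 = "n_gt10_resolved_lt50"
RULE_N100 = "n_gt100_resolved_lt100"
RULE_WINDOW_200 = "gt5_in_200bp_window"
RULE_WINDOW_50 = "gt2_in_50bp_window"
RULE_BREAKPOINT = "breakpoint_inconsistent_lt50bp"

WINDOW_DENSE_SPAN = 200
WINDOW_DENSE_MAX = 5  # more than this many starts in the span -> all removed
WINDOW_CROWD_SPAN = 50
WINDOW_CROWD_MAX = 2  # more than this -> keep only the longest
BREAKPOINT_SIZE_LIMIT = 50


@dataclass
class RepeatAnnotation:
    tandem_masked_frac: float
    composite_lc_frac: float
    n_count: int
    resolved_count: int
    unmasked_count: int
    repeat_class: str = "none"

    @property
    def length(self) -> int:
        return self.n_count + self.resolved_count


@dataclass
class FilterReport:
    failed_rules: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.failed_rules


def _frac_covered(length: int, intervals: list[tuple[int, int]]) -> float:
    if length == 0:
        return 0.0
    covered = [False] * length
    for s, e in intervals:
        if s < 0 or e > length:
            raise ValueError(f"annotation interval [{s},{e}) outside sequence")
        for i in range(s, e):
            covered[i] = True
    return sum(covered) / length


def annotate_repeat_content(
    sequence: str,
    tandem_intervals: list[tuple[int, int]] | None = None,
    lowcomplex_intervals: list[tuple[int, int]] | None = None,
) -> RepeatAnnotation:
    """Compute repeat/low-complexity fractions and base counts.

    Built-in detectors (the clustering soft-mask machinery) supply the
    fractions unless external annotation intervals are given.
    """
    upper = sequence.upper()
    n_count = upper.count("N")
    resolved = len(sequence) - n_count
    if tandem_intervals is not None:
        tandem_frac = _frac_covered(len(sequence), tandem_intervals)
    else:
        tandem_frac = mask_fraction(sequence, "tandem")
    if lowcomplex_intervals is not None:
        lc_frac = _frac_covered(len(sequence), lowcomplex_intervals)
    else:
        # composite analog: union of tandem and low-complexity detectors
        lc_frac = mask_fraction(sequence, "both")
    masked_frac = max(tandem_frac, lc_frac)
    unmasked = resolved - int(round(masked_frac * resolved))
    return RepeatAnnotation(
        tandem_masked_frac=tandem_frac,
        composite_lc_frac=lc_frac,
        n_count=n_count,
        resolved_count=resolved,
        unmasked_count=max(0, unmasked),
    )


def apply_sequence_filters(
    nui: RepresentativeNUI, ann: RepeatAnnotation
) -> FilterReport:
    """Fail a NUI on any of the four content rules:
    (1) >80% tandem-masked and <100 unmasked bases;
    (2) >80% composite low-complexity and <100 unmasked bases;
    (3) >10 N and <50 resolved bases;
    (4) >100 N and <100 resolved bases.
    """
    report = FilterReport()
    if ann.tandem_masked_frac > 0.8 and ann.unmasked_count < 100:
        report.failed_rules.append(RULE_TANDEM)
    if ann.composite_lc_frac > 0.8 and ann.unmasked_count < 100:
        report.failed_rules.append(RULE_LOWCOMPLEX)
    if ann.n_count > 10 and ann.resolved_count < 50:
        report.failed_rules.append(RULE_N10)
    if ann.n_count > 100 and ann.resolved_count < 100:
        report.failed_rules.append(RULE_N100)
    return report


def _window_groups(
    starts: list[int], span: int, min_count: int
) -> list[set[int]]:
    """Indices of starts falling in any window of `span` bp holding more
    than `min_count` starts, merged into maximal groups (sorted input)."""
    flagged: set[int] = set()
    n = len(starts)
    j = 0
    for i in range(n):
        while j < n and starts[j] - starts[i] <= span:
            j += 1
        if j - i > min_count:
            flagged.update(range(i, j))
        if j == n and starts[-1] - starts[i] <= span:
            continue
    if not flagged:
        return []
    groups: list[set[int]] = []
    for idx in sorted(flagged):
        if groups and idx - 1 in groups[-1]:
            groups[-1].add(idx)
        else:
            groups.append({idx})
    return groups


def apply_window_filters(
    nuis: list[RepresentativeNUI],
) -> tuple[list[RepresentativeNUI], dict[str, list[RepresentativeNUI]]]:
    """Remove crowded representatives.

    Per chromosome, over footprint start positions: any sliding 200 bp
    span holding more than five representatives removes them all; then
    any 50 bp span holding more than two keeps only the largest insert
    (tie: alphabetical sample id).
    """
    removed: dict[str, list[RepresentativeNUI]] = {
        RULE_WINDOW_200: [],
        RULE_WINDOW_50: [],
    }
    by_chrom: dict[str, list[RepresentativeNUI]] = {}
    for nui in nuis:
        by_chrom.setdefault(nui.chrom, []).append(nui)
    kept: list[RepresentativeNUI] = []
    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom], key=lambda r: (r.ref_start, r.ref_end))
        starts = [r.ref_start for r in items]
        dense = set().union(
            *_window_groups(starts, WINDOW_DENSE_SPAN, WINDOW_DENSE_MAX), set()
        )
        removed[RULE_WINDOW_200].extend(items[i] for i in sorted(dense))
        survivors = [r for i, r in enumerate(items) if i not in dense]
        starts2 = [r.ref_start for r in survivors]
        dropped2: set[int] = set()
        for group in _window_groups(starts2, WINDOW_CROWD_SPAN, WINDOW_CROWD_MAX):
            winner = min(
                group,
                key=lambda i: (-survivors[i].insert_size, survivors[i].sample_id),
            )
            for i in sorted(group):
                if i != winner:
                    removed[RULE_WINDOW_50].append(survivors[i])
                    dropped2.add(i)
        kept.extend(r for i, r in enumerate(survivors) if i not in dropped2)
    kept.sort(key=lambda r: (r.chrom, r.ref_start, r.ref_end))
    return kept, removed


def breakpoint_consistency_filter(
    nuis: list[RepresentativeNUI],
    clusters: dict[str, Cluster],
    min_samples: int = 2,
) -> tuple[list[RepresentativeNUI], list[RepresentativeNUI]]:
    """Representatives smaller than 50 bp are kept only if at least two
    distinct samples in their cluster share the representative's exact
    reference insertion point.  Larger representatives pass untouched."""
    kept, dropped = [], []
    for nui in nuis:
        if nui.insert_size >= BREAKPOINT_SIZE_LIMIT:
            kept.append(nui)
            continue
        cluster = clusters.get(nui.cluster_id)
        if cluster is None:
            kept.append(nui)
            continue
        samples_at_point = {
            m.sample_id
            for m in cluster.members
            if m.ref_start == nui.ref_start and m.ref_end == nui.ref_end
        }
        if len(samples_at_point) >= min_samples:
            kept.append(nui)
        else:
            dropped.append(nui)
    return kept, dropped


def classify_repeat_type(
    nui: RepresentativeNUI,
    family_intervals: list[tuple[int, int, str]],
    min_fraction: float = 0.5,
) -> str:
    """Label = family covering the largest share of the sequence iff that
    share is at least 50%, else "none"."""
    length = len(nui.sequence)
    coverage: dict[str, int] = {}
    for s, e, family in family_intervals:
        if s < 0 or e > length:
            raise ValueError(f"family interval [{s},{e}) outside sequence")
        coverage[family] = coverage.get(family, 0) + (e - s)
    if not coverage:
        return "none"
    best = max(sorted(coverage), key=lambda f: coverage[f])
    if coverage[best] / length >= min_fraction:
        return best
    return "none"


@dataclass
class FilterOutcome:
    kept: list[RepresentativeNUI]
    removed: dict[str, list[RepresentativeNUI]]

    @property
    def n_removed(self) -> int:
        return sum(len(v) for v in self.removed.values())


def run_filters(
    nuis: list[RepresentativeNUI],
    clusters: dict[str, Cluster] | None = None,
    annotations: dict[str, RepeatAnnotation] | None = None,
) -> FilterOutcome:
    """Full filter stage in canonical order; idempotent on its own output."""
    removed: dict[str, list[RepresentativeNUI]] = {}
    survivors = []
    for nui in nuis:
        ann = (
            annotations.get(nui.nui_id)
            if annotations is not None
            else None
        ) or annotate_repeat_content(nui.sequence)
        report = apply_sequence_filters(nui, ann)
        if report.passed:
            survivors.append(nui)
        else:
            # tally each removal once, under the first failed rule
            removed.setdefault(report.failed_rules[0], []).append(nui)
    survivors, window_removed = apply_window_filters(survivors)
    for rule, items in window_removed.items():
        if items:
            removed.setdefault(rule, []).extend(items)
    if clusters is not None:
        survivors, bp_removed = breakpoint_consistency_filter(survivors, clusters)
        if bp_removed:
            removed.setdefault(RULE_BREAKPOINT, []).extend(bp_removed)
    return FilterOutcome(kept=survivors, removed=removed)
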