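"""Optical-map concordance and external-callset novelty comparison."""

from __future__ import annotations

from dataclasses import dataclass

from .clustering import RepresentativeNUI

STATUS_CONCORDANT_SIZE = "concordant_size"
STATUS_SITE_ONLY = "concordant_site_only"
STATUS_UNSUPPORTED = "unsupported"
STATUS_NOT_EVALUATED = "not_evaluated"

LABEL_KNOWN = "known"
LABEL_NOVEL = "novel"

OPTICAL_PAD = 5000
OPTICAL_SIZE_ABS = 700
OPTICAL_SIZE_FRAC = 0.2
OPTICAL_MAX_LABEL_DISTANCE = 500_000
OPTICAL_MIN_NUI_SIZE = 1000

SMALL_LARGE_SPLIT = 50
RATIO_SMALL = (0.9, 1.1)
RATIO_LARGE = (0.5, 2.0)


@dataclass
class OpticalCall:
    sample: str
    chrom: str
    start: int
    end: int
    size: int

    @property
    def between_label_distance(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("optical insert size must be positive")
        if self.end < self.start:
            raise ValueError("bad label interval")


@dataclass
class ConcordanceRecord:
    nui_id: str
    status: str
    support_sample: str = "."


@dataclass
class NoveltyRecord:
    nui_id: str
    label: str  # known | novel


@dataclass
class ExternalVariant:
    chrom: str
    start: int
    end: int
    size: int
    source: str = "."

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("external variant size must be positive")


def size_concordant(nui_size: int, bn_size: int) -> bool:
    """|nui - bn| within min(700 bp, 20% of the optical size)."""
    return abs(nui_size - bn_size) <= min(
        OPTICAL_SIZE_ABS, OPTICAL_SIZE_FRAC * bn_size
    )


def optical_concordance(
    nuis: list[RepresentativeNUI],
    optical_calls: list[OpticalCall],
    pad: int = OPTICAL_PAD,
    max_label_distance: int = OPTICAL_MAX_LABEL_DISTANCE,
    min_nui_size: int = OPTICAL_MIN_NUI_SIZE,
) -> list[ConcordanceRecord]:
    """Evaluate each NUI against padded optical insertion calls.

    Only NUIs with insert_size >= 1 kb and no N are evaluated.  Optical
    calls with between-label distance > 500 kb are discarded first.
    Support from any sample counts.
    """
    usable = [
        c for c in optical_calls if c.between_label_distance <= max_label_distance
    ]
    records = []
    for nui in nuis:
        if nui.insert_size < min_nui_size or "N" in nui.sequence.upper():
            records.append(ConcordanceRecord(nui.nui_id, STATUS_NOT_EVALUATED))
            continue
        s, e = nui.footprint
        status = STATUS_UNSUPPORTED
        support = "."
        for call in usable:
            if call.chrom != nui.chrom:
                continue
            if not (s < call.end + pad and call.start - pad < e):
                continue
            if size_concordant(nui.insert_size, call.size):
                status, support = STATUS_CONCORDANT_SIZE, call.sample
                break
            if status == STATUS_UNSUPPORTED:
                status, support = STATUS_SITE_ONLY, call.sample
        records.append(ConcordanceRecord(nui.nui_id, status, support))
    return records


def _ratio_bounds(nui_size: int) -> tuple[float, float]:
    return RATIO_SMALL if nui_size < SMALL_LARGE_SPLIT else RATIO_LARGE


def compare_callsets(
    nuis: list[RepresentativeNUI], externals: list[ExternalVariant]
) -> dict[str, str]:
    """Label each NUI known/novel against an external insertion callset.

    Known iff some external variant overlaps the NUI's expanded footprint
    by >= 1 bp and the size ratio nui/external lies within the class
    bounds (inclusive): [0.9, 1.1] below 50 bp, [0.5, 2] at or above.
    """
    by_chrom: dict[str, list[ExternalVariant]] = {}
    for v in externals:
        by_chrom.setdefault(v.chrom, []).append(v)
    labels = {}
    for nui in nuis:
        s, e = nui.footprint
        lo, hi = _ratio_bounds(nui.insert_size)
        label = LABEL_NOVEL
        for v in by_chrom.get(nui.chrom, []):
            vs, ve = (v.start, v.end) if v.end > v.start else (v.start, v.start + 1)
            if s < ve and vs < e:
                ratio = nui.insert_size / v.size
                if lo <= ratio <= hi:
                    label = LABEL_KNOWN
                    break
        labels[nui.nui_id] = label
    return labels
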