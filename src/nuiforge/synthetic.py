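"""Seeded synthetic data: reference, population, alignments, truth tables.

Everything is a pure function of the configuration (seed included), so
two runs are byte-identical.  The generated truth is rich enough to
compute expected pipeline output without running the pipeline: planted
events carry their carriers and per-carrier sequences, gap fills carry
their expected closure status, and scaffold layouts record every splice.

Planted event sizes follow a three-mode mixture (short indel, ~300 bp,
~6 kb) truncated to [10, 10000].
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import AlignmentBlock, BedRecord, GenomeSequence, revcomp
from .validation import OpticalCall

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# rng stream tags so each stage draws independently from the same seed
_STREAM_REFERENCE = 1
_STREAM_POPULATION = 2
_STREAM_OPTICAL = 3
_STREAM_EXPRESSION = 4


@dataclass
class SimulationConfig:
    seed: int
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000}
    )
    # reference gaps and repeat tracts
    n_gaps: int = 4
    gap_len: tuple[int, int] = (600, 1200)
    gap_types: tuple[str, ...] = ("contig",)
    gap_spacing: int = 40_000
    repeat_tracts_per_chrom: int = 8
    repeat_tract_len: tuple[int, int] = (60, 200)
    repeat_unit_len: tuple[int, int] = (2, 6)
    # population
    n_samples: int = 12
    n_recurrent: int = 60
    n_private: int = 40
    size_weights: tuple[float, float, float] = (0.5, 0.35, 0.15)
    size_short: tuple[int, int] = (10, 49)
    size_mid: tuple[float, float] = (300.0, 50.0)  # mean, sd
    size_large: tuple[float, float] = (6000.0, 800.0)
    size_bounds: tuple[int, int] = (10, 10_000)
    min_event_spacing: int = 400
    edge_margin: int = 15_000
    gap_margin: int = 12_000
    # assembly corruption / layout
    corruption_rate: float = 0.0
    reverse_strand_fraction: float = 0.0
    scaffold_split_rate: float = 0.0
    split_margin: int = 3_000
    split_min_size: int | None = None  # events >= this become split alignments
    # donor gap fills
    fill_fraction: float = 1.0
    fill_n_fraction: float = 0.0
    fill_delta: int = 0  # fill length minus gap length
    # optical map emulation
    optical_noise_sd: float = 0.0
    optical_label_pad: int = 2_000
    optical_min_size: int = 1_000
    # expression emulation
    expr_genes: int = 200
    expr_tissues: tuple[str, ...] = ("brain", "liver", "testis")
    expr_n_per_tissue: int = 5
    expr_effect_genes: int = 5
    expr_effect_log2: float = 4.0
    expr_base_log2: float = 7.0
    expr_noise_sd: float = 0.5

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key in (
            "gap_len", "gap_types", "repeat_tract_len", "repeat_unit_len",
            "size_weights", "size_short", "size_mid", "size_large",
            "size_bounds", "expr_tissues",
        ):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def sample_names(self) -> list[str]:
        return [f"S{i:02d}" for i in range(1, self.n_samples + 1)]


@dataclass
class PlantedEvent:
    event_id: str
    chrom: str
    position: int  # reference insertion point (zero-length footprint)
    sequence: str
    carriers: tuple[str, ...]  # sorted sample ids
    carrier_seqs: dict[str, str] = field(default_factory=dict)  # corrupted copies

    @property
    def size(self) -> int:
        return len(self.sequence)

    @property
    def is_recurrent(self) -> bool:
        return len(self.carriers) >= 2

    def sequence_for(self, sample: str) -> str:
        return self.carrier_seqs.get(sample, self.sequence)


@dataclass
class GapFillTruth:
    chrom: str
    start: int
    end: int
    gap_type: str
    fill: str
    expected_status: str  # closed | minimized

    @property
    def gap_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class SpliceOp:
    ref_start: int
    ref_end: int  # == ref_start for pure insertions
    alt: str
    event_id: str


@dataclass
class ScaffoldTruth:
    name: str
    sample_id: str
    haplotype_id: str
    chrom: str
    is_reversed: bool
    ref_start: int
    ref_end: int
    splices: list[SpliceOp]
    length: int = 0

    def ref_to_scaffold(self, pos: int) -> int:
        """Donor-forward scaffold coordinate of a collinear ref position."""
        off = -self.ref_start
        for sp in self.splices:
            if sp.ref_end <= pos:
                off += len(sp.alt) - (sp.ref_end - sp.ref_start)
            elif sp.ref_start < pos:
                raise ValueError(f"position {pos} inside splice {sp.event_id}")
        return pos + off


@dataclass
class SyntheticTruth:
    config: SimulationConfig
    events: list[PlantedEvent]
    gap_fills: list[GapFillTruth]
    gap_track: list[BedRecord]
    scaffolds: list[ScaffoldTruth]

    def recurrent_events(self) -> list[PlantedEvent]:
        return [e for e in self.events if e.is_recurrent]

    def private_events(self) -> list[PlantedEvent]:
        return [e for e in self.events if not e.is_recurrent]

    def expected_representatives(self) -> dict[str, tuple[str, str]]:
        """event_id -> (sample expected to be chosen, expected sequence).

        Fully resolved copies outscore N-corrupted ones; ties break to the
        alphabetically first sample id.
        """
        out = {}
        for ev in self.recurrent_events():
            resolved = [s for s in ev.carriers if s not in ev.carrier_seqs]
            chosen = min(resolved) if resolved else min(ev.carriers)
            out[ev.event_id] = (chosen, ev.sequence_for(chosen))
        return out

    def sample_to_event_ids(self, recurrent_only: bool = True) -> dict[str, set[str]]:
        events = self.recurrent_events() if recurrent_only else self.events
        out: dict[str, set[str]] = {s: set() for s in self.config.sample_names()}
        for ev in events:
            for s in ev.carriers:
                out[s].add(ev.event_id)
        return out


# ---------------------------------------------------------------------------
# reference


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode()


def simulate_reference(
    config: SimulationConfig,
) -> tuple[list[GenomeSequence], list[BedRecord]]:
    """Reference chromosomes with planted repeat tracts and N-gap runs."""
    rng = np.random.default_rng([config.seed, _STREAM_REFERENCE])
    seqs = []
    gap_track: list[BedRecord] = []
    total = sum(config.chrom_sizes.values())
    gaps_per_chrom = _allocate(rng, config.n_gaps, config.chrom_sizes, total)
    for chrom, size in config.chrom_sizes.items():
        chars = list(_random_bases(rng, size))
        for _ in range(config.repeat_tracts_per_chrom):
            unit_len = int(rng.integers(config.repeat_unit_len[0], config.repeat_unit_len[1] + 1))
            tract_len = int(rng.integers(config.repeat_tract_len[0], config.repeat_tract_len[1] + 1))
            unit = _random_bases(rng, unit_len)
            start = int(rng.integers(0, size - tract_len))
            tract = (unit * (tract_len // unit_len + 1))[:tract_len]
            chars[start : start + tract_len] = list(tract)
        placed: list[tuple[int, int]] = []
        for g in range(gaps_per_chrom[chrom]):
            glen = int(rng.integers(config.gap_len[0], config.gap_len[1] + 1))
            pos = _place(
                rng,
                size,
                glen,
                placed,
                spacing=config.gap_spacing,
                margin=config.edge_margin,
            )
            if pos > size:
                raise ValueError(f"gap spec exceeds chromosome {chrom} length")
            placed.append((pos, pos + glen))
            gtype = config.gap_types[g % len(config.gap_types)]
            chars[pos : pos + glen] = ["N"] * glen
            gap_track.append(BedRecord(chrom, pos, pos + glen, gtype))
        seqs.append(GenomeSequence(chrom, "".join(chars)))
    gap_track.sort(key=lambda r: (r.chrom, r.start))
    return seqs, gap_track


def _allocate(rng, n, chrom_sizes, total) -> dict[str, int]:
    chroms = list(chrom_sizes)
    counts = {c: 0 for c in chroms}
    probs = [chrom_sizes[c] / total for c in chroms]
    for c in rng.choice(chroms, size=n, p=probs):
        counts[str(c)] += 1
    return counts


def _place(rng, size, length, placed, spacing, margin, max_tries=10_000) -> int:
    for _ in range(max_tries):
        pos = int(rng.integers(margin, size - length - margin))
        if all(
            pos + length + spacing <= s or e + spacing <= pos for s, e in placed
        ):
            return pos
    raise RuntimeError("could not place interval; loosen spacing or enlarge genome")


# ---------------------------------------------------------------------------
# population


def _draw_size(rng, config: SimulationConfig) -> int:
    lo, hi = config.size_bounds
    mode = rng.choice(3, p=np.asarray(config.size_weights) / sum(config.size_weights))
    if mode == 0:
        val = int(rng.integers(config.size_short[0], config.size_short[1] + 1))
    elif mode == 1:
        val = int(round(rng.normal(*config.size_mid)))
    else:
        val = int(round(rng.normal(*config.size_large)))
    return min(max(val, lo), hi)


def simulate_population(
    ref: list[GenomeSequence],
    gap_track: list[BedRecord],
    config: SimulationConfig,
) -> tuple[dict[str, list[GenomeSequence]], SyntheticTruth]:
    """Plant recurrent and private insertions plus donor gap fills, then
    build per-sample haplotype scaffolds (with optional N-corruption,
    strand reversal, and scaffold splitting)."""
    rng = np.random.default_rng([config.seed, _STREAM_POPULATION])
    samples = config.sample_names()
    ref_by_name = {r.name: r for r in ref}
    chroms = list(config.chrom_sizes)
    total = sum(config.chrom_sizes.values())
    probs = [config.chrom_sizes[c] / total for c in chroms]

    forbidden: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for g in gap_track:
        forbidden[g.chrom].append(
            (g.start - config.gap_margin, g.end + config.gap_margin)
        )

    events: list[PlantedEvent] = []
    n_total = config.n_recurrent + config.n_private
    placed: dict[str, list[tuple[int, int]]] = {c: list(forbidden[c]) for c in chroms}
    for i in range(n_total):
        chrom = str(rng.choice(chroms, p=probs))
        size = _draw_size(rng, config)
        pos = _place(
            rng,
            config.chrom_sizes[chrom],
            1,
            placed[chrom],
            spacing=config.min_event_spacing,
            margin=config.edge_margin,
        )
        placed[chrom].append((pos, pos + 1))
        seq = _random_bases(rng, size)
        if i < config.n_recurrent:
            k = int(rng.integers(2, config.n_samples + 1))
            carriers = tuple(
                sorted(rng.choice(samples, size=k, replace=False).tolist())
            )
        else:
            carriers = (str(rng.choice(samples)),)
        events.append(
            PlantedEvent(
                event_id=f"evt{i:04d}",
                chrom=chrom,
                position=pos,
                sequence=seq,
                carriers=carriers,
            )
        )
    events.sort(key=lambda e: (e.chrom, e.position))

    # N-corruption: never corrupt every carrier of a recurrent event, and
    # keep the N run at ~10% of the sequence so corrupted copies still
    # clear the 80% identity threshold against resolved ones
    if config.corruption_rate > 0:
        for ev in events:
            if not ev.is_recurrent or len(ev.sequence) < 50:
                continue
            corruptible = list(ev.carriers)
            rng.shuffle(corruptible)
            corruptible.pop()  # guaranteed resolved carrier
            for s in corruptible:
                if rng.random() < config.corruption_rate:
                    run = max(5, len(ev.sequence) // 10)
                    mid = (len(ev.sequence) - run) // 2
                    ev.carrier_seqs[s] = (
                        ev.sequence[:mid] + "N" * run + ev.sequence[mid + run :]
                    )

    gap_fills: list[GapFillTruth] = []
    for g in gap_track:
        if rng.random() >= config.fill_fraction:
            continue
        flen = (g.end - g.start) + config.fill_delta
        if flen <= 0:
            continue
        fill = _random_bases(rng, flen)
        status = "closed"
        if rng.random() < config.fill_n_fraction:
            run = max(3, flen // 10)
            mid = (flen - run) // 2
            fill = fill[:mid] + "N" * run + fill[mid + run :]
            status = "minimized"
        gap_fills.append(
            GapFillTruth(
                chrom=g.chrom,
                start=g.start,
                end=g.end,
                gap_type=g.name,
                fill=fill,
                expected_status=status,
            )
        )

    reversed_samples = {
        s for s in samples if rng.random() < config.reverse_strand_fraction
    }

    scaffolds: list[ScaffoldTruth] = []
    assemblies: dict[str, list[GenomeSequence]] = {s: [] for s in samples}
    for sample in samples:
        for chrom in chroms:
            splices = [
                SpliceOp(ev.position, ev.position, ev.sequence_for(sample), ev.event_id)
                for ev in events
                if ev.chrom == chrom and sample in ev.carriers
            ]
            splices += [
                SpliceOp(f.start, f.end, f.fill, f"fill:{f.gap_id}")
                for f in gap_fills
                if f.chrom == chrom
            ]
            splices.sort(key=lambda sp: sp.ref_start)
            pieces = _maybe_split(
                rng, config, chrom, config.chrom_sizes[chrom], splices
            )
            for k, (p_start, p_end, p_splices) in enumerate(pieces):
                name = f"{sample}.h1.{chrom}"
                if len(pieces) > 1:
                    name += f".p{k}"
                st = ScaffoldTruth(
                    name=name,
                    sample_id=sample,
                    haplotype_id="1",
                    chrom=chrom,
                    is_reversed=sample in reversed_samples,
                    ref_start=p_start,
                    ref_end=p_end,
                    splices=p_splices,
                )
                seq = _scaffold_sequence(ref_by_name[chrom].bases, st)
                st.length = len(seq)
                scaffolds.append(st)
                assemblies[sample].append(GenomeSequence(name, seq))

    truth = SyntheticTruth(
        config=config,
        events=events,
        gap_fills=gap_fills,
        gap_track=list(gap_track),
        scaffolds=scaffolds,
    )
    return assemblies, truth


def _maybe_split(rng, config, chrom, size, splices):
    if config.scaffold_split_rate <= 0 or rng.random() >= config.scaffold_split_rate:
        return [(0, size, splices)]
    # split inside a long splice-free stretch so anchors stay intact
    bounds = [0] + [sp.ref_start for sp in splices] + [size]
    stretches = []
    prev_end = 0
    for sp in splices:
        if sp.ref_start - prev_end >= 2 * config.split_margin:
            stretches.append((prev_end, sp.ref_start))
        prev_end = sp.ref_end
    if size - prev_end >= 2 * config.split_margin:
        stretches.append((prev_end, size))
    _ = bounds
    if not stretches:
        return [(0, size, splices)]
    s, e = stretches[int(rng.integers(len(stretches)))]
    cut = (s + e) // 2
    left = [sp for sp in splices if sp.ref_end <= cut]
    right = [sp for sp in splices if sp.ref_start >= cut]
    return [(0, cut, left), (cut, size, right)]


def _scaffold_sequence(chrom_bases: str, st: ScaffoldTruth) -> str:
    parts = []
    pos = st.ref_start
    for sp in st.splices:
        parts.append(chrom_bases[pos : sp.ref_start])
        parts.append(sp.alt)
        pos = sp.ref_end
    parts.append(chrom_bases[pos : st.ref_end])
    seq = "".join(parts)
    return revcomp(seq) if st.is_reversed else seq


# ---------------------------------------------------------------------------
# alignment emission


def emit_alignments(
    ref: list[GenomeSequence],
    truth: SyntheticTruth,
    split_min_size: int | None = None,
    mapq: int = 60,
) -> list[AlignmentBlock]:
    """Noise-free truth alignments whose gaps encode exactly the planted
    events.  Pure insertions become cigar I runs (or separate blocks when
    their size reaches ``split_min_size``); replacement splices (gap
    fills) always split the alignment into flanking blocks."""
    if split_min_size is None:
        split_min_size = truth.config.split_min_size
    ref_len = {r.name: len(r.bases) for r in ref}
    blocks: list[AlignmentBlock] = []
    for st in truth.scaffolds:
        segments = []  # (ref_b, q_b, cigar ops) in donor-forward coords
        cigar: list[tuple[int, str]] = []
        block_ref, block_q = st.ref_start, 0
        cur_ref, cur_q = st.ref_start, 0

        def close() -> None:
            nonlocal cigar, block_ref, block_q
            if cigar and any(op == "M" for _, op in cigar):
                segments.append((block_ref, block_q, cigar))
            cigar = []

        for sp in st.splices:
            mlen = sp.ref_start - cur_ref
            if mlen > 0:
                cigar.append((mlen, "M"))
                cur_ref += mlen
                cur_q += mlen
            is_replacement = sp.ref_end > sp.ref_start
            if is_replacement or (
                split_min_size is not None and len(sp.alt) >= split_min_size
            ):
                close()
                cur_ref = sp.ref_end
                cur_q += len(sp.alt)
                block_ref, block_q = cur_ref, cur_q
            else:
                cigar.append((len(sp.alt), "I"))
                cur_q += len(sp.alt)
        tail = st.ref_end - cur_ref
        if tail > 0:
            cigar.append((tail, "M"))
            cur_ref += tail
            cur_q += tail
        close()

        for ref_b, q_b, ops in segments:
            q_span = sum(n for n, op in ops if op in ("M", "I"))
            r_span = sum(n for n, op in ops if op in ("M", "D"))
            if st.is_reversed:
                qs = st.length - (q_b + q_span)
                qe = st.length - q_b
                strand = "-"
            else:
                qs, qe = q_b, q_b + q_span
                strand = "+"
            block = AlignmentBlock(
                query_name=st.name,
                query_length=st.length,
                query_start=qs,
                query_end=qe,
                strand=strand,
                ref_name=st.chrom,
                ref_length=ref_len[st.chrom],
                ref_start=ref_b,
                ref_end=ref_b + r_span,
                mapq=mapq,
                is_primary=True,
                cigar=list(ops),
            )
            block.validate()
            blocks.append(block)
    return blocks


def emit_flank_alignments(
    ref: list[GenomeSequence],
    truth: SyntheticTruth,
    gaps,
    flank_len: int = 10_000,
    mapq: int = 60,
) -> list[AlignmentBlock]:
    """Truth alignments of the two reference flanks of each gap to every
    scaffold that fully covers the flanked region."""
    blocks = []
    for gap in gaps:
        lname = f"{gap.chrom}:{gap.start}-{gap.end}:L"
        rname = f"{gap.chrom}:{gap.start}-{gap.end}:R"
        l_lo = max(0, gap.start - flank_len)
        r_hi = gap.end + flank_len
        for st in truth.scaffolds:
            if st.chrom != gap.chrom:
                continue
            if not (st.ref_start <= l_lo and r_hi <= st.ref_end):
                continue
            for qname, lo, hi in ((lname, l_lo, gap.start), (rname, gap.end, r_hi)):
                blocks.append(
                    _flank_block(st, qname, lo, hi, mapq)
                )
    return blocks


def _flank_block(
    st: ScaffoldTruth, qname: str, lo: int, hi: int, mapq: int
) -> AlignmentBlock:
    # splices strictly inside the flank appear as scaffold-only bases,
    # i.e. deletions from the flank query
    cigar: list[tuple[int, str]] = []
    pos = lo
    inner = [sp for sp in st.splices if lo < sp.ref_start and sp.ref_end < hi]
    for sp in inner:
        if sp.ref_end > sp.ref_start:
            raise ValueError("replacement splice inside a gap flank")
        if sp.ref_start > pos:
            cigar.append((sp.ref_start - pos, "M"))
            pos = sp.ref_start
        cigar.append((len(sp.alt), "D"))
    if hi > pos:
        cigar.append((hi - pos, "M"))
    t_s = st.ref_to_scaffold(lo)
    t_e = st.ref_to_scaffold(hi)
    qlen = hi - lo
    if st.is_reversed:
        strand = "-"
        t_s, t_e = st.length - t_e, st.length - t_s
        cigar = list(reversed(cigar))
    else:
        strand = "+"
    block = AlignmentBlock(
        query_name=qname,
        query_length=qlen,
        query_start=0,
        query_end=qlen,
        strand=strand,
        ref_name=st.name,
        ref_length=st.length,
        ref_start=t_s,
        ref_end=t_e,
        mapq=mapq,
        is_primary=True,
        cigar=cigar,
    )
    block.validate()
    return block


# ---------------------------------------------------------------------------
# optical and expression emulation


def simulate_optical_calls(
    truth: SyntheticTruth,
    noise_sd: float | None = None,
    label_pad: int | None = None,
    min_size: int | None = None,
) -> list[OpticalCall]:
    """One optical insertion call per carrier of each large planted event;
    sizes are the true size plus seeded Gaussian noise."""
    config = truth.config
    rng = np.random.default_rng([config.seed, _STREAM_OPTICAL])
    noise_sd = config.optical_noise_sd if noise_sd is None else noise_sd
    label_pad = config.optical_label_pad if label_pad is None else label_pad
    min_size = config.optical_min_size if min_size is None else min_size
    calls = []
    for ev in truth.events:
        if ev.size < min_size:
            continue
        for sample in ev.carriers:
            size = ev.size
            if noise_sd > 0:
                size = int(round(size + rng.normal(0.0, noise_sd)))
            calls.append(
                OpticalCall(
                    sample=sample,
                    chrom=ev.chrom,
                    start=max(0, ev.position - label_pad),
                    end=ev.position + label_pad,
                    size=max(1, size),
                )
            )
    return calls


@dataclass
class TruthEventRecord:
    """Flattened planted-event row for the truth table fixture."""

    event_id: str
    chrom: str
    position: int
    size: int
    carriers: str  # comma-joined sample ids
    sequence: str


def write_fixtures(config: SimulationConfig, outdir) -> None:
    """Emit the full fixture set (FASTA/PAF/BED/TSV) plus truth tables."""
    from pathlib import Path

    from .formats import write_alignments, write_bed, write_fasta, write_table
    from .gap_closure import load_gap_track
    from .validation import OpticalCall as _OC

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ref, gap_track = simulate_reference(config)
    write_fasta(ref, out / "ref.fa")
    write_bed(gap_track, out / "gaps.bed")
    assemblies, truth = simulate_population(ref, gap_track, config)
    asm_dir = out / "asm"
    asm_dir.mkdir(exist_ok=True)
    for sample, scaffolds in assemblies.items():
        write_fasta(scaffolds, asm_dir / f"{sample}.fa")
    write_alignments(emit_alignments(ref, truth), out / "aln.paf")
    gaps = load_gap_track(gap_track)
    write_alignments(emit_flank_alignments(ref, truth, gaps), out / "flanks.paf")
    optical = simulate_optical_calls(truth)
    write_table(optical, out / "optical.tsv", record_type=_OC)
    counts, labels, _effect = simulate_expression(config)
    counts.to_csv(out / "expr_counts.tsv", sep="\t")
    with open(out / "expr_labels.tsv", "w") as fh:
        for sample, tissue in labels.items():
            fh.write(f"{sample}\t{tissue}\n")
    rows = [
        TruthEventRecord(
            event_id=ev.event_id,
            chrom=ev.chrom,
            position=ev.position,
            size=ev.size,
            carriers=",".join(ev.carriers),
            sequence=ev.sequence,
        )
        for ev in truth.events
    ]
    write_table(rows, out / "truth_events.tsv", record_type=TruthEventRecord)


def simulate_expression(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, dict[str, str], dict[str, set[str]]]:
    """Gene x sample raw counts with planted per-tissue log2 shifts.

    Counts are rounded 2**N(base, sd) draws; effect genes get an extra
    ``expr_effect_log2`` shift in their tissue.  Returns (counts, sample
    tissue labels, tissue -> planted effect gene set).
    """
    rng = np.random.default_rng([config.seed, _STREAM_EXPRESSION])
    genes = [f"g{j:04d}" for j in range(config.expr_genes)]
    samples = []
    labels = {}
    for tissue in config.expr_tissues:
        for i in range(config.expr_n_per_tissue):
            name = f"{tissue}_{i}"
            samples.append(name)
            labels[name] = tissue
    log_means = np.full((len(genes), len(samples)), config.expr_base_log2)
    effect: dict[str, set[str]] = {t: set() for t in config.expr_tissues}
    if config.expr_effect_genes > 0:
        pool = rng.permutation(len(genes))
        k = config.expr_effect_genes
        for t_idx, tissue in enumerate(config.expr_tissues):
            chosen = pool[t_idx * k : (t_idx + 1) * k]
            effect[tissue] = {genes[g] for g in chosen}
            cols = [j for j, s in enumerate(samples) if labels[s] == tissue]
            for g in chosen:
                log_means[g, cols] += config.expr_effect_log2
    values = rng.normal(log_means, config.expr_noise_sd)
    counts = np.maximum(0, np.round(2.0**values)).astype(int)
    frame = pd.DataFrame(counts, index=genes, columns=samples)
    return frame, labels, effect
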