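"""Shared fixtures: synthetic bundles and small helpers."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from nuiforge.clustering import select_representatives
from nuiforge.formats import GenomeSequence
from nuiforge.insertion_calling import InsertionCall, call_sample
from nuiforge.synthetic import (
    SimulationConfig,
    emit_alignments,
    simulate_population,
    simulate_reference,
)


@dataclass
class SimBundle:
    config: SimulationConfig
    ref: list[GenomeSequence]
    gap_track: list
    assemblies: dict[str, list[GenomeSequence]]
    truth: object
    blocks: list
    calls: list[InsertionCall]


def make_bundle(config: SimulationConfig) -> SimBundle:
    ref, gap_track = simulate_reference(config)
    assemblies, truth = simulate_population(ref, gap_track, config)
    blocks = emit_alignments(ref, truth)
    calls = []
    for sample, scaffolds in assemblies.items():
        sample_blocks = [b for b in blocks if b.query_name.startswith(sample + ".")]
        calls.extend(call_sample(sample_blocks, scaffolds, sample))
    return SimBundle(config, ref, gap_track, assemblies, truth, blocks, calls)


@pytest.fixture(scope="session")
def small_bundle() -> SimBundle:
    """A fast, fully noise-free population for unit tests."""
    config = SimulationConfig(
        seed=11,
        chrom_sizes={"chr1": 400_000, "chr2": 300_000},
        n_samples=5,
        n_recurrent=12,
        n_private=6,
        n_gaps=2,
    )
    return make_bundle(config)


@pytest.fixture(scope="session")
def small_reps(small_bundle):
    return select_representatives(small_bundle.calls, small_bundle.ref)


def make_call(
    sample: str,
    chrom: str = "chr1",
    ref_start: int = 100,
    ref_end: int = 100,
    sequence: str = "ACGTACGTACGT",
    hap: str = "1",
) -> InsertionCall:
    return InsertionCall(
        sample_id=sample,
        haplotype_id=hap,
        chrom=chrom,
        ref_start=ref_start,
        ref_end=ref_end,
        query_name=f"{sample}.h{hap}.{chrom}",
        query_start=0,
        query_end=len(sequence),
        strand="+",
        sequence=sequence,
    )
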