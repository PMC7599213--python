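# nuiforge

Discovery of recurrent non-reference unique insertions (NUIs) from
assembly-to-reference alignments, and their linear integration into an
augmented "diversity" reference with a coordinate mapping table.

The pipeline has four main stages, mirrored by the package modules:

1. **Per-sample insertion calling** (`insertion_calling`) — insertions are
   derived from the cigar of individual alignments and from the gaps between
   adjacent alignments of one query; insert size is the query-gap size minus
   the reference-gap size (floor 10 bp). Calls on non-core contigs or in
   blacklist/segmental-duplication tracks are excluded.
2. **Clustering and representative selection** (`clustering`) — calls whose
   reference breakpoints overlap by ≥ 1 bp form components; singleton-sample
   components are dropped. Members are padded with 50 bp of reference context
   (only when some insert exceeds 50 bp), soft-masked (built-in tandem and
   low-complexity detectors), multiple-aligned (center-star), and scored
   against the column consensus (match +2 unmasked / +0.2 masked, mismatch −1,
   N −0.5, gap 0). Clusters form recursively at ≥ 80% pairwise identity
   (match +1, mismatch −4, N 0, gap open −4) to the best unassigned member,
   and each cluster's top becomes a representative if its footprint is free.
3. **Filtering** (`nui_filters`) — repeat/low-complexity content rules,
   undetermined-base rules, sliding 200 bp (> 5 → remove all) and 50 bp
   (> 2 → keep longest) window rules, and a breakpoint-consistency rule for
   insertions < 50 bp.
4. **Reference augmentation** (`hdr_build`, `gap_closure`) — reference N-gaps
   are closed (or minimized, when residual N remains) by anchoring 10 kb
   flanks in assemblies at mapq ≥ 30; deduplicated gap fills and surviving
   NUIs are spliced into the chromosomes, emitting an augmented FASTA plus a
   bidirectional interval mapping table with liftover support.

Supporting modules: `validation` (optical-map size/site concordance with the
min(700 bp, 20%) rule and a 500 kb label-distance exclusion; known/novel
comparison against external callsets at 0.9–1.1 / 0.5–2 size ratios),
`analysis` (rarefaction and power-law discovery projection, 3 bp frame
classification, genic priority annotation, Welch-t + Benjamini–Hochberg
tissue specificity), `synthetic` (fully seeded generators for references,
populations, truth alignments, optical calls, and expression matrices, with
exact truth tables), and `formats` (FASTA / PAF-with-cigar / BED / versioned
TSV round-trip I/O; all coordinates 0-based half-open).

## CLI

`nuiforge` exposes one subcommand per stage. A complete synthetic run:

```sh
nuiforge simulate --seed 1 --outdir fx
nuiforge call --ref fx/ref.fa --asm fx/asm/S01.fa --aln fx/aln.paf \
    --sample S01 --out fx/S01.calls.tsv          # repeat per sample
nuiforge cluster --calls fx/S01.calls.tsv --calls fx/S02.calls.tsv \
    --ref fx/ref.fa --out fx/reps.tsv
nuiforge filter --reps fx/reps.tsv --out fx/reps.filtered.tsv \
    --report fx/filter_report.tsv
nuiforge closegaps --ref fx/ref.fa --gaps fx/gaps.bed \
    --asm fx/asm/S01.fa --aln fx/flanks.paf --out fx/fills.tsv
nuiforge build --ref fx/ref.fa --reps fx/reps.filtered.tsv \
    --gapfills fx/fills.tsv --out-fa fx/hdr.fa --out-map fx/hdr.map.tsv
nuiforge liftover --map fx/hdr.map.tsv --chrom chr1 --pos 12345 \
    --direction ref2hdr
nuiforge validate --reps fx/reps.filtered.tsv --optical fx/optical.tsv \
    --out fx/concordance.tsv
nuiforge compare --reps fx/reps.filtered.tsv --external ext.tsv \
    --out fx/novelty.tsv
nuiforge saturate --sets sets.tsv --nperm 100 --seed 7 --out curve.tsv
nuiforge tissuespec --counts fx/expr_counts.tsv --labels fx/expr_labels.tsv \
    --out fx/tissue.tsv
nuiforge annotate --reps fx/reps.filtered.tsv --genes genes.bed \
    --out fx/annot.tsv
```

`nuiforge simulate` also accepts a YAML config (`--config sim.yaml`) covering
chromosome sizes, gap/repeat structure, population size, the event-size
mixture (short-indel, ~300 bp, and ~6 kb modes), assembly corruption,
strand reversal, scaffold splitting, optical noise, and the expression
design; see `nuiforge.synthetic.SimulationConfig` for all keys and defaults.

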