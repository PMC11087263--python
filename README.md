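# splinkmap

Map transposon integration sites in a genome from splinkerette-PCR junction
sequencing reads.

## The problem

The piggyBac DNA transposon integrates exclusively at TTAA tetranucleotides
and duplicates the target site, so after integration one genomic TTAA flanks
each end of the inserted cargo. Splinkerette PCR (spPCR) — a
ligation-mediated PCR whose hairpin adapter suppresses nonspecific
amplification — amplifies the genomic DNA flanking each inverted terminal
repeat (ITR), and paired-end sequencing of the nested-PCR product yields
*junction reads*: after the ITR primer is trimmed away, the genome-derived
portion of the read begins (or, for the opposite flank, ends) with the
duplicated TTAA. Mapping those reads back to the reference locates every
integration.

`splinkmap` implements that analysis for anyone characterizing transposon
integrations in an engineered cell line (e.g. verifying where a set of
piggyBac transgenes landed): primer/adapter trimming with junction-side
tagging, strict end-to-end ungapped alignment, TTAA-anchored candidate
assembly, two-stage validation, and classification of validated sites
against a gene annotation. Because raw spPCR datasets are rarely deposited,
the package ships a first-class read simulator with ground truth, so every
stage is testable end to end.

## The method

For a read set R aligned end-to-end (no clips, no gaps, ≤ 2 substitutions)
a read r with flank tag `side(r) ∈ {left, right}` is a junction read when
the reference sequence of its alignment interval `[s, e)` satisfies

    side = right  (3'TR primer):  G[s .. s+4)  = TTAA,  site at s
    side = left   (5'TR primer):  G[e−4 .. e)  = TTAA,  site at e−4

Junction reads are grouped by the genomic TTAA they anchor — reads from the
two flanks of one insertion overlap by exactly that duplicated
tetranucleotide — and reads identical in (start, end, strand) are collapsed
as PCR duplicates. A candidate site becomes a **validated insertion call**
when

1. both flanks carry ≥ 1 deduplicated junction read, and
2. no TTAA other than the duplicated target lies between the two flanks'
   innermost read boundaries (the default *between-reads* rule; stricter
   per-read and all-reads variants are available — see `docs/methods.md`).

Validated sites are classified against a GFF3 annotation as exon (CDS),
5'UTR, 3'UTR, intron or intergenic, with precedence exon > UTR > intron.

The package also provides the caliper-based tumour volume estimate used to
monitor grafts derived from engineered cells, V = L·W·H·π/6 (mm³).

## Worked example

Simulate a library of 12 insertions on a 500 kb toy genome (2×100 bp pairs,
20 pairs per flank, 1% substitution errors, 10% background pairs) and run
the full pipeline:

```sh
cat > config.yaml <<EOF
seed: 42
simulate:
  n_contigs: 1
  contig_length: 500000
  n_insertions: 12
  junction_depth: 20
  error_rate: 0.01
  background_fraction: 0.1
EOF
splinkmap run --config config.yaml --out run
```

The run summary (abridged) prints:

```json
{
  "candidate_count": 12,
  "validated_count": 12,
  "stages": {
    "trim":      {"pairs_in": 533, "pairs_out": 533, "tagged_left": 239,
                  "tagged_right": 240, "untagged": 54, ...},
    "align":     {"reads_in": 1066, "aligned_unique": 989, "unmapped": 77, ...},
    "junctions": {"junction_reads": 461, "dropped_untagged": 528, ...},
    "call":      {"candidates": 12, "validated": 12, "rejected": 0}
  }
}
```

All 533 simulated pairs survive trimming; 479 of the 480 junction pairs are
side-tagged (one drew too many errors inside its primer), the 53 background
pairs plus that read stay untagged. After alignment, the 461 deduplicated-to-
be junction reads anchor exactly 12 TTAA sites, and all 12 are validated —
they match the simulator's ground truth in `run/sim/truth.bed`. The calls
land in `run/calls/calls.bed`:

```
contig1	40854	40858	site0001	1	+
contig1	46660	46664	site0002	1	+
```

Each interval is the 4 bp duplicated TTAA; the score is the smaller of the
two flank supports. `run/calls/candidates.tsv` lists every candidate with
its per-flank support, status and rejection reason.

The same stages are available individually (`splinkmap simulate | trim |
align | call | annotate | volume`) and as library functions
(`splinkmap.run_pipeline`, `splinkmap.detect_junctions`, …). Externally
aligned reads can enter via SAM (`splinkmap.import_alignments`); clipped or
gapped records are excluded to preserve the end-to-end contract.

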