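# Methods

## Model of the data

A piggyBac integration at genomic TTAA position *p* (0-based, the interval
[p, p+4)) leaves the duplicated tetranucleotide on both sides of the
inserted cargo. Nested splinkerette PCR amplifies each transposon–genome
boundary from inside the ITRs outward, so the sequenced mate 1 of a junction
pair is

    [nested ITR primer][TTAA][genomic flank …]

with the 5'TR (left) nested primer reading into the upstream flank and the
3'TR (right) primer into the downstream flank; mate 2 is plain genomic
sequence further into the same flank (toward the splinkerette adapter). Two
facts carry the whole analysis: the genome-derived portion of a trimmed
junction read starts at a TTAA, and left- and right-flank reads of the same
insertion share exactly that genomic TTAA (a 4 bp alignment overlap). TTAA
is its own reverse complement, so both statements are orientation-free.

## Pipeline stages

**Trimming and side assignment** (`trim`). Primer search is prefix-anchored
Hamming matching: the leftmost anchor position where the whole primer fits
with at most ⌈0.1 × primer length⌉ substitutions (3 for the 30 bp nested
primers). Indels are not considered — nested-PCR products carry the primer
verbatim at the read start, and an indel-free match keeps every downstream
coordinate exact. Only the nested (secondary) primers assign a side; primary
primers are trimmed when present but carry no side information, since the
nested product dominates the sequenced material. Splinkerette adapter
sequence is removed from mate 3' ends when a full-length match is found.
Pairs in which both nested primers match mate 1 are ambiguous and discarded;
pairs whose reads fall below `min_length` (default 20 bp, the shortest
uniquely mappable length on the toy genomes used here) are discarded; both
discard classes are counted so that pairs-in = pairs-out + discards holds in
every run log. The side tag belongs to mate 1 only: the mate carries no ITR
evidence and is never allowed to nominate a junction.

**Alignment** (`align`). Strictly end-to-end and ungapped, ≤ 2 substitutions
(configurable), both strands, because junction logic depends on the exact
genomic coordinates of read termini — a gap or clip would move them. The
built-in aligner keeps a sorted k-mer index (k = 15) per contig and uses
pigeonhole seeding: a read with ≤ m mismatches split into m+1 chunks has at
least one error-free chunk, whose leading k-mer is looked up exactly; every
candidate offset is then verified by full Hamming comparison. Reads shorter
than (m+1)·k fall back to an exhaustive scan, so the guarantee is unchanged.
Reads with more than one equally best placement are flagged non-unique and
excluded from calling (counted, never randomly assigned — random placement
could fabricate sites); unmapped reads are counted. Placement depends only
on the read sequence, so results are memoized per distinct sequence.
External aligners can substitute for the built-in one via SAM import, where
any record with clip/indel CIGAR operations is excluded for the same reason
and uniqueness is read from MAPQ (< 10 → non-unique) or an NH tag.

**Junction detection and candidate assembly** (`call`). The genome-facing
terminus of a tagged read follows from its flank: left-side reads lie
upstream of the insertion, so their junction TTAA is at the alignment's
high-coordinate end; right-side reads at the low-coordinate end. The
terminal tetranucleotide is read from the *reference*, not the read, so
substitution errors cannot shift a junction. Each junction read records
whether a TTAA also occurs at a non-terminal position of its aligned
reference sequence (`internal_ttaa`). Junction reads are grouped by
(contig, ttaa_start); within a group, reads identical in (start, end,
strand) collapse as PCR duplicates — splinkerette libraries are heavily
amplified and fragment-end identity is the standard duplicate proxy in the
absence of UMIs.

**Validation.** A candidate is validated when (a) both flanks have at least
`min_support` (default 1) deduplicated junction reads, and (b) the
internal-TTAA rule holds. Three interpretations of rule (b) are
implemented behind `internal_ttaa_mode`:

- `between-reads` (default): no TTAA other than the duplicated target may
  lie in the gap between the two flanks' innermost alignment boundaries.
  Junction reads abut at the target TTAA, so the gap is normally empty and
  the rule guards against flanks joined across an intervening TTAA.
- `per-read`: each flank must contribute at least one read with
  `internal_ttaa = false`.
- `all-reads`: every supporting read must be clean.

`between-reads` is the default on two grounds. First, a chance TTAA
elsewhere in a junction read is expected every ~256 bp of random sequence
(~22% of 66 bp flank windows contain one) and carries no evidence against
the insertion; what identifies a real site is that the two flanks meet at a
single duplicated TTAA. Second, junction reads of one flank share their
start coordinate by construction (the chemistry pins mate 1's start to the
junction), so after duplicate collapse each flank is typically represented
by one alignment and the per-read relaxation ("at least one clean read")
degenerates to all-reads, rejecting roughly a quarter of true sites for a
chance flanking TTAA. The stricter modes remain available for reviewing
marginal calls, and every rejected candidate is written with its reason to
`candidates.tsv` in place of a manual genome-browser inspection step, which
is not reproducible.

**Annotation** (`annotate`). GFF3 gene models are read with gffutils;
five_prime_UTR/three_prime_UTR features are honored when present and
otherwise derived as exonic-minus-CDS, split by strand around the CDS span.
A site's category is decided by overlap (≥ 1 shared base of the 4 bp TTAA
interval) with fixed precedence CDS-exon > 5'UTR > 3'UTR > intron >
intergenic; "exon" therefore means coding exon, with UTR hits reported
separately. Exons of transcripts without any CDS count as exon. Ties across
transcripts resolve to the alphabetically first gene name, making
classification invariant to transcript order in the file. Lookup uses
per-category interval trees; a per-base painting oracle in the test suite
checks the equivalence.

## The synthetic-data generator

The simulator is the package's stand-in for a real spPCR sequencing run and
defines the conditions under which the pipeline is validated: one or more
uniform-composition contigs (every contig guaranteed ≥ 1 TTAA), insertions
placed only at TTAA sites, 2×100 bp pairs, 50 pairs per flank, a fixed
300 bp fragment span, constant Q40 qualities, substitution errors at a
configurable rate, and a configurable fraction of primer-less background
pairs drawn from random genomic positions (modelling genomic carry-over,
the simplest contaminant class consistent with the protocol). Left-flank
junction reads are emitted reverse-complemented relative to the reference so
both alignment orientations are exercised. Default placement enforces
≥ 2×read-length spacing between insertions (separating caller correctness
from collision handling; `enforce_spacing=False` relaxes it) and errors are
kept out of mate 1's junction TTAA (`protect_junction_ttaa=False` re-enables
them), so exact-recovery runs are deterministic and robustness can be
stressed separately.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: indels and instrument-specific quality profiles,
variable fragment-size distributions, chimeric PCR artifacts, repetitive
genome content beyond what uniform random sequence produces, and multiple
insertions closer than two read lengths. Real libraries also yield
variable-length reads after quality trimming, which would diversify the
per-flank read sets that the duplicate collapse reduces to one here.

## Numerical and procedural choices

- Coordinates are 0-based half-open everywhere internally; 1-based only in
  SAM. BED output intervals are the 4 bp TTAA itself, re-checked against
  the reference at write time (an assertion, not a filter).
- Deterministic ordering throughout: alignments sort by (contig, start,
  read id, mate), candidates by (contig, position); summaries serialize
  with sorted keys; identical config + seed give byte-identical artifacts.
- All randomness flows from explicit integer seeds through NumPy
  generators; the simulator derives its read-level stream from
  `seed + 1` so genome and reads are independently reproducible.
- Degenerate inputs: empty read sets and empty genomes are rejected with
  messages; an annotation file without features yields an empty model list
  and a warning rather than an error; out-of-range alignment intervals
  raise, since they indicate corrupt input rather than noise.
- Validation problem sizes: exact- and robust-recovery checks use 30
  insertions on a 1 Mb contig at depth 50 (≈ 3 000–3 750 pairs), sizes at
  which the built-in aligner's index build and the full pipeline complete
  in a few seconds while TTAA sites (~3 900 per Mb) vastly outnumber
  insertions, keeping placement non-trivial.

## Limitations

Only the piggyBac TTAA motif is exercised; the duplicated-motif logic is
parameterized internally but TA-site transposons (Sleeping Beauty) are
untested. No clonality or abundance estimation is attempted from read
counts, and no cross-sample recurrence statistics. The aligner is intended
for desk-scale genomes (≲ tens of Mb); for real mammalian genomes, align
externally in end-to-end mode and import the SAM. Category counts on real
data depend on the annotation release used; the classifier reports whatever
GFF3 it is given.
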