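"""Synthetic genomes, piggyBac insertions and splinkerette-style reads.

piggyBac integrates exclusively at TTAA tetranucleotides and duplicates the
target site, so after integration one genomic TTAA flanks each end of the
transposon.  A splinkerette junction read therefore looks like::

    [nested ITR primer][TTAA][genomic flank ...]          (read 1)
    [genomic sequence further into the same flank]        (read 2, mate)

This module generates toy genomes, places ground-truth insertions only at
TTAA sites, and emits paired FASTQ reads with that structure plus
configurable substitution errors and primer-less background pairs, so the
whole downstream pipeline can be exercised against a known truth set.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np

from ._seq import TTAA, decode, find_motif, revcomp
from .primers import DEFAULT_PRIMERS, PrimerSet

_MIN_CONTIG_LENGTH = 1000


@dataclass(frozen=True)
class ToyGenome:
    """A small reference genome: named contigs of uppercase A/C/G/T."""

    contigs: tuple[tuple[str, str], ...]
    seed: int = 0

    def __post_init__(self) -> None:
        names = [n for n, _ in self.contigs]
        if len(names) != len(set(names)):
            raise ValueError("contig names must be unique")
        for name, seq in self.contigs:
            if set(seq) - set("ACGT"):
                raise ValueError(f"contig {name} contains non-ACGT characters")

    @property
    def sequences(self) -> dict[str, str]:
        return dict(self.contigs)

    def write_fasta(self, path: str, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs:
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    @classmethod
    def from_fasta(cls, path: str) -> "ToyGenome":
        from Bio import SeqIO

        contigs = tuple(
            (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")
        )
        if not contigs:
            raise ValueError(f"no sequences found in {path}")
        return cls(contigs=contigs)


@dataclass(frozen=True)
class InsertionTruth:
    """A ground-truth integration event anchored at a genomic TTAA."""

    contig: str
    ttaa_start: int  # 0-based start of the duplicated TTAA tetranucleotide
    event_id: str


@dataclass(frozen=True)
class SimParams:
    """Read-simulation parameters.

    junction_depth is read pairs emitted per insertion flank;
    background_fraction is the proportion of *all* emitted pairs that are
    primer-less random genomic pairs; errors are substitutions only.
    """

    n_insertions: int = 30
    read_length: int = 100
    junction_depth: int = 50
    error_rate: float = 0.0
    background_fraction: float = 0.0
    seed: int = 0
    insert_size: int = 300
    # errors are kept out of read 1's junction TTAA so exact recovery is
    # deterministic; disable to stress-test the caller
    protect_junction_ttaa: bool = True
    # "hard mode": drop the ≥2×read_length spacing guarantee between events
    enforce_spacing: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must be in [0, 0.1)")
        if not 0 <= self.background_fraction < 1:
            raise ValueError("background_fraction must be in [0, 1)")
        if self.junction_depth < 1:
            raise ValueError("junction_depth must be >= 1")
        if self.n_insertions < 0:
            raise ValueError("n_insertions must be >= 0")
        if self.insert_size < self.read_length:
            raise ValueError("insert_size must be >= read_length")


def generate_genome(
    n_contigs: int, contig_length: int, seed: int, gc: float = 0.5
) -> ToyGenome:
    """Random uniform-composition genome, deterministic for a fixed seed.

    Every contig is guaranteed to contain at least one TTAA (one is planted
    at a random interior position in the vanishingly rare case none arose).
    """
    if contig_length < _MIN_CONTIG_LENGTH:
        raise ValueError(
            f"contig_length must be >= {_MIN_CONTIG_LENGTH}, got {contig_length}"
        )
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    rng = np.random.default_rng(seed)
    p_at = (1 - gc) / 2
    p_gc = gc / 2
    probs = [p_at, p_gc, p_gc, p_at]  # A C G T
    contigs = []
    for i in range(n_contigs):
        codes = rng.choice(4, size=contig_length, p=probs).astype(np.uint8)
        seq = decode(codes)
        if TTAA not in seq:
            pos = int(rng.integers(100, contig_length - 100))
            seq = seq[:pos] + TTAA + seq[pos + 4 :]
        contigs.append((f"contig{i + 1}", seq))
    return ToyGenome(contigs=tuple(contigs), seed=seed)


def place_insertions(genome: ToyGenome, params: SimParams) -> list[InsertionTruth]:
    """Choose TTAA sites for ground-truth insertions.

    Sites are kept >= insert_size from contig ends (so full fragments fit)
    and, by default, >= 2×read_length apart so each truth site is supported
    by unambiguous reads.  Deterministic for a fixed params.seed.
    """
    if params.n_insertions == 0:
        return []
    margin = params.insert_size
    min_spacing = 2 * params.read_length if params.enforce_spacing else 1
    eligible: list[tuple[str, int]] = []
    for name, seq in genome.contigs:
        for pos in find_motif(seq, TTAA):
            if margin <= pos and pos + 4 + margin <= len(seq):
                eligible.append((name, pos))
    rng = np.random.default_rng(params.seed)
    order = rng.permutation(len(eligible))
    chosen: dict[str, list[int]] = {}
    picked: list[tuple[str, int]] = []
    for idx in order:
        name, pos = eligible[idx]
        taken = chosen.setdefault(name, [])
        if all(abs(pos - q) >= min_spacing for q in taken):
            taken.append(pos)
            picked.append((name, pos))
            if len(picked) == params.n_insertions:
                break
    if len(picked) < params.n_insertions:
        raise ValueError(
            f"could not place {params.n_insertions} insertions: only "
            f"{len(picked)} of {len(eligible)} eligible TTAA sites satisfy "
            f"the {min_spacing} bp spacing constraint"
        )
    picked.sort()
    return [
        InsertionTruth(contig=name, ttaa_start=pos, event_id=f"ins{i:04d}")
        for i, (name, pos) in enumerate(picked)
    ]


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    seq1: str
    seq2: str
    is_background: bool = False


@dataclass
class SimOutput:
    """File paths and counters from a simulate_reads run."""

    fastq_1: str
    fastq_2: str
    truth_bed: str
    truth_tsv: str
    n_junction_pairs: int
    n_background_pairs: int


def _apply_errors(
    seq: str, rng: np.random.Generator, error_rate: float, protected: range
) -> str:
    if error_rate == 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(len(arr)) < error_rate)
    if protected:
        hit = hit[(hit < protected.start) | (hit >= protected.stop)]
    for i in hit:
        alts = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = alts[rng.integers(3)]
    return arr.tobytes().decode("ascii")


def simulate_read_pairs(
    genome: ToyGenome,
    truth: list[InsertionTruth],
    params: SimParams,
    primers: PrimerSet = DEFAULT_PRIMERS,
) -> list[ReadPair]:
    """Generate read pairs in memory; see the module docstring for layout.

    Per event and flank, ``junction_depth`` pairs are emitted.  Left-flank
    junction reads are reverse-complemented relative to the reference (the
    genome-derived portion still begins with TTAA, because TTAA is its own
    reverse complement), so both alignment orientations are exercised.
    """
    rl = params.read_length
    seqs = genome.sequences
    for primer in (primers.nested_5TR, primers.nested_3TR):
        if rl <= len(primer) + 4:
            raise ValueError(
                f"read_length {rl} too short for primer ({len(primer)} bp) + TTAA"
            )
    rng = np.random.default_rng(params.seed + 1)
    pairs: list[ReadPair] = []
    for ev in truth:
        seq = seqs[ev.contig]
        p = ev.ttaa_start
        for flank, primer in (("L", primers.nested_5TR), ("R", primers.nested_3TR)):
            glen = rl - len(primer)
            if flank == "R":
                genomic1 = seq[p : p + glen]
                genomic2 = revcomp(seq[p + params.insert_size - rl : p + params.insert_size])
            else:
                genomic1 = revcomp(seq[p + 4 - glen : p + 4])
                genomic2 = seq[p + 4 - params.insert_size : p + 4 - params.insert_size + rl]
            for d in range(params.junction_depth):
                r1 = primer + genomic1
                protected = (
                    range(len(primer), len(primer) + 4)
                    if params.protect_junction_ttaa
                    else range(0)
                )
                r1 = _apply_errors(r1, rng, params.error_rate, protected)
                r2 = _apply_errors(genomic2, rng, params.error_rate, range(0))
                pairs.append(
                    ReadPair(read_id=f"{ev.event_id}:{flank}:{d}", seq1=r1, seq2=r2)
                )
    n_junction = len(pairs)
    if params.background_fraction > 0 and n_junction > 0:
        n_bg = round(
            params.background_fraction * n_junction / (1 - params.background_fraction)
        )
        names = [n for n, _ in genome.contigs]
        lengths = np.array([len(s) for _, s in genome.contigs], dtype=float)
        weights = lengths / lengths.sum()
        for i in range(n_bg):
            name = names[rng.choice(len(names), p=weights)]
            seq = seqs[name]
            s = int(rng.integers(0, len(seq) - params.insert_size))
            fwd = seq[s : s + rl]
            rev = revcomp(seq[s + params.insert_size - rl : s + params.insert_size])
            if rng.random() < 0.5:
                r1, r2 = fwd, rev
            else:
                r1, r2 = rev, fwd
            r1 = _apply_errors(r1, rng, params.error_rate, range(0))
            r2 = _apply_errors(r2, rng, params.error_rate, range(0))
            pairs.append(ReadPair(read_id=f"bg:{i}", seq1=r1, seq2=r2, is_background=True))
    return pairs


def simulate_reads(
    genome: ToyGenome,
    truth: list[InsertionTruth],
    params: SimParams,
    primers: PrimerSet = DEFAULT_PRIMERS,
    out_dir: str = ".",
) -> SimOutput:
    """Write paired FASTQ (Phred+33, constant Q40) plus the truth table.

    The truth table is emitted both as BED (0-based half-open TTAA interval)
    and as TSV with the event id.  Byte-identical for identical inputs.
    """
    os.makedirs(out_dir, exist_ok=True)
    pairs = simulate_read_pairs(genome, truth, params, primers)
    fq1 = os.path.join(out_dir, "reads_1.fastq")
    fq2 = os.path.join(out_dir, "reads_2.fastq")
    with open(fq1, "w") as f1, open(fq2, "w") as f2:
        for pr in pairs:
            f1.write(f"@{pr.read_id}/1\n{pr.seq1}\n+\n{'I' * len(pr.seq1)}\n")
            f2.write(f"@{pr.read_id}/2\n{pr.seq2}\n+\n{'I' * len(pr.seq2)}\n")
    bed = os.path.join(out_dir, "truth.bed")
    tsv = os.path.join(out_dir, "truth.tsv")
    with open(bed, "w") as fh:
        for ev in truth:
            fh.write(f"{ev.contig}\t{ev.ttaa_start}\t{ev.ttaa_start + 4}\t{ev.event_id}\n")
    with open(tsv, "w") as fh:
        fh.write("event_id\tcontig\tttaa_start\n")
        for ev in truth:
            fh.write(f"{ev.event_id}\t{ev.contig}\t{ev.ttaa_start}\n")
    n_bg = sum(1 for p in pairs if p.is_background)
    return SimOutput(
        fastq_1=fq1,
        fastq_2=fq2,
        truth_bed=bed,
        truth_tsv=tsv,
        n_junction_pairs=len(pairs) - n_bg,
        n_background_pairs=n_bg,
    )


@dataclass(frozen=True)
class SimGene:
    """Planted gene structure used by the synthetic GFF3 generator."""

    gene_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # 0-based half-open, sorted
    cds: tuple[tuple[int, int], ...]


def simulate_annotation(
    genome: ToyGenome, n_genes: int, seed: int, gene_length: int = 3000
) -> tuple[str, list[SimGene]]:
    """Plant non-overlapping multi-exon genes and return (GFF3 text, truth).

    Each gene has 2–4 exons; the CDS starts and ends strictly inside the
    exonic span so every gene has both a 5' and a 3' UTR.  Only gene/mRNA/
    exon/CDS features are written — UTRs are left for the loader to derive.
    """
    rng = np.random.default_rng(seed)
    genes: list[SimGene] = []
    lines = ["##gff-version 3"]
    gi = 0
    for name, seq in genome.contigs:
        n_here = n_genes - len(genes)
        if n_here <= 0:
            break
        slot = len(seq) // max(n_here, 1)
        for k in range(n_here):
            lo = k * slot
            if slot < gene_length + 200:
                break
            start = lo + int(rng.integers(0, slot - gene_length - 100))
            n_ex = int(rng.integers(2, 5))
            # carve the gene span into alternating exons and introns
            cuts = np.sort(rng.choice(gene_length - 2, size=2 * n_ex - 1, replace=False) + 1)
            bounds = [0, *cuts.tolist(), gene_length]
            exons = tuple(
                (start + bounds[2 * i], start + bounds[2 * i + 1]) for i in range(n_ex)
            )
            exons = tuple((s, e) for s, e in exons if e > s)
            if len(exons) < 2:
                continue
            exonic = []
            for s, e in exons:
                exonic.extend(range(s, e))
            n_exonic = len(exonic)
            if n_exonic < 30:
                continue
            utr5_len = int(rng.integers(5, max(6, n_exonic // 4)))
            utr3_len = int(rng.integers(5, max(6, n_exonic // 4)))
            cds_bases = exonic[utr5_len : n_exonic - utr3_len]
            cds = _bases_to_intervals(cds_bases)
            strand = "+" if rng.random() < 0.5 else "-"
            gi += 1
            gid = f"gene{gi:03d}"
            genes.append(
                SimGene(gene_id=gid, contig=name, strand=strand, exons=exons, cds=cds)
            )
            g_s, g_e = exons[0][0], exons[-1][1]
            lines.append(
                f"{name}\tsim\tgene\t{g_s + 1}\t{g_e}\t.\t{strand}\t.\tID={gid};Name={gid}"
            )
            tid = f"{gid}.t1"
            lines.append(
                f"{name}\tsim\tmRNA\t{g_s + 1}\t{g_e}\t.\t{strand}\t.\tID={tid};Parent={gid}"
            )
            for s, e in exons:
                lines.append(
                    f"{name}\tsim\texon\t{s + 1}\t{e}\t.\t{strand}\t.\tParent={tid}"
                )
            for s, e in cds:
                lines.append(
                    f"{name}\tsim\tCDS\t{s + 1}\t{e}\t.\t{strand}\t0\tParent={tid}"
                )
    return "\n".join(lines) + "\n", genes


def _bases_to_intervals(bases: list[int]) -> tuple[tuple[int, int], ...]:
    if not bases:
        return ()
    out = []
    s = prev = bases[0]
    for b in bases[1:]:
        if b != prev + 1:
            out.append((s, prev + 1))
            s = b
        prev = b
    out.append((s, prev + 1))
    return tuple(out)
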