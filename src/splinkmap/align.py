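"""End-to-end (ungapped) read placement on desk-scale reference genomes.

Junction calling depends on the exact genomic coordinates of read termini,
so alignment is strictly end-to-end and ungapped: a read is placed where the
whole read matches with at most ``max_mismatch`` substitutions and no
indels.  Reads with more than one equally good placement are flagged
non-unique and excluded downstream — a random assignment could fabricate
insertion sites.

The built-in aligner uses a sorted k-mer index with a pigeonhole seeding
scheme (a read with <= m mismatches split into m+1 chunks has at least one
error-free chunk, whose leading k-mer is used as a seed), and falls back to
a full scan for reads too short for that guarantee.  External end-to-end
aligners can be substituted via SAM import.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pysam

from ._seq import encode, revcomp
from .simulate import ToyGenome
from .trim import SIDE_NONE, TrimmedRead


@dataclass
class AlignConfig:
    k: int = 15  # seed k-mer length
    max_mismatch: int = 2
    mapq_unique: int = 10  # SAM import: records below this MAPQ are non-unique


@dataclass(frozen=True, order=True)
class AlignmentRecord:
    """One ungapped end-to-end placement, 0-based half-open coordinates."""

    contig: str
    start: int
    end: int
    read_id: str
    mate: int
    strand: str
    side: str
    n_mismatches: int
    unique: bool


@dataclass
class AlignStats:
    reads_in: int = 0
    aligned_unique: int = 0
    aligned_multi: int = 0
    unmapped: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)

    def check_conservation(self) -> None:
        if self.reads_in != self.aligned_unique + self.aligned_multi + self.unmapped:
            raise AssertionError(f"alignment accounting violated: {self.as_dict()}")


class GenomeIndex:
    """Sorted k-mer index over every contig of a genome."""

    def __init__(self, genome: ToyGenome, k: int = 15):
        self.genome = genome
        self.k = k
        self._enc: dict[str, np.ndarray] = {}
        self._codes: dict[str, np.ndarray] = {}
        self._order: dict[str, np.ndarray] = {}
        powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        for name, seq in genome.contigs:
            arr = encode(seq)
            self._enc[name] = arr
            if len(arr) < k:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(arr, k)
            codes = windows.astype(np.int64) @ powers
            order = np.argsort(codes, kind="stable").astype(np.int64)
            self._codes[name] = codes[order]
            self._order[name] = order
        self._powers = powers

    def seed_hits(self, kmer_codes: np.ndarray, contig: str) -> np.ndarray:
        """Positions of each k-mer code in one contig (concatenated)."""
        codes = self._codes.get(contig)
        if codes is None:
            return np.empty(0, dtype=np.int64)
        lo = np.searchsorted(codes, kmer_codes, side="left")
        hi = np.searchsorted(codes, kmer_codes, side="right")
        order = self._order[contig]
        return np.concatenate([order[a:b] for a, b in zip(lo, hi)]) if len(lo) else np.empty(0, dtype=np.int64)

    def encoded(self, contig: str) -> np.ndarray:
        return self._enc[contig]


def _hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int(np.count_nonzero(a != b))


def _place_sequence(
    seq: str, index: GenomeIndex, cfg: AlignConfig
) -> list[tuple[str, int, str, int]]:
    """All equally best placements of *seq* as (contig, start, strand, mm)."""
    L = len(seq)
    hits: dict[tuple[str, int, str], int] = {}
    use_seeds = L >= (cfg.max_mismatch + 1) * cfg.k
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        arr = encode(s)
        if use_seeds:
            offsets = [round(i * L / (cfg.max_mismatch + 1)) for i in range(cfg.max_mismatch + 1)]
            codes = np.array(
                [int(arr[o : o + cfg.k].astype(np.int64) @ index._powers) for o in offsets],
                dtype=np.int64,
            )
            for name, _ in index.genome.contigs:
                enc = index.encoded(name)
                starts: set[int] = set()
                for o, code in zip(offsets, codes):
                    for pos in index.seed_hits(np.array([code]), name):
                        st = int(pos) - o
                        if 0 <= st <= len(enc) - L:
                            starts.add(st)
                for st in starts:
                    key = (name, st, strand)
                    if key not in hits:
                        mm = _hamming(enc[st : st + L], arr)
                        if mm <= cfg.max_mismatch:
                            hits[key] = mm
        else:
            for name, _ in index.genome.contigs:
                enc = index.encoded(name)
                if len(enc) < L:
                    continue
                windows = np.lib.stride_tricks.sliding_window_view(enc, L)
                mms = np.count_nonzero(windows != arr, axis=1)
                for st in np.flatnonzero(mms <= cfg.max_mismatch):
                    hits[(name, int(st), strand)] = int(mms[st])
    if not hits:
        return []
    best = min(hits.values())
    placements = sorted(
        (name, st, strand, mm) for (name, st, strand), mm in hits.items() if mm == best
    )
    return placements


def align_reads(
    trimmed_reads: list[TrimmedRead],
    genome: ToyGenome,
    config: AlignConfig | None = None,
    index: GenomeIndex | None = None,
) -> tuple[list[AlignmentRecord], AlignStats]:
    """Align trimmed reads end-to-end on both strands.

    Placement depends only on the read sequence, so results are memoized per
    distinct sequence.  Output ordering is deterministic: (contig, start,
    read_id, mate).
    """
    cfg = config or AlignConfig()
    if not genome.contigs or all(not s for _, s in genome.contigs):
        raise ValueError("empty genome")
    if not trimmed_reads:
        raise ValueError("empty read set")
    idx = index or GenomeIndex(genome, cfg.k)
    cache: dict[str, list[tuple[str, int, str, int]]] = {}
    stats = AlignStats()
    records: list[AlignmentRecord] = []
    for r in trimmed_reads:
        stats.reads_in += 1
        placements = cache.get(r.sequence)
        if placements is None:
            placements = _place_sequence(r.sequence, idx, cfg)
            cache[r.sequence] = placements
        if not placements:
            stats.unmapped += 1
            continue
        unique = len(placements) == 1
        name, st, strand, mm = placements[0]
        if unique:
            stats.aligned_unique += 1
        else:
            stats.aligned_multi += 1
        records.append(
            AlignmentRecord(
                contig=name,
                start=st,
                end=st + len(r.sequence),
                read_id=r.read_id,
                mate=r.mate,
                strand=strand,
                side=r.side,
                n_mismatches=mm,
                unique=unique,
            )
        )
    stats.check_conservation()
    records.sort()
    return records, stats


def write_sam(
    records: list[AlignmentRecord], genome: ToyGenome, path: str
) -> None:
    """Write alignments as plain-text SAM (MAPQ 60 unique / 0 multi)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name, seq in genome.contigs:
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for r in sorted(records):
            flag = 0x1 | (0x40 if r.mate == 1 else 0x80)
            if r.strand == "-":
                flag |= 0x10
            mapq = 60 if r.unique else 0
            cigar = f"{r.end - r.start}M"
            fh.write(
                f"{r.read_id}\t{flag}\t{r.contig}\t{r.start + 1}\t{mapq}\t"
                f"{cigar}\t*\t0\t0\t*\t*\tNM:i:{r.n_mismatches}\n"
            )


@dataclass
class ImportStats:
    records_in: int = 0
    imported: int = 0
    excluded_unmapped: int = 0
    excluded_clipped_or_gapped: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)

    def check_conservation(self) -> None:
        total = self.imported + self.excluded_unmapped + self.excluded_clipped_or_gapped
        if self.records_in != total:
            raise AssertionError(f"import accounting violated: {self.as_dict()}")


def import_alignments(
    sam_path: str,
    side_map: dict[str, str] | None = None,
    genome: ToyGenome | None = None,
    config: AlignConfig | None = None,
) -> tuple[list[AlignmentRecord], ImportStats]:
    """Normalize externally produced SAM records to AlignmentRecord.

    Soft/hard-clipped or gapped records violate the end-to-end contract and
    are excluded (counted).  Multi-mappers are detected by MAPQ below
    ``mapq_unique`` or an NH tag > 1 and marked unique=False.  The junction
    side is re-attached by read id from the trim stage's side map.
    """
    cfg = config or AlignConfig()
    sides = side_map or {}
    contigs = set(genome.sequences) if genome is not None else None
    stats = ImportStats()
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        for rec in sam:
            stats.records_in += 1
            if rec.is_unmapped or rec.reference_name is None:
                stats.excluded_unmapped += 1
                continue
            if contigs is not None and rec.reference_name not in contigs:
                raise ValueError(
                    f"SAM record {rec.query_name} refers to unknown contig "
                    f"{rec.reference_name}"
                )
            # end-to-end contract: CIGAR must be pure (mis)match
            if any(op not in (0, 7, 8) for op, _ in (rec.cigartuples or [])):
                stats.excluded_clipped_or_gapped += 1
                continue
            nh = rec.get_tag("NH") if rec.has_tag("NH") else 1
            unique = rec.mapping_quality >= cfg.mapq_unique and nh == 1
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            mate = 2 if rec.is_read2 else 1
            stats.imported += 1
            records.append(
                AlignmentRecord(
                    contig=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    read_id=rec.query_name,
                    mate=mate,
                    strand="-" if rec.is_reverse else "+",
                    # the junction side belongs to the primer-bearing mate 1
                    side=sides.get(rec.query_name, SIDE_NONE) if mate == 1 else SIDE_NONE,
                    n_mismatches=int(nm),
                    unique=unique,
                )
            )
    stats.check_conservation()
    records.sort()
    return records, stats
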