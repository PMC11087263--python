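"""Primer identification, trimming and junction-side tagging.

The nested ITR primers sit at the start of every true junction read; finding
one both trims it and tells us which transposon end (5'TR = left, 3'TR =
right) the read comes from.  Matching is Hamming-only (no indels) so that
coordinates downstream of the trim point stay exact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

from .primers import DEFAULT_PRIMERS, PrimerSet

_MIN_PRIMER_LENGTH = 10

SIDE_LEFT = "left"
SIDE_RIGHT = "right"
SIDE_NONE = "none"


@dataclass
class TrimConfig:
    max_mismatch_frac: float = 0.1
    min_length: int = 20  # shortest read kept after trimming


@dataclass(frozen=True)
class TrimmedRead:
    read_id: str
    mate: int  # 1 or 2
    sequence: str
    side: str = SIDE_NONE
    trimmed_bases: int = 0
    quality: str | None = None


@dataclass
class TrimStats:
    """Per-category read-pair accounting; in = out + discards always."""

    pairs_in: int = 0
    pairs_out: int = 0
    tagged_left: int = 0
    tagged_right: int = 0
    untagged: int = 0
    discarded_ambiguous: int = 0
    discarded_short: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)

    def check_conservation(self) -> None:
        if self.pairs_in != self.pairs_out + self.discarded_ambiguous + self.discarded_short:
            raise AssertionError(f"trim accounting violated: {self.as_dict()}")


def _hamming_leq(a: str, b: str, limit: int) -> bool:
    """True iff Hamming(a, b) <= limit; early exit keeps scans cheap."""
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return False
    return True


def match_primer(
    read_sequence: str, primer: str, max_mismatch_frac: float = 0.1
) -> int | None:
    """Leftmost anchor position where *primer* matches fully within the read.

    A match allows at most ceil(max_mismatch_frac × len(primer)) substitution
    mismatches; indels are not considered.  Returns None when no anchor
    position qualifies.
    """
    if len(primer) < _MIN_PRIMER_LENGTH:
        raise ValueError(
            f"primer must be >= {_MIN_PRIMER_LENGTH} bp, got {len(primer)}"
        )
    limit = math.ceil(max_mismatch_frac * len(primer))
    for i in range(len(read_sequence) - len(primer) + 1):
        if _hamming_leq(read_sequence[i : i + len(primer)], primer, limit):
            return i
    return None


class AmbiguousPrimerError(Exception):
    """Both nested primers match one read — side cannot be assigned."""


def _tag_and_trim_read1(
    seq: str, qual: str | None, primers: PrimerSet, cfg: TrimConfig
) -> tuple[str, str | None, str, int]:
    """Returns (sequence, quality, side, trimmed_bases) for a mate-1 read."""
    m5 = match_primer(seq, primers.nested_5TR, cfg.max_mismatch_frac)
    m3 = match_primer(seq, primers.nested_3TR, cfg.max_mismatch_frac)
    if m5 is not None and m3 is not None:
        raise AmbiguousPrimerError
    if m5 is not None:
        cut = m5 + len(primers.nested_5TR)
        side = SIDE_LEFT
    elif m3 is not None:
        cut = m3 + len(primers.nested_3TR)
        side = SIDE_RIGHT
    else:
        # primary (Sp1) primers are trimmed when present but never tag a side
        side = SIDE_NONE
        cut = 0
        for primary in (primers.primary_5TR, primers.primary_3TR):
            m = match_primer(seq, primary, cfg.max_mismatch_frac)
            if m is not None:
                cut = m + len(primary)
                break
    return seq[cut:], qual[cut:] if qual is not None else None, side, cut


def _trim_splinkerette(
    seq: str, qual: str | None, primers: PrimerSet, cfg: TrimConfig
) -> tuple[str, str | None, int]:
    """Remove splinkerette adapter read-through from a read's 3' end."""
    from ._seq import revcomp

    best: int | None = None
    for adapter in (
        primers.splinkerette_top,
        primers.splinkerette_hairpin,
        revcomp(primers.splinkerette_top),
        revcomp(primers.splinkerette_hairpin),
    ):
        m = match_primer(seq, adapter, cfg.max_mismatch_frac)
        if m is not None and (best is None or m < best):
            best = m
    if best is None:
        return seq, qual, 0
    return seq[:best], qual[:best] if qual is not None else None, len(seq) - best


def trim_and_tag(
    read_id: str,
    seq1: str,
    seq2: str,
    primers: PrimerSet = DEFAULT_PRIMERS,
    config: TrimConfig | None = None,
    qual1: str | None = None,
    qual2: str | None = None,
) -> tuple[TrimmedRead, TrimmedRead] | None:
    """Trim one read pair; returns None when the pair is discarded.

    Raises AmbiguousPrimerError when both nested primers match read 1
    (callers count and discard such pairs).
    """
    cfg = config or TrimConfig()
    if not seq1 or not seq2:
        raise ValueError("reads must be non-empty")
    s1, q1, side, cut1 = _tag_and_trim_read1(seq1, qual1, primers, cfg)
    s2, q2, cut2 = _trim_splinkerette(seq2, qual2, primers, cfg)
    if len(s1) < cfg.min_length or len(s2) < cfg.min_length:
        return None
    # the junction side is evidenced by the ITR primer on read 1 only; the
    # mate is splinkerette-side genomic sequence and stays untagged
    return (
        TrimmedRead(read_id, 1, s1, side, cut1, q1),
        TrimmedRead(read_id, 2, s2, SIDE_NONE, cut2, q2),
    )


def trim_pairs(
    pairs,
    primers: PrimerSet = DEFAULT_PRIMERS,
    config: TrimConfig | None = None,
) -> tuple[list[tuple[TrimmedRead, TrimmedRead]], TrimStats]:
    """Trim an iterable of (read_id, seq1, seq2[, qual1, qual2]) tuples."""
    cfg = config or TrimConfig()
    stats = TrimStats()
    out: list[tuple[TrimmedRead, TrimmedRead]] = []
    for item in pairs:
        read_id, seq1, seq2 = item[0], item[1], item[2]
        qual1 = item[3] if len(item) > 3 else None
        qual2 = item[4] if len(item) > 4 else None
        stats.pairs_in += 1
        try:
            res = trim_and_tag(read_id, seq1, seq2, primers, cfg, qual1, qual2)
        except AmbiguousPrimerError:
            stats.discarded_ambiguous += 1
            continue
        if res is None:
            stats.discarded_short += 1
            continue
        r1, _ = res
        if r1.side == SIDE_LEFT:
            stats.tagged_left += 1
        elif r1.side == SIDE_RIGHT:
            stats.tagged_right += 1
        else:
            stats.untagged += 1
        stats.pairs_out += 1
        out.append(res)
    stats.check_conservation()
    return out, stats


def trim_fastq(
    fastq_1: str,
    fastq_2: str,
    out_1: str,
    out_2: str,
    side_map_path: str,
    primers: PrimerSet = DEFAULT_PRIMERS,
    config: TrimConfig | None = None,
    stats_path: str | None = None,
) -> TrimStats:
    """File-level trimming: paired FASTQ in, trimmed FASTQ + side map out.

    The side map (read_id → left/right/none TSV) carries the junction-side
    tag to the aligner and to externally produced SAM files.
    """
    from Bio import SeqIO

    def _iter():
        it1 = SeqIO.parse(fastq_1, "fastq")
        it2 = SeqIO.parse(fastq_2, "fastq")
        for rec1, rec2 in zip(it1, it2):
            rid = rec1.id.rsplit("/", 1)[0]
            q1 = "".join(
                chr(q + 33) for q in rec1.letter_annotations["phred_quality"]
            )
            q2 = "".join(
                chr(q + 33) for q in rec2.letter_annotations["phred_quality"]
            )
            yield rid, str(rec1.seq).upper(), str(rec2.seq).upper(), q1, q2

    trimmed, stats = trim_pairs(_iter(), primers, config)
    with open(out_1, "w") as f1, open(out_2, "w") as f2, open(side_map_path, "w") as fm:
        fm.write("read_id\tside\n")
        for r1, r2 in trimmed:
            f1.write(f"@{r1.read_id}/1\n{r1.sequence}\n+\n{r1.quality or 'I' * len(r1.sequence)}\n")
            f2.write(f"@{r2.read_id}/2\n{r2.sequence}\n+\n{r2.quality or 'I' * len(r2.sequence)}\n")
            fm.write(f"{r1.read_id}\t{r1.side}\n")
    if stats_path:
        with open(stats_path, "w") as fh:
            json.dump(stats.as_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    return stats


def read_side_map(path: str) -> dict[str, str]:
    sides: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            rid, side = line.rstrip("\n").split("\t")
            sides[rid] = side
    return sides
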