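"""TTAA-anchored insertion-site calling from junction alignments.

piggyBac duplicates its TTAA target site, so after integration one genomic
TTAA abuts each end of the transposon.  A primer-tagged read whose
genome-facing terminus lands exactly on a TTAA is a junction read; junction
reads from the two flanks of the same insertion overlap by exactly that
duplicated tetranucleotide.  Calling proceeds in three steps:

1. ``detect_junctions`` — keep uniquely aligned, primer-tagged reads whose
   genome-facing terminus is a reference TTAA; flag reads that also contain
   a TTAA at a non-terminal position (``internal_ttaa``).
2. ``build_candidates`` — group junction reads by the genomic TTAA they
   anchor, collapse PCR duplicates (identical start/end/strand), and tally
   support on the upstream (left) and downstream (right) flank.
3. ``validate_sites`` — a candidate becomes a validated insertion call when
   both flanks are supported and the internal-TTAA rule holds; everything
   else is kept with an explicit rejection reason for review.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._seq import TTAA, find_motif
from .align import AlignmentRecord
from .trim import SIDE_NONE

JUNCTION_5P = "5p"  # TTAA at the alignment's 5' (lower-coordinate) terminus
JUNCTION_3P = "3p"  # TTAA at the alignment's 3' (upper-coordinate) terminus

MODE_PER_READ = "per-read"
MODE_ALL_READS = "all-reads"
MODE_BETWEEN_READS = "between-reads"

STATUS_VALIDATED = "validated"
STATUS_REJECTED = "rejected"

REASON_NONE = "none"
REASON_SINGLE_FLANK = "single_flank"
REASON_INTERNAL_TTAA = "internal_ttaa"


@dataclass
class CallConfig:
    # between-reads: a site is clean when no TTAA other than the duplicated
    # target site lies between the two flanks' innermost read boundaries.
    # A chance TTAA elsewhere in a junction read (expected every ~256 bp of
    # random sequence) is no evidence against an insertion, and junction
    # reads collapse to one alignment per flank after PCR dedup, so the
    # stricter per-read / all-reads modes reject true sites whose flank
    # happens to contain a second TTAA; they remain available for review.
    internal_ttaa_mode: str = MODE_BETWEEN_READS
    min_support: int = 1  # deduplicated junction reads required per flank

    def __post_init__(self) -> None:
        if self.internal_ttaa_mode not in (
            MODE_PER_READ,
            MODE_ALL_READS,
            MODE_BETWEEN_READS,
        ):
            raise ValueError(f"unknown internal_ttaa_mode {self.internal_ttaa_mode!r}")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")


@dataclass(frozen=True)
class JunctionRead:
    alignment: AlignmentRecord
    junction_end: str  # JUNCTION_5P or JUNCTION_3P
    ttaa_start: int
    internal_ttaa: bool

    @property
    def flank(self) -> str:
        """Which flank of the insertion the read supports.

        A read *ending* with the TTAA lies upstream of the insertion (left
        flank); a read *beginning* with it lies downstream (right flank).
        """
        return "left" if self.junction_end == JUNCTION_3P else "right"


@dataclass
class JunctionStats:
    alignments_in: int = 0
    junction_reads: int = 0
    dropped_no_ttaa: int = 0
    dropped_untagged: int = 0
    dropped_nonunique: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)

    def check_conservation(self) -> None:
        total = (
            self.junction_reads
            + self.dropped_no_ttaa
            + self.dropped_untagged
            + self.dropped_nonunique
        )
        if self.alignments_in != total:
            raise AssertionError(f"junction accounting violated: {self.as_dict()}")


def detect_junctions(
    alignments: list[AlignmentRecord], genome_seqs: dict[str, str]
) -> tuple[list[JunctionRead], JunctionStats]:
    """Identify junction reads among primer-tagged unique alignments.

    The genome-facing terminus follows from the flank the primer assigned:
    a side=left (5'TR) read lies upstream of the insertion, so its junction
    TTAA sits at the alignment's higher-coordinate (3') terminus; a
    side=right (3'TR) read lies downstream, junction at the lower-coordinate
    (5') terminus.  The terminal tetranucleotide is read from the
    *reference*, so substitution errors in the read cannot shift a junction.
    Untagged (side=none) alignments carry no ITR evidence and are never
    junction reads.
    """
    stats = JunctionStats()
    junctions: list[JunctionRead] = []
    for a in alignments:
        stats.alignments_in += 1
        seq = genome_seqs.get(a.contig)
        if seq is None or not (0 <= a.start < a.end <= len(seq)):
            raise ValueError(
                f"alignment {a.read_id} interval [{a.start},{a.end}) outside "
                f"contig {a.contig}"
            )
        if not a.unique:
            stats.dropped_nonunique += 1
            continue
        if a.side == SIDE_NONE:
            stats.dropped_untagged += 1
            continue
        ref = seq[a.start : a.end]
        if a.side == "left":
            junction_end, terminal = JUNCTION_3P, ref[-4:]
            ttaa_start = a.end - 4
        else:
            junction_end, terminal = JUNCTION_5P, ref[:4]
            ttaa_start = a.start
        if terminal != TTAA:
            stats.dropped_no_ttaa += 1
            continue
        L = len(ref)
        internal = any(0 < p < L - 4 for p in find_motif(ref))
        stats.junction_reads += 1
        junctions.append(
            JunctionRead(
                alignment=a,
                junction_end=junction_end,
                ttaa_start=ttaa_start,
                internal_ttaa=internal,
            )
        )
    stats.check_conservation()
    return junctions, stats


@dataclass
class CandidateSite:
    """A genomic TTAA with deduplicated junction support on each flank."""

    contig: str
    ttaa_start: int
    left_support: int
    right_support: int
    has_internal_ttaa_support_only: bool
    left_reads: tuple[JunctionRead, ...] = ()
    right_reads: tuple[JunctionRead, ...] = ()


def build_candidates(
    junctions: list[JunctionRead], config: CallConfig | None = None
) -> list[CandidateSite]:
    """Group junction reads by their genomic TTAA into candidate sites.

    Two junction reads support the same site iff their terminal TTAAs map to
    the identical genomic tetranucleotide — the 4 bp overlap created by
    target-site duplication.  Within a site, reads identical in (start, end,
    strand) are collapsed as PCR duplicates before support counting.
    """
    groups: dict[tuple[str, int], list[JunctionRead]] = {}
    for j in junctions:
        groups.setdefault((j.alignment.contig, j.ttaa_start), []).append(j)
    sites: list[CandidateSite] = []
    for (contig, pos), reads in sorted(groups.items()):
        seen: set[tuple[int, int, str]] = set()
        left: list[JunctionRead] = []
        right: list[JunctionRead] = []
        for j in sorted(reads, key=lambda j: (j.alignment.start, j.alignment.end, j.alignment.strand, j.alignment.read_id)):
            key = (j.alignment.start, j.alignment.end, j.alignment.strand)
            if key in seen:
                continue
            seen.add(key)
            (left if j.flank == "left" else right).append(j)
        dedup = left + right
        sites.append(
            CandidateSite(
                contig=contig,
                ttaa_start=pos,
                left_support=len(left),
                right_support=len(right),
                has_internal_ttaa_support_only=all(j.internal_ttaa for j in dedup),
                left_reads=tuple(left),
                right_reads=tuple(right),
            )
        )
    return sites


@dataclass
class InsertionCall:
    candidate: CandidateSite
    status: str
    rejection_reason: str = REASON_NONE

    @property
    def validated(self) -> bool:
        return self.status == STATUS_VALIDATED


def _internal_rule_ok(
    site: CandidateSite, genome_seqs: dict[str, str], mode: str
) -> bool:
    if mode == MODE_PER_READ:
        # at least one supporting read per flank free of internal TTAA
        return any(not j.internal_ttaa for j in site.left_reads) and any(
            not j.internal_ttaa for j in site.right_reads
        )
    if mode == MODE_ALL_READS:
        return all(
            not j.internal_ttaa for j in site.left_reads + site.right_reads
        )
    # between-reads: no TTAA in the gap between the flanks' innermost
    # alignment boundaries (junction reads abut at the duplicated TTAA, so
    # this gap is normally empty)
    lo = max(j.alignment.end for j in site.left_reads)
    hi = min(j.alignment.start for j in site.right_reads)
    if hi <= lo:
        return True
    span = genome_seqs[site.contig][lo:hi]
    return not find_motif(span)


def validate_sites(
    candidates: list[CandidateSite],
    genome_seqs: dict[str, str],
    config: CallConfig | None = None,
) -> list[InsertionCall]:
    """Apply the two validation rules to every candidate site.

    (a) junction support on *both* flanks (>= min_support deduplicated reads
        each); failing candidates are rejected as ``single_flank``;
    (b) the internal-TTAA rule in the configured mode; candidates failing
        only this are rejected as ``internal_ttaa``.
    """
    cfg = config or CallConfig()
    calls: list[InsertionCall] = []
    for site in candidates:
        seq = genome_seqs[site.contig]
        if seq[site.ttaa_start : site.ttaa_start + 4] != TTAA:
            raise AssertionError(
                f"candidate at {site.contig}:{site.ttaa_start} violates the "
                "TTAA invariant"
            )
        if site.left_support < cfg.min_support or site.right_support < cfg.min_support:
            calls.append(InsertionCall(site, STATUS_REJECTED, REASON_SINGLE_FLANK))
        elif not _internal_rule_ok(site, genome_seqs, cfg.internal_ttaa_mode):
            calls.append(InsertionCall(site, STATUS_REJECTED, REASON_INTERNAL_TTAA))
        else:
            calls.append(InsertionCall(site, STATUS_VALIDATED))
    return calls


def write_calls_bed(
    calls: list[InsertionCall], genome_seqs: dict[str, str], path: str
) -> None:
    """Validated calls as BED: [ttaa_start, ttaa_start+4), score = min support.

    The TTAA invariant is re-asserted on every emitted interval.
    """
    with open(path, "w") as fh:
        for i, c in enumerate(
            sorted(
                (c for c in calls if c.validated),
                key=lambda c: (c.candidate.contig, c.candidate.ttaa_start),
            )
        ):
            s = c.candidate.ttaa_start
            if genome_seqs[c.candidate.contig][s : s + 4] != TTAA:
                raise AssertionError(
                    f"output site {c.candidate.contig}:{s} violates the TTAA invariant"
                )
            score = min(c.candidate.left_support, c.candidate.right_support)
            fh.write(
                f"{c.candidate.contig}\t{s}\t{s + 4}\tsite{i + 1:04d}\t{score}\t+\n"
            )


def write_calls_tsv(calls: list[InsertionCall], path: str) -> None:
    """All candidates (validated and rejected) with support and reason."""
    with open(path, "w") as fh:
        fh.write(
            "contig\tttaa_start\tleft_support\tright_support\tstatus\trejection_reason\n"
        )
        for c in sorted(calls, key=lambda c: (c.candidate.contig, c.candidate.ttaa_start)):
            fh.write(
                f"{c.candidate.contig}\t{c.candidate.ttaa_start}\t"
                f"{c.candidate.left_support}\t{c.candidate.right_support}\t"
                f"{c.status}\t{c.rejection_reason}\n"
            )
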