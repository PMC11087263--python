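"""Classify insertion sites against a gene annotation.

Each validated site (a 4 bp TTAA interval) is assigned exactly one of five
categories — exon (CDS), 5'UTR, 3'UTR, intron, intergenic — with a fixed
precedence when transcripts or feature types overlap: coding exon beats UTR
beats intron beats intergenic, so a site is always labelled by the most
consequential feature it touches (>= 1 shared base counts as touching).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import gffutils
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

CAT_EXON = "exon"
CAT_UTR5 = "5'UTR"
CAT_UTR3 = "3'UTR"
CAT_INTRON = "intron"
CAT_INTERGENIC = "intergenic"
CATEGORIES = (CAT_EXON, CAT_UTR5, CAT_UTR3, CAT_INTRON, CAT_INTERGENIC)

Interval = tuple[int, int]  # 0-based half-open


@dataclass(frozen=True)
class GeneModel:
    """One transcript's structure in 0-based half-open coordinates."""

    transcript_id: str
    gene: str
    contig: str
    strand: str
    exons: tuple[Interval, ...]
    cds: tuple[Interval, ...]
    utr5: tuple[Interval, ...]
    utr3: tuple[Interval, ...]

    @property
    def span(self) -> Interval:
        return self.exons[0][0], self.exons[-1][1]


def _merge(intervals: list[Interval]) -> tuple[Interval, ...]:
    out: list[Interval] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return tuple(out)


def subtract_intervals(
    a: tuple[Interval, ...], b: tuple[Interval, ...]
) -> tuple[Interval, ...]:
    """Set difference a \\ b over sorted, merged interval lists."""
    out: list[Interval] = []
    for s, e in a:
        cur = s
        for bs, be in b:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
        if cur < e:
            out.append((cur, e))
    return tuple(out)


def _split_utrs(
    exons: tuple[Interval, ...], cds: tuple[Interval, ...], strand: str
) -> tuple[tuple[Interval, ...], tuple[Interval, ...]]:
    """UTRs = exonic minus CDS; sides assigned by strand around the CDS span."""
    if not cds:
        return (), ()
    leftover = subtract_intervals(exons, cds)
    cds_lo, cds_hi = cds[0][0], cds[-1][1]
    upstream = tuple(iv for iv in leftover if iv[1] <= cds_lo)
    downstream = tuple(iv for iv in leftover if iv[0] >= cds_hi)
    if strand == "+":
        return upstream, downstream
    return downstream, upstream


def load_annotation(gff3_path: str) -> list[GeneModel]:
    """Parse a GFF3 into per-transcript gene models.

    five_prime_UTR / three_prime_UTR features are used when present;
    otherwise UTRs are derived as exonic-minus-CDS, split by strand.
    Transcripts without a usable strand are skipped with a warning.
    """
    with open(gff3_path) as fh:
        has_features = any(
            line.strip() and not line.startswith("#") for line in fh
        )
    if not has_features:
        logger.warning("annotation %s contains no features", gff3_path)
        return []
    try:
        db = gffutils.create_db(
            gff3_path, ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils reports the offending line
        raise ValueError(f"failed to parse {gff3_path}: {exc}") from exc
    models: list[GeneModel] = []
    skipped = 0
    for tx in db.features_of_type(("mRNA", "transcript")):
        if tx.strand not in ("+", "-"):
            skipped += 1
            continue
        exons = _merge(
            [(f.start - 1, f.end) for f in db.children(tx, featuretype="exon")]
        )
        if not exons:
            skipped += 1
            continue
        cds = _merge([(f.start - 1, f.end) for f in db.children(tx, featuretype="CDS")])
        utr5 = _merge(
            [(f.start - 1, f.end) for f in db.children(tx, featuretype="five_prime_UTR")]
        )
        utr3 = _merge(
            [(f.start - 1, f.end) for f in db.children(tx, featuretype="three_prime_UTR")]
        )
        if cds and not (utr5 or utr3):
            utr5, utr3 = _split_utrs(exons, cds, tx.strand)
        gene = tx.id
        for parent in db.parents(tx, featuretype="gene"):
            gene = parent.attributes.get("Name", [parent.id])[0]
            break
        models.append(
            GeneModel(
                transcript_id=tx.id,
                gene=gene,
                contig=tx.seqid,
                strand=tx.strand,
                exons=exons,
                cds=cds,
                utr5=utr5,
                utr3=utr3,
            )
        )
    if skipped:
        logger.warning("skipped %d transcripts without strand or exons", skipped)
    models.sort(key=lambda m: (m.contig, m.span, m.transcript_id))
    return models


@dataclass(frozen=True)
class SiteAnnotation:
    contig: str
    start: int
    end: int
    category: str
    gene: str | None  # None iff intergenic


class AnnotationIndex:
    """Interval trees per contig and feature class for O(log n) lookup."""

    def __init__(self, models: list[GeneModel]):
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for m in models:
            coding_exons = m.cds if m.cds else m.exons  # ncRNA exons count as exon
            for cat, ivs in (
                (CAT_EXON, coding_exons),
                (CAT_UTR5, m.utr5),
                (CAT_UTR3, m.utr3),
                (CAT_INTRON, subtract_intervals((m.span,), m.exons)),
            ):
                tree = self._trees.setdefault((m.contig, cat), IntervalTree())
                for s, e in ivs:
                    if e > s:
                        tree.addi(s, e, m.gene)

    def classify(self, contig: str, start: int, end: int) -> SiteAnnotation:
        for cat in (CAT_EXON, CAT_UTR5, CAT_UTR3, CAT_INTRON):
            tree = self._trees.get((contig, cat))
            if tree:
                hits = tree.overlap(start, end)
                if hits:
                    gene = min(iv.data for iv in hits)  # deterministic tie-break
                    return SiteAnnotation(contig, start, end, cat, gene)
        return SiteAnnotation(contig, start, end, CAT_INTERGENIC, None)


def classify_site(
    contig: str, ttaa_start: int, models: list[GeneModel],
    index: AnnotationIndex | None = None,
) -> SiteAnnotation:
    """Classify one TTAA site interval [ttaa_start, ttaa_start+4)."""
    idx = index or AnnotationIndex(models)
    return idx.classify(contig, ttaa_start, ttaa_start + 4)


def classify_sites(
    sites: list[tuple[str, int]], models: list[GeneModel]
) -> list[SiteAnnotation]:
    idx = AnnotationIndex(models)
    return [idx.classify(c, s, s + 4) for c, s in sites]


def summarize_categories(annotations: list[SiteAnnotation]) -> dict[str, int]:
    """Category count table; counts always sum to the number of sites."""
    table = {cat: 0 for cat in CATEGORIES}
    for a in annotations:
        table[a.category] += 1
    return table


def write_annotated_tsv(annotations: list[SiteAnnotation], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tttaa_start\tttaa_end\tcategory\tgene\n")
        for a in sorted(annotations, key=lambda a: (a.contig, a.start)):
            fh.write(
                f"{a.contig}\t{a.start}\t{a.end}\t{a.category}\t{a.gene or '.'}\n"
            )
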