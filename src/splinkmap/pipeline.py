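"""End-to-end pipeline driver and run accounting.

One config (YAML-able dict) drives simulate → trim → align → call →
annotate; every stage persists its artifacts and its in/out/discard
counters, and identical config + seeds produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
from dataclasses import dataclass, field

from . import __version__
from .align import AlignConfig, align_reads, write_sam
from .annotate import (
    classify_sites,
    load_annotation,
    summarize_categories,
    write_annotated_tsv,
)
from .call import (
    CallConfig,
    build_candidates,
    detect_junctions,
    validate_sites,
    write_calls_bed,
    write_calls_tsv,
)
from .primers import DEFAULT_PRIMERS, PrimerSet
from .simulate import (
    SimParams,
    ToyGenome,
    generate_genome,
    place_insertions,
    simulate_reads,
)
from .trim import TrimConfig, TrimmedRead, read_side_map, trim_fastq

logger = logging.getLogger(__name__)


def ellipsoid_volume(L: float, W: float, H: float) -> float:
    """Ellipsoid approximation of a caliper-measured tumour volume.

    Three orthogonal caliper lengths (mm) give V = L×W×H×π/6 in mm³ — the
    volume of an ellipsoid whose axes are the measured diameters.
    """
    if L < 0 or W < 0 or H < 0:
        raise ValueError("caliper lengths must be non-negative")
    return L * W * H * math.pi / 6


@dataclass
class RunSummary:
    """Machine-readable account of one pipeline run."""

    stages: dict = field(default_factory=dict)
    candidate_count: int = 0
    validated_count: int = 0
    category_table: dict | None = None
    config: dict = field(default_factory=dict)
    seed: int | None = None
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "RunSummary":
        return cls(**json.loads(text))

    def check_conservation(self) -> None:
        """Per-stage in = out + discarded, for every stage that reports it."""
        rules = {
            "trim": ("pairs_in", ["pairs_out"], ["discarded_ambiguous", "discarded_short"]),
            "align": ("reads_in", ["aligned_unique", "aligned_multi"], ["unmapped"]),
            "junctions": (
                "alignments_in",
                ["junction_reads"],
                ["dropped_no_ttaa", "dropped_untagged", "dropped_nonunique"],
            ),
        }
        for stage, (key_in, keys_out, keys_drop) in rules.items():
            if stage not in self.stages:
                continue
            s = self.stages[stage]
            total = sum(s[k] for k in keys_out) + sum(s[k] for k in keys_drop)
            if s[key_in] != total:
                raise AssertionError(f"stage {stage} accounting violated: {s}")
        if "call" in self.stages:
            s = self.stages["call"]
            if s["candidates"] != s["validated"] + s["rejected"]:
                raise AssertionError(f"stage call accounting violated: {s}")


def _load_trimmed(fq1: str, fq2: str, side_map_path: str) -> list[TrimmedRead]:
    from Bio import SeqIO

    sides = read_side_map(side_map_path)
    reads: list[TrimmedRead] = []
    for path, mate in ((fq1, 1), (fq2, 2)):
        for rec in SeqIO.parse(path, "fastq"):
            rid = rec.id.rsplit("/", 1)[0]
            # the side tag belongs to the ITR-primer-bearing mate 1 only
            reads.append(
                TrimmedRead(
                    read_id=rid,
                    mate=mate,
                    sequence=str(rec.seq).upper(),
                    side=sides.get(rid, "none") if mate == 1 else "none",
                )
            )
    return reads


def run_pipeline(config: dict, out_dir: str) -> RunSummary:
    """Run every configured stage, persisting intermediates under out_dir.

    Config keys: ``seed``; either ``simulate`` (parameters for the synthetic
    generator) or ``reference`` + ``reads: {r1, r2}``; optional ``primers``
    (YAML file), ``gff``, and per-stage ``trim`` / ``align`` / ``call``
    sections.  Raises with the failing stage's name; partial outputs are
    left in place for debugging.
    """
    os.makedirs(out_dir, exist_ok=True)
    seed = int(config.get("seed", 0))
    primers = (
        PrimerSet.from_yaml(config["primers"]) if config.get("primers") else DEFAULT_PRIMERS
    )
    summary = RunSummary(config=config, seed=seed)

    stage = "input"
    try:
        if "simulate" in config:
            sim_cfg = dict(config["simulate"])
            n_contigs = sim_cfg.pop("n_contigs", 1)
            contig_length = sim_cfg.pop("contig_length", 1_000_000)
            params = SimParams(seed=seed, **sim_cfg)
            genome = generate_genome(n_contigs, contig_length, seed)
            truth = place_insertions(genome, params)
            sim_dir = os.path.join(out_dir, "sim")
            sim_out = simulate_reads(genome, truth, params, primers, sim_dir)
            ref_path = os.path.join(sim_dir, "genome.fa")
            genome.write_fasta(ref_path)
            fq1, fq2 = sim_out.fastq_1, sim_out.fastq_2
            summary.stages["simulate"] = {
                "n_insertions": len(truth),
                "junction_pairs": sim_out.n_junction_pairs,
                "background_pairs": sim_out.n_background_pairs,
            }
        else:
            genome = ToyGenome.from_fasta(config["reference"])
            fq1, fq2 = config["reads"]["r1"], config["reads"]["r2"]

        stage = "trim"
        trim_dir = os.path.join(out_dir, "trim")
        os.makedirs(trim_dir, exist_ok=True)
        t1 = os.path.join(trim_dir, "trimmed_1.fastq")
        t2 = os.path.join(trim_dir, "trimmed_2.fastq")
        side_map = os.path.join(trim_dir, "side_map.tsv")
        trim_stats = trim_fastq(
            fq1, fq2, t1, t2, side_map,
            primers, TrimConfig(**config.get("trim", {})),
            stats_path=os.path.join(trim_dir, "stats.json"),
        )
        summary.stages["trim"] = trim_stats.as_dict()

        stage = "align"
        align_dir = os.path.join(out_dir, "align")
        os.makedirs(align_dir, exist_ok=True)
        records, align_stats = align_reads(
            _load_trimmed(t1, t2, side_map), genome, AlignConfig(**config.get("align", {}))
        )
        write_sam(records, genome, os.path.join(align_dir, "aln.sam"))
        summary.stages["align"] = align_stats.as_dict()

        stage = "call"
        call_dir = os.path.join(out_dir, "calls")
        os.makedirs(call_dir, exist_ok=True)
        seqs = genome.sequences
        usable = [r for r in records if r.unique]
        junctions, jstats = detect_junctions(usable, seqs)
        jstats.alignments_in = len(records)
        jstats.dropped_nonunique += len(records) - len(usable)
        summary.stages["junctions"] = jstats.as_dict()
        call_cfg = CallConfig(**config.get("call", {}))
        candidates = build_candidates(junctions, call_cfg)
        calls = validate_sites(candidates, seqs, call_cfg)
        write_calls_bed(calls, seqs, os.path.join(call_dir, "calls.bed"))
        write_calls_tsv(calls, os.path.join(call_dir, "candidates.tsv"))
        summary.candidate_count = len(candidates)
        summary.validated_count = sum(1 for c in calls if c.validated)
        summary.stages["call"] = {
            "candidates": len(candidates),
            "validated": summary.validated_count,
            "rejected": len(candidates) - summary.validated_count,
        }

        stage = "annotate"
        if config.get("gff"):
            models = load_annotation(config["gff"])
            sites = [
                (c.candidate.contig, c.candidate.ttaa_start)
                for c in calls
                if c.validated
            ]
            annotations = classify_sites(sites, models)
            annot_dir = os.path.join(out_dir, "annot")
            os.makedirs(annot_dir, exist_ok=True)
            write_annotated_tsv(annotations, os.path.join(annot_dir, "annotated.tsv"))
            summary.category_table = summarize_categories(annotations)
            with open(os.path.join(annot_dir, "categories.json"), "w") as fh:
                json.dump(summary.category_table, fh, indent=2, sort_keys=True)
                fh.write("\n")
        else:
            logger.warning("no gene annotation configured; skipping classification")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary.check_conservation()
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        fh.write(summary.to_json())
    return summary
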