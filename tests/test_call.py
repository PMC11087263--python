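"""Junction detection, candidate assembly and two-stage validation."""

import random

import pytest

from splinkmap import (
    CallConfig,
    ToyGenome,
    build_candidates,
    detect_junctions,
    validate_sites,
)
from splinkmap._seq import TTAA, find_motif
from splinkmap.align import AlignmentRecord
from splinkmap.call import (
    JUNCTION_3P,
    JUNCTION_5P,
    JunctionRead,
    REASON_INTERNAL_TTAA,
    REASON_SINGLE_FLANK,
    STATUS_REJECTED,
    STATUS_VALIDATED,
    write_calls_bed,
)

from conftest import make_ttaa_free, plant_ttaa


def aln(contig, start, end, side, strand="+", read_id="r", mate=1, unique=True, mm=0):
    return AlignmentRecord(
        contig=contig, start=start, end=end, read_id=read_id, mate=mate,
        strand=strand, side=side, n_mismatches=mm, unique=unique,
    )


@pytest.fixture
def genome_one_site():
    """TTAA-free 2 kb backbone with a single TTAA at position 1000."""
    seq = plant_ttaa(make_ttaa_free(2000, seed=1), [1000])
    return {"chr1": seq}


class TestDetectJunctions:
    def test_right_flank_read_begins_with_ttaa(self, genome_one_site):
        a = aln("chr1", 1000, 1060, side="right")
        (j,), stats = detect_junctions([a], genome_one_site)
        assert (j.junction_end, j.ttaa_start) == (JUNCTION_5P, 1000)
        assert j.flank == "right"
        assert stats.junction_reads == 1

    def test_left_flank_read_ends_with_ttaa(self, genome_one_site):
        a = aln("chr1", 944, 1004, side="left", strand="-")
        (j,), _ = detect_junctions([a], genome_one_site)
        assert (j.junction_end, j.ttaa_start) == (JUNCTION_3P, 1000)
        assert j.flank == "left"

    def test_internal_ttaa_flag_matches_four_mer_scan(self):
        # read "TTAAGGTTAACC": TTAA at offsets 0 (terminal) and 6 (internal)
        seq = plant_ttaa(make_ttaa_free(2000, seed=2), [1000])
        seq = seq[:1000] + "TTAAGGTTAACC" + seq[1012:]
        genome = {"chr1": seq}
        a = aln("chr1", 1000, 1012, side="right")
        (j,), _ = detect_junctions([a], genome)
        assert j.ttaa_start == 1000
        assert j.internal_ttaa
        offsets = find_motif(seq[1000:1012])
        assert offsets == [0, 6]  # oracle: the only non-terminal hit is 6

    def test_reads_without_terminal_ttaa_dropped_and_counted(self, genome_one_site):
        a = aln("chr1", 500, 560, side="right")  # no TTAA anywhere near 500
        junctions, stats = detect_junctions([a], genome_one_site)
        assert junctions == []
        assert stats.dropped_no_ttaa == 1
        stats.check_conservation()

    def test_untagged_and_nonunique_reads_never_become_junctions(self, genome_one_site):
        alns = [
            aln("chr1", 1000, 1060, side="none"),
            aln("chr1", 1000, 1060, side="right", unique=False),
        ]
        junctions, stats = detect_junctions(alns, genome_one_site)
        assert junctions == []
        assert stats.dropped_untagged == 1 and stats.dropped_nonunique == 1

    def test_out_of_bounds_alignment_rejected(self, genome_one_site):
        with pytest.raises(ValueError, match="outside contig"):
            detect_junctions([aln("chr1", 1990, 2050, side="right")], genome_one_site)


class TestBuildCandidates:
    def test_flank_reads_sharing_one_ttaa_form_one_site(self, genome_one_site):
        alns = [
            aln("chr1", 944, 1004, side="left", strand="-", read_id="a"),
            aln("chr1", 1000, 1060, side="right", read_id="b"),
        ]
        junctions, _ = detect_junctions(alns, genome_one_site)
        (site,) = build_candidates(junctions)
        assert (site.contig, site.ttaa_start) == ("chr1", 1000)
        assert (site.left_support, site.right_support) == (1, 1)

    def test_distinct_ttaas_give_distinct_sites(self):
        seq = plant_ttaa(make_ttaa_free(3000, seed=3), [800, 2000])
        genome = {"chr1": seq}
        alns = [
            aln("chr1", 800, 860, side="right", read_id="a"),
            aln("chr1", 2000, 2060, side="right", read_id="b"),
        ]
        junctions, _ = detect_junctions(alns, genome)
        sites = build_candidates(junctions)
        assert [s.ttaa_start for s in sites] == [800, 2000]

    def test_pcr_duplicates_collapse_to_single_support(self, genome_one_site):
        alns = [
            aln("chr1", 1000, 1060, side="right", read_id=f"dup{i}") for i in range(10)
        ]
        junctions, _ = detect_junctions(alns, genome_one_site)
        (site,) = build_candidates(junctions)
        # oracle: ten identical (start, end, strand) tuples dedup to one
        assert len({(1000, 1060, "+")} ) == 1
        assert site.right_support == 1 and site.left_support == 0


class TestValidateSites:
    def _candidate(self, genome, left_ids=(), right_ids=(), internal=False):
        alns = [
            aln("chr1", 944 - 2 * i, 1004, side="left", strand="-", read_id=rid)
            for i, rid in enumerate(left_ids)
        ] + [
            aln("chr1", 1000, 1060 + 2 * i, side="right", read_id=rid)
            for i, rid in enumerate(right_ids)
        ]
        junctions, _ = detect_junctions(alns, genome)
        return build_candidates(junctions)

    def test_single_flank_rejected(self, genome_one_site):
        sites = self._candidate(genome_one_site, left_ids=("a", "b"))
        (call,) = validate_sites(sites, genome_one_site)
        assert call.status == STATUS_REJECTED
        assert call.rejection_reason == REASON_SINGLE_FLANK

    def test_clean_dual_flank_validated(self, genome_one_site):
        sites = self._candidate(genome_one_site, left_ids=("a",), right_ids=("b",))
        for mode in ("per-read", "all-reads", "between-reads"):
            (call,) = validate_sites(
                sites, genome_one_site, CallConfig(internal_ttaa_mode=mode)
            )
            assert call.status == STATUS_VALIDATED

    def test_internal_ttaa_only_rejected_per_read_accepted_between_reads(self):
        # a second TTAA inside both flanking windows makes every supporting
        # read dirty, but the inter-read span (the shared TTAA) is clean
        seq = plant_ttaa(make_ttaa_free(2000, seed=4), [970, 1000, 1030])
        genome = {"chr1": seq}
        sites = self._candidate(genome, left_ids=("a",), right_ids=("b",))
        (target,) = [s for s in sites if s.ttaa_start == 1000]
        assert target.has_internal_ttaa_support_only
        (per_read,) = validate_sites(
            [target], genome, CallConfig(internal_ttaa_mode="per-read")
        )
        assert (per_read.status, per_read.rejection_reason) == (
            STATUS_REJECTED,
            REASON_INTERNAL_TTAA,
        )
        (all_reads,) = validate_sites(
            [target], genome, CallConfig(internal_ttaa_mode="all-reads")
        )
        assert all_reads.status == STATUS_REJECTED
        (between,) = validate_sites(
            [target], genome, CallConfig(internal_ttaa_mode="between-reads")
        )
        assert between.status == STATUS_VALIDATED

    def test_min_support_threshold(self, genome_one_site):
        sites = self._candidate(
            genome_one_site, left_ids=("a",), right_ids=("b", "c")
        )
        (call,) = validate_sites(
            sites, genome_one_site, CallConfig(min_support=2)
        )
        assert call.rejection_reason == REASON_SINGLE_FLANK

    def test_permutation_invariance(self, genome_one_site):
        alns = [
            aln("chr1", 944, 1004, side="left", strand="-", read_id="a"),
            aln("chr1", 1000, 1060, side="right", read_id="b"),
            aln("chr1", 1000, 1062, side="right", read_id="c"),
        ]
        junctions, _ = detect_junctions(alns, genome_one_site)
        base = validate_sites(build_candidates(junctions), genome_one_site)
        for seed in range(5):
            shuffled = junctions[:]
            random.Random(seed).shuffle(shuffled)
            calls = validate_sites(build_candidates(shuffled), genome_one_site)
            assert calls == base

    def test_bed_output_asserts_ttaa_invariant(self, genome_one_site, tmp_path):
        sites = self._candidate(genome_one_site, left_ids=("a",), right_ids=("b",))
        calls = validate_sites(sites, genome_one_site)
        path = str(tmp_path / "calls.bed")
        write_calls_bed(calls, genome_one_site, path)
        with open(path) as fh:
            for line in fh:
                contig, start, end = line.split("\t")[:3]
                assert genome_one_site[contig][int(start) : int(end)] == TTAA
        # a corrupted coordinate must be caught, never silently emitted
        calls[0].candidate.ttaa_start = 5
        with pytest.raises(AssertionError, match="TTAA invariant"):
            write_calls_bed(calls, genome_one_site, str(tmp_path / "bad.bed"))
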