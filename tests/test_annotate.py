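"""Gene-model loading, UTR derivation and site classification."""

import random

import pytest

from splinkmap import classify_site, generate_genome, load_annotation, summarize_categories
from splinkmap.annotate import (
    CAT_EXON,
    CAT_INTERGENIC,
    CAT_INTRON,
    CAT_UTR3,
    CAT_UTR5,
    CATEGORIES,
    AnnotationIndex,
    SiteAnnotation,
    classify_sites,
    subtract_intervals,
)
from splinkmap.simulate import simulate_annotation


def _write(tmp_path, text, name="genes.gff3"):
    p = tmp_path / name
    p.write_text(text)
    return str(p)


def two_exon_gff(strand: str) -> str:
    # exon1 100-200 carries the whole CDS (120-180); exon2 300-400 is
    # entirely non-coding, on the CDS-distal side
    return (
        "##gff-version 3\n"
        f"c\tt\tgene\t101\t400\t.\t{strand}\t.\tID=g1;Name=GeneA\n"
        f"c\tt\tmRNA\t101\t400\t.\t{strand}\t.\tID=g1.t1;Parent=g1\n"
        f"c\tt\texon\t101\t200\t.\t{strand}\t.\tParent=g1.t1\n"
        f"c\tt\texon\t301\t400\t.\t{strand}\t.\tParent=g1.t1\n"
        f"c\tt\tCDS\t121\t180\t.\t{strand}\t0\tParent=g1.t1\n"
    )


class TestLoadAnnotation:
    @pytest.mark.parametrize(
        "strand,exon2_cat", [("+", CAT_UTR3), ("-", CAT_UTR5)]
    )
    def test_noncoding_exon_becomes_cds_distal_utr(self, tmp_path, strand, exon2_cat):
        (model,) = load_annotation(_write(tmp_path, two_exon_gff(strand)))
        assert model.gene == "GeneA"
        assert model.exons == ((100, 200), (300, 400))
        assert model.cds == ((120, 180),)
        exon2_utrs = model.utr3 if exon2_cat == CAT_UTR3 else model.utr5
        assert (300, 400) in exon2_utrs

    def test_explicit_utr_features_used_verbatim(self, tmp_path):
        text = two_exon_gff("+") + (
            "c\tt\tfive_prime_UTR\t101\t120\t.\t+\t.\tParent=g1.t1\n"
        )
        (model,) = load_annotation(_write(tmp_path, text))
        assert model.utr5 == ((100, 120),)
        assert model.utr3 == ()  # explicit UTRs suppress derivation

    def test_empty_gff_gives_empty_models_with_warning(self, tmp_path, caplog):
        path = _write(tmp_path, "##gff-version 3\n")
        with caplog.at_level("WARNING"):
            models = load_annotation(path)
        assert models == []
        assert "no features" in caplog.text

    def test_derived_utrs_equal_exon_minus_cds(self, tmp_path):
        """Loader-derived UTRs == independent interval subtraction oracle."""
        genome = generate_genome(2, 50_000, seed=12)
        gff, planted = simulate_annotation(genome, 10, seed=12)
        models = load_annotation(_write(tmp_path, gff))
        assert len(models) == len(planted)
        by_id = {g.gene_id: g for g in planted}
        for m in models:
            truth = by_id[m.gene]
            exonic = {b for s, e in truth.exons for b in range(s, e)}
            coding = {b for s, e in truth.cds for b in range(s, e)}
            leftover = exonic - coding
            cds_lo = min(coding)
            utr5, utr3 = set(), set()
            for b in leftover:
                upstream = b < cds_lo
                if (truth.strand == "+") == upstream:
                    utr5.add(b)
                else:
                    utr3.add(b)
            assert {b for s, e in m.utr5 for b in range(s, e)} == utr5
            assert {b for s, e in m.utr3 for b in range(s, e)} == utr3


class TestClassification:
    def test_site_inside_cds_is_exon_with_gene(self, tmp_path):
        models = load_annotation(_write(tmp_path, two_exon_gff("+")))
        a = classify_site("c", 140, models)
        assert (a.category, a.gene) == (CAT_EXON, "GeneA")

    def test_site_between_genes_is_intergenic_without_gene(self, tmp_path):
        models = load_annotation(_write(tmp_path, two_exon_gff("+")))
        a = classify_site("c", 5000, models)
        assert (a.category, a.gene) == (CAT_INTERGENIC, None)

    def test_intron_and_boundary_precedence(self, tmp_path):
        models = load_annotation(_write(tmp_path, two_exon_gff("+")))
        assert classify_site("c", 250, models).category == CAT_INTRON
        # TTAA straddling the CDS edge takes the higher-precedence category
        assert classify_site("c", 178, models).category == CAT_EXON

    def test_matches_per_base_membership_oracle(self, tmp_path):
        """Classification == painting every base with the best category."""
        genome = generate_genome(1, 80_000, seed=13)
        gff, _ = simulate_annotation(genome, 8, seed=13)
        models = load_annotation(_write(tmp_path, gff))
        length = len(genome.contigs[0][1])
        rank = {c: i for i, c in enumerate(CATEGORIES)}
        paint = [CAT_INTERGENIC] * length
        gene_of = [None] * length
        order = (  # paint lowest precedence first so best label wins
            (CAT_INTRON, lambda m: subtract_intervals((m.span,), m.exons)),
            (CAT_UTR3, lambda m: m.utr3),
            (CAT_UTR5, lambda m: m.utr5),
            (CAT_EXON, lambda m: m.cds if m.cds else m.exons),
        )
        for cat, get in order:
            for m in models:
                for s, e in get(m):
                    for b in range(s, e):
                        if rank[cat] < rank[paint[b]] or paint[b] == CAT_INTERGENIC:
                            paint[b] = cat
                            gene_of[b] = m.gene
        rng = random.Random(13)
        idx = AnnotationIndex(models)
        for _ in range(100):
            s = rng.randrange(0, length - 4)
            got = idx.classify("contig1", s, s + 4)
            best = min((paint[b] for b in range(s, s + 4)), key=lambda c: rank[c])
            assert got.category == best

    def test_transcript_order_permutation_invariant(self, tmp_path):
        genome = generate_genome(1, 60_000, seed=14)
        gff, _ = simulate_annotation(genome, 6, seed=14)
        header, *body = gff.strip().split("\n")
        # shuffle whole gene blocks (gene + its children)
        blocks, cur = [], []
        for line in body:
            if line.split("\t")[2] == "gene" and cur:
                blocks.append(cur)
                cur = []
            cur.append(line)
        blocks.append(cur)
        random.Random(0).shuffle(blocks)
        shuffled = header + "\n" + "\n".join(l for b in blocks for l in b) + "\n"
        m1 = load_annotation(_write(tmp_path, gff, "a.gff3"))
        m2 = load_annotation(_write(tmp_path, shuffled, "b.gff3"))
        rng = random.Random(1)
        sites = [("contig1", rng.randrange(0, 59_000)) for _ in range(50)]
        assert classify_sites(sites, m1) == classify_sites(sites, m2)


class TestSummary:
    def test_empty_input_gives_all_zero_table(self):
        table = summarize_categories([])
        assert set(table) == set(CATEGORIES)
        assert all(v == 0 for v in table.values())

    def test_single_category_counts(self):
        anns = [
            SiteAnnotation("c", i, i + 4, CAT_INTERGENIC, None) for i in range(3)
        ]
        table = summarize_categories(anns)
        assert table[CAT_INTERGENIC] == 3
        assert sum(table.values()) == 3

    def test_planted_composition_recovered(self):
        planted = {CAT_EXON: 1, CAT_UTR5: 1, CAT_UTR3: 1, CAT_INTRON: 8, CAT_INTERGENIC: 45}
        anns = []
        i = 0
        for cat, n in planted.items():
            for _ in range(n):
                anns.append(
                    SiteAnnotation("c", i, i + 4, cat, None if cat == CAT_INTERGENIC else "g")
                )
                i += 10
        table = summarize_categories(anns)
        assert table == planted
        assert sum(table.values()) == 56
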