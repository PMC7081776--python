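"""GFF3 gene models, exon union/intron derivation and structural classification."""

import numpy as np
import pytest

from circkit.annotation import (
    AnnotationIndex,
    EmptyAnnotationError,
    classify,
    load_annotation,
    union_intervals,
)
from circkit.fixtures import generate_universe
from circkit.model import CircCall, GenomicInterval, StructuralClass

from oracles import PerBaseClassifier


def _call(chrom, start, end):
    return CircCall(interval=GenomicInterval(chrom, start, end), source_tool="bed")


def test_union_intervals_oracle():
    rng = np.random.default_rng(3)
    for _ in range(100):
        ivs = [
            (int(s), int(s) + int(rng.integers(1, 30)))
            for s in rng.integers(0, 200, size=rng.integers(1, 12))
        ]
        merged = union_intervals(ivs)
        # naive membership oracle
        mask = np.zeros(300, dtype=bool)
        for s, e in ivs:
            mask[s:e] = True
        back = np.zeros(300, dtype=bool)
        for s, e in merged:
            assert s < e
            back[s:e] = True
        assert (mask == back).all()
        assert all(merged[i][1] < merged[i + 1][0] or merged[i][1] <= merged[i + 1][0]
                   for i in range(len(merged) - 1))
        assert merged == sorted(merged)


class TestLoadAnnotation:
    def test_transcript_exons_unioned_per_gene(self, mini_gff3):
        genes = load_annotation(mini_gff3)
        alpha = next(g for g in genes if g.gene_name == "alpha")
        # two transcripts with overlapping first exons -> two unioned exons
        assert [(e.start, e.end) for e in alpha.exons] == [(100, 250), (400, 600)]
        assert [(i.start, i.end) for i in alpha.introns] == [(250, 400)]
        # exons and introns tile the exon envelope without overlap
        covered = sum(e.span for e in alpha.exons) + sum(i.span for i in alpha.introns)
        assert covered == alpha.exons[-1].end - alpha.exons[0].start

    def test_single_exon_gene_has_no_introns(self, mini_gff3):
        beta = next(g for g in load_annotation(mini_gff3) if g.gene_name == "beta")
        assert len(beta.exons) == 1
        assert beta.introns == ()

    def test_exon_outside_gene_span_clipped_with_warning(self, tmp_path, caplog):
        text = "\n".join([
            "##gff-version 3",
            "c1\tt\tgene\t101\t200\t.\t+\t.\tID=g1;Name=g1",
            "c1\tt\texon\t51\t150\t.\t+\t.\tID=e1;Parent=g1",
            "",
        ])
        p = tmp_path / "bad.gff3"
        p.write_text(text)
        with caplog.at_level("WARNING"):
            (gene,) = load_annotation(p)
        assert [(e.start, e.end) for e in gene.exons] == [(100, 150)]
        assert "clipped" in caplog.text

    def test_no_gene_features_is_empty_annotation(self, tmp_path):
        p = tmp_path / "nogenes.gff3"
        p.write_text("##gff-version 3\nc1\tt\texon\t1\t10\t.\t+\t.\tID=e1\n")
        with pytest.raises(EmptyAnnotationError):
            load_annotation(p)

    def test_gene_name_precedence(self, tmp_path):
        text = "\n".join([
            "##gff-version 3",
            "c1\tt\tgene\t1\t100\t.\t+\t.\tID=gid1;Name=named;gene=sym1",
            "c1\tt\texon\t1\t100\t.\t+\t.\tID=e1;Parent=gid1",
            "c1\tt\tgene\t201\t300\t.\t+\t.\tID=gid2;gene=sym2",
            "c1\tt\texon\t201\t300\t.\t+\t.\tID=e2;Parent=gid2",
            "c1\tt\tgene\t401\t500\t.\t+\t.\tID=gid3",
            "c1\tt\texon\t401\t500\t.\t+\t.\tID=e3;Parent=gid3",
            "",
        ])
        p = tmp_path / "names.gff3"
        p.write_text(text)
        names = [g.gene_name for g in load_annotation(p)]
        assert names == ["named", "sym2", "gid3"]

    def test_invariant_under_feature_order(self, mini_gff3, tmp_path):
        lines = mini_gff3.read_text().splitlines()
        header, body = lines[0], lines[1:]
        # exon/transcript lines reversed within the file
        shuffled = tmp_path / "shuffled.gff3"
        shuffled.write_text("\n".join([header] + body[::-1]) + "\n")
        a = load_annotation(mini_gff3)
        b = load_annotation(shuffled)
        assert [(g.gene_name, g.exons, g.introns) for g in a] == [
            (g.gene_name, g.exons, g.introns) for g in b
        ]

    def test_gzip_input_accepted(self, mini_gff3, tmp_path):
        import gzip

        gz = tmp_path / "mini.gff3.gz"
        gz.write_bytes(gzip.compress(mini_gff3.read_bytes()))
        assert [g.gene_name for g in load_annotation(gz)] == [
            g.gene_name for g in load_annotation(mini_gff3)
        ]


@pytest.fixture(scope="module")
def index(tmp_path_factory):
    d = tmp_path_factory.mktemp("gff")
    text = "\n".join([
        "##gff-version 3",
        "c1\tt\tgene\t101\t600\t.\t+\t.\tID=gA;Name=alpha",
        "c1\tt\texon\t101\t200\t.\t+\t.\tID=e1;Parent=gA",
        "c1\tt\texon\t401\t600\t.\t+\t.\tID=e2;Parent=gA",
        "c1\tt\tgene\t2001\t2300\t.\t+\t.\tID=gB;Name=beta",
        "c1\tt\texon\t2001\t2300\t.\t+\t.\tID=e3;Parent=gB",
        "",
    ])
    p = d / "two_genes.gff3"
    p.write_text(text)
    return AnnotationIndex(load_annotation(p))


class TestClassify:

    def test_call_inside_exon_is_exonic(self, index):
        cls, gene = classify(_call("c1", 120, 180), index)
        assert (cls, gene) == (StructuralClass.EXONIC, "alpha")

    def test_call_fully_inside_intron_is_intronic(self, index):
        cls, gene = classify(_call("c1", 260, 380), index)
        assert (cls, gene) == (StructuralClass.INTRONIC, "alpha")

    def test_call_spanning_exon_intron_boundary(self, index):
        cls, gene = classify(_call("c1", 150, 300), index)
        assert (cls, gene) == (StructuralClass.EXON_INTRONIC, "alpha")

    def test_call_between_genes_is_intergenic(self, index):
        cls, gene = classify(_call("c1", 1000, 1200), index)
        assert (cls, gene) == (StructuralClass.INTERGENIC, None)

    def test_unannotated_chromosome_is_unclassified(self, index, caplog):
        with caplog.at_level("WARNING"):
            cls, gene = classify(_call("c9", 10, 50), index)
        assert (cls, gene) == (StructuralClass.UNCLASSIFIED, None)

    def test_multi_gene_overlap_picks_max_overlap(self, tmp_path):
        text = "\n".join([
            "##gff-version 3",
            "c1\tt\tgene\t101\t300\t.\t+\t.\tID=g1;Name=left",
            "c1\tt\texon\t101\t300\t.\t+\t.\tID=e1;Parent=g1",
            "c1\tt\tgene\t251\t700\t.\t+\t.\tID=g2;Name=right",
            "c1\tt\texon\t251\t700\t.\t+\t.\tID=e2;Parent=g2",
            "",
        ])
        p = tmp_path / "overlapping.gff3"
        p.write_text(text)
        index = AnnotationIndex(load_annotation(p))
        # 280..500: 20 bases in "left", 250 in "right"
        cls, gene = classify(_call("c1", 280, 500), index)
        assert gene == "right" and cls is StructuralClass.EXONIC


def test_classification_matches_per_base_scan_on_universes():
    """Interval arithmetic equals a literal base-by-base membership count."""
    for seed in (1, 2):
        u = generate_universe(n_genes=8, n_circ=16, genome_len=60_000, seed=seed)
        chrom_lengths = {c: len(s) for c, s in u.genome.items()}
        oracle = PerBaseClassifier(u.genes, chrom_lengths)
        index = AnnotationIndex(_genes_to_models(u))
        rng = np.random.default_rng(seed)
        queries = [(t.chrom, t.start, t.end) for t in u.truth]
        for _ in range(40):
            chrom = ("chrA", "chrB")[int(rng.integers(0, 2))]
            start = int(rng.integers(0, chrom_lengths[chrom] - 400))
            queries.append((chrom, start, start + int(rng.integers(1, 400))))
        for chrom, start, end in queries:
            got_cls, got_gene = index.classify_interval(
                GenomicInterval(chrom, start, end)
            )
            want_cls, want_gene = oracle.classify(chrom, start, end)
            assert (got_cls.value, got_gene) == (want_cls, want_gene)


def _genes_to_models(universe):
    """Planted genes via the real GFF3 writer + parser (not hand-built)."""
    import tempfile
    from pathlib import Path

    with tempfile.TemporaryDirectory() as d:
        paths = universe.write(d)
        return load_annotation(paths["gff3"])
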