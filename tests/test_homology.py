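"""Sequence extraction, hit filtering, host assignment and search backends."""

import numpy as np
import pytest

from circkit.fixtures import generate_universe
from circkit.homology import (
    BackendUnavailableError,
    BlastBackend,
    DEFAULT_BLACKLIST,
    HitRecord,
    MissingSequenceError,
    NaiveSearchBackend,
    OutOfBoundsError,
    SearchConfig,
    assign_host,
    extract_gene_name,
    extract_sequence,
    filter_hits,
    reverse_complement,
    search,
)
from circkit.model import NOT_ASSIGNED, GenomicInterval


@pytest.fixture()
def tiny_genome(tmp_path):
    p = tmp_path / "tiny.fa"
    p.write_text(">s1\nACGTACGT\n")
    return p


class TestExtractSequence:
    def test_forward_slice(self, tiny_genome):
        assert extract_sequence(tiny_genome, GenomicInterval("s1", 2, 5, "+")) == "GTA"

    def test_reverse_complement(self, tiny_genome):
        assert extract_sequence(tiny_genome, GenomicInterval("s1", 2, 5, "-")) == "TAC"

    def test_unknown_strand_is_forward(self, tiny_genome):
        assert extract_sequence(tiny_genome, GenomicInterval("s1", 2, 5, ".")) == "GTA"

    def test_missing_chromosome(self, tiny_genome):
        with pytest.raises(MissingSequenceError):
            extract_sequence(tiny_genome, GenomicInterval("s2", 0, 3))

    def test_out_of_bounds_names_chrom_and_length(self, tiny_genome):
        with pytest.raises(OutOfBoundsError) as exc:
            extract_sequence(tiny_genome, GenomicInterval("s1", 2, 99))
        assert "s1" in str(exc.value) and "8" in str(exc.value)

    def test_length_equals_span_on_universe_loci(self, universe):
        from pyfaidx import Fasta

        genome = Fasta(str(universe.paths["genome"]))
        for t in universe.truth[:10]:
            iv = GenomicInterval(t.chrom, t.start, t.end, "+")
            assert len(extract_sequence(genome, iv)) == iv.span


def test_reverse_complement_involution():
    seq = "ACGTTGCAANRY"
    assert reverse_complement(reverse_complement(seq)) == seq


def _hit(title, pident, bits=100.0, length=120, query="q1"):
    return HitRecord(
        query_id=query, subject_title=title, percent_identity=pident,
        alignment_length=length, bit_score=bits,
    )


class TestFilterHits:
    def test_blacklisted_title_removed_despite_high_identity(self):
        assert filter_hits([_hit("uncharacterized LOC101234", 99.0)]) == []

    def test_identity_just_below_threshold_removed(self):
        assert filter_hits([_hit("troponin T3", 89.9)]) == []

    def test_clean_hit_above_threshold_retained(self):
        hits = [_hit("myocyte-specific enhancer factor 2C", 95.0)]
        assert filter_hits(hits) == hits

    def test_threshold_is_inclusive(self):
        assert len(filter_hits([_hit("troponin T3", 90.0)])) == 1

    def test_blacklist_is_case_insensitive_substring(self):
        hits = [
            _hit("BAC Clone RP11-3F4", 99.0),
            _hit("Linkage Group 12 sequence", 99.0),
            _hit("calcium/calmodulin-dependent protein kinase", 95.0),
        ]
        kept = filter_hits(hits)
        assert [h.subject_title for h in kept] == [
            "calcium/calmodulin-dependent protein kinase"
        ]

    def test_idempotent_and_order_stable_on_random_lists(self):
        rng = np.random.default_rng(17)
        titles = [
            "troponin T3", "uncharacterized LOC1", "clone X17",
            "myosin heavy chain", "linkage group 4", "MHC class IA antigen",
        ]
        for _ in range(300):
            hits = [
                _hit(titles[int(rng.integers(0, len(titles)))],
                     float(rng.uniform(50, 100)),
                     bits=float(rng.uniform(40, 400)))
                for _ in range(int(rng.integers(0, 12)))
            ]
            once = filter_hits(hits)
            assert filter_hits(once) == once  # idempotent
            # order-stable: survivors appear in original relative order
            positions = [hits.index(h) for h in once]
            assert positions == sorted(positions)


class TestAssignHost:
    def test_empty_hits_is_not_assigned(self):
        assignment = assign_host([])
        assert assignment.gene_name == NOT_ASSIGNED
        assert assignment.source == "none"

    def test_highest_bit_score_wins(self):
        hits = [_hit("troponin T3 (tnnt3)", 95.0, bits=150.0),
                _hit("myoglobin (mb)", 92.0, bits=180.0)]
        assert assign_host(hits).gene_name == "mb"

    def test_deterministic_under_permutation_matches_brute_force(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            hits = [
                _hit(f"protein {i} (sym{i})", float(rng.uniform(90, 100)),
                     bits=float(rng.uniform(100, 500)))
                for i in range(int(rng.integers(1, 10)))
            ]
            best = max(
                hits,
                key=lambda h: (h.bit_score, h.percent_identity, [-ord(c) for c in h.subject_title]),
            )
            want = extract_gene_name(best.subject_title)
            perm = [hits[i] for i in rng.permutation(len(hits))]
            assert assign_host(perm).gene_name == want

    def test_not_assigned_sentinel_consistency(self):
        from circkit.homology import HostAssignment

        with pytest.raises(ValueError):
            HostAssignment(NOT_ASSIGNED, None, "homology")
        with pytest.raises(ValueError):
            HostAssignment("tnnt3", None, "none")


@pytest.mark.parametrize("title,expected", [
    ("XM_0031234 troponin T3 (tnnt3) [Oreochromis niloticus]", "tnnt3"),
    ("NM_001 myocyte-specific enhancer factor 2C", "myocyte-specific enhancer factor 2C"),
    ("db0004 synthetic muscle locus protein 4 (gmp004)", "gmp004"),
    ("lonesometoken", "lonesometoken"),
])
def test_gene_name_extraction(title, expected):
    assert extract_gene_name(title) == expected


@pytest.fixture(scope="module")
def db(tmp_path_factory):
    d = tmp_path_factory.mktemp("db")
    p = d / "db.fa"
    rng = np.random.default_rng(31)
    seqs = {
        "r1": "".join("ACGT"[i] for i in rng.integers(0, 4, 300)),
        "r2": "".join("ACGT"[i] for i in rng.integers(0, 4, 300)),
    }
    p.write_text(
        f">r1 first synthetic record (sym1)\n{seqs['r1']}\n"
        f">r2 second synthetic record (sym2)\n{seqs['r2']}\n"
    )
    return p, seqs


class TestNaiveBackend:

    def test_exact_substring_hits_at_full_identity(self, db):
        path, seqs = db
        backend = NaiveSearchBackend(path)
        hits = search(seqs["r1"][50:150], backend, SearchConfig(), query_id="q")
        assert hits[0].percent_identity == 100.0
        assert "sym1" in hits[0].subject_title
        assert hits[0].alignment_length == 100

    def test_reverse_complement_query_found(self, db):
        path, seqs = db
        backend = NaiveSearchBackend(path)
        hits = search(
            reverse_complement(seqs["r2"][10:110]), backend, SearchConfig(), "q"
        )
        assert hits[0].percent_identity == 100.0
        assert "sym2" in hits[0].subject_title

    def test_random_query_has_no_high_identity_hit(self, db):
        path, _ = db
        backend = NaiveSearchBackend(path)
        rng = np.random.default_rng(77)
        query = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
        hits = search(query, backend, SearchConfig(), "q")
        assert all(h.percent_identity < 90 for h in hits)
        assert filter_hits(hits) == []

    def test_empty_query_rejected(self, db):
        path, _ = db
        with pytest.raises(ValueError):
            search("", NaiveSearchBackend(path), SearchConfig())

    def test_empty_database_is_backend_unavailable(self, tmp_path):
        empty = tmp_path / "empty.fa"
        empty.write_text("")
        with pytest.raises(BackendUnavailableError):
            NaiveSearchBackend(empty)


def test_planted_circs_hit_only_their_true_host(universe):
    """Every planted genic circRNA matches its host gene at 100% identity and
    nothing else survives the 90% filter (cross-gene identity ~25%)."""
    from pyfaidx import Fasta

    backend = NaiveSearchBackend(universe.paths["database"])
    genome = Fasta(str(universe.paths["genome"]))
    config = SearchConfig()
    for t in universe.truth:
        seq = extract_sequence(genome, GenomicInterval(t.chrom, t.start, t.end, "+"))
        kept = filter_hits(search(seq, backend, config, t.circ_id), config)
        if t.true_host_gene == ".":
            assert kept == []
        else:
            assert kept, f"{t.circ_id} found no surviving hit"
            assert all(h.percent_identity == 100.0 for h in kept)
            assert assign_host(kept).gene_name == t.true_host_gene


def test_blast_backend_agrees_with_naive_backend(universe):
    """Independent cross-check: the external aligner's best hit names the
    same host gene as the internal identity scan."""
    from pyfaidx import Fasta

    naive = NaiveSearchBackend(universe.paths["database"])
    blast = BlastBackend(universe.paths["database"])
    genome = Fasta(str(universe.paths["genome"]))
    config = SearchConfig(backend="local_db")
    genic = [t for t in universe.truth if t.true_host_gene != "."][:4]
    assert genic
    for t in genic:
        seq = extract_sequence(genome, GenomicInterval(t.chrom, t.start, t.end, "+"))
        blast_hits = filter_hits(blast.search(t.circ_id, seq, config), config)
        naive_hits = filter_hits(naive.search(t.circ_id, seq, config), config)
        assert assign_host(blast_hits).gene_name == assign_host(naive_hits).gene_name \
            == t.true_host_gene
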