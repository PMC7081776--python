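from __future__ import annotations

import pytest

from circkit.fixtures import generate_universe


@pytest.fixture(scope="session")
def universe_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("universe")


@pytest.fixture(scope="session")
def universe(universe_dir):
    """Small written universe shared by read-only tests."""
    return generate_universe(
        n_genes=10, n_circ=20, genome_len=70_000, dropout=0.0, seed=11,
        out_dir=universe_dir,
    )


@pytest.fixture()
def mini_gff3(tmp_path):
    """Two genes on one chromosome: a two-transcript gene with overlapping
    exons (union must deduplicate) and a single-exon gene."""
    text = "\n".join(
        [
            "##gff-version 3",
            "chr1\ttest\tgene\t101\t600\t.\t+\t.\tID=geneA;Name=alpha",
            "chr1\ttest\tmRNA\t101\t600\t.\t+\t.\tID=rnaA1;Parent=geneA",
            "chr1\ttest\texon\t101\t200\t.\t+\t.\tID=eA1a;Parent=rnaA1",
            "chr1\ttest\texon\t401\t600\t.\t+\t.\tID=eA1b;Parent=rnaA1",
            "chr1\ttest\tmRNA\t101\t600\t.\t+\t.\tID=rnaA2;Parent=geneA",
            "chr1\ttest\texon\t151\t250\t.\t+\t.\tID=eA2a;Parent=rnaA2",
            "chr1\ttest\texon\t401\t600\t.\t+\t.\tID=eA2b;Parent=rnaA2",
            "chr1\ttest\tgene\t2001\t2300\t.\t-\t.\tID=geneB;Name=beta",
            "chr1\ttest\tmRNA\t2001\t2300\t.\t-\t.\tID=rnaB1;Parent=geneB",
            "chr1\ttest\texon\t2001\t2300\t.\t-\t.\tID=eB1a;Parent=rnaB1",
            "",
        ]
    )
    path = tmp_path / "mini.gff3"
    path.write_text(text)
    return path
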