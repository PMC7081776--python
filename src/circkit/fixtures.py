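"""Self-consistent synthetic test universe with a known truth table.

:func:`generate_universe` builds, deterministically for a fixed seed:

* a random genome (i.i.d. uniform nucleotides, so expected cross-locus
  identity is ~25% — far below the 90% homology filter, which separates
  true from false hits without tuning);
* a GFF3 annotation of multi-exon genes placed with wide intergenic gaps;
* a homology database FASTA holding each gene's genomic span under an
  informative title (plus blacklisted decoy records with identical
  sequence, which the hit filter must remove);
* back-splice calls planted in all four structural classes — exonic,
  intronic, exon-intronic and intergenic (the latter at least 1 kb from any
  gene) — emitted into one file per predictor in that predictor's dialect
  and coordinate convention, with per-tool dropout;
* a tab-separated truth table.

The emulation is structural only: sequences are uniform random (no codon
bias, repeats or splice motifs), back-splice positions ignore splice
signals, and no read-level noise exists, so coordinate-level operations are
exercised exactly while alignment heuristics are not stressed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .model import CircCall, GenomicInterval, StructuralClass, denormalize
from .io import DIALECTS

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

PREDICTOR_TOOLS = ("ciri", "ciri2", "circexplorer2", "find_circ", "circfinder")
INTERGENIC_MARKER = "."

#: class rotation for planted circRNAs
_CLASS_CYCLE = (
    StructuralClass.EXONIC,
    StructuralClass.INTRONIC,
    StructuralClass.EXON_INTRONIC,
    StructuralClass.INTERGENIC,
)

# gene geometry (bases); exons/introns are wide enough for >= 60 bp circRNAs
_EXON_LEN = (100, 200)
_INTRON_LEN = (100, 250)
_N_EXONS = (2, 6)
_GAP_LEN = (2600, 3200)  # intergenic gap before each gene
_INTERGENIC_BUFFER = 1000  # min distance of intergenic circRNAs from genes
_CIRC_SPAN = (60, 160)


class PackingError(ValueError):
    """Genes do not fit in the requested genome length."""


@dataclass(frozen=True)
class PlantedGene:
    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted circRNA and its isoform variants."""

    circ_id: str
    chrom: str
    start: int  # envelope over variants, 0-based half-open
    end: int
    true_host_gene: str  # gene symbol, or "." for intergenic
    true_class: StructuralClass
    variants: tuple[tuple[int, int], ...]
    variant_tools: tuple[tuple[str, ...], ...]  # tools reporting each variant

    @property
    def planted_variants(self) -> int:
        return len(self.variants)

    @property
    def tools_reporting(self) -> tuple[str, ...]:
        seen: set[str] = set()
        for tools in self.variant_tools:
            seen.update(tools)
        return tuple(sorted(seen))


@dataclass
class Universe:
    """In-memory synthetic universe; :meth:`write` materialises the files."""

    seed: int
    genome: dict  # chrom -> sequence string
    genes: list
    truth: list
    tool_calls: dict  # tool -> list[CircCall], internal coordinates
    db_records: list  # (record id, title line, sequence)
    paths: dict = field(default_factory=dict)

    def write(self, out_dir: PathLike) -> dict:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out_dir / "genome.fa",
            "gff3": out_dir / "annotation.gff3",
            "database": out_dir / "database.fa",
            "truth": out_dir / "truth.tsv",
        }
        _write_fasta(
            paths["genome"],
            [(chrom, chrom, self.genome[chrom]) for chrom in sorted(self.genome)],
        )
        _write_gff3(paths["gff3"], self.genes)
        _write_fasta(paths["database"], self.db_records)
        _write_truth(paths["truth"], self.truth)
        for tool in PREDICTOR_TOOLS:
            p = out_dir / f"{tool}_calls.tsv"
            _write_tool_file(p, tool, self.tool_calls.get(tool, []))
            paths[tool] = p
        self.paths = paths
        return paths


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _place_genes(
    rng: np.random.Generator, n_genes: int, chroms: Sequence[str], chrom_len: int
) -> tuple[list[PlantedGene], list[tuple[str, int, int]]]:
    """Lay out genes sequentially per chromosome; return genes and the
    intergenic zones (>= 1 kb from every gene) usable for intergenic circRNAs."""
    genes: list[PlantedGene] = []
    zones: list[tuple[str, int, int]] = []
    per_chrom = -(-n_genes // len(chroms))  # ceil
    idx = 0
    for chrom in chroms:
        cursor = 0
        for _ in range(per_chrom):
            if idx >= n_genes:
                break
            gap = int(rng.integers(*_GAP_LEN))
            n_exons = int(rng.integers(_N_EXONS[0], _N_EXONS[1] + 1))
            exon_lens = rng.integers(_EXON_LEN[0], _EXON_LEN[1] + 1, size=n_exons)
            intron_lens = rng.integers(
                _INTRON_LEN[0], _INTRON_LEN[1] + 1, size=max(0, n_exons - 1)
            )
            gstart = cursor + gap
            exons = []
            pos = gstart
            for j, elen in enumerate(exon_lens):
                exons.append((pos, pos + int(elen)))
                pos += int(elen)
                if j < len(intron_lens):
                    pos += int(intron_lens[j])
            gend = pos
            if gend > chrom_len:
                raise PackingError(
                    f"gene layout exceeds chromosome length {chrom_len}; "
                    "increase genome_len"
                )
            zones.append(
                (chrom, cursor + _INTERGENIC_BUFFER, gstart - _INTERGENIC_BUFFER)
            )
            genes.append(
                PlantedGene(
                    gene_id=f"gene{idx:03d}",
                    symbol=f"gmp{idx:03d}",
                    chrom=chrom,
                    start=gstart,
                    end=gend,
                    exons=tuple(exons),
                )
            )
            cursor = gend
            idx += 1
    return genes, zones


def _plant_interval(
    rng: np.random.Generator,
    cls: StructuralClass,
    gene: Optional[PlantedGene],
    zone: Optional[tuple[str, int, int]],
) -> tuple[int, int]:
    """One (start, end) of the requested class within the gene or zone."""
    if cls is StructuralClass.EXONIC:
        es, ee = gene.exons[int(rng.integers(0, len(gene.exons)))]
        lo, hi = es, ee
    elif cls is StructuralClass.INTRONIC:
        introns = gene.introns
        lo, hi = introns[int(rng.integers(0, len(introns)))]
    elif cls is StructuralClass.EXON_INTRONIC:
        j = int(rng.integers(0, len(gene.introns)))
        boundary = gene.exons[j][1]  # exon j ends, intron j begins
        left = int(rng.integers(15, min(60, boundary - gene.exons[j][0]) + 1))
        right = int(rng.integers(15, min(60, gene.introns[j][1] - boundary) + 1))
        return boundary - left, boundary + right
    else:  # intergenic
        _, lo, hi = zone
    width = hi - lo
    span = int(rng.integers(_CIRC_SPAN[0], min(_CIRC_SPAN[1], width) + 1))
    start = lo + int(rng.integers(0, width - span + 1))
    return start, start + span


def generate_universe(
    n_genes: int = 30,
    n_circ: int = 60,
    genome_len: int = 180_000,
    dropout: float = 0.0,
    seed: int = 0,
    max_variants: int = 1,
    out_dir: Optional[PathLike] = None,
) -> Universe:
    """Build a deterministic synthetic universe.

    Parameters
    ----------
    n_genes, n_circ : int
        Genes to place (2-6 exons each, split over two chromosomes) and
        circRNAs to plant, rotating through the four structural classes.
    genome_len : int
        Total genome size in bases (two equal chromosomes).  Raises
        :class:`PackingError` when the genes do not fit.
    dropout : float
        Per-tool, per-junction probability of NOT being reported; 0 means
        every tool file contains every planted junction.
    max_variants : int
        Each circRNA gets 1..max_variants distinct back-splice variants
        drawn from the same structural region.
    out_dir : path, optional
        When given, all files are written there (see :meth:`Universe.write`).
    """
    if not (0 <= dropout < 1):
        raise ValueError("dropout must be in [0, 1)")
    if n_genes < 1 or n_circ < 1 or max_variants < 1:
        raise ValueError("n_genes, n_circ and max_variants must be >= 1")
    rng = np.random.default_rng(seed)

    chroms = ("chrA", "chrB")
    chrom_len = genome_len // len(chroms)
    genes, zones = _place_genes(rng, n_genes, chroms, chrom_len)
    genome = {chrom: _random_sequence(rng, chrom_len) for chrom in chroms}

    # homology database: each gene's genomic span; every fifth gene also gets
    # a blacklisted decoy with the identical sequence
    db_records = []
    for i, g in enumerate(genes):
        seq = genome[g.chrom][g.start:g.end]
        db_records.append(
            (f"db{i:04d}", f"db{i:04d} synthetic muscle locus protein {i} ({g.symbol})", seq)
        )
        if i % 5 == 0:
            db_records.append(
                (f"dx{i:04d}", f"dx{i:04d} uncharacterized LOC9{i:05d} clone fragment", seq)
            )

    truth: list[TruthRecord] = []
    tool_calls: dict[str, list[CircCall]] = {tool: [] for tool in PREDICTOR_TOOLS}
    genic_i = 0
    zone_i = 0
    for k in range(n_circ):
        cls = _CLASS_CYCLE[k % len(_CLASS_CYCLE)]
        gene = zone = None
        if cls is StructuralClass.INTERGENIC:
            zone = zones[zone_i % len(zones)]
            zone_i += 1
            chrom, host = zone[0], INTERGENIC_MARKER
        else:
            gene = genes[genic_i % len(genes)]
            genic_i += 1
            chrom, host = gene.chrom, gene.symbol

        n_var = int(rng.integers(1, max_variants + 1))
        variants: list[tuple[int, int]] = []
        guard = 0
        while len(variants) < n_var and guard < 50 * n_var:
            iv = _plant_interval(rng, cls, gene, zone)
            guard += 1
            if iv not in variants:
                variants.append(iv)
        variants.sort()

        circ_id = f"circ{k:04d}"
        variant_tools: list[tuple[str, ...]] = []
        for v, (s, e) in enumerate(variants):
            reporting = tuple(
                tool for tool in PREDICTOR_TOOLS if rng.random() >= dropout
            )
            variant_tools.append(reporting)
            for tool in reporting:
                reads = int(rng.integers(5, 100))
                tool_calls[tool].append(
                    CircCall(
                        interval=GenomicInterval(chrom, s, e, "+"),
                        source_tool=tool,
                        sample_id="synthetic",
                        junction_reads=reads,
                        raw_id=f"{circ_id}.v{v}",
                    )
                )
        truth.append(
            TruthRecord(
                circ_id=circ_id,
                chrom=chrom,
                start=min(s for s, _ in variants),
                end=max(e for _, e in variants),
                true_host_gene=host,
                true_class=cls,
                variants=tuple(variants),
                variant_tools=tuple(variant_tools),
            )
        )

    for tool in PREDICTOR_TOOLS:
        tool_calls[tool].sort(key=CircCall.sort_key)

    universe = Universe(
        seed=seed,
        genome=genome,
        genes=genes,
        truth=truth,
        tool_calls=tool_calls,
        db_records=db_records,
    )
    if out_dir is not None:
        universe.write(out_dir)
    return universe


# ---------------------------------------------------------------------------
# file emission

def _write_fasta(path: Path, records, width: int = 70) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for _, title, seq in records:
            fh.write(f">{title}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _write_gff3(path: Path, genes: Sequence[PlantedGene]) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            # GFF3 is 1-based closed
            fh.write(
                f"{g.chrom}\tcirckit\tgene\t{g.start + 1}\t{g.end}\t.\t+\t.\t"
                f"ID={g.gene_id};Name={g.symbol}\n"
            )
            rna_id = f"rna_{g.gene_id}"
            fh.write(
                f"{g.chrom}\tcirckit\tmRNA\t{g.start + 1}\t{g.end}\t.\t+\t.\t"
                f"ID={rna_id};Parent={g.gene_id}\n"
            )
            for j, (es, ee) in enumerate(g.exons):
                fh.write(
                    f"{g.chrom}\tcirckit\texon\t{es + 1}\t{ee}\t.\t+\t.\t"
                    f"ID=exon_{g.gene_id}.{j};Parent={rna_id}\n"
                )


def _write_truth(path: Path, truth: Sequence[TruthRecord]) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write(
            "circ_id\tchrom\tstart\tend\ttrue_host_gene\ttrue_class\t"
            "tools_reporting\tplanted_variants\n"
        )
        for t in truth:
            fh.write(
                f"{t.circ_id}\t{t.chrom}\t{t.start}\t{t.end}\t{t.true_host_gene}\t"
                f"{t.true_class.value}\t{','.join(t.tools_reporting)}\t"
                f"{t.planted_variants}\n"
            )


def _write_tool_file(path: Path, tool: str, calls: Sequence[CircCall]) -> None:
    """Emit calls in the tool's own dialect and coordinate convention."""
    dialect = DIALECTS[tool]
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        if tool in ("ciri", "ciri2"):
            fh.write(
                "circRNA_ID\tchr\tcircRNA_start\tcircRNA_end\t#junction_reads\t"
                "SM_MS_SMS\t#non_junction_reads\tjunction_reads_ratio\t"
                "circRNA_type\tgene_id\tstrand\tjunction_reads_ID\n"
            )
            for c in calls:
                s1, e1 = denormalize(c.interval, dialect.coordinate_convention)
                reads = c.junction_reads or 0
                fh.write(
                    f"{c.chrom}:{s1}|{e1}\t{c.chrom}\t{s1}\t{e1}\t{reads}\t"
                    f"{reads}_0_0\t{reads * 3}\t0.25\texon\tn/a\t"
                    f"{c.interval.strand}\t.\n"
                )
        elif tool == "circexplorer2":
            for c in calls:
                reads = c.junction_reads or 0
                span = c.interval.span
                fh.write(
                    f"{c.chrom}\t{c.start}\t{c.end}\t{c.raw_id or '.'}\t0\t"
                    f"{c.interval.strand}\t{c.start}\t{c.end}\t0,0,0\t1\t{span}\t0\t"
                    f"{reads}\tcircRNA\tn/a\tn/a\n"
                )
        else:  # find_circ / circfinder: BED6-like, reads in the score column
            for c in calls:
                reads = c.junction_reads or 0
                fh.write(
                    f"{c.chrom}\t{c.start}\t{c.end}\t{c.raw_id or '.'}\t{reads}\t"
                    f"{c.interval.strand}\n"
                )
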