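"""Gene models from GFF3 and structural classification of circRNA calls.

A circRNA locus is classified by which parts of its best-overlapping gene it
covers: only exon bases -> exonic; only intron bases -> intronic; at least
one of each -> exon_intronic; no gene overlap at all -> intergenic.  A call
on a chromosome absent from the annotation is unclassified.

GFF3 parsing is delegated to :mod:`gffutils` (in-memory database); exons of
all transcripts of a gene are unioned, and introns are derived as the gaps
between consecutive unioned exons within the gene span.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import gffutils
from intervaltree import IntervalTree

from .model import CircCall, GenomicInterval, StructuralClass

log = logging.getLogger(__name__)

PathLike = Union[str, Path]


class EmptyAnnotationError(ValueError):
    """The GFF3 contains no gene features."""


@dataclass(frozen=True)
class GeneModel:
    """One gene with unioned exons and derived introns.

    Exons are non-overlapping, sorted, and clipped to the gene span; introns
    are the gaps between consecutive exons, so exons and introns together
    tile ``[exons[0].start, exons[-1].end)`` without overlap.
    """

    gene_id: str
    gene_name: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    introns: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        for e in self.exons:
            if e.start < self.interval.start or e.end > self.interval.end:
                raise ValueError(f"exon {e} outside gene span of {self.gene_id}")


def union_intervals(
    intervals: Iterable[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Union of half-open integer intervals, sorted and non-overlapping.

    Touching intervals (a.end == b.start) are coalesced, matching the
    exon-union semantics (adjacent exon copies describe contiguous sequence).
    """
    ivs = sorted(intervals)
    out: list[list[int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _build_gene(
    gene_id: str,
    gene_name: str,
    chrom: str,
    gene_start: int,
    gene_end: int,
    strand: str,
    exon_bounds: Sequence[tuple[int, int]],
) -> GeneModel:
    clipped = []
    for s, e in exon_bounds:
        cs, ce = max(s, gene_start), min(e, gene_end)
        if (cs, ce) != (s, e):
            log.warning(
                "exon %d-%d of gene %s extends past the gene span; clipped",
                s, e, gene_id,
            )
        if cs < ce:
            clipped.append((cs, ce))
    merged = union_intervals(clipped)
    exons = tuple(GenomicInterval(chrom, s, e, strand) for s, e in merged)
    introns = tuple(
        GenomicInterval(chrom, merged[i][1], merged[i + 1][0], strand)
        for i in range(len(merged) - 1)
    )
    return GeneModel(
        gene_id=gene_id,
        gene_name=gene_name,
        interval=GenomicInterval(chrom, gene_start, gene_end, strand),
        exons=exons,
        introns=introns,
    )


def _gene_name(feature) -> str:
    for key in ("Name", "gene", "ID"):
        if key in feature.attributes and feature.attributes[key]:
            return feature.attributes[key][0]
    return feature.id


def load_annotation(path: PathLike) -> list[GeneModel]:
    """Parse a GFF3 file (optionally gzipped) into gene models.

    Exons of all child transcripts are unioned per gene; a gene without any
    exon feature gets its full span as a single exon.  Exons that resolve to
    no gene parent are skipped with a warning.  Raises
    :class:`EmptyAnnotationError` when no gene features exist.
    """
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            data = fh.read()
    else:
        data = path.read_text()
    db = gffutils.create_db(
        data,
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        # GFF3 is 1-based closed; convert to internal 0-based half-open.
        gstart, gend = gene.start - 1, gene.end
        exon_bounds = [
            (ex.start - 1, ex.end)
            for ex in db.children(gene, featuretype="exon")
        ]
        if not exon_bounds:
            log.warning("gene %s has no exon features; using its full span", gene.id)
            exon_bounds = [(gstart, gend)]
        strand = gene.strand if gene.strand in ("+", "-") else "."
        genes.append(
            _build_gene(gene.id, _gene_name(gene), gene.seqid, gstart, gend,
                        strand, exon_bounds)
        )
    if not genes:
        raise EmptyAnnotationError(f"no gene features found in {path}")

    n_orphans = sum(
        1
        for exon in db.features_of_type("exon")
        if not any(db.parents(exon, featuretype="gene"))
    )
    if n_orphans:
        log.warning("%d exon feature(s) with no resolvable gene parent skipped",
                    n_orphans)
    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start, g.gene_name))
    return genes


def _overlap_bp(a: GenomicInterval, s: int, e: int) -> int:
    return max(0, min(a.end, e) - max(a.start, s))


class AnnotationIndex:
    """Interval-tree index over gene models for fast classification queries."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = list(genes)
        self._trees: dict[str, IntervalTree] = {}
        for gene in self.genes:
            tree = self._trees.setdefault(gene.interval.chrom, IntervalTree())
            tree.addi(gene.interval.start, gene.interval.end, gene)

    @property
    def chromosomes(self) -> set[str]:
        return set(self._trees)

    def overlapping_genes(self, interval: GenomicInterval) -> list[GeneModel]:
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(interval.start, interval.end)]

    def classify_interval(
        self, interval: GenomicInterval
    ) -> tuple[StructuralClass, Optional[str]]:
        """Classify an interval; returns (class, host gene name or None).

        Among overlapping genes the one with the most overlapped bases wins
        (ties broken by lexicographic gene name).  Within a gene-span overlap
        that touches neither modeled exon nor intron bases (possible with
        clipped annotations), the call is treated as intronic: inside the
        gene but outside any modeled exon.
        """
        if interval.chrom not in self._trees:
            log.warning(
                "chromosome %s absent from the annotation; call unclassified",
                interval.chrom,
            )
            return StructuralClass.UNCLASSIFIED, None
        candidates = self.overlapping_genes(interval)
        if not candidates:
            return StructuralClass.INTERGENIC, None
        gene = min(
            candidates,
            key=lambda g: (-_overlap_bp(interval, g.interval.start, g.interval.end),
                           g.gene_name),
        )
        s, e = interval.start, interval.end
        exon_bp = sum(_overlap_bp(x, s, e) for x in gene.exons)
        intron_bp = sum(_overlap_bp(x, s, e) for x in gene.introns)
        if exon_bp and intron_bp:
            cls = StructuralClass.EXON_INTRONIC
        elif exon_bp:
            cls = StructuralClass.EXONIC
        else:
            cls = StructuralClass.INTRONIC
        return cls, gene.gene_name


def classify(
    call: CircCall, genes: Union[AnnotationIndex, Sequence[GeneModel]]
) -> tuple[StructuralClass, Optional[str]]:
    """Classify one call against gene models (strand-insensitive)."""
    index = genes if isinstance(genes, AnnotationIndex) else AnnotationIndex(genes)
    return index.classify_interval(call.interval)
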