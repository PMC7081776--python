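"""Shared data model for back-splice calls and the internal coordinate convention.

All coordinates inside the package are 0-based half-open (BED-compatible):
an interval (start, end) covers the bases start .. end-1 and its span is
``end - start``.  Predictor outputs that use 1-based closed coordinates
(CIRI/CIRI2) are converted on entry by :func:`normalize` and converted back
only when re-emitting in that dialect.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

STRAND_UNKNOWN = "."
VALID_STRANDS = ("+", "-", STRAND_UNKNOWN)

#: closed set of recognised upstream predictors (plus plain BED input)
SOURCE_TOOLS = ("ciri", "ciri2", "circexplorer2", "find_circ", "circfinder", "bed")

ZERO_HALF_OPEN = "zero_half_open"
ONE_CLOSED = "one_closed"
CONVENTIONS = (ZERO_HALF_OPEN, ONE_CLOSED)

NOT_ASSIGNED = "NOT ASSIGNED"


class CoordinateError(ValueError):
    """Raised for malformed genomic coordinates."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic interval in 0-based half-open coordinates.

    Parameters
    ----------
    chrom : str
        Sequence (chromosome/contig/linkage-group) name, matched verbatim.
    start, end : int
        0-based half-open bounds; ``0 <= start < end`` is enforced.
    strand : str
        One of ``+``, ``-`` or ``.`` (unknown).
    """

    chrom: str
    start: int
    end: int
    strand: str = STRAND_UNKNOWN

    def __post_init__(self) -> None:
        if not self.chrom:
            raise CoordinateError("chrom must be non-empty")
        if self.start < 0 or self.end <= self.start:
            raise CoordinateError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise CoordinateError(f"invalid strand {self.strand!r}")

    @property
    def span(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Share at least one base (strand-insensitive)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def normalize(
    chrom: str,
    start: int,
    end: int,
    convention: str,
    strand: str = STRAND_UNKNOWN,
) -> GenomicInterval:
    """Convert predictor coordinates to the internal 0-based half-open form.

    ``one_closed`` input ``(s, e)`` maps to ``(s - 1, e)``; ``zero_half_open``
    passes through unchanged.  Span in bases is invariant under the shift.
    """
    if convention not in CONVENTIONS:
        raise CoordinateError(f"unknown coordinate convention {convention!r}")
    if convention == ONE_CLOSED:
        if start < 1:
            raise CoordinateError(
                f"1-based start must be >= 1, got {start} on {chrom}"
            )
        if end < start:
            raise CoordinateError(
                f"malformed 1-based interval {chrom}:{start}-{end} (end < start)"
            )
        start, end = start - 1, end
    else:
        if start < 0:
            raise CoordinateError(f"negative start {start} on {chrom}")
        if end <= start:
            raise CoordinateError(
                f"malformed 0-based interval {chrom}:{start}-{end}"
            )
    return GenomicInterval(chrom, start, end, strand)


def denormalize(interval: GenomicInterval, convention: str) -> tuple[int, int]:
    """Re-emit internal coordinates under the given convention (round-trip of
    :func:`normalize`)."""
    if convention not in CONVENTIONS:
        raise CoordinateError(f"unknown coordinate convention {convention!r}")
    if convention == ONE_CLOSED:
        return interval.start + 1, interval.end
    return interval.start, interval.end


def span_bp(interval: GenomicInterval) -> int:
    """Interval size in base pairs (always >= 1 for a valid interval)."""
    return interval.end - interval.start


@dataclass(frozen=True)
class CircCall:
    """One back-splice event as reported by one predictor for one sample."""

    interval: GenomicInterval
    source_tool: str
    sample_id: str = ""
    junction_reads: Optional[int] = None
    raw_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.source_tool not in SOURCE_TOOLS:
            raise ValueError(
                f"unknown source tool {self.source_tool!r}; expected one of {SOURCE_TOOLS}"
            )
        if self.junction_reads is not None and self.junction_reads < 0:
            raise ValueError("junction_reads must be non-negative")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.source_tool, self.sample_id)


@dataclass(frozen=True)
class CircCluster:
    """A merged group of overlapping (or contiguous) calls: one circRNA locus.

    ``n_variants`` counts distinct (start, end) back-splice pairs among the
    members — the number of circRNA isoform types at the locus; min/max span
    are the extremes over members.
    """

    locus: GenomicInterval
    members: tuple[CircCall, ...]
    n_variants: int
    min_span_bp: int
    max_span_bp: int

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must have at least one member")
        if not (1 <= self.n_variants <= len(self.members)):
            raise ValueError("n_variants out of range")
        if self.min_span_bp > self.max_span_bp:
            raise ValueError("min_span_bp > max_span_bp")

    @classmethod
    def from_members(cls, members: Sequence[CircCall]) -> "CircCluster":
        """Build a cluster with its envelope and per-cluster statistics.

        Cluster strand is the members' consensus: the shared strand if all
        stranded members agree, otherwise unknown.
        """
        if not members:
            raise ValueError("cannot build a cluster from zero members")
        members = tuple(sorted(members, key=CircCall.sort_key))
        chroms = {m.chrom for m in members}
        if len(chroms) > 1:
            raise ValueError(f"cluster members span chromosomes {sorted(chroms)}")
        strands = {m.interval.strand for m in members} - {STRAND_UNKNOWN}
        strand = strands.pop() if len(strands) == 1 else STRAND_UNKNOWN
        spans = [m.interval.span for m in members]
        return cls(
            locus=GenomicInterval(
                members[0].chrom,
                min(m.start for m in members),
                max(m.end for m in members),
                strand,
            ),
            members=members,
            n_variants=len({(m.start, m.end) for m in members}),
            min_span_bp=min(spans),
            max_span_bp=max(spans),
        )


class StructuralClass(str, enum.Enum):
    """Structural composition of a circRNA locus relative to gene models."""

    EXONIC = "exonic"
    INTRONIC = "intronic"
    EXON_INTRONIC = "exon_intronic"
    INTERGENIC = "intergenic"
    #: only when the call's chromosome has no annotation at all
    UNCLASSIFIED = "unclassified"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value
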