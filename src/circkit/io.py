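"""Readers for the predictor output dialects and writers for BED/annotation tables.

Each supported predictor format is described declaratively by a
:class:`DialectSpec` (column indices + coordinate convention), so supporting
a new tool version is a configuration change.  Column layouts follow the
upstream tools' own documentation:

* CIRI / CIRI2 — tab-separated, 1-based closed coordinates; circRNA id,
  chrom, start, end, junction reads in the first five columns; CIRI2 adds a
  strand column.
* CircExplorer2 — BED12-like, 0-based half-open, back-splice read count in
  column 13.
* find_circ — BED6-like, 0-based half-open, read count in the score column.
* circFinder (circRNA_finder) — BED6-like, 0-based half-open.
* bed — plain BED with 3 to 6 columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .model import (
    NOT_ASSIGNED,
    ONE_CLOSED,
    STRAND_UNKNOWN,
    VALID_STRANDS,
    ZERO_HALF_OPEN,
    CircCall,
    CoordinateError,
    normalize,
)

log = logging.getLogger(__name__)

PathLike = Union[str, Path]


class EmptyInputError(ValueError):
    """A predictor file yielded zero parseable records."""


class DialectError(KeyError):
    """Unknown dialect name."""


@dataclass(frozen=True)
class DialectSpec:
    """Declarative description of one predictor output format.

    ``column_map`` maps semantic fields (chrom, start, end, strand,
    junction_reads, id) to 0-based column indices; chrom/start/end are
    mandatory, the rest optional.  Optional columns are used when present on
    a line and silently ignored when the line is too short.
    """

    name: str
    column_map: dict
    coordinate_convention: str
    header_lines: int = 0
    comment_prefix: str = "#"

    def __post_init__(self) -> None:
        for required in ("chrom", "start", "end"):
            if required not in self.column_map:
                raise ValueError(f"dialect {self.name}: column_map lacks {required!r}")


DIALECTS: dict[str, DialectSpec] = {
    "ciri": DialectSpec(
        name="ciri",
        column_map={"id": 0, "chrom": 1, "start": 2, "end": 3, "junction_reads": 4, "strand": 10},
        coordinate_convention=ONE_CLOSED,
        header_lines=1,
    ),
    "ciri2": DialectSpec(
        name="ciri2",
        column_map={"id": 0, "chrom": 1, "start": 2, "end": 3, "junction_reads": 4, "strand": 10},
        coordinate_convention=ONE_CLOSED,
        header_lines=1,
    ),
    "circexplorer2": DialectSpec(
        name="circexplorer2",
        column_map={"chrom": 0, "start": 1, "end": 2, "id": 3, "strand": 5, "junction_reads": 12},
        coordinate_convention=ZERO_HALF_OPEN,
    ),
    "find_circ": DialectSpec(
        name="find_circ",
        column_map={"chrom": 0, "start": 1, "end": 2, "id": 3, "junction_reads": 4, "strand": 5},
        coordinate_convention=ZERO_HALF_OPEN,
    ),
    "circfinder": DialectSpec(
        name="circfinder",
        column_map={"chrom": 0, "start": 1, "end": 2, "id": 3, "junction_reads": 4, "strand": 5},
        coordinate_convention=ZERO_HALF_OPEN,
    ),
    "bed": DialectSpec(
        name="bed",
        column_map={"chrom": 0, "start": 1, "end": 2, "id": 3, "strand": 5},
        coordinate_convention=ZERO_HALF_OPEN,
    ),
}


def get_dialect(name: str) -> DialectSpec:
    try:
        return DIALECTS[name]
    except KeyError:
        raise DialectError(
            f"unknown dialect {name!r}; known: {sorted(DIALECTS)}"
        ) from None


@dataclass
class ParseResult:
    """Calls plus bookkeeping: parsed + skipped = data lines seen."""

    calls: list
    n_data_lines: int
    n_skipped: int

    @property
    def n_parsed(self) -> int:
        return len(self.calls)


def _parse_line(
    fields: Sequence[str], dialect: DialectSpec, sample_id: str, source_tool: str
) -> CircCall:
    cmap = dialect.column_map
    chrom = fields[cmap["chrom"]]
    start = int(fields[cmap["start"]])
    end = int(fields[cmap["end"]])

    strand = STRAND_UNKNOWN
    si = cmap.get("strand")
    if si is not None and si < len(fields) and fields[si] in ("+", "-"):
        strand = fields[si]

    junction_reads = None
    ji = cmap.get("junction_reads")
    if ji is not None and ji < len(fields):
        try:
            junction_reads = int(fields[ji])
            if junction_reads < 0:
                junction_reads = None
        except ValueError:
            junction_reads = None

    raw_id = None
    ii = cmap.get("id")
    if ii is not None and ii < len(fields) and fields[ii] not in ("", "."):
        raw_id = fields[ii]

    interval = normalize(chrom, start, end, dialect.coordinate_convention, strand)

    # CIRI composite ids encode chrom:start|end (1-based); the coordinate
    # columns win on mismatch, with a warning.
    if raw_id and ":" in raw_id and "|" in raw_id:
        try:
            id_chrom, rest = raw_id.split(":", 1)
            id_start, id_end = rest.split("|", 1)
            if (id_chrom, int(id_start), int(id_end)) != (chrom, start, end):
                log.warning(
                    "id %s disagrees with coordinate columns %s:%d-%d; "
                    "using the coordinate columns",
                    raw_id, chrom, start, end,
                )
        except ValueError:
            pass

    return CircCall(
        interval=interval,
        source_tool=source_tool,
        sample_id=sample_id,
        junction_reads=junction_reads,
        raw_id=raw_id,
    )


def read_calls(
    path: PathLike,
    dialect: Union[str, DialectSpec],
    sample_id: str = "",
    source_tool: Optional[str] = None,
    strict: bool = False,
) -> ParseResult:
    """Parse one predictor file into calls, counting skipped malformed lines.

    Malformed lines (wrong field count, non-numeric or inverted coordinates)
    are skipped with a warning unless ``strict`` is set, in which case the
    first one aborts the parse.  A file with zero parseable data lines raises
    :class:`EmptyInputError`.
    """
    if isinstance(dialect, str):
        dialect = get_dialect(dialect)
    if source_tool is None:
        source_tool = dialect.name

    path = Path(path)
    calls: list[CircCall] = []
    n_data = 0
    n_skipped = 0
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= dialect.header_lines:
                continue
            line = line.rstrip("\n")
            if not line or line.startswith(dialect.comment_prefix):
                continue
            n_data += 1
            fields = line.split("\t")
            try:
                calls.append(_parse_line(fields, dialect, sample_id, source_tool))
            except (IndexError, ValueError, CoordinateError) as exc:
                if strict:
                    raise ValueError(
                        f"{path}:{lineno}: malformed {dialect.name} line: {exc}"
                    ) from exc
                n_skipped += 1
                log.warning("%s:%d: skipping malformed %s line (%s)",
                            path, lineno, dialect.name, exc)
    if not calls:
        raise EmptyInputError(
            f"no parseable {dialect.name} records in {path} "
            f"({n_data} data lines, {n_skipped} skipped)"
        )
    return ParseResult(calls=calls, n_data_lines=n_data, n_skipped=n_skipped)


def parse_calls(
    path: PathLike,
    dialect: Union[str, DialectSpec],
    sample_id: str = "",
    source_tool: Optional[str] = None,
    strict: bool = False,
) -> list:
    """Like :func:`read_calls` but returns only the call list."""
    return read_calls(path, dialect, sample_id, source_tool, strict).calls


def write_bed(calls: Iterable[CircCall], path: PathLike) -> int:
    """Write calls as sorted 6-column BED (0-based half-open, LF endings).

    Returns the number of records written.  The name column carries the
    original predictor id when present, else ``.``; score carries the
    junction read count when present, else 0.
    """
    rows = sorted(calls, key=CircCall.sort_key)
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for c in rows:
            name = c.raw_id if c.raw_id else "."
            score = c.junction_reads if c.junction_reads is not None else 0
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{name}\t{score}\t{c.interval.strand}\n"
            )
    return len(rows)


ANNOTATION_COLUMNS = (
    "chrom",
    "start",
    "end",
    "n_variants",
    "min_span_bp",
    "max_span_bp",
    "host_gene",
    "assignment_evidence",
    "structural_class",
)


def write_annotation_table(records: Iterable, path: PathLike) -> int:
    """Write final annotation records as a fixed-header TSV.

    ``records`` are :class:`circkit.pipeline.AnnotatedCirc`; the host-gene
    column renders the literal ``NOT ASSIGNED`` sentinel when no assignment
    survived, and the structural column is ``.`` when classification was not
    requested.
    """
    n = 0
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for rec in records:
            fh.write("\t".join(str(v) for v in rec.as_row()) + "\n")
            n += 1
    return n
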