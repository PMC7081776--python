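"""Host-gene assignment by sequence similarity.

The locus sequence of each circRNA cluster (the genomic span between its
back-splice coordinates) is extracted from the reference FASTA and searched
against a nucleotide database.  Hits below 90% identity and hits whose
titles match a configurable blacklist of non-informative descriptions
("uncharacterized", "clone", "linkage group", ...) are discarded; the best
surviving hit names the presumptive host gene, and a query with no
surviving hit is marked with the literal sentinel ``NOT ASSIGNED``.

Two interchangeable backends implement the search contract:

* ``local_db`` — shells out to the standard ``blastn`` executable against a
  ``makeblastdb`` database, with ``-perc_identity 90 -max_target_seqs 1000
  -max_hsps 1`` by default, parsing its tabular output.
* ``naive_internal`` — a pure-Python windowed-identity scan over a FASTA
  database, used for fully deterministic offline runs and testing.
"""

from __future__ import annotations

import logging
import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from pyfaidx import Fasta

from .model import NOT_ASSIGNED, STRAND_UNKNOWN, GenomicInterval

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: the list in the pipeline's description ends in "and others": treat as config
DEFAULT_BLACKLIST = (
    "uncharacterized",
    "clone",
    "linkage group",
    "unplaced",
    "scaffold",
    "predicted",
    "hypothetical",
)

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class MissingSequenceError(KeyError):
    """Requested chromosome absent from the genome FASTA."""


class OutOfBoundsError(ValueError):
    """Interval extends past the end of its chromosome."""


class BackendUnavailableError(RuntimeError):
    """The requested search backend cannot run."""


@dataclass(frozen=True)
class SearchConfig:
    """Similarity-search parameters (defaults follow the pipeline contract)."""

    min_percent_identity: float = 90.0
    max_targets: int = 1000
    max_alignments_per_pair: int = 1
    threads: int = 1
    taxon_filter: Optional[str] = None
    backend: str = "naive_internal"

    def __post_init__(self) -> None:
        if not (0 < self.min_percent_identity <= 100):
            raise ValueError("min_percent_identity must be in (0, 100]")
        if self.max_targets < 1 or self.max_alignments_per_pair < 1 or self.threads < 1:
            raise ValueError("max_targets, max_alignments_per_pair and threads must be >= 1")
        if self.backend not in ("local_db", "naive_internal"):
            raise ValueError(f"unknown backend {self.backend!r}")


@dataclass(frozen=True)
class HitRecord:
    """One similarity-search alignment result."""

    query_id: str
    subject_title: str
    percent_identity: float
    alignment_length: int
    bit_score: float
    e_value: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.percent_identity <= 100):
            raise ValueError("percent_identity must be in (0, 100]")
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")


@dataclass(frozen=True)
class HostAssignment:
    """Final host-gene call for one circRNA locus."""

    gene_name: str
    evidence: Optional[object] = None
    source: str = "none"  # homology | annotation | none

    def __post_init__(self) -> None:
        if self.source not in ("homology", "annotation", "none"):
            raise ValueError(f"unknown assignment source {self.source!r}")
        if (self.gene_name == NOT_ASSIGNED) != (self.source == "none"):
            raise ValueError("gene_name is NOT ASSIGNED iff source is none")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_sequence(genome: Union[Fasta, PathLike], interval: GenomicInterval) -> str:
    """Extract the genomic substring [start, end), uppercased.

    Reverse-complemented for minus-strand intervals; unknown strand is
    treated as plus with a warning (predictor strand calls are often
    absent).
    """
    if not isinstance(genome, Fasta):
        genome = Fasta(str(genome))
    if interval.chrom not in genome:
        raise MissingSequenceError(
            f"chromosome {interval.chrom!r} not present in the genome FASTA"
        )
    chrom_len = len(genome[interval.chrom])
    if interval.end > chrom_len:
        raise OutOfBoundsError(
            f"interval end {interval.end} exceeds length {chrom_len} of {interval.chrom}"
        )
    seq = str(genome[interval.chrom][interval.start:interval.end]).upper()
    if interval.strand == "-":
        return reverse_complement(seq)
    if interval.strand == STRAND_UNKNOWN:
        log.debug("strand unknown for %s:%d-%d; using forward strand",
                  interval.chrom, interval.start, interval.end)
    return seq


def filter_hits(
    hits: Sequence[HitRecord],
    config: SearchConfig = SearchConfig(),
    blacklist: Sequence[str] = DEFAULT_BLACKLIST,
) -> list[HitRecord]:
    """Drop low-identity and non-informative hits, preserving input order.

    A hit survives iff its percent identity is >= the configured minimum and
    its subject title, lowercased, contains none of the blacklist
    substrings.  Idempotent and order-stable.
    """
    lowered = [b.lower() for b in blacklist]
    out = []
    for hit in hits:
        if hit.percent_identity < config.min_percent_identity:
            continue
        title = hit.subject_title.lower()
        if any(b in title for b in lowered):
            continue
        out.append(hit)
    return out


_SYMBOL_RE = re.compile(r"\(([^()\s][^()]*)\)\s*$")
_ORGANISM_RE = re.compile(r"\[[^\[\]]*\]")


def extract_gene_name(subject_title: str) -> str:
    """Pull a gene symbol or cleaned description out of a database title.

    Database description lines typically look like
    ``ACCESSION description words (SYMBOL) [organism]``.  The leading
    accession token and any bracketed organism qualifier are stripped; a
    trailing parenthesised symbol, when present, wins over the free-text
    description.
    """
    title = _ORGANISM_RE.sub("", subject_title).strip()
    m = _SYMBOL_RE.search(title)
    if m:
        return m.group(1).strip()
    tokens = title.split()
    if len(tokens) > 1:
        tokens = tokens[1:]  # drop the accession
    return " ".join(tokens).strip() or subject_title.strip()


def assign_host(hits: Sequence[HitRecord]) -> HostAssignment:
    """Pick the best surviving hit as host gene, or NOT ASSIGNED if none.

    Best-hit key: highest bit score, ties by highest percent identity, then
    lexicographically smallest subject title — deterministic under any
    permutation of hits with distinct keys.
    """
    if not hits:
        return HostAssignment(NOT_ASSIGNED, None, "none")
    best = min(
        hits,
        key=lambda h: (-h.bit_score, -h.percent_identity, h.subject_title),
    )
    return HostAssignment(extract_gene_name(best.subject_title), best, "homology")


def read_fasta_records(path: PathLike) -> list[tuple[str, str, str]]:
    """Plain FASTA reader returning (id, full title line, sequence)."""
    records = []
    name = title = None
    chunks: list[str] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    records.append((name, title, "".join(chunks).upper()))
                title = line[1:].strip()
                name = title.split()[0] if title else ""
                chunks = []
            elif line:
                chunks.append(line.strip())
    if name is not None:
        records.append((name, title, "".join(chunks).upper()))
    return records


class NaiveSearchBackend:
    """Exact windowed-identity scan over a small FASTA database.

    For each database record the query is slid over every offset; percent
    identity at an offset is the fraction of matching bases over the query
    length, and the best offset is reported.  The score is proportional to
    the number of identities (2 points per matching base, mirroring the
    reward of a typical nucleotide scoring scheme), so longer exact matches
    rank above shorter ones.  Both query orientations are scanned.  Intended
    for deterministic offline runs on fixture-scale databases.
    """

    name = "naive_internal"

    def __init__(self, database_fasta: PathLike):
        self.records = read_fasta_records(database_fasta)
        if not self.records:
            raise BackendUnavailableError(
                f"database FASTA {database_fasta} contains no records"
            )
        self._encoded = [
            (name, title, np.frombuffer(seq.encode(), dtype=np.uint8))
            for name, title, seq in self.records
        ]

    @staticmethod
    def _best_identity(query: np.ndarray, subject: np.ndarray) -> float:
        """Best fraction of per-base matches of query over all offsets."""
        q, s = len(query), len(subject)
        if q > s or q == 0:
            return 0.0
        windows = np.lib.stride_tricks.sliding_window_view(subject, q)
        matches = (windows == query).sum(axis=1)
        return float(matches.max()) / q

    def search(self, query_id: str, query: str, config: SearchConfig) -> list[HitRecord]:
        if config.taxon_filter is not None:
            log.warning("naive_internal backend has no taxonomy support; "
                        "taxon filter %r ignored", config.taxon_filter)
        if len(query) < 20:
            log.warning("query %s is shorter than 20 bases; identity scan is "
                        "unreliable for very short queries", query_id)
        q_fwd = np.frombuffer(query.upper().encode(), dtype=np.uint8)
        q_rev = np.frombuffer(
            reverse_complement(query.upper()).encode(), dtype=np.uint8
        )
        hits = []
        for name, title, subject in self._encoded:
            ident = max(
                self._best_identity(q_fwd, subject),
                self._best_identity(q_rev, subject),
            )
            if ident <= 0:
                continue
            pct = round(100.0 * ident, 3)
            n_matches = int(round(ident * len(query)))
            hits.append(
                HitRecord(
                    query_id=query_id,
                    subject_title=title,
                    percent_identity=pct,
                    alignment_length=len(query),
                    bit_score=2.0 * n_matches,
                    e_value=0.0,
                )
            )
        hits.sort(key=lambda h: (-h.bit_score, -h.percent_identity, h.subject_title))
        # max_hsps analogue is inherent (one alignment per subject reported)
        return hits[: config.max_targets]


class BlastBackend:
    """Tabular-output wrapper around the standard ``blastn`` executable.

    The database is built once with ``makeblastdb`` (or an existing database
    prefix can be supplied).  Output columns are pinned to
    ``qseqid stitle pident length evalue bitscore``.
    """

    name = "local_db"
    _OUTFMT = "6 qseqid stitle pident length evalue bitscore"

    def __init__(self, database_fasta: PathLike, db_prefix: Optional[PathLike] = None):
        for exe in ("blastn", "makeblastdb"):
            if shutil.which(exe) is None:
                raise BackendUnavailableError(
                    f"{exe} not found on PATH; install BLAST+ or use the "
                    "naive_internal backend"
                )
        if db_prefix is None:
            self._tmp = tempfile.TemporaryDirectory(prefix="circkit_blastdb_")
            db_prefix = Path(self._tmp.name) / "db"
            subprocess.run(
                ["makeblastdb", "-in", str(database_fasta), "-dbtype", "nucl",
                 "-out", str(db_prefix), "-parse_seqids"],
                check=True, capture_output=True,
            )
        self.db_prefix = str(db_prefix)

    def search(self, query_id: str, query: str, config: SearchConfig) -> list[HitRecord]:
        if len(query) < 20:
            log.warning("query %s is shorter than 20 bases", query_id)
        cmd = [
            "blastn",
            "-db", self.db_prefix,
            "-perc_identity", str(config.min_percent_identity),
            "-max_target_seqs", str(config.max_targets),
            "-max_hsps", str(config.max_alignments_per_pair),
            "-num_threads", str(config.threads),
            "-outfmt", self._OUTFMT,
        ]
        if config.taxon_filter is not None:
            cmd += ["-taxids", str(config.taxon_filter)]
        proc = subprocess.run(
            cmd,
            input=f">{query_id}\n{query}\n",
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0:
            raise BackendUnavailableError(
                f"blastn failed (exit {proc.returncode}): {proc.stderr.strip()}"
            )
        hits = []
        for line in proc.stdout.splitlines():
            fields = line.split("\t")
            if len(fields) < 6:
                continue
            hits.append(
                HitRecord(
                    query_id=fields[0],
                    subject_title=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    e_value=float(fields[4]),
                    bit_score=float(fields[5]),
                )
            )
        return hits


def make_backend(config: SearchConfig, database_fasta: PathLike):
    if config.backend == "naive_internal":
        return NaiveSearchBackend(database_fasta)
    return BlastBackend(database_fasta)


def search(
    query: str,
    database,
    config: SearchConfig = SearchConfig(),
    query_id: str = "query",
) -> list[HitRecord]:
    """Run one query through a backend handle (see :func:`make_backend`)."""
    if not query:
        raise ValueError("query sequence is empty")
    return database.search(query_id, query, config)
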