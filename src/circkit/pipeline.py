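"""End-to-end orchestration: parse -> consensus -> merge -> assign -> classify.

The full workflow mirrors the staged shell pipeline it replaces: predictor
outputs are parsed into a common coordinate frame, intersected across tools
into a joint prediction, merged into loci, sequence-extracted and searched
against a homology database for host-gene assignment, and (when an
annotation is supplied) structurally classified.  All ordering rules are
fixed, so two runs on identical inputs produce byte-identical tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

from pyfaidx import Fasta

from .annotation import AnnotationIndex, load_annotation
from .homology import (
    DEFAULT_BLACKLIST,
    HostAssignment,
    SearchConfig,
    assign_host,
    extract_sequence,
    filter_hits,
    make_backend,
)
from .intervals import MergePolicy, consensus_detailed, merge_calls
from .io import read_calls, write_annotation_table, write_bed
from .model import (
    NOT_ASSIGNED,
    CircCall,
    CircCluster,
    GenomicInterval,
    StructuralClass,
)

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

MODES = ("host_gene", "structural", "both")


class ConfigError(ValueError):
    """Invalid run configuration (reported before any work starts)."""


@dataclass(frozen=True)
class InputSpec:
    """One predictor output file with its dialect and sample label."""

    path: PathLike
    dialect: str
    sample_id: str = ""


@dataclass(frozen=True)
class RunConfig:
    inputs: tuple
    genome_path: PathLike
    database_path: Optional[PathLike] = None
    annotation_path: Optional[PathLike] = None
    merge_policy: MergePolicy = MergePolicy()
    search_config: SearchConfig = SearchConfig()
    consensus_min_tools: Optional[int] = None  # None = full intersection
    junction_slack: int = 0
    output_dir: Optional[PathLike] = None
    mode: str = "host_gene"
    blacklist: tuple = DEFAULT_BLACKLIST
    alias_map: Optional[dict] = None  # verbatim chrom names otherwise

    def __post_init__(self) -> None:
        if not self.inputs:
            raise ConfigError("at least one input file is required")
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode in ("structural", "both") and self.annotation_path is None:
            raise ConfigError(f"mode={self.mode} requires an annotation file")
        if self.mode == "structural" and self.merge_policy.merging_enabled:
            raise ConfigError(
                "structural mode requires merging disabled (--np): merged "
                "envelopes mix structural components"
            )


@dataclass(frozen=True)
class AnnotatedCirc:
    """Final record for one circRNA locus."""

    cluster: CircCluster
    host: HostAssignment
    structural: Optional[StructuralClass] = None
    consensus_support: Optional[int] = None

    def as_row(self) -> tuple:
        if self.host.source == "homology":
            hit = self.host.evidence
            evidence = f"homology:{hit.subject_title}|identity={hit.percent_identity}"
        elif self.host.source == "annotation":
            evidence = f"annotation:{self.host.evidence}"
        else:
            evidence = "."
        locus = self.cluster.locus
        return (
            locus.chrom,
            locus.start,
            locus.end,
            self.cluster.n_variants,
            self.cluster.min_span_bp,
            self.cluster.max_span_bp,
            self.host.gene_name,
            evidence,
            self.structural.value if self.structural is not None else ".",
        )


@dataclass(frozen=True)
class GeneSummary:
    gene: str
    n_clusters: int
    n_variants: int
    min_span_bp: int
    max_span_bp: int


@dataclass
class RunResult:
    records: list
    summary: list
    counters: dict


def summarize_by_gene(records: Sequence[AnnotatedCirc]) -> list[GeneSummary]:
    """Per-host-gene rollup: circRNA type counts and span extremes.

    One row per assigned host gene plus a single aggregate row for all
    NOT ASSIGNED loci; sorted by descending variant count, then gene name.
    """
    groups: dict[str, list[AnnotatedCirc]] = {}
    for rec in records:
        groups.setdefault(rec.host.gene_name, []).append(rec)
    rows = [
        GeneSummary(
            gene=gene,
            n_clusters=len(recs),
            n_variants=sum(r.cluster.n_variants for r in recs),
            min_span_bp=min(r.cluster.min_span_bp for r in recs),
            max_span_bp=max(r.cluster.max_span_bp for r in recs),
        )
        for gene, recs in groups.items()
    ]
    rows.sort(key=lambda r: (-r.n_variants, r.gene))
    return rows


def _apply_aliases(calls: list, alias_map: dict) -> list:
    out = []
    for c in calls:
        new_chrom = alias_map.get(c.chrom, c.chrom)
        if new_chrom != c.chrom:
            c = replace(c, interval=replace(c.interval, chrom=new_chrom))
        out.append(c)
    return out


def run(config: RunConfig) -> RunResult:
    """Execute the full pipeline; see the module docstring for the stages."""
    counters = {
        "inputs": len(config.inputs),
        "parsed": 0,
        "skipped_lines": 0,
        "consensus_passed": 0,
        "clusters": 0,
        "hits_filtered_out": 0,
        "not_assigned": 0,
        "unclassified": 0,
    }

    # stage: parse
    call_sets: dict[str, list] = {}
    for spec in config.inputs:
        try:
            result = read_calls(spec.path, spec.dialect, spec.sample_id)
        except Exception as exc:
            raise RuntimeError(f"parse stage failed on {spec.path}: {exc}") from exc
        calls = result.calls
        if config.alias_map:
            calls = _apply_aliases(calls, config.alias_map)
        counters["parsed"] += result.n_parsed
        counters["skipped_lines"] += result.n_skipped
        call_sets.setdefault(calls[0].source_tool, []).extend(calls)

    # stage: consensus (joint prediction) when more than one tool set exists
    if len(call_sets) > 1:
        detailed = consensus_detailed(
            call_sets, config.consensus_min_tools, config.junction_slack
        )
        support = {id(call): n for call, n in detailed}
        calls = [call for call, _ in detailed]
    else:
        calls = sorted(next(iter(call_sets.values())), key=CircCall.sort_key)
        support = {}
    counters["consensus_passed"] = len(calls)

    # stage: merge
    clusters = merge_calls(calls, config.merge_policy)
    counters["clusters"] = len(clusters)

    # stage: sequence extraction + homology search
    genome = Fasta(str(config.genome_path))
    backend = None
    if config.database_path is not None:
        backend = make_backend(config.search_config, config.database_path)

    index = None
    if config.annotation_path is not None:
        index = AnnotationIndex(load_annotation(config.annotation_path))

    records: list[AnnotatedCirc] = []
    for i, cluster in enumerate(clusters):
        homology_host = HostAssignment(NOT_ASSIGNED, None, "none")
        if backend is not None:
            seq = extract_sequence(genome, cluster.locus)
            query_id = f"locus_{i:05d}"
            hits = backend.search(query_id, seq, config.search_config)
            kept = filter_hits(hits, config.search_config, config.blacklist)
            counters["hits_filtered_out"] += len(hits) - len(kept)
            homology_host = assign_host(kept)

        structural = None
        host = homology_host
        if index is not None and config.mode in ("structural", "both"):
            structural, ann_gene = index.classify_interval(cluster.locus)
            if structural is StructuralClass.UNCLASSIFIED:
                counters["unclassified"] += 1
            if (
                ann_gene is not None
                and structural not in (StructuralClass.INTERGENIC,
                                       StructuralClass.UNCLASSIFIED)
            ):
                # annotation overlap is the more direct evidence when the
                # locus sits inside a modeled gene; homology covers the rest
                host = HostAssignment(ann_gene, ann_gene, "annotation")

        if host.gene_name == NOT_ASSIGNED:
            counters["not_assigned"] += 1

        member_support = (
            max((support[id(m)] for m in cluster.members if id(m) in support),
                default=None)
            if support
            else None
        )
        records.append(
            AnnotatedCirc(
                cluster=cluster,
                host=host,
                structural=structural,
                consensus_support=member_support,
            )
        )

    summary = summarize_by_gene(records)

    if config.output_dir is not None:
        _write_outputs(config, records, summary, counters)

    for key in ("parsed", "consensus_passed", "clusters", "not_assigned"):
        log.info("stage counter %s = %d", key, counters[key])
    return RunResult(records=records, summary=summary, counters=counters)


def _write_outputs(
    config: RunConfig,
    records: Sequence[AnnotatedCirc],
    summary: Sequence[GeneSummary],
    counters: dict,
) -> None:
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        ann_path = out_dir / "circ_annotations.tsv"
        write_annotation_table(records, ann_path)
        written.append(ann_path)

        sum_path = out_dir / "gene_summary.tsv"
        with open(sum_path, "wt", encoding="utf-8", newline="\n") as fh:
            fh.write("gene\tn_clusters\tn_variants\tmin_span_bp\tmax_span_bp\n")
            for row in summary:
                fh.write(
                    f"{row.gene}\t{row.n_clusters}\t{row.n_variants}\t"
                    f"{row.min_span_bp}\t{row.max_span_bp}\n"
                )
        written.append(sum_path)

        bed_path = out_dir / "consensus_loci.bed"
        envelope_calls = [
            CircCall(interval=r.cluster.locus, source_tool="bed")
            for r in records
        ]
        write_bed(envelope_calls, bed_path)
        written.append(bed_path)

        log_path = out_dir / "run_log.txt"
        with open(log_path, "wt", encoding="utf-8", newline="\n") as fh:
            for key in sorted(counters):
                fh.write(f"{key}\t{counters[key]}\n")
        written.append(log_path)

        cfg_path = out_dir / "effective_config.txt"
        with open(cfg_path, "wt", encoding="utf-8", newline="\n") as fh:
            fh.write(f"mode\t{config.mode}\n")
            fh.write(f"merge_mode\t{config.merge_policy.mode}\n")
            fh.write(f"max_gap\t{config.merge_policy.max_gap}\n")
            fh.write(f"merging_enabled\t{config.merge_policy.merging_enabled}\n")
            fh.write(f"consensus_min_tools\t{config.consensus_min_tools}\n")
            fh.write(f"junction_slack\t{config.junction_slack}\n")
            fh.write(f"min_percent_identity\t{config.search_config.min_percent_identity}\n")
            fh.write(f"max_targets\t{config.search_config.max_targets}\n")
            fh.write(f"max_alignments_per_pair\t{config.search_config.max_alignments_per_pair}\n")
            fh.write(f"backend\t{config.search_config.backend}\n")
            fh.write(f"blacklist\t{','.join(config.blacklist)}\n")
        written.append(cfg_path)
    except Exception:
        for p in written:  # no partial outputs on failure
            p.unlink(missing_ok=True)
        raise
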