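"""Native interval merging and multi-predictor consensus.

These two operations replace the external genome-arithmetic calls a shell
pipeline would make: clustering overlapping (or contiguous) back-splice
calls into loci, and intersecting per-tool call sets into a joint
prediction.  Both are single sorted sweeps and are validated in the test
suite against brute-force connected-component oracles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .model import CircCall, CircCluster

log = logging.getLogger(__name__)


class ConsensusConfigError(ValueError):
    """min_tools exceeds the number of provided tool sets."""


@dataclass(frozen=True)
class MergePolicy:
    """How calls are grouped into clusters.

    ``overlap_only`` merges calls sharing at least one base; ``contiguous``
    additionally bridges gaps of up to ``max_gap`` bases.  With
    ``merging_enabled=False`` (the CLI's --np flag) every call stays a
    singleton cluster, which structural classification requires.
    """

    mode: str = "overlap_only"
    max_gap: int = 0
    merging_enabled: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("overlap_only", "contiguous"):
            raise ValueError(f"unknown merge mode {self.mode!r}")
        if self.max_gap < 0:
            raise ValueError("max_gap must be non-negative")
        if self.mode == "overlap_only" and self.max_gap != 0:
            raise ValueError("overlap_only implies max_gap = 0")


def merge_calls(
    calls: Iterable[CircCall], policy: MergePolicy = MergePolicy()
) -> list[CircCluster]:
    """Cluster calls into loci under the merge policy.

    Two calls on the same chromosome share a cluster iff they are
    transitively connected by pairs that overlap (share >= 1 base) or, in
    contiguous mode, lie at most ``max_gap`` bases apart.  Half-open
    touching intervals (a.end == b.start) do NOT overlap; contiguous mode
    with max_gap=0 merges exactly those.  Merging is strand-insensitive.
    Output is sorted by (chrom, locus start, locus end).
    """
    calls = sorted(calls, key=CircCall.sort_key)
    if not policy.merging_enabled:
        return [CircCluster.from_members([c]) for c in calls]

    clusters: list[CircCluster] = []
    group: list[CircCall] = []
    group_end = -1
    for call in calls:
        if group and call.chrom == group[0].chrom and (
            call.start < group_end
            or (policy.mode == "contiguous" and call.start - group_end <= policy.max_gap)
        ):
            group.append(call)
            group_end = max(group_end, call.end)
        else:
            if group:
                clusters.append(CircCluster.from_members(group))
            group = [call]
            group_end = call.end
    if group:
        clusters.append(CircCluster.from_members(group))
    return clusters


def _junction_groups(
    tagged: Sequence[tuple[str, CircCall]], slack: int
) -> list[list[tuple[str, CircCall]]]:
    """Connected components of calls under the same-junction relation:
    same chromosome, |start difference| <= slack and |end difference| <= slack
    (transitively closed)."""
    if slack == 0:
        by_key: dict[tuple, list] = {}
        for tool, call in tagged:
            by_key.setdefault((call.chrom, call.start, call.end), []).append((tool, call))
        return [by_key[k] for k in sorted(by_key)]

    # union-find over calls sorted by start; only neighbours within slack
    # on start can be related, so a bounded window scan suffices.
    items = sorted(tagged, key=lambda tc: (tc[1].chrom, tc[1].start, tc[1].end, tc[0]))
    parent = list(range(len(items)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i, (_, a) in enumerate(items):
        for j in range(i + 1, len(items)):
            _, b = items[j]
            if b.chrom != a.chrom or b.start - a.start > slack:
                break
            if abs(b.end - a.end) <= slack:
                union(i, j)

    comps: dict[int, list] = {}
    for i, item in enumerate(items):
        comps.setdefault(find(i), []).append(item)
    groups = list(comps.values())
    groups.sort(key=lambda g: (g[0][1].chrom, g[0][1].start, g[0][1].end))
    return groups


def consensus_detailed(
    call_sets: Mapping[str, Sequence[CircCall]],
    min_tools: int | None = None,
    junction_slack: int = 0,
) -> list[tuple[CircCall, int]]:
    """Joint prediction across tools with per-junction support counts.

    Two calls support the same back-splice junction iff they sit on the same
    chromosome with start and end coordinates each within ``junction_slack``
    bases (transitively closed).  ``min_tools`` defaults to the number of
    provided tool sets (full intersection).  The representative call for a
    surviving junction is the one from the lexicographically first
    supporting tool (ties: smallest start, then end).  Returns
    ``(representative, number of distinct supporting tools)`` pairs sorted
    by coordinate.
    """
    if not call_sets:
        raise ConsensusConfigError("no tool call sets provided")
    n_tools = len(call_sets)
    if min_tools is None:
        min_tools = n_tools
    if min_tools < 1 or min_tools > n_tools:
        raise ConsensusConfigError(
            f"min_tools={min_tools} out of range for {n_tools} tool set(s)"
        )
    if junction_slack < 0:
        raise ValueError("junction_slack must be non-negative")

    tagged = [
        (tool, call)
        for tool in sorted(call_sets)
        for call in call_sets[tool]
    ]
    result: list[tuple[CircCall, int]] = []
    for group in _junction_groups(tagged, junction_slack):
        support = {tool for tool, _ in group}
        if len(support) >= min_tools:
            tool, call = min(
                group, key=lambda tc: (tc[0], tc[1].start, tc[1].end)
            )
            result.append((call, len(support)))
    result.sort(key=lambda cs: cs[0].sort_key())
    return result


def consensus(
    call_sets: Mapping[str, Sequence[CircCall]],
    min_tools: int | None = None,
    junction_slack: int = 0,
) -> list[CircCall]:
    """Like :func:`consensus_detailed` but returns only the calls."""
    return [call for call, _ in consensus_detailed(call_sets, min_tools, junction_slack)]
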