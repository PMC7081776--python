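"""Independent brute-force oracles used to validate the interval engine and
the structural classifier.  Deliberately naive: graph connected components
for merging, exhaustive support counting for consensus, and per-base
membership scans for classification."""

from __future__ import annotations

import numpy as np


def brute_force_merge(intervals, mode="overlap_only", max_gap=0):
    """Connected components of the pairwise overlap/gap relation.

    ``intervals`` are (chrom, start, end) triples.  Overlap means sharing at
    least one base (half-open); contiguous mode also relates two intervals
    whose gap is at most ``max_gap``.  Returns sorted envelopes with sorted
    member index tuples.
    """
    n = len(intervals)

    def related(a, b):
        if a[0] != b[0]:
            return False
        if a[1] < b[2] and b[1] < a[2]:
            return True
        if mode == "contiguous":
            gap = max(b[1] - a[2], a[1] - b[2])
            return gap <= max_gap
        return False

    seen = [False] * n
    components = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            j = stack.pop()
            comp.append(j)
            for k in range(n):
                if not seen[k] and related(intervals[j], intervals[k]):
                    seen[k] = True
                    stack.append(k)
        comp.sort()
        chrom = intervals[comp[0]][0]
        components.append(
            (
                chrom,
                min(intervals[j][1] for j in comp),
                max(intervals[j][2] for j in comp),
                tuple(comp),
            )
        )
    components.sort()
    return components


def brute_force_consensus(call_sets, min_tools, slack=0):
    """Exhaustive same-junction support counting.

    ``call_sets`` maps tool -> list of (chrom, start, end).  Junction groups
    are the transitive closure of the |dstart| <= slack and |dend| <= slack
    relation; returns the sorted set of junction keys (one per surviving
    group: the lexicographically smallest member) with >= min_tools distinct
    supporting tools.
    """
    tagged = [
        (tool, iv) for tool in sorted(call_sets) for iv in call_sets[tool]
    ]
    n = len(tagged)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = tagged[i][1], tagged[j][1]
            if a[0] == b[0] and abs(a[1] - b[1]) <= slack and abs(a[2] - b[2]) <= slack:
                parent[find(j)] = find(i)

    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(tagged[i])
    survivors = []
    for members in groups.values():
        tools = {t for t, _ in members}
        if len(tools) >= min_tools:
            survivors.append(min(iv for _, iv in members))
    return sorted(survivors)


class PerBaseClassifier:
    """Base-by-base membership oracle over one synthetic universe.

    For every gene a boolean exon mask and gene mask over the chromosome are
    materialised; a query interval is classified by literally counting which
    bases of the best-overlapping gene it covers.
    """

    def __init__(self, genes, chrom_lengths):
        self.masks = {}  # gene -> (chrom, gene_mask, exon_mask)
        self.chroms = set(chrom_lengths)
        for g in genes:
            length = chrom_lengths[g.chrom]
            gene_mask = np.zeros(length, dtype=bool)
            gene_mask[g.start:g.end] = True
            exon_mask = np.zeros(length, dtype=bool)
            for s, e in g.exons:
                exon_mask[s:e] = True
            self.masks[g.symbol] = (g.chrom, gene_mask, exon_mask)

    def classify(self, chrom, start, end):
        if chrom not in self.chroms:
            return "unclassified", None
        best_symbol, best_overlap = None, 0
        for symbol in sorted(self.masks):
            gchrom, gene_mask, _ = self.masks[symbol]
            if gchrom != chrom:
                continue
            overlap = int(gene_mask[start:end].sum())
            if overlap > best_overlap:
                best_symbol, best_overlap = symbol, overlap
        if best_symbol is None:
            return "intergenic", None
        _, gene_mask, exon_mask = self.masks[best_symbol]
        exon_bp = int((gene_mask[start:end] & exon_mask[start:end]).sum())
        intron_bp = int((gene_mask[start:end] & ~exon_mask[start:end]).sum())
        if exon_bp and intron_bp:
            return "exon_intronic", best_symbol
        if exon_bp:
            return "exonic", best_symbol
        return "intronic", best_symbol
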