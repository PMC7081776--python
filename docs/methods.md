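# Methods

## Problem and model

A back-splice junction is identified by a `(chromosome, start, end)` pair:
the transcript's 3' end at `end` is joined back to the 5' acceptor at
`start`. Different predictors report these pairs in different file layouts
and coordinate conventions, with only partial agreement between tools.
`circkit` models the downstream annotation problem as four independent,
deterministic operations over these pairs: multi-tool consensus, interval
merging, homology-based host-gene assignment, and annotation-based
structural classification.

### Coordinate convention

Everything internal is 0-based half-open (BED-compatible), chosen because
three of the five supported dialects are BED-like. 1-based closed input
`(s, e)` maps to `(s − 1, e)`; span in bp (`end − start`) is invariant
under the shift, and re-emission under the source convention is an exact
round trip. Chromosome names are matched verbatim — no `chr`-prefix
harmonisation — because silent renaming is itself a notorious source of
"linkage group"-style annotation noise; an explicit per-run alias map is
available instead (`RunConfig.alias_map`).

Strand may be unknown (`.`): several dialects omit it. Merging, consensus
and classification are strand-insensitive by default, since predictor
strand calls are unreliable; sequence extraction treats unknown strand as
forward.

### Consensus (joint prediction)

Calls from different tools support the same junction iff they lie on the
same chromosome with `|Δstart| ≤ slack` and `|Δend| ≤ slack`
(transitively closed; `slack` defaults to 0, i.e. exact agreement).
Consensus is junction-keyed rather than overlap-keyed on purpose: distinct
circRNA isoforms of one gene overlap heavily but have different back-splice
junctions, and overlap-keyed intersection would conflate them. The
threshold `min_tools` defaults to *all* provided tool sets (full
intersection), the conservative choice that minimises false positives at
the cost of sensitivity. The representative call for a surviving junction
comes from the lexicographically first supporting tool (ties: smallest
start, then end) — an arbitrary but fixed rule that makes output ordering
deterministic.

### Merging

Within a chromosome, calls are clustered by transitive connectivity under
"share ≥ 1 base" (overlap mode) or "gap ≤ max_gap" (contiguous mode);
half-open touching intervals (`a.end == b.start`) do **not** overlap, and
contiguous mode with `max_gap = 0` merges exactly those. The
implementation is a single sorted sweep; the test suite proves it equal to
a brute-force connected-components construction on 1,000 random interval
sets. A cluster records its envelope, the number of distinct
`(start, end)` variants (circRNA types at the locus), and min/max member
span in bp. With merging disabled every call is a singleton cluster.

### Host-gene assignment by homology

The genomic span `[start, end)` of each locus is extracted from the
reference FASTA (via pyfaidx) and searched against a nucleotide database.
The extracted sequence is the *linear* genomic span, not a
junction-reconstructed circular sequence — the simpler contract that a
coordinate-driven pipeline implies; it caps homology precision for very
short exonic circRNAs, which is an accepted limitation.

Search parameters: minimum percent identity **90**, at most **1000**
target sequences, at most **1** alignment per query/subject pair. Hits are
then filtered by a title blacklist (defaults: `uncharacterized`, `clone`,
`linkage group`, `unplaced`, `scaffold`, `predicted`, `hypothetical`);
the blacklist is configuration (`--blacklist FILE`), not code, because any
fixed list of non-informative descriptions is inherently open-ended.
Filtering is order-stable and idempotent. The best surviving hit — highest
bit score, ties by identity, then lexicographic title — names the host
gene; no surviving hit yields the literal sentinel `NOT ASSIGNED`.

Gene names are extracted from database titles by one isolated heuristic
(`extract_gene_name`): strip the leading accession token and any bracketed
organism qualifier; a trailing parenthesised symbol wins over the cleaned
description. It is the one genuinely under-determined rule in the
pipeline, so it lives in a single function with its own tests.

Two backends implement the same search contract: `local_db` shells out to
BLAST+ (`makeblastdb`/`blastn`, tabular output with pinned columns), and
`naive_internal` is a deterministic windowed-identity scan (best per-base
match fraction of the query over every offset of every database record,
both orientations; score = 2 × matching bases). The naive backend makes
the whole pipeline runnable and testable with zero external processes; on
fixture data the two backends are cross-checked against each other in the
test suite. Taxonomy filtering is passed to BLAST when requested and
ignored with a warning by the naive backend.

### Structural classification

GFF3 gene models are parsed with gffutils; exons of all transcripts are
unioned per gene (touching exons coalesce), introns are the gaps between
consecutive unioned exons, and exons extending past the gene span are
clipped with a warning. Classification of an interval: no overlapping gene
→ *intergenic*; otherwise the gene with the most overlapped bases wins
(ties: lexicographic gene name), and within it ≥1 exon base and 0 intron
bases → *exonic*, 0 and ≥1 → *intronic*, ≥1 of each → *exon-intronic*. A
gene-span overlap touching neither modeled exons nor introns (possible
with clipped annotations) counts as intronic — inside the gene, outside
any modeled exon. A chromosome absent from the annotation yields
*unclassified*. Gene queries use an interval tree; equivalence with a
literal per-base membership scan is asserted over 20 generated genomes.

Structural mode requires merging disabled: a merged envelope spanning
several isoforms mixes their components, so classifying it would be
meaningless. This is enforced as a configuration error before any work.

### Reconciling the two host-gene sources

When both an annotation and a database are supplied (`--mode both`), the
annotation-derived gene wins wherever the locus overlaps a modeled gene
(direct positional evidence), and homology covers intergenic/unclassified
loci. The `assignment_evidence` column records which source produced each
name, so the reconciliation is transparent and auditable.

## Synthetic data generator

`circkit.fixtures.generate_universe` emulates the full input universe with
a known truth table. Genes (2–6 exons, exons 100–200 bp, introns
100–250 bp) are packed on two chromosomes with 2.6–3.2 kb intergenic gaps;
genome sequence is i.i.d. uniform nucleotides, so expected cross-locus
identity is ~25% and the 90% homology filter separates true from false
hits with a wide margin by construction, not by tuning. circRNAs rotate
through the four structural classes (spans 60–160 bp, a realistic range
for single/few-exon circRNAs); intergenic ones are placed ≥1 kb from every
gene to keep the truth labels unambiguous (boundary-straddling cases are
exercised by hand-built fixtures in the tests instead). Each planted
junction is emitted into each tool's file, in that tool's dialect and
coordinate convention, with independent per-tool dropout probability; the
homology database holds each gene's genomic span under an informative
title, plus blacklisted decoy records (`uncharacterized …  clone …`) with
*identical* sequence that the hit filter must remove. Everything is
deterministic for a fixed seed.

What the generator does **not** emulate: read-level noise, splice-motif
placement, repeats and paralogy, expression levels, or real predictor
false positives. Passing tests therefore demonstrate correctness of the
coordinate arithmetic, filtering rules and orchestration — not robustness
to alignment artefacts in real data.

## Default parameters

| parameter | default | rationale |
|---|---|---|
| `min_percent_identity` | 90 | standard stringent nucleotide-identity cutoff for within-species host assignment |
| `max_targets` / `max_hsps` | 1000 / 1 | wide candidate set, one alignment per pair |
| `min_tools` | all provided | full intersection; most conservative consensus |
| `junction_slack` | 0 bp | exact junction agreement; relaxable per run |
| `max_gap` (contiguous) | 0 bp | merge only touching loci unless asked otherwise |
| blacklist | 7 substrings above | open-ended list, shipped as config |

## Verification scales

The acceptance suite runs the merge/consensus oracles on 1,000 random
sets of ≤50 intervals, the per-base classifier oracle on 20 universes of
~70 kb, end-to-end truth recovery on a 30-gene / 60-circRNA dropout-free
universe, the filter rules on 1,000 random hit lists, and the consensus
recovery statistic over 200 seeded universes at 20% dropout, checking the
recovered fraction against the exact binomial 99% interval around
(0.8)^5. These sizes give tight oracle coverage while keeping the whole
suite in seconds.

## Known limitations

* Homology uses the linear locus span; junction-spanning sequence is not
  reconstructed.
* No GTF input, no UTR/CDS sub-classification, no antisense categories.
* The naive search backend is O(database × query) and intended for
  fixture-scale databases; use the BLAST backend for real genomes.
* Poor annotation quality degrades structural calls; the package only
  warns on orphan exons and clipped features, it does not repair models.
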