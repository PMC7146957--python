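# Methods

This note records the models, conventions and numerical choices behind
`goclust`, and what the synthetic fixtures do and do not establish.

## Similarity model

Term similarity is computed over **test-set gene members** (the gene column
of the enrichment file), not over full annotation sets: enrichment outputs
carry only the test-set members, and redundancy between enriched terms is a
statement about the genes that actually drove the enrichment.  Two
coefficients are offered for gene sets A, B:

- Jaccard, `JC = |A∩B| / |A∪B|`;
- overlap, `OC = |A∩B| / min(|A|,|B|)` (default).

`0 ≤ JC ≤ OC ≤ 1` always; `OC = 1` whenever one set contains the other,
which is exactly the parent/child redundancy the clustering is meant to
collapse.  Edges are kept when the coefficient is **≥** the cutoff
(inclusive): with the conventional default cutoff of 0.5, a pair sharing
exactly half its genes is connected.

Trimming removes terms whose reference-annotation size `n` exceeds
`max_size` **strictly** (`n == max_size` is kept).  It thresholds on `n`,
not on the test-set count `x`: breadth of a term is a property of the
annotation, not of the experiment.  Dialects that do not report `n`
(g:Profiler GEM) leave those terms untrimmable; they are kept.

## Enrichment-file normalization

Gene identifiers are trimmed, upper-cased and deduplicated before any set
arithmetic — mixed capitalization across tools would silently destroy
overlaps — and `x` is always recomputed as `|genes|`.  When a file carries
both a raw and a corrected p-value (BiNGO, g:Profiler), the **corrected**
value is used: it is the headline number enrichment tools report and the one
users filter on.  Duplicate accessions within one file collapse to the row
with the smaller p-value.  Rows with an empty gene list are an error rather
than a silent drop, because a memberless term cannot participate in an
overlap network at all.

## Ontology conventions

Only OBO 1.2 flat files are parsed.  Term **depth** is the length of the
shortest `is_a` path from the namespace root (root depth 0).  Shortest-path,
`is_a`-only depth is the conservative convention: `part_of` is not a
subsumption relation and may cross namespaces, so it is parsed and available
to ancestry queries behind an explicit flag but never contributes to depth.
Obsolete terms are retained in the graph (so inputs naming them can be
diagnosed) but rejected by depth/ancestor queries; enrichment rows that
resolve to obsolete or unknown terms are dropped with a warning and listed
in the run report.  The `data-version` header is echoed into every output
file so results can be matched to the ontology release used for enrichment.

## Markov Clustering

Dense NumPy implementation; GO-term networks are at most a few thousand
nodes, so O(n³) iterations are trivial and no sparse machinery is needed.
Choices, all deterministic:

- edge **weights** (similarity values) feed the matrix — not a binarized
  adjacency — so stronger overlaps carry more flow;
- self-loop weight **1.0** on every node before column normalization
  (guarantees aperiodicity and gives isolated terms a well-defined singleton
  limit);
- expansion power fixed at **2**; inflation `r` is the user-facing
  granularity (default **1.5**; larger r → more, smaller clusters);
- pruning floor **1e-5**: entries below it are zeroed during inflation
  before renormalizing;
- convergence when the largest absolute entry change falls below **1e-6**,
  capped at **100** iterations (non-convergence is a warning and clusters
  are read from the last iterate).

Cluster extraction reads attractors (diagonal mass > 1e-8) and assigns each
node to the attractor with the largest entry in its column.  Exact ties
(relative tolerance 1e-9) go to the attractor whose unambiguously assigned
cluster holds more total test-set genes, then to the lexicographically
smallest attractor accession.  This yields a strict partition — every term
in exactly one cluster — which is asserted on every run, together with the
invariant that no cluster spans two connected components.

## Ordering, labels, representatives

"Cluster size" for ordering is the size of the **union** of member gene sets
(summing per-term counts would double-count shared genes, and a 20-term
cluster can legitimately cover only 33 distinct genes).  Ties break by
member count, then by smallest member accession, so labels are reproducible.
Sub-cluster labels are ASCII, `C1-1`, `C1-2`, …

Three representative candidates are tagged per cluster: largest `x`,
smallest p-value, highest within-cluster degree; ties break toward smaller
p-value then smaller accession.

## Cohesion statistic

For each cluster, **all** member pairs are rescored with the run's
coefficient — including pairs below the network cutoff, so non-overlapping
pairs appear as zeros — and summarized as `P(≥ t)`, the fraction of pairs at
or above threshold `t` (default 0.5; the boundary counts toward the
proportion).  Singleton clusters report "not applicable" rather than 0 or 1.
The cumulative curves plotted per cluster are ordinary empirical CDFs of the
same multiset.

## Cluster hierarchy reconstruction

Ancestor relations among cluster members are computed in the full ontology
(non-member intermediates still mediate reachability), restricted to member
pairs, then **transitively reduced over members only**: an edge implied by
two other member edges is dropped for readability.  Surviving edges are
tagged `direct` when the parent is an immediate parent in the ontology and
`transitive` when the connection runs only through non-member terms.  In the
rare diamond where a parent is simultaneously an immediate parent and an
ancestor through another member, the reduction wins and the edge is dropped;
this keeps the drawing a minimal DAG.  Multi-root clusters yield a forest;
no artificial root is added.

## Synthetic planted designs

The fixture generator emulates the *structure* of enrichment results, not
their statistics: blocks of terms share a planted fraction of their genes.

- Single-level default: 2 blocks × 5 terms × 20 genes, within-block shared
  fraction 0.8 (every within-block pair has OC ≥ 0.8), between-block
  fraction 0 (disjoint blocks).  `n` values are drawn uniformly in
  [50, 1800], p-values log-uniformly in [1e-12, 0.05].
- Two-level designs plant two sub-blocks per block (sub-core fraction 0.8,
  disjoint across sub-blocks) plus two **connector** terms per block whose
  gene sets straddle both sub-cores (OC exactly 0.5 to every block member)
  and whose `n` lies in (2000, 3400].  The main run (max_size 3500) keeps
  the connectors, so each block coheres into one cluster; a sub-clustering
  run with max_size 2000 trims them — they appear in the "not passed"
  report — and the sub-blocks separate.  This mirrors how lowering the
  term-size cutoff during sub-clustering of real data removes the broad
  terms that glue distinct themes together.

Overlap fractions are realized exactly by construction (core/unique gene
allocation, not random sampling), so recovery results are stable across
seeds; the seed only permutes gene labels and draws `n` and p values.

What the fixtures deliberately do **not** emulate: realistic GO DAG topology
(fixture ontologies are shallow trees), heavy-tailed term sizes, partially
overlapping blocks with ambiguous boundaries, or noisy gene membership.
Perfect recovery (ARI = 1.0) on these designs therefore validates the
mechanics of the pipeline — trimming, network construction, MCL, ordering,
sub-clustering — not clustering quality on borderline real data, where
cluster boundaries genuinely depend on the cutoff and granularity chosen.

## Test design notes

The MCL implementation is checked against an independently coded, naive
pure-Python dense iteration: exhaustively on all graphs of up to 5 nodes
with every per-edge weight combination from {0.5, 1.0}, exhaustively on all
2¹⁵ six-node topologies at each uniform weight, and on seeded random
six-node graphs with mixed weights — about 125k graphs in under two minutes.
Full per-edge enumeration at six nodes (3¹⁵ ≈ 14M weighted graphs) adds no
new edge-weight regimes and is omitted as disproportionate.

Figure tests assert on the machine-readable companion tables written next to
every plot, never on rendered pixels.  SVG output is made byte-deterministic
(fixed hash salt, no timestamps) so whole-directory determinism can be
asserted.

## Known limitations

- Similarity is member-overlap only; semantic-similarity measures (Resnik,
  Lin, …) are out of scope by design.
- No annotation-file fallback: enrichment rows must carry their gene
  members.
- The dense MCL is sized for thousands of terms, not for generic large
  graphs.
- agriGO/GOrilla column layouts vary by version; the readers target the
  documented current exports and fail loudly otherwise.
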