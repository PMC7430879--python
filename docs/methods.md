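# Methods

## The network model

The curated immune network is a directed multigraph. Nodes carry one of five
classes (cell, cytokine, antibody, effector molecule, antigen) plus a
functional subtype; edges are keyed by the full (source, target, effect)
triple, so a pair of components may be linked by several edges that differ
in effect — a dendritic cell can activate, polarize and inhibit the same
naive T-cell population, and those are three distinct curated facts. Eight
effects are allowed: activate, recruit, promote survival (positive);
inhibit, kill (negative); secrete (production); differentiate, polarize
(fate). Both vocabularies are closed by default because the quality-control
step depends on rejecting out-of-vocabulary terms; loaders accept a
non-strict mode for exploratory data.

Repeated curated mentions of the same interaction are merged on the triple
key. The merged record keeps the first mention's position, the union of
optional annotations (first non-empty value per field) and the concatenated
references — so provenance is never lost in deduplication, and the
operation is idempotent.

Quality control follows the "no nonsensical edges" principle: R1 every edge
endpoint must exist in the node table; R2 *secrete* requires a cell-type
source and a non-cell target (a cell cannot be secreted); R3 duplicate node
names; R4 isolated nodes (warning); R5 self-interactions (warning —
self-loops are unusual but not provably wrong, e.g. autocrine signaling
collapses to one when node granularity is coarse). Rules are passed as a
mapping and can be disabled or extended.

## Summary statistics and conventions

Let n be the node count and m the number of distinct non-self triples.

- **Density** D = m / (n(n−1)). The numerator counts effect-resolved
  triples; the denominator counts ordered non-self pairs. Self-loop
  triples, if present, are excluded from the numerator since the
  denominator has no slot for them. With the curated scale (n = 253,
  m = 1112) this gives 0.0174, i.e. 0.02 at two decimals.
- **Path metrics** are computed on the simple digraph obtained by
  collapsing parallel effects and dropping self-loops, because parallel
  effects do not create new routes. Distances are hop counts
  (all-pairs BFS via `scipy.sparse.csgraph`). The **diameter** is the
  longest *finite* geodesic, so disconnected digraphs still report a
  number; the **mean path length** L averages over ordered reachable
  non-self pairs, dropping unreachable pairs (the igraph `unconn=TRUE`
  convention, cross-checked against igraph in the test suite). By
  construction L ≤ diameter and both are invariant to effect multiplicity.
- **Degrees** are counted on the multigraph: each effect-resolved edge
  contributes once, so Σ in-degree = Σ out-degree = m.
- **Shortest-path sets**: distance and the number of distinct shortest
  node sequences come from a BFS with a path-count dynamic program (counts
  are exact even when path enumeration is truncated); the paths themselves
  are enumerated by backtracking the shortest-path DAG. The
  source-equals-target convention is distance 0 with the single empty
  path; stimulus analyses exclude self-pairs. Only shortest paths are
  enumerated — all-simple-path enumeration is combinatorial and
  deliberately out of scope.

## Null model

The mean path length is compared against Erdős–Rényi G(n, m) digraphs:
exactly m distinct directed non-self edges drawn uniformly among n labeled
nodes. G(n, m) rather than G(n, p) because the comparison holds the edge
count fixed; a binomial variant (p = m/(n(n−1))) sits behind a flag.
Sampling draws pair codes without replacement and decodes them around the
diagonal, which keeps replicate streams deterministic given the seed across
library versions. Replicates use the same drop-unreachable convention as
the observed statistic. The matched m is the triple count; since parallel
effects collapse in the observed statistic, the ER reference is, if
anything, slightly denser — which shortens null paths and is therefore
conservative for the claim that hubs shorten observed paths. The observed
value's position is summarized by the add-one empirical quantile
(k+1)/(R+1) (k replicates at or below the observed value), which can never
degenerate to 0 or 1; default R = 1000.

## Stimulus-response analysis

The composite activation score for a (cell type, stimulus) pair is the sum
over a panel of activation markers of the difference in mean arcsinh-scale
expression between stimulated and unstimulated conditions; biological
replicates are averaged before differencing. The score is linear: scaling
every marker difference by c scales every score by c.

The predictor is the number of distinct shortest directed paths from the
stimulus node to the cell node, over the full typed network (paths may run
through cytokines, effector molecules, etc.). Cells at distance 1 are
"directly activated" and excluded by default: their responses follow from
the direct interaction, not from network position. Association is measured
by Pearson r with its parametric p, and by a permutation test: scores are
shuffled uniformly across the retained pairs (a stratified-by-stimulus
option exists for pooled multi-stimulus designs), and the empirical p is
add-one smoothed, (1 + #{|r*| ≥ |r|})/(R + 1), two-sided on |r| by default
(the conservative choice; a one-sided greater alternative is a flag).
Default R = 10,000.

## Synthetic data: what it emulates and what it does not

The generators reproduce the statistical structure the analyses assume, at
the curated scale by default:

- **Network**: 253 nodes in the published class mix (109 cytokines,
  51 cells, 59 effector molecules, 30 antigens, 4 antibodies), m = 1112
  distinct triples. Edges are drawn class-by-class: an (source type,
  target type) class from a weight table whose defaults follow the
  observed composition (cytokine-on-cell actions ≈ 40%, cellular cytokine
  secretion ≈ 33%, direct cell:cell contact ≈ 12%, the remainder over
  antibody/effector/antigen classes); endpoints within a class with
  probability ∝ (1 + degree)^γ (preferential attachment, default γ = 1.5,
  chosen to produce the right-skewed degree distributions curated networks
  show — γ = 0 recovers uniform sampling); effects from a
  class-conditional table that emits *secrete* only from cell sources onto
  non-cell targets, so generated tables pass validation by construction.
  A drawn class is retained across duplicate-triple rejections so the
  realized composition tracks the configured weights even where
  preferential attachment concentrates collisions. Node names come from
  realistic immune vocabularies (IL/CCL/CXCL series, canonical cell
  types), padded deterministically for larger configurations.
- **Raw mentions**: the unique edge list is inflated to 2799 rows by
  re-sampling interactions with fresh references, emulating repeated
  textbook mentions; deduplication recovers the unique list exactly.
- **Difference catalog**: 59 records; category counts (26, 14, 12, 7) and
  per-node assignment counts are allocated from their weight vectors by
  largest-remainder quota and then shuffled, so the configured composition
  — category 1 modal, category 4 smallest (the seven components with no
  cross-species equivalent), differences concentrated on B and NK cells —
  holds exactly at any seed; the seed randomizes only pairing and order.
  The catalog includes an unspecified-T-cell aggregate ("T") that matches
  no network node, exercising the overlay's unmatched-name path.
- **Activation data**: on a layered stimulus network (antigen → sentinel
  cells → cytokines → responder cells, so every responder is non-direct at
  distance 3 with a controlled path count), the expected score is
  β · n_shortest, split equally across markers, with Gaussian noise σ per
  marker, replicate and condition (noise at marker level so the scoring
  pipeline is exercised end-to-end; σ = 0 recovers planted scores
  exactly). Defaults β = 1, σ = 1, five markers, four replicates — a
  signal-to-noise ratio in the range of clear cytometry activation
  responses.

What the generators do **not** emulate: the real curated topology (its
exact diameter of 7 and mean path length of 3.25 arise from the specific
wiring of immune biology, which no distribution-level generator
reproduces); single-cell event-level cytometry noise, spillover or gating;
and textual curation errors. Passing tests therefore demonstrate that the
pipeline's logic and statistics behave correctly under the assumed data
structure, not that any particular biological claim holds for new data.
The degree-preserving (configuration-model) null is also out of scope; the
reference model is plain G(n, m).

## Numerical and design choices

- Column headers match case-insensitively through an alias map; unknown
  columns survive per-record as extras; row order is preserved.
- Name canonicalization is exact and case-sensitive after whitespace
  trimming, partitioned by domain (node names vs immune-process, location
  and disease terms) so an alias in one namespace never rewrites another;
  a conflicting double mapping is a configuration error, and unmapped
  names are reported rather than dropped.
- Ties in ranked outputs (cross-tab rows, multi-effect pairs) break
  lexicographically for deterministic output.
- Pathway coverage matches on (source, target) pairs by default — claims
  rarely pin an effect label — with effect-strict matching behind a flag.
  A both-empty network overlap has Jaccard 1 (identical edge sets).
- Degenerate inputs: density requires n ≥ 2; edgeless networks report
  absent path metrics; the correlation requires ≥ 3 pairs and non-zero
  variance in both variables (constant scores surface an error rather
  than a silent NaN).
- Empirical p-values and quantiles always use add-one smoothing; the
  permutation comparison uses a 1e-12 tolerance when comparing |r*| to
  |r| so regenerated observed statistics are counted as at-least-as-
  extreme.
- Study problem sizes (200 calibration datasets at 499 permutations, a
  3-point slope grid over 20 seeds at 24 pairs, 200-replicate null
  comparisons) were chosen to give stable acceptance statistics at
  interactive runtimes on a single CPU.

## Known limitations

- The loaders' header alias map covers the spellings printed in the
  source material; unusual exports may need an extended alias map.
- Path enumeration returns all shortest paths; in dense networks with
  highly degenerate geodesics the list can be large (the count is exact
  regardless, and `max_paths` caps the enumeration).
- The ER comparison matches node and edge counts only; differences in the
  degree sequence are part of the signal, not controlled for.
- Activation scores assume a shared unstimulated baseline per cell type
  and marker; batch effects between conditions are not modeled.
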