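# immunet

Analysis of curated directed immune interaction networks.

The immune system can be written down as a directed graph: nodes are immune
system components — cells, cytokines, antibodies, effector molecules and
antigens — and each edge is a directional interaction annotated with one of
eight effects (*activate*, *recruit*, *promote survival*, *inhibit*, *kill*,
*secrete*, *differentiate*, *polarize*) and a provenance reference. `immunet`
is for immunologists and systems biologists working with such manually
curated interaction tables. It covers the full path from raw curated tables
to network-level inference:

- **`network_io`** — schema-checked loading of edge/node CSV tables,
  merging of repeated mentions into unique (source, target, effect) triples,
  ontology-driven name canonicalization, and curation sense checks
  (e.g. an edge asserting the *secretion of a cell* is flagged as
  nonsensical).
- **`graph_stats`** — the directed multigraph object and its summaries:
  density `D = m / (n(n−1))`, diameter, mean directed geodesic `L`
  (unreachable pairs dropped), degree profiles per node class, edge-type
  cross-tabulations, multi-effect pair queries, GraphML/SIF export.
- **`null_models`** — comparison of `L` against Erdős–Rényi `G(n, m)`
  digraphs with matched node and edge counts: hub-rich immune topologies
  route signals in fewer steps than size alone predicts.
- **`pathway_query`** — coverage of literature pathways against the network
  (present / absent / unreported-crosstalk partition), exact shortest-path
  sets with counts, and two-network overlap with Jaccard similarity.
- **`species_diff`** — the mouse/human difference catalog (categories 1–4)
  and its overlay onto network nodes.
- **`stimulus_response`** — composite activation scores
  `A(cell, stimulus) = Σ_markers (mean stimulated − mean unstimulated)`
  from arcsinh-scale marker summaries, and the Pearson correlation of `A`
  with the number of shortest directed paths from the stimulus node to each
  cell, with a permutation test (scores shuffled across cell–stimulus
  pairs, add-one empirical p).
- **`synthetic_data`** — generators for networks, activation datasets and
  difference catalogs with the statistical structure the analyses assume,
  so every stage is testable without any download.

## Worked example

```
$ python analysis/01_simulate_tables.py --seed 7
wrote 2799 raw mentions -> 1112 unique interactions over 253 nodes; 59 species differences

$ python analysis/02_network_statistics.py
n=253 m=1112 density=0.0174 diameter=6 L=2.45
edge classes: {'cytokine->cell': 457, 'cell->cytokine secretion': 370, 'other': 163, 'cell->cell': 122}

$ python analysis/03_null_model.py
observed L = 2.454 vs ER null 3.870 ± 0.030 over 1000 replicates
observed sits below the null mean (empirical quantile 0.0010)

$ python analysis/06_stimulus_response.py
worked example (LPS, 24 non-direct cells): r = 0.86, parametric p = 7.8e-08, permutation p = 0.0001
null calibration: KS p = 0.857 over 200 datasets (empirical p-values uniform under beta = 0)
```

Reading these numbers: 2799 raw curated mentions collapse to 1112 unique
directed interactions over 253 typed nodes, giving density
1112/(253·252) ≈ 0.017 ≈ 0.02 — only ~2% of possible directed links exist.
The mean geodesic of the hub-rich network (2.35 hops) sits far below the
matched random-graph expectation (3.87), i.e. immune signals disseminate
faster than network size alone predicts (the synthetic wiring reproduces
the curated scale and composition, not the published topology — the
released network's diameter is 7 with L = 3.25). In the stimulus-response
study,
cells that are *not* directly activated by LPS but are reachable through
more distinct shortest paths show proportionally higher activation scores
(r = 0.86 on data with a planted unit slope; the permutation p confirms the
association is not an artifact of the score distribution).

The same steps run from the `immunet` console script
(`immunet simulate network --seed 7 --out tables/`,
`immunet stats --edges tables/edges.csv --nodes tables/nodes.csv`, …).

## Working with the released curated tables

The published interaction and node tables are not bundled here. To analyze
them, download the supplementary tables from the publisher (complete
interaction table, node attributes table, final edge list, difference
catalog), export the spreadsheets as CSV, and place them under `data/` as
`interaction_table.csv` and `node_attributes.csv`. The loaders match column
headers case-insensitively through an alias map (`Source Node` / `source` /
`source_node` all work). When these files are present, the acceptance tests
additionally verify the published summary values (2799 → 1112 interactions,
253 nodes, density 0.02, diameter 7, mean path length 3.25) on them.

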