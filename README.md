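# causalmaps

Network analysis of **signed causal maps** — the directed graphs of labeled
factors that participatory modeling and systems-mapping projects in public
health produce (a prominent example is the CDC/NCIPC map linking adverse
childhood experiences to adolescent suicide: 361 factors, 946 signed causal
links). Each edge `u -> v` asserts that factor `u` causally influences factor
`v`, with polarity `+` (increase causes increase), `-` (increase causes
decrease) or unspecified.

The package is for modelers and analysts who want to interrogate such a map
quantitatively: compare maps structurally, rank factors, decompose a map into
themes, and answer intervention what-if questions.

## What it computes

**Structure.** Density `m / n(n-1)`; the neighborhood clustering coefficient
of a node with neighbor set *N* (|N| = k) as (directed edges among
*N*) / k(k-1), averaged over nodes for the map-level coefficient; average
shortest-path length and diameter by BFS (on the undirected projection of the
largest component by default, since maps with sources and sinks are never
strongly connected — the convention is reported with every result); degree
histograms and the source (in-degree 0) / sink (out-degree 0) / hub
(degree ≥ mean + 2 sd) classes.

**Centrality.** Degree, Katz (x = αWx + β1, default α = 0.9/λ_max, incoming
convention), betweenness (Σ σ_st(v)/σ_st, directed, unnormalized), load
(unit packets per ordered pair split equally among shortest-path successors
at each branch), and reachability-scaled closeness
(|R|/(n-1) · |R|/Σ_{u∈R} d(u,v)). Rankings use competition ranks: tied scores
share a rank (1, 2, 2, 3, …).

**Communities.** Louvain and Leiden on the undirected projection (reciprocal
edge pairs collapse to weight 2), Newman modularity with resolution γ,
adjusted-Rand / best-Jaccard partition comparison, and *derivative maps*:
the map reduced to one super-node per community with directed inter-community
edges weighted by original edge counts (edge-conserving).

**Interventions.** All simple feedback loops with sign-parity classification
(even number of `-` edges → reinforcing, odd → balancing, any unsigned edge →
undetermined); all simple paths or a maximum set of internally-vertex-disjoint
paths between an intervention and an outcome factor (the count equals the
pair's vertex connectivity, by Menger's theorem); ripple shells — BFS layers
downstream of an intervention node.

**Coding.** Per-node annotations on two axes (four Social-Ecological Model
levels × seven CDC prevention strategies), inter-coder agreement as per-node
Jaccard similarity (shared categories over all categories used), aggregated
as the unweighted node mean in percent, plus conflict reports and the
strategy-by-level percentage heatmap matrix.

A seeded synthetic-map generator (planted-partition blocks × Zipf hub
propensities, signed edges) reproduces the statistical signatures these
analyses assume — sparse, hub-skewed, community-structured, with sources and
sinks — so the whole pipeline is testable without external data.

## Worked example

```python
import causalmaps as cm

cfg = cm.SyntheticMapConfig(n=200, target_density=0.02, n_communities=4, seed=42)
cmap, truth = cm.generate_map(cfg)

print(cm.summarize(cmap).as_row())
part = cm.leiden_partition(cmap, seed=42)
print(part.n_communities, round(part.modularity, 3))
loops, complete = cm.enumerate_loops(cmap, max_length=6)
print(len(loops), sum(l.classification == "reinforcing" for l in loops))
```

prints

```
{'name': 'synthetic(n=200, seed=42)', 'nodes': 200, 'edges': 746,
 'avg_clustering': 0.132, 'avg_path_length': 2.772, 'density': 0.019,
 'diameter': 6, 'n_sources': 16, 'n_sinks': 21, 'n_hubs': 12}
7 0.491
1061 535
```

— a 200-factor map at the requested 2% density with 16 parameter-like
sources and 21 outcome-like sinks; Leiden finds 7 communities at modularity
0.491 (the generator planted 4; extra splits at this sparsity are expected);
of the 1061 simple feedback loops up to length 6, 535 are reinforcing
(amplifying) and the rest balancing (dampening).

The same analyses are available from the shell:

```sh
causalmap simulate --n 200 --density 0.02 --seed 42 --out map.csv
causalmap summary map.csv
causalmap communities map.csv --seed 42 --out-dir out/
causalmap loops map.csv --max-length 6 --out loops.json
causalmap run study.yml        # whole pipeline from a YAML config + manifest
```

Maps are read and written as edge-list CSV (`source,target,polarity`) or
GraphML (polarity as an edge attribute), with DOT export for rendering.
All CSV outputs use fixed column orders (`node,community`;
`from,to,weight`; the summary row order shown above) so runs diff cleanly.

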