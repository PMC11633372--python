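# Methods

This note documents the models, conventions and parameter choices behind
`causalmaps`, and what the synthetic tests do and do not establish about
real maps.

## The data model

A causal map is a *simple* directed graph: unique labeled nodes, at most one
edge per ordered pair, each edge carrying a polarity in {+, −, unspecified}.
Self-loops are rejected by default because causal-map semantics describe
influences between distinct factors; a flag admits them for maps that use
self-influence as a modeling device. Duplicate rows in an input file are
collapsed when their polarities agree (with a warning) and rejected when they
conflict — silently picking one would corrupt every signed analysis
downstream. Edge weights and edge types are deliberately out of scope: maps
are compared by their directed, signed topology only.

## Structural statistics

* **Density** is directed: m / n(n−1).
* **Clustering** follows the neighborhood convention: for a node with
  neighbor set N (union of in- and out-neighbors, k = |N|), the coefficient
  is (directed edges among N) / k(k−1), and 0 when k < 2 (a convention —
  the quantity is genuinely undefined there, and 0 is the conservative
  choice for averaging). The map-level coefficient is the unweighted node
  mean. Note this differs from transitivity-style directed clustering
  (e.g. Fagiolo's), which corrects for reciprocal pairs; the neighborhood
  version is the one used in the systems-mapping literature this package
  serves.
* **Average path length and diameter** need a convention on maps that are
  not strongly connected (any map with a source or sink). Default: BFS on
  the undirected projection restricted to the largest connected component,
  which is the only convention under which a single APL/diameter is
  well-defined for typical maps; `mode="directed"` instead averages over
  reachable ordered pairs in the largest weakly connected component. Every
  result carries the mode and the fraction of nodes covered, so the
  convention is never implicit.
* **Hubs** default to degree ≥ mean + 2·sd (computed separately for in- and
  out-degree, either qualifying); there is no field-standard numeric rule,
  so the threshold is a parameter.

## Centralities

Five measures, chosen for their complementary readings on causal maps:

| measure | reading on a causal map | convention |
|---|---|---|
| degree | direct influence/exposure | total (in+out) by default |
| Katz | attenuated influence over all walks | incoming; α = 0.9/λ_max, β = 1 |
| betweenness | shortest-path brokerage | directed, unnormalized |
| load | packet-splitting brokerage | successor splitting (below) |
| closeness | accessibility | incoming distances, reachability-scaled |

Katz's α must satisfy α < 1/λ_max for the walk series to converge; the
default 0.9/λ_max is computed per map from the adjacency spectral radius and
reported in the output metadata (an explicit inadmissible α raises, with the
bound). Incoming conventions for Katz and closeness make outcome-like
factors rank highly, which matches how these maps are read (what does the
system drive?); both flip to outgoing via configuration. Scores are
reported unit-norm (Katz) or in natural units (others); ranks use
competition ranking with an absolute tie tolerance of 1e−9 for
floating-point measures and exact equality for integer degree.

**Load** is implemented in-package: a unit packet per ordered pair travels
the shortest-path DAG toward the target, dividing equally among the
successors one step closer to the target at every branch; a node's load is
the transiting mass. Because the division rule at a node depends only on
the node and the target, all sources for a fixed target aggregate into one
backward BFS sweep, giving O(n(n+m)) overall. The widely available library
routine of the same name splits among *predecessors* from the source side,
which disagrees with the successor-splitting definition whenever shortest
paths re-merge asymmetrically; the test suite pins the successor variant
against an explicit per-pair packet simulation.

## Communities and derivative maps

Detection and modularity operate on the undirected projection with integer
weights (a reciprocal pair becomes one edge of weight 2): community
structure in causal maps is about association density, not direction, and
this matches the standard tooling's behavior. Modularity is Newman's Q with
resolution γ (default 1). Louvain is the seeded two-phase greedy; Leiden
adds the refinement phase whose practical value is the guarantee that every
returned community induces a connected subgraph — asserted in tests over
seeds and random maps, since Louvain can and does violate it. Seeds are
mandatory: both algorithms are move-order dependent, and partitions are
relabeled canonically (by size, then lexicographically smallest member) so
identical runs are byte-identical.

The derivative map reduces a partitioned map to super-nodes with directed
inter-community edge counts as weights, retaining intra-community counts as
self-weights so that Σ inter + Σ intra = m exactly — the conservation law
the tests enforce. Community *names* are human judgments and are only ever
user-supplied annotations.

Partition comparison reports the adjusted Rand index plus a best-match table
(maximum Jaccard pairing), which is the machine-checkable counterpart of
"these two algorithms found mostly the same themes".

## Intervention analytics

* **Feedback loops**: all simple directed cycles, via bounded Johnson-style
  enumeration, classified by sign parity — an even count of negative edges
  reinforces a perturbation, an odd count balances it; any unspecified
  polarity yields "undetermined" rather than an assumed `+`. The parity rule
  is rotation-invariant, which the property tests check. Cycle counts are
  worst-case exponential, so both a length cap (default 10) and a count cap
  (default 10 000) apply; hitting the count cap flags the result incomplete
  instead of raising.
* **Disjoint paths**: "independent causal routes" is read as internally
  vertex-disjoint (endpoints shared) — the stronger reading, and the one
  that counts distinct mechanisms an intervention can act through. Computed
  by unit-capacity max flow with node splitting, so the cardinality equals
  the pair's internal vertex connectivity (Menger); the returned path list
  is sorted for stable output. Maximum sets are not unique; only the
  cardinality is canonical.
* **Ripple shells**: BFS layers over out-edges from the intervention node up
  to a user horizon, plus the edges connecting consecutive (or equal) shells
  for concentric rendering. Shells partition the reachable set — a tested
  invariant.

## Coding and agreement

Vocabularies are closed (four SEM levels, seven prevention strategies);
assignments outside them are rejected at entry. Agreement between two
coders on a node is |A ∩ B| / |A ∪ B| — the union denominator is the only
reading consistent with "shared one of three categories used in total =
1/3". The aggregate is the unweighted mean over nodes coded by at least one
of the two coders, in percent; nodes coded by neither are excluded (not
counted as trivial agreement) and listed. Whether to pool ratios instead of
averaging nodes is genuinely open; the node mean was chosen because it
weights every factor equally regardless of how many categories it attracted.
Heatmap cells are percentages of nodes carrying a (strategy, level) pair;
multi-membership means totals can exceed 100% and are deliberately not
normalized. The default heatmap denominator is the coder's coded-node count,
with the map's full node count available as an explicit argument.

## Synthetic generator

The generator targets the *summary statistics* of expert-elicited
public-health maps rather than any specific random-graph family: a
planted-partition block model (k near-equal communities, within/between
mixing ratio p_intra : p_inter, rescaled to hit a target density) modulated
by Zipf node propensities (rank^(−hub_exponent), normalized to mean 1,
independently permuted for in- and out-roles) over independent directed
edge draws; each edge is positive with probability p_positive, else
negative.

Defaults are the conditions of a large expert-elicited map: n = 361 and
target density 0.007 (the published NCIPC figures), k = 8 communities
(within the ~10-community range such maps decompose into), hub_exponent
0.8 (marked but not extreme degree skew, matching the "few hubs, many
low-degree nodes" signature), p_positive 0.7 (causal maps are predominantly
reinforcing links). Seeds are mandatory config fields; there is no hidden
global RNG. At these sparse defaults some nodes naturally end with
in-degree 0 or out-degree 0, giving the source/sink structure the degree
classifier expects.

What passing synthetic tests shows: the algorithms are correct on graphs
with realistic size, sparsity, skew and planted structure. What it does not
show: anything about the semantic content of real maps — label quality,
coder behavior, or whether a real map's communities are meaningful. The
generator's labels are generic by design.

Problem sizes in the test and acceptance suites — 100 oracle maps at
n ≤ 25, 20 planted-recovery runs at n = 200, 50 Menger trials at n ≤ 20 —
were chosen so every brute-force oracle (exhaustive path/cycle enumeration,
O(n²) modularity sums, per-pair packet simulation) remains exact and fast;
they match the regimes where exhaustive verification is feasible at all.

## Numerical choices and degenerate inputs

Katz converges iteratively to tolerance 1e−12 (tests require agreement with
a dense linear solve to 1e−8). Metrics that are undefined on an input —
density below two nodes, path statistics with no connected pair, agreement
with no jointly coded node — raise typed errors rather than returning
sentinel values; the comparison report catches these per cell so one
degenerate map cannot sink a multi-map study. Community detection on an
edgeless map is rejected (every partition is vacuously optimal).

## Known limitations

* No quantitative effect propagation: polarities compose by parity only;
  the package does not simulate magnitudes or dynamics.
* Loop/path enumeration caps mean very dense maps get flagged-incomplete
  results rather than exhaustive ones.
* APL/diameter on partially connected maps are convention-dependent;
  results are comparable only under the same mode.
* The Leiden connectivity guarantee applies to the undirected projection,
  not to strong connectivity in the directed sense.
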