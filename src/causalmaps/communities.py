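"""Community detection, modularity and community-level derivative maps.

Detection runs on the undirected projection with unit edge weights
(reciprocal directed pairs collapse to weight 2), which is also how
modularity is scored.  Louvain gives the classic two-phase greedy
optimum; Leiden adds a refinement phase that guarantees every returned
community induces a connected subgraph.  Derivative maps reduce a map
to its communities: super-nodes sized by membership, directed
inter-community edges weighted by the number of original edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import networkx as nx
from sklearn.metrics import adjusted_rand_score

from .model import CausalMap
from .coding import CodingTable

__all__ = [
    "Partition",
    "DerivativeMap",
    "modularity",
    "louvain_partition",
    "leiden_partition",
    "derivative_map",
    "partition_agreement",
    "community_category_profile",
]


@dataclass
class Partition:
    """A node->community assignment with its modularity score."""

    assignment: dict[str, int]
    modularity: float
    algorithm: str
    seed: int
    resolution: float = 1.0

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def communities(self) -> list[list[str]]:
        groups: dict[int, list[str]] = {}
        for node, cid in self.assignment.items():
            groups.setdefault(cid, []).append(node)
        return [sorted(groups[cid]) for cid in sorted(groups)]


def modularity(cmap: CausalMap, assignment: dict[str, int], resolution: float = 1.0) -> float:
    """Newman modularity Q of an assignment, on the undirected projection.

    Q = (1/2m') sum_ij [A_ij - gamma k_i k_j / 2m'] delta(c_i, c_j),
    with A the weighted projected adjacency and m' its total weight.
    """
    missing = set(cmap.nodes) - set(assignment)
    if missing:
        raise ValueError(f"assignment missing {len(missing)} nodes, e.g. {sorted(missing)[:3]}")
    und = cmap.undirected_projection()
    groups: dict[int, set[str]] = {}
    for node, cid in assignment.items():
        groups.setdefault(cid, set()).add(node)
    return nx.community.modularity(und, groups.values(), weight="weight", resolution=resolution)


def _canonical_partition(cmap: CausalMap, communities: list[set[str]]) -> dict[str, int]:
    """Relabel communities 0..k-1 deterministically (by size desc, then members)."""
    ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
    assignment: dict[str, int] = {}
    for cid, members in enumerate(ordered):
        for node in members:
            assignment[node] = cid
    for node in cmap.nodes:  # isolates some backends drop
        assignment.setdefault(node, len(ordered))
    return assignment


def louvain_partition(cmap: CausalMap, seed: int = 0, resolution: float = 1.0) -> Partition:
    """Louvain detection: greedy local moves + aggregation until no
    modularity gain remains.  Seeded, since move order matters."""
    if cmap.m == 0:
        raise ValueError("community detection needs at least one edge")
    und = cmap.undirected_projection()
    communities = nx.community.louvain_communities(
        und, weight="weight", resolution=resolution, seed=seed
    )
    assignment = _canonical_partition(cmap, [set(c) for c in communities])
    return Partition(assignment, modularity(cmap, assignment, resolution), "louvain", seed, resolution)


def leiden_partition(cmap: CausalMap, seed: int = 0, resolution: float = 1.0) -> Partition:
    """Leiden detection (local moves, refinement, aggregation).

    The refinement phase guarantees each community induces a connected
    subgraph of the undirected projection - the property that motivates
    preferring Leiden over Louvain on large maps.
    """
    if cmap.m == 0:
        raise ValueError("community detection needs at least one edge")
    und = cmap.undirected_projection()
    nodes = list(und.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in und.edges]
    weights = [und.edges[u, v]["weight"] for u, v in und.edges]
    g = ig.Graph(n=len(nodes), edges=edges, directed=False)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=resolution,
        seed=seed,
    )
    communities = [{nodes[i] for i in comm} for comm in part]
    assignment = _canonical_partition(cmap, communities)
    return Partition(assignment, modularity(cmap, assignment, resolution), "leiden", seed, resolution)


@dataclass
class DerivativeMap:
    """The community-level reduction of a causal map."""

    communities: dict[int, dict]  # id -> {"size": int, "members": [node], "label": str|None}
    inter_edges: dict[tuple[int, int], int]  # (a, b) -> directed edge count, a != b
    intra_edges: dict[int, int] = field(default_factory=dict)  # self-weights

    def total_edges(self) -> int:
        return sum(self.inter_edges.values()) + sum(self.intra_edges.values())

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for cid, info in self.communities.items():
            attrs = {"size": info["size"]}
            if info.get("label") is not None:
                attrs["label"] = info["label"]
            g.add_node(cid, **attrs)
        for (a, b), w in self.inter_edges.items():
            g.add_edge(a, b, weight=w)
        return g


def derivative_map(
    cmap: CausalMap, partition: Partition, labels: dict[int, str] | None = None
) -> DerivativeMap:
    """Reduce a map to one super-node per community.

    The weight of the directed super-edge a->b counts the original
    edges from members of a to members of b; within-community edges are
    kept as self-weights so the reduction conserves the edge count
    exactly.  Community labels are user-supplied annotations (naming
    themes is a human judgment, never inferred here).
    """
    assignment = partition.assignment
    missing = set(cmap.nodes) - set(assignment)
    if missing:
        raise ValueError(f"partition missing {len(missing)} nodes")
    members: dict[int, list[str]] = {}
    for node in cmap.nodes:
        members.setdefault(assignment[node], []).append(node)
    communities = {
        cid: {"size": len(ms), "members": sorted(ms), "label": (labels or {}).get(cid)}
        for cid, ms in members.items()
    }
    inter: dict[tuple[int, int], int] = {}
    intra: dict[int, int] = {cid: 0 for cid in members}
    for u, v, _ in cmap.edges():
        a, b = assignment[u], assignment[v]
        if a == b:
            intra[a] += 1
        else:
            inter[a, b] = inter.get((a, b), 0) + 1
    return DerivativeMap(communities, inter, intra)


def partition_agreement(p1: Partition, p2: Partition) -> dict:
    """Compare two partitions of the same node set.

    Returns the adjusted Rand index plus a best-match table pairing
    each community of ``p1`` with its maximum-Jaccard community of
    ``p2``, which supports side-by-side "which themes match" reporting.
    """
    if set(p1.assignment) != set(p2.assignment):
        raise ValueError("partitions cover different node sets")
    nodes = sorted(p1.assignment)
    ari = float(adjusted_rand_score(
        [p1.assignment[v] for v in nodes], [p2.assignment[v] for v in nodes]
    ))
    groups1: dict[int, set[str]] = {}
    groups2: dict[int, set[str]] = {}
    for v in nodes:
        groups1.setdefault(p1.assignment[v], set()).add(v)
        groups2.setdefault(p2.assignment[v], set()).add(v)
    matches = []
    for cid1, mem1 in sorted(groups1.items()):
        best_cid, best_j = None, -1.0
        for cid2, mem2 in sorted(groups2.items()):
            j = len(mem1 & mem2) / len(mem1 | mem2)
            if j > best_j:
                best_cid, best_j = cid2, j
        matches.append({"community_1": cid1, "community_2": best_cid,
                        "jaccard": best_j, "size_1": len(mem1),
                        "size_2": len(groups2[best_cid])})
    return {"ari": ari, "best_matches": matches,
            "n_communities": (len(groups1), len(groups2))}


def community_category_profile(
    partition: Partition, coding: CodingTable, coder: str
) -> dict[int, dict]:
    """Tally one coder's category assignments within each community.

    For every community: the counts of social-ecological levels and of
    prevention strategies over member nodes (multi-membership counted
    per category), the dominant categories, and any uncoded members.
    """
    profiles: dict[int, dict] = {}
    members: dict[int, list[str]] = {}
    for node, cid in partition.assignment.items():
        members.setdefault(cid, []).append(node)
    for cid, ms in sorted(members.items()):
        levels: dict[str, int] = {}
        strategies: dict[str, int] = {}
        uncoded = []
        for node in sorted(ms):
            lv = coding.categories(coder, node, "sem_level")
            st = coding.categories(coder, node, "strategy")
            if not lv and not st:
                uncoded.append(node)
            for c in lv:
                levels[c] = levels.get(c, 0) + 1
            for c in st:
                strategies[c] = strategies.get(c, 0) + 1
        profiles[cid] = {
            "size": len(ms),
            "sem_levels": dict(sorted(levels.items(), key=lambda kv: (-kv[1], kv[0]))),
            "strategies": dict(sorted(strategies.items(), key=lambda kv: (-kv[1], kv[0]))),
            "dominant_level": max(levels, key=levels.get) if levels else None,
            "dominant_strategy": max(strategies, key=strategies.get) if strategies else None,
            "uncoded": uncoded,
        }
    return profiles
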