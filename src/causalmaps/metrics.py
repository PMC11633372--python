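"""Whole-network and local structure statistics for causal maps.

Covers the descriptive layer used to compare systems maps: density,
the neighborhood clustering coefficient, average shortest-path length
and diameter, degree distributions, and the source/sink/hub degree
classes that matter for intervention planning (sources are model
parameters, sinks are outcomes, hubs are high-leverage factors).
"""

from __future__ import annotations

import statistics
from collections import Counter
from dataclasses import dataclass, asdict

import networkx as nx

from .model import CausalMap

__all__ = [
    "NetworkSummary",
    "density",
    "local_clustering",
    "average_clustering",
    "path_length_stats",
    "degree_classes",
    "degree_distributions",
    "summarize",
]


class UndefinedMetricError(ValueError):
    """A metric is undefined on this input (too small or disconnected)."""


def density(cmap: CausalMap) -> float:
    """Directed density m / (n(n-1)): realized over possible ordered pairs."""
    n = cmap.n
    if n < 2:
        raise UndefinedMetricError(f"density undefined for n={n} < 2")
    return cmap.m / (n * (n - 1))


def local_clustering(cmap: CausalMap, node: str) -> float:
    """Neighborhood clustering of one node on the directed graph.

    With N the union of in- and out-neighbors (the node excluded) and
    k = |N|, returns (directed edges among N) / (k(k-1)); 0 when k < 2.
    E.g. four neighbors with three edges among them give 3/12 = 0.25.
    """
    g = cmap.graph
    if node not in g:
        raise KeyError(f"unknown node: {node!r}")
    neighbors = (set(g.predecessors(node)) | set(g.successors(node))) - {node}
    k = len(neighbors)
    if k < 2:
        return 0.0
    among = sum(1 for u in neighbors for v in neighbors if u != v and g.has_edge(u, v))
    return among / (k * (k - 1))


def average_clustering(cmap: CausalMap) -> float:
    """Unweighted mean of :func:`local_clustering` over all nodes."""
    if cmap.n == 0:
        raise UndefinedMetricError("average clustering undefined on an empty map")
    return statistics.fmean(local_clustering(cmap, v) for v in cmap.nodes)


def path_length_stats(cmap: CausalMap, mode: str = "undirected") -> dict:
    """Average shortest-path length and diameter by breadth-first search.

    A causal map with sources and sinks is never strongly connected, so
    a single APL/diameter only exists under a convention.  The default
    projects edges to undirected and measures all pairs in the largest
    connected component; ``mode="directed"`` instead averages over the
    reachable ordered pairs within the largest weakly connected
    component.  The returned dict records the convention and the
    fraction of nodes covered by the component used.
    """
    if mode not in {"directed", "undirected"}:
        raise ValueError(f"mode must be 'directed' or 'undirected', got {mode!r}")
    g = cmap.graph
    if mode == "undirected":
        und = g.to_undirected(as_view=False)
        components = list(nx.connected_components(und))
        if not components or max(len(c) for c in components) < 2:
            raise UndefinedMetricError("no connected pair of nodes")
        comp = max(components, key=len)
        sub = und.subgraph(comp)
        apl = nx.average_shortest_path_length(sub)
        diam = nx.diameter(sub)
        coverage = len(comp) / cmap.n
    else:
        components = list(nx.weakly_connected_components(g))
        comp = max(components, key=len, default=set())
        sub = g.subgraph(comp)
        total = count = diam = 0
        for source, dists in nx.all_pairs_shortest_path_length(sub):
            for target, d in dists.items():
                if target != source:
                    total += d
                    count += 1
                    diam = max(diam, d)
        if count == 0:
            raise UndefinedMetricError("no connected ordered pair of nodes")
        apl = total / count
        coverage = len(comp) / cmap.n
    return {
        "avg_path_length": apl,
        "diameter": diam,
        "mode": mode,
        "component_coverage": coverage,
    }


def degree_classes(
    cmap: CausalMap, hub_rule: str | int = "mean+2sd"
) -> tuple[list[str], list[str], list[str]]:
    """Sources (in-degree 0), sinks (out-degree 0) and hubs.

    ``hub_rule`` is either an integer threshold or the default
    ``"mean+2sd"``: a node is a hub when its in- OR out-degree is at
    least the mean plus two standard deviations of that degree type.
    """
    g = cmap.graph
    sources = sorted(v for v in g if g.in_degree(v) == 0)
    sinks = sorted(v for v in g if g.out_degree(v) == 0)
    in_deg = {v: g.in_degree(v) for v in g}
    out_deg = {v: g.out_degree(v) for v in g}
    if isinstance(hub_rule, (int, float)):
        thr_in = thr_out = float(hub_rule)
    elif hub_rule == "mean+2sd":
        thr_in = _mean_plus_2sd(list(in_deg.values()))
        thr_out = _mean_plus_2sd(list(out_deg.values()))
    else:
        raise ValueError(f"unknown hub rule: {hub_rule!r}")
    hubs = sorted(v for v in g if in_deg[v] >= thr_in or out_deg[v] >= thr_out)
    return sources, sinks, hubs


def _mean_plus_2sd(values: list[int]) -> float:
    if len(values) < 2:
        return float("inf")
    mean = statistics.fmean(values)
    sd = statistics.pstdev(values)
    return mean + 2 * sd if sd > 0 else float("inf")


def degree_distributions(cmap: CausalMap) -> tuple[dict[int, int], dict[int, int]]:
    """Exact in- and out-degree histograms (degree -> node count)."""
    g = cmap.graph
    in_hist = Counter(d for _, d in g.in_degree())
    out_hist = Counter(d for _, d in g.out_degree())
    return dict(sorted(in_hist.items())), dict(sorted(out_hist.items()))


@dataclass
class NetworkSummary:
    """The comparison-table statistic bundle for one map."""

    name: str
    n: int
    m: int
    density: float
    avg_clustering: float
    avg_path_length: float | None
    diameter: int | None
    path_mode: str
    component_coverage: float | None
    in_degree_hist: dict[int, int]
    out_degree_hist: dict[int, int]
    sources: list[str]
    sinks: list[str]
    hubs: list[str]

    def as_dict(self) -> dict:
        return asdict(self)

    def as_row(self) -> dict:
        """One comparison-table row, figures rounded to 3 decimals."""
        return {
            "name": self.name,
            "nodes": self.n,
            "edges": self.m,
            "avg_clustering": round(self.avg_clustering, 3),
            "avg_path_length": None if self.avg_path_length is None else round(self.avg_path_length, 3),
            "density": round(self.density, 3),
            "diameter": self.diameter,
            "n_sources": len(self.sources),
            "n_sinks": len(self.sinks),
            "n_hubs": len(self.hubs),
        }


def summarize(
    cmap: CausalMap, path_mode: str = "undirected", hub_rule: str | int = "mean+2sd"
) -> NetworkSummary:
    """Compute the full :class:`NetworkSummary` for one map."""
    try:
        paths = path_length_stats(cmap, mode=path_mode)
        apl, diam, coverage = paths["avg_path_length"], paths["diameter"], paths["component_coverage"]
    except UndefinedMetricError:
        apl = diam = coverage = None
    in_hist, out_hist = degree_distributions(cmap)
    sources, sinks, hubs = degree_classes(cmap, hub_rule)
    return NetworkSummary(
        name=cmap.name,
        n=cmap.n,
        m=cmap.m,
        density=density(cmap),
        avg_clustering=average_clustering(cmap),
        avg_path_length=apl,
        diameter=diam,
        path_mode=path_mode,
        component_coverage=coverage,
        in_degree_hist=in_hist,
        out_degree_hist=out_hist,
        sources=sources,
        sinks=sinks,
        hubs=hubs,
    )
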