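"""The five node-centrality measures used to rank factors in causal maps.

Degree (direct influence), Katz (attenuated influence over all walks),
betweenness (shortest-path brokerage), load (packet-splitting
brokerage) and closeness (accessibility).  Rankings use competition
ranks: nodes with equal scores - to a tolerance for floating-point
measures - share a rank, and the next distinct score takes the next
rank (1, 2, 2, 3, ...).

Directionality conventions matter on causal maps.  Katz and closeness
default to the *incoming* convention (a node is central when many
others reach it), which places outcome-like factors at the top; both
can be flipped to the outgoing convention.  Degree uses total
(in + out) degree by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .model import CausalMap

__all__ = [
    "CentralityConfig",
    "degree_centrality",
    "katz_centrality",
    "betweenness_centrality",
    "load_centrality",
    "closeness_centrality",
    "rank_nodes",
    "centrality_table",
]

MEASURES = ("degree", "katz", "betweenness", "load", "closeness")


@dataclass
class CentralityConfig:
    """Knobs for the centrality layer.

    ``katz_alpha=None`` means "0.9 / lambda_max", computed per map from
    the adjacency spectral radius so the Katz series always converges;
    the value actually used is reported back via :func:`katz_centrality`.
    """

    katz_alpha: float | None = None
    katz_beta: float = 1.0
    direction: str = "in"  # walk/distance convention for katz & closeness
    degree_direction: str = "total"  # "in" | "out" | "total"
    normalize_degree: bool = False
    tie_tolerance: float = 1e-9
    metadata: dict = field(default_factory=dict)


def degree_centrality(cmap: CausalMap, direction: str = "total", normalized: bool = False) -> dict[str, float]:
    """In-, out- or total-degree score per node."""
    if cmap.n < 2:
        raise ValueError("degree centrality undefined for n < 2")
    g = cmap.graph
    if direction == "in":
        deg = dict(g.in_degree())
    elif direction == "out":
        deg = dict(g.out_degree())
    elif direction == "total":
        deg = {v: g.in_degree(v) + g.out_degree(v) for v in g}
    else:
        raise ValueError(f"direction must be in/out/total, got {direction!r}")
    if normalized:
        return {v: d / (cmap.n - 1) for v, d in deg.items()}
    return {v: float(d) for v, d in deg.items()}


def spectral_radius(cmap: CausalMap) -> float:
    """Largest adjacency-eigenvalue modulus (0 for edgeless/acyclic-free cases)."""
    if cmap.m == 0:
        return 0.0
    a = nx.to_numpy_array(cmap.graph, nodelist=cmap.nodes)
    return float(np.max(np.abs(np.linalg.eigvals(a))))


def katz_centrality(
    cmap: CausalMap, config: CentralityConfig | None = None
) -> tuple[dict[str, float], dict]:
    """Katz scores x = alpha*W x + beta*1, reported unit-norm.

    ``W`` aggregates incoming walks by default (``config.direction``
    flips it).  Solved iteratively to machine-level tolerance; raises
    when alpha is at or beyond the 1/lambda_max divergence bound.
    Returns (scores, metadata) with the alpha/beta/convention used.
    """
    cfg = config or CentralityConfig()
    lam = spectral_radius(cmap)
    if cfg.katz_alpha is None:
        alpha = 0.9 / lam if lam > 0 else 0.1
    else:
        alpha = cfg.katz_alpha
        if lam > 0 and alpha >= 1.0 / lam:
            raise ValueError(
                f"katz alpha={alpha} is not admissible: needs alpha < 1/lambda_max = {1.0 / lam:.6g}"
            )
    g = cmap.graph if cfg.direction == "in" else cmap.graph.reverse(copy=False)
    scores = nx.katz_centrality(
        g, alpha=alpha, beta=cfg.katz_beta, max_iter=10000, tol=1e-12, normalized=True
    )
    meta = {"alpha": alpha, "beta": cfg.katz_beta, "direction": cfg.direction, "lambda_max": lam}
    return dict(scores), meta


def betweenness_centrality(cmap: CausalMap, normalized: bool = False) -> dict[str, float]:
    """Directed shortest-path betweenness, unnormalized by default.

    Score of v = sum over ordered pairs (s, t) of the fraction of
    shortest s->t paths passing through v (Brandes accumulation).
    """
    return dict(nx.betweenness_centrality(cmap.graph, normalized=normalized))


def load_centrality(cmap: CausalMap, normalized: bool = False) -> dict[str, float]:
    """Packet-splitting load: unit flow per ordered pair, split equally
    among shortest-path successors at each branch; endpoints excluded.

    A packet from s to t travels the shortest-path DAG toward t and at
    every node divides evenly among the successors one step closer to
    t; a node's load is the total mass that transits it.  The division
    rule depends only on the current node and the target, so all
    sources for one target are aggregated in a single backward BFS
    sweep (O(n(n+m)) overall).  This successor-splitting variant
    differs from betweenness whenever shortest paths re-merge
    asymmetrically.
    """
    g = cmap.graph
    score = {v: 0.0 for v in g}
    for t in g:
        # distance of every node TO t (BFS over reversed edges)
        dist = {t: 0}
        frontier = [t]
        while frontier:
            nxt = []
            for v in frontier:
                for u in g.predecessors(v):
                    if u not in dist:
                        dist[u] = dist[v] + 1
                        nxt.append(u)
            frontier = nxt
        transiting = {v: 0.0 for v in dist}
        for v in sorted(dist, key=dist.get, reverse=True):
            if v == t:
                continue
            mass = 1.0 + transiting[v]  # own packet plus pass-through
            succ = [w for w in g.successors(v) if dist.get(w) == dist[v] - 1]
            share = mass / len(succ)
            for w in succ:
                transiting[w] += share
        for v, m in transiting.items():
            if v != t:
                score[v] += m
    if normalized:
        n = g.number_of_nodes()
        scale = 1.0 / ((n - 1) * (n - 2)) if n > 2 else 1.0
        return {v: s * scale for v, s in score.items()}
    return score


def closeness_centrality(cmap: CausalMap, direction: str = "in") -> dict[str, float]:
    """Reachability-scaled closeness (Wasserman-Faust).

    For node v with R = nodes that can reach v (incoming convention):
    (|R|/(n-1)) * (|R| / sum of distances from R to v); 0 when R is
    empty.  ``direction="out"`` scores how easily v reaches others.
    """
    g = cmap.graph if direction == "in" else cmap.graph.reverse(copy=False)
    return dict(nx.closeness_centrality(g, wf_improved=True))


def rank_nodes(
    scores: dict[str, float], tolerance: float = 1e-9, k: int | None = None
) -> tuple[dict[str, int], list[tuple[int, float, list[str]]]]:
    """Competition ranks (ties share a rank: 1, 2, 2, 3, ...).

    Scores within ``tolerance`` of a tie group's leading score join the
    group.  Returns (node -> rank, top table) where the top table lists
    the first ``k`` ranks (all, if ``k`` is None) as
    (rank, group score, members sorted by node id).
    """
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    ranks: dict[str, int] = {}
    table: list[tuple[int, float, list[str]]] = []
    rank = 0
    group_score = None
    for node, score in ordered:
        if group_score is None or group_score - score > tolerance:
            rank += 1
            group_score = score
            table.append((rank, score, []))
        ranks[node] = rank
        table[-1][2].append(node)
    if k is not None:
        table = [row for row in table if row[0] <= k]
    return ranks, table


def centrality_table(
    cmap: CausalMap, config: CentralityConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """All five measures plus their competition ranks, one row per node.

    Returns (table, metadata); the metadata records the Katz alpha and
    the direction conventions so a run is reproducible from its output.
    """
    cfg = config or CentralityConfig()
    katz, katz_meta = katz_centrality(cmap, cfg)
    columns = {
        "degree": degree_centrality(cmap, cfg.degree_direction, cfg.normalize_degree),
        "katz": katz,
        "betweenness": betweenness_centrality(cmap),
        "load": load_centrality(cmap),
        "closeness": closeness_centrality(cmap, cfg.direction),
    }
    frame = pd.DataFrame({m: pd.Series(s) for m, s in columns.items()}).loc[cmap.nodes]
    for measure in MEASURES:
        tol = 0.0 if measure == "degree" else cfg.tie_tolerance
        ranks, _ = rank_nodes(dict(frame[measure]), tolerance=tol)
        frame[f"{measure}_rank"] = pd.Series(ranks)
    frame.index.name = "node"
    meta = {"katz": katz_meta, "degree_direction": cfg.degree_direction,
            "closeness_direction": cfg.direction, "tie_tolerance": cfg.tie_tolerance}
    return frame, meta
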