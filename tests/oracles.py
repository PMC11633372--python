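"""Independent brute-force oracles used to check the library.

Everything here works from a plain adjacency-dict representation and
never calls into causalmaps' computational paths (only the CausalMap
edge accessors), so agreement between the two is meaningful.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np


def adjacency(cmap) -> dict[str, list[str]]:
    adj: dict[str, list[str]] = {v: [] for v in cmap.nodes}
    for u, v, _ in cmap.edges():
        adj[u].append(v)
    for v in adj:
        adj[v].sort()
    return adj


def reverse_adjacency(cmap) -> dict[str, list[str]]:
    radj: dict[str, list[str]] = {v: [] for v in cmap.nodes}
    for u, v, _ in cmap.edges():
        radj[v].append(u)
    return radj


def bfs_distances(adj: dict[str, list[str]], source: str) -> dict[str, int]:
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def all_shortest_paths(adj, source, target) -> list[list[str]]:
    dist = bfs_distances(adj, source)
    if target not in dist:
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == target:
            paths.append(list(path))
            return
        for v in adj[u]:
            if dist.get(v) == dist[u] + 1 and dist[v] <= dist[target]:
                path.append(v)
                extend(path)
                path.pop()

    extend([source])
    return paths


def betweenness_oracle(cmap) -> dict[str, float]:
    """Sum over ordered pairs of (shortest paths through v) / (all shortest paths)."""
    adj = adjacency(cmap)
    nodes = cmap.nodes
    score = {v: 0.0 for v in nodes}
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            paths = all_shortest_paths(adj, s, t)
            if not paths:
                continue
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                score[v] += through / len(paths)
    return score


def load_oracle(cmap) -> dict[str, float]:
    """Packet simulation: one unit per ordered pair, split equally among
    shortest-path successors at each node; transiting mass is scored."""
    adj = adjacency(cmap)
    nodes = cmap.nodes
    score = {v: 0.0 for v in nodes}
    for t in nodes:
        # distance of every node TO t
        radj = {v: [] for v in nodes}
        for u in nodes:
            for v in adj[u]:
                radj[v].append(u)
        dist_to_t = bfs_distances(radj, t)
        for s in nodes:
            if s == t or s not in dist_to_t:
                continue
            mass = {s: 1.0}
            for u in sorted(dist_to_t, key=dist_to_t.get, reverse=True):
                if u not in mass or u == t:
                    continue
                succ = [v for v in adj[u] if v in dist_to_t and dist_to_t[v] == dist_to_t[u] - 1]
                share = mass[u] / len(succ)
                for v in succ:
                    mass[v] = mass.get(v, 0.0) + share
            for v, m in mass.items():
                if v not in (s, t):
                    score[v] += m
    return score


def closeness_oracle(cmap) -> dict[str, float]:
    """Wasserman-Faust closeness on incoming distances."""
    adj = adjacency(cmap)
    nodes = cmap.nodes
    n = len(nodes)
    dist_from = {v: bfs_distances(adj, v) for v in nodes}
    score = {}
    for v in nodes:
        reachers = {u: dist_from[u][v] for u in nodes if u != v and v in dist_from[u]}
        if not reachers:
            score[v] = 0.0
        else:
            r = len(reachers)
            score[v] = (r / (n - 1)) * (r / sum(reachers.values()))
    return score


def katz_oracle(cmap, alpha: float, beta: float = 1.0) -> dict[str, float]:
    """Dense linear solve of x = alpha A^T x + beta 1, unit-normalized."""
    nodes = cmap.nodes
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    for u, v, _ in cmap.edges():
        a[index[u], index[v]] = 1.0
    x = np.linalg.solve(np.eye(n) - alpha * a.T, beta * np.ones(n))
    x /= np.linalg.norm(x)
    return {v: float(x[index[v]]) for v in nodes}


def local_clustering_oracle(cmap, node: str) -> float:
    adj = adjacency(cmap)
    edge_set = {(u, v) for u, v, _ in cmap.edges()}
    neighbors = {v for v in adj[node]} | {u for u, v in edge_set if v == node}
    neighbors.discard(node)
    k = len(neighbors)
    if k < 2:
        return 0.0
    among = sum(
        1 for a, b in permutations(neighbors, 2) if (a, b) in edge_set
    )
    return among / (k * (k - 1))


def simple_cycles_oracle(cmap) -> set[tuple[str, ...]]:
    """All simple directed cycles, canonicalized to start at their min node."""
    adj = adjacency(cmap)
    cycles: set[tuple[str, ...]] = set()

    def search(start, path, on_path):
        u = path[-1]
        for v in adj[u]:
            if v == start and len(path) > 0:
                cycles.add(tuple(path))
            elif v > start and v not in on_path:
                path.append(v)
                on_path.add(v)
                search(start, path, on_path)
                on_path.discard(v)
                path.pop()

    for start in sorted(adj):
        search(start, [start], {start})
    return cycles


def simple_paths_oracle(cmap, source, target, max_edges) -> set[tuple[str, ...]]:
    adj = adjacency(cmap)
    found: set[tuple[str, ...]] = set()

    def walk(path, on_path):
        u = path[-1]
        if u == target:
            found.add(tuple(path))
            return
        if len(path) - 1 >= max_edges:
            return
        for v in adj[u]:
            if v not in on_path:
                path.append(v)
                on_path.add(v)
                walk(path, on_path)
                on_path.discard(v)
                path.pop()

    if source in adj:
        walk([source], {source})
    return found


def max_disjoint_paths_oracle(cmap, source, target, max_edges=30) -> int:
    """Maximum number of internally-vertex-disjoint paths, by exhaustive
    search over subsets of all simple paths (branch and bound)."""
    paths = [list(p) for p in simple_paths_oracle(cmap, source, target, max_edges)]
    interiors = [frozenset(p[1:-1]) for p in paths]
    best = 0

    def extend(i, used, count):
        nonlocal best
        best = max(best, count)
        if count + (len(paths) - i) <= best:
            return
        for j in range(i, len(paths)):
            if not (interiors[j] & used):
                extend(j + 1, used | interiors[j], count + 1)

    extend(0, frozenset(), 0)
    return best


def floyd_warshall_oracle(cmap, undirected: bool) -> dict[tuple[str, str], int]:
    nodes = cmap.nodes
    inf = float("inf")
    dist = {(u, v): (0 if u == v else inf) for u in nodes for v in nodes}
    for u, v, _ in cmap.edges():
        dist[u, v] = 1
        if undirected:
            dist[v, u] = 1
    for k in nodes:
        for i in nodes:
            dik = dist[i, k]
            if dik == inf:
                continue
            for j in nodes:
                if dik + dist[k, j] < dist[i, j]:
                    dist[i, j] = dik + dist[k, j]
    return {pair: d for pair, d in dist.items() if d < inf and pair[0] != pair[1]}


def modularity_oracle(cmap, assignment: dict[str, int], resolution: float = 1.0) -> float:
    """Direct double sum over the weighted undirected projection."""
    nodes = cmap.nodes
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    for u, v, _ in cmap.edges():
        if u == v:
            continue
        a[index[u], index[v]] += 1.0
        a[index[v], index[u]] += 1.0
    two_m = a.sum()
    if two_m == 0:
        return 0.0
    k = a.sum(axis=1)
    q = 0.0
    for i, u in enumerate(nodes):
        for j, v in enumerate(nodes):
            if assignment[u] == assignment[v]:
                q += a[i, j] - resolution * k[i] * k[j] / two_m
    return q / two_m


def ranks_oracle(scores: dict[str, float]) -> dict[str, int]:
    """Sort, group exactly-equal scores, number groups from 1."""
    distinct = sorted(set(scores.values()), reverse=True)
    position = {s: i + 1 for i, s in enumerate(distinct)}
    return {v: position[s] for v, s in scores.items()}
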