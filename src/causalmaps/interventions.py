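"""Systems-intervention analytics on signed causal maps.

Three what-if primitives:

* **Feedback loops** - all simple directed cycles, each classified by
  the sign parity of its edges: an even number of negative links makes
  the loop *reinforcing* (it amplifies a perturbation), an odd number
  makes it *balancing* (it dampens one); any unspecified polarity
  leaves it *undetermined*.
* **Intervention paths** - the routes from an intervention factor to
  an outcome factor: either every simple path (with its net polarity),
  or a maximum set of internally-vertex-disjoint paths, whose size
  equals the vertex connectivity between the pair (Menger's theorem)
  and counts truly independent causal routes.
* **Ripple shells** - breadth-first layers downstream of an
  intervention node: which parts of the system are touched at each
  causal distance, out to a user-set horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .model import CausalMap, Polarity

__all__ = [
    "FeedbackLoop",
    "PathSet",
    "RippleShells",
    "classify_loop",
    "enumerate_loops",
    "disjoint_paths",
    "all_paths",
    "ripple_shells",
]

REINFORCING = "reinforcing"
BALANCING = "balancing"
UNDETERMINED = "undetermined"

DEFAULT_MAX_LENGTH = 10
DEFAULT_MAX_COUNT = 10_000


def classify_loop(polarities: list[Polarity]) -> str:
    """Classify a cycle's polarity sequence by sign parity.

    Even count of negative links -> reinforcing; odd -> balancing; any
    unspecified link -> undetermined (never assumed positive).
    """
    if not polarities:
        raise ValueError("cannot classify an empty polarity sequence")
    if any(p is Polarity.UNSPECIFIED for p in polarities):
        return UNDETERMINED
    negatives = sum(1 for p in polarities if p is Polarity.NEGATIVE)
    return BALANCING if negatives % 2 else REINFORCING


def _net_polarity(polarities: list[Polarity]) -> str:
    if any(p is Polarity.UNSPECIFIED for p in polarities):
        return UNDETERMINED
    negatives = sum(1 for p in polarities if p is Polarity.NEGATIVE)
    return "net-negative" if negatives % 2 else "net-positive"


@dataclass
class FeedbackLoop:
    """A simple directed cycle with its edge polarities and class."""

    cycle: list[str]  # first node implicitly repeated at the end
    polarities: list[Polarity]
    classification: str

    def __len__(self) -> int:
        return len(self.cycle)


def enumerate_loops(
    cmap: CausalMap,
    max_length: int = DEFAULT_MAX_LENGTH,
    max_count: int = DEFAULT_MAX_COUNT,
) -> tuple[list[FeedbackLoop], bool]:
    """All simple directed cycles of length <= max_length, classified.

    Cycle enumeration is worst-case exponential, so both caps are
    mandatory; when ``max_count`` is hit the result is returned as-is
    with the ``complete`` flag False (never an exception).  Cycles are
    canonicalized to start at their smallest node id.  A map without
    cycles (a DAG) yields an empty list.
    """
    if max_length <= 0 or max_count <= 0:
        raise ValueError("max_length and max_count must be positive")
    g = cmap.graph
    loops: list[FeedbackLoop] = []
    complete = True
    for cycle in nx.simple_cycles(g, length_bound=max_length):
        if len(loops) >= max_count:
            complete = False
            break
        start = cycle.index(min(cycle))
        cycle = cycle[start:] + cycle[:start]
        pols = [
            cmap.polarity(cycle[i], cycle[(i + 1) % len(cycle)])
            for i in range(len(cycle))
        ]
        loops.append(FeedbackLoop(cycle, pols, classify_loop(pols)))
    loops.sort(key=lambda l: (len(l.cycle), l.cycle))
    return loops, complete


@dataclass
class PathSet:
    """Directed source->target paths plus per-path net polarity."""

    source: str
    target: str
    paths: list[list[str]]
    net_polarities: list[str]
    disjointness: str  # "internally-vertex-disjoint" | "all-simple"
    complete: bool = True

    def __len__(self) -> int:
        return len(self.paths)


def _path_polarity(cmap: CausalMap, path: list[str]) -> str:
    return _net_polarity([cmap.polarity(u, v) for u, v in zip(path, path[1:])])


def disjoint_paths(cmap: CausalMap, source: str, target: str) -> PathSet:
    """A maximum set of internally-vertex-disjoint source->target paths.

    Computed by unit-capacity max flow with node splitting, so the
    number of paths equals the internal vertex connectivity between the
    pair (Menger).  Endpoints are shared; no intermediate node appears
    on two paths.  An unreachable target gives an empty path set.
    """
    for node in (source, target):
        if not cmap.has_node(node):
            raise KeyError(f"unknown node: {node!r}")
    if source == target:
        raise ValueError("source and target must differ")
    g = cmap.graph
    try:
        paths = sorted(nx.node_disjoint_paths(g, source, target))
    except nx.NetworkXNoPath:
        paths = []
    return PathSet(
        source, target, paths,
        [_path_polarity(cmap, p) for p in paths],
        "internally-vertex-disjoint",
    )


def all_paths(
    cmap: CausalMap,
    source: str,
    target: str,
    max_length: int = DEFAULT_MAX_LENGTH,
    max_count: int = DEFAULT_MAX_COUNT,
) -> PathSet:
    """Every simple directed source->target path within the caps.

    ``max_length`` bounds the number of edges per path.  Hitting
    ``max_count`` truncates the enumeration and clears the ``complete``
    flag.  Each path carries its net polarity (sign parity of its
    edges, undetermined if any edge is unsigned).
    """
    if max_length <= 0 or max_count <= 0:
        raise ValueError("max_length and max_count must be positive")
    for node in (source, target):
        if not cmap.has_node(node):
            raise KeyError(f"unknown node: {node!r}")
    paths: list[list[str]] = []
    complete = True
    for path in nx.all_simple_paths(cmap.graph, source, target, cutoff=max_length):
        if len(paths) >= max_count:
            complete = False
            break
        paths.append(path)
    paths.sort(key=lambda p: (len(p), p))
    return PathSet(
        source, target, paths,
        [_path_polarity(cmap, p) for p in paths],
        "all-simple", complete,
    )


@dataclass
class RippleShells:
    """Breadth-first distance layers downstream of an intervention node."""

    center: str
    shells: dict[int, set[str]]  # distance -> nodes at exactly that out-distance
    max_depth: int
    shell_edges: list[tuple[str, str, Polarity]] = field(default_factory=list)

    def reached(self) -> set[str]:
        return set().union(*self.shells.values())


def ripple_shells(cmap: CausalMap, center: str, max_depth: int) -> RippleShells:
    """Nodes affected at each directed distance from an intervention.

    Shell d holds the nodes whose shortest out-distance from the center
    is exactly d; shells beyond ``max_depth`` are omitted.  Also
    collects the edges that run between consecutive shells (or within
    one), for rendering concentric ripple diagrams.
    """
    if not cmap.has_node(center):
        raise KeyError(f"unknown node: {center!r}")
    if max_depth < 0:
        raise ValueError("max_depth must be >= 0")
    dist = nx.single_source_shortest_path_length(cmap.graph, center, cutoff=max_depth)
    shells: dict[int, set[str]] = {}
    for node, d in dist.items():
        shells.setdefault(d, set()).add(node)
    reached = set(dist)
    edges = [
        (u, v, pol)
        for u, v, pol in cmap.edges()
        if u in reached and v in reached and dist[v] in (dist[u], dist[u] + 1)
    ]
    return RippleShells(center, shells, max_depth, edges)
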