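"""Core data model for signed causal maps.

A causal map is a simple directed graph whose nodes are labeled factors
(e.g. "access to care") and whose edges assert a causal influence of the
source factor on the target factor.  Each edge carries a polarity:
positive (an increase in the source increases the target), negative
(an increase in the source decreases the target) or unspecified.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Any, Iterable, Iterator, Mapping

import networkx as nx

__all__ = ["Polarity", "CausalMap", "ValidationFinding", "validate_map"]


class Polarity(enum.Enum):
    """Edge polarity of a causal link: ``+``, ``-`` or unspecified."""

    POSITIVE = "+"
    NEGATIVE = "-"
    UNSPECIFIED = ""

    @classmethod
    def from_symbol(cls, symbol: Any) -> "Polarity":
        """Parse a polarity from its serialized symbol.

        Accepts ``+``/``-`` (and a few common spellings), an empty or
        missing value for unspecified, or an existing :class:`Polarity`.
        """
        if isinstance(symbol, Polarity):
            return symbol
        if symbol is None:
            return cls.UNSPECIFIED
        text = str(symbol).strip().lower()
        if text in {"+", "pos", "positive", "1", "+1"}:
            return cls.POSITIVE
        if text in {"-", "−", "neg", "negative", "-1"}:
            return cls.NEGATIVE
        if text in {"", "nan", "none", "unspecified", "0"}:
            return cls.UNSPECIFIED
        raise ValueError(f"unrecognized polarity symbol: {symbol!r}")

    @property
    def sign(self) -> int:
        """+1, -1 or 0 (unspecified)."""
        return {"+": 1, "-": -1, "": 0}[self.value]

    def __str__(self) -> str:  # serialized form
        return self.value


class CausalMap:
    """A simple signed digraph of labeled factors.

    Thin wrapper around :class:`networkx.DiGraph` that enforces causal-map
    invariants on construction: unique node ids, edge endpoints present,
    at most one edge per ordered pair, and (by default) no self-loops.

    Parameters
    ----------
    name:
        Free-text label of the map.
    allow_self_loops:
        Permit edges from a node to itself.  Off by default: causal-map
        semantics describe effects between distinct factors, and a
        self-influence is usually a modeling artifact.
    """

    def __init__(self, name: str = "causal map", *, allow_self_loops: bool = False):
        self.name = name
        self.allow_self_loops = allow_self_loops
        self._g = nx.DiGraph()

    # -- construction -------------------------------------------------

    def add_node(self, node: str, label: str | None = None, **annotations: Any) -> None:
        node = str(node)
        self._g.add_node(node, label=label if label is not None else node, **annotations)

    def add_edge(
        self,
        source: str,
        target: str,
        polarity: Polarity | str | None = Polarity.UNSPECIFIED,
    ) -> None:
        source, target = str(source), str(target)
        if source == target and not self.allow_self_loops:
            raise ValueError(f"self-loop on {source!r} (allow_self_loops=False)")
        pol = Polarity.from_symbol(polarity)
        for endpoint in (source, target):
            if endpoint not in self._g:
                self.add_node(endpoint)
        if self._g.has_edge(source, target):
            existing = self._g.edges[source, target]["polarity"]
            if existing is not pol:
                raise ValueError(
                    f"duplicate edge {source!r}->{target!r} with conflicting "
                    f"polarities ({existing.value or 'unspecified'} vs "
                    f"{pol.value or 'unspecified'})"
                )
        self._g.add_edge(source, target, polarity=pol)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, Polarity | str | None]] | Iterable[tuple[str, str]],
        *,
        name: str = "causal map",
        nodes: Iterable[str] = (),
        allow_self_loops: bool = False,
    ) -> "CausalMap":
        """Build a map from (source, target[, polarity]) triples."""
        cmap = cls(name, allow_self_loops=allow_self_loops)
        for node in nodes:
            cmap.add_node(node)
        for edge in edges:
            if len(edge) == 2:
                u, v = edge  # type: ignore[misc]
                cmap.add_edge(u, v)
            else:
                u, v, p = edge  # type: ignore[misc]
                cmap.add_edge(u, v, p)
        return cmap

    # -- views ---------------------------------------------------------

    @property
    def graph(self) -> nx.DiGraph:
        """The underlying directed graph (polarity stored per edge)."""
        return self._g

    @property
    def n(self) -> int:
        return self._g.number_of_nodes()

    @property
    def m(self) -> int:
        return self._g.number_of_edges()

    @property
    def nodes(self) -> list[str]:
        return list(self._g.nodes)

    def edges(self) -> Iterator[tuple[str, str, Polarity]]:
        for u, v, data in self._g.edges(data=True):
            yield u, v, data["polarity"]

    def polarity(self, source: str, target: str) -> Polarity:
        return self._g.edges[source, target]["polarity"]

    def has_node(self, node: str) -> bool:
        return node in self._g

    def has_edge(self, source: str, target: str) -> bool:
        return self._g.has_edge(source, target)

    def node_annotations(self, node: str) -> Mapping[str, Any]:
        return dict(self._g.nodes[node])

    def undirected_projection(self) -> nx.Graph:
        """Undirected projection with integer edge weights.

        Each directed edge contributes weight 1, so a reciprocal pair
        u->v, v->u collapses to a single undirected edge of weight 2.
        Used by community detection and modularity.
        """
        und = nx.Graph()
        und.add_nodes_from(self._g.nodes)
        for u, v in self._g.edges:
            if und.has_edge(u, v):
                und.edges[u, v]["weight"] += 1
            else:
                und.add_edge(u, v, weight=1)
        return und

    def copy(self) -> "CausalMap":
        clone = CausalMap(self.name, allow_self_loops=self.allow_self_loops)
        clone._g = self._g.copy()
        return clone

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CausalMap):
            return NotImplemented
        if set(self._g.nodes) != set(other._g.nodes):
            return False
        mine = {(u, v): p for u, v, p in self.edges()}
        theirs = {(u, v): p for u, v, p in other.edges()}
        return mine == theirs

    def __repr__(self) -> str:
        return f"CausalMap({self.name!r}, n={self.n}, m={self.m})"


@dataclass
class ValidationFinding:
    """One invariant violation found in a map."""

    kind: str  # "dangling-endpoint" | "self-loop" | "duplicate-node" ...
    detail: str
    subject: tuple = field(default_factory=tuple)

    def __str__(self) -> str:
        return f"[{self.kind}] {self.detail}"


def validate_map(cmap: CausalMap) -> list[ValidationFinding]:
    """Report violations of causal-map invariants; empty list iff valid.

    ``CausalMap`` construction already rejects most violations, so for
    maps built through the public API this mainly checks self-loops and
    polarity typing; it exists so maps assembled by other code paths
    (e.g. direct graph manipulation) can be audited before analysis.
    """
    findings: list[ValidationFinding] = []
    g = cmap.graph
    for u, v, data in g.edges(data=True):
        if u == v:
            findings.append(
                ValidationFinding("self-loop", f"edge {u!r}->{v!r} is a self-loop", (u, v))
            )
        if u not in g or v not in g:  # unreachable via nx, kept for audited graphs
            findings.append(
                ValidationFinding(
                    "dangling-endpoint", f"edge {u!r}->{v!r} has a missing endpoint", (u, v)
                )
            )
        pol = data.get("polarity")
        if not isinstance(pol, Polarity):
            findings.append(
                ValidationFinding(
                    "bad-polarity", f"edge {u!r}->{v!r} polarity is {pol!r}", (u, v)
                )
            )
    return findings
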