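"""Reading and writing causal maps.

Formats
-------
edge-list CSV
    Header ``source,target,polarity`` (polarity column optional; empty
    cell = unspecified).  An optional companion node table
    (``node`` or ``id[,label]`` header) declares isolated nodes.
GraphML
    Standard GraphML with the polarity symbol stored in an edge
    attribute named ``polarity``.
DOT
    Export only, for rendering with Graphviz.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable

import networkx as nx

from .model import CausalMap, Polarity, ValidationFinding

logger = logging.getLogger(__name__)

__all__ = ["load_map", "write_map", "validate_records", "sniff_format"]

_CSV_HEADER = ["source", "target", "polarity"]


class MapParseError(ValueError):
    """Raised when an input file cannot be parsed as a causal map."""


def sniff_format(path: str | Path) -> str:
    """Guess the file format ("csv" or "graphml") from suffix, then content."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".graphml", ".xml"}:
        return "graphml"
    if suffix in {".csv", ".tsv", ".txt", ".edges"}:
        return "csv"
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        head = fh.read(200).lstrip()
    return "graphml" if head.startswith("<") else "csv"


def validate_records(
    nodes: Iterable[str],
    edges: Iterable[tuple[str, str, Polarity]],
    *,
    allow_self_loops: bool = False,
) -> list[ValidationFinding]:
    """Validate raw (nodes, edges) records against causal-map invariants.

    Unlike :class:`CausalMap` construction, this never raises: it returns
    one finding per violation (dangling endpoints, self-loops, duplicate
    edges, conflicting polarities on a duplicated edge).
    """
    findings: list[ValidationFinding] = []
    node_set = set(nodes)
    seen: dict[tuple[str, str], Polarity] = {}
    for u, v, pol in edges:
        for endpoint in (u, v):
            if endpoint not in node_set:
                findings.append(
                    ValidationFinding(
                        "dangling-endpoint",
                        f"edge {u!r}->{v!r} references undeclared node {endpoint!r}",
                        (u, v),
                    )
                )
        if u == v and not allow_self_loops:
            findings.append(
                ValidationFinding("self-loop", f"edge {u!r}->{v!r} is a self-loop", (u, v))
            )
        if (u, v) in seen:
            if seen[u, v] is not pol:
                findings.append(
                    ValidationFinding(
                        "conflicting-duplicate",
                        f"edge {u!r}->{v!r} duplicated with conflicting polarities",
                        (u, v),
                    )
                )
            else:
                findings.append(
                    ValidationFinding(
                        "duplicate-edge", f"edge {u!r}->{v!r} appears more than once", (u, v)
                    )
                )
        else:
            seen[u, v] = pol
    return findings


def load_map(
    path: str | Path,
    format: str | None = None,
    *,
    name: str | None = None,
    allow_self_loops: bool = False,
    node_table: str | Path | None = None,
) -> CausalMap:
    """Load a causal map from an edge-list CSV or GraphML file.

    Duplicate edges with identical polarity are collapsed with a logged
    warning; duplicates with conflicting polarities raise.  A missing
    polarity column yields all-unspecified edges.  ``node_table`` may
    point to a one/two-column CSV declaring nodes (including isolates).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or sniff_format(path)).lower()
    if fmt == "csv":
        nodes, edges = _read_edge_csv(path)
        sidecar = path.with_suffix(".nodes.csv")
        if node_table is None and sidecar.exists() and sidecar != path:
            node_table = sidecar
    elif fmt == "graphml":
        nodes, edges = _read_graphml(path)
    else:
        raise ValueError(f"unsupported format: {format!r}")

    if node_table is not None:
        nodes = list(nodes) + _read_node_table(Path(node_table))

    findings = validate_records(nodes, edges, allow_self_loops=allow_self_loops)
    fatal = [f for f in findings if f.kind in {"dangling-endpoint", "conflicting-duplicate"}
             or (f.kind == "self-loop" and not allow_self_loops)]
    if fatal:
        raise MapParseError(
            f"{path}: invalid causal map: " + "; ".join(str(f) for f in fatal[:5])
        )
    for f in findings:
        if f.kind == "duplicate-edge":
            logger.warning("%s: collapsing %s", path, f.detail)

    cmap = CausalMap(name or path.stem, allow_self_loops=allow_self_loops)
    for node in nodes:
        cmap.add_node(node)
    for u, v, pol in edges:
        cmap.add_edge(u, v, pol)
    return cmap


def _read_edge_csv(path: Path) -> tuple[list[str], list[tuple[str, str, Polarity]]]:
    edges: list[tuple[str, str, Polarity]] = []
    nodes: list[str] = []
    with open(path, "r", encoding="utf-8-sig", newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delimiter = "\t" if sample.count("\t") > sample.count(",") else ","
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            return [], []
        cols = [c.strip().lower() for c in header]
        try:
            i_src = cols.index("source")
            i_tgt = cols.index("target")
        except ValueError as exc:
            raise MapParseError(
                f"{path}: line 1: expected 'source' and 'target' columns, got {header!r}"
            ) from exc
        i_pol = cols.index("polarity") if "polarity" in cols else None
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            try:
                u = row[i_src].strip()
                v = row[i_tgt].strip()
                pol = Polarity.from_symbol(row[i_pol]) if i_pol is not None and i_pol < len(row) else Polarity.UNSPECIFIED
            except (IndexError, ValueError) as exc:
                raise MapParseError(f"{path}: line {lineno}: {exc}") from exc
            if not u or not v:
                raise MapParseError(f"{path}: line {lineno}: empty source or target")
            edges.append((u, v, pol))
            nodes.extend(endpoint for endpoint in (u, v) if endpoint not in nodes)
    # stable de-dup while preserving first-seen order
    return list(dict.fromkeys(nodes)), edges


def _read_graphml(path: Path) -> tuple[list[str], list[tuple[str, str, Polarity]]]:
    try:
        g = nx.read_graphml(path)
    except Exception as exc:  # noqa: BLE001 - surface as one parse error
        raise MapParseError(f"{path}: not valid GraphML: {exc}") from exc
    nodes = [str(n) for n in g.nodes]
    edges = []
    edge_iter = g.edges(data=True)
    for u, v, data in edge_iter:
        edges.append((str(u), str(v), Polarity.from_symbol(data.get("polarity", ""))))
    return nodes, edges


def _read_node_table(path: Path) -> list[str]:
    nodes: list[str] = []
    with open(path, "r", encoding="utf-8-sig", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            return []
        cols = [c.strip().lower() for c in header]
        idx = cols.index("node") if "node" in cols else (cols.index("id") if "id" in cols else 0)
        for row in reader:
            if row and row[idx].strip():
                nodes.append(row[idx].strip())
    return nodes


def write_map(cmap: CausalMap, path: str | Path, format: str | None = None) -> Path:
    """Write a map to edge-list CSV, GraphML or DOT.

    CSV and GraphML round-trip exactly through :func:`load_map`; DOT is
    an export for visualization only.  Isolated nodes are preserved in
    GraphML; for CSV they are written to a ``<stem>.nodes.csv`` sidecar.
    """
    path = Path(path)
    fmt = (format or _format_from_suffix(path)).lower()
    if fmt == "csv":
        _write_edge_csv(cmap, path)
    elif fmt == "graphml":
        g = nx.DiGraph()
        g.add_nodes_from(cmap.nodes)
        for u, v, pol in cmap.edges():
            g.add_edge(u, v, polarity=pol.value)
        nx.write_graphml(g, path)
    elif fmt == "dot":
        _write_dot(cmap, path)
    else:
        raise ValueError(f"unsupported format: {format!r}")
    return path


def _format_from_suffix(path: Path) -> str:
    return {".graphml": "graphml", ".dot": "dot", ".gv": "dot"}.get(path.suffix.lower(), "csv")


def _write_edge_csv(cmap: CausalMap, path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        for u, v, pol in sorted(cmap.edges()):
            writer.writerow([u, v, pol.value])
    isolates = [n for n in cmap.nodes if cmap.graph.degree(n) == 0]
    if isolates:
        sidecar = path.with_suffix(".nodes.csv")
        with open(sidecar, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["node"])
            for n in sorted(isolates):
                writer.writerow([n])


def _quote_dot(s: str) -> str:
    return '"' + s.replace('"', r"\"") + '"'


def _write_dot(cmap: CausalMap, path: Path) -> None:
    lines = [f"digraph {_quote_dot(cmap.name)} {{"]
    for n in cmap.nodes:
        lines.append(f"  {_quote_dot(n)};")
    for u, v, pol in cmap.edges():
        attrs = []
        if pol is Polarity.POSITIVE:
            attrs.append('label="+"')
        elif pol is Polarity.NEGATIVE:
            attrs.append('label="-"  style=dashed')
        suffix = f" [{' '.join(attrs)}]" if attrs else ""
        lines.append(f"  {_quote_dot(u)} -> {_quote_dot(v)}{suffix};")
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
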