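"""Qualitative coding of map factors and inter-coder agreement.

Each factor of a map can be annotated on two axes: the level of the
Social-Ecological Model it operates at (individual, relationship,
community, societal) and the prevention strategies it relates to
(seven shorthand categories from the CDC suicide-prevention technical
package).  A node may carry several categories per axis.  Agreement
between two coders on a node is the Jaccard similarity of their
category sets - the fraction of all categories used that both coders
endorsed - and the aggregate is the unweighted mean over nodes coded
by both, reported as a percentage.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "SEM_LEVELS",
    "STRATEGIES",
    "AXES",
    "CodingTable",
    "intercoder_agreement",
    "aggregate_agreement",
    "heatmap_matrix",
    "conflict_report",
]

SEM_LEVELS = ("individual", "relationship", "community", "societal")
STRATEGIES = ("economic", "care", "environments", "connectedness", "coping", "support", "prevent")
AXES = {"sem_level": SEM_LEVELS, "strategy": STRATEGIES}


class UndefinedAgreementError(ValueError):
    """Agreement is undefined (no jointly coded node, or two empty sets)."""


@dataclass
class CodingTable:
    """Per-(coder, node) category sets on both axes.

    Stored sparsely: absent entries mean "uncoded".  Consensus records
    use the reserved coder id ``consensus``; categories added during
    coder discussion (rather than taken from either initial coding)
    carry the provenance flag ``discussion-added``.
    """

    _data: dict[tuple[str, str, str], set[str]] = field(default_factory=dict)
    provenance: dict[tuple[str, str, str, str], str] = field(default_factory=dict)

    def assign(
        self, coder: str, node: str, axis: str, category: str,
        provenance: str = "initial",
    ) -> None:
        if axis not in AXES:
            raise ValueError(f"unknown axis {axis!r}; expected one of {sorted(AXES)}")
        if category not in AXES[axis]:
            raise ValueError(f"unknown {axis} category {category!r}")
        self._data.setdefault((coder, node, axis), set()).add(category)
        self.provenance[(coder, node, axis, category)] = provenance

    def categories(self, coder: str, node: str, axis: str) -> set[str]:
        return set(self._data.get((coder, node, axis), set()))

    def coders(self) -> list[str]:
        return sorted({c for c, _, _ in self._data})

    def nodes(self, coder: str | None = None) -> list[str]:
        return sorted({n for c, n, _ in self._data if coder is None or c == coder})

    # -- long-format CSV I/O: coder,node,axis,category[,provenance] ----

    @classmethod
    def read_csv(cls, path: str | Path) -> "CodingTable":
        table = cls()
        frame = pd.read_csv(path, dtype=str).fillna("")
        required = {"coder", "node", "axis", "category"}
        if not required.issubset(frame.columns):
            raise ValueError(f"{path}: expected columns {sorted(required)}")
        for row in frame.itertuples(index=False):
            table.assign(
                row.coder, row.node, row.axis, row.category,
                getattr(row, "provenance", "") or "initial",
            )
        return table

    def write_csv(self, path: str | Path) -> Path:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["coder", "node", "axis", "category", "provenance"])
            for (coder, node, axis), cats in sorted(self._data.items()):
                for cat in sorted(cats):
                    prov = self.provenance.get((coder, node, axis, cat), "initial")
                    writer.writerow([coder, node, axis, cat, prov])
        return Path(path)


def intercoder_agreement(set1: set[str], set2: set[str]) -> float:
    """Jaccard agreement |set1 & set2| / |set1 | set2|.

    E.g. coders sharing one category out of three used in total agree
    at 1/3.  Undefined when both sets are empty.
    """
    if not set1 and not set2:
        raise UndefinedAgreementError("agreement undefined for two empty category sets")
    return len(set1 & set2) / len(set1 | set2)


def aggregate_agreement(
    table: CodingTable, coder_a: str, coder_b: str, axis: str
) -> dict:
    """Mean per-node agreement between two coders on one axis, as a percent.

    Nodes coded by neither coder are excluded (agreement is undefined
    there); nodes coded by exactly one contribute their Jaccard score
    of 0.  Returns the aggregate plus the per-node breakdown.
    """
    if axis not in AXES:
        raise ValueError(f"unknown axis {axis!r}")
    nodes = sorted(set(table.nodes(coder_a)) | set(table.nodes(coder_b)))
    per_node: dict[str, float] = {}
    skipped: list[str] = []
    for node in nodes:
        s1 = table.categories(coder_a, node, axis)
        s2 = table.categories(coder_b, node, axis)
        if not s1 and not s2:
            skipped.append(node)
            continue
        per_node[node] = intercoder_agreement(s1, s2)
    if not per_node:
        raise UndefinedAgreementError(
            f"no node coded by {coder_a!r} or {coder_b!r} on axis {axis!r}"
        )
    mean = sum(per_node.values()) / len(per_node)
    return {
        "axis": axis,
        "coders": (coder_a, coder_b),
        "agreement_percent": 100.0 * mean,
        "n_nodes": len(per_node),
        "per_node": per_node,
        "skipped_uncoded": skipped,
    }


def heatmap_matrix(
    table: CodingTable, coder: str, total_nodes: int | None = None
) -> pd.DataFrame:
    """Strategy x SEM-level matrix of node percentages for one coder.

    Cell (s, l) = 100 * (nodes assigned both strategy s and level l) /
    total nodes.  Because nodes may carry several categories per axis,
    row and column totals can exceed 100%; cells are never normalized
    against each other.  ``total_nodes`` defaults to the number of
    nodes the coder touched (pass the map's node count to use the full
    denominator including uncoded nodes).
    """
    nodes = table.nodes(coder)
    if not nodes:
        raise ValueError(f"coder {coder!r} has no coded nodes")
    denom = total_nodes if total_nodes is not None else len(nodes)
    matrix = pd.DataFrame(0.0, index=list(STRATEGIES), columns=list(SEM_LEVELS))
    for node in nodes:
        for s in table.categories(coder, node, "strategy"):
            for l in table.categories(coder, node, "sem_level"):
                matrix.loc[s, l] += 1
    matrix = 100.0 * matrix / denom
    matrix.index.name = "strategy"
    matrix.columns.name = "sem_level"
    return matrix


def conflict_report(table: CodingTable, coder_a: str, coder_b: str) -> list[dict]:
    """Per-node coding conflicts between two coders, with consensus slots.

    One record per (node, axis) where the category sets differ: the
    one-sided categories of each coder, the shared ones, and empty
    fields for recording the discussion outcome (consensus categories,
    including any that neither coder used initially, to be flagged
    ``discussion-added`` when filled in).
    """
    report: list[dict] = []
    nodes = sorted(set(table.nodes(coder_a)) | set(table.nodes(coder_b)))
    for node in nodes:
        for axis in AXES:
            s1 = table.categories(coder_a, node, axis)
            s2 = table.categories(coder_b, node, axis)
            if s1 == s2:
                continue
            report.append({
                "node": node,
                "axis": axis,
                f"only_{coder_a}": sorted(s1 - s2),
                f"only_{coder_b}": sorted(s2 - s1),
                "shared": sorted(s1 & s2),
                "consensus": [],
                "discussion_added": [],
            })
    return report
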