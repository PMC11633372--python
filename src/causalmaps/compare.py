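"""Multi-map comparison reports and the one-command pipeline runner.

`compare_maps` lines several causal maps up side by side, smallest
first, with the whole-network statistics as rows and a per-measure
top-k node ranking for each map.  `run_pipeline` drives every analysis
stage from one declarative YAML config and writes a manifest recording
every seed and parameter, so a study is reproducible from its output
directory alone.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from .model import CausalMap
from .io import load_map, write_map
from .synthetic import SyntheticMapConfig, generate_map
from .metrics import NetworkSummary, summarize
from .centrality import CentralityConfig, centrality_table, rank_nodes, MEASURES
from .communities import louvain_partition, leiden_partition, derivative_map, partition_agreement
from .interventions import enumerate_loops, disjoint_paths, all_paths, ripple_shells
from .coding import CodingTable, aggregate_agreement, heatmap_matrix, conflict_report

logger = logging.getLogger(__name__)

__all__ = ["ComparisonReport", "compare_maps", "run_pipeline"]

SUMMARY_ROWS = ["nodes", "edges", "avg_clustering", "avg_path_length", "density", "diameter"]


@dataclass
class ComparisonReport:
    """Side-by-side statistics and rankings for several maps."""

    summaries: list[NetworkSummary]  # ordered by node count ascending
    summary_table: pd.DataFrame      # SUMMARY_ROWS x map names
    top_nodes: dict[str, pd.DataFrame]  # map name -> (rank rows x measures)
    errors: dict[str, dict[str, str]]   # map name -> {cell: message}
    notes: dict[str, str]


def compare_maps(
    maps: list[CausalMap],
    k: int = 5,
    notes: dict[str, str] | None = None,
    centrality_config: CentralityConfig | None = None,
) -> ComparisonReport:
    """Compare maps at the network and node level, smallest map first.

    Per map: the summary statistics (nodes, edges, clustering, average
    path length, density, diameter) and the top-``k`` competition-ranked
    nodes under each of the five centralities.  Metric failures on one
    map are recorded per cell, not fatal.
    """
    if not maps:
        raise ValueError("need at least one map")
    ordered = sorted(maps, key=lambda m: m.n)
    summaries: list[NetworkSummary] = []
    errors: dict[str, dict[str, str]] = {}
    columns: dict[str, dict] = {}
    top: dict[str, pd.DataFrame] = {}
    for cmap in ordered:
        cell_errors: dict[str, str] = {}
        try:
            summary = summarize(cmap)
            summaries.append(summary)
            columns[cmap.name] = {r: summary.as_row()[r] for r in SUMMARY_ROWS}
        except Exception as exc:  # noqa: BLE001 - per-map cells degrade gracefully
            cell_errors["summary"] = str(exc)
            columns[cmap.name] = {r: None for r in SUMMARY_ROWS}
        try:
            top[cmap.name] = _top_k_table(cmap, k, centrality_config)
        except Exception as exc:  # noqa: BLE001
            cell_errors["centrality"] = str(exc)
        if cell_errors:
            errors[cmap.name] = cell_errors
    table = pd.DataFrame(columns).reindex(SUMMARY_ROWS)
    table.index.name = "measure"
    return ComparisonReport(summaries, table, top, errors, notes or {})


def _top_k_table(cmap: CausalMap, k: int, config: CentralityConfig | None) -> pd.DataFrame:
    frame, _ = centrality_table(cmap, config)
    data: dict[str, list[str]] = {}
    depth = 0
    for measure in MEASURES:
        _, table = rank_nodes(dict(frame[measure]), k=k)
        entries = [f"{rank}: {node}" for rank, _, members in table for node in members]
        data[measure] = entries
        depth = max(depth, len(entries))
    padded = {m: v + [""] * (depth - len(v)) for m, v in data.items()}
    return pd.DataFrame(padded)


# ---------------------------------------------------------------------------
# pipeline runner


KNOWN_STAGES = ("summary", "centrality", "communities", "loops", "paths", "ripple", "coding")


def run_pipeline(config_path: str | Path, out_dir: str | Path | None = None) -> Path:
    """Run the analysis stages named in a YAML config; return the output dir.

    Config keys: ``input`` (map file) or ``synthesis`` (generator
    parameters), ``stages`` (subset of summary/centrality/communities/
    loops/paths/ripple/coding), ``seed``, per-stage parameter blocks,
    ``out_dir``.  The config is validated before anything runs; a
    ``manifest.json`` capturing versions, seeds and all parameters is
    written alongside the stage outputs.
    """
    config_path = Path(config_path)
    config = yaml.safe_load(config_path.read_text(encoding="utf-8")) or {}
    stages = config.get("stages", ["summary"])
    unknown = [s for s in stages if s not in KNOWN_STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}; known: {list(KNOWN_STAGES)}")
    if ("input" in config) == ("synthesis" in config):
        raise ValueError("config must set exactly one of 'input' or 'synthesis'")
    if "paths" in stages and not {"source", "target"} <= set(config.get("paths", {})):
        raise ValueError("'paths' stage needs paths: {source: ..., target: ...}")
    if "ripple" in stages and "center" not in config.get("ripple", {}):
        raise ValueError("'ripple' stage needs ripple: {center: ...}")
    if "coding" in stages and "table" not in config.get("coding", {}):
        raise ValueError("'coding' stage needs coding: {table: <csv path>}")

    seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("out_dir", config_path.with_suffix("")))
    out.mkdir(parents=True, exist_ok=True)

    if "input" in config:
        cmap = load_map(config["input"])
        ground_truth = None
    else:
        syn = dict(config["synthesis"])
        syn.setdefault("seed", seed)
        cfg = SyntheticMapConfig(**syn)
        cmap, ground_truth = generate_map(cfg)
        write_map(cmap, out / "map.csv")
        pd.DataFrame(
            sorted(ground_truth.items()), columns=["node", "community"]
        ).to_csv(out / "ground_truth.csv", index=False)

    manifest = {
        "causalmaps_version": __version__,
        "networkx_version": nx.__version__,
        "python_version": platform.python_version(),
        "config": config,
        "seed": seed,
        "map": {"name": cmap.name, "n": cmap.n, "m": cmap.m},
        "stages_run": list(stages),
    }

    for stage in stages:
        params = dict(config.get(stage, {}))
        logger.info("stage %s %s", stage, params)
        manifest[f"stage:{stage}"] = _run_stage(stage, cmap, params, seed, out)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n",
                                       encoding="utf-8")
    return out


def _run_stage(stage: str, cmap: CausalMap, params: dict, seed: int, out: Path) -> dict:
    if stage == "summary":
        summary = summarize(cmap, path_mode=params.get("path_mode", "undirected"))
        (out / "summary.json").write_text(
            json.dumps(summary.as_dict(), indent=2, default=str) + "\n", encoding="utf-8")
        pd.DataFrame([summary.as_row()]).to_csv(out / "summary.csv", index=False)
        return {"path_mode": summary.path_mode}
    if stage == "centrality":
        frame, meta = centrality_table(cmap)
        frame.round(10).to_csv(out / "centrality.csv")
        k = int(params.get("k", 5))
        _top_k_table(cmap, k, None).to_csv(out / "centrality_top.csv", index=False)
        return meta
    if stage == "communities":
        resolution = float(params.get("resolution", 1.0))
        results = {}
        partitions = {}
        for algo, fn in (("louvain", louvain_partition), ("leiden", leiden_partition)):
            part = fn(cmap, seed=seed, resolution=resolution)
            partitions[algo] = part
            pd.DataFrame(
                sorted(part.assignment.items()), columns=["node", "community"]
            ).to_csv(out / f"communities_{algo}.csv", index=False)
            deriv = derivative_map(cmap, part)
            rows = [
                {"from": a, "to": b, "weight": w}
                for (a, b), w in sorted(deriv.inter_edges.items())
            ]
            pd.DataFrame(rows, columns=["from", "to", "weight"]).to_csv(
                out / f"derivative_{algo}.csv", index=False)
            nx.write_graphml(deriv.to_networkx(), out / f"derivative_{algo}.graphml")
            results[algo] = {"n_communities": part.n_communities,
                             "modularity": part.modularity}
        agreement = partition_agreement(partitions["louvain"], partitions["leiden"])
        results["louvain_vs_leiden_ari"] = agreement["ari"]
        results["seed"] = seed
        results["resolution"] = resolution
        return results
    if stage == "loops":
        loops, complete = enumerate_loops(
            cmap, int(params.get("max_length", 10)), int(params.get("max_count", 10_000)))
        payload = [
            {"cycle": l.cycle, "polarities": [p.value for p in l.polarities],
             "classification": l.classification}
            for l in loops
        ]
        (out / "loops.json").write_text(
            json.dumps({"complete": complete, "loops": payload}, indent=2) + "\n",
            encoding="utf-8")
        return {"n_loops": len(loops), "complete": complete}
    if stage == "paths":
        src, tgt = str(params["source"]), str(params["target"])
        mode = params.get("mode", "disjoint")
        if mode == "disjoint":
            pset = disjoint_paths(cmap, src, tgt)
        else:
            pset = all_paths(cmap, src, tgt,
                             int(params.get("max_length", 10)),
                             int(params.get("max_count", 10_000)))
        (out / "paths.json").write_text(json.dumps({
            "source": src, "target": tgt, "disjointness": pset.disjointness,
            "complete": pset.complete, "paths": pset.paths,
            "net_polarities": pset.net_polarities}, indent=2) + "\n", encoding="utf-8")
        return {"n_paths": len(pset), "mode": mode}
    if stage == "ripple":
        shells = ripple_shells(cmap, str(params["center"]), int(params.get("max_depth", 3)))
        (out / "ripple.json").write_text(json.dumps({
            "center": shells.center, "max_depth": shells.max_depth,
            "shells": {d: sorted(s) for d, s in sorted(shells.shells.items())}},
            indent=2) + "\n", encoding="utf-8")
        return {"n_reached": len(shells.reached())}
    if stage == "coding":
        table = CodingTable.read_csv(params["table"])
        coders = params.get("coders") or table.coders()[:2]
        result: dict = {"coders": coders}
        if len(coders) >= 2:
            a, b = coders[0], coders[1]
            agreement = {
                axis: aggregate_agreement(table, a, b, axis)["agreement_percent"]
                for axis in ("sem_level", "strategy")
            }
            (out / "agreement.json").write_text(
                json.dumps(agreement, indent=2) + "\n", encoding="utf-8")
            pd.DataFrame(conflict_report(table, a, b)).to_csv(
                out / "conflicts.csv", index=False)
            result["agreement_percent"] = agreement
        for coder in coders:
            heatmap_matrix(table, coder, total_nodes=cmap.n).round(4).to_csv(
                out / f"heatmap_{coder}.csv")
        return result
    raise AssertionError(f"unhandled stage {stage!r}")
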