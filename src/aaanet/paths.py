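"""Shortest interaction paths between a pair of proteins.

Enumerates ALL distinct shortest paths (not one arbitrary route) between a
source and a target and exports the induced subnetwork for visualization,
in SIF or JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import islice
from pathlib import Path

import networkx as nx

from .network import PPINetwork


@dataclass
class PathQueryResult:
    """Shortest paths between one source/target pair.

    ``status`` is "ok" or "disconnected"; ``truncated`` flags that more
    shortest paths existed than the requested cap.
    """

    source: str
    target: str
    paths: list[list[str]] = field(default_factory=list)
    status: str = "ok"
    truncated: bool = False

    @property
    def length(self) -> int | None:
        return len(self.paths[0]) - 1 if self.paths else None


def shortest_paths(
    net: PPINetwork, source: str, target: str, max_paths: int = 100
) -> PathQueryResult:
    """All distinct shortest source-target paths, lexicographically sorted.

    Returns an empty list with status "disconnected" when no path exists;
    collects at most ``max_paths`` paths and sets ``truncated`` when more
    exist.
    """
    net._require(source)
    net._require(target)
    if source == target:
        raise ValueError("source and target must differ")
    if max_paths < 1:
        raise ValueError("max_paths must be >= 1")
    try:
        gen = nx.all_shortest_paths(net.graph, source, target)
        collected = list(islice(gen, max_paths + 1))
    except nx.NetworkXNoPath:
        return PathQueryResult(source, target, [], status="disconnected")
    truncated = len(collected) > max_paths
    paths = sorted(collected)[:max_paths]
    return PathQueryResult(source, target, paths, status="ok", truncated=truncated)


def _path_edges(paths: list[list[str]]) -> set[tuple[str, str]]:
    edges = set()
    for p in paths:
        for a, b in zip(p, p[1:]):
            edges.add((a, b) if a <= b else (b, a))
    return edges


def export_path_subnetwork(
    net: PPINetwork,
    paths: list[list[str]],
    fmt: str,
    out_path: str | Path,
) -> None:
    """Write the union of path nodes/edges as SIF ("pp" interactions) or
    JSON (nodes carry a source/target/intermediate role tag).

    Every consecutive node pair in every path must be an edge of ``net``.
    """
    edges = _path_edges(paths)
    for e in edges:
        if not net.graph.has_edge(*e):
            raise ValueError(f"path edge {e} not present in the network")
    nodes = sorted({n for p in paths for n in p})
    if fmt == "sif":
        with open(out_path, "w") as fh:
            for a, b in sorted(edges):
                fh.write(f"{a}\tpp\t{b}\n")
    elif fmt == "json":
        endpoints_src = {p[0] for p in paths}
        endpoints_tgt = {p[-1] for p in paths}

        def role(n: str) -> str:
            if n in endpoints_src:
                return "source"
            if n in endpoints_tgt:
                return "target"
            return "intermediate"

        payload = {
            "nodes": [{"id": n, "role": role(n)} for n in nodes],
            "edges": [list(e) for e in sorted(edges)],
        }
        with open(out_path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'sif' or 'json'")
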