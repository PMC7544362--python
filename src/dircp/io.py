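"""Edge-list and partition readers/writers plus JSON detection reports.

Formats are deliberately plain text: two-column whitespace-separated edge
lists (``source target`` per line, ``#`` comments allowed), two-column TSV
partitions (``node<TAB>set``), and JSON reports.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .graph import BLOCK_NAMES, DirectedGraph, Partition, profile_log_likelihood
from .quality import MonteCarloResult, dcpm

logger = logging.getLogger("dircp")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


def read_edge_list(path: str | Path, allow_self_loops: bool = True) -> DirectedGraph:
    """Read a directed graph from a two-column edge list.

    Node labels are arbitrary strings, ordered by first appearance.  Blank
    lines and ``#`` comments are skipped.  Duplicate edges are collapsed and
    self-loops dropped when ``allow_self_loops`` is false; both are counted
    and logged as warnings.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    labels: dict[str, int] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        tokens = stripped.split()
        if len(tokens) != 2:
            raise DataError(
                f"{path}:{lineno}: expected 'source target', got {line.strip()!r}"
            )
        for tok in tokens:
            labels.setdefault(tok, len(labels))
        edges.append((tokens[0], tokens[1]))
    if not labels:
        raise DataError(f"{path}: empty edge list")

    n = len(labels)
    adjacency = np.zeros((n, n), dtype=np.int8)
    duplicates = 0
    dropped_loops = 0
    for src, dst in edges:
        u, v = labels[src], labels[dst]
        if u == v and not allow_self_loops:
            dropped_loops += 1
            continue
        if adjacency[u, v]:
            duplicates += 1
        adjacency[u, v] = 1
    if duplicates:
        logger.warning("%s: collapsed %d duplicate edge(s)", path, duplicates)
    if dropped_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, dropped_loops)
    return DirectedGraph(adjacency, tuple(labels))


def write_edge_list(path: str | Path, graph: DirectedGraph) -> None:
    lines = [
        f"{graph.node_labels[u]}\t{graph.node_labels[v]}"
        for u, v in np.argwhere(graph.adjacency == 1)
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_partition(path: str | Path, graph: DirectedGraph, partition: Partition) -> None:
    """Write ``node<TAB>set`` lines in graph node order."""
    if partition.n != graph.n:
        raise DataError("partition does not cover the graph")
    lines = [
        f"{label}\t{BLOCK_NAMES[code]}"
        for label, code in zip(graph.node_labels, partition.labels)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_partition(path: str | Path, graph: DirectedGraph) -> Partition:
    """Read a ``node<TAB>set`` partition; must cover the graph exactly."""
    path = Path(path)
    assigned: dict[str, int] = {}
    name_to_code = {name: i for i, name in enumerate(BLOCK_NAMES)}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        tokens = stripped.split("\t") if "\t" in stripped else stripped.split()
        if len(tokens) != 2:
            raise DataError(f"{path}:{lineno}: expected 'node<TAB>set'")
        node, set_name = tokens
        if set_name not in name_to_code:
            raise DataError(
                f"{path}:{lineno}: unknown set name {set_name!r} "
                f"(expected one of {BLOCK_NAMES})"
            )
        if node not in graph.node_labels:
            raise DataError(f"{path}:{lineno}: node {node!r} not in graph")
        assigned[node] = name_to_code[set_name]
    missing = [lbl for lbl in graph.node_labels if lbl not in assigned]
    if missing:
        raise DataError(f"{path}: missing assignment for node(s) {missing}")
    labels = np.array([assigned[lbl] for lbl in graph.node_labels], dtype=np.int64)
    return Partition(labels)


def build_report(
    graph: DirectedGraph,
    partition: Partition,
    detector_name: str,
    seed: int,
    mc_results: list[MonteCarloResult] | None = None,
) -> dict:
    """JSON-serializable detection report with likelihood and quality figures."""
    ll, p1_hat, p2_hat = profile_log_likelihood(graph, partition)
    report = {
        "version": __version__,
        "detector": detector_name,
        "seed": int(seed),
        "n": graph.n,
        "m": graph.m,
        "set_sizes": {name: int(c) for name, c in zip(BLOCK_NAMES, partition.sizes)},
        "log_likelihood": ll,
        "p1_hat": p1_hat,
        "p2_hat": p2_hat,
        "dcpm": dcpm(graph, partition) if graph.m else None,
    }
    if mc_results:
        report["monte_carlo"] = [
            {
                "null_model": r.null_model,
                "replicates": r.replicates,
                "observed_statistic": r.observed_statistic,
                "p_value": r.p_value,
            }
            for r in mc_results
        ]
    return report


def write_report(path: str | Path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
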