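"""Partition-quality measures and the Monte Carlo significance test.

Two measures assess a detected "L" partition when no ground truth exists:

* **DCPM** (directed core-periphery modularity): the mean-centred edge mass
  aligned with the "L" mask, normalized by edge count,
  ``DCPM(g) = (1/m) * sum_{u,v} (A_uv - m/n^2) * M_{g_u, g_v}``; it lies in
  (-1, 1), is 0 for a single-block partition, and equals ``1 - m/n^2`` for
  the perfect "L".
* **L-statistic**: the edge density on within-"L" ordered pairs minus the
  density on off-"L" pairs; this is the Monte Carlo test statistic.

The Monte Carlo test re-runs a detector on null replicates (directed
Erdos-Renyi with the observed edge count, or a degree-preserving directed
configuration model) and compares the observed L-statistic with the null
sample.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Mapping

import numpy as np

from .advhits import detect_advhits
from .assign import detect_degree_baseline
from .graph import (
    BLOCK_MASK,
    DirectedGraph,
    Partition,
    block_edge_counts,
    mask_pair_count,
)
from .hits import detect_hits
from .maxlike import detect_maxlike

#: Detector registry shared by the Monte Carlo test, benchmarks and the CLI.
DETECTORS: Mapping[str, Callable[..., Partition]] = {
    "hits": detect_hits,
    "advhits": detect_advhits,
    "maxlike": detect_maxlike,
    "degree": detect_degree_baseline,
}


@dataclasses.dataclass(frozen=True)
class MonteCarloResult:
    """Outcome of a Monte Carlo significance test of a detected partition."""

    observed_statistic: float
    null_statistics: np.ndarray
    p_value: float
    null_model: str
    replicates: int
    detector_name: str


def _mask_counts(graph: DirectedGraph, partition: Partition) -> tuple[float, float, float, float]:
    if partition.n != graph.n:
        raise ValueError("partition does not cover the graph")
    counts = block_edge_counts(graph.adjacency, partition.labels)
    e1 = float((counts * BLOCK_MASK).sum())
    n1 = float(mask_pair_count(partition.sizes))
    return e1, n1, float(graph.m) - e1, float(graph.n) ** 2 - n1


def dcpm(graph: DirectedGraph, partition: Partition) -> float:
    """Directed core-periphery modularity of a partition.

    Sums ``A_uv - m/n^2`` over ordered pairs on the "L" mask (diagonal
    included) and divides by ``m``.  Undefined (raises) for an edgeless graph.
    """
    if graph.m == 0:
        raise ValueError("DCPM is undefined for an edgeless graph")
    e1, n1, _, _ = _mask_counts(graph, partition)
    m = float(graph.m)
    return float((e1 - (m / float(graph.n) ** 2) * n1) / m)


def l_statistic(graph: DirectedGraph, partition: Partition) -> float:
    """Within-"L" edge density minus off-"L" edge density, in [-1, 1].

    Raises for degenerate partitions where one of the two ordered-pair
    classes is empty (the contrast is then undefined and must not be
    silently reported as 0).
    """
    e1, n1, e2, n2 = _mask_counts(graph, partition)
    if n1 == 0 or n2 == 0:
        raise ValueError("L-statistic undefined: a pair class is empty")
    return float(e1 / n1 - e2 / n2)


def sample_er_null(n: int, m: int, seed: int) -> DirectedGraph:
    """Directed Erdos-Renyi null without self-loops and with exactly m edges.

    The ``m`` edges are placed uniformly at random without replacement among
    the ``n * (n - 1)`` ordered non-self pairs.
    """
    n = int(n)
    m = int(m)
    if n < 1:
        raise ValueError("need at least one node")
    if not 0 <= m <= n * (n - 1):
        raise ValueError(f"edge count {m} outside [0, {n * (n - 1)}]")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n * (n - 1), size=m, replace=False)
    src, off = np.divmod(chosen, n - 1)
    dst = np.where(off >= src, off + 1, off)  # skip the diagonal
    adjacency = np.zeros((n, n), dtype=np.int8)
    adjacency[src, dst] = 1
    return DirectedGraph(adjacency, tuple(f"v{i}" for i in range(n)))


def sample_config_null(
    graph: DirectedGraph, seed: int, swap_factor: int = 10
) -> DirectedGraph:
    """Degree-preserving randomization by directed double-edge swaps.

    Performs ``swap_factor * m`` attempted swaps ``(a->b, c->d) =>
    (a->d, c->b)``, rejecting any swap that would create a self-loop or a
    duplicate edge, so the output is a simple digraph with exactly the input
    in- and out-degree sequences.
    """
    rng = np.random.default_rng(seed)
    edges = np.argwhere(graph.adjacency == 1)
    m = edges.shape[0]
    if m < 2:
        return DirectedGraph(graph.adjacency.copy(), graph.node_labels)
    edge_set = {(int(a), int(b)) for a, b in edges}
    edges = [tuple(int(x) for x in e) for e in edges]
    attempts = int(swap_factor) * m
    idx = rng.integers(0, m, size=(attempts, 2))
    for e1_i, e2_i in idx:
        if e1_i == e2_i:
            continue
        a, b = edges[e1_i]
        c, d = edges[e2_i]
        if a == d or c == b:
            continue
        if (a, d) in edge_set or (c, b) in edge_set:
            continue
        edge_set.discard((a, b))
        edge_set.discard((c, d))
        edge_set.add((a, d))
        edge_set.add((c, b))
        edges[e1_i] = (a, d)
        edges[e2_i] = (c, b)
    adjacency = np.zeros_like(graph.adjacency)
    arr = np.array(edges)
    adjacency[arr[:, 0], arr[:, 1]] = 1
    return DirectedGraph(adjacency, graph.node_labels)


def _resolve_detector(detector) -> tuple[str, Callable[..., Partition]]:
    if callable(detector):
        return getattr(detector, "__name__", "custom"), detector
    name = str(detector).lower()
    if name not in DETECTORS:
        raise ValueError(
            f"unknown detector {detector!r}; choose from {sorted(DETECTORS)}"
        )
    return name, DETECTORS[name]


def monte_carlo_test(
    graph: DirectedGraph,
    detector,
    null_model: str = "er",
    replicates: int = 250,
    seed: int = 0,
    swap_factor: int = 10,
) -> MonteCarloResult:
    """Monte Carlo significance test of the structure a detector finds.

    The observed statistic is the L-statistic of the detector's partition of
    ``graph``.  Each replicate draws a null graph (``er``: directed ER with
    the same n and m; ``config``: degree-preserving edge-swap randomization),
    re-runs the same detector on it and records its L-statistic.  The exact
    Monte Carlo p-value is ``(1 + #{null >= observed}) / (1 + R)``, with
    floor ``1/(R+1)``.  A replicate whose detection or statistic fails is
    resampled once and then scored conservatively as -1.
    """
    if null_model not in ("er", "config"):
        raise ValueError("null_model must be 'er' or 'config'")
    if replicates < 1:
        raise ValueError("need at least one null replicate")
    name, det = _resolve_detector(detector)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(2 * replicates + 1, dtype=np.uint64) % (2**31)

    observed_part = det(graph, seed=int(seeds[0]))
    observed = l_statistic(graph, observed_part)

    null_stats = np.empty(replicates, dtype=np.float64)
    for r in range(replicates):
        base = int(seeds[1 + 2 * r])
        det_seed = int(seeds[2 + 2 * r])
        stat = -1.0
        for attempt in range(2):
            try:
                if null_model == "er":
                    g0 = sample_er_null(graph.n, graph.m, seed=base + attempt)
                else:
                    g0 = sample_config_null(graph, seed=base + attempt, swap_factor=swap_factor)
                stat = l_statistic(g0, det(g0, seed=det_seed))
                break
            except ValueError:
                continue
        null_stats[r] = stat

    p_value = (1.0 + float((null_stats >= observed).sum())) / (1.0 + replicates)
    return MonteCarloResult(
        observed_statistic=float(observed),
        null_statistics=null_stats,
        p_value=float(p_value),
        null_model=null_model,
        replicates=int(replicates),
        detector_name=name,
    )
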