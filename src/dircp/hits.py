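"""Hits detector: hub/authority scores clustered into the four "L" sets.

Hub and authority scores are the principal left/right singular vectors of the
adjacency matrix (equivalently, the fixed point of the alternating iteration
``a <- A^T h``, ``h <- A a`` with normalization).  Authorities are heavily
pointed-to nodes and align with core-in; hubs point at many authorities and
align with core-out.  Periphery affinities are the complements
``max(score) - score``: a node far from the top authority is periphery-out
material, a node far from the top hub periphery-in material.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .assign import assign_clusters_to_sets, kmeans_pp
from .graph import DirectedGraph, Partition


@dataclasses.dataclass(frozen=True)
class HitsScores:
    """Unit-norm, non-negative authority and hub vectors."""

    authority: np.ndarray
    hub: np.ndarray


def _leading_eigenvector(matvec, n: int, tol: float = 1e-13, max_iter: int = 10000) -> np.ndarray:
    # Deterministic power iteration from the all-ones vector.  For a
    # non-negative symmetric operator the Perron eigenvector is non-negative,
    # so the start vector is never orthogonal to the leading eigenspace; on a
    # degenerate leading eigenspace this converges to the (deterministic)
    # projection of the start vector.
    x = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        y = matvec(x)
        norm = np.linalg.norm(y)
        if norm == 0.0:
            return x
        y /= norm
        if np.abs(y - x).max() < tol:
            return y
        x = y
    return x


def compute_hits(graph: DirectedGraph) -> HitsScores:
    """Principal singular-vector hub/authority scores of the adjacency matrix.

    Raises a ``ValueError`` on an edgeless graph, where the scores carry no
    structure.
    """
    if graph.m == 0:
        raise ValueError("HITS scores are undefined for an edgeless graph")
    adj = graph.adjacency.astype(np.float64)
    authority = _leading_eigenvector(lambda x: adj.T @ (adj @ x), graph.n)
    authority = np.clip(authority, 0.0, None)
    authority /= np.linalg.norm(authority)
    hub = adj @ authority
    hub_norm = np.linalg.norm(hub)
    if hub_norm == 0.0:  # cannot happen for m >= 1; keep defensive
        hub = np.full(graph.n, 1.0 / np.sqrt(graph.n))
    else:
        hub /= hub_norm
    return HitsScores(authority=authority, hub=hub)


def hits_score_matrix(scores: HitsScores) -> np.ndarray:
    """Four-column set-affinity matrix from hub/authority scores.

    Columns, in block order: ``Pout = max(a) - a``, ``Cin = a``,
    ``Cout = h``, ``Pin = max(h) - h``; every row is then rescaled to unit
    Euclidean norm.
    """
    a = np.asarray(scores.authority, dtype=np.float64)
    h = np.asarray(scores.hub, dtype=np.float64)
    mat = np.column_stack([a.max() - a, a, h, h.max() - h])
    norms = np.linalg.norm(mat, axis=1)
    norms[norms == 0.0] = 1.0  # impossible for a graph with >= 1 edge
    return mat / norms[:, None]


def detect_hits(graph: DirectedGraph, seed: int) -> Partition:
    """Full Hits pipeline: scores -> score matrix -> k-means++ -> set naming."""
    scores = compute_hits(graph)
    mat = hits_score_matrix(scores)
    clusters = kmeans_pp(mat, seed=seed)
    return assign_clusters_to_sets(graph, clusters)
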