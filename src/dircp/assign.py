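"""Shared final stages of every detector.

All detectors reduce a graph to a per-node score matrix, cluster the rows
with k-means++ into (at most) four clusters, and then name the anonymous
clusters by choosing, over all injective maps from occupied clusters into
``{Pout, Cin, Cout, Pin}``, the one maximizing the DCP profile likelihood.
The naive degree baseline lives here too: it clusters nodes on their raw
(in-degree, out-degree) pairs and names the clusters the same way.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
from sklearn.cluster import KMeans

from .graph import (
    BLOCK_MASK,
    DirectedGraph,
    Partition,
    block_edge_counts,
    loglik_from_counts,
)


def kmeans_pp(scores: np.ndarray, seed: int, n_init: int = 10) -> np.ndarray:
    """Cluster score rows with k-means++ into four clusters.

    Returns integer cluster labels in ``{0, .., 3}``.  Uses Lloyd iterations
    from k-means++ seeding, keeping the best of ``n_init`` initializations by
    within-cluster sum of squares; deterministic given ``seed``.  With fewer
    than four nodes, k equals the node count; with coincident rows fewer than
    four clusters may end up occupied.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim != 2 or scores.shape[0] < 1:
        raise ValueError("score matrix must be a non-empty 2-d array")
    k = min(4, scores.shape[0])
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        max_iter=300,
        tol=1e-6,
        random_state=int(seed) % (2**32),
    )
    with warnings.catch_warnings():
        # duplicate rows legitimately yield fewer distinct clusters
        warnings.simplefilter("ignore")
        labels = km.fit_predict(scores)
    return labels.astype(np.int64)


def assign_clusters_to_sets(graph: DirectedGraph, clusters: np.ndarray) -> Partition:
    """Name anonymous clusters by maximum DCP profile likelihood.

    Enumerates every injective map from the occupied clusters into the four
    set names (24 maps when four clusters are occupied) and returns the
    partition with the largest profile log-likelihood.  Exact likelihood ties
    are broken by the lexicographically smallest map in block order, so the
    result is deterministic and invariant to renaming cluster integers.
    """
    clusters = np.asarray(clusters, dtype=np.int64)
    if clusters.size != graph.n:
        raise ValueError("cluster labels must cover every node of the graph")
    occupied, compact = np.unique(clusters, return_inverse=True)
    k = occupied.size
    if k > 4:
        raise ValueError("at most four clusters are supported")
    counts = block_edge_counts(graph.adjacency, compact, k=k)
    sizes = np.bincount(compact, minlength=k).astype(np.float64)
    m = float(graph.m)
    n_sq = float(graph.n) ** 2

    best_ll = -np.inf
    best_map: tuple[int, ...] | None = None
    for blocks in itertools.permutations(range(4), k):
        sub = BLOCK_MASK[np.ix_(blocks, blocks)]
        e1 = float((counts * sub).sum())
        n1 = float((np.outer(sizes, sizes) * sub).sum())
        ll, _, _ = loglik_from_counts(e1, n1, m - e1, n_sq - n1)
        if ll > best_ll:  # strict: first (lexicographic) map wins ties
            best_ll = ll
            best_map = blocks
    assert best_map is not None
    mapping = np.array(best_map, dtype=np.int64)
    return Partition(mapping[compact])


def detect_degree_baseline(graph: DirectedGraph, seed: int) -> Partition:
    """Naive classifier: k-means++ on raw (in-degree, out-degree) features."""
    feats = np.column_stack([graph.in_degrees, graph.out_degrees]).astype(np.float64)
    clusters = kmeans_pp(feats, seed=seed)
    return assign_clusters_to_sets(graph, clusters)
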