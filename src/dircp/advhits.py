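"""AdvHits detector: iterative four-score propagation with a reward-penalty matrix.

Instead of deriving periphery affinities from hub/authority scores, AdvHits
maintains one affinity score per node per set and propagates them through the
graph.  An edge (or missing edge) between u and v rewards the affinity of u
for set i when it matches the idealized "L" block pattern and penalizes it
otherwise, encoded by the +-1 reward-penalty matrix ``D = 2*M - 1`` where M is
the block mask.  Present and missing edges are weighted by ``1 - m/n^2`` and
``m/n^2`` respectively, so each class contributes equally in expectation.
"""

from __future__ import annotations

import numpy as np

from .assign import assign_clusters_to_sets, kmeans_pp
from .graph import BLOCK_MASK, DirectedGraph, Partition

#: Denominator threshold under which a node's four raw scores are treated as
#: equal and its normalized affinities set to 1/4 each.
_UNIFORM_EPS = 1e-10


def reward_penalty_matrix() -> np.ndarray:
    """The 4x4 +-1 reward-penalty matrix ``D = 2*mask - 1``.

    Row ``i`` of D (``e_i``) scores outgoing edges of a set-``i`` candidate;
    column ``i`` (``d_i``) scores its incoming edges.
    """
    return (2 * BLOCK_MASK - 1).astype(np.float64)


def normalize_scores(raw: np.ndarray) -> np.ndarray:
    """Shift-and-rescale each row of a raw score matrix onto the simplex.

    Per node the row minimum ``B(u)`` is subtracted and the row divided by
    its new sum, so entries are non-negative and sum to one.  Rows whose
    shifted sum falls below ``1e-10`` (all four scores equal up to floating
    point error) get the uninformative affinity ``(1/4, 1/4, 1/4, 1/4)``.
    """
    raw = np.asarray(raw, dtype=np.float64)
    shifted = raw - raw.min(axis=1, keepdims=True)
    denom = shifted.sum(axis=1, keepdims=True)
    flat = denom[:, 0] < _UNIFORM_EPS
    out = np.empty_like(shifted)
    safe = np.where(denom < _UNIFORM_EPS, 1.0, denom)
    out[:] = shifted / safe
    out[flat] = 0.25
    return out


def raw_update(
    graph: DirectedGraph, s_nrm: np.ndarray, d: np.ndarray, i: int
) -> np.ndarray:
    """One raw-score column update for set ``i``.

    With ``w1 = 1 - m/n^2`` and ``w2 = m/n^2``, the new raw score of node u
    for set i sums four terms over all ordered pairs involving u: present
    out-edges weighted by ``w1`` against ``e_i`` (row i of D), missing
    out-edges by ``-w2`` against ``e_i``, present in-edges by ``w1`` against
    ``d_i`` (column i of D), and missing in-edges by ``-w2`` against ``d_i``.
    The all-ones matrix implicit in the missing-edge terms includes the
    diagonal (self-pairs are part of the model).
    """
    adj = graph.adjacency.astype(np.float64)
    n = graph.n
    w2 = graph.m / float(n * n)
    w1 = 1.0 - w2
    se = s_nrm @ d[i, :]  # S e_i^T
    sd = s_nrm @ d[:, i]  # S d_i
    a_se = adj @ se
    at_sd = adj.T @ sd
    # (J - A) @ x == sum(x) - A @ x, J the all-ones matrix incl. diagonal
    out_term = w1 * a_se - w2 * (se.sum() - a_se)
    in_term = w1 * at_sd - w2 * (sd.sum() - at_sd)
    return out_term + in_term


def _node_update(
    adj: np.ndarray, w1: float, w2: float, s_nrm: np.ndarray, d: np.ndarray, u: int
) -> np.ndarray:
    """All four raw scores of node ``u`` under the current normalized scores."""
    se = s_nrm @ d.T  # column i is S e_i^T
    sd = s_nrm @ d  # column i is S d_i
    row = adj[u, :]
    col = adj[:, u]
    out_term = w1 * (row @ se) - w2 * (se.sum(axis=0) - row @ se)
    in_term = w1 * (col @ sd) - w2 * (sd.sum(axis=0) - col @ sd)
    return out_term + in_term


def advhits_scores(
    graph: DirectedGraph,
    seed: int,
    tol: float = 1e-8,
    max_sync_iters: int = 1000,
) -> np.ndarray:
    """Converged normalized n x 4 AdvHits affinity matrix.

    Raw scores start i.i.d. uniform(0, 1).  Each synchronous outer iteration
    updates the four raw columns in block order Gauss-Seidel style,
    renormalizing after every column and recording the largest entrywise
    change of the normalized matrix; iteration stops when the largest change
    in an outer iteration falls below ``tol``.  If the synchronous scheme has
    not converged after ``max_sync_iters`` iterations, an asynchronous
    fallback updates one node's four scores (and renormalizes that row) at a
    time, in ascending node order, capped at the same number of sweeps.
    """
    rng = np.random.default_rng(seed)
    d = reward_penalty_matrix()
    raw = rng.uniform(0.0, 1.0, size=(graph.n, 4))
    s_nrm = normalize_scores(raw)

    for _ in range(max_sync_iters):
        largest = 0.0
        for i in range(4):
            raw[:, i] = raw_update(graph, s_nrm, d, i)
            new_nrm = normalize_scores(raw)
            largest = max(largest, float(np.abs(new_nrm - s_nrm).max()))
            s_nrm = new_nrm
        if largest < tol:
            return s_nrm

    # Asynchronous fallback: node-by-node updates, forced termination.
    adj = graph.adjacency.astype(np.float64)
    w2 = graph.m / float(graph.n**2)
    w1 = 1.0 - w2
    for _ in range(max_sync_iters):
        largest = 0.0
        for u in range(graph.n):
            raw[u, :] = _node_update(adj, w1, w2, s_nrm, d, u)
            new_row = normalize_scores(raw[u : u + 1, :])[0]
            largest = max(largest, float(np.abs(new_row - s_nrm[u]).max()))
            s_nrm[u] = new_row
        if largest < tol:
            break
    return s_nrm


def detect_advhits(
    graph: DirectedGraph,
    seed: int,
    tol: float = 1e-8,
    max_sync_iters: int = 1000,
) -> Partition:
    """Full AdvHits pipeline: propagate scores, cluster, name the clusters."""
    s_nrm = advhits_scores(graph, seed=seed, tol=tol, max_sync_iters=max_sync_iters)
    clusters = kmeans_pp(s_nrm, seed=seed)
    return assign_clusters_to_sets(graph, clusters)
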