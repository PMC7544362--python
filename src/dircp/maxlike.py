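"""MaxLike detector: Kernighan-Lin single-node-move profile-likelihood ascent.

The detector fits the DCP(p1, p2) block model by maximizing the two-parameter
profile log-likelihood over hard partitions.  A sweep moves every node exactly
once: at each step the single best (node, new set) move over still-unlocked
nodes is applied -- even when it worsens the likelihood -- the node is locked,
and the best state seen during the sweep (including its start) is kept.
Sweeps repeat until one fails to improve, and the whole search restarts from
several uniform-random initial partitions, returning the best result.

Move evaluation is O(1) via cached per-node block edge counts.
"""

from __future__ import annotations

import numpy as np
from scipy.special import xlogy

from .graph import (
    BLOCK_MASK,
    DirectedGraph,
    Partition,
    block_edge_counts,
    loglik_from_counts,
    mask_pair_count,
)


# _MOVE_DELTA[r, s] is the size-vector change of moving one node from r to s;
# used to vectorize the closed-form mask pair count a*b + b^2 + c*b + c^2 + c*d.
_MOVE_DELTA = (-np.eye(4)[:, None, :] + np.eye(4)[None, :, :]).astype(np.float64)


class BlockCountCache:
    """Per-node out/in edge counts into each block, plus global mask totals.

    ``ko[v, b]`` counts out-edges of ``v`` to nodes other than ``v`` in block
    ``b``; ``kin[v, b]`` the in-edge analogue; self-loops are tracked
    separately so they are not double counted.  ``e1`` is the total edge count
    on mask blocks for the current labels.
    """

    def __init__(self, graph: DirectedGraph, labels: np.ndarray) -> None:
        adj = graph.adjacency.astype(np.float64)
        self.adjacency = adj
        self.n = graph.n
        self.m = float(graph.m)
        self.labels = np.asarray(labels, dtype=np.int64).copy()
        self.self_loop = np.diag(adj).copy()
        onehot = np.eye(4)[self.labels]
        self.ko = adj @ onehot
        self.kin = adj.T @ onehot
        # remove each node's own self-loop from its out/in counts
        self.ko[np.arange(self.n), self.labels] -= self.self_loop
        self.kin[np.arange(self.n), self.labels] -= self.self_loop
        self.sizes = np.bincount(self.labels, minlength=4).astype(np.int64)
        counts = block_edge_counts(graph.adjacency, self.labels)
        self.e1 = float((counts * BLOCK_MASK).sum())

    # -- derived quantities -------------------------------------------------
    @property
    def n1(self) -> int:
        return mask_pair_count(self.sizes)

    def loglik(self) -> float:
        n_sq = float(self.n) ** 2
        ll, _, _ = loglik_from_counts(
            self.e1, float(self.n1), self.m - self.e1, n_sq - float(self.n1)
        )
        return ll

    def node_mask_contrib(self) -> np.ndarray:
        """``C[v, c]``: edges incident to ``v`` on mask blocks were ``v`` in ``c``."""
        diag = np.diag(BLOCK_MASK).astype(np.float64)
        return (
            self.ko @ BLOCK_MASK.T.astype(np.float64)
            + self.kin @ BLOCK_MASK.astype(np.float64)
            + self.self_loop[:, None] * diag[None, :]
        )

    def n1_table(self) -> np.ndarray:
        """``N1_table[r, s]``: mask pair count after moving one node r -> s."""
        sz = self.sizes[None, None, :] + _MOVE_DELTA
        a, b, c, d = sz[..., 0], sz[..., 1], sz[..., 2], sz[..., 3]
        return a * b + b * b + c * b + c * c + c * d

    def move(self, node: int, new_label: int) -> None:
        """Apply a single-node move and update every cached count."""
        old = int(self.labels[node])
        if new_label == old:
            return
        contrib = self._contrib_single(node)
        self.e1 += contrib[new_label] - contrib[old]
        row = self.adjacency[node, :].copy()
        col = self.adjacency[:, node].copy()
        row[node] = 0.0
        col[node] = 0.0
        out_nb = np.flatnonzero(row)
        in_nb = np.flatnonzero(col)
        self.kin[out_nb, old] -= 1.0
        self.kin[out_nb, new_label] += 1.0
        self.ko[in_nb, old] -= 1.0
        self.ko[in_nb, new_label] += 1.0
        self.sizes[old] -= 1
        self.sizes[new_label] += 1
        self.labels[node] = new_label

    def _contrib_single(self, node: int) -> np.ndarray:
        diag = np.diag(BLOCK_MASK).astype(np.float64)
        return (
            BLOCK_MASK.astype(np.float64) @ self.ko[node]
            + BLOCK_MASK.T.astype(np.float64) @ self.kin[node]
            + self.self_loop[node] * diag
        )


def _loglik_grid(e1: np.ndarray, n1: np.ndarray, m: float, n_sq: float) -> np.ndarray:
    """Vectorized profile log-likelihood over arrays of (E1, N1) counts."""
    e2 = m - e1
    n2 = n_sq - n1
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(n1 > 0, e1 / np.where(n1 > 0, n1, 1.0), 0.0)
        p2 = np.where(n2 > 0, e2 / np.where(n2 > 0, n2, 1.0), 0.0)
    return (
        xlogy(e1, p1)
        + xlogy(n1 - e1, 1.0 - p1)
        + xlogy(e2, p2)
        + xlogy(n2 - e2, 1.0 - p2)
    )


def delta_log_likelihood(
    graph: DirectedGraph,
    partition: Partition,
    cache: BlockCountCache,
    node: int,
    new_label: int,
) -> float:
    """Likelihood change of moving ``node`` to ``new_label``, from cached counts."""
    old = int(cache.labels[node])
    if new_label == old:
        return 0.0
    contrib = cache._contrib_single(node)
    e1_new = cache.e1 + contrib[new_label] - contrib[old]
    sizes = cache.sizes.copy()
    sizes[old] -= 1
    sizes[new_label] += 1
    n1_new = float(mask_pair_count(sizes))
    n_sq = float(cache.n) ** 2
    ll_new, _, _ = loglik_from_counts(
        float(e1_new), n1_new, cache.m - float(e1_new), n_sq - n1_new
    )
    return ll_new - cache.loglik()


def kl_sweep(graph: DirectedGraph, partition: Partition) -> tuple[Partition, float]:
    """One Kernighan-Lin sweep from ``partition``.

    Every node is moved exactly once (single best move over unlocked nodes,
    negative moves included) and locked; the best-likelihood state seen during
    the sweep, the start included, is returned together with its likelihood.
    Ties keep the earlier state; equal-delta moves prefer the lowest node
    index, then block order.
    """
    n = graph.n
    cache = BlockCountCache(graph, partition.labels)
    n_sq = float(n) ** 2
    ll_run = cache.loglik()
    best_ll = ll_run
    best_labels = cache.labels.copy()
    locked = np.zeros(n, dtype=bool)
    rows = np.arange(n)

    for _ in range(n):
        contrib = cache.node_mask_contrib()
        e1_new = cache.e1 + contrib - contrib[rows, cache.labels][:, None]
        n1_new = cache.n1_table()[cache.labels]
        ll_new = _loglik_grid(e1_new, n1_new, cache.m, n_sq)
        ll_new[rows, cache.labels] = -np.inf
        ll_new[locked, :] = -np.inf
        flat = int(np.argmax(ll_new))
        node, label = divmod(flat, 4)
        ll_run = float(ll_new[node, label])
        cache.move(node, label)
        locked[node] = True
        if ll_run > best_ll:
            best_ll = ll_run
            best_labels = cache.labels.copy()

    return Partition(best_labels), float(best_ll)


def _ascend(graph: DirectedGraph, labels: np.ndarray, tol: float = 1e-10) -> tuple[Partition, float]:
    current = Partition(labels)
    cur_ll = BlockCountCache(graph, labels).loglik()
    while True:
        nxt, ll = kl_sweep(graph, current)
        if ll > cur_ll + tol:
            current, cur_ll = nxt, ll
        else:
            return current, cur_ll


def detect_maxlike(
    graph: DirectedGraph, seed: int, n_restarts: int = 11
) -> Partition:
    """MaxLike detector: repeated KL sweeps from uniform-random restarts.

    Each restart draws i.i.d. uniform set labels, runs sweeps until one fails
    to improve the likelihood by more than ``1e-10``, and the best partition
    over all restarts is returned (ties keep the earlier restart).
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    best: Partition | None = None
    best_ll = -np.inf
    for _ in range(n_restarts):
        labels = rng.integers(0, 4, size=graph.n)
        part, ll = _ascend(graph, labels)
        if ll > best_ll:
            best, best_ll = part, ll
    assert best is not None
    return best
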