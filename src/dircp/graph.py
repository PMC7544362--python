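"""Core data model for directed core-periphery analysis.

A directed core-periphery ("L") structure partitions the nodes of a directed
graph into four sets,

* ``Pout`` -- periphery-out: sends edges into the core-in set only,
* ``Cin``  -- core-in: densely receives from everything but ``Pin``, and is
  internally dense,
* ``Cout`` -- core-out: densely sends to all receiving sets, internally dense,
* ``Pin``  -- periphery-in: receives from core-out only.

The idealized 4x4 block indicator matrix of this structure has ones exactly on
the blocks (Pout->Cin), (Cin->Cin), (Cout->Cin), (Cout->Cout) and (Cout->Pin);
drawn as a matrix these ones trace out an "L".

This module holds the graph/partition containers, the block mask, the
two-parameter stochastic block model ``DCP(p1, p2)`` used as the synthetic
benchmark generator, and the two-parameter profile log-likelihood that every
detector uses to map anonymous clusters onto the four named sets.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.special import xlogy

#: Canonical block order used everywhere in this package.
BLOCK_NAMES: tuple[str, str, str, str] = ("Pout", "Cin", "Cout", "Pin")

POUT, CIN, COUT, PIN = range(4)

_NAME_TO_BLOCK = {name: i for i, name in enumerate(BLOCK_NAMES)}


def build_block_mask() -> np.ndarray:
    """Return the idealized 4x4 binary block mask of the "L" structure.

    Rows index the source block and columns the target block, both in the
    order ``(Pout, Cin, Cout, Pin)``.  Exactly five entries are one:
    Pout->Cin, Cin->Cin, Cout->Cin, Cout->Cout and Cout->Pin.
    """
    mask = np.zeros((4, 4), dtype=np.int64)
    mask[POUT, CIN] = 1
    mask[CIN, CIN] = 1
    mask[COUT, CIN] = 1
    mask[COUT, COUT] = 1
    mask[COUT, PIN] = 1
    return mask


#: Module-level copy of the mask; treat as read-only.
BLOCK_MASK = build_block_mask()
BLOCK_MASK.setflags(write=False)


@dataclasses.dataclass(frozen=True)
class DirectedGraph:
    """A directed, unweighted graph held as a dense binary adjacency matrix.

    Parameters
    ----------
    adjacency : (n, n) array of {0, 1}
        ``adjacency[u, v] == 1`` iff there is an edge ``u -> v``.  Self-loops
        (diagonal ones) are permitted; multi-edges are not representable.
    node_labels : sequence of str
        Distinct node identifiers, one per row of ``adjacency``.
    """

    adjacency: np.ndarray
    node_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if adj.shape[0] < 1:
            raise ValueError("graph must have at least one node")
        vals = np.unique(adj)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        labels = tuple(str(x) for x in self.node_labels)
        if len(labels) != adj.shape[0]:
            raise ValueError("node_labels length must match adjacency size")
        if len(set(labels)) != len(labels):
            raise ValueError("node labels must be distinct")
        object.__setattr__(self, "adjacency", adj.astype(np.int8))
        object.__setattr__(self, "node_labels", labels)

    @property
    def n(self) -> int:
        """Number of nodes."""
        return self.adjacency.shape[0]

    @property
    def m(self) -> int:
        """Number of directed edges (a reciprocated pair contributes 2)."""
        return int(self.adjacency.sum())

    @property
    def in_degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=0), dtype=np.int64)

    @property
    def out_degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1), dtype=np.int64)

    def index_of(self, label: str) -> int:
        return self.node_labels.index(label)


@dataclasses.dataclass(frozen=True)
class Partition:
    """A hard assignment of every node to one of the four named sets.

    ``labels`` holds integer codes in {0, 1, 2, 3} following ``BLOCK_NAMES``
    order.  Empty sets are allowed (detectors may output fewer than four
    occupied sets on degenerate graphs).
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.array(self.labels, dtype=np.int64)  # copy: never freeze caller's array
        if lab.ndim != 1 or lab.size < 1:
            raise ValueError("labels must be a non-empty 1-d vector")
        if lab.min() < 0 or lab.max() > 3:
            raise ValueError("labels must take values in {0, 1, 2, 3}")
        lab.setflags(write=False)
        object.__setattr__(self, "labels", lab)

    @classmethod
    def from_names(cls, names: Sequence[str]) -> "Partition":
        """Build a partition from set names (``Pout``/``Cin``/``Cout``/``Pin``)."""
        try:
            codes = [_NAME_TO_BLOCK[str(s)] for s in names]
        except KeyError as exc:  # pragma: no cover - message only
            raise ValueError(f"unknown set name: {exc.args[0]!r}") from exc
        return cls(np.array(codes, dtype=np.int64))

    @property
    def n(self) -> int:
        return self.labels.size

    @property
    def sizes(self) -> np.ndarray:
        """Counts ``(nPout, nCin, nCout, nPin)``."""
        return np.bincount(self.labels, minlength=4)

    @property
    def names(self) -> list[str]:
        return [BLOCK_NAMES[i] for i in self.labels]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return bool(np.array_equal(self.labels, other.labels))

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash(self.labels.tobytes())


@dataclasses.dataclass(frozen=True)
class DCPParams:
    """Parameters of the ``DCP(p1, p2)`` stochastic block model.

    ``p1`` is the edge probability on ordered pairs inside the "L" (signal),
    ``p2`` the probability outside it (noise); the model requires
    ``0 <= p2 < p1 <= 1``.  ``sizes`` are the four planted set sizes in
    ``(Pout, Cin, Cout, Pin)`` order.
    """

    sizes: tuple[int, int, int, int]
    p1: float
    p2: float

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.sizes)
        if len(sizes) != 4 or any(s < 0 for s in sizes):
            raise ValueError("sizes must be four non-negative integers")
        if sum(sizes) < 1:
            raise ValueError("at least one node is required")
        if not (0.0 <= self.p2 < self.p1 <= 1.0):
            raise ValueError(
                f"require 0 <= p2 < p1 <= 1, got p1={self.p1}, p2={self.p2}"
            )
        object.__setattr__(self, "sizes", sizes)
        object.__setattr__(self, "p1", float(self.p1))
        object.__setattr__(self, "p2", float(self.p2))

    @property
    def n(self) -> int:
        return sum(self.sizes)


def planted_labels(sizes: Sequence[int]) -> np.ndarray:
    """Integer label vector with blocks contiguous in canonical order."""
    return np.repeat(np.arange(4, dtype=np.int64), np.asarray(sizes, dtype=np.int64))


def sample_dcp(params: DCPParams, seed: int) -> tuple[DirectedGraph, Partition]:
    """Draw one graph from ``DCP(p1, p2)`` together with its planted partition.

    Nodes are ordered with the ``Pout`` block first, then ``Cin``, ``Cout``,
    ``Pin``.  Every ordered node pair, including self-pairs ``(u, u)``,
    carries an edge independently with probability ``p1`` if the pair lies on
    the "L" mask and ``p2`` otherwise.  The same ``(params, seed)`` always
    yields the same graph.
    """
    if not isinstance(params, DCPParams):
        params = DCPParams(*params)
    rng = np.random.default_rng(seed)
    labels = planted_labels(params.sizes)
    on_l = BLOCK_MASK[np.ix_(labels, labels)].astype(bool)
    prob = np.where(on_l, params.p1, params.p2)
    adjacency = (rng.random((params.n, params.n)) < prob).astype(np.int8)
    node_labels = tuple(f"v{i}" for i in range(params.n))
    return DirectedGraph(adjacency, node_labels), Partition(labels)


def block_edge_counts(adjacency: np.ndarray, labels: np.ndarray, k: int = 4) -> np.ndarray:
    """``k x k`` matrix of directed edge counts between label groups."""
    onehot = np.eye(k, dtype=np.float64)[labels]
    return onehot.T @ (adjacency @ onehot)


def loglik_from_counts(e1: float, n1: float, e2: float, n2: float) -> tuple[float, float, float]:
    """Profile log-likelihood and MLEs from within/off-mask edge/pair counts.

    Uses the ``0 * log 0 = 0`` convention so that degenerate densities
    (``p_hat`` of 0 or 1, or empty pair classes) stay finite.
    """
    p1_hat = e1 / n1 if n1 > 0 else 0.0
    p2_hat = e2 / n2 if n2 > 0 else 0.0
    ll = (
        xlogy(e1, p1_hat)
        + xlogy(n1 - e1, 1.0 - p1_hat)
        + xlogy(e2, p2_hat)
        + xlogy(n2 - e2, 1.0 - p2_hat)
    )
    return float(ll), float(p1_hat), float(p2_hat)


def mask_pair_count(sizes: Sequence[int]) -> int:
    """Ordered pairs (self-pairs included) lying on the "L" mask.

    Equals ``a*b + b^2 + c*b + c^2 + c*d`` for sizes ``(a, b, c, d)``.
    """
    s = np.asarray(sizes, dtype=np.int64)
    return int((np.outer(s, s) * BLOCK_MASK).sum())


def profile_log_likelihood(
    graph: DirectedGraph, partition: Partition
) -> tuple[float, float, float]:
    """Two-parameter profile log-likelihood of a partition under DCP.

    With ``E1``/``N1`` the edge/pair counts on mask blocks and ``E2``/``N2``
    off the mask (self-pairs included throughout), the MLEs are
    ``p1_hat = E1/N1`` and ``p2_hat = E2/N2`` and the returned value is the
    Bernoulli log-likelihood at those densities; it is always ``<= 0``.

    Returns
    -------
    (log_likelihood, p1_hat, p2_hat)
    """
    if partition.n != graph.n:
        raise ValueError(
            f"partition covers {partition.n} nodes but graph has {graph.n}"
        )
    counts = block_edge_counts(graph.adjacency, partition.labels)
    sizes = partition.sizes
    e1 = float((counts * BLOCK_MASK).sum())
    n1 = float(mask_pair_count(sizes))
    e2 = float(graph.m) - e1
    n2 = float(graph.n) ** 2 - n1
    return loglik_from_counts(e1, n1, e2, n2)
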