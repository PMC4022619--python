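"""Dispersal kernels, probability of connectivity (PC), and dPC node importance.

The dispersal kernel is a negative exponential p(d) = exp(-k d) calibrated so
that the probability of moving farther than the species' maximum movement
distance d_max equals a stated tail probability (0.05 by default), i.e.
k = -ln(tail_prob) / d_max.

The PC numerator is sum_i sum_j a_i a_j p*_ij over all ordered node pairs,
where a_i is waterhole surface area and p*_ij is the maximum over paths of
the product of link probabilities (1 on the diagonal, 0 across components).
Because -ln is monotone, the max-product path is the shortest path under
weights -ln p, which is how it is computed here. Node importance is the
patch-removal statistic dPC_k = 100 (PC - PC_-k) / PC, the percentage of the
PC numerator lost when node k is deleted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .errors import ValidationError
from .network import ResourceNetwork

PairMode = Literal["max_product", "component"]


@dataclass(frozen=True)
class DispersalKernel:
    """Negative exponential kernel calibrated at a maximum movement distance.

    Attributes
    ----------
    d_max : maximum movement distance (m).
    tail_prob : probability of moving farther than ``d_max``.
    """

    d_max: float
    tail_prob: float = 0.05

    @property
    def decay_rate(self) -> float:
        """k, per meter: -ln(tail_prob) / d_max."""
        return -math.log(self.tail_prob) / self.d_max

    def probability(self, distance):
        """Dispersal probability exp(-k d); accepts scalars or arrays."""
        return np.exp(-self.decay_rate * np.asarray(distance, dtype=float))


def calibrate_kernel(d_max: float, tail_prob: float = 0.05) -> DispersalKernel:
    """Kernel with p(0) = 1 and p(d_max) = tail_prob."""
    if not d_max > 0:
        raise ValidationError(f"d_max must be positive, got {d_max}")
    if not 0 < tail_prob < 1:
        raise ValidationError(f"tail_prob must be in (0, 1), got {tail_prob}")
    return DispersalKernel(float(d_max), float(tail_prob))


def assign_link_probabilities(
    network: ResourceNetwork, kernel: DispersalKernel
) -> ResourceNetwork:
    """Attach p = exp(-k * length) to every link; requires a pruned network."""
    if network.lengths.size and network.lengths.max() > kernel.d_max + 1e-9:
        raise ValidationError(
            "network contains links longer than the kernel's d_max; prune first"
        )
    return replace(network, probabilities=kernel.probability(network.lengths))


@dataclass(frozen=True)
class PairProbabilities:
    """Symmetric matrix of maximum-product path probabilities p*_ij."""

    ids: tuple[str, ...]
    matrix: np.ndarray  # (n, n), diagonal 1, zeros across components


def max_product_paths(
    network: ResourceNetwork, mode: PairMode = "max_product"
) -> PairProbabilities:
    """p*_ij for all node pairs.

    ``max_product`` computes the maximum over paths of the product of link
    probabilities via Dijkstra on -ln p. ``component`` is the coarser variant
    where p* = 1 for nodes in the same component and 0 otherwise.
    """
    if network.n_links and network.probabilities is None:
        raise ValidationError("assign link probabilities before computing p*")
    n = network.n_nodes
    if network.probabilities is not None and network.probabilities.size:
        if network.probabilities.min() <= 0:
            raise ValidationError("link probabilities must be strictly positive")
    if mode == "component":
        mat = _component_indicator(network)
    elif mode == "max_product":
        mat = _max_product_matrix(network)
    else:
        raise ValidationError(f"unknown pair-probability mode {mode!r}")
    return PairProbabilities(network.nodes.ids, mat)


def _neglog_graph(network: ResourceNetwork) -> coo_matrix:
    n = network.n_nodes
    if network.n_links == 0:
        return coo_matrix((n, n))
    w = -np.log(network.probabilities)
    i, j = network.edges[:, 0], network.edges[:, 1]
    m = coo_matrix((w, (i, j)), shape=(n, n))
    return (m + m.T).tocsr()

def _max_product_matrix(network: ResourceNetwork) -> np.ndarray:
    n = network.n_nodes
    graph = _neglog_graph(network)
    d = dijkstra(graph, directed=False)
    with np.errstate(over="ignore"):
        mat = np.exp(-d)
    mat[~np.isfinite(d)] = 0.0
    np.fill_diagonal(mat, 1.0)
    return mat


def _component_indicator(network: ResourceNetwork) -> np.ndarray:
    n = network.n_nodes
    adj = network.adjacency(np.ones(network.n_links))
    _, labels = connected_components(adj, directed=False)
    mat = (labels[:, None] == labels[None, :]).astype(float)
    return mat


def pc_numerator(
    pairs: PairProbabilities,
    areas: Sequence[float] | np.ndarray,
    include_self: bool = True,
) -> float:
    """sum_i sum_j a_i a_j p*_ij over ordered pairs (m^4).

    Self-pairs (i = j, p* = 1) are included by default, following the
    standard Conefor-style definition; ``include_self=False`` drops them for
    sensitivity checks.
    """
    a = np.asarray(areas, dtype=float)
    if a.shape[0] != len(pairs.ids):
        raise ValidationError("areas do not cover all nodes in the pair matrix")
    if np.any(a <= 0) or not np.all(np.isfinite(a)):
        raise ValidationError("every node needs a positive, finite area")
    total = float(a @ pairs.matrix @ a)
    if not include_self:
        total -= float(np.sum(a * a))
    return total


@dataclass(frozen=True)
class ConnectivityResult:
    """PC numerator, per-node dPC (%) and importance ranks for one network."""

    ids: tuple[str, ...]
    areas: np.ndarray
    d_max: float
    pc: float  # PC numerator, m^4
    dpc: np.ndarray  # percent, in [0, 100]
    rank: np.ndarray  # 1 = most important
    pairs: PairProbabilities

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.ids, "area_m2": self.areas, "dPC": self.dpc, "rank": self.rank}
        )


def _rank_by_importance(
    scores: np.ndarray, areas: np.ndarray, ids: Sequence[str]
) -> np.ndarray:
    """Rank 1 = largest score; ties broken by larger area, then lexical id."""
    neg_ids = np.array(ids)
    order = np.lexsort((neg_ids, -areas, -scores))
    rank = np.empty(len(scores), dtype=int)
    rank[order] = np.arange(1, len(scores) + 1)
    return rank


def node_importance(
    network: ResourceNetwork,
    kernel: DispersalKernel,
    include_self: bool = True,
    mode: PairMode = "max_product",
) -> ConnectivityResult:
    """Patch-removal dPC for every node, by full leave-one-out recomputation.

    For each node k the pairwise probabilities are recomputed on the network
    without k and dPC_k = 100 (PC - PC_-k) / PC. Removing a node can only
    lose area and paths, so dPC is always in [0, 100].
    """
    if network.n_nodes == 0:
        raise ValidationError("node importance needs at least one node")
    net = assign_link_probabilities(network, kernel)
    pairs = max_product_paths(net, mode=mode)
    areas = net.nodes.areas
    pc = pc_numerator(pairs, areas, include_self=include_self)
    n = net.n_nodes
    dpc = np.zeros(n)
    for k in range(n):
        keep = np.ones(n, dtype=bool)
        keep[k] = False
        sub = _subnetwork(net, keep)
        sub_pairs = max_product_paths(sub, mode=mode)
        pc_minus = pc_numerator(sub_pairs, areas[keep], include_self=include_self) \
            if keep.any() else 0.0
        dpc[k] = 100.0 * (pc - pc_minus) / pc if pc > 0 else 0.0
    rank = _rank_by_importance(dpc, areas, net.nodes.ids)
    return ConnectivityResult(
        net.nodes.ids, areas, kernel.d_max, pc, dpc, rank, pairs
    )


def _subnetwork(network: ResourceNetwork, keep: np.ndarray) -> ResourceNetwork:
    """Node-induced subnetwork by boolean mask (links re-indexed)."""
    new_index = np.cumsum(keep) - 1
    if network.n_links:
        emask = keep[network.edges[:, 0]] & keep[network.edges[:, 1]]
        edges = new_index[network.edges[emask]]
        lengths = network.lengths[emask]
        probs = None if network.probabilities is None else network.probabilities[emask]
    else:
        edges = np.empty((0, 2), dtype=np.intp)
        lengths = np.empty(0)
        probs = None if network.probabilities is None else np.empty(0)
    return replace(
        network,
        nodes=network.nodes.subset(keep),
        edges=edges.astype(np.intp).reshape(-1, 2),
        lengths=lengths,
        probabilities=probs,
    )


def aggregate_importance(results: Sequence[ConnectivityResult]) -> pd.DataFrame:
    """Sum per-node dPC across distance thresholds and rank by the sum.

    Returns one row per node with a dPC column per distance, the aggregate
    (cross-distance sum), and the aggregate rank (ties broken by larger area
    then lexical id).
    """
    if not results:
        raise ValidationError("no connectivity results to aggregate")
    ids = results[0].ids
    for r in results[1:]:
        if r.ids != ids:
            raise ValidationError("mismatched node sets across distances")
    df = pd.DataFrame({"id": ids, "area_m2": results[0].areas})
    agg = np.zeros(len(ids))
    for r in results:
        df[f"dPC_{r.d_max:g}m"] = r.dpc
        agg += r.dpc
    df["dPC_aggregate"] = agg
    df["rank"] = _rank_by_importance(agg, results[0].areas, ids)
    return df
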