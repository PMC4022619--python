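"""Spatial graph extraction and structural metrics.

A resource network is the complete graph on waterhole centroids with
Euclidean link lengths, optionally pruned to links no longer than a species'
maximum movement distance. Link density L is the fraction of realized links
out of the complete graph on the same node set; clusters are connected
components with at least two nodes (isolated waterholes are counted
separately but remain members of the network).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import connected_components as _cc
from scipy.spatial.distance import pdist

from .errors import ValidationError
from .landscape_io import WaterholeTable


@dataclass(frozen=True)
class Link:
    """An unordered link between two waterholes (endpoint ids)."""

    a: str
    b: str
    length: float
    probability: float | None = None


@dataclass(frozen=True)
class ResourceNetwork:
    """Waterhole nodes plus unordered distance-weighted links.

    Links are stored columnar (``edges`` holds index pairs into ``nodes``,
    ``lengths`` the Euclidean centroid distances in meters) and exposed as
    :class:`Link` objects through :attr:`links`. ``probabilities`` is filled
    by the connectivity module once a dispersal kernel is applied.
    """

    nodes: WaterholeTable
    edges: np.ndarray  # (m, 2) int array, i < j
    lengths: np.ndarray  # (m,) float, meters
    probabilities: np.ndarray | None = None
    threshold: float | None = None  # d_max used for pruning, if any

    def __post_init__(self) -> None:
        if self.edges.size and self.edges.max() >= len(self.nodes):
            raise ValidationError("link endpoint index out of range")
        if self.threshold is not None and self.lengths.size:
            if self.lengths.max() > self.threshold + 1e-9:
                raise ValidationError("link longer than the recorded threshold")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_links(self) -> int:
        return int(self.edges.shape[0])

    @property
    def links(self) -> Iterator[Link]:
        ids = self.nodes.ids
        probs = self.probabilities
        for k in range(self.n_links):
            i, j = self.edges[k]
            yield Link(
                ids[i], ids[j], float(self.lengths[k]),
                None if probs is None else float(probs[k]),
            )

    def index_of(self, waterhole_id: str) -> int:
        return self.nodes.ids.index(waterhole_id)

    def adjacency(self, weights: np.ndarray | None = None) -> csr_matrix:
        """Symmetric sparse adjacency; default weight is link length."""
        w = self.lengths if weights is None else weights
        i, j = (self.edges[:, 0], self.edges[:, 1]) if self.n_links else ((), ())
        n = self.n_nodes
        m = coo_matrix((w, (i, j)), shape=(n, n))
        return (m + m.T).tocsr()


@dataclass(frozen=True)
class NetworkMetrics:
    """Structural summary of one network state."""

    n_nodes: int
    total_water_area: float  # m^2
    n_links: int
    link_density: float  # in [0, 1]
    component_sizes: tuple[int, ...]  # descending
    n_clusters: int  # components with >= 2 nodes
    n_isolates: int


def link_density(n_links: int, n_nodes: int) -> float:
    """Realized links over the link count of the complete graph; 0 if n < 2."""
    if n_nodes < 2:
        return 0.0
    return n_links / (n_nodes * (n_nodes - 1) / 2)


def build_complete_network(table: WaterholeTable) -> ResourceNetwork:
    """Complete graph on centroids: n(n-1)/2 links with Euclidean lengths."""
    n = len(table)
    if n == 0:
        raise ValidationError("cannot build a network from an empty table")
    if n == 1:
        return ResourceNetwork(
            table, np.empty((0, 2), dtype=np.intp), np.empty(0, dtype=float)
        )
    lengths = pdist(table.coords)
    i, j = np.triu_indices(n, k=1)
    edges = np.column_stack([i, j]).astype(np.intp)
    return ResourceNetwork(table, edges, lengths)


def prune_by_distance(network: ResourceNetwork, d_max: float) -> ResourceNetwork:
    """Keep links with length <= d_max (equality kept); nodes unchanged."""
    if not d_max > 0:
        raise ValidationError(f"d_max must be positive, got {d_max}")
    keep = network.lengths <= d_max
    return replace(
        network,
        edges=network.edges[keep],
        lengths=network.lengths[keep],
        probabilities=None if network.probabilities is None
        else network.probabilities[keep],
        threshold=float(d_max),
    )


def component_labels(network: ResourceNetwork) -> np.ndarray:
    """Connected-component label per node, in node order."""
    if network.n_nodes == 0:
        return np.empty(0, dtype=int)
    _, labels = _cc(network.adjacency(np.ones(network.n_links)), directed=False)
    return labels


def compute_metrics(network: ResourceNetwork) -> NetworkMetrics:
    """Link density, component sizes, cluster and isolate counts."""
    labels = component_labels(network)
    sizes = np.bincount(labels) if labels.size else np.empty(0, dtype=int)
    sizes_desc = tuple(sorted((int(s) for s in sizes), reverse=True))
    return NetworkMetrics(
        n_nodes=network.n_nodes,
        total_water_area=network.nodes.total_area,
        n_links=network.n_links,
        link_density=link_density(network.n_links, network.n_nodes),
        component_sizes=sizes_desc,
        n_clusters=sum(1 for s in sizes_desc if s >= 2),
        n_isolates=sum(1 for s in sizes_desc if s == 1),
    )
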