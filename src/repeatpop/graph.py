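"""Weighted read-similarity graph, repeat clusters, abundances and layouts.

The graph G has reads as vertices and bit-score-weighted similarity hits as
edges; edges below 100 bits are excluded (the threshold is inclusive: a
weight of exactly 100.0 is retained). Clusters are communities found by
greedy modularity maximization (Clauset-Newman-Moore) on the weighted
graph, renumbered by descending size. A cluster meta-graph collapses each
cluster to a vertex with summed inter-cluster edge weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from ._utils import rng_for
from .similarity import SimilarityHit

logger = logging.getLogger(__name__)

MIN_EDGE_BITS = 100.0


def mean_degree(n_vertices: int, n_edges: int) -> float:
    """Mean degree 2E/V of a simple undirected graph, to two decimals."""
    if n_vertices == 0:
        return 0.0
    return round(2 * n_edges / n_vertices, 2)


@dataclass
class ClusterAssignment:
    """Partition of graph vertices into clusters ranked by size.

    cluster_of maps read id -> cluster index; clusters[i] is the member
    list of cluster i. Clusters are ordered by descending size, ties broken
    by the lexicographically smallest member read id.
    """

    cluster_of: dict[str, int]
    clusters: list[list[str]]

    def __len__(self) -> int:
        return len(self.clusters)

    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]


def build_graph(
    hits: Iterable[SimilarityHit],
    labels: Mapping[str, tuple[str, str]] | None = None,
    min_bits: float = MIN_EDGE_BITS,
) -> nx.Graph:
    """Simple undirected graph over reads appearing in >= 1 retained edge.

    Edges keep the maximum bit-score per pair; hits with bit-score below
    min_bits are excluded (>= min_bits retained). Vertices carry
    individual/population attributes when labels are given.
    """
    g = nx.Graph()
    for hit in hits:
        if hit.bitscore < min_bits or hit.read_a == hit.read_b:
            continue
        a, b = hit.read_a, hit.read_b
        if g.has_edge(a, b):
            if hit.bitscore > g[a][b]["weight"]:
                g[a][b]["weight"] = hit.bitscore
        else:
            g.add_edge(a, b, weight=hit.bitscore)
    if labels is not None:
        for node in g.nodes:
            ind, pop = labels.get(node, (None, None))
            g.nodes[node]["individual"] = ind
            g.nodes[node]["population"] = pop
    logger.info(
        "graph: %d vertices, %d edges, mean degree %.2f",
        g.number_of_nodes(),
        g.number_of_edges(),
        mean_degree(g.number_of_nodes(), g.number_of_edges()),
    )
    return g


def largest_component(g: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Ties are broken in favour of the component containing the
    lexicographically smallest read id. The number of discarded vertices is
    logged.
    """
    if g.number_of_nodes() == 0:
        return g.copy()
    comps = list(nx.connected_components(g))
    comps.sort(key=lambda c: (-len(c), min(c)))
    keep = comps[0]
    discarded = g.number_of_nodes() - len(keep)
    logger.info("largest component: kept %d vertices, discarded %d", len(keep), discarded)
    return g.subgraph(keep).copy()


def detect_communities(g: nx.Graph, weighted: bool = True) -> ClusterAssignment:
    """Greedy modularity (Clauset-Newman-Moore) clusters, size-ranked.

    Communities are merged agglomeratively while modularity increases; the
    returned partition is the modularity maximum along the merge sequence.
    Run on edge weights by default.
    """
    if g.number_of_nodes() == 0:
        return ClusterAssignment({}, [])
    if g.number_of_edges() == 0:
        communities = [{n} for n in g.nodes]
    else:
        communities = [
            set(c)
            for c in nx.community.greedy_modularity_communities(
                g, weight="weight" if weighted else None
            )
        ]
    ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
    clusters = [sorted(c) for c in ordered]
    cluster_of = {
        node: idx for idx, members in enumerate(clusters) for node in members
    }
    return ClusterAssignment(cluster_of, clusters)


def abundance_matrix(
    assignment: ClusterAssignment,
    labels: Mapping[str, tuple[str, str]],
) -> tuple[pd.DataFrame, pd.Series]:
    """Individuals x clusters read-count table plus population labels.

    The grand total equals the number of clustered reads. Reads without an
    individual label are an error.
    """
    individuals: dict[str, str] = {}
    counts: dict[tuple[str, int], int] = {}
    for read_id, cluster in assignment.cluster_of.items():
        if read_id not in labels:
            raise KeyError(f"read {read_id!r} has no individual label")
        ind, pop = labels[read_id]
        individuals[ind] = pop
        key = (ind, cluster)
        counts[key] = counts.get(key, 0) + 1
    index = sorted(individuals)
    columns = [f"cluster_{i}" for i in range(len(assignment))]
    mat = pd.DataFrame(0, index=index, columns=columns, dtype=int)
    for (ind, cluster), n in counts.items():
        mat.loc[ind, f"cluster_{cluster}"] = n
    pops = pd.Series({ind: individuals[ind] for ind in index}, name="population")
    return mat, pops


def cluster_metagraph(g: nx.Graph, assignment: ClusterAssignment) -> nx.Graph:
    """Meta-graph: one vertex per cluster, edge weight = summed cross-cluster bits.

    Intra-cluster weight is stored as a node attribute so that total edge
    weight is conserved: sum(node intra) + sum(meta edges) = sum(G edges).
    """
    meta = nx.Graph()
    for idx in range(len(assignment)):
        meta.add_node(idx, intra_weight=0.0, size=len(assignment.clusters[idx]))
    for a, b, data in g.edges(data=True):
        ca = assignment.cluster_of.get(a)
        cb = assignment.cluster_of.get(b)
        if ca is None or cb is None:
            raise KeyError(f"edge ({a}, {b}) has unassigned endpoint")
        w = data.get("weight", 1.0)
        if ca == cb:
            meta.nodes[ca]["intra_weight"] += w
        else:
            if meta.has_edge(ca, cb):
                meta[ca][cb]["weight"] += w
            else:
                meta.add_edge(ca, cb, weight=w)
    return meta


def layout_cluster(
    g: nx.Graph,
    assignment: ClusterAssignment,
    cluster_id: int,
    seed: int = 0,
    iterations: int = 500,
) -> dict[str, tuple[float, float]]:
    """Fruchterman-Reingold layout of one cluster's induced subgraph.

    Vertices start in the unit square from the seed; forces use
    k = sqrt(area/|V|) with attraction d^2/k on edges, repulsion k^2/d on
    all pairs, and a linearly cooling displacement cap. Deterministic per
    seed. A single vertex is placed at the origin.
    """
    if not 0 <= cluster_id < len(assignment):
        raise KeyError(f"unknown cluster id {cluster_id}")
    members = assignment.clusters[cluster_id]
    sub = g.subgraph(members)
    n = len(members)
    if n == 1:
        return {members[0]: (0.0, 0.0)}
    rng = rng_for(seed, f"layout/{cluster_id}")
    pos = rng.random((n, 2))
    index = {node: i for i, node in enumerate(members)}
    edges = np.array(
        [[index[a], index[b]] for a, b in sub.edges()], dtype=int
    ).reshape(-1, 2)
    k = np.sqrt(1.0 / n)
    t0 = 0.1
    for step in range(iterations):
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(delta, axis=-1)
        np.fill_diagonal(dist, 1.0)
        dist = np.maximum(dist, 1e-9)
        # repulsion k^2/d between all pairs
        disp = (delta / dist[..., None] * (k * k / dist)[..., None]).sum(axis=1)
        # attraction d^2/k along edges
        if len(edges):
            ea, eb = edges[:, 0], edges[:, 1]
            dvec = pos[ea] - pos[eb]
            d = np.maximum(np.linalg.norm(dvec, axis=-1), 1e-9)
            force = (dvec / d[:, None]) * (d * d / k)[:, None]
            np.add.at(disp, ea, -force)
            np.add.at(disp, eb, force)
        t = t0 * (1.0 - step / iterations)
        lengths = np.maximum(np.linalg.norm(disp, axis=-1), 1e-9)
        pos = pos + disp / lengths[:, None] * np.minimum(lengths, t)[:, None]
    return {node: (float(pos[i, 0]), float(pos[i, 1])) for node, i in index.items()}
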