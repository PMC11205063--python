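"""Global network metrics: CC, ASPL, Q, density, average degree, efficiency.

All measures treat the network as unweighted and undirected.  The clustering
coefficient (CC) is the Watts-Strogatz average of local clustering (nodes of
degree < 2 contribute 0), with global transitivity available as a variant.
The average shortest path length (ASPL) is the mean breadth-first distance
over unordered pairs; on a disconnected graph it is computed on the largest
connected component with a logged warning, since the quantity is otherwise
undefined.  Modularity (Q) is the Newman-Girvan modularity of the best
partition found by seeded Louvain community detection across several
restarts.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, asdict
from decimal import ROUND_HALF_UP, Decimal

import networkx as nx
import numpy as np

from .errors import EmptyResultError

logger = logging.getLogger(__name__)

DEFAULT_LOUVAIN_RUNS = 10


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero (the convention used for the printed
    descriptive statistics), avoiding banker's rounding surprises."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MetricSet:
    """The global structure measures for one group network."""

    cc: float
    aspl: float
    q: float
    density: float
    average_degree: float
    efficiency: float
    n_nodes: int
    n_edges: int

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    METRIC_NAMES = ("cc", "aspl", "q", "density", "average_degree",
                    "efficiency")


def clustering_coefficient(g: nx.Graph, variant: str = "local_average") -> float:
    """Network clustering: how often two neighbors of a node are themselves
    connected.

    ``local_average`` averages the per-node triangle density
    (Watts-Strogatz), counting degree-<2 nodes as 0; ``transitivity`` is
    3 x triangles / connected triples.
    """
    if g.number_of_nodes() == 0:
        raise EmptyResultError("clustering undefined on the empty graph")
    if variant == "local_average":
        return float(nx.average_clustering(g, count_zeros=True))
    if variant == "transitivity":
        return float(nx.transitivity(g))
    raise ValueError(f"unknown clustering variant: {variant!r}")


def _largest_component(g: nx.Graph) -> nx.Graph:
    comps = sorted(nx.connected_components(g),
                   key=lambda c: (-len(c), sorted(map(str, c))[0]))
    return g.subgraph(comps[0])


def aspl(g: nx.Graph) -> float:
    """Average shortest path length over unordered node pairs.

    Unweighted breadth-first distances.  Disconnected graphs are restricted
    to the largest connected component (warned); an edgeless graph has no
    finite paths and is an error.
    """
    if g.number_of_nodes() < 2:
        raise EmptyResultError("ASPL needs at least 2 nodes")
    if g.number_of_edges() == 0:
        raise EmptyResultError("ASPL undefined on an edgeless graph")
    if not nx.is_connected(g):
        sub = _largest_component(g)
        logger.warning("graph disconnected: ASPL computed on largest "
                       "component (%d of %d nodes)",
                       sub.number_of_nodes(), g.number_of_nodes())
        g = sub
    return float(nx.average_shortest_path_length(g))


def modularity_q(g: nx.Graph, seed: int = 0, runs: int = DEFAULT_LOUVAIN_RUNS,
                 resolution: float = 1.0) -> tuple[float, list[set]]:
    """Newman-Girvan modularity of the best Louvain partition.

    Community detection runs the multilevel (Louvain) algorithm ``runs``
    times, each restart presenting the vertices in a fresh seeded random
    order (Louvain's result depends on traversal order), and keeps the
    highest-modularity partition; the result is deterministic given
    ``seed``.  The modularity value itself is the standard Newman-Girvan
    quantity evaluated on the returned partition.

    Returns
    -------
    (q, partition)
        Modularity value and the partition (list of node sets) achieving it.
    """
    import igraph as ig

    if g.number_of_edges() < 1:
        raise EmptyResultError("modularity needs at least one edge")
    nodes = list(g.nodes)
    n = len(nodes)
    index = {u: i for i, u in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in g.edges]

    best_q, best_part = -1.0, None
    for r in range(runs):
        rng = np.random.default_rng(seed + r)
        perm = rng.permutation(n)  # igraph vertex k holds nodes[perm[k]]
        remap = np.empty_like(perm)
        remap[perm] = np.arange(n)
        h = ig.Graph(n=n, edges=[(int(remap[a]), int(remap[b]))
                                 for a, b in edges])
        # igraph draws from its own RNG; pin it so runs are reproducible
        ig.set_random_number_generator(random.Random(seed + r))
        clustering = h.community_multilevel(resolution=resolution)
        part: list[set] = [set() for _ in range(len(clustering))]
        for k, comm in enumerate(clustering.membership):
            part[comm].add(nodes[perm[k]])
        part = [c for c in part if c]
        q = nx.community.modularity(g, part, weight=None,
                                    resolution=resolution)
        if q > best_q:
            best_q, best_part = q, part
    assert best_part is not None
    return float(best_q), best_part


def global_efficiency(g: nx.Graph) -> float:
    """Mean inverse shortest-path distance over unordered pairs
    (1/infinity = 0 for disconnected pairs)."""
    if g.number_of_nodes() < 2:
        raise EmptyResultError("efficiency needs at least 2 nodes")
    return float(nx.global_efficiency(g))


def metric_set(g: nx.Graph, seed: int = 0, cc_variant: str = "local_average",
               louvain_runs: int = DEFAULT_LOUVAIN_RUNS) -> MetricSet:
    """Bundle all six global measures for one network (deterministic given
    ``seed``)."""
    n = g.number_of_nodes()
    m = g.number_of_edges()
    q, _ = modularity_q(g, seed=seed, runs=louvain_runs)
    return MetricSet(
        cc=clustering_coefficient(g, variant=cc_variant),
        aspl=aspl(g),
        q=q,
        density=float(nx.density(g)),
        average_degree=2.0 * m / n if n else 0.0,
        efficiency=global_efficiency(g),
        n_nodes=n,
        n_edges=m,
    )
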