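"""Network construction: node equating, cosine similarity, TMFG filtering.

The association between two response types is the cosine of their binary
production vectors (columns of the response matrix): co-occurrence
normalized by how often each word is produced at all, in [0, 1].  The dense
cosine matrix is then filtered to a triangulated maximally filtered graph
(TMFG): a planar maximal graph grown greedily by inserting one vertex at a
time into the triangular face where its total similarity to the face's
corners is largest.  The result keeps 3n - 6 of the strongest mutually
consistent associations; edges whose similarity is exactly zero (forced in
only by the triangulation) are dropped from the final binary network, which
is analyzed unweighted.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .errors import EmptyResultError, IntegrityError

logger = logging.getLogger(__name__)


def equate_nodes(matrices: Mapping[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Restrict every group/timepoint matrix to the common token set.

    Compared networks must share a node universe so structural differences
    are not confounded by vocabulary differences; the common set is the
    intersection of all cells' produced-token sets (the strictest reading),
    in identical sorted column order.

    Raises
    ------
    EmptyResultError
        The intersection is empty.
    ValueError
        Fewer than two matrices supplied.
    """
    if len(matrices) < 2:
        raise ValueError("node equating needs at least two matrices")
    common: set[str] | None = None
    for m in matrices.values():
        produced = set(m.columns[m.sum(axis=0).to_numpy() > 0])
        common = produced if common is None else common & produced
    assert common is not None
    if not common:
        raise EmptyResultError("no tokens common to all groups/timepoints")
    cols = sorted(common)
    logger.info("equated node set: %d tokens common to %d cells",
                len(cols), len(matrices))
    return {k: m.loc[:, cols] for k, m in matrices.items()}


def cosine_similarity(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise cosine similarity between response types.

    cell(i, j) = x_i . x_j / (||x_i|| ||x_j||) over the binary production
    columns; the diagonal is defined as 1.  Values lie in [0, 1] for binary
    input.

    Raises
    ------
    IntegrityError
        A token column sums to zero (norm undefined), named in the message.
    """
    X = matrix.to_numpy(dtype=float)
    norms = np.linalg.norm(X, axis=0)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise IntegrityError(
            f"zero-sum column(s): {', '.join(map(str, matrix.columns[zero]))}")
    S = (X.T @ X) / np.outer(norms, norms)
    S = np.clip((S + S.T) / 2.0, 0.0, 1.0)  # enforce exact symmetry
    np.fill_diagonal(S, 1.0)
    return pd.DataFrame(S, index=matrix.columns, columns=matrix.columns)


def _tmfg_edges(W: np.ndarray) -> list[tuple[int, int]]:
    """Greedy TMFG on a symmetric similarity matrix; returns 3n-6 edges.

    Seed clique: the 4 vertices with the largest similarity row sums (ties
    broken toward the lowest index).  Each insertion picks the
    (vertex, triangular face) pair maximizing the summed similarity from the
    vertex to the face's corners, ties broken by lowest vertex index then
    lowest face creation index, and splits that face into three.
    """
    n = W.shape[0]
    W = W.copy()
    np.fill_diagonal(W, 0.0)

    rowsums = W.sum(axis=1)
    # stable: sort by (-rowsum, index)
    seed = sorted(np.argsort(-rowsums, kind="stable")[:4])
    edges = [(seed[i], seed[j]) for i in range(4) for j in range(i + 1, 4)]
    faces: list[tuple[int, int, int]] = [
        (seed[0], seed[1], seed[2]),
        (seed[0], seed[1], seed[3]),
        (seed[0], seed[2], seed[3]),
        (seed[1], seed[2], seed[3]),
    ]
    remaining = sorted(set(range(n)) - set(seed))
    if not remaining:
        return edges

    rem = np.array(remaining)
    # gains[i, f] = similarity gain of inserting remaining vertex i into face f
    gains = np.empty((len(rem), len(faces)))
    for f, (a, b, c) in enumerate(faces):
        gains[:, f] = W[rem, a] + W[rem, b] + W[rem, c]

    while rem.size:
        best = gains.max()
        cand_i, cand_f = np.nonzero(gains == best)
        # lowest vertex label first, then lowest face index
        order = np.lexsort((cand_f, rem[cand_i]))
        i, f = int(cand_i[order[0]]), int(cand_f[order[0]])
        v = int(rem[i])
        a, b, c = faces[f]
        edges.extend([(min(v, a), max(v, a)), (min(v, b), max(v, b)),
                      (min(v, c), max(v, c))])
        # replace face f, append two new faces
        faces[f] = (a, b, v)
        faces.append((a, c, v))
        faces.append((b, c, v))
        rem = np.delete(rem, i)
        gains = np.delete(gains, i, axis=0)
        if rem.size:
            new_cols = np.empty((rem.size, 2))
            gains[:, f] = W[rem, a] + W[rem, b] + W[rem, v]
            new_cols[:, 0] = W[rem, a] + W[rem, c] + W[rem, v]
            new_cols[:, 1] = W[rem, b] + W[rem, c] + W[rem, v]
            gains = np.hstack([gains, new_cols])
    return edges


def tmfg(similarity: pd.DataFrame, drop_zero_edges: bool = True,
         provenance: Mapping[str, str] | None = None) -> nx.Graph:
    """Filter a similarity matrix to a triangulated maximally filtered graph.

    For fewer than 4 nodes the complete graph is returned.  The triangulated
    graph is planar with exactly 3n - 6 edges; edges whose similarity is
    exactly 0 were forced in by the triangulation, carry no co-occurrence
    evidence, and are removed from the binary network when
    ``drop_zero_edges`` is true.  Surviving cosine values are kept as edge
    ``weight`` annotations only — downstream metrics are unweighted.

    Raises
    ------
    IntegrityError
        The input matrix is not symmetric.
    """
    S = similarity.to_numpy(dtype=float)
    if S.shape[0] != S.shape[1] or not np.allclose(S, S.T, atol=1e-12):
        raise IntegrityError("similarity matrix must be square and symmetric")
    labels = list(similarity.index)
    n = len(labels)

    if n < 4:
        idx_edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    else:
        idx_edges = _tmfg_edges(S)

    g = nx.Graph()
    g.add_nodes_from(labels)
    n_zero = 0
    for i, j in idx_edges:
        w = float(S[i, j])
        if drop_zero_edges and w == 0.0:
            n_zero += 1
            continue
        g.add_edge(labels[i], labels[j], weight=w)
    if n_zero:
        logger.info("dropped %d zero-similarity triangulation edges", n_zero)
    g.graph.update(provenance or {})
    return g


# ---------------------------------------------------------------------------
# export / import


def export_network(g: nx.Graph, path: str | Path,
                   fmt: str = "edge_list") -> Path:
    """Write a network as a 3-column edge list or GraphML (Cytoscape-ready).

    Round-trip safe: :func:`import_network` on the written file recovers the
    same nodes, edges and weights (weights to full float precision in edge
    lists via repr).
    """
    path = Path(path)
    if fmt == "edge_list":
        rows = [{"source": u, "target": v,
                 "weight": d.get("weight", 1.0)}
                for u, v, d in sorted(g.edges(data=True))]
        df = pd.DataFrame(rows, columns=["source", "target", "weight"])
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
        # edge lists lose isolated nodes; record them on a comment-free side
        # channel only when present
        isolates = [n for n in g.nodes if g.degree(n) == 0]
        if isolates:
            logger.warning("edge list omits %d isolated node(s)", len(isolates))
    elif fmt == "graphml":
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format: {fmt!r}")
    return path


def import_network(path: str | Path, fmt: str = "edge_list") -> nx.Graph:
    """Read a network written by :func:`export_network`."""
    path = Path(path)
    if fmt == "edge_list":
        df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
        g = nx.Graph()
        for row in df.itertuples(index=False):
            g.add_edge(row.source, row.target, weight=float(row.weight))
        return g
    if fmt == "graphml":
        return nx.read_graphml(path)
    raise ValueError(f"unknown network format: {fmt!r}")
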