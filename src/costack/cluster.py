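"""Expression normalization, neighbour graph, and community detection.

The clustering contract: cells below the minimum-total-count filter are
excluded upstream, counts are total-count normalized per cell and
log1p-transformed, a k-nearest-neighbour graph (k = 15, cosine
similarity) connects cells with similar expression, and a standard
seeded modularity-based community algorithm (Louvain) partitions the
graph.  Community detection and 2-D embedding are pluggable standard
algorithms; the bespoke content here is the normalization + graph contract
and the determinism guarantees (fixed seed => fixed partition).
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .errors import ParameterError


def normalize(counts: pd.DataFrame, target_sum: float = 1e4) -> pd.DataFrame:
    """Total-count normalize each cell to ``target_sum``, then log1p.

    A zero-total row is an error: such cells should have been removed by
    the minimum-count filter before clustering.
    """
    mat = counts.to_numpy(dtype=float)
    totals = mat.sum(axis=1)
    if np.any(totals == 0):
        bad = counts.index[totals == 0].tolist()[:5]
        raise ParameterError(f"zero-total cells reached normalize (e.g. {bad}); "
                             "apply the minimum-count filter first")
    scaled = mat * (target_sum / totals)[:, None]
    return pd.DataFrame(np.log1p(scaled), index=counts.index, columns=counts.columns)


def knn_graph(X: pd.DataFrame, k: int = 15, metric: str = "cosine") -> nx.Graph:
    """Symmetrized k-nearest-neighbour graph with similarity edge weights.

    Each cell is connected to its ``k`` nearest by cosine distance; edges
    carry ``weight = 1 - distance`` (cosine similarity) and the graph is
    made undirected by union.  A zero-norm expression row has no cosine
    direction and is an error naming the offending cell.
    """
    mat = X.to_numpy(dtype=float)
    if len(mat) < k + 1:
        raise ParameterError(f"need >= k+1 = {k + 1} cells, got {len(mat)}")
    if metric == "cosine":
        norms = np.linalg.norm(mat, axis=1)
        if np.any(norms == 0):
            bad = X.index[norms == 0].tolist()[:5]
            raise ParameterError(f"zero-norm expression rows (cosine undefined): {bad}")
    nn = NearestNeighbors(n_neighbors=k + 1, metric=metric).fit(mat)
    dist, idx = nn.kneighbors(mat)
    ids = X.index.to_numpy()
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i in range(len(mat)):
        for d, j in zip(dist[i], idx[i]):
            if j == i:
                continue
            w = max(0.0, 1.0 - float(d)) if metric == "cosine" else 1.0 / (1.0 + float(d))
            u, v = ids[i], ids[j]
            if g.has_edge(u, v):
                # union symmetrization keeps the larger similarity
                g[u][v]["weight"] = max(g[u][v]["weight"], w)
            else:
                g.add_edge(u, v, weight=w)
    return g


def cluster_cells(graph: nx.Graph, seed: int = 0, resolution: float = 1.0) -> pd.Series:
    """Seeded Louvain partition; returns a cell_id -> community id series.

    Communities are relabeled deterministically in order of their smallest
    member node, so the same seed always yields the same ids.
    """
    if graph.number_of_nodes() == 0:
        raise ParameterError("cannot cluster an empty graph")
    comms = nx.community.louvain_communities(
        graph, weight="weight", resolution=resolution, seed=seed
    )
    comms = sorted(comms, key=lambda c: min(c))
    mapping = {}
    for cid, members in enumerate(comms):
        for node in members:
            mapping[node] = cid
    nodes = sorted(graph.nodes())
    return pd.Series([mapping[n] for n in nodes], index=nodes, name="cluster")


def embed(X: pd.DataFrame, seed: int = 0, method: str = "umap", **kwargs) -> np.ndarray:
    """2-D embedding via a standard pluggable algorithm (UMAP by default)."""
    if method != "umap":
        raise ParameterError(f"unknown embedding method {method!r}")
    import umap  # optional dependency, imported lazily

    reducer = umap.UMAP(n_components=2, random_state=seed, **kwargs)
    return reducer.fit_transform(X.to_numpy(dtype=float))
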