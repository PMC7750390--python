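"""Per-day weighted network construction and basic measures.

Networks are built from symmetric dyadic count matrices; density,
components, degree and local clustering are computed on the binary graph
(edge iff the dyad interacted at least once), matching count-of-ties
style definitions.  Mean-weight edge filtering is a visualisation aid
only and is never used in inference.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .proximity import dyad_count

__all__ = [
    "to_graph",
    "edge_density",
    "components",
    "degree_and_clustering",
    "filter_by_mean_degree",
    "average_matrices",
    "network_measures",
]


def _values(matrix: pd.DataFrame) -> np.ndarray:
    v = matrix.to_numpy(dtype=float).copy()
    np.fill_diagonal(v, 0.0)
    v = np.nan_to_num(v)
    if not np.allclose(v, v.T):
        raise ValueError("interaction matrix must be symmetric")
    return v


def to_graph(matrix: pd.DataFrame) -> nx.Graph:
    """Binary graph with edge iff the dyad has >= 1 interaction; weights kept."""
    v = _values(matrix)
    g = nx.Graph()
    g.add_nodes_from(matrix.index)
    ids = list(matrix.index)
    iu, ju = np.nonzero(np.triu(v, 1) >= 1)
    g.add_weighted_edges_from((ids[i], ids[j], v[i, j]) for i, j in zip(iu, ju))
    return g


def edge_density(matrix: pd.DataFrame) -> float:
    """Fraction of possible dyads with at least one interaction."""
    v = _values(matrix)
    n = v.shape[0]
    iu = np.triu_indices(n, 1)
    return float((v[iu] >= 1).sum() / dyad_count(n))


def components(matrix: pd.DataFrame) -> list[set]:
    """Connected components of the binary graph, largest first."""
    g = to_graph(matrix)
    return sorted(nx.connected_components(g), key=len, reverse=True)


def degree_and_clustering(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-node binary degree and local clustering coefficient.

    Clustering is the fraction of a node's neighbour pairs that are
    themselves connected, 0 for degree < 2.
    """
    g = to_graph(matrix)
    deg = dict(g.degree())
    clust = nx.clustering(g)  # unweighted
    return pd.DataFrame(
        {
            "animal_id": list(matrix.index),
            "degree": [deg[a] for a in matrix.index],
            "clustering": [clust[a] for a in matrix.index],
        }
    )


def filter_by_mean_degree(matrix: pd.DataFrame) -> pd.DataFrame:
    """Retain edges with weight >= the mean nonzero edge weight.

    Interpretation of 'filtered by mean degree' network displays; used
    for visualisation only.
    """
    v = _values(matrix)
    iu = np.triu_indices(v.shape[0], 1)
    nz = v[iu][v[iu] > 0]
    out = matrix.copy()
    if nz.size == 0:
        return out
    mean_w = nz.mean()
    w = v.copy()
    w[v < mean_w] = 0.0
    out.iloc[:, :] = w
    np.fill_diagonal(out.values, np.nan)
    return out


def average_matrices(matrices: list[pd.DataFrame]) -> pd.DataFrame:
    """Element-wise arithmetic mean of interaction matrices (same roster)."""
    if not matrices:
        raise ValueError("no matrices to average")
    first = matrices[0]
    for m in matrices[1:]:
        if not (m.index.equals(first.index) and m.columns.equals(first.columns)):
            raise ValueError("matrices must share dimension and roster")
    stack = np.stack([m.to_numpy(dtype=float) for m in matrices])
    out = pd.DataFrame(stack.mean(axis=0), index=first.index, columns=first.columns)
    np.fill_diagonal(out.values, np.nan)
    return out


def network_measures(matrix: pd.DataFrame) -> dict:
    """Summary measures for one network: density, components, degree stats."""
    comps = components(matrix)
    node = degree_and_clustering(matrix)
    return {
        "edge_density": edge_density(matrix),
        "component_count": len(comps),
        "largest_component": len(comps[0]) if comps else 0,
        "mean_degree": float(node["degree"].mean()),
        "mean_clustering": float(node["clustering"].mean()),
    }
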