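"""Jaccard similarity of country assemblages and the country network.

Countries are compared by the Jaccard similarity of their established
non-native species sets, J(A,B) = |A∩B| / |A∪B| (two empty assemblages
are defined as similarity 0).  The country graph has one node per country
(attributes: richness, region) and an undirected edge wherever similarity
exceeds a threshold (default 0: every positive similarity).  The underlying
country × species incidence can also be exported as a true bipartite graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .records import OccurrenceMatrix

__all__ = [
    "SimilarityMatrix",
    "jaccard_matrix",
    "build_country_graph",
    "network_metrics",
    "bipartite_graph",
]


@dataclass
class SimilarityMatrix:
    countries: list[str]
    values: np.ndarray  # symmetric, unit diagonal, entries in [0, 1]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.countries), len(self.countries)):
            raise ValueError("similarity shape does not match country labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if np.any((v < 0) | (v > 1)):
            raise ValueError("similarities must lie in [0, 1]")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.countries, columns=self.countries
        )


def jaccard_matrix(matrix: OccurrenceMatrix) -> SimilarityMatrix:
    """Pairwise Jaccard similarity between country assemblages."""
    if len(matrix.countries) < 2:
        raise ValueError("need at least 2 countries")
    B = matrix.presence.astype(np.int64)
    inter = B @ B.T
    sizes = B.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(countries=list(matrix.countries), values=sim)


def build_country_graph(
    sim: SimilarityMatrix,
    richness: pd.Series,
    regions: pd.Series,
    threshold: float = 0.0,
) -> nx.Graph:
    """Country graph: nodes always present, edges where similarity > threshold."""
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must lie in [0, 1)")
    missing = [c for c in sim.countries if c not in richness.index or c not in regions.index]
    if missing:
        raise ValueError(f"attributes missing for countries: {missing}")
    g = nx.Graph(threshold=threshold)
    for c in sim.countries:
        g.add_node(c, richness=int(richness[c]), region=str(regions[c]))
    n = len(sim.countries)
    for i in range(n):
        for j in range(i + 1, n):
            w = float(sim.values[i, j])
            if w > threshold:
                g.add_edge(sim.countries[i], sim.countries[j], weight=w)
    return g


def network_metrics(graph: nx.Graph) -> pd.DataFrame:
    """Degree, strength (weighted degree) and isolation per country.

    Rows are ranked by descending strength with a lexicographic country
    tie-break, so the ordering is deterministic.
    """
    rows = [
        {
            "country": node,
            "degree": graph.degree(node),
            "strength": float(graph.degree(node, weight="weight")),
            "is_isolated": graph.degree(node) == 0,
        }
        for node in graph.nodes
    ]
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        ["strength", "country"], ascending=[False, True]
    ).reset_index(drop=True)


def bipartite_graph(matrix: OccurrenceMatrix) -> nx.Graph:
    """Country-species incidence as a bipartite graph (bipartite attr 0/1)."""
    g = nx.Graph()
    g.add_nodes_from(matrix.countries, bipartite=0)
    g.add_nodes_from(matrix.species, bipartite=1)
    rows, cols = np.nonzero(matrix.presence)
    g.add_edges_from(
        (matrix.countries[i], matrix.species[j]) for i, j in zip(rows, cols)
    )
    return g


def write_graph_outputs(graph: nx.Graph, outdir: str | Path, stem: str = "network") -> None:
    """GraphML plus an edge-list CSV."""
    outdir = Path(outdir)
    nx.write_graphml(graph, outdir / f"{stem}.graphml")
    edges = pd.DataFrame(
        [
            {"source": u, "target": v, "weight": d.get("weight", 1.0)}
            for u, v, d in sorted(graph.edges(data=True))
        ]
    )
    edges.to_csv(outdir / f"{stem}_edges.csv", index=False)
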