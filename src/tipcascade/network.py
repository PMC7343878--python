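"""Social network container and Erdős–Rényi generation.

Networks are undirected simple graphs held as :class:`networkx.Graph` objects
with a cached sparse adjacency matrix for the cascade dynamics.  Synthetic
ER networks record their generation metadata (linking probability, target
mean degree, seed).  Edge lists are exchanged as whitespace-delimited text
with a one-line header ``N <count>`` so isolated nodes survive round trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .errors import ParameterError


@dataclass
class SocialNetwork:
    """An undirected simple graph over nodes ``0 .. N-1``."""

    graph: nx.Graph
    link_prob: float | None = None
    mean_degree_target: float | None = None
    seed: int | None = None
    _adjacency: sp.csr_array | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ParameterError("self-loops are not allowed")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def adjacency(self) -> sp.csr_array:
        """Sparse adjacency in node order 0..N-1 (cached)."""
        if self._adjacency is None:
            self._adjacency = nx.to_scipy_sparse_array(
                self.graph, nodelist=range(self.n_nodes), format="csr", dtype=np.float64
            )
        return self._adjacency

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    @property
    def mean_degree(self) -> float:
        return float(self.degrees.mean())

    @classmethod
    def from_edges(cls, N: int, edges, **meta) -> "SocialNetwork":
        G = nx.Graph()
        G.add_nodes_from(range(N))
        G.add_edges_from((int(u), int(v)) for u, v in edges)
        return cls(graph=G, **meta)

    @classmethod
    def from_edgelist(cls, path: str | Path) -> "SocialNetwork":
        """Read an edge list with header line ``N <count>`` and 0-based ids."""
        lines = Path(path).read_text().split("\n")
        header = lines[0].split()
        if len(header) != 2 or header[0] != "N":
            raise ParameterError(f"{path}: first line must be 'N <count>'")
        N = int(header[1])
        edges = [tuple(map(int, ln.split())) for ln in lines[1:] if ln.strip()]
        return cls.from_edges(N, edges)

    def to_edgelist(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"N {self.n_nodes}\n")
            for u, v in sorted(self.graph.edges):
                fh.write(f"{u} {v}\n")

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, path)


def generate_er_network(
    N: int,
    mean_degree: float | None = None,
    link_prob: float | None = None,
    seed: int | None = None,
) -> SocialNetwork:
    """Sample a G(N, l) Erdős–Rényi network.

    Exactly one of ``mean_degree`` (K) or ``link_prob`` (l) must be given;
    when K is supplied the linking probability is ``l = K / (N - 1)``, so the
    expected mean degree equals K.

    Parameters
    ----------
    N : int
        Number of nodes, at least 2.
    mean_degree : float, optional
        Target mean degree K with ``0 < K <= N - 1``.
    link_prob : float, optional
        Linking probability l with ``0 < l <= 1``.
    seed : int, optional
        RNG seed recorded in the metadata.
    """
    if N < 2:
        raise ParameterError(f"need at least two nodes, got N={N}")
    if (mean_degree is None) == (link_prob is None):
        raise ParameterError("supply exactly one of mean_degree or link_prob")
    if link_prob is None:
        if not (0 < mean_degree <= N - 1):
            raise ParameterError(f"mean degree must lie in (0, N-1], got {mean_degree}")
        link_prob = mean_degree / (N - 1)
    if not (0 < link_prob <= 1):
        raise ParameterError(f"linking probability must lie in (0, 1], got {link_prob}")

    if link_prob >= 1.0:
        G = nx.complete_graph(N)
    else:
        G = nx.fast_gnp_random_graph(N, link_prob, seed=seed)
    return SocialNetwork(
        graph=G, link_prob=link_prob, mean_degree_target=link_prob * (N - 1), seed=seed
    )
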