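"""Core data model: networks, cross-network vertex similarity, alignments.

Networks are simple graphs held as dense adjacency matrices addressed by
string vertex identifiers at the API boundary.  Vertex similarity between
two networks is a sparse non-negative matrix Theta in arbitrary units
(e.g. BLAST bit scores); an absent entry means similarity 0.  An alignment
is an injective partial map between the two vertex sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

__all__ = [
    "Network",
    "SimilarityMatrix",
    "Alignment",
    "validate_inputs",
    "invert_alignment",
    "induced_edge_alignment",
]


class NetworkError(ValueError):
    """Raised when a network, similarity matrix or alignment is malformed."""


@dataclass
class Network:
    """A simple weighted or binary graph.

    Parameters
    ----------
    vertex_ids
        Ordered unique string identifiers, one per vertex.
    adjacency
        N x N matrix of edge weights; 0 means "no edge".  The diagonal is
        ignored throughout (self-loops are never scored).
    directed
        If False the adjacency must be symmetric.
    weight_kind
        ``"binary"`` (entries in {0, 1}) or ``"continuous"``.
    """

    vertex_ids: List[str]
    adjacency: np.ndarray
    directed: bool = False
    weight_kind: str = "continuous"
    _index: Dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertex_ids = [str(v) for v in self.vertex_ids]
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        n = len(self.vertex_ids)
        if self.adjacency.shape != (n, n):
            raise NetworkError(
                f"adjacency must be {n}x{n}, got {self.adjacency.shape}"
            )
        if len(set(self.vertex_ids)) != n:
            raise NetworkError("vertex identifiers must be unique")
        if not np.all(np.isfinite(self.adjacency)):
            raise NetworkError("adjacency contains non-finite entries")
        if not self.directed and not np.allclose(
            self.adjacency, self.adjacency.T
        ):
            raise NetworkError(
                "undirected network has an asymmetric adjacency matrix"
            )
        if self.weight_kind == "binary":
            vals = np.unique(self.adjacency)
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise NetworkError(
                    "binary network has entries outside {0, 1}"
                )
        elif self.weight_kind != "continuous":
            raise NetworkError(f"unknown weight_kind {self.weight_kind!r}")
        self._index = {v: i for i, v in enumerate(self.vertex_ids)}

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_ids)

    def index_of(self, vertex: str) -> int:
        try:
            return self._index[vertex]
        except KeyError:
            raise NetworkError(f"unknown vertex id {vertex!r}") from None

    def weight(self, u: str, v: str) -> float:
        return float(self.adjacency[self.index_of(u), self.index_of(v)])

    def offdiag_weights(self) -> np.ndarray:
        """All pair weights: upper triangle if undirected, else all i != j."""
        n = self.n_vertices
        if self.directed:
            mask = ~np.eye(n, dtype=bool)
            return self.adjacency[mask]
        iu = np.triu_indices(n, k=1)
        return self.adjacency[iu]


@dataclass
class SimilarityMatrix:
    """Sparse cross-network vertex similarities theta(i, i') >= 0."""

    rows: List[str]
    cols: List[str]
    entries: Dict[Tuple[str, str], float]

    def __post_init__(self) -> None:
        self.rows = [str(v) for v in self.rows]
        self.cols = [str(v) for v in self.cols]
        row_set, col_set = set(self.rows), set(self.cols)
        if len(row_set) != len(self.rows) or len(col_set) != len(self.cols):
            raise NetworkError("similarity matrix ids must be unique")
        clean: Dict[Tuple[str, str], float] = {}
        for (i, j), theta in self.entries.items():
            theta = float(theta)
            if not np.isfinite(theta) or theta < 0:
                raise NetworkError(
                    f"similarity theta({i!r}, {j!r}) = {theta} must be "
                    "finite and non-negative"
                )
            if i not in row_set:
                raise NetworkError(f"unknown row vertex id {i!r} in theta")
            if j not in col_set:
                raise NetworkError(f"unknown column vertex id {j!r} in theta")
            if theta > 0:
                clean[(str(i), str(j))] = theta
        self.entries = clean

    def get(self, i: str, j: str) -> float:
        return self.entries.get((i, j), 0.0)

    def transpose(self) -> "SimilarityMatrix":
        return SimilarityMatrix(
            rows=list(self.cols),
            cols=list(self.rows),
            entries={(j, i): t for (i, j), t in self.entries.items()},
        )

    def to_dense(self, g: Network, g2: Network) -> np.ndarray:
        """Dense theta matrix in the vertex order of the two networks."""
        dense = np.zeros((g.n_vertices, g2.n_vertices))
        for (i, j), theta in self.entries.items():
            dense[g.index_of(i), g2.index_of(j)] = theta
        return dense

    def nonzero_values(self) -> np.ndarray:
        return np.fromiter(self.entries.values(), dtype=float,
                           count=len(self.entries))


@dataclass
class Alignment:
    """Injective partial map from vertices of G to vertices of G'."""

    pairs: Dict[str, str]

    def __post_init__(self) -> None:
        self.pairs = {str(i): str(j) for i, j in self.pairs.items()}
        if len(set(self.pairs.values())) != len(self.pairs):
            raise NetworkError("alignment is not injective")

    def __len__(self) -> int:
        return len(self.pairs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return self.pairs == other.pairs

    def __contains__(self, vertex: str) -> bool:
        return vertex in self.pairs

    def partner(self, vertex: str) -> str | None:
        return self.pairs.get(vertex)

    def items(self) -> Iterable[Tuple[str, str]]:
        return self.pairs.items()

    def restricted_to(self, g: Network, g2: Network) -> "Alignment":
        """Drop pairs referring to vertices absent from either network."""
        keep = {
            i: j
            for i, j in self.pairs.items()
            if i in g._index and j in g2._index
        }
        return Alignment(keep)


def validate_inputs(
    g: Network, g2: Network, theta: SimilarityMatrix
) -> Tuple[Network, SimilarityMatrix, Network | SimilarityMatrix]:
    """Cross-check vertex identifiers between networks and theta.

    Returns the (g, g2, theta) triple unchanged if consistent; raises
    :class:`NetworkError` naming the offending identifier otherwise.
    """
    g_ids, g2_ids = set(g.vertex_ids), set(g2.vertex_ids)
    for i in theta.rows:
        if i not in g_ids:
            raise NetworkError(f"theta row id {i!r} not in first network")
    for j in theta.cols:
        if j not in g2_ids:
            raise NetworkError(f"theta column id {j!r} not in second network")
    return g, g2, theta


def invert_alignment(a: Alignment) -> Alignment:
    """Swap the roles of the two networks: (i, i') becomes (i', i)."""
    return Alignment({j: i for i, j in a.pairs.items()})


def induced_edge_alignment(
    a: Alignment, g: Network, g2: Network
) -> List[Tuple[Tuple[str, str], Tuple[str, str]]]:
    """Vertex-pair tuples ((i, j), (A(i), A(j))) induced by the alignment.

    Covers every pair of distinct aligned vertices whether or not either
    network actually has an edge there — the shared *absence* of an edge is
    informative and is scored too.  Unordered pairs for undirected networks,
    ordered pairs for directed ones.
    """
    aligned = [(i, j) for i, j in a.pairs.items()]
    out: List[Tuple[Tuple[str, str], Tuple[str, str]]] = []
    directed = g.directed or g2.directed
    for u in range(len(aligned)):
        i, ip = aligned[u]
        for v in range(len(aligned)):
            if directed:
                if u == v:
                    continue
            elif v <= u:
                continue
            j, jp = aligned[v]
            out.append(((i, j), (ip, jp)))
    return out
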