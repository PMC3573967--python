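"""Log-likelihood-ratio scoring of alignments.

Three score tables drive the alignment:

* ``s_edge(a, a')     = log Q(a, a') / (P(a) P'(a'))`` — how much more likely
  the pair of edge weights (a in G, a' in G') is under shared ancestry of the
  incident vertex pairs than under independence;
* ``s_aligned(theta)     = log Q_o(theta) / P(theta)`` — evidence from the
  vertex similarity of a putative ortholog pair;
* ``s_not_aligned(theta) = log Q_u(theta) / P(theta)`` — the (usually
  negative) evidence carried by similarity between non-partner pairs.

All distributions are estimated empirically from a current alignment as
binned histograms with Laplace smoothing, so the scoring parameters are
inferred from the data being aligned rather than supplied by the user.
The total score of an alignment A is S(A) = Se(A) + Sv(A): the edge part
sums s_edge over all pairs of aligned vertices (absence of an edge in both
networks is scored, not skipped) and the vertex part sums s_aligned over
aligned pairs plus s_not_aligned over each aligned vertex's non-partners.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence, TextIO, Tuple

import numpy as np

from .core import Alignment, Network, NetworkError, SimilarityMatrix

__all__ = [
    "BinSpec",
    "ScoreTables",
    "ScoreBreakdown",
    "estimate_score_tables",
    "edge_score",
    "vertex_scores",
    "edge_score_total",
    "vertex_score_total",
    "total_score",
    "write_score_tables",
    "read_score_tables",
]


@dataclass(frozen=True)
class BinSpec:
    """Discretization of edge weights and vertex similarities.

    Bins are left-closed, right-open; the last bin is right-closed and
    lookups outside the range clamp to the extreme bins.  The first theta
    bin is reserved for theta = 0 (absent similarity).
    """

    edge_bin_edges: np.ndarray
    theta_bin_edges: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "edge_bin_edges", np.asarray(self.edge_bin_edges, float)
        )
        object.__setattr__(
            self, "theta_bin_edges", np.asarray(self.theta_bin_edges, float)
        )
        for name, edges in (
            ("edge", self.edge_bin_edges),
            ("theta", self.theta_bin_edges),
        ):
            if edges.ndim != 1 or edges.size < 3:
                raise NetworkError(f"{name} bins need at least 2 bins")
            if not np.all(np.diff(edges) > 0):
                raise NetworkError(f"{name} bin edges must strictly increase")

    @property
    def n_edge_bins(self) -> int:
        return self.edge_bin_edges.size - 1

    @property
    def n_theta_bins(self) -> int:
        return self.theta_bin_edges.size - 1

    def edge_bin(self, w) -> np.ndarray:
        return _bin_index(self.edge_bin_edges, w)

    def theta_bin(self, theta) -> np.ndarray:
        return _bin_index(self.theta_bin_edges, theta)

    @classmethod
    def for_data(
        cls,
        g: Network,
        g2: Network,
        theta: SimilarityMatrix,
        n_edge_bins: int = 8,
        n_theta_bins: int = 8,
    ) -> "BinSpec":
        """Default bins: {0},{1} for binary networks, equal-width otherwise;
        theta gets a reserved zero bin plus equal-width bins over (0, max]."""
        if g.weight_kind == "binary" and g2.weight_kind == "binary":
            edge_edges = np.array([0.0, 0.5, 1.0])
        else:
            w_max = max(
                float(g.adjacency.max(initial=0.0)),
                float(g2.adjacency.max(initial=0.0)),
            )
            if w_max <= 0:
                w_max = 1.0
            edge_edges = np.linspace(0.0, w_max, n_edge_bins + 1)
        vals = theta.nonzero_values()
        if vals.size == 0:
            theta_edges = np.array([0.0, 0.5, 1.0])
        else:
            t_max = float(vals.max())
            t_min = float(vals.min())
            width = t_max / (n_theta_bins - 1)
            tiny = min(t_min, width) / 2.0
            inner = np.linspace(0.0, t_max, n_theta_bins)
            inner[0] = tiny
            theta_edges = np.concatenate([[0.0], inner])
        return cls(edge_edges, theta_edges)


def _bin_index(edges: np.ndarray, values) -> np.ndarray:
    idx = np.searchsorted(edges, np.asarray(values, float), side="right") - 1
    return np.clip(idx, 0, edges.size - 2)


class ScoreBreakdown(NamedTuple):
    total: float
    edge: float
    vertex: float


@dataclass
class ScoreTables:
    """Empirical distributions and the log-likelihood-ratio tables.

    ``joint_edge`` estimates the joint distribution of edge weights over
    aligned vertex pairs, the two marginals come from all vertex pairs of
    each whole network (pooled into one histogram when the alignment is to
    treat G and G' symmetrically), and the three theta distributions compare
    partner pairs / non-partner pairs against a background of similarities
    involving unaligned vertices.
    """

    joint_edge: np.ndarray
    marginal_edge_g: np.ndarray
    marginal_edge_g2: np.ndarray
    q_ortho_theta: np.ndarray
    q_unrel_theta: np.ndarray
    background_theta: np.ndarray
    s_edge: np.ndarray
    s_aligned: np.ndarray
    s_not_aligned: np.ndarray
    pseudocount: float

    @classmethod
    def from_counts(
        cls,
        joint_edge_counts: np.ndarray,
        marginal_g_counts: np.ndarray,
        marginal_g2_counts: np.ndarray,
        q_ortho_counts: np.ndarray,
        q_unrel_counts: np.ndarray,
        background_counts: np.ndarray,
        pseudocount: float = 1.0,
    ) -> "ScoreTables":
        """Build normalized tables from raw histogram counts.

        Every cell receives the pseudocount before normalization so all
        log-ratios are finite.
        """
        if pseudocount <= 0:
            raise NetworkError("pseudocount must be positive")

        def norm(c: np.ndarray) -> np.ndarray:
            c = np.asarray(c, float) + pseudocount
            return c / c.sum()

        joint = norm(joint_edge_counts)
        mg = norm(marginal_g_counts)
        mg2 = norm(marginal_g2_counts)
        q_o = norm(q_ortho_counts)
        q_u = norm(q_unrel_counts)
        bg = norm(background_counts)
        s_edge = np.log(joint / np.outer(mg, mg2))
        s_aligned = np.log(q_o / bg)
        s_not_aligned = np.log(q_u / bg)
        return cls(
            joint_edge=joint,
            marginal_edge_g=mg,
            marginal_edge_g2=mg2,
            q_ortho_theta=q_o,
            q_unrel_theta=q_u,
            background_theta=bg,
            s_edge=s_edge,
            s_aligned=s_aligned,
            s_not_aligned=s_not_aligned,
            pseudocount=float(pseudocount),
        )


def estimate_score_tables(
    g: Network,
    g2: Network,
    theta: SimilarityMatrix,
    a: Alignment,
    bins: BinSpec,
    pseudocount: float = 1.0,
    pooled: bool = True,
) -> ScoreTables:
    """Maximum-likelihood estimation of the score tables from an alignment.

    Parameters
    ----------
    pooled
        If True (default) the two edge-weight marginals are pooled into one
        histogram, the joint histogram is symmetrized, and the non-partner
        theta distribution is estimated from the symmetric set of cross
        pairs with at least one aligned endpoint; this makes the scoring
        exactly invariant under swapping the two networks.
    """
    if len(a) < 2:
        raise NetworkError("need at least 2 aligned pairs to estimate tables")
    b_edge, b_theta = bins.n_edge_bins, bins.n_theta_bins

    # joint edge-weight histogram over aligned vertex pairs
    idx_g = np.array([g.index_of(i) for i in a.pairs], dtype=int)
    idx_g2 = np.array([g2.index_of(j) for j in a.pairs.values()], dtype=int)
    sub_g = g.adjacency[np.ix_(idx_g, idx_g)]
    sub_g2 = g2.adjacency[np.ix_(idx_g2, idx_g2)]
    k = idx_g.size
    if g.directed or g2.directed:
        mask = ~np.eye(k, dtype=bool)
        w_pairs, w2_pairs = sub_g[mask], sub_g2[mask]
    else:
        iu = np.triu_indices(k, k=1)
        w_pairs, w2_pairs = sub_g[iu], sub_g2[iu]
    joint = np.zeros((b_edge, b_edge))
    np.add.at(joint, (bins.edge_bin(w_pairs), bins.edge_bin(w2_pairs)), 1.0)
    if pooled:
        joint = (joint + joint.T) / 2.0

    marg_g = np.bincount(
        bins.edge_bin(g.offdiag_weights()), minlength=b_edge
    ).astype(float)
    marg_g2 = np.bincount(
        bins.edge_bin(g2.offdiag_weights()), minlength=b_edge
    ).astype(float)
    if pooled:
        marg_g = marg_g2 = (marg_g + marg_g2) / 2.0

    # theta histograms; zeros counted in closed form (theta is sparse)
    n, n2 = g.n_vertices, g2.n_vertices
    domain = set(a.pairs)
    codomain = set(a.pairs.values())
    partner = set(a.pairs.items())

    q_o = np.zeros(b_theta)
    ortho_vals = np.array([theta.get(i, j) for i, j in a.pairs.items()])
    np.add.at(q_o, bins.theta_bin(ortho_vals), 1.0)

    q_u = np.zeros(b_theta)
    if pooled:
        # pairs with >=1 aligned endpoint, excluding the partner pairs
        total_u = n * n2 - (n - k) * (n2 - k) - k
        u_vals = [
            t for (i, j), t in theta.entries.items()
            if (i in domain or j in codomain) and (i, j) not in partner
        ]
    else:
        total_u = k * (n2 - 1)
        u_vals = [
            t for (i, j), t in theta.entries.items()
            if i in domain and a.pairs[i] != j
        ]
    if u_vals:
        np.add.at(q_u, bins.theta_bin(np.asarray(u_vals)), 1.0)
    q_u[0] += max(total_u - len(u_vals), 0)

    bg = np.zeros(b_theta)
    total_bg = n * n2 - k * k
    if total_bg < 10 * b_theta:
        import logging

        logging.getLogger(__name__).warning(
            "fewer than %d theta pairs involve an unaligned vertex; "
            "falling back to all theta values for the background",
            10 * b_theta,
        )
        total_bg = n * n2
        bg_vals = list(theta.entries.values())
    else:
        bg_vals = [
            t for (i, j), t in theta.entries.items()
            if i not in domain or j not in codomain
        ]
    if bg_vals:
        np.add.at(bg, bins.theta_bin(np.asarray(bg_vals)), 1.0)
    bg[0] += max(total_bg - len(bg_vals), 0)

    return ScoreTables.from_counts(
        joint, marg_g, marg_g2, q_o, q_u, bg, pseudocount
    )


def edge_score(tables: ScoreTables, w: float, w2: float, bins: BinSpec) -> float:
    """s_edge for one pair of edge weights (bin lookup with clamping)."""
    return float(tables.s_edge[int(bins.edge_bin(w)), int(bins.edge_bin(w2))])


def vertex_scores(
    tables: ScoreTables, theta_value: float, bins: BinSpec
) -> Tuple[float, float]:
    """(s_aligned, s_not_aligned) for one similarity value."""
    b = int(bins.theta_bin(theta_value))
    return float(tables.s_aligned[b]), float(tables.s_not_aligned[b])


def edge_score_total(
    g: Network,
    g2: Network,
    a: Alignment,
    tables: ScoreTables,
    bins: BinSpec,
) -> float:
    """Se(A): sum of s_edge over all pairs of aligned vertices."""
    if len(a) < 2:
        return 0.0
    idx_g = np.array([g.index_of(i) for i in a.pairs], dtype=int)
    idx_g2 = np.array([g2.index_of(j) for j in a.pairs.values()], dtype=int)
    sub_g = g.adjacency[np.ix_(idx_g, idx_g)]
    sub_g2 = g2.adjacency[np.ix_(idx_g2, idx_g2)]
    k = idx_g.size
    if g.directed or g2.directed:
        mask = ~np.eye(k, dtype=bool)
        w, w2 = sub_g[mask], sub_g2[mask]
    else:
        iu = np.triu_indices(k, k=1)
        w, w2 = sub_g[iu], sub_g2[iu]
    return float(tables.s_edge[bins.edge_bin(w), bins.edge_bin(w2)].sum())


def vertex_score_total(
    theta: SimilarityMatrix,
    a: Alignment,
    tables: ScoreTables,
    bins: BinSpec,
) -> float:
    """Sv(A): aligned-pair similarity scores plus, for each aligned vertex,
    the not-aligned scores against every non-partner in the other network.

    Absent theta entries fall in the reserved zero bin; their contribution
    is added in closed form so the cost stays O(nnz(theta))."""
    if len(a) == 0:
        return 0.0
    n2 = len(theta.cols)
    s_na0 = float(tables.s_not_aligned[0])
    total = 0.0
    nonzero_na = 0
    domain = set(a.pairs)
    for i, j in a.pairs.items():
        t = theta.get(i, j)
        total += float(tables.s_aligned[int(bins.theta_bin(t))])
    for (i, j), t in theta.entries.items():
        if i in domain and a.pairs[i] != j:
            total += float(tables.s_not_aligned[int(bins.theta_bin(t))])
            nonzero_na += 1
    total += (len(a) * (n2 - 1) - nonzero_na) * s_na0
    return total


def total_score(
    g: Network,
    g2: Network,
    theta: SimilarityMatrix,
    a: Alignment,
    tables: ScoreTables,
    bins: BinSpec,
) -> ScoreBreakdown:
    """S(A) = Se(A) + Sv(A), with both components."""
    se = edge_score_total(g, g2, a, tables, bins)
    sv = vertex_score_total(theta, a, tables, bins)
    return ScoreBreakdown(total=se + sv, edge=se, vertex=sv)


# -- serialization ----------------------------------------------------------

_VECTORS = (
    "marginal_edge_g",
    "marginal_edge_g2",
    "q_ortho_theta",
    "q_unrel_theta",
    "background_theta",
    "s_aligned",
    "s_not_aligned",
)
_MATRICES = ("joint_edge", "s_edge")


def write_score_tables(
    tables: ScoreTables, bins: BinSpec, fh: TextIO
) -> None:
    """Flat TSV dump of bin edges and all table cells (full precision)."""
    def fmt(x: float) -> str:
        return "%.17g" % x

    fh.write("# netalign score tables\n")
    fh.write("edge_bin_edges\t" + "\t".join(map(fmt, bins.edge_bin_edges)) + "\n")
    fh.write("theta_bin_edges\t" + "\t".join(map(fmt, bins.theta_bin_edges)) + "\n")
    fh.write("pseudocount\t" + fmt(tables.pseudocount) + "\n")
    for name in _VECTORS:
        vec = getattr(tables, name)
        fh.write(name + "\t" + "\t".join(map(fmt, vec)) + "\n")
    for name in _MATRICES:
        mat = getattr(tables, name)
        for r, row in enumerate(mat):
            fh.write(f"{name}[{r}]\t" + "\t".join(map(fmt, row)) + "\n")


def read_score_tables(fh: TextIO) -> Tuple[ScoreTables, BinSpec]:
    rows: dict = {}
    mats: dict = {}
    for line in fh:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        key, *vals = line.split("\t")
        vec = np.array([float(v) for v in vals])
        if "[" in key:
            name, r = key[:-1].split("[")
            mats.setdefault(name, {})[int(r)] = vec
        else:
            rows[key] = vec
    bins = BinSpec(rows["edge_bin_edges"], rows["theta_bin_edges"])
    mat_arrays = {
        name: np.vstack([d[r] for r in sorted(d)]) for name, d in mats.items()
    }
    tables = ScoreTables(
        joint_edge=mat_arrays["joint_edge"],
        marginal_edge_g=rows["marginal_edge_g"],
        marginal_edge_g2=rows["marginal_edge_g2"],
        q_ortho_theta=rows["q_ortho_theta"],
        q_unrel_theta=rows["q_unrel_theta"],
        background_theta=rows["background_theta"],
        s_edge=mat_arrays["s_edge"],
        s_aligned=rows["s_aligned"],
        s_not_aligned=rows["s_not_aligned"],
        pseudocount=float(rows["pseudocount"][0]),
    )
    return tables, bins
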