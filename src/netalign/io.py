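"""Readers and writers for all supported text formats, plus the empirical
preprocessing steps: BLAST-derived vertex similarity, orphan removal and
co-expression network construction.

All files are TSV with '#'-prefixed comment headers.  Floats are written
with 17 significant digits so round-trips reproduce the in-memory values
bit-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .core import Alignment, Network, NetworkError, SimilarityMatrix
from .simulate import SimulatedPair

logger = logging.getLogger(__name__)

__all__ = [
    "read_network",
    "write_network",
    "read_theta",
    "write_theta",
    "read_theta_from_blast",
    "read_alignment",
    "write_alignment",
    "read_truth_table",
    "write_simulated_pair",
    "drop_orphans",
    "ExpressionMatrix",
    "read_expression",
    "coexpression_network",
]

PathLike = Union[str, Path]
BLAST_EVALUE_CUTOFF = 1e-10

def _fmt(x: float) -> str:
    return "%.17g" % float(x)


# -- networks ---------------------------------------------------------------

def read_network(
    path: PathLike,
    format: str = "edgelist",
    directed: bool = False,
) -> Network:
    """Read a network from an edge-list or dense-matrix TSV.

    Edge-list rows are ``vertex1<TAB>vertex2[<TAB>weight]`` (weight defaults
    to 1).  Undirected duplicates must agree on the weight; a conflicting
    duplicate raises an error naming the pair.
    """
    if format == "matrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#",
                         float_precision="round_trip")
        ids = [str(v) for v in df.index]
        if [str(c) for c in df.columns] != ids:
            raise NetworkError("matrix row and column ids differ")
        adj = df.to_numpy(dtype=float)
        kind = "binary" if np.all(np.isin(adj, (0.0, 1.0))) else "continuous"
        return Network(ids, adj, directed=directed, weight_kind=kind)
    if format != "edgelist":
        raise NetworkError(f"unknown network format {format!r}")

    edges: Dict[Tuple[str, str], float] = {}
    ids: List[str] = []
    seen = set()

    def add_vertex(v: str) -> None:
        if v not in seen:
            seen.add(v)
            ids.append(v)

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise NetworkError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}"
                )
            u, v = parts[0], parts[1]
            try:
                w = float(parts[2]) if len(parts) == 3 else 1.0
            except ValueError:
                raise NetworkError(
                    f"{path}:{lineno}: non-numeric weight {parts[2]!r}"
                ) from None
            add_vertex(u)
            add_vertex(v)
            key = (u, v) if directed else (min(u, v), max(u, v))
            if key in edges and edges[key] != w:
                raise NetworkError(
                    f"{path}:{lineno}: conflicting duplicate edge "
                    f"({u!r}, {v!r}): {edges[key]} vs {w}"
                )
            edges[key] = w

    n = len(ids)
    index = {v: i for i, v in enumerate(ids)}
    adj = np.zeros((n, n))
    for (u, v), w in edges.items():
        adj[index[u], index[v]] = w
        if not directed:
            adj[index[v], index[u]] = w
    kind = "binary" if np.all(np.isin(adj, (0.0, 1.0))) else "continuous"
    return Network(ids, adj, directed=directed, weight_kind=kind)


def write_network(g: Network, path: PathLike, format: str = "edgelist") -> None:
    if format == "matrix":
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(g.vertex_ids) + "\n")
            for i, vid in enumerate(g.vertex_ids):
                fh.write(vid + "\t" + "\t".join(map(_fmt, g.adjacency[i])) + "\n")
        return
    if format != "edgelist":
        raise NetworkError(f"unknown network format {format!r}")
    with open(path, "w") as fh:
        fh.write(f"# netalign network directed={g.directed} "
                 f"weight_kind={g.weight_kind}\n")
        n = g.n_vertices
        for i in range(n):
            for j in range(n if g.directed else n):
                if not g.directed and j <= i:
                    continue
                if i == j:
                    continue
                w = g.adjacency[i, j]
                if w != 0:
                    fh.write(f"{g.vertex_ids[i]}\t{g.vertex_ids[j]}\t{_fmt(w)}\n")


# -- vertex similarity ------------------------------------------------------

def read_theta(
    path: PathLike,
    rows: Optional[List[str]] = None,
    cols: Optional[List[str]] = None,
) -> SimilarityMatrix:
    """Sparse triplet TSV: vertex_g, vertex_g2, theta.  Row/column id lists
    default to the ids seen in the file."""
    entries: Dict[Tuple[str, str], float] = {}
    seen_rows: List[str] = []
    seen_cols: List[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise NetworkError(
                    f"{path}:{lineno}: expected 3 columns, got {len(parts)}"
                )
            i, j, t = parts
            try:
                entries[(i, j)] = float(t)
            except ValueError:
                raise NetworkError(
                    f"{path}:{lineno}: non-numeric theta {t!r}"
                ) from None
            if i not in seen_rows:
                seen_rows.append(i)
            if j not in seen_cols:
                seen_cols.append(j)
    return SimilarityMatrix(
        rows if rows is not None else seen_rows,
        cols if cols is not None else seen_cols,
        entries,
    )


def write_theta(theta: SimilarityMatrix, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("# netalign theta triplets: vertex_g\tvertex_g2\ttheta\n")
        for (i, j), t in sorted(theta.entries.items()):
            fh.write(f"{i}\t{j}\t{_fmt(t)}\n")


def read_theta_from_blast(
    path: PathLike,
    rows: Optional[List[str]] = None,
    cols: Optional[List[str]] = None,
    evalue_cutoff: float = BLAST_EVALUE_CUTOFF,
) -> SimilarityMatrix:
    """Vertex similarity from 12-column tabular BLAST output (-outfmt 6).

    Hits with e-value >= the cutoff (default 1e-10) are discarded; the
    similarity of a pair is the maximum bit score over its retained hits.
    """
    entries: Dict[Tuple[str, str], float] = {}
    seen_rows: List[str] = []
    seen_cols: List[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise NetworkError(
                    f"{path}:{lineno}: expected 12 BLAST columns, got "
                    f"{len(parts)}"
                )
            query, subject = parts[0], parts[1]
            try:
                evalue = float(parts[10])
                bitscore = float(parts[11])
            except ValueError:
                raise NetworkError(
                    f"{path}:{lineno}: non-numeric e-value or bit score"
                ) from None
            if evalue >= evalue_cutoff:
                continue
            key = (query, subject)
            if key not in entries or bitscore > entries[key]:
                entries[key] = bitscore
            if query not in seen_rows:
                seen_rows.append(query)
            if subject not in seen_cols:
                seen_cols.append(subject)
    return SimilarityMatrix(
        rows if rows is not None else seen_rows,
        cols if cols is not None else seen_cols,
        entries,
    )


# -- alignments -------------------------------------------------------------

def read_alignment(path: PathLike) -> Alignment:
    """Two-or-more-column TSV; the first two columns are the vertex pair."""
    pairs: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise NetworkError(
                    f"{path}:{lineno}: expected >= 2 columns"
                )
            pairs[parts[0]] = parts[1]
    return Alignment(pairs)


def write_alignment(
    path: PathLike,
    alignment: Alignment,
    theta: Optional[SimilarityMatrix] = None,
    total_score: Optional[float] = None,
    edge_component: Optional[float] = None,
    vertex_component: Optional[float] = None,
    seed: Optional[int] = None,
    n_outer_iterations: Optional[int] = None,
    pair_vertex_scores: Optional[Dict[str, float]] = None,
) -> None:
    with open(path, "w") as fh:
        if total_score is not None:
            fh.write(f"# total_score\t{_fmt(total_score)}\n")
            fh.write(f"# edge_score\t{_fmt(edge_component)}\n")
            fh.write(f"# vertex_score\t{_fmt(vertex_component)}\n")
        if seed is not None:
            fh.write(f"# seed\t{seed}\n")
        if n_outer_iterations is not None:
            fh.write(f"# outer_iterations\t{n_outer_iterations}\n")
        fh.write("# vertex_g\tvertex_g2\ttheta\ts_aligned\n")
        for i, j in sorted(alignment.items()):
            t = theta.get(i, j) if theta is not None else 0.0
            s = pair_vertex_scores.get(i, 0.0) if pair_vertex_scores else 0.0
            fh.write(f"{i}\t{j}\t{_fmt(t)}\t{_fmt(s)}\n")


# -- simulation output ------------------------------------------------------

def write_simulated_pair(pair: SimulatedPair, directory: PathLike) -> Dict[str, Path]:
    """Write a benchmark pair as two edge lists, a theta triplet file and a
    truth/labels table; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "network_g": directory / "network_g.tsv",
        "network_g2": directory / "network_g2.tsv",
        "theta": directory / "theta.tsv",
        "truth": directory / "truth.tsv",
    }
    write_network(pair.g, paths["network_g"])
    write_network(pair.g2, paths["network_g2"])
    write_theta(pair.theta, paths["theta"])
    with open(paths["truth"], "w") as fh:
        fh.write("# vertex_g\tlabel\ttrue_partner\tdecoy\n")
        for v in pair.g.vertex_ids:
            fh.write(
                f"{v}\t{pair.labels[v]}\t{pair.truth.get(v, '-')}\t"
                f"{pair.decoys.get(v, '-')}\n"
            )
    return paths


def read_truth_table(path: PathLike) -> Tuple[Dict[str, str], Dict[str, str], Dict[str, str]]:
    """Read the truth/labels TSV back: (truth, labels, decoys)."""
    truth: Dict[str, str] = {}
    labels: Dict[str, str] = {}
    decoys: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            v, lab, partner, decoy = line.split("\t")
            labels[v] = lab
            if partner != "-":
                truth[v] = partner
            if decoy != "-":
                decoys[v] = decoy
    return truth, labels, decoys


# -- preprocessing ----------------------------------------------------------

def drop_orphans(
    g: Network, g2: Network, theta: SimilarityMatrix
) -> Tuple[Network, Network, SimilarityMatrix]:
    """Remove vertices that have no similarity hit in the other network and
    no edge in their own network; such orphans carry no alignment signal."""
    theta_rows = {i for (i, _j) in theta.entries}
    theta_cols = {j for (_i, j) in theta.entries}

    def keep_ids(net: Network, hit: set) -> List[str]:
        degree = np.count_nonzero(net.adjacency, axis=1)
        return [
            v for k, v in enumerate(net.vertex_ids)
            if degree[k] > 0 or v in hit
        ]

    keep_g = keep_ids(g, theta_rows)
    keep_g2 = keep_ids(g2, theta_cols)
    idx_g = [g.index_of(v) for v in keep_g]
    idx_g2 = [g2.index_of(v) for v in keep_g2]
    new_g = Network(
        keep_g, g.adjacency[np.ix_(idx_g, idx_g)], g.directed, g.weight_kind
    )
    new_g2 = Network(
        keep_g2, g2.adjacency[np.ix_(idx_g2, idx_g2)], g2.directed,
        g2.weight_kind,
    )
    kg, kg2 = set(keep_g), set(keep_g2)
    new_theta = SimilarityMatrix(
        keep_g, keep_g2,
        {k: t for k, t in theta.entries.items() if k[0] in kg and k[1] in kg2},
    )
    return new_g, new_g2, new_theta


# -- co-expression networks -------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x profiles expression values; NaN marks a missing observation."""

    gene_ids: List[str]
    profile_ids: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise NetworkError("duplicate gene ids")
        if len(set(self.profile_ids)) != len(self.profile_ids):
            raise NetworkError("duplicate profile ids")
        if len(self.profile_ids) < 2:
            raise NetworkError("need at least 2 expression profiles")
        if self.values.shape != (len(self.gene_ids), len(self.profile_ids)):
            raise NetworkError("expression matrix shape mismatch")


def read_expression(path: PathLike) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return ExpressionMatrix(
        [str(v) for v in df.index],
        [str(c) for c in df.columns],
        df.to_numpy(dtype=float),
    )


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def coexpression_network(
    expr: ExpressionMatrix,
    detection_frac: float = 0.75,
    corr_threshold: float = 0.5,
    fdr_q: float = 0.001,
) -> Network:
    """Weighted co-expression network by absolute Spearman rank correlation.

    Genes observed in fewer than ``detection_frac`` of the profiles are
    excluded.  Correlations are computed over pairwise-complete profiles;
    absolute values strictly below ``corr_threshold`` are hard-set to 0
    (a value exactly at the threshold is kept), and surviving correlations
    must be significant at Benjamini-Hochberg q < ``fdr_q``.  Pairs with
    fewer than 3 complete observations are skipped with a warning.
    """
    n_profiles = len(expr.profile_ids)
    detected = np.mean(~np.isnan(expr.values), axis=1) >= detection_frac
    genes = [v for v, keep in zip(expr.gene_ids, detected) if keep]
    vals = expr.values[detected]
    n = len(genes)
    adj = np.zeros((n, n))
    tested: List[Tuple[int, int, float, float]] = []  # i, j, |rho|, p
    for i in range(n):
        for j in range(i + 1, n):
            complete = ~np.isnan(vals[i]) & ~np.isnan(vals[j])
            n_obs = int(complete.sum())
            if n_obs < 3:
                logger.warning(
                    "skipping pair (%s, %s): only %d complete observations",
                    genes[i], genes[j], n_obs,
                )
                continue
            rho, p = stats.spearmanr(vals[i, complete], vals[j, complete])
            if np.isnan(rho):
                continue
            tested.append((i, j, abs(float(rho)), float(p)))
    if tested:
        q = _bh_adjust(np.array([t[3] for t in tested]))
        for (i, j, arho, _p), qv in zip(tested, q):
            if arho >= corr_threshold and qv < fdr_q:
                adj[i, j] = adj[j, i] = arho
    return Network(genes, adj, directed=False, weight_kind="continuous")
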