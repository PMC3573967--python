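"""Alignment search: iterated linear assignment with annealing noise.

Maximizing the total score over injective maps is a quadratic assignment
problem (the edge term couples pairs of assignments).  It is attacked by
linearizing around the current alignment: holding the partners of all other
vertices fixed, the score gain of pairing i with i' is a simple matrix
M[i, i'], and maximizing its sum is a linear assignment problem.  The LAP
is re-solved repeatedly with i.i.d. Gaussian noise added to M, the noise
amplitude decaying linearly to zero as in simulated annealing, which lets
the search escape local score maxima.  The outer loop alternates this
search with re-estimation of the score tables until the alignment stops
changing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import (
    Alignment,
    Network,
    NetworkError,
    SimilarityMatrix,
    invert_alignment,
    validate_inputs,
)
from .scoring import (
    BinSpec,
    ScoreTables,
    estimate_score_tables,
    total_score,
)

__all__ = [
    "AlignerConfig",
    "AlignmentResult",
    "AssignmentProblem",
    "initial_alignment",
    "build_assignment_matrix",
    "solve_linear_assignment",
    "align_networks",
    "fit_and_align",
]


@dataclass(frozen=True)
class AlignerConfig:
    """Knobs of the annealed LAP search (all in score units / counts)."""

    max_inner_iterations: int = 100
    noise_initial_sd: float = 1.0
    max_outer_iterations: int = 10
    convergence_patience: int = 3
    random_seed: int = 0
    allow_unaligned: bool = True

    def __post_init__(self) -> None:
        if self.max_inner_iterations < 1 or self.max_outer_iterations < 1:
            raise NetworkError("iteration counts must be >= 1")
        if self.convergence_patience < 1:
            raise NetworkError("convergence_patience must be >= 1")
        if self.noise_initial_sd < 0:
            raise NetworkError("noise_initial_sd must be >= 0")

    def noise_sd(self, iteration: int) -> float:
        """Linear decay to 0, leaving the last iterations noise-free."""
        decay_len = max(1, self.max_inner_iterations - self.convergence_patience)
        return self.noise_initial_sd * max(0.0, 1.0 - iteration / decay_len)


@dataclass
class AlignmentResult:
    alignment: Alignment
    total_score: float
    edge_component: float
    vertex_component: float
    tables: ScoreTables
    trajectory: List[Tuple[int, float, float]] = field(default_factory=list)
    converged: bool = False
    n_outer_iterations: int = 1


@dataclass
class AssignmentProblem:
    """LAP instance: score matrix over (i, i') plus zero-valued dummy
    rows/columns that stand for leaving a vertex unaligned."""

    matrix: np.ndarray
    row_ids: List[str]
    col_ids: List[str]

    @property
    def n_rows_real(self) -> int:
        return len(self.row_ids)

    @property
    def n_cols_real(self) -> int:
        return len(self.col_ids)


def initial_alignment(
    theta: SimilarityMatrix, min_theta: float = 0.0
) -> Alignment:
    """Bidirectional best hits by vertex similarity.

    A pair (i, i') is kept when i' is the unique best partner of i and vice
    versa and theta(i, i') >= min_theta.  Ties for best partner disqualify
    the vertex, so e.g. a gene with two equally similar candidate orthologs
    (a paralog pair) seeds nothing and is left for the edge score to decide.
    """
    if min_theta < 0:
        raise NetworkError("min_theta must be >= 0")
    best_row: dict = {}
    best_col: dict = {}
    for (i, j), t in theta.entries.items():
        if t < min_theta:
            continue
        if i not in best_row or t > best_row[i][0]:
            best_row[i] = (t, j, False)
        elif t == best_row[i][0]:
            best_row[i] = (t, j, True)
        if j not in best_col or t > best_col[j][0]:
            best_col[j] = (t, i, False)
        elif t == best_col[j][0]:
            best_col[j] = (t, i, True)
    pairs = {}
    for i, (t, j, tie) in best_row.items():
        if tie:
            continue
        tc, ic, tie_c = best_col[j]
        if tie_c or ic != i:
            continue
        pairs[i] = j
    return Alignment(pairs)


def build_assignment_matrix(
    g: Network,
    g2: Network,
    theta: SimilarityMatrix,
    current: Alignment,
    tables: ScoreTables,
    bins: BinSpec,
    allow_unaligned: bool = True,
) -> AssignmentProblem:
    """Linearize the score around ``current``.

    M[i, i'] = sum over aligned j (j != i, current(j) != i') of
    s_edge(A_ij, A'_{i', current(j)})  +  s_aligned(theta_ii')
    + sum over j' != i' of s_not_aligned(theta_ij').

    The last term (the not-aligned row sum) is constant in i' up to the
    excluded partner, so it never changes which partner is preferred; it is
    kept so that M[i, i'] is the exact score gain of pairing i with i'
    relative to leaving i unaligned, which is what the zero-valued dummy
    rows/columns represent in the LAP.
    """
    n, n2 = g.n_vertices, g2.n_vertices
    s_edge = tables.s_edge

    aligned = [(i, j) for i, j in current.items()]
    m = np.zeros((n, n2))
    if aligned:
        jg = np.array([g.index_of(i) for i, _ in aligned], dtype=int)
        jg2 = np.array([g2.index_of(j) for _, j in aligned], dtype=int)
        bg = bins.edge_bin(g.adjacency[:, jg])      # n x k
        bg2 = bins.edge_bin(g2.adjacency[:, jg2])   # n2 x k
        for b in range(bins.n_edge_bins):
            x = (bg == b).astype(float)
            y = s_edge[b][bg2]                      # n2 x k
            m += x @ y.T
        # remove terms with j == i and with current(j) == i'
        for t in range(jg.size):
            m[jg[t], :] -= s_edge[bg[jg[t], t], bg2[:, t]]
            m[:, jg2[t]] -= s_edge[bg[:, t], bg2[jg2[t], t]]
            m[jg[t], jg2[t]] += s_edge[bg[jg[t], t], bg2[jg2[t], t]]

    theta_dense = theta.to_dense(g, g2)
    tb = bins.theta_bin(theta_dense)
    s_na = tables.s_not_aligned[tb]
    m += tables.s_aligned[tb] - s_na + s_na.sum(axis=1, keepdims=True)

    if allow_unaligned:
        full = np.zeros((n + n2, n + n2))
        full[:n, :n2] = m
        matrix = full
    else:
        matrix = m
    return AssignmentProblem(matrix, list(g.vertex_ids), list(g2.vertex_ids))


def solve_linear_assignment(problem: AssignmentProblem) -> Alignment:
    """Maximize the sum of selected cells; dummy assignments are dropped."""
    if not np.all(np.isfinite(problem.matrix)):
        raise NetworkError("assignment matrix contains non-finite entries")
    rows, cols = linear_sum_assignment(problem.matrix, maximize=True)
    pairs = {}
    for r, c in zip(rows, cols):
        if r < problem.n_rows_real and c < problem.n_cols_real:
            pairs[problem.row_ids[r]] = problem.col_ids[c]
    return Alignment(pairs)


def _orientation_key(g: Network) -> tuple:
    return (tuple(g.vertex_ids), g.adjacency.tobytes())


def _needs_swap(g: Network, g2: Network) -> bool:
    """Canonical orientation makes the search invariant under swapping the
    two input networks: the computation always runs in one fixed order."""
    return _orientation_key(g2) < _orientation_key(g)


def _transpose_tables(tables: ScoreTables) -> ScoreTables:
    return ScoreTables(
        joint_edge=tables.joint_edge.T.copy(),
        marginal_edge_g=tables.marginal_edge_g2,
        marginal_edge_g2=tables.marginal_edge_g,
        q_ortho_theta=tables.q_ortho_theta,
        q_unrel_theta=tables.q_unrel_theta,
        background_theta=tables.background_theta,
        s_edge=tables.s_edge.T.copy(),
        s_aligned=tables.s_aligned,
        s_not_aligned=tables.s_not_aligned,
        pseudocount=tables.pseudocount,
    )


def align_networks(
    g: Network,
    g2: Network,
    theta: SimilarityMatrix,
    start: Alignment,
    tables: ScoreTables,
    bins: BinSpec,
    config: AlignerConfig = AlignerConfig(),
) -> AlignmentResult:
    """Annealed iterated-LAP search with fixed score tables.

    Tracks the best-scoring alignment ever visited (so the returned score
    is never below the start's), stops once the alignment is unchanged for
    ``convergence_patience`` consecutive zero-noise iterations, and is
    deterministic for a fixed ``random_seed``.
    """
    if _needs_swap(g, g2):
        res = align_networks(
            g2, g, theta.transpose(), invert_alignment(start),
            _transpose_tables(tables), bins, config,
        )
        res.alignment = invert_alignment(res.alignment)
        return res

    rng = np.random.default_rng(config.random_seed)
    n, n2 = g.n_vertices, g2.n_vertices

    def score(a: Alignment) -> tuple:
        return total_score(g, g2, theta, a, tables, bins)

    best = start
    best_sb = score(start)
    current = start
    trajectory: List[Tuple[int, float, float]] = []
    stable = 0
    converged = False
    in_zero_phase = False
    for t in range(config.max_inner_iterations):
        sd = config.noise_sd(t)
        if sd == 0.0 and not in_zero_phase:
            # refine the best alignment found, not the last noisy proposal
            in_zero_phase = True
            current = best
        problem = build_assignment_matrix(
            g, g2, theta, current, tables, bins, config.allow_unaligned
        )
        if sd > 0:
            problem.matrix[:n, :n2] += rng.normal(0.0, sd, size=(n, n2))
        proposal = solve_linear_assignment(problem)
        sb = score(proposal)
        trajectory.append((t, sd, sb.total))
        if sb.total > best_sb.total:
            best, best_sb = proposal, sb
        if sd == 0.0:
            stable = stable + 1 if proposal == current else 0
            if stable >= config.convergence_patience:
                converged = True
                current = proposal
                break
        current = proposal

    return AlignmentResult(
        alignment=best,
        total_score=best_sb.total,
        edge_component=best_sb.edge,
        vertex_component=best_sb.vertex,
        tables=tables,
        trajectory=trajectory,
        converged=converged,
    )


def fit_and_align(
    g: Network,
    g2: Network,
    theta: SimilarityMatrix,
    bins: Optional[BinSpec] = None,
    config: AlignerConfig = AlignerConfig(),
    start: Optional[Alignment] = None,
    pseudocount: float = 1.0,
    pooled: bool = True,
    initial_min_theta: float = 0.0,
) -> AlignmentResult:
    """Full pipeline: seed, then alternate table estimation and alignment.

    The scoring parameters are re-estimated from the current alignment so
    that its likelihood is maximal, the networks are re-aligned under the
    new tables, and the loop repeats until the alignment is unchanged
    between outer iterations (or ``max_outer_iterations`` is hit).
    """
    validate_inputs(g, g2, theta)
    if _needs_swap(g, g2):
        res = fit_and_align(
            g2, g, theta.transpose(), bins, config,
            None if start is None else invert_alignment(start),
            pseudocount, pooled, initial_min_theta,
        )
        res.alignment = invert_alignment(res.alignment)
        res.tables = _transpose_tables(res.tables)
        return res

    if bins is None:
        bins = BinSpec.for_data(g, g2, theta)
    current = start if start is not None else initial_alignment(
        theta, initial_min_theta
    )
    if len(current) < 2:
        raise NetworkError(
            "initial alignment has fewer than 2 pairs; provide a start "
            "alignment or lower the similarity threshold"
        )

    trajectory: List[Tuple[int, float, float]] = []
    result: Optional[AlignmentResult] = None
    converged = False
    outer = 0
    for outer in range(config.max_outer_iterations):
        tables = estimate_score_tables(
            g, g2, theta, current, bins, pseudocount, pooled
        )
        inner_cfg = AlignerConfig(
            max_inner_iterations=config.max_inner_iterations,
            noise_initial_sd=config.noise_initial_sd,
            max_outer_iterations=config.max_outer_iterations,
            convergence_patience=config.convergence_patience,
            random_seed=config.random_seed + 10007 * outer,
            allow_unaligned=config.allow_unaligned,
        )
        result = align_networks(g, g2, theta, current, tables, bins, inner_cfg)
        trajectory.extend(
            (outer * config.max_inner_iterations + t, sd, sc)
            for t, sd, sc in result.trajectory
        )
        if result.alignment == current:
            converged = True
            break
        current = result.alignment

    assert result is not None
    result.trajectory = trajectory
    result.converged = converged
    result.n_outer_iterations = outer + 1
    return result
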