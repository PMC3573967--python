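"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written directly from the score definitions with plain
loops, deliberately sharing no code with the package internals.
"""

from __future__ import annotations

import itertools
from typing import Dict, Iterator, Tuple

import numpy as np

from netalign import Alignment, BinSpec, Network, ScoreTables, SimilarityMatrix


def naive_total_score(
    g: Network,
    g2: Network,
    theta: SimilarityMatrix,
    a: Alignment,
    tables: ScoreTables,
    bins: BinSpec,
) -> float:
    """Triple-loop evaluation of S(A) = Se(A) + Sv(A)."""
    items = list(a.items())
    directed = g.directed or g2.directed
    se = 0.0
    for x in range(len(items)):
        for y in range(len(items)):
            if directed:
                if x == y:
                    continue
            elif y <= x:
                continue
            (i, ip), (j, jp) = items[x], items[y]
            se += tables.s_edge[
                int(bins.edge_bin(g.weight(i, j))),
                int(bins.edge_bin(g2.weight(ip, jp))),
            ]
    sv = 0.0
    for i, ip in items:
        sv += tables.s_aligned[int(bins.theta_bin(theta.get(i, ip)))]
        for jp in theta.cols:
            if jp != ip:
                sv += tables.s_not_aligned[int(bins.theta_bin(theta.get(i, jp)))]
    return se + sv


def enumerate_partial_injective_maps(
    rows: list, cols: list
) -> Iterator[Dict[str, str]]:
    """Every injective partial map from rows to cols (including empty)."""
    n = len(rows)
    for k in range(n + 1):
        for row_subset in itertools.combinations(rows, k):
            for col_subset in itertools.permutations(cols, k):
                yield dict(zip(row_subset, col_subset))


def best_alignment_bruteforce(
    g: Network,
    g2: Network,
    theta: SimilarityMatrix,
    tables: ScoreTables,
    bins: BinSpec,
) -> Tuple[float, Dict[str, str]]:
    """Exhaustive search over all injective partial maps (small n only).

    Uses precomputed lookup arrays for speed but scores exactly per the
    definitions (validated against ``naive_total_score`` in the suite).
    """
    n, n2 = g.n_vertices, g2.n_vertices
    bg = np.asarray(bins.edge_bin(g.adjacency))
    bg2 = np.asarray(bins.edge_bin(g2.adjacency))
    td = theta.to_dense(g, g2)
    tb = np.asarray(bins.theta_bin(td))
    s_al = tables.s_aligned[tb]
    s_na = tables.s_not_aligned[tb]
    na_rowsum = s_na.sum(axis=1)
    s_edge = tables.s_edge

    best_score = 0.0
    best_map: Dict[int, int] = {}

    # DFS over rows: each row is left unaligned or paired with a free column
    def dfs(row: int, used_cols: list, pairs: list, score: float) -> None:
        nonlocal best_score, best_map
        if row == n:
            if score > best_score + 1e-12:
                best_score = score
                best_map = dict(pairs)
            return
        dfs(row + 1, used_cols, pairs, score)
        for c in range(n2):
            if c in used_cols:
                continue
            gain = s_al[row, c] + na_rowsum[row] - s_na[row, c]
            for r2, c2 in pairs:
                gain += s_edge[bg[row, r2], bg2[c, c2]]
            dfs(row + 1, used_cols + [c], pairs + [(row, c)], score + gain)

    dfs(0, [], [], 0.0)
    mapping = {
        g.vertex_ids[r]: g2.vertex_ids[c] for r, c in best_map.items()
    }
    return best_score, mapping


def bbh_bruteforce(theta: SimilarityMatrix, min_theta: float) -> Dict[str, str]:
    """Bidirectional best hits by direct search; ties disqualify."""
    pairs = {}
    for i in theta.rows:
        row = {j: theta.get(i, j) for j in theta.cols}
        m = max(row.values(), default=0.0)
        if m < min_theta or m <= 0:
            continue
        best_js = [j for j, t in row.items() if t == m]
        if len(best_js) != 1:
            continue
        j = best_js[0]
        col = {i2: theta.get(i2, j) for i2 in theta.rows}
        m2 = max(col.values())
        best_is = [i2 for i2, t in col.items() if t == m2]
        if len(best_is) == 1 and best_is[0] == i:
            pairs[i] = j
    return pairs


def random_instance(seed: int, n: int = 6, binary: bool = True):
    """A random test instance: two networks, theta, bins and score tables
    estimated from a random starting alignment."""
    import netalign as na

    rng = np.random.default_rng(seed)
    def net(prefix: str) -> Network:
        a = np.triu((rng.random((n, n)) < 0.5) * 1.0, 1)
        if not binary:
            a *= np.triu(rng.random((n, n)), 1)
        a = a + a.T
        return Network(
            [f"{prefix}{k}" for k in range(n)], a,
            weight_kind="binary" if binary else "continuous",
        )

    g, g2 = net("x"), net("y")
    entries = {}
    for i in g.vertex_ids:
        for j in g2.vertex_ids:
            if rng.random() < 0.3:
                entries[(i, j)] = float(rng.uniform(0.1, 1.0))
    theta = SimilarityMatrix(g.vertex_ids, g2.vertex_ids, entries)
    bins = na.BinSpec.for_data(g, g2, theta, n_edge_bins=2, n_theta_bins=4)
    k = max(2, n // 2)
    start_rows = rng.choice(n, k, replace=False)
    start_cols = rng.choice(n, k, replace=False)
    start = Alignment({
        g.vertex_ids[r]: g2.vertex_ids[c]
        for r, c in zip(start_rows, start_cols)
    })
    tables = na.estimate_score_tables(g, g2, theta, start, bins)
    return g, g2, theta, bins, tables, start
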