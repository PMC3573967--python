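"""Synthetic benchmark pairs with known ortholog/analog/paralog structure.

A pair of networks is derived from a common ancestor: a configurable
fraction of vertices are orthologs (present in both networks, edge states
copied from the ancestor and partially diverged), the rest are unrelated
vertices with independent random edges.  Orthologs come in three kinds:

* ``ortholog_vertex_similar`` — high vertex similarity to the true partner;
* ``paralog_case`` — high similarity to the true partner *and* to a decoy
  vertex with identical similarity but independent edges (scenarios
  ``ii``/``iii``), so only edge information can resolve the pair;
* ``analog`` — no vertex similarity at all, identifiable only through
  conserved interactions.

Scenario ``iii`` additionally sprinkles spurious weak similarities on
random cross pairs, modelling noise intrinsic to biological data.
Scenario ``ia`` equals ``i`` with normally instead of uniformly
distributed edge weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .core import Alignment, Network, NetworkError, SimilarityMatrix

__all__ = [
    "ScenarioConfig",
    "SimulatedPair",
    "generate_scenario",
    "empirical_edge_density",
    "empirical_conservation",
]

SCENARIOS = ("i", "ia", "ii", "iii")

HIGH_THETA_RANGE = (0.75, 1.0)
WEAK_THETA_RANGE = (0.05, 0.3)
NORMAL_WEIGHT_MEAN = 0.5
NORMAL_WEIGHT_SD = 0.15


@dataclass(frozen=True)
class ScenarioConfig:
    """Generator parameters; defaults are the benchmark conditions
    (80% orthologs, 50% edge density, 60% interaction similarity, 62.5% of
    orthologs vertex-similar, 12.5% of orthologs with a paralog decoy)."""

    scenario: str = "i"
    n: int = 200
    frac_ortholog: float = 0.8
    edge_density: float = 0.5
    interaction_similarity: float = 0.6
    frac_vertex_similar_of_orthologs: float = 0.625
    frac_paralog_of_orthologs: float = 0.125
    spurious_rate: float = 1.0
    weight_distribution: Optional[str] = None  # default by scenario
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise NetworkError(f"unknown scenario {self.scenario!r}")
        if self.n < 4:
            raise NetworkError("need at least 4 vertices")
        for name in (
            "frac_ortholog",
            "edge_density",
            "interaction_similarity",
            "frac_vertex_similar_of_orthologs",
            "frac_paralog_of_orthologs",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise NetworkError(f"{name} must be in [0, 1], got {v}")
        if self.spurious_rate < 0:
            raise NetworkError("spurious_rate must be >= 0")
        if self.weight_distribution is None:
            object.__setattr__(
                self,
                "weight_distribution",
                "normal" if self.scenario == "ia" else "uniform",
            )
        if self.weight_distribution not in ("uniform", "normal"):
            raise NetworkError(
                f"unknown weight_distribution {self.weight_distribution!r}"
            )

    @property
    def has_paralogs(self) -> bool:
        return self.scenario in ("ii", "iii")

    @property
    def has_spurious(self) -> bool:
        return self.scenario == "iii"


@dataclass
class SimulatedPair:
    """Two networks, their similarity matrix, and the ground truth."""

    g: Network
    g2: Network
    theta: SimilarityMatrix
    truth: Dict[str, str]
    labels: Dict[str, str]
    decoys: Dict[str, str] = field(default_factory=dict)

    def truth_alignment(self) -> Alignment:
        return Alignment(dict(self.truth))


def _draw_weights(rng: np.random.Generator, size: int, distribution: str) -> np.ndarray:
    if distribution == "uniform":
        return rng.uniform(0.0, 1.0, size)
    # truncated normal on [0, 1], same scale as the uniform case
    out = np.empty(size)
    remaining = np.arange(size)
    while remaining.size:
        draw = rng.normal(NORMAL_WEIGHT_MEAN, NORMAL_WEIGHT_SD, remaining.size)
        ok = (draw >= 0.0) & (draw <= 1.0)
        out[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
    return out


def _random_adjacency(
    rng: np.random.Generator, n: int, density: float, distribution: str
) -> np.ndarray:
    iu = np.triu_indices(n, k=1)
    m = iu[0].size
    present = rng.random(m) < density
    weights = _draw_weights(rng, m, distribution) * present
    adj = np.zeros((n, n))
    adj[iu] = weights
    return adj + adj.T


def generate_scenario(config: ScenarioConfig) -> SimulatedPair:
    """Generate one benchmark pair; fully reproducible from ``config.seed``.

    All category counts (orthologs, vertex-similar orthologs, decoys) are
    exact rounded counts, not merely expectations.  Divergence of an
    ortholog-pair edge state keeps it identical with probability
    ``interaction_similarity`` and otherwise redraws it conditioned on
    being different, preserving the marginal edge density (exactly so for
    density >= 0.5), so measured conservation equals the configured
    probability.
    """
    rng = np.random.default_rng(config.seed)
    n, d = config.n, config.edge_density
    n_orth = round(config.frac_ortholog * n)
    n_green = round(config.frac_vertex_similar_of_orthologs * n_orth)
    n_blue = round(config.frac_paralog_of_orthologs * n_orth) if config.has_paralogs else 0
    if n_green + n_blue > n_orth:
        raise NetworkError(
            "vertex-similar plus paralog fractions exceed the ortholog count"
        )
    n_free2 = n - n_orth
    if n_blue > n_free2:
        raise NetworkError(
            f"{n_blue} paralog decoys need non-ortholog slots in the second "
            f"network but only {n_free2} exist"
        )

    a_ids = [f"a{k:04d}" for k in range(n)]
    b_ids = [f"b{k:04d}" for k in range(n)]

    adj_g = _random_adjacency(rng, n, d, config.weight_distribution)
    adj_g2 = _random_adjacency(rng, n, d, config.weight_distribution)

    g_orth = rng.choice(n, n_orth, replace=False)
    g2_orth = rng.choice(n, n_orth, replace=False)

    # ortholog-block edge states of G' copied from G, then diverged
    iu = np.triu_indices(n_orth, k=1)
    old = adj_g[np.ix_(g_orth, g_orth)][iu]
    new = old.copy()
    diverged = rng.random(old.size) >= config.interaction_similarity
    z_present_to_absent = min(1.0, (1.0 - d) / d) if d > 0 else 1.0
    div_idx = np.flatnonzero(diverged)
    was_absent = old[div_idx] == 0.0
    # absent -> present with a fresh weight
    idx_abs = div_idx[was_absent]
    new[idx_abs] = _draw_weights(rng, idx_abs.size, config.weight_distribution)
    # present -> absent (density-preserving prob) or a fresh weight
    idx_pres = div_idx[~was_absent]
    to_absent = rng.random(idx_pres.size) < z_present_to_absent
    new[idx_pres[to_absent]] = 0.0
    idx_redraw = idx_pres[~to_absent]
    new[idx_redraw] = _draw_weights(
        rng, idx_redraw.size, config.weight_distribution
    )
    block = np.zeros((n_orth, n_orth))
    block[iu] = new
    block = block + block.T
    adj_g2[np.ix_(g2_orth, g2_orth)] = block

    # categories among the orthologs
    order = rng.permutation(n_orth)
    green = order[:n_green]
    blue = order[n_green:n_green + n_blue]

    truth = {a_ids[g_orth[t]]: b_ids[g2_orth[t]] for t in range(n_orth)}
    labels = {v: "unrelated" for v in a_ids}
    for t in range(n_orth):
        labels[a_ids[g_orth[t]]] = "analog"
    for t in green:
        labels[a_ids[g_orth[t]]] = "ortholog_vertex_similar"
    for t in blue:
        labels[a_ids[g_orth[t]]] = "paralog_case"

    free2 = np.setdiff1d(np.arange(n), g2_orth)
    decoy_slots = rng.choice(free2, n_blue, replace=False) if n_blue else np.array([], int)

    entries: Dict[tuple, float] = {}
    for t in green:
        entries[(a_ids[g_orth[t]], b_ids[g2_orth[t]])] = float(
            rng.uniform(*HIGH_THETA_RANGE)
        )
    decoys: Dict[str, str] = {}
    for slot, t in zip(decoy_slots, blue):
        i = a_ids[g_orth[t]]
        val = float(rng.uniform(*HIGH_THETA_RANGE))
        entries[(i, b_ids[g2_orth[t]])] = val
        entries[(i, b_ids[slot])] = val  # decoy: equal similarity, no shared edges
        decoys[i] = b_ids[slot]

    if config.has_spurious and config.spurious_rate > 0:
        n_spurious = rng.poisson(config.spurious_rate * n)
        ii = rng.integers(0, n, n_spurious)
        jj = rng.integers(0, n, n_spurious)
        vals = rng.uniform(*WEAK_THETA_RANGE, n_spurious)
        for i, j, v in zip(ii, jj, vals):
            key = (a_ids[i], b_ids[j])
            if key not in entries:
                entries[key] = float(v)

    g = Network(a_ids, adj_g, directed=False, weight_kind="continuous")
    g2 = Network(b_ids, adj_g2, directed=False, weight_kind="continuous")
    theta = SimilarityMatrix(a_ids, b_ids, entries)
    return SimulatedPair(g, g2, theta, truth, labels, decoys)


def empirical_edge_density(g: Network) -> float:
    """Fraction of unordered vertex pairs carrying an edge."""
    n = g.n_vertices
    if n < 2:
        return 0.0
    return float(np.count_nonzero(g.offdiag_weights())) / (n * (n - 1) / 2)


def empirical_conservation(pair: SimulatedPair) -> float:
    """Fraction of identical edge states between true ortholog pairs."""
    if len(pair.truth) < 2:
        raise NetworkError("need at least 2 true pairs")
    gi = np.array([pair.g.index_of(i) for i in pair.truth], dtype=int)
    g2i = np.array([pair.g2.index_of(j) for j in pair.truth.values()], dtype=int)
    sub = pair.g.adjacency[np.ix_(gi, gi)]
    sub2 = pair.g2.adjacency[np.ix_(g2i, g2i)]
    iu = np.triu_indices(gi.size, k=1)
    return float(np.mean(sub[iu] == sub2[iu]))
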