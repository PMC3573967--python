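# Methods

## Model

`netalign` performs global pairwise alignment of two biological networks
*G* and *G′* — protein–protein interaction networks, gene co-expression
networks, or any graphs with binary or continuous edge weights. An
alignment *A* is an injective partial map between the vertex sets; it
induces an alignment of vertex pairs, and the aim is to align vertices
descending from a common ancestor (orthologs).

The scoring rests on a simple evolutionary picture. At speciation the edge
state *a* = *A*<sub>ij</sub> between two vertices and the state
*a′* = *A′*<sub>A(i)A(j)</sub> between their orthologs are identical;
divergence then decorrelates them, so the joint distribution *Q*(*a*, *a′*)
over truly orthologous vertex pairs interpolates between perfect
correlation and the product of the marginals *P*(*a*)*P′*(*a′*). The same
logic applies to the vertex similarity θ (any non-negative cross-network
measure, typically BLAST bit scores, in arbitrary units): the similarity of
ortholog pairs follows a distribution *Q*<sup>o</sup>(θ) that decays toward
a background *P*(θ), and similarities between unrelated pairs follow
*Q*<sup>u</sup>(θ). Three log-likelihood-ratio tables result:

* `s_edge(a, a′) = log Q(a, a′) / (P(a) P′(a′))`
* `s_aligned(θ) = log Q^o(θ) / P(θ)`
* `s_not_aligned(θ) = log Q^u(θ) / P(θ)`

and the score of an alignment is S(A) = S<sub>e</sub>(A) + S<sub>v</sub>(A),
where S<sub>e</sub> sums `s_edge` over **all** pairs of aligned vertices
(shared *absence* of an edge is evidence too, and is scored, not skipped)
and S<sub>v</sub> sums `s_aligned` over aligned pairs plus `s_not_aligned`
over every aligned vertex's non-partners. The index range of the
not-aligned sum is restricted to vertices in the domain of *A*, which makes
the empty alignment score exactly 0; under partial alignments this term is
not perfectly symmetric in (G, G′), which is why the score-swap invariance
is only exact for total alignments (the pair sets then coincide). The
*search* is nevertheless exactly symmetric for all inputs, see below.

No divergence time is estimated: it is absorbed into the empirical
histograms, which are re-estimated from the data being aligned.

## Parameter estimation

All distributions are realized as binned histograms with Laplace smoothing
(pseudocount λ = 1 per cell by default) so every log-ratio is finite.
Default bins: binary networks get the two bins {0}, {1}; continuous weights
get 8 equal-width bins over [0, max observed]; θ gets a bin reserved for
θ = 0 plus 7 equal-width bins over (0, max θ]. Bins are left-closed,
right-open (last bin closed) and lookups clamp out-of-range values to the
extreme bins, since alignment-time queries may see values outside the
training range. All bin edges are user-overridable.

Given an alignment, `estimate_score_tables` computes: the joint edge
histogram from the induced aligned vertex pairs; the marginals from all
vertex pairs of each whole network; *Q*<sup>o</sup> from the partner
similarities θ<sub>iA(i)</sub>; *Q*<sup>u</sup> from non-partner cross
pairs with at least one aligned endpoint; and *P*(θ) from pairs involving
at least one unaligned vertex (vertices that appeared or vanished after
speciation). When fewer than 10·K such background values exist the
estimator falls back to all θ values and logs a warning, since tiny
networks would otherwise give degenerate backgrounds. Zero-θ pairs are
counted in closed form, so estimation is O(nnz(Θ)) in the similarity data.

By default the two edge marginals are pooled and the joint histogram
symmetrized ("pooled marginals"), which enforces exact G ↔ G′ symmetry of
the scoring; per-network marginals are available as an option.

## Alignment search

Maximizing S(A) is a quadratic assignment problem (the edge term couples
pairs of assignments). It is linearized around the current alignment: the
gain of pairing i with i′, holding all other partners fixed, is

M[i, i′] = Σ<sub>j aligned, j≠i, A(j)≠i′</sub>
s_edge(A<sub>ij</sub>, A′<sub>i′A(j)</sub>) + s_aligned(θ<sub>ii′</sub>)
+ Σ<sub>j′≠i′</sub> s_not_aligned(θ<sub>ij′</sub>).

The trailing row sum is constant across candidate partners, so it never
changes which i′ is preferred; it is kept because the matrix is extended
with zero-valued dummy rows/columns representing "leave unaligned", and
with the row sum included M[i, i′] is the exact score change relative to
that option. The resulting linear assignment problem is solved with the
Jonker–Volgenant-style solver in `scipy.optimize.linear_sum_assignment`.

The LAP is re-solved iteratively with i.i.d. Gaussian noise added to the
real block of M, the standard deviation decaying linearly from
`noise_initial_sd` (default 1.0, in score units) to zero over the inner
iterations (default 100), as in simulated annealing, to escape local score
maxima. Every proposal is scored exactly with the full S(A) and the best
alignment ever visited is tracked, so the returned score is never below the
start's. When the noise first reaches zero, the search restarts from the
best alignment found and iterates noise-free until the alignment is
unchanged for `convergence_patience` (default 3) consecutive iterations.
On 200 seeded random instances with N ≤ 6, the search recovers the
exhaustively verified optimum in 96.5% of cases (acceptance suite).

The outer loop alternates table estimation and search until the alignment
is unchanged between outer iterations (at most 10 by default). The seed of
each inner search is derived deterministically from the configured seed, so
reruns are byte-identical. Internally all computations run in a canonical
orientation of the two inputs (fixed by comparing vertex-id lists and
adjacency bytes), so swapping the input networks and transposing Θ returns
the exact inverse alignment under the same seed.

The initial alignment is the set of bidirectional best hits by θ above a
threshold; ties for best partner disqualify a vertex, so paralog pairs with
identical similarity seed nothing and are resolved by edge information
alone. Per-iteration cost is dominated by the O(N³) LAP solve.

## Benchmark generator

`generate_scenario` emulates four divergence scenarios. A pair of networks
shares a configurable fraction of orthologous vertices (default 80%); the
ortholog-block edge states of G′ are copied from G and each is kept with
probability `interaction_similarity` (default 0.6); all other pairs get
independent random edges at the configured density (default 0.5, weights
uniform on (0, 1]; scenario `ia` uses a normal distribution with mean 0.5
and sd 0.15 truncated to [0, 1], chosen to stay on the uniform scale).
Orthologs split into three categories with exact rounded counts: plain
vertex-similar orthologs (62.5% of orthologs, θ drawn uniformly from
[0.75, 1.0] — the strong/weak separation is what matters, the scale is
arbitrary); paralog cases (scenarios `ii`/`iii`, 12.5% of orthologs) whose
G-vertex gets an *equal* θ to its true partner and to a decoy vertex with
independent edges, occupying a non-ortholog slot so network size stays n;
and analogs (the remainder) with no θ at all, identifiable only through
edge conservation. Scenario `iii` adds Poisson(rate · n) spurious weak θ
entries (uniform on [0.05, 0.3]) on random cross pairs (default rate 1 per
vertex).

Divergence of an edge state redraws it *conditioned on being different*
from the ancestral state: an absent edge becomes present with a fresh
weight, and a present edge becomes absent with probability (1 − d)/d (else
gets a fresh weight). This keeps the marginal edge density exactly at d for
d ≥ 0.5 and makes the measured conservation equal the configured
probability (independent redraws would collide on the shared-absence state
with probability (1 − d)², inflating measured conservation to
p + (1 − p)(1 − d)² and biasing the G′ density). For d < 0.5 the
present→absent probability clips at 1 and density preservation is only
approximate; the default 0.5 is exact.

What the generator does *not* model: sequence evolution (θ values are
drawn, not computed from sequences), degree heterogeneity (edges are
Erdős–Rényi-like, whereas real interaction networks are heavy-tailed and
sparse), experimental false negatives/positives beyond the divergence
kernel, and multi-domain/many-to-many homology. Passing the benchmark
therefore shows that the scoring and search recover planted structure
under the stated noise model, not that empirical alignments of arbitrary
real networks reach the same accuracy.

## Evaluation

Against simulation truth: a pair (i, i′) is correct iff it matches the
planted mapping; a vertex aligned to a wrong partner is misaligned; two
vertices without true partners aligned together are neutral (aligned but
neither correct nor wrong). Sensitivity is NC/NA, coverage NC/NO with NO
the number of planted pairs. Against an orthologous-group table (one table
per species): NA counts aligned pairs where both members carry group ids,
NC those sharing a group, NO the number of distinct groups present in both
species — so coverage can exceed 1 when several correct pairs fall in one
group. Group-based evaluation is pairwise; equivalence-class rules used by
multi-way aligners coincide with it in the pairwise setting.

## Empirical preprocessing

Vertex similarity from 12-column tabular BLAST output keeps hits with
e-value < 10⁻¹⁰ and takes the maximum bit score per pair. Orphans — vertices
with no similarity hit *and* no edge — are removed before alignment.
Co-expression networks use absolute Spearman correlation over
pairwise-complete observations among genes detected in ≥ 75% of profiles;
values strictly below the hard threshold (default 0.5, dataset-specific and
exposed as a flag) are set to 0, values exactly at it are kept, and
surviving correlations must pass Benjamini–Hochberg q < 0.001 (a standard,
conservative stand-in for more elaborate FDR estimators; the p-values come
from the large-sample t approximation). Pairs with fewer than 3 complete
observations are skipped with a warning.

## Numerical and I/O choices

All randomness flows through `numpy.random.default_rng` seeds. Distribution
vectors are validated to sum to 1 within 10⁻⁹. LAP ties are resolved by the
solver deterministically (with annealing noise, exact ties are measure-zero).
Files are TSV with `#` comment headers; floats are serialized with 17
significant digits so score tables and networks round-trip bit-exactly.
Self-loops are never scored and adjacency diagonals are ignored; directed
adjacencies are supported throughout (induced pairs become ordered) but the
benchmark scenarios are undirected.

## Problem sizes

The shipped test and acceptance suites run the full pipeline at n = 200
(five seeds per scenario) and the analog-recovery check at n = 600, the
sizes at which the benchmark's qualitative transitions (full analog
recovery above ~500 vertices) are visible; generator statistics are
averaged over ten seeds at n = 200. A single n = 200 run takes a few
seconds on one core, n = 600 around half a minute.
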