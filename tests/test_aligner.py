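import itertools

import numpy as np
import pytest

from netalign import (
    AlignerConfig,
    Alignment,
    BinSpec,
    Network,
    NetworkError,
    SimilarityMatrix,
    align_networks,
    build_assignment_matrix,
    estimate_score_tables,
    fit_and_align,
    initial_alignment,
    invert_alignment,
    solve_linear_assignment,
    total_score,
)
from netalign.aligner import AssignmentProblem
from netalign.scoring import ScoreTables
from oracles import bbh_bruteforce, best_alignment_bruteforce, random_instance


class TestInitialAlignment:
    def test_identity_diagonal_theta(self):
        theta = SimilarityMatrix(
            ["a", "b", "c"], ["x", "y", "z"],
            {("a", "x"): 5.0, ("b", "y"): 4.0, ("c", "z"): 3.0,
             ("a", "y"): 1.0},
        )
        assert initial_alignment(theta, 2.0) == Alignment(
            {"a": "x", "b": "y", "c": "z"}
        )

    def test_tied_best_partner_is_excluded(self):
        theta = SimilarityMatrix(
            ["a", "b"], ["x", "y", "z"],
            {("a", "x"): 5.0, ("a", "y"): 5.0, ("b", "z"): 2.0},
        )
        assert initial_alignment(theta) == Alignment({"b": "z"})

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_bbh(self, seed):
        rng = np.random.default_rng(seed)
        rows = [f"a{i}" for i in range(10)]
        cols = [f"b{i}" for i in range(10)]
        entries = {
            (i, j): float(rng.integers(1, 20))
            for i in rows for j in cols if rng.random() < 0.4
        }
        theta = SimilarityMatrix(rows, cols, entries)
        assert initial_alignment(theta, 3.0).pairs == bbh_bruteforce(theta, 3.0)


class TestAssignmentMatrix:
    def test_empty_current_reduces_to_vertex_term(self):
        g, g2, theta, bins, tables, _ = random_instance(1)
        prob = build_assignment_matrix(
            g, g2, theta, Alignment({}), tables, bins
        )
        n, n2 = g.n_vertices, g2.n_vertices
        for i in range(n):
            vi = g.vertex_ids[i]
            na_row = sum(
                tables.s_not_aligned[int(bins.theta_bin(theta.get(vi, jp)))]
                for jp in g2.vertex_ids
            )
            for j in range(n2):
                t = theta.get(vi, g2.vertex_ids[j])
                b = int(bins.theta_bin(t))
                expected = (
                    tables.s_aligned[b] - tables.s_not_aligned[b] + na_row
                )
                assert prob.matrix[i, j] == pytest.approx(expected, abs=1e-12)

    def test_flat_tables_give_zero_matrix(self):
        g, g2, theta, bins, _, start = random_instance(2)
        flat = ScoreTables.from_counts(
            np.ones((bins.n_edge_bins,) * 2),
            np.ones(bins.n_edge_bins), np.ones(bins.n_edge_bins),
            np.ones(bins.n_theta_bins), np.ones(bins.n_theta_bins),
            np.ones(bins.n_theta_bins), 1.0,
        )
        prob = build_assignment_matrix(g, g2, theta, start, flat, bins)
        assert np.max(np.abs(prob.matrix)) < 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_cells_match_hand_expanded_sum(self, seed):
        g, g2, theta, bins, tables, current = random_instance(40 + seed, n=4)
        prob = build_assignment_matrix(g, g2, theta, current, tables, bins)
        for i in range(4):
            for ip in range(4):
                vi, vip = g.vertex_ids[i], g2.vertex_ids[ip]
                b = int(bins.theta_bin(theta.get(vi, vip)))
                na_row = sum(
                    tables.s_not_aligned[
                        int(bins.theta_bin(theta.get(vi, jp)))
                    ]
                    for jp in g2.vertex_ids
                )
                expected = (
                    tables.s_aligned[b] - tables.s_not_aligned[b] + na_row
                )
                for j, jp in current.items():
                    if j == vi or jp == vip:
                        continue
                    expected += tables.s_edge[
                        int(bins.edge_bin(g.weight(vi, j))),
                        int(bins.edge_bin(g2.weight(vip, jp))),
                    ]
                assert prob.matrix[i, ip] == pytest.approx(expected, abs=1e-9)


class TestLinearAssignment:
    def test_two_by_two(self):
        prob = AssignmentProblem(
            np.array([[2.0, 1.0], [1.0, 2.0]]), ["a", "b"], ["x", "y"]
        )
        assert solve_linear_assignment(prob) == Alignment({"a": "x", "b": "y"})

    def test_zero_matrix_still_returns_injective_map(self):
        prob = AssignmentProblem(np.zeros((3, 3)), list("abc"), list("xyz"))
        a = solve_linear_assignment(prob)
        assert len(set(a.pairs.values())) == len(a)

    def test_rejects_non_finite(self):
        prob = AssignmentProblem(
            np.array([[np.nan, 1.0], [1.0, 2.0]]), ["a", "b"], ["x", "y"]
        )
        with pytest.raises(NetworkError, match="non-finite"):
            solve_linear_assignment(prob)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_permutations(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.normal(size=(6, 6))
        prob = AssignmentProblem(
            m, [f"a{i}" for i in range(6)], [f"b{i}" for i in range(6)]
        )
        a = solve_linear_assignment(prob)
        got = sum(m[i, int(a.pairs[f"a{i}"][1:])] for i in range(6))
        best = max(
            sum(m[i, p[i]] for i in range(6))
            for p in itertools.permutations(range(6))
        )
        assert got == pytest.approx(best, abs=1e-12)


class TestAlignNetworks:
    def test_identical_rings_align_identically(self, ring6):
        g, g2, theta = ring6
        bins = BinSpec.for_data(g, g2, theta)
        start = initial_alignment(theta)
        tables = estimate_score_tables(g, g2, theta, start, bins)
        cfg = AlignerConfig(noise_initial_sd=0.0, random_seed=0)
        res = align_networks(g, g2, theta, start, tables, bins, cfg)
        assert res.alignment == Alignment(
            {f"x{i}": f"y{i}" for i in range(6)}
        )
        assert res.converged

    def test_single_vertex_pair(self):
        g = Network(["a"], np.zeros((1, 1)))
        g2 = Network(["x"], np.zeros((1, 1)))
        theta = SimilarityMatrix(["a"], ["x"], {("a", "x"): 1.0})
        bins = BinSpec(np.array([0.0, 0.5, 1.0]), np.array([0.0, 0.5, 1.0]))
        tables = ScoreTables.from_counts(
            np.ones((2, 2)), np.ones(2), np.ones(2),
            np.array([1.0, 9.0]), np.ones(2), np.array([9.0, 1.0]), 1.0,
        )
        res = align_networks(
            g, g2, theta, Alignment({}), tables, bins, AlignerConfig()
        )
        single = total_score(
            g, g2, theta, Alignment({"a": "x"}), tables, bins
        ).total
        assert res.total_score == pytest.approx(max(0.0, single))

    @pytest.mark.parametrize("seed", range(10))
    def test_score_never_below_start(self, seed):
        g, g2, theta, bins, tables, start = random_instance(60 + seed, n=8)
        cfg = AlignerConfig(max_inner_iterations=15, random_seed=seed)
        res = align_networks(g, g2, theta, start, tables, bins, cfg)
        start_score = total_score(g, g2, theta, start, tables, bins).total
        assert res.total_score >= start_score - 1e-9
        assert res.total_score == pytest.approx(
            res.edge_component + res.vertex_component, abs=1e-6
        )

    def test_matches_exhaustive_search_on_most_small_instances(self):
        # smoke-sized version; the full 200-instance check runs in the
        # acceptance suite
        hits = 0
        n_instances = 30
        for seed in range(n_instances):
            g, g2, theta, bins, tables, _ = random_instance(
                1000 + seed, n=3 + seed % 4
            )
            cfg = AlignerConfig(random_seed=seed)
            res = align_networks(
                g, g2, theta, Alignment({}), tables, bins, cfg
            )
            best, _ = best_alignment_bruteforce(g, g2, theta, tables, bins)
            assert res.total_score <= best + 1e-9
            if res.total_score >= best - 1e-9:
                hits += 1
        assert hits >= 0.9 * n_instances


class TestFitAndAlign:
    def test_swapped_inputs_return_inverse_alignment(self):
        import netalign as na

        pair = na.generate_scenario(
            na.ScenarioConfig(scenario="ii", n=60, seed=3)
        )
        cfg = AlignerConfig(random_seed=5, max_inner_iterations=30)
        fwd = fit_and_align(pair.g, pair.g2, pair.theta, config=cfg)
        rev = fit_and_align(
            pair.g2, pair.g, pair.theta.transpose(), config=cfg
        )
        assert fwd.alignment == invert_alignment(rev.alignment)
        assert fwd.total_score == pytest.approx(rev.total_score, abs=1e-9)

    def test_deterministic_for_fixed_seed(self):
        import netalign as na

        pair = na.generate_scenario(
            na.ScenarioConfig(scenario="i", n=50, seed=9)
        )
        cfg = AlignerConfig(random_seed=2, max_inner_iterations=30)
        r1 = fit_and_align(pair.g, pair.g2, pair.theta, config=cfg)
        r2 = fit_and_align(pair.g, pair.g2, pair.theta, config=cfg)
        assert r1.alignment == r2.alignment
        assert r1.total_score == r2.total_score

    def test_degenerate_flat_theta_converges(self):
        rng = np.random.default_rng(4)

        def net(prefix):
            a = np.triu((rng.random((20, 20)) < 0.5) * 1.0, 1)
            a = a + a.T
            return Network(
                [f"{prefix}{i}" for i in range(20)], a, weight_kind="binary"
            )

        g, g2 = net("a"), net("b")
        theta = SimilarityMatrix(
            g.vertex_ids, g2.vertex_ids,
            {(f"a{i}", f"b{i}"): 1.0 for i in range(20)},
        )
        cfg = AlignerConfig(random_seed=0, max_inner_iterations=20)
        res = fit_and_align(g, g2, theta, config=cfg)
        assert np.isfinite(res.total_score)

    def test_rejects_tiny_initial_alignment(self):
        g = Network(["a", "b"], np.zeros((2, 2)))
        g2 = Network(["x", "y"], np.zeros((2, 2)))
        theta = SimilarityMatrix(["a", "b"], ["x", "y"], {("a", "x"): 1.0})
        with pytest.raises(NetworkError, match="fewer than 2"):
            fit_and_align(g, g2, theta)
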