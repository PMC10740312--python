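"""Expression cleaning, thresholding diagnostics and network utilities."""

import numpy as np
import pandas as pd
import pytest

from icongems.coexpr_net import (
    CoexpressionNetwork,
    ExpressionMatrix,
    binarize,
    clean_expression,
    correlation_matrix,
    count_components,
    detect_modules,
    import_string_ppi,
    mean_connectivity,
    network_stats,
    rewire_random,
    scale_free_fit,
    scale_free_r2,
    select_threshold,
    tom_similarity,
)


def _net_from_edges(n, edges):
    A = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        A[i, j] = A[j, i] = 1
    return A


class TestCleanExpression:
    def test_gene_with_missing_value_removed(self):
        raw = pd.DataFrame(
            {"c1": [1.0, np.nan, 3.0], "c2": [2.0, 2.0, 4.0]},
            index=["a", "b", "c"],
        )
        em = clean_expression(raw)
        assert em.genes == ["a", "c"]
        assert any("missing" in line for line in em.cleaning_log)

    def test_duplicate_genes_averaged(self):
        raw = pd.DataFrame(
            {"c1": [1.0, 3.0], "c2": [2.0, 4.0]}, index=["a", "a"]
        )
        em = clean_expression(raw)
        assert em.genes == ["a"]
        np.testing.assert_allclose(em.values, [[2.0, 3.0]])

    def test_outliers_winsorized_at_mad_fence(self):
        """Independent one-pass oracle recomputes the MAD fence."""
        row = np.array([10.0, 11.0, 9.0, 10.0, 12.0, 10.0, 200.0])
        raw = pd.DataFrame([row], index=["a"], columns=[f"c{i}" for i in range(7)])
        em = clean_expression(raw)

        med = sorted(row)[len(row) // 2]
        mad = sorted(abs(x - med) for x in row)[len(row) // 2]
        fence = med + 5 * mad
        assert em.values[0, -1] == pytest.approx(fence)
        assert em.values[0, 0] == 10.0  # inliers untouched

    def test_fewer_than_two_conditions_rejected(self):
        with pytest.raises(ValueError):
            clean_expression(pd.DataFrame({"c1": [1.0]}, index=["a"]))


class TestCorrelationMatrix:
    def test_exact_linear_relations(self):
        em = ExpressionMatrix(
            genes=["a", "b", "c"],
            conditions=["x", "y", "z", "w"],
            values=np.array(
                [[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0], [9.0, 8.0, 7.0, 6.0]]
            ),
        )
        C = correlation_matrix(em)
        assert C[0, 1] == pytest.approx(1.0)
        assert C[0, 2] == pytest.approx(-1.0)

    def test_matches_sigma_formula_oracle(self):
        """Direct sum-formula Pearson on a 3x4 fixture."""
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 10, (3, 4))
        em = ExpressionMatrix(
            genes=list("abc"), conditions=list("wxyz"), values=vals
        )
        C = correlation_matrix(em)

        def pearson(x, y):
            n = len(x)
            sx, sy = sum(x), sum(y)
            sxy = sum(a * b for a, b in zip(x, y))
            sxx = sum(a * a for a in x)
            syy = sum(b * b for b in y)
            num = n * sxy - sx * sy
            den = ((n * sxx - sx**2) * (n * syy - sy**2)) ** 0.5
            return num / den

        for i in range(3):
            for j in range(3):
                assert C[i, j] == pytest.approx(
                    pearson(vals[i], vals[j]), abs=1e-10
                )

    def test_constant_row_zero_with_warning(self):
        em = ExpressionMatrix(
            genes=["a", "b"],
            conditions=["x", "y", "z"],
            values=np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]]),
        )
        with pytest.warns(UserWarning, match="constant"):
            C = correlation_matrix(em)
        assert C[0, 1] == 0.0


class TestBinarize:
    def test_threshold_and_boundary(self):
        C = np.array([[1.0, 0.95, 0.91, -0.99], [0.95, 1, 0, 0],
                      [0.91, 0, 1, 0], [-0.99, 0, 0, 1]])
        A = binarize(C, 0.91)
        assert A[0, 1] == 1          # above threshold
        assert A[0, 2] == 1          # exactly at threshold -> edge
        assert A[0, 3] == 0          # negative correlation: no edge (signed)
        assert np.all(np.diag(A) == 0)

    def test_absolute_mode(self):
        C = np.array([[1.0, -0.95], [-0.95, 1.0]])
        assert binarize(C, 0.9)[0, 1] == 0
        assert binarize(C, 0.9, absolute=True)[0, 1] == 1

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            binarize(np.eye(2), 1.5)


class TestScaleFree:
    def test_exact_power_law_histogram_r2_one(self):
        # p(k) proportional to k^-3 over k in {1, 2, 4, 8}: exactly collinear
        degrees = [1] * 512 + [2] * 64 + [4] * 8 + [8] * 1
        assert scale_free_fit(degrees) == pytest.approx(1.0, abs=1e-12)

    def test_regular_graph_degenerate(self):
        # cycle: every node degree 2 -> single support point
        A = _net_from_edges(5, [(i, (i + 1) % 5) for i in range(5)])
        with pytest.warns(UserWarning, match="fewer than 3"):
            assert scale_free_r2(A) == 0.0

    def test_matches_independent_regression_oracle(self):
        """Preferential-attachment toy vs a separate least-squares fit."""
        import networkx as nx

        G = nx.barabasi_albert_graph(50, 2, seed=4)
        A = nx.to_numpy_array(G, dtype=int)
        got = scale_free_r2(A, n_bins=15)

        degrees = A.sum(axis=1)
        distinct = np.unique(degrees[degrees > 0])
        assert len(distinct) <= 15  # exercise the exact-degree path
        x = np.log10(distinct)
        y = np.log10([(degrees == k).mean() for k in distinct])
        X = np.column_stack([x, np.ones_like(x)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert got == pytest.approx(max(0.0, r2), abs=1e-10)


class TestConnectivityAndComponents:
    @pytest.mark.parametrize(
        "nodes,edges,expected",
        [(1495, 16540, 22.1271), (1138, 71454, 125.5782)],
    )
    def test_average_degree_from_counts(self, nodes, edges, expected):
        """2E/V reproduces the reported organism-network average degrees."""
        assert 2 * edges / nodes == pytest.approx(expected, abs=5e-5)

    def test_single_edge(self):
        assert mean_connectivity(_net_from_edges(2, [(0, 1)])) == 1.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mean_connectivity(np.zeros((0, 0)))

    def test_two_triangles_plus_isolates(self):
        A = _net_from_edges(
            9, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]
        )
        assert count_components(A) == 2  # singletons not counted

    def test_empty_edge_set(self):
        assert count_components(np.zeros((4, 4), dtype=int)) == 0

    def test_path_graph_vs_union_find_oracle(self):
        A = _net_from_edges(6, [(i, i + 1) for i in range(5)])

        parent = list(range(6))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(6):
            for j in range(i + 1, 6):
                if A[i, j]:
                    parent[find(i)] = find(j)
        roots = {find(i) for i in range(6)}
        sizes = [sum(find(i) == r for i in range(6)) for r in roots]
        assert count_components(A) == sum(s >= 2 for s in sizes) == 1

    def test_relabel_invariance(self):
        rng = np.random.default_rng(0)
        A = _net_from_edges(8, [(0, 1), (2, 3), (3, 4), (6, 7)])
        perm = rng.permutation(8)
        assert count_components(A[np.ix_(perm, perm)]) == count_components(A)


class TestSelectThreshold:
    def _block_expr(self):
        """3 tight gene blocks + noise; blocks separate at high threshold."""
        rng = np.random.default_rng(12)
        n_per, N = 6, 12
        latents = rng.standard_normal((3, N))
        rows, genes = [], []
        for b in range(3):
            for k in range(n_per):
                rows.append(10 + 3 * latents[b] + 0.3 * rng.standard_normal(N))
                genes.append(f"b{b}g{k}")
        return ExpressionMatrix(
            genes=genes,
            conditions=[f"c{i}" for i in range(N)],
            values=np.maximum(np.array(rows), 0.0),
        )

    def test_matches_exhaustive_scan_oracle(self):
        """Selection equals an independent recomputation of all diagnostics."""
        em = self._block_expr()
        grid = np.round(np.arange(0.5, 0.96, 0.05), 2)
        t_sel, diag = select_threshold(em, grid)

        import warnings as _w

        C = correlation_matrix(em)
        rows = []
        for t in sorted(grid):
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                A = binarize(C, t)
                rows.append((t, scale_free_r2(A), count_components(A)))
        ok = [r for r in rows if r[1] >= 0.5]
        if ok:
            max_count = max(r[2] for r in ok)
            best = min(r[0] for r in ok if r[2] == max_count)
        else:  # fallback rule: first maximal-R^2 candidate
            max_r2 = max(r[1] for r in rows)
            best = next(r[0] for r in rows if r[1] == max_r2)
        assert t_sel == pytest.approx(best)

    def test_fallback_when_no_candidate_qualifies(self):
        # two genes: a 2-node network can never satisfy a 3-point fit
        em = ExpressionMatrix(
            genes=["a", "b"],
            conditions=["x", "y", "z"],
            values=np.array([[1.0, 2.0, 3.0], [1.1, 2.2, 2.9]]),
        )
        with pytest.warns(UserWarning):
            t, diag = select_threshold(em, [0.6, 0.7])
        assert t in (0.6, 0.7)
        assert list(diag["threshold"]) == [0.6, 0.7]

    def test_single_candidate(self):
        em = self._block_expr()
        t, _ = select_threshold(em, [0.8])
        assert t == 0.8

    def test_edge_count_monotone_in_threshold(self):
        _, diag = select_threshold(
            self._block_expr(), np.round(np.arange(0.5, 0.99, 0.02), 2)
        )
        edges = diag["n_edges"].to_numpy()
        assert np.all(np.diff(edges) <= 0)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            select_threshold(self._block_expr(), [])


class TestNetworkStats:
    def test_star_graph(self):
        A = _net_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        s = network_stats(A)
        assert (s["nodes"], s["edges"], s["average_degree"]) == (4, 3, 1.5)
        assert s["degree_distribution"] == {1: 3, 3: 1}

    def test_empty_graph(self):
        s = network_stats(np.zeros((5, 5), dtype=int))
        assert s == {
            "nodes": 5,
            "edges": 0,
            "average_degree": 0.0,
            "degree_distribution": {0: 5},
        }

    def test_degree_histogram_sums_to_node_count(self):
        rng = np.random.default_rng(2)
        A = np.triu((rng.random((10, 10)) < 0.3).astype(int), 1)
        A = A + A.T
        s = network_stats(A)
        assert sum(s["degree_distribution"].values()) == 10


class TestRewireRandom:
    def _toy_net(self, n=20, n_edges=16, seed=1):
        rng = np.random.default_rng(seed)
        edges = set()
        while len(edges) < n_edges:
            i, j = rng.integers(0, n, 2)
            if i != j:
                edges.add((min(i, j), max(i, j)))
        A = _net_from_edges(n, edges)
        return CoexpressionNetwork(genes=[f"g{i}" for i in range(n)], adjacency=A)

    @pytest.mark.parametrize("fraction", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_conserves_node_and_edge_counts(self, fraction):
        net = self._toy_net()
        out = rewire_random(net, fraction, seed=3)
        assert len(out.genes) == len(net.genes)
        assert out.n_edges == net.n_edges

    def test_fraction_zero_identity(self):
        net = self._toy_net()
        out = rewire_random(net, 0.0, seed=9)
        np.testing.assert_array_equal(out.adjacency, net.adjacency)

    def test_full_rewire_changes_edge_set(self):
        net = self._toy_net(n=40, n_edges=100)
        out = rewire_random(net, 1.0, seed=5)
        assert out.n_edges == net.n_edges
        assert not np.array_equal(out.adjacency, net.adjacency)

    def test_half_rewire_survivor_count(self):
        """Set-difference oracle: exactly half the original edges survive."""
        net = self._toy_net(n_edges=16)
        out = rewire_random(net, 0.5, seed=7)
        orig = set(net.edges())
        new = set(out.edges())
        assert len(orig & new) == 8

    def test_deterministic_given_seed(self):
        net = self._toy_net()
        a = rewire_random(net, 0.5, seed=11)
        b = rewire_random(net, 0.5, seed=11)
        np.testing.assert_array_equal(a.adjacency, b.adjacency)


class TestStringImport:
    def _links(self, tmp_path, lines):
        p = tmp_path / "links.txt"
        p.write_text("protein1 protein2 combined_score\n" + "\n".join(lines) + "\n")
        return str(p)

    def test_score_boundary_strictly_greater(self, tmp_path):
        path = self._links(tmp_path, ["p1 p2 901", "p1 p3 900", "p2 p3 899"])
        net = import_string_ppi(path, {"p1": "a", "p2": "b", "p3": "c"})
        assert set(net.edges()) == {("a", "b")}

    def test_reciprocal_duplicates_collapse(self, tmp_path):
        path = self._links(tmp_path, ["p1 p2 950", "p2 p1 950"])
        net = import_string_ppi(path, {"p1": "a", "p2": "b"})
        assert net.n_edges == 1

    def test_unmapped_proteins_dropped_with_warning(self, tmp_path):
        path = self._links(tmp_path, ["p1 p2 950", "p1 px 999"])
        with pytest.warns(UserWarning, match="unmapped"):
            net = import_string_ppi(path, {"p1": "a", "p2": "b"})
        assert net.n_edges == 1

    def test_malformed_line_skipped(self, tmp_path):
        path = self._links(tmp_path, ["p1 p2 950", "oops"])
        with pytest.warns(UserWarning, match="malformed"):
            net = import_string_ppi(path, {"p1": "a", "p2": "b"})
        assert net.n_edges == 1


class TestTomSimilarity:
    def test_triangle_all_ones(self):
        A = _net_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        tom = tom_similarity(A)
        np.testing.assert_allclose(tom, 1.0)

    def test_disconnected_pairs_zero(self):
        A = _net_from_edges(4, [(0, 1), (2, 3)])
        tom = tom_similarity(A)
        assert tom[0, 2] == 0.0
        assert tom[1, 3] == 0.0

    def test_shared_neighbors_full_overlap(self):
        # nodes 0,1 adjacent and sharing neighbors 2 and 3
        A = _net_from_edges(4, [(0, 1), (0, 2), (1, 2), (0, 3), (1, 3)])
        tom = tom_similarity(A)
        # l=2 shared, a=1, min k = 3: (2+1)/(3+1-1) = 1
        assert tom[0, 1] == pytest.approx(1.0)

    def test_range_and_diagonal(self):
        rng = np.random.default_rng(8)
        A = np.triu((rng.random((12, 12)) < 0.3).astype(int), 1)
        A = A + A.T
        tom = tom_similarity(A)
        assert np.all((tom >= 0) & (tom <= 1))
        np.testing.assert_allclose(np.diag(tom), 1.0)
        np.testing.assert_allclose(tom, tom.T)


class TestDetectModules:
    def test_two_cliques_recovered(self):
        A = _net_from_edges(
            6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]
        )
        tom = tom_similarity(A)
        labels = detect_modules(tom, n_modules=2, genes=list("abcdef"))
        assert labels["a"] == labels["b"] == labels["c"]
        assert labels["d"] == labels["e"] == labels["f"]
        assert labels["a"] != labels["d"]

    def test_single_module(self):
        tom = np.eye(4)
        labels = detect_modules(tom, n_modules=1)
        assert set(labels.values()) == {"ME1"}

    def test_too_many_modules_rejected(self):
        with pytest.raises(ValueError):
            detect_modules(np.eye(3), n_modules=4)

    def test_three_block_recovery_adjusted_rand(self):
        """Noisy 3-block TOM vs the ground-truth partition (ARI = 1)."""
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(21)
        truth = np.repeat([0, 1, 2], 4)
        tom = np.full((12, 12), 0.0)
        for b in range(3):
            idx = np.flatnonzero(truth == b)
            tom[np.ix_(idx, idx)] = 0.9
        tom += rng.uniform(0, 0.05, (12, 12))
        tom = (tom + tom.T) / 2
        np.fill_diagonal(tom, 1.0)
        labels = detect_modules(np.clip(tom, 0, 1), n_modules=3)
        pred = [labels[f"g{i}"] for i in range(12)]
        assert adjusted_rand_score(truth, pred) == 1.0

    def test_labels_ordered_by_size(self):
        A = _net_from_edges(
            7, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (5, 6)]
        )
        tom = tom_similarity(A)
        labels = detect_modules(tom, n_modules=2)
        sizes = {
            m: sum(1 for v in labels.values() if v == m)
            for m in set(labels.values())
        }
        assert sizes["ME1"] >= sizes["ME2"]
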