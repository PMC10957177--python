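import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fosmap.network import (
    CorrelationMatrix,
    CorrelationNetwork,
    centrality_table,
    compare_mean_correlation,
    detect_modules,
    fisher_z,
    identify_hubs,
    interregional_correlation,
    inverse_fisher,
    network_density,
    one_tailed_r_pvalue,
    read_correlation_csv,
    threshold_network,
    write_correlation_csv,
)


def _mat(R, n=6, labels=None):
    R = np.asarray(R, float)
    labels = labels or [f"r{i}" for i in range(len(R))]
    r = pd.DataFrame(R, index=labels, columns=labels)
    return CorrelationMatrix(r, pd.DataFrame(float(n), index=labels, columns=labels))


def _uniform_mat(value, size, n=6):
    R = np.full((size, size), float(value))
    np.fill_diagonal(R, 1.0)
    return _mat(R, n=n)


class TestCorrelation:
    @pytest.mark.parametrize(
        "y,expected", [((2, 4, 6), 1.0), ((3, 2, 1), -1.0), ((1, 3, 2), 0.5)]
    )
    def test_hand_pearson(self, y, expected):
        lnd = pd.DataFrame({"x": [1, 2, 3], "y": y})
        mat = interregional_correlation(lnd)
        assert mat.r.loc["x", "y"] == pytest.approx(expected)

    def test_constant_region_missing(self):
        lnd = pd.DataFrame({"x": [1, 2, 3], "c": [5, 5, 5]})
        mat = interregional_correlation(lnd)
        assert np.isnan(mat.r.loc["x", "c"])
        assert mat.r.loc["c", "c"] == 1.0

    def test_pairwise_minimum_subjects(self):
        lnd = pd.DataFrame({"x": [1, 2, 3, 4], "y": [2, 1, np.nan, np.nan]})
        mat = interregional_correlation(lnd)
        assert np.isnan(mat.r.loc["x", "y"])  # only 2 shared subjects
        assert mat.n.loc["x", "y"] == 2

    def test_affine_invariance(self, rng):
        """Per-region positive affine transforms leave correlations unchanged."""
        lnd = pd.DataFrame(rng.normal(size=(8, 4)), columns=list("abcd"))
        scaled = lnd * np.array([2.0, 0.5, 3.0, 1.1]) + np.array([1, -2, 0, 4])
        np.testing.assert_allclose(
            interregional_correlation(lnd).r, interregional_correlation(scaled).r, atol=1e-12
        )


class TestFisher:
    def test_fixed_point_and_spec_value(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.82) == pytest.approx(1.1568, abs=1e-4)

    def test_round_trip(self, rng):
        r = rng.uniform(-0.999, 0.999, size=1000)
        np.testing.assert_allclose(inverse_fisher(fisher_z(r)), r, atol=1e-12)

    def test_unit_r_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.floats(-0.999, 0.999), st.floats(-0.999, 0.999))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_transform_is_odd_and_monotone(self, a, b):
        assert fisher_z(-a) == pytest.approx(-fisher_z(a), abs=1e-12)
        if a < b:
            assert fisher_z(a) < fisher_z(b)


class TestCompareMeanCorrelation:
    def test_identical_matrices(self):
        m = _uniform_mat(0.4, 5)
        z, p = compare_mean_correlation(m, m)
        assert z == 0.0 and p == 1.0

    def test_strongly_coupled_vs_uncoupled(self):
        a, b = _uniform_mat(0.5, 63), _uniform_mat(0.0, 63)
        z, p = compare_mean_correlation(a, b)
        assert z > 0 and p < 0.001

    def test_antisymmetry(self, rng):
        R = rng.uniform(-0.5, 0.9, size=(6, 6))
        R = (R + R.T) / 2
        np.fill_diagonal(R, 1.0)
        a, b = _mat(R), _uniform_mat(0.1, 6)
        z_ab, _ = compare_mean_correlation(a, b)
        z_ba, _ = compare_mean_correlation(b, a)
        assert z_ab == pytest.approx(-z_ba)


class TestOneTailedP:
    def test_spec_threshold_value(self):
        assert one_tailed_r_pvalue(0.82, 6) == pytest.approx(0.0228, abs=0.0005)

    def test_zero_r_is_half(self):
        assert one_tailed_r_pvalue(0.0, 10) == pytest.approx(0.5)

    def test_sub_threshold_r(self):
        assert one_tailed_r_pvalue(0.7, 6) == pytest.approx(0.0607, abs=0.0005)

    def test_small_n_large_r_not_significant(self):
        assert one_tailed_r_pvalue(0.83, 4) == pytest.approx(0.0851, abs=0.0005)


class TestThresholdNetwork:
    def test_strong_uniform_matrix_is_complete(self):
        # p(0.9, 6) ~= 0.0073 < 0.05, so all pairs pass both conditions
        assert one_tailed_r_pvalue(0.9, 6) < 0.05
        G = threshold_network(_uniform_mat(0.9, 4, n=6))
        assert network_density(G) == 1.0

    def test_below_r_min_empty(self):
        G = threshold_network(_uniform_mat(0.5, 4, n=6))
        assert G.number_of_edges() == 0 and network_density(G) == 0.0

    def test_both_conditions_required(self):
        # r = 0.83 >= r_min but p(0.83, 4) ~= 0.085 >= alpha
        G = threshold_network(_uniform_mat(0.83, 3, n=4))
        assert G.number_of_edges() == 0

    def test_isolated_nodes_retained_and_weights_set(self):
        R = np.eye(3)
        R[0, 1] = R[1, 0] = 0.95
        G = threshold_network(_mat(R, n=8))
        assert G.number_of_nodes() == 3
        assert G.edges[("r0", "r1")]["weight"] == pytest.approx(0.95)

    def test_permutation_invariance(self, rng):
        R = rng.uniform(0.5, 0.99, size=(5, 5))
        R = (R + R.T) / 2
        np.fill_diagonal(R, 1.0)
        labels = list("abcde")
        mat = _mat(R, n=8, labels=labels)
        perm = [3, 1, 4, 0, 2]
        mat_p = _mat(R[np.ix_(perm, perm)], n=8, labels=[labels[i] for i in perm])
        G, Gp = threshold_network(mat), threshold_network(mat_p)
        assert set(map(frozenset, G.edges)) == set(map(frozenset, Gp.edges))


class TestDensity:
    def test_values(self):
        K4 = nx.complete_graph(4)
        assert network_density(K4) == 1.0
        G = nx.Graph([(0, 1), (1, 2), (2, 3)])
        G.add_nodes_from(range(4))
        assert network_density(G) == 0.5
        E = nx.empty_graph(5)
        assert network_density(E) == 0.0


class TestModules:
    def test_two_blocks_recovered(self):
        R = np.full((6, 6), 0.0)
        R[:3, :3] = 0.9
        R[3:, 3:] = 0.9
        np.fill_diagonal(R, 1.0)
        labels = detect_modules(_mat(R), cut=0.7)
        assert labels.nunique() == 2
        assert labels.iloc[:3].nunique() == 1 and labels.iloc[3:].nunique() == 1

    def test_equal_correlations_deterministic(self):
        mat = _uniform_mat(0.3, 5)
        a, b = detect_modules(mat, cut=0.7), detect_modules(mat, cut=0.7)
        pd.testing.assert_series_equal(a, b)
        # all merge heights equal: any ratio < 1 applies no merge
        assert a.nunique() == 5
        assert detect_modules(mat, cut=1.0).nunique() == 1

    def test_absolute_cut(self):
        mat = _uniform_mat(0.4, 4)  # all distances 0.6
        assert detect_modules(mat, cut=0.7, absolute=True).nunique() == 1
        assert detect_modules(mat, cut=0.5, absolute=True).nunique() == 4


def _brute_betweenness(G):
    """All-pairs shortest-path enumeration over simple paths (<= 8 nodes)."""
    nodes = list(G.nodes)
    bc = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        paths = []
        best = np.inf
        for path in nx.all_simple_paths(G, s, t):
            length = sum(1.0 / G.edges[u, v]["weight"] for u, v in zip(path, path[1:]))
            if length < best - 1e-12:
                best, paths = length, [path]
            elif abs(length - best) <= 1e-12:
                paths.append(path)
        for path in paths:
            for v in path[1:-1]:
                bc[v] += 1.0 / len(paths)
    n = len(nodes)
    norm = (n - 1) * (n - 2) / 2
    return {v: bc[v] / norm for v in nodes}


def _brute_eigenvector(G):
    """Dense eigendecomposition on the largest component."""
    comps = [sorted(c) for c in nx.connected_components(G) if len(c) > 1]
    out = dict.fromkeys(G.nodes, 0.0)
    if not comps:
        return out
    comp = sorted(comps, key=lambda c: (-len(c), str(c[0])))[0]
    A = nx.to_numpy_array(G.subgraph(comp), nodelist=comp, weight="weight")
    w, v = np.linalg.eigh(A)
    vec = np.abs(v[:, -1])
    vec /= np.linalg.norm(vec)
    for node, val in zip(comp, vec):
        out[node] = val
    return out


class TestCentralities:
    def test_star_graph(self):
        G = nx.star_graph(4)
        nx.set_edge_attributes(G, 1.0, "weight")
        cent = centrality_table(G)
        assert cent.loc[0, "degree"] == 4 and (cent.loc[1:, "degree"] == 1).all()
        assert cent.loc[0, "betweenness"] == pytest.approx(1.0)
        assert (cent.loc[1:, "betweenness"] == 0).all()

    def test_triangle_eigenvector_symmetric(self):
        G = nx.complete_graph(3)
        nx.set_edge_attributes(G, 0.9, "weight")
        cent = centrality_table(G)
        np.testing.assert_allclose(cent["eigenvector"], 1 / np.sqrt(3), atol=1e-8)

    def test_path_middle_betweenness(self):
        G = nx.path_graph(3)
        nx.set_edge_attributes(G, 1.0, "weight")
        cent = centrality_table(G)
        assert cent.loc[1, "betweenness"] == pytest.approx(1.0)
        assert cent.loc[0, "betweenness"] == 0.0

    def test_empty_graph_all_zero(self):
        G = nx.empty_graph(4)
        cent = centrality_table(G)
        assert (cent[["degree", "betweenness", "eigenvector"]] == 0).all().all()

    def test_matches_brute_force_oracles(self, rng):
        """Betweenness (path enumeration) and eigenvector (dense eigh)
        agree with networkx on random weighted graphs of <= 8 nodes."""
        for _ in range(60):
            n = int(rng.integers(3, 9))
            G = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(2**31)))
            for u, v in G.edges:
                G.edges[u, v]["weight"] = float(rng.uniform(0.3, 1.0))
            cent = centrality_table(G)
            if G.number_of_edges() == 0:
                continue
            bb = _brute_betweenness(G)
            ee = _brute_eigenvector(G)
            for v in G.nodes:
                assert cent.loc[v, "betweenness"] == pytest.approx(bb[v], abs=1e-9)
                assert cent.loc[v, "eigenvector"] == pytest.approx(ee[v], abs=1e-6)


class TestHubs:
    def _cent(self, G):
        nx.set_edge_attributes(G, 1.0, "weight")
        return centrality_table(G)

    def test_star_center_is_unique_hub(self):
        assert identify_hubs(self._cent(nx.star_graph(4))) == {0}

    def test_too_few_connected_nodes(self):
        G = nx.Graph([(0, 1), (1, 2)])
        G.add_nodes_from(range(6))
        assert identify_hubs(self._cent(G)) == set()

    def test_degenerate_complete_graph_all_tie(self):
        cent = self._cent(nx.complete_graph(5))
        assert identify_hubs(cent) == {0, 1, 2, 3, 4}

    def test_bowtie_center_is_unique_hub(self):
        """Two triangles sharing a vertex: the shared vertex tops degree,
        betweenness and eigenvector centrality simultaneously."""
        G = nx.Graph([(0, 1), (0, 2), (1, 2), (2, 3), (2, 4), (3, 4)])
        assert identify_hubs(self._cent(G)) == {2}

    def test_quantile_bounds(self):
        cent = self._cent(nx.star_graph(5))
        with pytest.raises(ValueError):
            identify_hubs(cent, quantile=1.0)


class TestCorrelationCSV:
    def test_round_trip(self, tmp_path, rng):
        R = rng.uniform(-0.5, 0.9, size=(4, 4))
        R = (R + R.T) / 2
        np.fill_diagonal(R, 1.0)
        mat = _mat(R, labels=["LC", "PAG", "TEa", "LSr"])
        path = tmp_path / "corr.csv"
        write_correlation_csv(mat, path)
        back = read_correlation_csv(path)
        pd.testing.assert_frame_equal(back.r, mat.r)


class TestCorrelationNetworkEstimator:
    def _planted(self, seed, m=8, rho=0.6):
        from fosmap.simulate import Factor, HubSpec, SynthConfig, generate_counts

        modA = tuple(f"A{i}" for i in range(m))
        modB = tuple(f"B{i}" for i in range(m))
        cfg = SynthConfig(
            seed=seed,
            group_sizes={"g": 8},
            regions=modA + modB + ("HUB",),
            baseline_log_mean=8.0,
            baseline_log_sd=0.1,
            factors=(Factor(modA, 0.8), Factor(modB, 0.8)),
            factor_corr=rho,
            hub=HubSpec("HUB"),
        )
        counts, truth = generate_counts(cfg)
        wide = counts.pivot(index="subject_id", columns="region_acronym", values="density")
        return np.log(wide.where(wide > 0)), truth

    def test_recovers_planted_modules_and_hub(self):
        from sklearn.metrics import adjusted_rand_score

        hits, aris = 0, []
        for seed in range(20):
            lnd, truth = self._planted(seed)
            net = CorrelationNetwork(r_min=0.5).fit(lnd)
            member = sorted(truth.modules)
            ari = adjusted_rand_score(
                [truth.modules[r] for r in member], net.modules_[member].to_numpy()
            )
            aris.append(ari)
            hits += int(truth.hub in net.hubs_)
        assert np.mean(aris) >= 0.9
        assert hits >= 14  # full-scale recovery rates are checked in acceptance

    def test_fitted_attributes_consistent(self):
        lnd, _ = self._planted(0)
        net = CorrelationNetwork(r_min=0.5).fit(lnd)
        G = net.graph_
        assert net.density_ == pytest.approx(
            2 * G.number_of_edges() / (G.number_of_nodes() * (G.number_of_nodes() - 1))
        )
        assert set(net.centralities_.index) == set(G.nodes)
        for _, _, d in G.edges(data=True):
            assert d["weight"] >= 0.5

    def test_sklearn_clone(self):
        from sklearn.base import clone

        net = CorrelationNetwork(r_min=0.6, hub_quantile=0.9)
        assert clone(net).get_params()["hub_quantile"] == 0.9
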