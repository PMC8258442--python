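import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thicknet import (
    CohortTable,
    DensitySweep,
    NodeSet,
    SyntheticSpec,
    ValidationError,
    WeightedNetwork,
    correlation_network,
    generate_cohort,
    qc_density_bounds,
    sweep_networks,
    threshold_by_density,
)

from _oracles import random_weighted_graph


def _cohort_from_matrix(X, nodes):
    df = pd.DataFrame(X, columns=nodes.columns)
    df.insert(0, "age", 50.0)
    df.index = pd.Index([f"s{i}" for i in range(len(df))], name="subject")
    return CohortTable(df)


class TestCorrelationNetwork:
    def test_perfect_positive_collinearity(self):
        nodes = NodeSet.from_columns("t", ["lh_a", "lh_b", "lh_c"])
        X = np.array([[1, 2, 5.0], [2, 4, 5.1], [3, 6, 4.9]])
        W = correlation_network(_cohort_from_matrix(X, nodes), nodes)
        assert W.weights[0, 1] == pytest.approx(1.0)
        assert np.all(np.diag(W.weights) == 0)

    def test_negative_correlation_excluded(self):
        nodes = NodeSet.from_columns("t", ["lh_a", "lh_b", "lh_c"])
        X = np.array([[1, 6, 5.0], [2, 4, 5.1], [3, 2, 4.9]])
        W = correlation_network(_cohort_from_matrix(X, nodes), nodes)
        assert W.weights[0, 1] == 0.0  # r = -1 stored as 0

    def test_zero_variance_region_named(self):
        nodes = NodeSet.from_columns("t", ["lh_a", "lh_b", "lh_c"])
        X = np.array([[1, 2.0, 3], [2, 2.0, 4], [3, 2.0, 5]])
        with pytest.raises(ValidationError, match="lh_b"):
            correlation_network(_cohort_from_matrix(X, nodes), nodes)

    def test_too_few_subjects(self):
        nodes = NodeSet.from_columns("t", ["lh_a", "lh_b", "lh_c"])
        X = np.array([[1, 2, 3.0], [2, 3, 4]])
        with pytest.raises(ValidationError, match="3 subjects"):
            correlation_network(_cohort_from_matrix(X, nodes), nodes)

    def test_block_structure_within_fisher_z_bounds(self, nodes12):
        cols = nodes12.columns
        spec = SyntheticSpec(
            n_subjects=200, regions=nodes12,
            blocks=(tuple(cols[:6]), tuple(cols[6:])),
            r_in=0.6, r_out=0.0, atrophy_slope=0.0, seed=31,
        )
        cohort = generate_cohort(spec)
        W = correlation_network(cohort, nodes12)
        from scipy.stats import norm

        # family-wise 99% Fisher-z envelope across the 15 within-block pairs
        z_fw = norm.ppf(1 - (1 - 0.99 ** (1 / 15)) / 2)
        half = z_fw / np.sqrt(200 - 3)
        within = W.weights[:6, :6][np.triu_indices(6, 1)]
        assert np.all(np.abs(np.arctanh(within) - np.arctanh(0.6)) < half)

    def test_subject_order_invariance(self, nodes6):
        spec = SyntheticSpec(n_subjects=40, regions=nodes6, seed=13)
        cohort = generate_cohort(spec)
        W1 = correlation_network(cohort, nodes6)
        W2 = correlation_network(
            cohort.subset(list(reversed(cohort.subjects))), nodes6
        )
        np.testing.assert_allclose(W1.weights, W2.weights, atol=1e-12)


class TestThresholding:
    def test_toy_half_density(self, toy_weighted):
        B = threshold_by_density(toy_weighted, 50)
        assert B.n_edges == 3
        expected = {(0, 1), (1, 2), (0, 2)}  # top-3 weights: triangle
        got = {
            (i, j)
            for i in range(4)
            for j in range(i + 1, 4)
            if B.adjacency[i, j]
        }
        assert got == expected

    def test_saturation_gives_complete_graph(self):
        n = 5
        M = np.full((n, n), 0.5)
        np.fill_diagonal(M, 0)
        W = WeightedNetwork(tuple(f"lh_{i}" for i in range(n)), M)
        B = threshold_by_density(W, 99.9)
        assert B.n_edges == n * (n - 1) // 2

    def test_shortfall_warns_with_realized_density(self):
        M = np.zeros((4, 4))
        M[0, 1] = M[1, 0] = 0.9
        M[2, 3] = M[3, 2] = 0.4
        W = WeightedNetwork(("lh_a", "lh_b", "lh_c", "lh_d"), M)
        with pytest.warns(UserWarning, match="33.3"):
            B = threshold_by_density(W, 50)
        assert B.n_edges == 2

    def test_toy_sweep_rounding(self, toy_weighted):
        nets = sweep_networks(
            toy_weighted, DensitySweep((25.0, 50.0), 25.0)
        )
        assert [n.n_edges for n in nets] == [2, 3]

    def test_sweep_structure_and_counts(self, toy_weighted):
        nets = sweep_networks(toy_weighted, DensitySweep())
        assert len(nets) == 36
        counts = [n.n_edges for n in nets]
        assert counts == sorted(counts)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000), st.integers(5, 12))
    def test_nestedness_property(self, seed, n):
        rng = np.random.default_rng(seed)
        M = random_weighted_graph(rng, n)
        W = WeightedNetwork(tuple(f"lh_{i}" for i in range(n)), M)
        nets = sweep_networks(W, DensitySweep())
        prev = np.zeros((n, n))
        for net in nets:
            assert np.all(net.adjacency >= prev)
            prev = net.adjacency

    def test_scale_invariance(self, toy_weighted):
        scaled = WeightedNetwork(
            toy_weighted.labels, toy_weighted.weights * 0.5
        )
        for d in (25, 50, 75):
            a = threshold_by_density(toy_weighted, d).adjacency
            b = threshold_by_density(scaled, d).adjacency
            np.testing.assert_array_equal(a, b)

    def test_invalid_density(self, toy_weighted):
        from thicknet import ParameterError

        with pytest.raises(ParameterError):
            threshold_by_density(toy_weighted, 0)


class TestDensityQC:
    def test_disconnected_network_flagged(self):
        from thicknet.networks import BinaryNetwork

        A = np.zeros((4, 4), dtype=np.int8)
        for i, j in [(0, 1), (1, 2), (0, 2)]:
            A[i, j] = A[j, i] = 1
        net = BinaryNetwork(("lh_a", "lh_b", "lh_c", "lh_d"), A, 50.0, 50.0)
        rep = qc_density_bounds([net], n_rand=10, seed=1)
        assert not rep.loc[0, "connected"]
        assert "disconnected" in rep.loc[0, "flag"]

    def test_ring_lattice_is_small_world(self):
        import networkx as nx
        from thicknet.networks import BinaryNetwork

        G = nx.watts_strogatz_graph(20, 4, 0.0, seed=1)
        A = nx.to_numpy_array(G).astype(np.int8)
        net = BinaryNetwork(tuple(f"lh_{i}" for i in range(20)), A, 21.1, 21.1)
        rep = qc_density_bounds([net], n_rand=50, seed=11)
        assert rep.loc[0, "sigma"] > 1.5
        assert rep.loc[0, "flag"] == ""

    def test_dense_random_graph_flagged_random_topology(self):
        import networkx as nx
        from thicknet.networks import BinaryNetwork

        G = nx.gnp_random_graph(20, 0.5, seed=2)
        A = nx.to_numpy_array(G).astype(np.int8)
        net = BinaryNetwork(tuple(f"lh_{i}" for i in range(20)), A, 50.0, 50.0)
        rep = qc_density_bounds([net], n_rand=50, seed=11)
        assert 0.9 < rep.loc[0, "sigma"] < 1.1
        assert "random-topology" in rep.loc[0, "flag"]


def test_density_sweep_invariants():
    with pytest.raises(ValidationError, match="increasing"):
        DensitySweep((10.0, 10.0), 10.0)
    with pytest.raises(ValidationError, match="median"):
        DensitySweep((10.0, 20.0), 15.0)
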