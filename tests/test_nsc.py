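import math

import numpy as np
import pandas as pd
import pytest
from conftest import chain_network, disjoint_network, make_groups, make_scores
from hypothesis import given, settings
from hypothesis import strategies as st

from netcentroid import CompositeNetwork, adjust_scores, build_neighborhoods, fit, psi, sign_agreement
from netcentroid.nsc import balanced_overall_centroid, delta_grid, edge_statistics, soft_threshold
from netcentroid.scoring import EdgeScoreMatrix


class TestBalancedCentroid:
    def test_mean_of_class_means(self):
        assert balanced_overall_centroid(np.array([[1.0, 3.0]]))[0] == 2.0

    def test_equal_sizes_equals_grand_mean(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 10))
        idx = np.array([0] * 5 + [1] * 5)
        cm, overall, *_ = edge_statistics(X, idx, 2)
        assert np.allclose(overall, X.mean(axis=1))

    def test_unbalanced_sizes_bias_correction(self):
        # groups of 9 and 1 with class means 0 and 10: balanced centroid 5,
        # grand mean would be 1
        X = np.array([[0.0] * 9 + [10.0]])
        X[0, :9] += np.linspace(-0.1, 0.1, 9)  # nonzero within-class variance
        X[0, :9] -= X[0, :9].mean()
        idx = np.array([0] * 9 + [1])
        cm, overall, *_ = edge_statistics(X, idx, 2)
        assert overall[0] == pytest.approx(5.0)
        assert X.mean() == pytest.approx(1.0)


class TestEdgeStatistics:
    def three_edge_toy(self):
        X = np.array([
            [0.0, 0.0, 2.0, 2.0],   # s = 0
            [0.0, 1.0, 0.0, 1.0],   # s = sqrt(0.5)
            [0.0, 2.0, 1.0, 3.0],   # s = sqrt(2)
        ])
        idx = np.array([0, 0, 1, 1])
        return X, idx

    def test_hand_computed_d(self):
        X, idx = self.three_edge_toy()
        cm, overall, s, s0, m, d = edge_statistics(X, idx, 2)
        assert s0 == pytest.approx(math.sqrt(0.5))
        assert np.allclose(m, math.sqrt(0.75))
        # edge 0: class means 0 and 2, overall 1, s=0 -> d = -1/(m*s0)
        expected = -1.0 / (math.sqrt(0.75) * math.sqrt(0.5))
        assert d[0, 0] == pytest.approx(expected)
        assert d[0, 1] == pytest.approx(-expected)

    def test_zero_numerator_gives_zero_d(self):
        X = np.array([[1.0, -1.0, 1.0, -1.0], [0.0, 1.0, 2.0, 3.0]])
        idx = np.array([0, 0, 1, 1])
        *_, d = edge_statistics(X, idx, 2)
        assert d[0, 0] == 0.0 and d[0, 1] == 0.0

    def test_scaling_acts_through_s0_offset_only(self):
        X, idx = self.three_edge_toy()
        _, _, s, s0, m, d = edge_statistics(X, idx, 2)
        X2 = X.copy()
        X2[2] *= 2.0
        _, _, s2, s02, m2, d2 = edge_statistics(X2, idx, 2)
        # numerator and s_i of the scaled edge both double ...
        assert s2[2] == pytest.approx(2 * s[2])
        # ... so d would be unchanged were it not for the s0 offset
        numer = X[2, :2].mean() - X[2].mean()
        assert d2[2, 0] == pytest.approx(2 * numer / (m[0] * (2 * s[2] + s02)))
        assert d2[2, 0] != pytest.approx(d[2, 0])

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError, match="more samples"):
            edge_statistics(np.zeros((2, 2)), np.array([0, 1]), 2)


class TestNeighborhoods:
    def test_path_graph(self):
        nb = build_neighborhoods(chain_network(2))
        assert nb.sizes.tolist() == [1, 1]
        assert nb.adjacency[0, 1] and nb.adjacency[1, 0]

    def test_tf_star(self):
        net = CompositeNetwork.from_edges(
            [("TF1", "G1", "TF"), ("TF1", "G2", "TF"), ("TF1", "G3", "TF")])
        nb = build_neighborhoods(net)
        assert nb.sizes.tolist() == [2, 2, 2]
        assert nb.sizes_tf.tolist() == [2, 2, 2]
        assert nb.sizes_ppi.tolist() == [0, 0, 0]

    def test_triangle(self):
        net = CompositeNetwork.from_edges(
            [("A", "B", "PPI"), ("B", "C", "PPI"), ("A", "C", "PPI")])
        nb = build_neighborhoods(net)
        assert nb.sizes.tolist() == [2, 2, 2]

    def test_symmetry_and_partition(self):
        net = CompositeNetwork.from_edges(
            [("TF1", "G1", "TF"), ("TF1", "P1", "PPI"), ("P1", "P2", "PPI"),
             ("A", "B", "PPI")])
        nb = build_neighborhoods(net)
        assert (nb.adjacency != nb.adjacency.T).nnz == 0
        assert np.array_equal(nb.sizes, nb.sizes_tf + nb.sizes_ppi)
        assert nb.sizes[3] == 0  # isolated edge


def star_neighborhood(n_edges=5):
    net = CompositeNetwork.from_edges(
        [("HUB", f"X{i}", "PPI") for i in range(n_edges)])
    return build_neighborhoods(net)


class TestSignAgreement:
    def test_counting(self):
        nb = star_neighborhood(5)
        d = np.array([[1.0], [1.0], [1.0], [1.0], [-1.0]])
        p = sign_agreement(d, nb)
        assert p[0, 0] == pytest.approx(3 / 4)
        assert p[4, 0] == pytest.approx(0.0)  # all neighbours opposite

    def test_zero_d_neighbor_never_agrees_with_signed_edge(self):
        nb = star_neighborhood(3)
        d = np.array([[1.0], [0.0], [1.0]])
        p = sign_agreement(d, nb)
        assert p[0, 0] == pytest.approx(0.5)
        assert p[1, 0] == pytest.approx(0.0)  # sign(0)=0 matches no signed neighbour

    def test_empty_neighborhood_is_nan(self):
        nb = build_neighborhoods(disjoint_network(2))
        p = sign_agreement(np.ones((2, 1)), nb)
        assert np.isnan(p).all()


class TestPsi:
    def test_midpoint_and_endpoint(self):
        assert psi(0.5) == pytest.approx(1.0, abs=1e-12)
        assert psi(1.0) == pytest.approx(2 * math.exp(2.5) / (1 + math.exp(2.5)), abs=1e-10)
        assert psi(1.0) == pytest.approx(1.8483, abs=1e-4)

    def test_out_of_range_errors(self):
        for bad in (-0.1, 1.1):
            with pytest.raises(ValueError):
                psi(bad)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_symmetry(self, p):
        assert psi(p) + psi(1 - p) == pytest.approx(2.0, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=0.0, max_value=1.0), st.floats(min_value=0.0, max_value=1.0))
    def test_strictly_increasing(self, a, b):
        if a != b:
            lo, hi = min(a, b), max(a, b)
            assert psi(lo) < psi(hi)


class TestAdjustScores:
    def test_unanimous_neighbors(self):
        # three mutually neighbouring edges, all d = 1: p = 1, mean = 1
        nb = star_neighborhood(3)
        d = np.ones((3, 1))
        d_star = adjust_scores(d, nb)
        assert np.allclose(d_star, 1.0 + psi(1.0))
        assert d_star[0, 0] == pytest.approx(2.8483, abs=1e-3)

    def test_empty_neighborhood_unadjusted(self):
        nb = build_neighborhoods(disjoint_network(3))
        d = np.array([[1.0], [-2.0], [0.5]])
        assert np.array_equal(adjust_scores(d, nb), d)

    def test_zero_mean_neighbors_no_change(self):
        nb = star_neighborhood(3)
        d = np.array([[1.0], [1.0], [-1.0]])
        d_star = adjust_scores(d, nb)
        assert d_star[0, 0] == pytest.approx(1.0)  # neighbours (1,-1): mean 0

    def test_literal_form_scales_with_neighbor_count(self):
        nb = star_neighborhood(3)
        d = np.ones((3, 1))
        lit = adjust_scores(d, nb, form="literal")
        # |N1|=0, |N2|=2: A = (2*2)/2 = 2, twice the mean form's A = 1
        assert np.allclose(lit, 1.0 + psi(1.0) * 2.0)


class TestDeltaGrid:
    def test_delta_max_is_mean_of_group_maxima(self):
        d_star = np.array([[3.0, 1.0], [-1.0, -5.0]])
        grid, delta_max, group_max = delta_grid(d_star)
        assert delta_max == pytest.approx(4.0)
        assert group_max.tolist() == [3.0, 5.0]

    def test_grid_has_30_values_from_zero_to_max(self):
        d_star = np.random.default_rng(0).normal(size=(10, 3))
        grid, delta_max, _ = delta_grid(d_star)
        assert len(grid) == 30
        assert grid[0] == 0.0 and grid[-1] == pytest.approx(delta_max)
        assert np.allclose(np.diff(grid), grid[1] - grid[0])

    def test_all_zero_statistics_degenerate(self):
        grid, delta_max, _ = delta_grid(np.zeros((4, 2)))
        assert delta_max == 0.0 and grid.tolist() == [0.0]


class TestSoftThreshold:
    @pytest.mark.parametrize("d_star,delta_k,expected", [
        (2.0, 0.5, 1.5),
        (-0.3, 0.5, 0.0),
        (-2.0, 0.5, -1.5),
        (2.0, 0.0, 2.0),
    ])
    def test_examples(self, d_star, delta_k, expected):
        assert soft_threshold(np.array([[d_star]]), np.array([delta_k]))[0, 0] == expected

    def test_magnitude_never_grows_and_sign_preserved(self):
        rng = np.random.default_rng(1)
        d_star = rng.normal(size=(20, 2))
        dp = soft_threshold(d_star, np.array([0.4, 0.9]))
        assert (np.abs(dp) <= np.abs(d_star) + 1e-15).all()
        assert ((np.sign(dp) == np.sign(d_star)) | (dp == 0)).all()


@pytest.fixture
def fitted(two_groups):
    net = chain_network(6)
    scores = make_scores(net, two_groups, seed=7,
                         shift={0: (1.5, -1.5), 1: (1.2, -1.2), 5: (-1.0, 1.0)})
    return make_scores, fit(scores, two_groups), scores


class TestFittedModel:
    def test_full_shrinkage_collapses_centroids(self, fitted):
        _, model, _ = fitted
        assert model.n_selected(model.delta_max) == 0
        cent = model.shrunken_centroids(model.delta_max)
        assert np.allclose(cent, model.overall_centroid[:, None])

    def test_dprime_inversion_recovers_dprime(self, fitted):
        _, model, _ = fitted
        delta = model.grid[10]
        cent = model.shrunken_centroids(delta)
        back = (cent - model.overall_centroid[:, None]) / (
            model.m[None, :] * (model.s + model.s0)[:, None])
        assert np.allclose(back, model.d_prime(delta), atol=1e-10)

    def test_adjustment_shifts_centroid_even_at_zero_delta(self, two_groups):
        net = chain_network(4)
        scores = make_scores(net, two_groups, seed=11, shift={1: (2.0, -2.0), 2: (1.8, -1.8)})
        model = fit(scores, two_groups, adjust=True)
        raw_class_means = model.class_means
        cent0 = model.shrunken_centroids(0.0)
        assert not np.allclose(cent0, raw_class_means)  # psi-term active: d* != d

    def test_selection_monotone_along_grid(self, fitted):
        _, model, _ = fitted
        prev = None
        for delta in model.grid:
            sel = {
                g: set(df["edge_id"]) for g, df in
                model.select_subnetwork(delta).per_group.items()
            }
            if prev is not None:
                for g in sel:
                    assert sel[g] <= prev[g]
            prev = sel

    def test_delta_zero_selects_all_nonzero_dstar(self, fitted):
        _, model, _ = fitted
        sel = model.select_subnetwork(0.0)
        for k, g in enumerate(model.group_labels):
            expected = {model.edge_ids[i] for i in np.flatnonzero(np.abs(model.d_star[:, k]) > 0)}
            assert set(sel.per_group[g]["edge_id"]) == expected

    def test_planted_edge_survives_longest(self, two_groups):
        net = chain_network(5)
        scores = make_scores(net, two_groups, seed=13, shift={2: (3.0, -3.0)})
        model = fit(scores, two_groups)
        target = model.edge_ids[2]
        survivors = None
        for delta in model.grid:
            ids = model.select_subnetwork(delta).edge_ids
            if ids:
                survivors = ids
        assert survivors == {target}

    def test_permutation_invariance(self, two_groups):
        net = chain_network(5)
        scores = make_scores(net, two_groups, seed=17, shift={1: (1.0, -1.0)})
        model = fit(scores, two_groups)
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(two_groups.samples))
        data_p = scores.data.iloc[:, perm]
        model_p = fit(EdgeScoreMatrix(net, data_p), two_groups)
        assert np.allclose(model.d, model_p.d)
        assert np.allclose(model.d_star, model_p.d_star)
        assert model.s0 == pytest.approx(model_p.s0)


class TestClassify:
    def test_posteriors_sum_to_one(self, fitted):
        _, model, scores = fitted
        pred = model.classify(scores, model.grid[3])
        assert np.allclose(pred.posteriors.sum(axis=1), 1.0, atol=1e-10)
        # argmin delta == argmax posterior
        assert (pred.scores.idxmin(axis=1) == pred.posteriors.idxmax(axis=1)).all()

    def test_midpoint_sample_is_equivocal(self, fitted):
        _, model, scores = fitted
        cent = model.shrunken_centroids(0.0)
        mid = cent.mean(axis=1)
        df = pd.DataFrame({"Q": mid}, index=model.edge_ids)
        pred = model.classify(df, 0.0)
        assert np.allclose(pred.posteriors.loc["Q"], [0.5, 0.5], atol=1e-10)
        assert pred.labels["Q"] == model.group_labels[0]  # tie -> first label

    def test_sample_at_centroid_gets_its_class(self, fitted):
        _, model, scores = fitted
        cent = model.shrunken_centroids(0.0)
        df = pd.DataFrame({"Q": cent[:, 1]}, index=model.edge_ids)
        pred = model.classify(df, 0.0)
        assert pred.labels["Q"] == model.group_labels[1]

    def test_edge_mismatch_errors(self, fitted):
        _, model, scores = fitted
        df = scores.data.iloc[:-1]
        with pytest.raises(ValueError, match="edge universe"):
            model.classify(df, 0.0)


class TestOracleEquivalence:
    def test_matches_reference_nsc_without_adjustment(self):
        from _reference import ReferenceNSC

        rng = np.random.default_rng(2024)
        groups = make_groups([10, 10], ["A", "B"])
        net = disjoint_network(20)
        X = rng.normal(size=(20, 20))
        X[:4, :10] += rng.normal(1.0, 0.2, size=(4, 1))
        data = pd.DataFrame(X, index=net.edge_ids, columns=groups.samples)
        scores = EdgeScoreMatrix(net, data)
        model = fit(scores, groups, adjust=False)
        ref = ReferenceNSC(X, list(groups.assignments))
        assert np.allclose(model.d, ref.d, atol=1e-8)
        assert model.delta_max == pytest.approx(ref.delta_max, abs=1e-12)
        for delta in (0.0, ref.grid[10], ref.grid[25]):
            assert np.allclose(model.d_prime(delta), ref.d_prime(delta), atol=1e-8)
        Xnew = rng.normal(size=(20, 6))
        dfnew = pd.DataFrame(Xnew, index=net.edge_ids,
                             columns=[f"T{i}" for i in range(6)])
        delta = ref.grid[8]
        pred = model.classify(dfnew, delta)
        labels, disc, post = ref.classify(Xnew, delta)
        assert pred.labels.tolist() == labels
        assert np.allclose(pred.scores.to_numpy(), disc, atol=1e-8)
        assert np.allclose(pred.posteriors.to_numpy(), post, atol=1e-8)


def dense_vs_scattered_dstar():
    """Star-connected and scattered planted edges with identical per-edge d."""
    groups = make_groups([5, 5], ["A", "B"])
    edges = [("HUB", f"A{i}", "PPI") for i in range(4)]          # connected star
    edges += [(f"B{i}", f"C{i}", "PPI") for i in range(4)]        # scattered
    edges += [(f"D{i}", f"E{i}", "PPI") for i in range(8)]        # null filler
    net = CompositeNetwork.from_edges(edges)
    rng = np.random.default_rng(99)
    n = 10
    jitter = rng.normal(0, 0.1, size=n)  # identical pattern for all signal edges
    signal = np.where(np.arange(n) < 5, 1.0, -1.0) + jitter
    rows = [signal.copy() for _ in range(8)]
    rows += [rng.normal(0, 1, size=n) for _ in range(8)]
    data = pd.DataFrame(np.vstack(rows), index=net.edge_ids, columns=groups.samples)
    model = fit(EdgeScoreMatrix(net, data), groups, adjust=True)
    star = np.abs(model.d_star[:4]).mean()
    scattered = np.abs(model.d_star[4:8]).mean()
    assert np.allclose(model.d[:4], model.d[4:8])  # identical raw statistics
    return star, scattered, model


class TestDenseSignalPreference:
    def test_star_edges_get_larger_adjusted_statistic(self):
        star, scattered, model = dense_vs_scattered_dstar()
        assert star > scattered
        # scattered edges have empty neighbourhoods: unadjusted
        assert np.allclose(model.d_star[4:8], model.d[4:8])
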