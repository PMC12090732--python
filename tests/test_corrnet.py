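from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from symbiocor.corrnet import (
    cluster_profiles,
    correlate_pair,
    cross_network,
    detect_outliers,
    edge_list,
    signed_counts,
    spearman_rho,
)


def brute_force_permutation_p(x, y):
    """Independent oracle: exhaustive two-sided permutation p for Spearman
    rho, using scipy's spearmanr directly."""
    rho_obs = stats.spearmanr(x, y).statistic
    hits = total = 0
    for perm in permutations(y):
        total += 1
        if abs(stats.spearmanr(x, perm).statistic) >= abs(rho_obs) - 1e-12:
            hits += 1
    return rho_obs, hits / total


class TestCorrelatePair:
    def test_monotone_quadruple_exact_p(self):
        rho, p = correlate_pair([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 24)

    def test_antitone_rho_minus_one(self):
        rho, _ = correlate_pair([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_tied_rho_equals_pearson_on_average_ranks(self):
        x = [1, 1, 2, 3, 5]
        y = [2, 4, 4, 1, 9]
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        assert spearman_rho(x, y) == pytest.approx(np.corrcoef(rx, ry)[0, 1])

    @pytest.mark.parametrize("n,seed", [(4, 0), (5, 1), (6, 2), (7, 3), (6, 4)])
    def test_exact_p_matches_enumeration_oracle(self, n, seed):
        """For n <= 7 the permutation p is exact: it must equal a direct
        enumeration over all n! reorderings, including tied data."""
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 4, size=n).astype(float)
        y = rng.integers(0, 4, size=n).astype(float)
        while np.ptp(x) == 0 or np.ptp(y) == 0:
            x = rng.integers(0, 4, size=n).astype(float)
            y = rng.integers(0, 4, size=n).astype(float)
        rho, p = correlate_pair(x, y)
        rho_ref, p_ref = brute_force_permutation_p(x, y)
        assert rho == pytest.approx(rho_ref)
        assert p == pytest.approx(p_ref)

    def test_monte_carlo_p_bounded_below(self, rng):
        x = np.arange(12.0)
        y = x + rng.normal(scale=0.01, size=12)
        _, p = correlate_pair(x, y, B=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError, match="constant"):
            correlate_pair([1, 1, 1, 1], [1, 2, 3, 4])


class TestCrossNetwork:
    def test_self_network_diagonal_rho_one(self, rng):
        mat = pd.DataFrame(
            rng.integers(1, 100, size=(5, 9)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(9)],
        )
        net = cross_network(mat, mat, B=99, seed=0)
        assert np.allclose(np.diag(net.rho.to_numpy()), 1.0)

    def test_rank_invariance_under_scaling(self, rng):
        a = pd.DataFrame(rng.integers(1, 50, (3, 8)))
        b = pd.DataFrame(rng.integers(1, 50, (4, 8)))
        n1 = cross_network(a, b, B=199, seed=1)
        n2 = cross_network(a * 10, b, B=199, seed=1)
        pd.testing.assert_frame_equal(n1.rho, n2.rho)
        pd.testing.assert_frame_equal(n1.p, n2.p)

    def test_constant_genes_excluded(self, rng):
        a = pd.DataFrame(rng.integers(1, 50, (3, 8)))
        a.iloc[1] = 7
        net = cross_network(a, pd.DataFrame(rng.integers(1, 50, (2, 8))), B=99, seed=0)
        assert 1 in net.excluded_rows
        assert net.rho.shape[0] == 2

    def test_transpose_is_argument_swap(self, rng):
        a = pd.DataFrame(rng.integers(1, 50, (3, 8)))
        b = pd.DataFrame(rng.integers(1, 50, (4, 8)))
        n1 = cross_network(a, b, B=199, seed=2)
        n2 = cross_network(b, a, B=199, seed=2)
        pd.testing.assert_frame_equal(n1.rho.T, n2.rho)

    def test_too_few_samples_raise(self, rng):
        a = pd.DataFrame(rng.integers(1, 50, (3, 3)))
        with pytest.raises(ValueError, match=">= 4"):
            cross_network(a, a, B=9, seed=0)


class TestSignedCounts:
    def _hand_network(self):
        rho = pd.DataFrame(
            [[0.9, -0.8, 0.1], [-0.7, 0.0, 0.6], [0.5, -0.4, 0.3]],
            index=list("abc"),
            columns=list("xyz"),
        )
        p = pd.DataFrame(
            [[0.01, 0.01, 0.5], [0.01, 0.01, 0.01], [0.5, 0.04, 0.2]],
            index=list("abc"),
            columns=list("xyz"),
        )
        from symbiocor.corrnet import CorrelationNetwork

        return CorrelationNetwork(rho, p, alpha=0.05, B=99, seed=0)

    def test_hand_enumeration(self):
        pos, neg, prof = signed_counts(self._hand_network())
        # significant cells: (a,x)+, (a,y)-, (b,x)-, (b,z)+, (c,y)-
        # (b,y) has p<alpha but rho == 0 and counts in neither class
        assert (pos, neg) == (2, 3)
        assert prof.loc["a", "n_pos"] == 1 and prof.loc["a", "n_neg"] == 1

    def test_totals_conserve_per_gene_profiles(self):
        pos, neg, prof = signed_counts(self._hand_network())
        assert prof["n_pos"].sum() == pos and prof["n_neg"].sum() == neg

    def test_all_insignificant_gives_zero(self):
        net = self._hand_network()
        net.p[:] = 0.5
        assert signed_counts(net)[:2] == (0, 0)


class TestOutliers:
    def test_equal_counts_give_no_outliers(self):
        prof = pd.DataFrame({"n_pos": [3] * 6, "n_neg": [1] * 6})
        out = detect_outliers(prof)
        assert not out["outlier"].any()

    def test_extreme_gene_flagged_with_trigger(self):
        prof = pd.DataFrame(
            {"n_pos": [1, 2, 3, 2, 100], "n_neg": [1, 1, 1, 1, 1]},
            index=list("abcde"),
        )
        out = detect_outliers(prof)
        assert out.loc["e", "outlier"]
        assert out.loc["e", "triggered_by"] == "n_pos"
        assert out["outlier"].sum() == 1

    def test_fence_matches_quantile_computation(self, rng):
        vals = rng.integers(0, 30, size=40)
        prof = pd.DataFrame({"n_pos": vals, "n_neg": np.zeros(40, dtype=int)})
        out = detect_outliers(prof)
        q1, q3 = np.percentile(vals, [25, 75])
        fence = q3 + 1.5 * (q3 - q1)
        assert set(out.index[out["outlier"]]) == set(np.flatnonzero(vals > fence))

    def test_too_few_profiles_raise(self):
        with pytest.raises(ValueError, match="5"):
            detect_outliers(pd.DataFrame({"n_pos": [1, 2]}))


class TestClusterProfiles:
    @pytest.mark.parametrize("method,distance", [("ward", "euclidean"), ("upgma", "bray_curtis")])
    def test_planted_blobs_recovered(self, method, distance, rng):
        a = rng.normal(10, 0.5, size=(10, 3)).clip(0.1)
        b = rng.normal(100, 0.5, size=(10, 3))
        prof = pd.DataFrame(np.vstack([a, b]))
        labels, _ = cluster_profiles(prof, method=method, distance=distance, k=2)
        truth = [0] * 10 + [1] * 10
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_equals_n_gives_singletons(self, rng):
        prof = pd.DataFrame(rng.normal(size=(6, 2)))
        labels, _ = cluster_profiles(prof, k=6)
        assert labels.nunique() == 6

    def test_duplicated_rows_merge_first(self):
        prof = pd.DataFrame(
            [[1.0, 1.0], [1.0, 1.0], [9.0, 9.0], [5.0, 2.0]], index=list("abcd")
        )
        labels, Z = cluster_profiles(prof, k=3)
        assert labels["a"] == labels["b"]
        assert Z[0, 2] == pytest.approx(0.0)  # first merge at distance zero

    def test_k_larger_than_n_raises(self):
        with pytest.raises(ValueError, match="k="):
            cluster_profiles(pd.DataFrame([[1.0], [2.0]]), k=5)


class TestEdgeList:
    def _net(self, rng):
        a = pd.DataFrame(rng.normal(size=(6, 10)).cumsum(axis=1))
        b = pd.DataFrame(rng.normal(size=(6, 10)).cumsum(axis=1))
        return cross_network(a, b, B=199, seed=3)

    def test_cutoff_zero_keeps_all_significant(self, rng):
        net = self._net(rng)
        edges = edge_list(net, 0.0)
        assert len(edges) == int(net.significant().to_numpy().sum())

    def test_cutoff_one_keeps_only_max(self, rng):
        net = self._net(rng)
        edges = edge_list(net, 1.0)
        sig_abs = np.abs(net.rho.to_numpy()[net.significant().to_numpy()])
        if sig_abs.size:
            assert edges["rho"].abs().max() == pytest.approx(sig_abs.max())
            assert (edges["rho"].abs() >= sig_abs.max() - 1e-12).all()

    def test_retained_count_matches_quantile_definition(self, rng):
        net = self._net(rng)
        q = 0.75
        edges = edge_list(net, q)
        sig_abs = np.abs(net.rho.to_numpy()[net.significant().to_numpy()])
        threshold = np.quantile(sig_abs, q)
        assert len(edges) == int((sig_abs >= threshold - 1e-12).sum())

    def test_empty_network_gives_empty_list(self):
        rho = pd.DataFrame([[0.1]], index=["a"], columns=["x"])
        p = pd.DataFrame([[0.9]], index=["a"], columns=["x"])
        from symbiocor.corrnet import CorrelationNetwork

        net = CorrelationNetwork(rho, p, alpha=0.05, B=9, seed=0)
        assert edge_list(net, 0.5).empty
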