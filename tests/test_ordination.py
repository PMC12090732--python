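from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kstest, rankdata

from symbiocor.ordination import (
    AnosimResult,
    DistanceMatrix,
    anosim,
    bray_curtis,
    dbrda,
    euclidean,
    forward_select,
    pcoa,
    robust_aitchison,
    simper,
)


def classical_rda(Y, X):
    """Independent oracle: redundancy analysis of a response matrix on
    centred predictors, by direct least squares."""
    Yc = Y - Y.mean(axis=0)
    Xc = X - X.mean(axis=0)
    B, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    Yhat = Xc @ B
    eig = np.linalg.svd(Yhat, compute_uv=False) ** 2
    total = (Yc**2).sum()
    return np.sort(eig[eig > 1e-10])[::-1], (Yhat**2).sum() / total


def brute_force_anosim(d, groups):
    """Independent oracle: ANOSIM R and exact permutation p by explicit
    loops over sample pairs and all label permutations."""
    n = len(groups)
    ranks = squareform(rankdata(squareform(d)))

    def r_stat(g):
        rb, nb, rw, nw = 0.0, 0, 0.0, 0
        for i in range(n):
            for j in range(i + 1, n):
                if g[i] == g[j]:
                    rw += ranks[i, j]
                    nw += 1
                else:
                    rb += ranks[i, j]
                    nb += 1
        return (rb / nb - rw / nw) / (n * (n - 1) / 4)

    r_obs = r_stat(groups)
    hits = total = 0
    for perm in iter_permutations(range(n)):
        total += 1
        if r_stat([groups[i] for i in perm]) >= r_obs - 1e-12:
            hits += 1
    return r_obs, hits / total


class TestDistances:
    def test_bray_curtis_hand_formula(self):
        D = bray_curtis(np.array([[1, 2, 3], [3, 2, 1]]))
        assert D.d[0, 1] == pytest.approx((2 + 0 + 2) / 12)

    def test_bray_curtis_identical_and_disjoint(self):
        D = bray_curtis(np.array([[1, 2, 0, 0], [1, 2, 0, 0], [0, 0, 3, 4]]))
        assert D.d[0, 1] == pytest.approx(0.0)
        assert D.d[0, 2] == pytest.approx(1.0)

    def test_bray_curtis_all_zero_sample_raises(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(np.array([[1, 2], [0, 0]]))

    def test_rclr_equals_classical_clr_on_dense_data(self, rng):
        y = rng.integers(1, 200, size=(5, 7)).astype(float)
        D = robust_aitchison(y)
        logs = np.log(y)
        clr = logs - logs.mean(axis=1, keepdims=True)
        expected = squareform(pdist(clr))
        assert np.allclose(D.d, expected)

    def test_rclr_scale_invariance_per_sample(self, rng):
        y = rng.integers(1, 100, size=(4, 6)).astype(float)
        y2 = y.copy()
        y2[1] *= 37
        assert np.allclose(robust_aitchison(y).d, robust_aitchison(y2).d)

    def test_self_distance_zero_with_zeros_present(self):
        y = np.array([[5, 0, 3], [5, 0, 3]], dtype=float)
        assert robust_aitchison(y).d[0, 1] == pytest.approx(0.0)

    def test_no_shared_positive_feature_raises(self):
        y = np.array([[5, 0], [0, 7]], dtype=float)
        with pytest.raises(ValueError, match="share no positive"):
            robust_aitchison(y)


class TestPcoa:
    def test_recovers_planted_configuration(self, rng):
        pts = rng.normal(size=(9, 2))
        res = pcoa(euclidean(pts))
        assert res.coordinates.shape == (9, 2)
        centred = pts - pts.mean(axis=0)
        R, _ = orthogonal_procrustes(res.coordinates, centred)
        assert np.abs(res.coordinates @ R - centred).max() < 1e-8

    def test_identical_samples_identical_coordinates(self):
        y = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 7.0]])
        res = pcoa(euclidean(y))
        assert np.allclose(res.coordinates[0], res.coordinates[1])

    def test_inertia_equals_positive_eigenvalue_sum(self, rng):
        res = pcoa(bray_curtis(rng.integers(1, 50, size=(6, 10))))
        assert res.total_inertia == pytest.approx(res.eigenvalues.sum())

    def test_non_euclidean_distance_reports_negative_eigenvalues(self, rng):
        res = pcoa(bray_curtis(rng.integers(0, 20, size=(8, 5))))
        assert (res.negative_eigenvalues < 0).all()


class TestDbrda:
    def test_saturated_model_r2_one(self, rng):
        Y = rng.normal(size=(7, 4))
        Yc = Y - Y.mean(axis=0)
        _, _, vt = np.linalg.svd(Yc, full_matrices=False)
        X = Yc @ vt.T  # all principal components
        res = dbrda(euclidean(Y), X[:, :4], B=9, seed=0)
        assert res.r2 == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_classical_rda_oracle(self, seed):
        """With Euclidean distances, dbRDA is algebraically identical to
        RDA on the raw coordinates: eigenvalues and R2 agree to 1e-8."""
        rng = np.random.default_rng(seed)
        Y = rng.normal(size=(10, 8))
        X = rng.normal(size=(10, 2))
        res = dbrda(euclidean(Y), X, B=9, seed=0, compute_scores=True)
        eig_ref, r2_ref = classical_rda(Y, X)
        assert res.r2 == pytest.approx(r2_ref, abs=1e-8)
        assert np.allclose(
            np.sort(res.eigenvalues_constrained)[::-1], eig_ref, atol=1e-8
        )

    def test_null_predictor_p_uniform(self, rng):
        Y = rng.normal(size=(12, 5))
        D = euclidean(Y)
        pvals = [
            dbrda(D, rng.normal(size=(12, 1)), B=99, seed=s).p
            for s in range(200)
        ]
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_rank_deficient_predictors_raise(self, rng):
        Y = rng.normal(size=(8, 3))
        x = rng.normal(size=8)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="rank-deficient"):
            dbrda(euclidean(Y), X, B=9, seed=0)

    def test_partialling_reduces_constrained_inertia(self, rng):
        Y = rng.normal(size=(14, 4))
        shared = rng.normal(size=(14, 1))
        X = shared + 0.2 * rng.normal(size=(14, 1))
        full = dbrda(euclidean(Y + shared), X, B=9, seed=0)
        part = dbrda(euclidean(Y + shared), X, condition=shared, B=9, seed=0)
        assert part.constrained_inertia < full.constrained_inertia
        assert part.conditioned_inertia > 0


class TestForwardSelect:
    def test_planted_informative_enters_first(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            signal = rng.normal(size=12)
            Y = np.outer(signal, rng.normal(size=4)) + 0.3 * rng.normal(size=(12, 4))
            cand = pd.DataFrame(
                {"info": signal + 0.1 * rng.normal(size=12)}
                | {f"noise{i}": rng.normal(size=12) for i in range(4)}
            )
            fs = forward_select(
                euclidean(Y), cand, alpha=0.05, B=99, seed=seed,
                use_adjr2_guard=False,
            )
            if fs.selected and fs.selected[0] == "info":
                hits += 1
        assert hits >= 9

    def test_all_noise_rarely_selects(self):
        picks = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            Y = rng.normal(size=(12, 4))
            cand = pd.DataFrame({f"n{i}": rng.normal(size=12) for i in range(4)})
            fs = forward_select(
                euclidean(Y), cand, alpha=0.05, B=99, seed=seed,
                use_adjr2_guard=False,
            )
            picks += len(fs.selected)
        # ~ alpha * candidates * trials first-step expectation; generous cap
        assert picks <= 12

    def test_degenerate_alpha_admits_all_in_p_order(self, rng):
        Y = rng.normal(size=(14, 5))
        cand = pd.DataFrame({f"c{i}": rng.normal(size=14) for i in range(3)})
        fs = forward_select(
            euclidean(Y), cand, alpha=1.1, B=99, seed=0, use_adjr2_guard=False
        )
        assert sorted(fs.selected) == ["c0", "c1", "c2"]


class TestAnosim:
    def test_complete_separation_r_one(self):
        y = np.vstack([np.zeros((3, 2)), np.ones((3, 2)) * 9])
        y += np.arange(6)[:, None] * 0.01
        res = anosim(euclidean(y), ["a"] * 3 + ["b"] * 3, B=99, seed=0)
        assert res.R == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_small_n_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=(7, 3))
        groups = ["a", "a", "a", "b", "b", "b", "b"]
        res = anosim(euclidean(y), groups, B=99, seed=0, pairwise=False)
        r_ref, p_ref = brute_force_anosim(euclidean(y).d, groups)
        assert res.exact
        assert res.R == pytest.approx(r_ref)
        assert res.p == pytest.approx(p_ref)

    def test_random_labels_mean_r_near_zero(self, rng):
        y = rng.normal(size=(12, 4))
        D = euclidean(y)
        rs = []
        for _ in range(1000):
            labels = rng.permutation(["a"] * 6 + ["b"] * 6)
            rs.append(anosim(D, labels, B=9, seed=0, pairwise=False).R)
        assert abs(np.mean(rs)) < 0.05

    def test_invariant_under_monotone_distance_transform(self, rng):
        y = rng.normal(size=(10, 3))
        D = euclidean(y)
        D2 = DistanceMatrix(D.sample_ids, D.d**2, "euclidean")
        groups = ["a"] * 5 + ["b"] * 5
        r1 = anosim(D, groups, B=99, seed=1, pairwise=False)
        r2 = anosim(D2, groups, B=99, seed=1, pairwise=False)
        assert r1.R == pytest.approx(r2.R)
        assert r1.p == pytest.approx(r2.p)

    def test_pairwise_bonferroni(self, rng):
        y = np.vstack(
            [rng.normal(loc, 0.3, size=(3, 2)) for loc in (0.0, 5.0, 10.0)]
        )
        res = anosim(
            euclidean(y), ["a"] * 3 + ["b"] * 3 + ["c"] * 3, B=99, seed=0
        )
        assert isinstance(res, AnosimResult)
        assert len(res.pairwise) == 3
        assert (
            res.pairwise["p_bonferroni"]
            == (res.pairwise["p"] * 3).clip(upper=1.0)
        ).all()

    def test_singleton_group_raises(self, rng):
        y = rng.normal(size=(5, 2))
        with pytest.raises(ValueError, match="singleton"):
            anosim(euclidean(y), ["a", "a", "a", "a", "b"], B=9, seed=0)


class TestCrossLibraryReferences:
    """Statistics agree with scikit-bio's independent implementations."""

    def test_anosim_statistic_matches_scikit_bio(self, rng):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.stats.distance import anosim as skbio_anosim

        y = rng.normal(size=(10, 4))
        D = euclidean(y)
        groups = ["a"] * 5 + ["b"] * 5
        ours = anosim(D, groups, B=99, seed=0, pairwise=False)
        ref = skbio_anosim(
            SkbioDM(D.d, ids=D.sample_ids), grouping=list(groups), permutations=99
        )
        assert ours.R == pytest.approx(ref["test statistic"])

    def test_pcoa_eigenvalues_match_scikit_bio(self, rng):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.stats.ordination import pcoa as skbio_pcoa

        y = rng.integers(1, 40, size=(7, 9))
        D = bray_curtis(y)
        ours = pcoa(D)
        ref = skbio_pcoa(SkbioDM(D.d, ids=D.sample_ids), method="eigh")
        ref_pos = np.sort(ref.eigvals[ref.eigvals > 1e-10])[::-1]
        assert np.allclose(np.sort(ours.eigenvalues)[::-1], ref_pos, atol=1e-8)


class TestSimper:
    def test_two_sample_hand_computation(self):
        y = np.array([[1.0, 2.0], [3.0, 1.0]])
        res = simper(y, ["a", "b"])
        by_var = res.contributions.set_index("variable")["contribution"]
        assert by_var[0] == pytest.approx(2 / 7)
        assert by_var[1] == pytest.approx(1 / 7)

    def test_contributions_sum_to_mean_between_group_bray_curtis(self, rng):
        y = rng.integers(0, 50, size=(8, 6)).astype(float) + 1
        groups = ["a"] * 4 + ["b"] * 4
        res = simper(y, groups)
        D = bray_curtis(y)
        between = [D.d[i, j] for i in range(4) for j in range(4, 8)]
        assert res.overall_dissimilarity == pytest.approx(
            np.mean(between), abs=1e-9
        )
        assert res.contributions["contribution"].sum() == pytest.approx(
            res.overall_dissimilarity, abs=1e-9
        )

    def test_constant_variable_contributes_nothing_everywhere_equal(self):
        y = np.array([[5.0, 1.0], [5.0, 9.0], [5.0, 2.0], [5.0, 8.0]])
        res = simper(y, ["a", "a", "b", "b"])
        by_var = res.contributions.set_index("variable")["contribution"]
        assert by_var[1] > by_var[0] >= 0

    def test_three_groups_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            simper(np.ones((3, 2)), ["a", "b", "c"])
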