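"""PCA reduction, Ward tree, cluster-count selection and v-test contracts."""

import numpy as np
import pandas as pd
import pytest

from rfaclust import (PCAWardClusterer, choose_k_inertia, cluster_panel,
                      pca_reduce, vtest_characterize, ward_linkage)
from rfaclust.cluster import _relabel_by_size


# ----------------------------------------------------------------------
# PCA reduction
# ----------------------------------------------------------------------

class TestPCAReduce:
    def test_isotropic_sample_retains_three_of_four_components(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((1000, 4))
        X = (X - X.mean(0)) / X.std(0)
        scores, loadings, var = pca_reduce(X, variance_threshold=0.70)
        assert scores.shape[1] == 3          # each component carries ~25%
        assert np.allclose(var, 0.25, atol=0.04)

    def test_rank_one_matrix_gives_single_component(self):
        v = np.linspace(-1, 1, 20)[:, None]
        X = v @ np.array([[1.0, 2.0, -1.0]])
        scores, loadings, var = pca_reduce(X, variance_threshold=0.99)
        assert scores.shape[1] == 1
        np.testing.assert_allclose(var, [1.0], atol=1e-12)

    def test_sign_convention_makes_top_loading_positive(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((50, 5))
        _, loadings, _ = pca_reduce(X, 0.95)
        for j in range(loadings.shape[1]):
            assert loadings[np.argmax(np.abs(loadings[:, j])), j] > 0

    @pytest.mark.parametrize("bad", [0.0, 1.5, -0.1])
    def test_invalid_threshold_rejected(self, bad):
        with pytest.raises(ValueError):
            pca_reduce(np.random.default_rng(0).normal(size=(10, 3)), bad)

    def test_explicit_component_count_overrides_threshold(self):
        X = np.random.default_rng(2).standard_normal((40, 6))
        scores, _, _ = pca_reduce(X, n_components=2)
        assert scores.shape[1] == 2


# ----------------------------------------------------------------------
# Ward linkage
# ----------------------------------------------------------------------

class TestWardLinkage:
    def test_hand_computed_merge_heights(self):
        """{0, 1, 10} on a line: merging {0},{1} costs 0.5; merging
        {0,1} (centroid 0.5) with {10} costs (2*1/3)*9.5^2 = 60.1667."""
        Z = ward_linkage(np.array([0.0, 1.0, 10.0]))
        np.testing.assert_allclose(Z[:, 2], [0.5, 361.0 / 6.0], rtol=1e-12)

    def test_duplicated_points_merge_at_height_zero(self):
        Z = ward_linkage(np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]]))
        assert Z[0, 2] == 0.0

    def test_heights_non_decreasing(self):
        X = np.random.default_rng(3).standard_normal((30, 4))
        Z = ward_linkage(X)
        assert (np.diff(Z[:, 2]) >= -1e-12).all()

    def test_row_permutation_gives_identical_tree_heights_and_cuts(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((25, 3))
        perm = rng.permutation(25)
        Za, Zb = ward_linkage(X), ward_linkage(X[perm])
        np.testing.assert_allclose(np.sort(Za[:, 2]), np.sort(Zb[:, 2]), rtol=1e-9)
        from rfaclust import adjusted_rand_index
        _, _, a = choose_k_inertia(Za, 2, 5)
        _, _, b = choose_k_inertia(Zb, 2, 5)
        assert adjusted_rand_index(a[perm], b) == pytest.approx(1.0)

    def test_merge_heights_sum_to_total_inertia(self):
        """Ward identity: the merge costs add up to the total inertia of the
        point cloud around its centroid."""
        X = np.random.default_rng(5).standard_normal((40, 3))
        Z = ward_linkage(X)
        total = ((X - X.mean(0)) ** 2).sum()
        assert Z[:, 2].sum() == pytest.approx(total, rel=1e-9)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            ward_linkage(np.array([[1.0, 2.0]]))


# ----------------------------------------------------------------------
# cluster-count selection
# ----------------------------------------------------------------------

class TestChooseK:
    def test_three_separated_blobs_give_k_three(self):
        rng = np.random.default_rng(6)
        centers = np.array([[0, 0], [8, 0], [4, 7]])
        X = np.vstack([c + rng.standard_normal((30, 2)) for c in centers])
        k, ratios, assignments = choose_k_inertia(ward_linkage(X), 2, 6)
        assert k == 3
        sizes = np.bincount(assignments)[1:]
        assert sorted(sizes) == [30, 30, 30]

    def test_two_antipodal_duplicated_sets_give_k_min(self):
        X = np.array([[0.0], [0.0], [0.0], [9.0], [9.0], [9.0]])
        k, _, _ = choose_k_inertia(ward_linkage(X), 2, 4)
        assert k == 2

    def test_bounds_validated(self):
        Z = ward_linkage(np.random.default_rng(0).normal(size=(10, 2)))
        with pytest.raises(ValueError):
            choose_k_inertia(Z, 1, 5)
        with pytest.raises(ValueError):
            choose_k_inertia(Z, 2, 10)

    def test_cut_inertia_matches_brute_force_on_tiny_input(self):
        """On <= 8 points the within-inertia of the chosen cut equals the
        directly computed within-cluster sum of squares of the partition,
        i.e. total inertia minus the retained between-cluster gains."""
        rng = np.random.default_rng(7)
        X = rng.standard_normal((8, 2)) + np.repeat([[0, 0], [6, 6]], 4, axis=0)
        Z = ward_linkage(X)
        k, _, labels = choose_k_inertia(Z, 2, 4)
        # within-inertia implied by the tree: all merge gains below the cut
        within_tree = Z[: 8 - k, 2].sum()
        within_direct = sum(
            ((X[labels == g] - X[labels == g].mean(0)) ** 2).sum()
            for g in np.unique(labels)
        )
        assert within_tree == pytest.approx(within_direct, rel=1e-9)

    def test_labels_renumbered_by_decreasing_size(self):
        labels = _relabel_by_size(np.array([5, 5, 5, 2, 2, 9]))
        assert list(labels) == [1, 1, 1, 2, 2, 3]


# ----------------------------------------------------------------------
# v-test
# ----------------------------------------------------------------------

class TestVTest:
    def test_hand_example(self):
        """N=4, values (-1,-1,1,1), cluster A = first two:
        v_A = -1 / sqrt((1/2)*(2/3)) = -sqrt(3)."""
        X = pd.DataFrame({"m": [-1.0, -1.0, 1.0, 1.0]})
        prof = vtest_characterize(X, np.array([1, 1, 2, 2]), alpha=0.05)
        vA = prof.table.query("cluster == 1")["v"].iloc[0]
        assert vA == pytest.approx(-np.sqrt(3), rel=1e-12)

    def test_single_cluster_covering_everyone_rejected(self):
        X = pd.DataFrame({"m": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            vtest_characterize(X, np.array([1, 1, 1]))

    def test_size_weighted_cluster_deviations_sum_to_zero(self, small_processed,
                                                          small_solution):
        X = small_processed.values
        labels = small_solution.assignments
        for col in X.columns[:5]:
            total = sum(
                (labels == g).sum() * (X.loc[(labels == g).to_numpy(), col].mean()
                                       - X[col].mean())
                for g in labels.unique()
            )
            assert total == pytest.approx(0.0, abs=1e-8)

    def test_significance_matches_quantile_threshold(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.standard_normal((60, 3)), columns=list("abc"))
        prof = vtest_characterize(X, rng.integers(1, 3, 60), alpha=0.05)
        from scipy.stats import norm
        thr = norm.ppf(0.975)
        assert (prof.table["significant"] == (prof.table["v"].abs() > thr)).all()

    def test_planted_suppressed_markers_rank_negative(self, small_cohort,
                                                      small_processed,
                                                      small_solution):
        """The low-inflammation cluster shows negative v on the shifted
        markers (suppressed relative to the overall mean)."""
        prof = small_solution.vtest
        # cluster whose mean v over baseline markers is lowest
        base = small_cohort.dataset.baseline_panel
        sub = prof.table[prof.table["marker"].isin(base)]
        low = sub.groupby("cluster")["v"].mean().idxmin()
        lows = sub[sub["cluster"] == low]
        assert (lows["direction"] == "suppressed").mean() > 0.8


# ----------------------------------------------------------------------
# the estimator
# ----------------------------------------------------------------------

class TestPCAWardClusterer:
    def test_fingerprint_depends_only_on_parameters(self):
        a = PCAWardClusterer(k_min=2, k_max=6)
        b = PCAWardClusterer(k_max=6, k_min=2)
        c = PCAWardClusterer(k_max=5)
        assert a.fingerprint() == b.fingerprint() != c.fingerprint()

    def test_solution_packages_fitted_state(self, small_processed, small_cohort):
        sol = cluster_panel(small_processed.values,
                            small_cohort.dataset.baseline_panel)
        assert sol.cluster_sizes.sum() == len(small_processed.values)
        assert sol.k == len(sol.cluster_sizes)
        assert np.cumsum(sol.variance_explained)[-1] >= 0.70
        assert sol.vtest is not None

    def test_forced_k_bypasses_criterion(self, small_processed):
        est = PCAWardClusterer(k=4)
        labels = est.fit_predict(small_processed.values)
        assert est.k_ == 4 and len(np.unique(labels)) == 4
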