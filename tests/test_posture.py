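"""Eigenworms, posture libraries, mirror merging, meta-postures, abundance."""

import warnings

import numpy as np
import pandas as pd
import pytest

from wormobs.posture import (Eigenworms, PostureLibrary, abundance_over_time,
                             assign_meta_postures, build_posture_library,
                             compute_eigenworms, eligible_for_eigenworms,
                             find_mirror_pairs, merge_mirror_classes)
from wormobs.simulate import default_bend_modes


def two_mode_cloud(n, noise=0.05, seed=0, scales=(1.0, 0.6)):
    rng = np.random.default_rng(seed)
    modes = default_bend_modes()
    coeff = rng.normal(size=(n, 2)) * scales
    return coeff @ modes + rng.normal(0, noise, size=(n, 24))


class TestEligibility:
    @pytest.mark.parametrize("duration,speed,angvel,expected", [
        (6.0, 0.02, 10.0, True),     # passes all three filters
        (6.0, 0.005, 10.0, False),   # too slow
        (4.0, 0.02, 10.0, False),    # too short
        (6.0, 0.02, 60.0, False),    # turning too much
        (5.0, 0.02, 10.0, True),     # duration boundary inclusive
        (6.0, 0.01, 10.0, False),    # speed boundary strict (> 0.01)
        (6.0, 0.02, 50.0, False),    # angular velocity boundary strict (< 50)
    ])
    def test_moving_worm_filter(self, duration, speed, angvel, expected):
        assert eligible_for_eigenworms(duration, speed, angvel) is expected


class TestEigenworms:
    def test_two_constructed_modes_dominate(self):
        X = two_mode_cloud(2000, noise=0.01, seed=1)
        ew = compute_eigenworms(X)
        assert ew.explained_variance_ratio_[:2].sum() >= 0.99
        # top-2 eigenvectors span the constructed modes: principal angles ~ 0
        modes = default_bend_modes()
        overlap = np.linalg.svd(ew.components_[:2] @ modes.T, compute_uv=False)
        assert np.degrees(np.arccos(np.clip(overlap, -1, 1))).max() < 10

    def test_full_basis_reconstructs_exactly(self):
        X = two_mode_cloud(100, noise=0.2, seed=2)
        ew = Eigenworms().fit(X)
        X_rec = ew.inverse_transform(ew.transform(X))
        assert np.allclose(X_rec, X, atol=1e-10)

    def test_matches_pca_cross_check(self):
        from sklearn.decomposition import PCA
        X = two_mode_cloud(500, noise=0.1, seed=3)
        ew = Eigenworms(n_modes=4).fit(X)
        pca = PCA(n_components=4).fit(X)
        # same subspace and variances, up to per-component sign
        assert np.allclose(np.abs(np.sum(ew.components_ * pca.components_, axis=1)),
                           1.0, atol=1e-6)
        assert np.allclose(ew.explained_variance_ratio_,
                           pca.explained_variance_ratio_, atol=1e-6)

    def test_identical_vectors_warn_of_empty_basis(self):
        X = np.tile(np.linspace(-0.2, 0.2, 24), (30, 1))
        with pytest.warns(UserWarning, match="zero posture variance"):
            ew = Eigenworms().fit(X)
        assert np.allclose(ew.explained_variance_ratio_, 0.0)

    def test_rank_deficient_sample_warns(self):
        X = two_mode_cloud(10, seed=4)
        with pytest.warns(UserWarning, match="rank-deficient"):
            Eigenworms().fit(X)

    def test_orthonormal_and_sorted(self):
        X = two_mode_cloud(300, noise=0.2, seed=5)
        ew = Eigenworms().fit(X)
        assert np.allclose(ew.components_ @ ew.components_.T,
                           np.eye(len(ew.components_)), atol=1e-10)
        assert np.all(np.diff(ew.eigenvalues_) <= 1e-12)
        assert ew.explained_variance_ratio_.sum() == pytest.approx(1.0)


class TestMirrorPairs:
    def test_explicit_pair_and_singleton(self):
        v = np.full(24, 0.5)
        w = np.zeros(24)
        w[0] = 3.0
        w[1] = 1.0  # far from its own negation and from -v
        pairs = find_mirror_pairs(np.stack([v, -v, w]))
        assert pairs[0] == 1 and pairs[1] == 0
        assert pairs[2] == 2

    def test_near_zero_centroids_self_pair(self):
        rng = np.random.default_rng(0)
        C = rng.normal(0, 1e-4, size=(10, 24))
        pairs = find_mirror_pairs(C)
        classes = merge_mirror_classes(pairs)
        # every centroid is (near) its own mirror; pairing must not create
        # chains — merged class count stays >= half
        assert len(np.unique(classes)) >= 5

    def test_exact_symmetric_set_fully_paired(self):
        # construction oracle: 100 vectors and their exact negations
        rng = np.random.default_rng(6)
        V = rng.normal(size=(100, 24))
        C = np.vstack([V, -V])
        pairs = find_mirror_pairs(C)
        n_paired = sum(1 for i, j in pairs.items() if i != j)
        assert n_paired / len(C) >= 0.90
        # each exact pair maps i <-> i+100
        exact = sum(1 for i in range(100) if pairs[i] == i + 100)
        assert exact >= 90

    def test_involution_merging_negated_dataset_gives_same_classes(self):
        X = two_mode_cloud(800, noise=0.1, seed=7)
        X = np.vstack([X, -X])
        lib1 = PostureLibrary(k=40, random_state=0).fit(X)
        lib2 = PostureLibrary(k=40, random_state=0).fit(-X)
        assert lib1.n_classes_ == lib2.n_classes_


class TestPostureLibrary:
    def test_three_separated_clusters_recovered(self):
        rng = np.random.default_rng(8)
        means = np.array([np.full(24, 0.3),
                          np.full(24, 0.9),
                          np.r_[np.full(12, 0.9), np.full(12, 0.3)]])
        labels = rng.integers(0, 3, 600)
        X = means[labels] + rng.normal(0, 0.03, (600, 24))
        # mirror merging disabled: this checks the clustering stage alone
        lib = PostureLibrary(k=3, match_quantile=0.0, random_state=0).fit(X)
        assert lib.n_classes_ == 3
        # brute-force oracle: assign to nearest true mean
        d = np.linalg.norm(X[:, None] - means[None], axis=2)
        truth = d.argmin(axis=1)
        pred = lib.predict(X)
        # map predicted class -> majority truth label
        agree = sum((pd.Series(truth[pred == c]).mode()[0] == truth[pred == c]).sum()
                    for c in np.unique(pred))
        assert agree / len(X) >= 0.99
        for m in means:
            assert np.min(np.linalg.norm(lib.centroids_ - m, axis=1)) < 0.05

    def test_negation_symmetric_data_halves_library(self):
        X = two_mode_cloud(2500, noise=0.15, seed=9)
        X = np.vstack([X, -X])
        lib = build_posture_library(X, k=200, rng_seed=0)
        assert 40.0 <= lib.reduction_percent <= 60.0

    def test_symmetric_postures_behave_as_their_own_mirror(self):
        rng = np.random.default_rng(10)
        X = rng.normal(0, 0.01, size=(300, 24))  # all near the zero posture
        lib = PostureLibrary(k=5, random_state=0).fit(X)
        # pairing near-zero centroids with each other (or themselves) is
        # harmless: classification stays mirror-invariant and non-collapsed
        assert lib.n_classes_ >= 3
        probe = rng.normal(0, 0.01, size=(50, 24))
        assert np.array_equal(lib.predict(probe), lib.predict(-probe))

    def test_requires_at_least_k_vectors(self):
        with pytest.raises(ValueError, match="at least k"):
            PostureLibrary(k=200).fit(two_mode_cloud(100))

    def test_seeded_fit_is_reproducible(self):
        X = two_mode_cloud(600, seed=11)
        l1 = PostureLibrary(k=20, random_state=3).fit(X)
        l2 = PostureLibrary(k=20, random_state=3).fit(X)
        assert np.array_equal(l1.centroids_, l2.centroids_)
        assert l1.mirror_map_ == l2.mirror_map_

    def test_prediction_invariant_under_mirroring(self):
        X = two_mode_cloud(2000, noise=0.1, seed=12)
        X = np.vstack([X, -X])
        lib = PostureLibrary(k=50, random_state=1).fit(X)
        probe = two_mode_cloud(100, noise=0.1, seed=13)
        assert np.array_equal(lib.predict(probe), lib.predict(-probe))


class TestMetaPostures:
    def test_three_curvature_regimes_recovered(self):
        # mirror-merged class representatives are sign-canonical, so three
        # bend-amplitude regimes lie at three radii along the mode axis
        rng = np.random.default_rng(14)
        modes = default_bend_modes()
        amps = np.array([0.1, 0.8, 2.0])  # stiff / bent / strongly bent
        labels = rng.integers(0, 3, 300)
        mix = 0.9 * modes[0] + 0.1 * modes[1]
        X = amps[labels][:, None] * mix + rng.normal(0, 0.02, (300, 24))
        groups = assign_meta_postures(X, k=3, rng_seed=0)
        agree = 0
        for g in range(3):
            member_truth = labels[groups.group_of_class == g]
            if len(member_truth):
                agree += (member_truth == pd.Series(member_truth).mode()[0]).sum()
        assert agree / len(X) >= 0.90

    def test_three_postures_three_groups(self):
        X = np.eye(3, 24)
        groups = assign_meta_postures(X, k=3, rng_seed=0)
        assert sorted(len(m) for m in groups.member_vectors) == [1, 1, 1]

    def test_low_curvature_group_has_tighter_angles(self):
        rng = np.random.default_rng(15)
        modes = default_bend_modes()
        stiff = 0.1 * rng.normal(size=(100, 1)) * modes[0]
        bent = 1.5 * rng.normal(size=(100, 1)) * modes[0]
        X = np.vstack([stiff, bent])
        groups = assign_meta_postures(X, k=2, rng_seed=0)
        iqrs = [np.subtract(*np.percentile(np.concatenate(m), [75, 25]))
                for m in groups.member_vectors]
        assert min(iqrs) < max(iqrs) / 2

    def test_partition_is_complete(self):
        X = two_mode_cloud(50, seed=16)
        groups = assign_meta_postures(X, k=3, rng_seed=1)
        assert sum(len(m) for m in groups.member_vectors) == 50
        assert set(groups.group_of_class) == {0, 1, 2}


class TestAbundance:
    def test_uniform_assignments_give_half_half_and_zero_z(self):
        ids = np.array([0, 1, 0, 1])
        hat = np.array([0.1, 0.2, 1.1, 1.2])
        ab = abundance_over_time(ids, hat, bin_hours=1.0)
        assert np.allclose(ab.raw.to_numpy(), 0.5)
        assert np.allclose(ab.zscore.fillna(0).to_numpy(), 0.0)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(17)
        ids = rng.integers(0, 7, 500)
        hat = rng.uniform(0, 5, 500)
        ab = abundance_over_time(ids, hat, bin_hours=1.0)
        assert np.allclose(ab.raw.sum(axis=1), 1.0)

    def test_class_present_only_in_first_bin_has_positive_z_there(self):
        ids = np.array([0] * 10 + [1] * 30)
        hat = np.concatenate([np.full(10, 0.5), np.full(10, 1.5),
                              np.full(10, 2.5), np.full(10, 3.5)])
        ab = abundance_over_time(ids, hat, bin_hours=1.0)
        z0 = ab.zscore[0].to_numpy()
        assert z0[0] > 0 and np.all(z0[1:] < 0)

    def test_empty_bin_flagged_as_nan(self):
        ids = np.array([0, 0])
        hat = np.array([0.5, 2.5])  # nothing in [1, 2)
        ab = abundance_over_time(ids, hat, bin_hours=1.0, n_classes=1)
        assert np.isnan(ab.raw.iloc[1, 0])

    def test_scripted_regime_switch_flips_z_sign(self):
        # class 0 dominates bins 0-2, class 1 dominates bins 3-5
        rng = np.random.default_rng(18)
        hat = rng.uniform(0, 6, 1200)
        ids = np.where(hat < 3,
                       rng.choice([0, 1], 1200, p=[0.9, 0.1]),
                       rng.choice([0, 1], 1200, p=[0.1, 0.9]))
        ab = abundance_over_time(ids, hat, bin_hours=1.0)
        z = ab.zscore[0].to_numpy()
        assert np.all(z[:3] > 0) and np.all(z[3:] < 0)
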