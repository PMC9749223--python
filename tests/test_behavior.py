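"""Dispersal classification, densities, turn features/classifier, summaries."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from wormobs.behavior import (TurnClassifier, bin_turns, classify_dispersal,
                              extract_turn_features, is_quiescent,
                              per_track_mean_speeds, records_from_kinematics,
                              speed_angvel_density, summarize_condition,
                              train_turn_classifier, turn_feature_matrix,
                              N_TURN_FEATURES)
from wormobs.simulate import make_turn_shape_dataset, render_turn_shape
from wormobs.track import KinematicsBin


def kbin(speed, angvel, track_id=0, bin_index=0, hat=1.0):
    return KinematicsBin(track_id=track_id, bin_index=bin_index, speed=speed,
                         angular_velocity=angvel, hat=hat, n_frames=20)


class TestDispersal:
    @pytest.mark.parametrize("speed,angvel,expected", [
        (0.02, 5.0, "dispersal"),        # fast and straight
        (0.005, 5.0, "non_dispersal"),   # too slow
        (0.02, 20.0, "non_dispersal"),   # too curvy
        (0.005, 20.0, "non_dispersal"),  # both fail
        (0.01, 5.0, "dispersal"),        # speed boundary: minimum included
        (0.02, 15.0, "non_dispersal"),   # angular boundary: 'below 15' strict
        (0.01, 15.0, "non_dispersal"),
        (0.0, 0.0, "non_dispersal"),
    ])
    def test_threshold_truth_table(self, speed, angvel, expected):
        assert classify_dispersal(speed, angvel) == expected

    def test_quiescence_is_speed_below_dispersal_floor(self):
        assert is_quiescent(0.005) and not is_quiescent(0.01)


class TestDensity:
    def test_single_bin_puts_all_mass_in_one_cell(self):
        h, _, _ = speed_angvel_density([kbin(0.02, 5.0)])
        assert h.sum() == pytest.approx(1.0)
        assert (h > 0).sum() == 1

    def test_mass_normalized(self):
        rng = np.random.default_rng(0)
        bins = [kbin(s, a) for s, a in rng.uniform(0, 1, (200, 2))]
        h, _, _ = speed_angvel_density(bins)
        assert h.sum() == pytest.approx(1.0, abs=1e-12)

    def test_state_mixture_is_bimodal(self):
        # quiescent-like: slow + curvy; dispersal-like: fast + straight
        rng = np.random.default_rng(1)
        bins = (
            [kbin(rng.normal(0.003, 0.001), rng.normal(60, 10)) for _ in range(300)]
            + [kbin(rng.normal(0.03, 0.003), rng.normal(5, 2)) for _ in range(300)]
        )
        se = np.linspace(0, 0.05, 11)
        ae = np.linspace(0, 100, 11)
        h, _, _ = speed_angvel_density(bins, se, ae)
        # two separated occupied regions: slow/high-angvel and fast/low-angvel
        assert h[:2, 4:].sum() > 0.4
        assert h[4:, :2].sum() > 0.4


class TestTurnFeatures:
    def test_feature_vector_has_fixed_length_and_is_finite(self):
        mask = render_turn_shape(np.zeros(24))
        f = extract_turn_features(mask)
        assert f.shape == (N_TURN_FEATURES,)
        assert np.all(np.isfinite(f))

    def test_straight_bar_is_solid_and_eccentric(self):
        f = extract_turn_features(render_turn_shape(np.zeros(24)))
        solidity, eccentricity = f[6], f[5]
        assert solidity > 0.9
        assert eccentricity > 0.95

    def test_omega_blob_less_solid_than_bar(self):
        bar = extract_turn_features(render_turn_shape(np.zeros(24)))
        omega = extract_turn_features(
            render_turn_shape(np.full(24, np.deg2rad(340) / 24)))
        assert omega[6] < bar[6] - 0.2          # solidity drops
        assert omega[11] > bar[11]              # deeper convexity defect

    def test_identical_masks_give_identical_features(self):
        mask = render_turn_shape(np.full(24, 0.05))
        assert np.array_equal(extract_turn_features(mask),
                              extract_turn_features(mask.copy()))

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            extract_turn_features(np.zeros((5, 5), bool))


@pytest.fixture(scope="module")
def shape_set():
    masks, labels = make_turn_shape_dataset(150, 150, seed=21)
    return masks, labels


class TestTurnClassifier:
    def test_held_out_accuracy(self, shape_set):
        masks, labels = shape_set
        _, acc = train_turn_classifier(masks, labels, n_trees=200, seed=0)
        assert acc >= 0.90

    def test_same_seed_identical_predictions(self, shape_set):
        masks, labels = shape_set
        idx = np.r_[0:50, 150:200]  # stratified subset: 50 turns, 50 non-turns
        X = turn_feature_matrix([masks[i] for i in idx])
        y = labels[idx]
        c1 = TurnClassifier(n_trees=100, random_state=5).fit(X, y)
        c2 = TurnClassifier(n_trees=100, random_state=5).fit(X, y)
        assert np.array_equal(c1.predict(X), c2.predict(X))
        assert np.array_equal(c1.predict_score(X), c2.predict_score(X))

    def test_single_class_training_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 17))
        with pytest.raises(ValueError, match="both turn and non-turn"):
            TurnClassifier().fit(X, np.ones(10))

    def test_no_signal_features_give_chance_accuracy(self):
        # identical feature vectors with balanced labels: the forest cannot
        # do better than the majority class
        X = np.tile(np.arange(17.0), (40, 1))
        y = np.array([0, 1] * 20)
        clf = TurnClassifier(n_trees=50, random_state=0).fit(X, y)
        acc = (clf.predict(X) == y).mean()
        assert acc == pytest.approx(0.5, abs=0.05)

    def test_precision_recall_across_seeds(self):
        masks, labels = make_turn_shape_dataset(120, 120, seed=30)
        X = turn_feature_matrix(masks)
        from sklearn.model_selection import train_test_split
        for seed in range(3):
            Xtr, Xte, ytr, yte = train_test_split(
                X, labels, test_size=0.25, stratify=labels, random_state=seed)
            clf = TurnClassifier(n_trees=200, random_state=seed).fit(Xtr, ytr)
            pred = clf.predict(Xte)
            tp = ((pred == 1) & (yte == 1)).sum()
            assert tp / max((pred == 1).sum(), 1) >= 0.85   # precision
            assert tp / (yte == 1).sum() >= 0.85            # recall


class TestTurnBinning:
    def test_multiple_flags_in_window_count_once(self):
        flags = np.zeros(20, int)
        flags[[2, 3, 5, 8, 9, 11, 15]] = 1  # 7 flags, one 10-s window @ 2 fps
        assert bin_turns(flags, frame_rate=2.0).tolist() == [1]

    def test_no_flags_gives_zero(self):
        assert bin_turns(np.zeros(40, int), frame_rate=2.0).tolist() == [0, 0]

    def test_flags_in_first_and_third_window(self):
        flags = np.zeros(60, int)
        flags[5] = 1
        flags[45] = 1
        assert bin_turns(flags, frame_rate=2.0).tolist() == [1, 0, 1]


class TestSummaries:
    def test_all_dispersal_gives_fraction_one(self):
        bins = [kbin(0.02, 5.0, track_id=t, hat=h)
                for t in range(3) for h in (0.6, 1.5, 2.5)]
        records = records_from_kinematics(bins)
        out = summarize_condition(records, np.array([0.0, 1.0, 2.0, 3.0]))
        assert np.allclose(out["dispersal_fraction"].dropna(), 1.0)

    def test_per_track_mean_speeds(self):
        bins = [kbin(0.01, 5, track_id=0), kbin(0.03, 5, track_id=1)]
        means = per_track_mean_speeds(records_from_kinematics(bins))
        assert sorted(means.to_list()) == [0.01, 0.03]

    def test_empty_time_bin_reported_missing(self):
        records = records_from_kinematics([kbin(0.02, 5.0, hat=0.5)])
        out = summarize_condition(records, np.array([0.0, 1.0, 2.0]))
        assert out.loc[1, "n_records"] == 0
        assert np.isnan(out.loc[1, "dispersal_fraction"])

    def test_recovered_dispersal_fraction_matches_mixture(self):
        # known mixture of dispersal / non-dispersal bins
        rng = np.random.default_rng(2)
        q = 0.3
        n = 1000
        is_disp = rng.random(n) < q
        bins = [kbin(0.03 if d else 0.003, 5.0 if d else 60.0, track_id=i)
                for i, d in enumerate(is_disp)]
        records = records_from_kinematics(bins)
        frac = np.mean([r.state == "dispersal" for r in records])
        se = np.sqrt(q * (1 - q) / n)
        assert abs(frac - is_disp.mean()) < 1e-12
        assert abs(frac - q) < 2 * se + 0.05

    def test_mann_whitney_type_one_error_calibrated(self):
        # equal speed distributions in two conditions: p-values ~ Uniform(0,1)
        rng = np.random.default_rng(3)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            a = rng.lognormal(-4, 0.5, 30)
            b = rng.lognormal(-4, 0.5, 30)
            if mannwhitneyu(a, b).pvalue < 0.05:
                rejections += 1
        assert abs(rejections / n_rep - 0.05) <= 0.03
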