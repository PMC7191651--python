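"""Encoding models and comparison machinery: slopes, counts, maps, gradients."""

import numpy as np
import pytest

import emodecode as em
from emodecode.regression import SignificanceThreshold


def _thr(r):
    return SignificanceThreshold(r, 0.01, 1, 1000, 100)


class TestSplitDimensions:
    def test_arithmetic(self):
        s = em.EmotionScoreMatrix(
            video_ids=["a", "b", "c"],
            category_scores=np.zeros((3, 1)),
            dimension_scores=np.array([[5.0], [9.0], [2.0]]),
            category_names=["c0"],
            dimension_names=["valence"],
        )
        fs = em.split_dimensions(s)
        np.testing.assert_allclose(fs.matrix, [[0, 0], [4, 0], [0, 3]])
        assert fs.feature_names == ["valence_pos", "valence_neg"]

    def test_default_config_yields_28_columns(self):
        s = em.generate_scores(30, 34, 14, 0.7, seed=0)
        assert em.split_dimensions(s).matrix.shape == (30, 28)

    def test_out_of_range_scores_raise(self):
        s = em.generate_scores(10, 2, 2, 0.5, seed=0)
        s.dimension_scores[0, 0] = 12.0  # corrupt after construction
        with pytest.raises(ValueError):
            em.split_dimensions(s)


class TestEncodeVoxelwise:
    def test_noiseless_generating_features_reach_ceiling(self, scores120, scheme120):
        parc = em.make_parcellation(region_names=["sig"], voxels_per_region=6)
        truth = em.GroundTruth(np.ones((1, 9)), noise_sd=0.0)
        ds = em.generate_dataset(scores120, parc, truth, subject_seed=4)
        acc = em.encode_voxelwise(
            em.feature_set_from_scores(scores120, "joint"), ds, scheme120, [1e-3, 1e-1]
        )
        assert np.nanmin(acc) > 0.95

    def test_shuffled_features_hit_alpha_level(self, category_primacy):
        """Features decoupled from responses: significant count near chance."""
        sc = category_primacy["scores"]
        ds = category_primacy["dataset"]
        rng = np.random.default_rng(55)
        shuffled = em.FeatureSet(
            "shuffled",
            rng.permutation(sc.category_scores, axis=0),
            list(sc.category_names),
            list(sc.video_ids),
        )
        acc = em.encode_voxelwise(shuffled, ds, category_primacy["scheme"], [1.0, 10.0])
        thr = em.permutation_threshold(ds.responses[:, 0], 2000, alpha=0.05, n_tests=1, seed=0)
        frac = em.count_significant(acc, thr) / ds.n_voxels
        assert frac < 0.15  # two-tailed alpha=0.05 -> ~2.5% in the upper tail

    def test_constant_voxel_flagged_not_fatal(self, scores120, scheme120, caplog):
        rng = np.random.default_rng(5)
        parc = em.make_parcellation(region_names=["a"], voxels_per_region=3)
        resp = rng.standard_normal((120, 3))
        resp[:, 1] = 4.2
        ds = em.ResponseDataset("x", resp, parc, list(scores120.video_ids))
        with caplog.at_level("WARNING"):
            acc = em.encode_voxelwise(
                em.feature_set_from_scores(scores120, "category"), ds, scheme120, [1.0]
            )
        assert np.isnan(acc[1]) and not np.isnan(acc[[0, 2]]).any()
        assert "undefined accuracy" in caplog.text

    def test_joint_model_adds_little_over_category(self, category_primacy):
        """On category-driven data the joint model's significant-voxel gain
        over the category model is small relative to its gain over the
        dimension model."""
        ds = category_primacy["dataset"]
        acc_joint = em.encode_voxelwise(
            em.feature_set_from_scores(category_primacy["scores"], "joint"),
            ds, category_primacy["scheme"], category_primacy["grid"],
        )
        thr = category_primacy["threshold"]
        c_cat = em.count_significant(category_primacy["acc_cat"], thr)
        c_dim = em.count_significant(category_primacy["acc_dim"], thr)
        c_joint = em.count_significant(acc_joint, thr)
        assert c_joint - c_dim > 0
        assert (c_joint - c_cat) < 0.3 * (c_joint - c_dim)


class TestSlopeCompare:
    def test_parity_line(self):
        rng = np.random.default_rng(6)
        a = rng.random(50)
        res = em.slope_compare(a, a.copy())
        assert res.theta_deg == pytest.approx(45.0, abs=1e-10)
        assert res.deviation_deg == pytest.approx(0.0, abs=1e-10)

    def test_noiseless_line_matches_arctangent(self):
        b = np.linspace(0.05, 0.5, 40)
        res = em.slope_compare(2.0 * b, b)
        assert res.theta_deg == pytest.approx(np.degrees(np.arctan(2.0)), abs=1e-8)

    def test_swap_negates_deviation(self):
        rng = np.random.default_rng(7)
        b = rng.random(60)
        a = 1.5 * b + 0.05 * rng.standard_normal(60)
        reps = [
            (a + 0.01 * rng.standard_normal(60), b + 0.01 * rng.standard_normal(60))
            for _ in range(6)
        ]
        fwd = em.slope_compare(a, b, jackknife_replicates=reps)
        rev = em.slope_compare(b, a, jackknife_replicates=[(rb, ra) for ra, rb in reps])
        assert fwd.deviation_deg == pytest.approx(-rev.deviation_deg, abs=1e-8)

    def test_all_zero_accuracies_raise(self):
        with pytest.raises(ValueError, match="undefined slope"):
            em.slope_compare(np.zeros(10), np.zeros(10))

    def test_jackknife_se_shrinks_with_more_groups(self):
        """With fixed fold size, more folds (more videos) tighten the SE."""
        from emodecode.regression import pearson_columns

        def se_for(g, seed):
            rng = np.random.default_rng(seed)
            n = 40 * g
            truth = rng.standard_normal((n, 30))
            pred_a = truth + 1.5 * rng.standard_normal(truth.shape)
            pred_b = truth + 1.5 * rng.standard_normal(truth.shape)
            scheme = em.CVScheme(n, g, 2)
            acc_a = pearson_columns(pred_a, truth)
            acc_b = pearson_columns(pred_b, truth)
            reps = list(
                zip(
                    em.fold_deleted_accuracies(pred_a, truth, scheme),
                    em.fold_deleted_accuracies(pred_b, truth, scheme),
                )
            )
            return em.slope_compare(acc_a, acc_b, jackknife_replicates=reps).se_deg

        se4 = np.mean([se_for(4, s) for s in range(3)])
        se16 = np.mean([se_for(16, s) for s in range(3)])
        assert se16 < se4


class TestCountSignificant:
    def test_reference_cases(self):
        thr = _thr(0.111)
        assert em.count_significant(np.zeros(20), thr) == 0
        assert em.count_significant(np.ones(20), thr) == 20
        acc = np.array([0.05, 0.111, 0.112, 0.3, np.nan, -0.5])
        assert em.count_significant(acc, thr) == int(np.nansum(acc > 0.111))


class TestBestModelMap:
    def test_dominant_model_everywhere(self):
        rng = np.random.default_rng(8)
        base = rng.random(30) * 0.5 + 0.2
        labels = em.best_model_map({"A": base + 0.2, "B": base}, thresholds=0.0)
        assert all(l == "A" for l in labels)

    def test_no_significant_voxels(self):
        labels = em.best_model_map(
            {"A": np.full(5, 0.01), "B": np.full(5, 0.02)}, thresholds=0.5
        )
        assert all(l is None for l in labels)

    def test_monotone_rescaling_invariance(self):
        rng = np.random.default_rng(9)
        accs = {"A": rng.random(40), "B": rng.random(40), "C": rng.random(40)}
        before = em.best_model_map(accs, thresholds=0.2)
        rescaled = {k: np.tanh(3.0 * v) for k, v in accs.items()}
        after = em.best_model_map(rescaled, thresholds=np.tanh(3.0 * 0.2))
        assert list(before) == list(after)

    def test_recovers_generator_identity(self):
        """Voxels driven by different feature sets are labelled by their
        generating model in at least 95% of cases at high SNR."""
        rng = np.random.default_rng(10)
        n_videos, n_per = 150, 40
        feats = {k: rng.standard_normal((n_videos, 8)) for k in ("emo", "vis", "sem")}
        resp = np.empty((n_videos, 3 * n_per))
        owner = np.repeat(list(feats), n_per)
        for i, k in enumerate(feats):
            W = rng.standard_normal((8, n_per))
            resp[:, i * n_per : (i + 1) * n_per] = feats[k] @ W + 0.5 * rng.standard_normal(
                (n_videos, n_per)
            )
        scheme = em.CVScheme(n_videos, 6, 3)
        ids = [f"v{i}" for i in range(n_videos)]
        parc = em.make_parcellation(region_names=["all"], voxels_per_region=3 * n_per)
        ds = em.ResponseDataset("x", resp, parc, ids)
        accs = {
            k: em.encode_voxelwise(
                em.FeatureSet(k, feats[k], [f"f{j}" for j in range(8)], ids),
                ds, scheme, [1.0, 10.0],
            )
            for k in feats
        }
        labels = em.best_model_map(accs, thresholds=0.2)
        ok = np.mean([l == o for l, o in zip(labels, owner) if l is not None])
        assert ok >= 0.95

    def test_misaligned_vectors_raise(self):
        with pytest.raises(ValueError):
            em.best_model_map({"A": np.zeros(4), "B": np.zeros(5)})


class TestGradientBinnedCompare:
    def test_equal_count_bins(self):
        rng = np.random.default_rng(11)
        grad = rng.standard_normal(100)
        prof = em.gradient_binned_compare(
            {"A": rng.random(100), "B": rng.random(100)}, grad, n_bins=10
        )
        np.testing.assert_array_equal(prof.bin_sizes, np.full(10, 10))

    def test_monotone_construction(self):
        grad = np.linspace(0, 1, 120)
        acc = 0.1 + 0.5 * grad  # accuracy rises linearly with the gradient
        prof = em.gradient_binned_compare({"A": acc, "B": acc * 0.5}, grad, n_bins=10)
        assert (np.diff(prof.mean_accuracy["A"]) > 0).all()

    def test_identical_models_never_significant(self):
        rng = np.random.default_rng(12)
        acc = rng.random(80)
        prof = em.gradient_binned_compare(
            {"A": acc, "B": acc.copy()}, rng.standard_normal(80), n_bins=8
        )
        assert not prof.significant.any()

    def test_separated_models_flagged_with_anova_interaction(self):
        rng = np.random.default_rng(13)
        grad = np.linspace(0, 1, 200)
        a = 0.5 + 0.3 * grad + 0.02 * rng.standard_normal(200)
        b = 0.5 - 0.3 * grad + 0.02 * rng.standard_normal(200)
        prof = em.gradient_binned_compare({"A": a, "B": b}, grad, n_bins=10)
        assert prof.significant[-1] and prof.significant[0]
        assert prof.anova_interaction_p < 0.01

    def test_too_many_bins_raise(self):
        with pytest.raises(ValueError):
            em.gradient_binned_compare({"A": np.zeros(5), "B": np.zeros(5)}, np.zeros(5), n_bins=6)
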