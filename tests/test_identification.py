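"""Identification statistics against brute-force oracles and chance levels."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

import emodecode as em


def _table(values, prefix="e"):
    values = np.asarray(values, dtype=float)
    return em.AccuracyTable(
        values=values,
        row_names=[f"r{i}" for i in range(values.shape[0])],
        col_names=[f"{prefix}{j}" for j in range(values.shape[1])],
    )


def _brute_force_emotion_identify(A, B, set_size):
    """Exhaustive n-way identification oracle with np.corrcoef."""
    n_emotions = A.shape[1]
    per_emotion = []
    for e in range(n_emotions):
        others = [f for f in range(n_emotions) if f != e]
        hits = total = 0
        for combo in combinations(others, set_size - 1):
            total += 1
            congr = np.corrcoef(A[:, e], B[:, e])[0, 1]
            rivals = [np.corrcoef(A[:, e], B[:, f])[0, 1] for f in combo]
            hits += congr > max(rivals)
        per_emotion.append(100 * hits / total)
    return np.mean(per_emotion), np.array(per_emotion)


class TestEmotionIdentify:
    @pytest.mark.parametrize("set_size", [2, 3, 4])
    def test_matches_exhaustive_oracle(self, set_size):
        rng = np.random.default_rng(10)
        A, B = rng.standard_normal((5, 4)), rng.standard_normal((5, 4))
        res = em.emotion_identify(_table(A), _table(B), set_size, n_resamples=None)
        mean_oracle, per_oracle = _brute_force_emotion_identify(A, B, set_size)
        assert res.accuracy == pytest.approx(mean_oracle, abs=1e-9)
        np.testing.assert_allclose(res.per_emotion, per_oracle, atol=1e-9)

    def test_resampling_approximates_enumeration(self):
        rng = np.random.default_rng(11)
        A, B = rng.standard_normal((8, 6)), rng.standard_normal((8, 6))
        exact = em.emotion_identify(_table(A), _table(B), 3, n_resamples=None)
        sampled = em.emotion_identify(_table(A), _table(B), 3, n_resamples=20_000, seed=1)
        assert sampled.accuracy == pytest.approx(exact.accuracy, abs=2.0)

    def test_self_identification_is_perfect(self):
        rng = np.random.default_rng(12)
        A = rng.standard_normal((6, 5))
        for s in (2, 3, 5):
            res = em.emotion_identify(_table(A), _table(A), s, n_resamples=None)
            assert res.accuracy == 100.0

    @pytest.mark.parametrize("set_size", [2, 5, 10])
    def test_chance_calibration(self, set_size):
        """Independent tables: accuracy converges to 100 / set_size, with the
        CI taken over independent table pairs (the tables dominate variance)."""
        rng = np.random.default_rng(13)
        means = []
        for _ in range(40):
            A = rng.standard_normal((12, 20))
            B = rng.standard_normal((12, 20))
            res = em.emotion_identify(
                _table(A), _table(B), set_size, n_resamples=40,
                seed=int(rng.integers(2**31)),
            )
            means.append(res.accuracy)
        means = np.asarray(means)
        ci = stats.t.ppf(0.995, len(means) - 1) * means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - 100 / set_size) < ci

    def test_monotone_in_set_size(self):
        rng = np.random.default_rng(14)
        A = rng.standard_normal((10, 8))
        B = 0.7 * A + 0.3 * rng.standard_normal(A.shape)  # informative pair
        accs = [
            em.emotion_identify(_table(A), _table(B), s, n_resamples=None).accuracy
            for s in (2, 3, 5, 8)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(accs, accs[1:]))

    def test_invalid_set_size(self):
        A = np.random.default_rng(0).standard_normal((4, 3))
        with pytest.raises(ValueError):
            em.emotion_identify(_table(A), _table(A), 1)
        with pytest.raises(ValueError):
            em.emotion_identify(_table(A), _table(A), 4)


class TestCongruencyStats:
    def test_self_congruence_is_one(self):
        A = np.random.default_rng(1).standard_normal((7, 4))
        congr, _ = em.congruency_stats(_table(A), _table(A))
        assert congr == pytest.approx(1.0)

    def test_independent_tables_near_zero(self):
        rng = np.random.default_rng(2)
        congr, incongr = em.congruency_stats(
            _table(rng.standard_normal((200, 6))), _table(rng.standard_normal((200, 6)))
        )
        assert abs(congr) < 0.2 and abs(incongr) < 0.2

    def test_three_emotion_definition_oracle(self):
        rng = np.random.default_rng(3)
        A, B = rng.standard_normal((5, 3)), rng.standard_normal((5, 3))
        congr, incongr = em.congruency_stats(_table(A), _table(B))
        diag = [np.corrcoef(A[:, e], B[:, e])[0, 1] for e in range(3)]
        off = [
            np.corrcoef(A[:, e], B[:, f])[0, 1]
            for e in range(3) for f in range(3) if e != f
        ]
        assert congr == pytest.approx(np.mean(diag), abs=1e-10)
        assert incongr == pytest.approx(np.mean(off), abs=1e-10)

    def test_zero_variance_pattern_raises(self):
        A = np.random.default_rng(4).standard_normal((5, 3))
        bad = A.copy()
        bad[:, 1] = 2.0
        with pytest.raises(ValueError, match="zero-variance"):
            em.congruency_stats(_table(bad), _table(A))


class TestVideoIdentify:
    def test_perfect_decoder_scores_100(self):
        truth = np.random.default_rng(5).standard_normal((10, 6))
        np.testing.assert_allclose(em.video_identify(truth, truth), 100.0)

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(6)
        pred, truth = rng.standard_normal((6, 4)), rng.standard_normal((6, 4))
        acc = em.video_identify(pred, truth)
        for v in range(6):
            own = stats.pearsonr(pred[v], truth[v]).statistic
            score = 0.0
            for f in range(6):
                if f == v:
                    continue
                other = stats.pearsonr(pred[v], truth[f]).statistic
                score += 1.0 if own > other else (0.5 if own == other else 0.0)
            assert acc[v] == pytest.approx(100 * score / 5, abs=1e-9)

    def test_exact_ties_earn_half_credit(self):
        truth = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [3.0, 1.0, 2.0]])
        acc = em.video_identify(truth.copy(), truth)
        # videos 0 and 1 tie with each other's truth row: (0.5 + 1) / 2
        assert acc[0] == pytest.approx(75.0)
        assert acc[1] == pytest.approx(75.0)
        assert acc[2] == pytest.approx(100.0)

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError, match="constant"):
            em.video_identify(np.ones((4, 3)), np.random.default_rng(0).standard_normal((4, 3)))


class TestVideoIdentifyEncoding:
    def test_perfect_prediction_and_noise_mask(self):
        rng = np.random.default_rng(7)
        measured = rng.standard_normal((40, 30))
        acc = em.video_identify_encoding(measured, measured, np.ones(30, bool))
        np.testing.assert_allclose(acc, 100.0)
        noise_pred = rng.standard_normal((40, 30))
        acc_null = em.video_identify_encoding(noise_pred, measured, np.ones(30, bool))
        assert abs(acc_null.mean() - 50.0) < 10.0

    def test_empty_mask_raises(self):
        X = np.random.default_rng(8).standard_normal((5, 4))
        with pytest.raises(ValueError, match="no voxels"):
            em.video_identify_encoding(X, X, np.zeros(4, bool))

    def test_category_model_identifies_better_than_dimension_model(self):
        """On category-generated responses, identification via predicted
        activity favors the category encoder in nearly every replicate."""
        wins = 0
        n_rep = 20
        for rep in range(n_rep):
            rng = np.random.default_rng(300 + rep)
            s = em.generate_category_driven_scores(150, 8, 3, 0.6, seed=int(rng.integers(2**31)))
            parc = em.make_parcellation(region_names=["a", "b"], voxels_per_region=20)
            gains = np.zeros((2, 11))
            gains[:, :8] = 1.0
            truth = em.GroundTruth(gains, noise_sd=1.0)
            ds = em.generate_dataset(s, parc, truth, subject_seed=int(rng.integers(2**31)))
            scheme = em.CVScheme(150, 6, 3)
            _, p_cat = em.encode_voxelwise(
                em.feature_set_from_scores(s, "category"), ds, scheme, [1.0, 10.0],
                return_predictions=True,
            )
            _, p_dim = em.encode_voxelwise(
                em.feature_set_from_scores(s, "dimension"), ds, scheme, [1.0, 10.0],
                return_predictions=True,
            )
            mask = np.ones(ds.n_voxels, bool)
            wins += (
                em.video_identify_encoding(p_cat, ds.responses, mask).mean()
                >= em.video_identify_encoding(p_dim, ds.responses, mask).mean()
            )
        assert wins >= 0.9 * n_rep
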