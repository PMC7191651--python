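"""Shared synthetic fixtures: small planted-structure worlds built once per session."""

import numpy as np
import pytest

import emodecode as em


@pytest.fixture(scope="session")
def scores120():
    return em.generate_scores(120, 6, 3, sparsity=0.6, seed=11)


@pytest.fixture(scope="session")
def scheme120():
    return em.CVScheme(120, n_outer=6, n_inner=4)


@pytest.fixture(scope="session")
def planted_world(scores120):
    """5 regions x 8 voxels; region 1 informative for all emotions, region 3
    for emotion 2 only; the rest pure noise."""
    parc = em.make_parcellation(
        region_names=[f"r{i}" for i in range(5)], voxels_per_region=8
    )
    gains = np.zeros((5, 9))
    gains[1, :] = 1.0
    gains[3, 2] = 1.0
    truth = em.GroundTruth(gains, noise_sd=0.5)
    dataset = em.generate_dataset(scores120, parc, truth, subject_seed=2, subject_id="A")
    return {"parcellation": parc, "truth": truth, "dataset": dataset}


@pytest.fixture(scope="session")
def planted_pair():
    """Two subjects sharing a 20 x 14 informativeness map at high SNR,
    plus their region-wise accuracy tables and the decoding threshold."""
    scores = em.generate_scores(300, 10, 4, sparsity=0.7, seed=21)
    n_reg = 20
    parc = em.make_parcellation(
        region_names=[f"r{i:02d}" for i in range(n_reg)], voxels_per_region=10
    )
    rng = np.random.default_rng(5)
    gains = (rng.random((n_reg, 14)) < 0.3) * 1.0
    truth = em.GroundTruth(gains, noise_sd=1.0)
    ds_a = em.generate_dataset(scores, parc, truth, subject_seed=101, subject_id="A")
    ds_b = em.generate_dataset(scores, parc, truth, subject_seed=202, subject_id="B")
    scheme = em.CVScheme(300, 6, 4)
    grid = [0.1, 1.0, 10.0, 100.0]
    table_a = em.region_decode(ds_a, scores, scheme, grid)
    table_b = em.region_decode(ds_b, scores, scheme, grid)
    threshold = em.permutation_threshold(
        scores.matrix()[:, 0], 20_000, alpha=0.01, n_tests=n_reg, seed=0
    )
    return {
        "scores": scores,
        "gains": gains,
        "table_a": table_a,
        "table_b": table_b,
        "threshold": threshold,
    }


@pytest.fixture(scope="session")
def category_primacy():
    """Responses driven by category scores; dimensions are noisy linear
    readouts of the categories. The regime where category models must win."""
    scores = em.generate_category_driven_scores(
        400, 10, 4, sparsity=0.7, coupling=1.0, dim_noise=0.5, seed=42
    )
    parc = em.make_parcellation(
        region_names=[f"r{i}" for i in range(12)], voxels_per_region=15
    )
    rng = np.random.default_rng(7)
    gains = np.zeros((12, 14))
    gains[:, :10] = (rng.random((12, 10)) < 0.4) * 1.0  # category columns only
    truth = em.GroundTruth(gains, noise_sd=1.0)
    dataset = em.generate_dataset(scores, parc, truth, subject_seed=3)
    scheme = em.CVScheme(400, 6, 4)
    grid = [0.1, 1.0, 10.0, 100.0]
    acc_cat, pred_cat = em.encode_voxelwise(
        em.feature_set_from_scores(scores, "category"), dataset, scheme, grid,
        return_predictions=True,
    )
    acc_dim, pred_dim = em.encode_voxelwise(
        em.feature_set_from_scores(scores, "dimension"), dataset, scheme, grid,
        return_predictions=True,
    )
    threshold = em.permutation_threshold(
        dataset.responses[:, 0], 180_000, alpha=0.01, n_tests=dataset.n_voxels, seed=0
    )
    return {
        "scores": scores,
        "dataset": dataset,
        "scheme": scheme,
        "grid": grid,
        "acc_cat": acc_cat,
        "acc_dim": acc_dim,
        "pred_cat": pred_cat,
        "pred_dim": pred_dim,
        "threshold": threshold,
    }
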