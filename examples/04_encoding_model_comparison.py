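"""Compare category vs dimension encoding models voxel by voxel.

Responses are generated from category scores while the dimension ratings
are noisy linear readouts of the categories. The category model should
predict more voxels significantly, win the total-least-squares slope
comparison (deviation above the 45-degree parity line), and dominate
across bins of a synthetic principal-gradient value.
"""

import numpy as np

import emodecode as em

scores = em.generate_category_driven_scores(
    400, n_cat=10, n_dim=4, sparsity=0.7, coupling=1.0, dim_noise=0.5, seed=42
)
parcellation = em.make_parcellation(
    region_names=[f"region{i:02d}" for i in range(12)], voxels_per_region=15
)
rng = np.random.default_rng(7)
gains = np.zeros((12, 14))
gains[:, :10] = (rng.random((12, 10)) < 0.4) * 1.0  # only categories drive voxels
truth = em.GroundTruth(gains, noise_sd=1.0)
dataset = em.generate_dataset(scores, parcellation, truth, subject_seed=3)
scheme = em.CVScheme(400, 6, 4)
grid = [0.1, 1.0, 10.0, 100.0]

acc = {}
pred = {}
for which in ("category", "dimension", "joint"):
    features = em.feature_set_from_scores(scores, which)
    acc[which], pred[which] = em.encode_voxelwise(
        features, dataset, scheme, grid, return_predictions=True
    )

threshold = em.permutation_threshold(
    dataset.responses[:, 0], n_perm=180_000, alpha=0.01, n_tests=dataset.n_voxels, seed=0
)
print(f"voxel-level critical |r|: {threshold.r_threshold:.3f}")
for which in acc:
    print(f"  {which:>9}: {em.count_significant(acc[which], threshold):3d} significant voxels")

replicates = list(
    zip(
        em.fold_deleted_accuracies(pred["category"], dataset.responses, scheme),
        em.fold_deleted_accuracies(pred["dimension"], dataset.responses, scheme),
    )
)
slope = em.slope_compare(acc["category"], acc["dimension"], jackknife_replicates=replicates)
print(
    f"slope angle {slope.theta_deg:.1f} deg, deviation from parity "
    f"{slope.deviation_deg:+.1f} deg (jackknife p = {slope.p_value:.2g})"
)

gradient = rng.standard_normal(dataset.n_voxels)  # stand-in per-voxel gradient value
profile = em.gradient_binned_compare(
    {"category": acc["category"], "dimension": acc["dimension"]}, gradient, n_bins=10
)
wins = int(np.sum(profile.mean_accuracy["category"] > profile.mean_accuracy["dimension"]))
print(f"category model leads in {wins}/10 gradient bins "
      f"({int(profile.significant.sum())} significantly)")
print(
    "A positive slope deviation and higher significant-voxel count mean the "
    "category model explains voxel responses the dimension model cannot."
)
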