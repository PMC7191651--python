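"""Generate a synthetic emotion-rating/fMRI world and decode it region by region.

Plants signal in 3 of 10 regions, trains one cross-validated ridge
decoder per (region, emotion), and checks the recovered accuracies
against a Bonferroni-corrected permutation threshold.
"""

import numpy as np

import emodecode as em

scores = em.generate_scores(n_videos=300, n_cat=10, n_dim=4, sparsity=0.7, seed=0)
parcellation = em.make_parcellation(
    region_names=[f"region{i:02d}" for i in range(10)], voxels_per_region=12
)

gains = np.zeros((10, 14))
gains[[2, 5, 8], :] = 1.0  # three informative regions, all emotions
truth = em.GroundTruth(gains, noise_sd=1.5)
dataset = em.generate_dataset(scores, parcellation, truth, subject_seed=1)

scheme = em.CVScheme(n_videos=300, n_outer=6, n_inner=4)
table = em.region_decode(dataset, scores, scheme, lam_grid=[0.1, 1.0, 10.0, 100.0])
threshold = em.permutation_threshold(
    scores.matrix()[:, 0], n_perm=10_000, alpha=0.01, n_tests=10, seed=0
)

mean_acc = np.nanmean(table.values, axis=1)
print(f"critical |r| (p < 0.01, Bonferroni over 10 regions): {threshold.r_threshold:.3f}")
for region, acc in sorted(zip(table.row_names, mean_acc), key=lambda t: -t[1]):
    flag = "*" if acc > threshold.r_threshold else " "
    print(f"  {region}  mean r = {acc:+.3f} {flag}")
print(
    "Starred regions decode emotion scores better than chance; they should "
    "be exactly the three regions with planted signal."
)
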