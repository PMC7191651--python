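"""Synthetic emotion-rating and fMRI-response generators with planted structure.

The generator emulates the study design this package analyzes: a large set
of short videos, each rated on sparse emotion *categories* (proportion of
raters endorsing, mostly exactly zero) and near-Gaussian affective
*dimensions* (Likert 1-9, neutral 5), shown to several subjects whose
voxel responses follow a linear encoding of the scores.

Signal is planted through a :class:`GroundTruth`: a nonnegative
region x emotion *informativeness map* shared across subjects, combined
with subject-specific random weights. A voxel in region ``r`` responds as

    y_v = sum_e  gain[r, e] * w[v, e] * score[., e]  +  noise

so regions with zero gain for every emotion contain pure noise, and the
set of informative regions — but not the voxel weights — is common to all
simulated subjects. This mirrors the cross-subject consistency analyses
while providing an exact ground truth for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import EmotionScoreMatrix, RegionParcellation, ResponseDataset

__all__ = [
    "GroundTruth",
    "generate_scores",
    "generate_category_driven_scores",
    "generate_dataset",
    "extract_trial_responses",
]


@dataclass
class GroundTruth:
    """Planted signal structure shared by all simulated subjects.

    ``informativeness_map`` has one row per region (parcellation registry
    order) and one column per emotion (categories first, then
    dimensions); entries are nonnegative gains. ``subject_weights`` is
    filled in as datasets are generated, keyed by subject id.
    """

    informativeness_map: np.ndarray
    noise_sd: float = 1.0
    subject_weights: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.informativeness_map = np.asarray(self.informativeness_map, dtype=float)
        if (self.informativeness_map < 0).any():
            raise ValueError("informativeness gains must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def informative_cells(self) -> np.ndarray:
        """Boolean region x emotion mask of cells carrying signal."""
        return self.informativeness_map > 0


def generate_scores(
    n_videos: int,
    n_cat: int = 34,
    n_dim: int = 14,
    sparsity: float = 0.7,
    seed: int | None = 0,
) -> EmotionScoreMatrix:
    """Generate an emotion score table.

    Category columns are zero-inflated Beta: a fraction ``sparsity`` of
    entries is exactly 0 and the rest are Beta(1.5, 5) draws in (0, 1],
    matching the sparse rater-proportion shape of real category ratings.
    Dimension columns are Normal(5, 1.5) truncated to [1, 9], centered on
    the neutral point 5. Deterministic given ``seed``.
    """
    if n_videos < 2 or n_cat < 0 or n_dim < 0 or (n_cat == 0 and n_dim == 0):
        raise ValueError("need n_videos >= 2 and at least one emotion column")
    if not 0 <= sparsity < 1:
        raise ValueError("sparsity must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    cats = rng.beta(1.5, 5.0, size=(n_videos, n_cat))
    # clip away exact zeros from the Beta draw itself so that all zeros
    # come from the inflation mask (keeps the sparsity fraction exact-ish)
    cats = np.clip(cats, 1e-9, 1.0)
    zero_mask = rng.random(size=(n_videos, n_cat)) < sparsity
    cats[zero_mask] = 0.0
    a, b = (1 - 5) / 1.5, (9 - 5) / 1.5
    dims = stats.truncnorm.rvs(a, b, loc=5.0, scale=1.5, size=(n_videos, n_dim), random_state=rng)
    return EmotionScoreMatrix(
        video_ids=[f"video{i:05d}" for i in range(n_videos)],
        category_scores=cats,
        dimension_scores=dims.reshape(n_videos, n_dim),
        category_names=[f"category{i:02d}" for i in range(n_cat)],
        dimension_names=[f"dimension{i:02d}" for i in range(n_dim)],
    )


def generate_category_driven_scores(
    n_videos: int,
    n_cat: int = 34,
    n_dim: int = 14,
    sparsity: float = 0.7,
    coupling: float = 1.0,
    dim_noise: float = 0.5,
    seed: int | None = 0,
) -> EmotionScoreMatrix:
    """Score table whose dimensions are noisy linear readouts of the categories.

    Category columns are generated as in :func:`generate_scores`; each
    dimension is ``5 + coupling * (standardized categories @ m) + noise``
    clipped to [1, 9], with a random unit mixing vector ``m`` per
    dimension. This emulates the situation where broad affective
    dimensions carry only information already present in the categories —
    the regime in which category-based models should win every
    comparison.
    """
    base = generate_scores(n_videos, n_cat, max(n_dim, 0) or 0, sparsity, seed)
    rng = np.random.default_rng(None if seed is None else seed + 1)
    cats = base.category_scores
    cz = cats - cats.mean(axis=0)
    sd = cz.std(axis=0)
    cz = cz / np.where(sd == 0, 1.0, sd)
    M = rng.standard_normal((n_cat, n_dim))
    M /= np.linalg.norm(M, axis=0, keepdims=True)
    raw = cz @ M
    raw = raw / raw.std(axis=0)
    dims = 5.0 + coupling * raw + dim_noise * rng.standard_normal(raw.shape)
    dims = np.clip(dims, 1.0, 9.0)
    return EmotionScoreMatrix(
        video_ids=list(base.video_ids),
        category_scores=cats,
        dimension_scores=dims,
        category_names=list(base.category_names),
        dimension_names=[f"dimension{i:02d}" for i in range(n_dim)],
    )


def generate_dataset(
    scores: EmotionScoreMatrix,
    parcellation: RegionParcellation,
    truth: GroundTruth,
    subject_seed: int = 0,
    subject_id: str | None = None,
) -> ResponseDataset:
    """Simulate one subject's videos x voxels responses.

    Each voxel gets standard-normal weights per emotion (drawn from
    ``subject_seed``), scaled by its region's gain for that emotion;
    responses are the linear combination of z-scored emotion scores plus
    i.i.d. Gaussian noise of sd ``truth.noise_sd``. The drawn weight
    tensor is recorded in ``truth.subject_weights``.
    """
    n_emotions = scores.n_categories + scores.n_dimensions
    gains = truth.informativeness_map
    if gains.shape != (parcellation.n_regions, n_emotions):
        raise ValueError(
            f"informativeness_map must be n_regions x n_emotions = "
            f"{(parcellation.n_regions, n_emotions)}, got {gains.shape}"
        )
    rng = np.random.default_rng(subject_seed)
    if subject_id is None:
        subject_id = f"sub-{subject_seed:02d}"
    n_vox = parcellation.n_voxels
    weights = rng.standard_normal((n_vox, n_emotions))
    region_index = {r: i for i, r in enumerate(parcellation.region_names)}
    vox_region = np.array([region_index[r] for r in parcellation.region_labels])
    effective = weights * gains[vox_region, :]
    # z-score the design so category (proportion) and dimension (Likert)
    # columns inject comparable signal per unit gain
    design = scores.matrix()
    sd = design.std(axis=0)
    sd[sd == 0] = 1.0
    design = (design - design.mean(axis=0)) / sd
    responses = design @ effective.T
    responses += truth.noise_sd * rng.standard_normal(responses.shape)
    truth.subject_weights[subject_id] = weights
    return ResponseDataset(
        subject_id=subject_id,
        responses=responses,
        parcellation=parcellation,
        video_ids=list(scores.video_ids),
        meta={"subject_seed": subject_seed, "noise_sd": truth.noise_sd},
    )


def extract_trial_responses(
    volume_series: np.ndarray,
    onsets: np.ndarray,
    durations: np.ndarray,
    shift_s: float = 4.0,
    tr_s: float = 2.0,
) -> np.ndarray:
    """Average volumes within each stimulus window, hemodynamically shifted.

    The response to a stimulus with onset ``t0`` and duration ``d``
    (both in seconds) is the mean of the volumes acquired in
    ``[t0 + shift, t0 + shift + d)``; the default shift of 4 s
    compensates for hemodynamic delay. Returns trials x voxels.
    """
    volume_series = np.asarray(volume_series, dtype=float)
    if volume_series.ndim == 1:
        volume_series = volume_series[:, None]
    n_vol = volume_series.shape[0]
    onsets = np.asarray(onsets, dtype=float)
    durations = np.asarray(durations, dtype=float)
    if onsets.shape != durations.shape:
        raise ValueError("onsets and durations must align")
    out = np.empty((len(onsets), volume_series.shape[1]))
    times = np.arange(n_vol) * tr_s
    for i, (t0, d) in enumerate(zip(onsets, durations)):
        lo, hi = t0 + shift_s, t0 + shift_s + d
        idx = np.flatnonzero((times >= lo) & (times < hi))
        if idx.size == 0 or idx[-1] >= n_vol or hi > n_vol * tr_s:
            raise ValueError(
                f"trial {i}: window [{lo}, {hi}) s exceeds the series "
                f"({n_vol} volumes of {tr_s} s)"
            )
        out[i] = volume_series[idx].mean(axis=0)
    return out
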