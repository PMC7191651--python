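"""Region-wise and ensemble decoders predicting emotion scores from brain activity.

A *region-wise decoder* for an emotion is a cross-validated ridge
regression from one region's voxel pattern to that emotion's score; with
the default 370-region registry this yields 370 decoders per emotion.
An *ensemble decoder* averages predictions from the regions that decode
best, where both the region ranking and the ensemble size are selected
by nested cross-validation on training data only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import EmotionScoreMatrix, ResponseDataset
from .regression import (
    DEFAULT_LAMBDA_GRID,
    CVScheme,
    cv_predict,
    pearson_columns,
)

__all__ = [
    "AccuracyTable",
    "EnsemblePrediction",
    "region_decode",
    "ensemble_decode",
    "subset_categories",
]


@dataclass
class AccuracyTable:
    """Pearson accuracies, rows = regions (or voxels), columns = emotions."""

    values: np.ndarray
    row_names: list[str]
    col_names: list[str]
    subject_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_names), len(self.col_names)):
            raise ValueError("accuracy values do not match row/column names")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_names, columns=self.col_names)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().rename_axis("region").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, subject_id: str = "") -> "AccuracyTable":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            values=frame.to_numpy(),
            row_names=[str(r) for r in frame.index],
            col_names=[str(c) for c in frame.columns],
            subject_id=subject_id,
        )


@dataclass
class EnsemblePrediction:
    """Decoded scores from the ensemble decoder plus its region selections."""

    decoded: np.ndarray  # videos x emotions, original score units
    emotion_names: list[str]
    video_ids: list[str]
    selected_regions: dict  # emotion -> list (per outer fold) of region names
    accuracy: np.ndarray  # per emotion, Pearson r over all videos
    subject_id: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.decoded, index=self.video_ids, columns=self.emotion_names)


def _check_regions(dataset: ResponseDataset) -> dict[str, np.ndarray]:
    voxels = {}
    for region in dataset.parcellation.region_names:
        idx = dataset.parcellation.voxels_of(region)
        if idx.size < 2:
            raise ValueError(f"region '{region}' has fewer than 2 voxels")
        voxels[region] = idx
    return voxels


def region_decode(
    dataset: ResponseDataset,
    scores: EmotionScoreMatrix,
    scheme: CVScheme,
    lam_grid=DEFAULT_LAMBDA_GRID,
    return_predictions: bool = False,
):
    """Train one cross-validated decoder per (region, emotion).

    Returns an :class:`AccuracyTable` of out-of-fold Pearson accuracies
    (regions x emotions); with ``return_predictions=True`` also a dict of
    per-region out-of-fold predicted score matrices.
    """
    if dataset.video_ids != scores.video_ids:
        raise ValueError("dataset and scores are not aligned on video_ids")
    region_voxels = _check_regions(dataset)
    Y = scores.matrix()
    acc = np.empty((len(region_voxels), Y.shape[1]))
    preds: dict[str, np.ndarray] = {}
    for i, (region, vox) in enumerate(region_voxels.items()):
        oof = cv_predict(dataset.responses[:, vox], Y, scheme, lam_grid)
        acc[i] = pearson_columns(oof, Y)
        if return_predictions:
            preds[region] = oof
    table = AccuracyTable(
        values=acc,
        row_names=list(region_voxels),
        col_names=scores.emotion_names,
        subject_id=dataset.subject_id,
        metadata={"scheme": scheme.to_json(), "lam_grid": list(map(float, lam_grid))},
    )
    return (table, preds) if return_predictions else table


def _default_n_grid(n_regions: int) -> list[int]:
    grid = []
    n = 1
    while n < n_regions:
        grid.append(n)
        n *= 2
    grid.append(n_regions)
    return grid


def ensemble_decode(
    dataset: ResponseDataset,
    scores: EmotionScoreMatrix,
    scheme: CVScheme,
    lam_grid=DEFAULT_LAMBDA_GRID,
    n_grid: list[int] | None = None,
) -> EnsemblePrediction:
    """Decode every emotion by averaging the best regions' predictions.

    Per emotion and outer fold, regions are ranked by their inner
    (training-fold) out-of-fold accuracy; candidate ensemble sizes N from
    ``n_grid`` (powers of two up to all regions by default) are compared
    by the inner accuracy of the averaged prediction and the best N is
    kept. Test-fold predictions of the selected regions are z-scored per
    region (so differently scaled regions contribute equally), averaged,
    and mapped back with the mean of the selected regions' own training
    statistics — a singleton ensemble therefore reproduces that region's
    prediction exactly. Ranking and size selection never see test rows.
    """
    if dataset.video_ids != scores.video_ids:
        raise ValueError("dataset and scores are not aligned on video_ids")
    region_voxels = _check_regions(dataset)
    regions = list(region_voxels)
    Y = scores.matrix()
    n_videos, n_emotions = Y.shape
    if n_grid is None:
        n_grid = _default_n_grid(len(regions))

    # per-region nested-CV artifacts (inner out-of-fold + test predictions)
    per_region = {
        region: cv_predict(
            dataset.responses[:, vox], Y, scheme, lam_grid, return_details=True
        )[1]
        for region, vox in region_voxels.items()
    }

    decoded = np.empty((n_videos, n_emotions))
    selected: dict[str, list[list[str]]] = {e: [] for e in scores.emotion_names}
    folds = scheme.outer_splits()
    for fi, (train_idx, test_idx) in enumerate(folds):
        for e in range(n_emotions):
            y_tr = Y[train_idx, e]
            inner_r = np.full(len(regions), -np.inf)
            for ri, region in enumerate(regions):
                p = per_region[region][fi].inner_pred[:, e]
                r = pearson_columns(p[:, None], y_tr[:, None])[0]
                inner_r[ri] = -np.inf if np.isnan(r) else r
            order = np.argsort(-inner_r, kind="stable")  # ties -> registry order
            best_n, best_score = n_grid[0], -np.inf
            # z-scored inner predictions of each region, ranked order
            inner_z = []
            for ri in order:
                p = per_region[regions[ri]][fi].inner_pred[:, e]
                s = p.std()
                inner_z.append((p - p.mean()) / (s if s > 0 else 1.0))
            inner_z = np.asarray(inner_z)
            cum = np.cumsum(inner_z, axis=0)
            for n in n_grid:
                avg = cum[n - 1] / n
                r = pearson_columns(avg[:, None], y_tr[:, None])[0]
                if not np.isnan(r) and r > best_score:
                    best_score, best_n = r, n
            chosen = [regions[ri] for ri in order[:best_n]]
            selected[scores.emotion_names[e]].append(chosen)
            # assemble the test prediction from the chosen regions
            zsum = np.zeros(len(test_idx))
            means, sds = [], []
            for region in chosen:
                fit = per_region[region][fi]
                p_tr = fit.inner_pred[:, e]
                m, s = p_tr.mean(), p_tr.std()
                s = s if s > 0 else 1.0
                zsum += (fit.test_pred[:, e] - m) / s
                means.append(m)
                sds.append(s)
            decoded[test_idx, e] = zsum / best_n * np.mean(sds) + np.mean(means)

    accuracy = pearson_columns(decoded, Y)
    return EnsemblePrediction(
        decoded=decoded,
        emotion_names=scores.emotion_names,
        video_ids=list(scores.video_ids),
        selected_regions=selected,
        accuracy=accuracy,
        subject_id=dataset.subject_id,
    )


def subset_categories(
    scores: EmotionScoreMatrix, k: int = 14, seed: int | None = 0
) -> EmotionScoreMatrix:
    """Keep a seeded random subset of k category columns; dimensions untouched."""
    if k > scores.n_categories or k < 1:
        raise ValueError("k must lie in [1, n_categories]")
    if k == scores.n_categories:
        return scores
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(scores.n_categories, size=k, replace=False))
    return EmotionScoreMatrix(
        video_ids=list(scores.video_ids),
        category_scores=scores.category_scores[:, keep],
        dimension_scores=scores.dimension_scores.copy(),
        category_names=[scores.category_names[i] for i in keep],
        dimension_names=list(scores.dimension_names),
    )
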