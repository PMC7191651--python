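"""Voxel-wise encoding models and model-comparison machinery.

An encoding model predicts each voxel's response from a stimulus feature
set (emotion category scores, affective dimension scores, their
concatenation, or any other videos x features matrix such as visual-object
or semantic features). Model comparisons include:

* slope angles of the total-least-squares fit through the origin on
  voxel accuracy scatter plots, with fold-jackknife t tests against the
  45 deg parity line;
* counts of voxels exceeding a permutation significance threshold;
* per-voxel best-model assignment among several feature sets;
* accuracy profiles along a per-voxel scalar gradient (e.g., the
  principal connectivity gradient), in ten equal-count bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import EmotionScoreMatrix, ResponseDataset
from .regression import (
    DEFAULT_LAMBDA_GRID,
    CVScheme,
    SignificanceThreshold,
    cv_predict,
    pearson_columns,
)

__all__ = [
    "FeatureSet",
    "SlopeComparison",
    "GradientProfile",
    "feature_set_from_scores",
    "split_dimensions",
    "encode_voxelwise",
    "fold_deleted_accuracies",
    "slope_compare",
    "count_significant",
    "best_model_map",
    "gradient_binned_compare",
]

logger = logging.getLogger(__name__)


@dataclass
class FeatureSet:
    """A named videos x features matrix aligned to the video list."""

    name: str
    matrix: np.ndarray
    feature_names: list[str]
    video_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.video_ids), len(self.feature_names)):
            raise ValueError("feature matrix does not match ids/names")


def feature_set_from_scores(scores: EmotionScoreMatrix, which: str) -> FeatureSet:
    """Build the category, dimension or joint feature set from a score table."""
    if which == "category":
        return FeatureSet("category", scores.category_scores, list(scores.category_names), list(scores.video_ids))
    if which == "dimension":
        return FeatureSet("dimension", scores.dimension_scores, list(scores.dimension_names), list(scores.video_ids))
    if which == "joint":
        return FeatureSet("joint", scores.matrix(), scores.emotion_names, list(scores.video_ids))
    raise ValueError("which must be 'category', 'dimension' or 'joint'")


def split_dimensions(scores: EmotionScoreMatrix) -> FeatureSet:
    """Split each affective dimension at the neutral point 5.

    Each dimension d yields two nonnegative columns: ``d_pos = max(0, s - 5)``
    and ``d_neg = max(0, 5 - s)`` — 28 columns for the default 14
    dimensions.
    """
    s = scores.dimension_scores
    if s.size and (s.min() < 1 or s.max() > 9):
        raise ValueError("dimension scores must lie in [1, 9]")
    cols, names = [], []
    for j, d in enumerate(scores.dimension_names):
        cols.append(np.maximum(0.0, s[:, j] - 5.0))
        names.append(f"{d}_pos")
        cols.append(np.maximum(0.0, 5.0 - s[:, j]))
        names.append(f"{d}_neg")
    return FeatureSet(
        "dimension_split", np.column_stack(cols), names, list(scores.video_ids)
    )


def encode_voxelwise(
    features: FeatureSet,
    dataset: ResponseDataset,
    scheme: CVScheme,
    lam_grid=DEFAULT_LAMBDA_GRID,
    return_predictions: bool = False,
):
    """Out-of-fold encoding accuracy (Pearson r) for every voxel.

    Voxels with constant measured response have undefined correlation;
    they are returned as NaN and their count is logged. With
    ``return_predictions=True`` the out-of-fold predicted activity matrix
    is returned as well.
    """
    if features.video_ids != dataset.video_ids:
        raise ValueError("features and dataset are not aligned on video_ids")
    oof = cv_predict(features.matrix, dataset.responses, scheme, lam_grid)
    acc = pearson_columns(oof, dataset.responses)
    n_bad = int(np.isnan(acc).sum())
    if n_bad:
        logger.warning(
            "%d voxel(s) with undefined accuracy (constant response or "
            "prediction) excluded from aggregates",
            n_bad,
        )
    return (acc, oof) if return_predictions else acc


def fold_deleted_accuracies(
    pred: np.ndarray, truth: np.ndarray, scheme: CVScheme
) -> list[np.ndarray]:
    """Per-voxel accuracies recomputed omitting one outer fold's videos.

    These leave-one-fold-out replicates feed the jackknife in
    :func:`slope_compare`.
    """
    out = []
    for _, test_idx in scheme.outer_splits():
        keep = np.setdiff1d(np.arange(pred.shape[0]), test_idx)
        out.append(pearson_columns(pred[keep], truth[keep]))
    return out


@dataclass
class SlopeComparison:
    """TLS slope angle of accA vs accB with a jackknife test against parity."""

    theta_deg: float
    deviation_deg: float  # theta - 45; > 0 means model A wins
    se_deg: float
    t_stat: float
    p_value: float
    n_points: int
    n_jackknife: int
    jackknife_thetas: np.ndarray | None = None

    def to_json(self) -> dict:
        return {
            "theta_deg": self.theta_deg,
            "deviation_deg": self.deviation_deg,
            "se_deg": self.se_deg,
            "t_stat": self.t_stat,
            "p_value": self.p_value,
            "n_points": self.n_points,
            "n_jackknife": self.n_jackknife,
        }


def _tls_angle(acc_a: np.ndarray, acc_b: np.ndarray) -> float:
    """Angle (deg) of the total-least-squares line through the origin.

    Model A is the vertical axis, model B the horizontal, so 45 deg is
    parity and larger angles mean A predicts better.
    """
    x, y = acc_b, acc_a
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    if sxx == 0 and syy == 0:
        raise ValueError("undefined slope: all accuracies are zero")
    M = np.array([[sxx, sxy], [sxy, syy]])
    vals, vecs = np.linalg.eigh(M)
    v = vecs[:, np.argmax(vals)]
    if v[0] < 0:
        v = -v
    return float(np.degrees(np.arctan2(v[1], v[0])))


def slope_compare(
    acc_a: np.ndarray,
    acc_b: np.ndarray,
    group_mask: np.ndarray | None = None,
    jackknife_replicates: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> SlopeComparison:
    """Compare two models' voxel accuracies by a TLS slope angle.

    Both axes carry sampling noise, so the line is fitted by the
    principal axis (total least squares) through the origin; the parity
    line is 45 deg. ``jackknife_replicates`` is a list of
    (acc_a, acc_b) pairs re-evaluated with one group of videos deleted
    (see :func:`fold_deleted_accuracies`); the jackknife SE over their
    angles yields a two-tailed t test of the deviation from parity.
    NaN accuracies (undefined voxels) are dropped pairwise.
    """
    acc_a = np.asarray(acc_a, dtype=float)
    acc_b = np.asarray(acc_b, dtype=float)
    if acc_a.shape != acc_b.shape:
        raise ValueError("accuracy vectors must align")
    if group_mask is None:
        group_mask = np.ones(acc_a.shape, dtype=bool)
    group_mask = np.asarray(group_mask, dtype=bool)
    valid = group_mask & ~np.isnan(acc_a) & ~np.isnan(acc_b)
    if valid.sum() < 3:
        raise ValueError("need at least 3 voxels in the group")
    theta = _tls_angle(acc_a[valid], acc_b[valid])

    se = t_stat = p_value = float("nan")
    thetas = None
    g = 0
    if jackknife_replicates is not None:
        g = len(jackknife_replicates)
        if g < 2:
            raise ValueError("need at least 2 jackknife replicates")
        thetas = np.array(
            [_tls_angle(a[valid], b[valid]) for a, b in jackknife_replicates]
        )
        se = float(np.sqrt((g - 1) / g * ((thetas - thetas.mean()) ** 2).sum()))
        if se > 0:
            t_stat = (theta - 45.0) / se
            p_value = float(2 * stats.t.sf(abs(t_stat), df=g - 1))
    return SlopeComparison(
        theta_deg=theta,
        deviation_deg=theta - 45.0,
        se_deg=se,
        t_stat=t_stat,
        p_value=p_value,
        n_points=int(valid.sum()),
        n_jackknife=g,
        jackknife_thetas=thetas,
    )


def count_significant(acc: np.ndarray, threshold: SignificanceThreshold) -> int:
    """Number of voxels with accuracy strictly above the critical r."""
    acc = np.asarray(acc, dtype=float)
    return int(np.nansum(acc > threshold.r_threshold))


def best_model_map(
    acc_by_model: dict[str, np.ndarray],
    thresholds: dict[str, SignificanceThreshold] | SignificanceThreshold | float | None = None,
    priority: list[str] | None = None,
) -> np.ndarray:
    """Per-voxel winning model among several accuracy vectors.

    Only voxels significant under at least one model receive a label;
    the rest are None. Ties go to the earlier model in ``priority``
    (insertion order of ``acc_by_model`` by default).
    """
    if len(acc_by_model) < 2:
        raise ValueError("need at least 2 models")
    names = priority if priority is not None else list(acc_by_model)
    mats = [np.asarray(acc_by_model[n], dtype=float) for n in names]
    n_vox = mats[0].shape[0]
    for m in mats:
        if m.shape != (n_vox,):
            raise ValueError("accuracy vectors are misaligned")
    A = np.vstack(mats)

    def _thr(name: str) -> float:
        if thresholds is None:
            return -np.inf
        if isinstance(thresholds, dict):
            t = thresholds[name]
        else:
            t = thresholds
        return t.r_threshold if isinstance(t, SignificanceThreshold) else float(t)

    sig = np.zeros(n_vox, dtype=bool)
    for i, name in enumerate(names):
        sig |= A[i] > _thr(name)
    with np.errstate(invalid="ignore"):
        winner = np.nanargmax(np.where(np.isnan(A), -np.inf, A), axis=0)
    labels = np.array([names[w] for w in winner], dtype=object)
    labels[~sig] = None
    return labels


@dataclass
class GradientProfile:
    """Mean accuracy per model in equal-count bins of a per-voxel gradient."""

    bin_sizes: np.ndarray
    bin_gradient_means: np.ndarray
    mean_accuracy: dict = field(default_factory=dict)  # model -> per-bin means
    p_values: np.ndarray | None = None  # paired t per bin (2-model case), Bonferroni-corrected
    significant: np.ndarray | None = None
    alpha: float = 0.01
    anova_interaction_p: float | None = None

    def to_json(self) -> dict:
        return {
            "bin_sizes": self.bin_sizes.tolist(),
            "bin_gradient_means": self.bin_gradient_means.tolist(),
            "mean_accuracy": {k: list(map(float, v)) for k, v in self.mean_accuracy.items()},
            "p_values": None if self.p_values is None else self.p_values.tolist(),
            "significant": None if self.significant is None else self.significant.tolist(),
            "alpha": self.alpha,
            "anova_interaction_p": self.anova_interaction_p,
        }


def gradient_binned_compare(
    acc_by_model: dict[str, np.ndarray],
    gradient: np.ndarray,
    n_bins: int = 10,
    alpha: float = 0.01,
) -> GradientProfile:
    """Compare model accuracies along a per-voxel gradient.

    Voxels are ranked by the gradient and split into ``n_bins``
    equal-count bins (sizes differ by at most 1). Per bin, mean accuracy
    is reported for every model; when exactly two models are given, a
    per-bin two-tailed paired t test is run with Bonferroni correction
    over bins, and a two-factor (bin x model) ANOVA interaction p value
    is attached.
    """
    gradient = np.asarray(gradient, dtype=float)
    n_vox = gradient.shape[0]
    if n_bins > n_vox:
        raise ValueError("more bins than voxels")
    if n_bins < 1:
        raise ValueError("need at least one bin")
    mats = {k: np.asarray(v, dtype=float) for k, v in acc_by_model.items()}
    for v in mats.values():
        if v.shape != (n_vox,):
            raise ValueError("accuracy vectors must align with the gradient")
    order = np.argsort(gradient, kind="stable")
    bins = np.array_split(order, n_bins)
    sizes = np.array([len(b) for b in bins])
    grad_means = np.array([gradient[b].mean() for b in bins])
    mean_acc = {
        k: np.array([np.nanmean(v[b]) for b in bins]) for k, v in mats.items()
    }
    p_values = significant = None
    anova_p = None
    if len(mats) == 2:
        (name_a, va), (name_b, vb) = mats.items()
        raw = np.empty(n_bins)
        for i, b in enumerate(bins):
            a, c = va[b], vb[b]
            ok = ~np.isnan(a) & ~np.isnan(c)
            if ok.sum() < 2 or np.allclose(a[ok], c[ok]):
                raw[i] = 1.0
            else:
                raw[i] = stats.ttest_rel(a[ok], c[ok]).pvalue
        p_values = np.minimum(raw * n_bins, 1.0)
        significant = p_values < alpha
        anova_p = _bin_model_interaction_p(mats, bins)
    return GradientProfile(
        bin_sizes=sizes,
        bin_gradient_means=grad_means,
        mean_accuracy=mean_acc,
        p_values=p_values,
        significant=significant,
        alpha=alpha,
        anova_interaction_p=anova_p,
    )


def _bin_model_interaction_p(mats: dict[str, np.ndarray], bins: list[np.ndarray]) -> float:
    """Interaction p from a two-factor ANOVA on voxel accuracies (bin x model)."""
    import pandas as pd
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    rows = []
    for model, v in mats.items():
        for bi, b in enumerate(bins):
            for a in v[b]:
                if not np.isnan(a):
                    rows.append((model, bi, a))
    frame = pd.DataFrame(rows, columns=["model", "bin", "acc"])
    fit = ols("acc ~ C(bin) * C(model)", data=frame).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    return float(table.loc["C(bin):C(model)", "PR(>F)"])
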