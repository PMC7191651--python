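"""Unsupervised characterization of emotion-related response structure.

Covers the map-and-cluster analyses: a 2-D UMAP embedding with
out-of-sample projection (so decoded scores can be placed on the map
built from reported scores), selection of emotion-predicted voxels,
k-means clustering of activity patterns, histograms of each emotion's
top-scoring videos over clusters, and the Shannon entropy of those
histograms against a permutation baseline. Concentrated (low-entropy)
histograms indicate that an emotion's top videos fall into few activity
clusters — the signature of categorical organization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .regression import SignificanceThreshold, pearson_eval

__all__ = [
    "EmbeddingModel",
    "ClusterProfile",
    "fit_embedding",
    "map_reconstruction_corr",
    "select_emotion_voxels",
    "cluster_patterns",
    "top_sample_histogram",
    "histogram_entropy",
    "entropy_baseline",
    "sorted_histograms",
    "profile_emotions",
]


@dataclass
class EmbeddingModel:
    """A fitted 2-D embedding that can project new points."""

    reducer: object
    n_features: int
    params: dict
    training_coords: np.ndarray

    def project(self, new_features: np.ndarray) -> np.ndarray:
        X = np.asarray(new_features, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected points with {self.n_features} features, got {X.shape}"
            )
        return np.asarray(self.reducer.transform(X))


def fit_embedding(
    features: np.ndarray,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    metric: str = "euclidean",
    seed: int = 0,
) -> EmbeddingModel:
    """Fit a 2-D UMAP over feature space (emotion scores or voxel patterns).

    The fitted mapping projects new points via ``EmbeddingModel.project``,
    which is what allows reconstructing the emotion map from decoded
    scores. Deterministic given ``seed``.
    """
    import umap  # deferred: numba compilation is slow at import time

    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 10:
        raise ValueError("need at least 10 training points")
    params = {
        "n_neighbors": n_neighbors,
        "min_dist": min_dist,
        "metric": metric,
        "seed": seed,
    }
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        metric=metric,
        random_state=seed,
    )
    coords = reducer.fit_transform(X)
    return EmbeddingModel(
        reducer=reducer,
        n_features=X.shape[1],
        params=params,
        training_coords=np.asarray(coords),
    )


def map_reconstruction_corr(
    true_coords: np.ndarray, decoded_coords: np.ndarray
) -> tuple[float, float]:
    """Per-axis Pearson r between true and reconstructed 2-D positions."""
    A = np.asarray(true_coords, dtype=float)
    B = np.asarray(decoded_coords, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 2:
        raise ValueError("coordinate sets must align and be 2-D")
    return pearson_eval(B[:, 0], A[:, 0]), pearson_eval(B[:, 1], A[:, 1])


def select_emotion_voxels(
    acc_category: np.ndarray,
    acc_dimension: np.ndarray,
    threshold: SignificanceThreshold | float,
) -> np.ndarray:
    """Voxels significantly predicted by either emotion encoding model."""
    a = np.asarray(acc_category, dtype=float)
    b = np.asarray(acc_dimension, dtype=float)
    if a.shape != b.shape:
        raise ValueError("accuracy vectors must align")
    thr = threshold.r_threshold if isinstance(threshold, SignificanceThreshold) else float(threshold)
    best = np.fmax(a, b)  # fmax ignores NaN on one side
    return np.where(np.isnan(best), False, best > thr)


@dataclass
class ClusterProfile:
    """k-means assignments plus per-emotion top-sample histograms/entropies."""

    k: int
    assignments: np.ndarray
    inertia: float
    histograms: dict = field(default_factory=dict)  # emotion -> counts over k
    entropies: dict = field(default_factory=dict)  # emotion -> bits
    baseline_entropy: float | None = None
    top_frac: float = 0.05

    def to_json(self) -> dict:
        return {
            "k": self.k,
            "inertia": self.inertia,
            "assignments": self.assignments.tolist(),
            "histograms": {e: h.tolist() for e, h in self.histograms.items()},
            "entropies": {e: float(v) for e, v in self.entropies.items()},
            "baseline_entropy": self.baseline_entropy,
            "top_frac": self.top_frac,
        }


def cluster_patterns(
    responses: np.ndarray,
    mask: np.ndarray | None,
    k: int = 27,
    seed: int = 0,
    n_restarts: int = 10,
) -> ClusterProfile:
    """k-means over videos' activity patterns in the masked voxels.

    Clustering sees only brain activity — never the emotion scores. Ten
    seeded restarts, best inertia kept.
    """
    from sklearn.cluster import KMeans

    X = np.asarray(responses, dtype=float)
    if mask is not None:
        mask = np.asarray(mask)
        cols = np.flatnonzero(mask) if mask.dtype == bool else mask.astype(int)
        if cols.size == 0:
            raise ValueError("voxel mask selects no voxels")
        X = X[:, cols]
    if k < 1 or k > X.shape[0]:
        raise ValueError("k must lie in [1, n_videos]")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(X)
    return ClusterProfile(k=k, assignments=labels, inertia=float(km.inertia_))


def top_sample_histogram(
    scores_column: np.ndarray,
    assignments: np.ndarray,
    top_frac: float = 0.05,
    k: int | None = None,
) -> np.ndarray:
    """Cluster histogram of the videos scoring in an emotion's top fraction.

    Selects ``floor(top_frac * n_videos)`` highest-scoring videos (ties
    at the cutoff resolved by video order) and counts them per cluster.
    """
    s = np.asarray(scores_column, dtype=float)
    a = np.asarray(assignments, dtype=int)
    if s.shape != a.shape:
        raise ValueError("scores and assignments must align")
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must lie in (0, 1]")
    m = int(np.floor(top_frac * len(s)))
    if m < 1:
        raise ValueError("top fraction selects no videos")
    top = np.argsort(-s, kind="stable")[:m]
    if k is None:
        k = int(a.max()) + 1
    return np.bincount(a[top], minlength=k)


def histogram_entropy(hist: np.ndarray) -> float:
    """Shannon entropy (bits) of a normalized cluster histogram."""
    h = np.asarray(hist, dtype=float)
    if h.sum() <= 0 or (h < 0).any():
        raise ValueError("histogram must have positive mass")
    return float(sps.entropy(h, base=2))


def entropy_baseline(
    assignments: np.ndarray,
    n_select: int,
    n_perm: int = 1000,
    alpha: float = 0.01,
    n_emotions: int = 1,
    seed: int | None = 0,
) -> float:
    """Permutation baseline: low quantile of entropies of random selections.

    Draws ``n_select`` videos at random ``n_perm`` times, computes each
    selection's cluster-histogram entropy, and returns the
    ``alpha / n_emotions`` quantile — emotions whose top-sample entropy
    falls below it are more concentrated than chance (Bonferroni over
    emotions).
    """
    a = np.asarray(assignments, dtype=int)
    if not 1 <= n_select <= len(a):
        raise ValueError("n_select out of range")
    k = int(a.max()) + 1
    rng = np.random.default_rng(seed)
    ents = np.empty(n_perm)
    for i in range(n_perm):
        pick = rng.choice(len(a), size=n_select, replace=False)
        ents[i] = histogram_entropy(np.bincount(a[pick], minlength=k))
    return float(np.quantile(ents, alpha / n_emotions))


def sorted_histograms(histograms: dict | np.ndarray) -> np.ndarray:
    """Descending, normalized frequency curves (one row per emotion)."""
    if isinstance(histograms, dict):
        H = np.vstack([np.asarray(h, dtype=float) for h in histograms.values()])
    else:
        H = np.atleast_2d(np.asarray(histograms, dtype=float))
    sums = H.sum(axis=1, keepdims=True)
    if (sums <= 0).any():
        raise ValueError("histograms must have positive mass")
    return np.sort(H / sums, axis=1)[:, ::-1]


def profile_emotions(
    profile: ClusterProfile,
    feature_matrix: np.ndarray,
    feature_names: list[str],
    top_frac: float = 0.05,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int | None = 0,
) -> ClusterProfile:
    """Fill a cluster profile with per-emotion histograms and entropies.

    ``feature_matrix`` columns define the emotions (e.g., category
    scores, or the 28 positive/negative dimension-split columns); the
    shared permutation baseline is Bonferroni-corrected by the number of
    emotions profiled.
    """
    F = np.asarray(feature_matrix, dtype=float)
    if F.shape[1] != len(feature_names):
        raise ValueError("feature matrix does not match names")
    n_select = int(np.floor(top_frac * F.shape[0]))
    for j, name in enumerate(feature_names):
        hist = top_sample_histogram(F[:, j], profile.assignments, top_frac, k=profile.k)
        profile.histograms[name] = hist
        profile.entropies[name] = histogram_entropy(hist)
    profile.baseline_entropy = entropy_baseline(
        profile.assignments,
        n_select,
        n_perm=n_perm,
        alpha=alpha,
        n_emotions=len(feature_names),
        seed=seed,
    )
    profile.top_frac = top_frac
    return profile
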