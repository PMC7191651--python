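"""Correlation-based identification analyses.

Two tasks share the same logic of matching a query vector to the most
correlated candidate:

* *emotion identification* — does one subject's region-wise decoding
  accuracy pattern for an emotion pick out the same emotion's pattern in
  another subject, among a candidate set of given size? Chance is
  100 / set_size %.
* *video identification* — does a decoded score vector (or predicted
  voxel pattern) pick out the true video's vector against every other
  candidate, pairwise? Chance is 50%.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .decoding import AccuracyTable
from .regression import pearson_columns

__all__ = [
    "IdentificationResult",
    "emotion_identify",
    "congruency_stats",
    "video_identify",
    "video_identify_encoding",
]


@dataclass
class IdentificationResult:
    """Identification accuracies (percent) plus the correlation summaries."""

    accuracy: float  # mean over emotions and resamples, %
    per_emotion: np.ndarray  # % per emotion
    set_size: int
    n_resamples: int | None  # None -> exhaustive enumeration
    seed: int | None
    congruent_mean: float
    incongruent_mean: float
    emotion_names: list[str]

    def to_json(self) -> dict:
        return {
            "accuracy_percent": self.accuracy,
            "per_emotion_percent": {
                e: float(a) for e, a in zip(self.emotion_names, self.per_emotion)
            },
            "set_size": self.set_size,
            "n_resamples": self.n_resamples,
            "seed": self.seed,
            "congruent_mean_r": self.congruent_mean,
            "incongruent_mean_r": self.incongruent_mean,
        }


def _pattern_correlations(tableA: AccuracyTable, tableB: AccuracyTable) -> np.ndarray:
    if tableA.row_names != tableB.row_names:
        raise ValueError("tables use different region registries")
    if tableA.col_names != tableB.col_names:
        raise ValueError("tables use different emotion sets")
    A, B = tableA.values, tableB.values
    if (A.std(axis=0) == 0).any() or (B.std(axis=0) == 0).any():
        raise ValueError("undefined correlation: zero-variance accuracy pattern")
    Az = (A - A.mean(axis=0)) / A.std(axis=0)
    Bz = (B - B.mean(axis=0)) / B.std(axis=0)
    return Az.T @ Bz / A.shape[0]


def congruency_stats(tableA: AccuracyTable, tableB: AccuracyTable) -> tuple[float, float]:
    """Mean same-emotion (congruent) and different-emotion (incongruent) r."""
    C = _pattern_correlations(tableA, tableB)
    off = C[~np.eye(C.shape[0], dtype=bool)]
    return float(np.diag(C).mean()), float(off.mean())


def emotion_identify(
    tableA: AccuracyTable,
    tableB: AccuracyTable,
    set_size: int,
    n_resamples: int | None = 10_000,
    seed: int | None = 0,
) -> IdentificationResult:
    """n-way cross-subject emotion identification from accuracy patterns.

    For each emotion, the query is table A's region-wise accuracy
    pattern; the candidate set holds table B's pattern for the same
    emotion plus ``set_size - 1`` distinct other emotions' patterns
    (sampled without replacement per resample, or enumerated exhaustively
    when ``n_resamples`` is None). A trial is correct iff the congruent
    candidate's correlation is strictly maximal — ties count as
    incorrect. Accuracy is reported in percent.
    """
    C = _pattern_correlations(tableA, tableB)
    n_emotions = C.shape[0]
    if not 2 <= set_size <= n_emotions:
        raise ValueError("set_size must lie in [2, n_emotions]")
    k = set_size - 1
    per_emotion = np.empty(n_emotions)
    if n_resamples is None:
        for e in range(n_emotions):
            others = [f for f in range(n_emotions) if f != e]
            hits = total = 0
            for combo in combinations(others, k):
                total += 1
                if C[e, e] > max(C[e, f] for f in combo):
                    hits += 1
            per_emotion[e] = 100.0 * hits / total
    else:
        rng = np.random.default_rng(seed)
        for e in range(n_emotions):
            others = np.array([f for f in range(n_emotions) if f != e])
            keys = rng.random((n_resamples, len(others)))
            pick = np.argpartition(keys, k - 1, axis=1)[:, :k]
            competitor_r = C[e, others[pick]]
            per_emotion[e] = 100.0 * np.mean(C[e, e] > competitor_r.max(axis=1))
    congr, incongr = congruency_stats(tableA, tableB)
    return IdentificationResult(
        accuracy=float(per_emotion.mean()),
        per_emotion=per_emotion,
        set_size=set_size,
        n_resamples=n_resamples,
        seed=seed,
        congruent_mean=congr,
        incongruent_mean=incongr,
        emotion_names=list(tableA.col_names),
    )


def _row_correlations(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth must have the same shape")
    if pred.shape[0] < 2:
        raise ValueError("need at least 2 videos")
    if (pred.std(axis=1) == 0).any():
        raise ValueError("undefined correlation: constant prediction vector")
    if (truth.std(axis=1) == 0).any():
        raise ValueError("undefined correlation: constant truth vector")
    Pz = (pred - pred.mean(axis=1, keepdims=True)) / pred.std(axis=1, keepdims=True)
    Tz = (truth - truth.mean(axis=1, keepdims=True)) / truth.std(axis=1, keepdims=True)
    return Pz @ Tz.T / pred.shape[1]


def video_identify(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Pairwise video identification accuracy (percent) per video.

    For video v, every other video f serves once as the false candidate:
    the trial is correct when corr(pred_v, truth_v) > corr(pred_v,
    truth_f); exact ties earn half credit. Returns the per-video percent
    of correct pairwise comparisons (chance 50%).
    """
    R = _row_correlations(pred, truth)
    n = R.shape[0]
    own = np.diag(R)
    wins = (own[:, None] > R).sum(axis=1).astype(float)
    ties = (own[:, None] == R).sum(axis=1) - 1  # exclude the self match
    return 100.0 * (wins + 0.5 * ties) / (n - 1)


def video_identify_encoding(
    pred_activity: np.ndarray,
    measured: np.ndarray,
    voxel_mask: np.ndarray,
) -> np.ndarray:
    """Video identification via predicted voxel activity patterns.

    Feature vectors are the masked voxel patterns; candidates are the
    measured patterns of the true and false videos.
    """
    mask = np.asarray(voxel_mask)
    if mask.dtype == bool:
        if not mask.any():
            raise ValueError("voxel mask selects no voxels")
        cols = np.flatnonzero(mask)
    else:
        cols = mask.astype(int)
        if cols.size == 0:
            raise ValueError("voxel mask selects no voxels")
    return video_identify(np.asarray(pred_activity)[:, cols], np.asarray(measured)[:, cols])
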