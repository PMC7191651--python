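"""Regularized linear regression with nested cross-validation and permutation nulls.

This is the statistical engine shared by the decoding and encoding
analyses: ridge regression solved in closed form on z-scored data,
out-of-fold prediction with an inner cross-validation loop selecting the
penalty per target, Pearson-correlation evaluation, and permutation-based
significance thresholds with Bonferroni correction.

All normalization statistics (predictor and target means/SDs) are
computed from training rows only and predictions are returned in the
original target units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "LinearModel",
    "CVScheme",
    "SignificanceThreshold",
    "FoldFit",
    "ridge_fit",
    "cv_predict",
    "pearson_eval",
    "pearson_columns",
    "permutation_threshold",
    "normal_approx_threshold",
    "DEFAULT_LAMBDA_GRID",
]

DEFAULT_LAMBDA_GRID: tuple[float, ...] = tuple(np.logspace(-3, 3, 10))


def _zstats(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = A.mean(axis=0)
    sd = A.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mean, sd


@dataclass
class LinearModel:
    """A fitted ridge model: weights on z-scored data plus the z statistics."""

    weights: np.ndarray  # predictors x targets, on z-scored data
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: np.ndarray
    y_sd: np.ndarray
    lam: float | np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Z = (X - self.x_mean) / self.x_sd
        return Z @ self.weights * self.y_sd + self.y_mean


def _solve_ridge(Xz: np.ndarray, Yz: np.ndarray, lam: float) -> np.ndarray:
    n, p = Xz.shape
    if lam == 0:
        W, _, rank, _ = np.linalg.lstsq(Xz, Yz, rcond=None)
        if rank < min(n - 1, p):
            warnings.warn(
                "unpenalized fit on rank-deficient predictors; minimum-norm "
                "solution returned",
                stacklevel=3,
            )
        return W
    if p <= n:
        G = Xz.T @ Xz + lam * np.eye(p)
        return np.linalg.solve(G, Xz.T @ Yz)
    # kernel form for wide problems
    K = Xz @ Xz.T + lam * np.eye(n)
    return Xz.T @ np.linalg.solve(K, Yz)


def ridge_fit(X: np.ndarray, Y: np.ndarray, lam: float) -> LinearModel:
    """Closed-form ridge fit on z-scored predictors and targets.

    Weights solve ``min ||Yz - Xz W||^2 + lam ||W||^2`` where ``Xz`` and
    ``Yz`` are column-z-scored with the training statistics stored on the
    returned model. With all weights forced to zero the model predicts the
    training target mean.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if np.isnan(X).any() or np.isnan(Y).any():
        raise ValueError("missing values are not allowed")
    if lam < 0:
        raise ValueError("penalty must be nonnegative")
    xm, xs = _zstats(X)
    ym, ys = _zstats(Y)
    Xz = (X - xm) / xs
    Yz = (Y - ym) / ys
    W = _solve_ridge(Xz, Yz, lam)
    return LinearModel(W, xm, xs, ym, ys, lam)


def _ridge_path(Xz: np.ndarray, Yz: np.ndarray, lams: np.ndarray) -> list[np.ndarray]:
    """Weights for every lambda from one SVD of the design."""
    U, s, Vt = np.linalg.svd(Xz, full_matrices=False)
    UtY = U.T @ Yz
    out = []
    for lam in lams:
        if lam == 0:
            d = np.where(s > s.max(initial=0) * 1e-12, 1.0 / np.where(s == 0, 1.0, s), 0.0)
        else:
            d = s / (s**2 + lam)
        out.append(Vt.T @ (d[:, None] * UtY))
    return out


@dataclass
class CVScheme:
    """Fold assignment for (nested) cross-validation over videos.

    Outer folds are contiguous blocks in video order by default; set
    ``shuffle=True`` (with ``seed``) for a seeded permutation. Inner
    folds partition each outer-fold training set the same way. Outer
    test rows never enter inner selection.
    """

    n_videos: int
    n_outer: int = 6
    n_inner: int = 5
    seed: int | None = None
    shuffle: bool = False
    _order: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_videos < self.n_outer:
            raise ValueError("fewer videos than outer folds")
        if self.n_outer < 2 or self.n_inner < 2:
            raise ValueError("need at least 2 outer and 2 inner folds")
        order = np.arange(self.n_videos)
        if self.shuffle:
            order = np.random.default_rng(self.seed).permutation(order)
        self._order = order

    @property
    def fold_assignment(self) -> np.ndarray:
        fold = np.empty(self.n_videos, dtype=int)
        for k, chunk in enumerate(np.array_split(self._order, self.n_outer)):
            fold[chunk] = k
        return fold

    def outer_splits(self) -> list[tuple[np.ndarray, np.ndarray]]:
        chunks = np.array_split(self._order, self.n_outer)
        splits = []
        for k, test in enumerate(chunks):
            train = np.concatenate([c for j, c in enumerate(chunks) if j != k])
            splits.append((train, test))
        return splits

    def inner_splits(self, train_idx: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
        """Local (0..len(train)-1) inner train/validation splits."""
        local = np.arange(len(train_idx))
        chunks = np.array_split(local, self.n_inner)
        out = []
        for k, val in enumerate(chunks):
            tr = np.concatenate([c for j, c in enumerate(chunks) if j != k])
            out.append((tr, val))
        return out

    def to_json(self) -> dict:
        return {
            "n_videos": self.n_videos,
            "n_outer": self.n_outer,
            "n_inner": self.n_inner,
            "seed": self.seed,
            "shuffle": self.shuffle,
        }


@dataclass
class FoldFit:
    """Per-outer-fold artifacts of one nested-CV regression."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    test_pred: np.ndarray  # len(test_idx) x targets, original units
    inner_pred: np.ndarray | None  # len(train_idx) x targets (inner out-of-fold)
    lam: np.ndarray  # chosen penalty per target
    x_mean: np.ndarray
    y_mean: np.ndarray
    y_sd: np.ndarray


def pearson_columns(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r between two equal-shape matrices.

    Columns with zero variance on either side yield NaN (callers decide
    whether that is an error).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    num = (Ac * Bc).sum(axis=0)
    den = np.sqrt((Ac**2).sum(axis=0) * (Bc**2).sum(axis=0))
    # a literally constant column is undefined even if centering leaves
    # O(eps) jitter that would correlate spuriously
    constant = (np.ptp(A, axis=0) == 0) | (np.ptp(B, axis=0) == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r = np.where(constant | (den == 0), np.nan, r)
    return np.clip(r, -1.0, 1.0)


def pearson_eval(pred: np.ndarray, true: np.ndarray) -> float:
    """Pearson correlation between a prediction and a truth vector."""
    pred = np.asarray(pred, dtype=float).ravel()
    true = np.asarray(true, dtype=float).ravel()
    if pred.shape != true.shape:
        raise ValueError("vectors must have equal length")
    if len(pred) < 3:
        raise ValueError("need at least 3 samples")
    if pred.std() == 0 or true.std() == 0:
        raise ValueError("undefined correlation: zero-variance input")
    return float(pearson_columns(pred[:, None], true[:, None])[0])


def _fit_one_fold(
    X: np.ndarray,
    Y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    scheme: CVScheme,
    lam_grid: np.ndarray,
    need_inner: bool,
) -> FoldFit:
    Xtr, Ytr = X[train_idx], Y[train_idx]
    xm, xs = _zstats(Xtr)
    ym, ys = _zstats(Ytr)
    n_targets = Y.shape[1]
    n_lam = len(lam_grid)

    if n_lam > 1 or need_inner:
        inner_preds = np.empty((n_lam, len(train_idx), n_targets))
        for itr, ival in scheme.inner_splits(train_idx):
            Xi, Yi = Xtr[itr], Ytr[itr]
            ixm, ixs = _zstats(Xi)
            iym, iys = _zstats(Yi)
            Ws = _ridge_path((Xi - ixm) / ixs, (Yi - iym) / iys, lam_grid)
            Zval = (Xtr[ival] - ixm) / ixs
            for li, W in enumerate(Ws):
                inner_preds[li, ival] = Zval @ W * iys + iym
        # inner score per (lambda, target); NaN (constant target) -> -inf
        scores = np.stack(
            [pearson_columns(inner_preds[li], Ytr) for li in range(n_lam)]
        )
        scores = np.where(np.isnan(scores), -np.inf, scores)
        lam_idx = scores.argmax(axis=0)
        inner_best = inner_preds[lam_idx, :, np.arange(n_targets)].T
    else:
        lam_idx = np.zeros(n_targets, dtype=int)
        inner_best = None

    # refit on the full training fold at each selected lambda
    Xz = (Xtr - xm) / xs
    Yz = (Ytr - ym) / ys
    Ztest = (X[test_idx] - xm) / xs
    test_pred = np.empty((len(test_idx), n_targets))
    for li in np.unique(lam_idx):
        cols = np.flatnonzero(lam_idx == li)
        W = _ridge_path(Xz, Yz[:, cols], lam_grid[li : li + 1])[0]
        test_pred[:, cols] = Ztest @ W * ys[cols] + ym[cols]
    return FoldFit(
        train_idx=train_idx,
        test_idx=test_idx,
        test_pred=test_pred,
        inner_pred=inner_best,
        lam=lam_grid[lam_idx],
        x_mean=xm,
        y_mean=ym,
        y_sd=ys,
    )


def cv_predict(
    X: np.ndarray,
    Y: np.ndarray,
    scheme: CVScheme,
    lam_grid=DEFAULT_LAMBDA_GRID,
    return_details: bool = False,
):
    """Out-of-fold predictions with per-target penalty chosen by inner CV.

    For each outer fold the penalty is selected per target on the
    training portion only (inner out-of-fold Pearson r), the model is
    refitted on the whole training fold at that penalty, and the held-out
    rows are predicted. Every row is predicted exactly once.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    lam_grid = np.asarray(list(lam_grid), dtype=float)
    if lam_grid.size == 0:
        raise ValueError("lam_grid must be non-empty")
    if (lam_grid < 0).any():
        raise ValueError("penalties must be nonnegative")
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    if X.shape[0] != scheme.n_videos:
        raise ValueError("scheme was built for a different number of videos")

    oof = np.empty_like(Y, dtype=float)
    details: list[FoldFit] = []
    for train_idx, test_idx in scheme.outer_splits():
        fit = _fit_one_fold(X, Y, train_idx, test_idx, scheme, lam_grid, return_details)
        oof[test_idx] = fit.test_pred
        if return_details:
            details.append(fit)
    if squeeze:
        oof = oof[:, 0]
    return (oof, details) if return_details else oof


@dataclass
class SignificanceThreshold:
    """A permutation-derived critical correlation with Bonferroni correction."""

    r_threshold: float
    alpha: float
    n_tests: int
    n_permutations: int
    n_samples: int

    def to_json(self) -> dict:
        return {
            "r_threshold": self.r_threshold,
            "alpha": self.alpha,
            "n_tests": self.n_tests,
            "n_permutations": self.n_permutations,
            "n_samples": self.n_samples,
        }


def permutation_threshold(
    reference: np.ndarray,
    n_perm: int,
    alpha: float = 0.01,
    n_tests: int = 1,
    seed: int | None = 0,
) -> SignificanceThreshold:
    """Critical |r| for a two-tailed permutation test at alpha / n_tests.

    Rows of ``reference`` (the true scores or measured responses) are
    permuted; the null |r| between each column and its permuted copy is
    pooled over permutations and the (1 - alpha/n_tests) quantile is the
    threshold. ``n_perm`` must resolve the Bonferroni-corrected tail
    (at least 10 / (alpha / n_tests) permutations).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be positive")
    tail = alpha / n_tests
    if n_perm < 10.0 / tail:
        raise ValueError(
            f"insufficient permutations: need at least {int(np.ceil(10 / tail))} "
            f"to resolve alpha/n_tests = {tail:g}"
        )
    ref = np.asarray(reference, dtype=float)
    if ref.ndim == 1:
        ref = ref[:, None]
    n, c = ref.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    sd = ref.std(axis=0)
    if (sd == 0).any():
        raise ValueError("undefined correlation: constant reference column")
    Z = (ref - ref.mean(axis=0)) / sd

    rng = np.random.default_rng(seed)
    abs_r = np.empty(n_perm * c)
    chunk = max(1, min(n_perm, int(4e7 / (n * c))))
    pos = 0
    if c == 1:
        z = Z[:, 0]
        for start in range(0, n_perm, chunk):
            m = min(chunk, n_perm - start)
            Zp = np.tile(z, (m, 1))
            rng.permuted(Zp, axis=1, out=Zp)
            abs_r[pos : pos + m] = np.abs(Zp @ z) / n
            pos += m
    else:
        for start in range(0, n_perm, chunk):
            m = min(chunk, n_perm - start)
            idx = np.tile(np.arange(n), (m, 1))
            rng.permuted(idx, axis=1, out=idx)
            for i in range(m):
                r = (Z[idx[i]] * Z).mean(axis=0)
                abs_r[pos : pos + c] = np.abs(r)
                pos += c
    thr = float(np.quantile(abs_r, 1.0 - tail))
    return SignificanceThreshold(
        r_threshold=thr,
        alpha=alpha,
        n_tests=n_tests,
        n_permutations=n_perm,
        n_samples=n,
    )


def normal_approx_threshold(n: int, alpha: float = 0.01, n_tests: int = 1) -> float:
    """Normal-approximation critical |r|: z_{1 - alpha/(2 m)} / sqrt(n - 1)."""
    z = stats.norm.ppf(1.0 - alpha / (2.0 * n_tests))
    return float(z / np.sqrt(n - 1))
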