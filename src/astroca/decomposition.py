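"""Activity-pattern decomposition across recordings: NMF and LDA.

Each recording is summarized by the concatenated per-threshold histograms
of the four event features (max_size, duration, distance, max_slope),
giving a nonnegative feature matrix X with one row per recording.  NMF
factorizes X ~ W H into k nonnegative components H (recurring activity
patterns) and per-recording weights W; k = 3 is the default, with a sweep
utility for k = 2..10.  LDA projects the same rows onto at most
(n_classes - 1) axes that maximize between-condition vs within-condition
scatter; within-class covariance shrinkage handles the wide, collinear
histogram space.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .feature_stats import FEATURES, FeatureHistogram

__all__ = [
    "FeatureMatrix",
    "FactorizationResult",
    "LdaProjection",
    "build_feature_matrix",
    "run_nmf",
    "sweep_k",
    "mean_component_weights",
    "match_components",
    "run_lda",
    "class_separation",
]

log = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Recordings x features matrix with row and column bookkeeping."""

    X: np.ndarray
    recording_ids: list[str]
    conditions: list[str]
    columns: list[str]

    def __post_init__(self) -> None:
        if np.any(self.X < 0):
            raise ValueError("feature matrix must be nonnegative")
        if self.X.shape != (len(self.recording_ids), len(self.columns)):
            raise ValueError("X shape inconsistent with labels")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, index=self.recording_ids, columns=self.columns)
        df.insert(0, "condition", self.conditions)
        return df


@dataclass
class FactorizationResult:
    """NMF weights W (recordings x k) and components H (k x features)."""

    W: np.ndarray
    H: np.ndarray
    k: int
    reconstruction_error: float
    seed: int

    def __post_init__(self) -> None:
        if np.any(self.W < 0) or np.any(self.H < 0):
            raise ValueError("NMF factors must be nonnegative")


@dataclass
class LdaProjection:
    """Discriminant coordinates of the recordings with class centroids."""

    coordinates: np.ndarray
    labels: list[str]
    classes: list[str]
    centroids: np.ndarray
    degenerate: bool = False


def build_feature_matrix(
    per_recording: list[tuple[str, str, dict[str, FeatureHistogram]]],
    normalization: str = "block_max",
    prune_zero_columns: bool = True,
) -> FeatureMatrix:
    """Concatenate per-recording (level x bin) histograms of the four features.

    ``per_recording`` holds (recording_id, condition, {feature: histogram})
    triples sharing bin edges and ladder.  ``normalization='block_max'``
    rescales each feature block so its column maximum is 1, preventing one
    feature from dominating by magnitude; ``'none'`` keeps raw frequencies.
    All-zero rows (recordings without events) are retained and flagged.
    """
    if normalization not in ("block_max", "none"):
        raise ValueError("normalization must be 'block_max' or 'none'")
    ref = per_recording[0][2]
    rows, ids, conds = [], [], []
    columns: list[str] = []
    for feat in FEATURES:
        h = ref[feat]
        for li, level in enumerate(h.levels):
            columns += [f"{feat}|L{level:g}|b{b:02d}" for b in range(h.freq.shape[1])]
    for rid, cond, hists in per_recording:
        blocks = []
        for feat in FEATURES:
            h = hists[feat]
            if h.freq.shape != ref[feat].freq.shape or not np.allclose(
                h.bin_edges, ref[feat].bin_edges
            ):
                raise ValueError(f"inconsistent binning for recording {rid}")
            blocks.append(h.freq.ravel())
        row = np.concatenate(blocks)
        if not row.any():
            log.warning("recording %s has zero events; all-zero row retained", rid)
        rows.append(row)
        ids.append(rid)
        conds.append(cond)
    X = np.asarray(rows, dtype=float)

    if normalization == "block_max":
        width = X.shape[1] // len(FEATURES)
        for b in range(len(FEATURES)):
            blk = X[:, b * width : (b + 1) * width]
            m = blk.max()
            if m > 0:
                blk /= m
    if prune_zero_columns:
        keep = X.any(axis=0)
        X = X[:, keep]
        columns = [c for c, k in zip(columns, keep) if k]
    return FeatureMatrix(X=X, recording_ids=ids, conditions=conds, columns=columns)


def _fit_once(X: np.ndarray, k: int, init, seed, W0=None, H0=None, max_iter=5000) -> NMF:
    model = NMF(
        n_components=k,
        init=init,
        solver="cd",
        tol=1e-12,
        max_iter=max_iter,
        random_state=seed,
    )
    with warnings.catch_warnings():
        # a fixed iteration budget per restart is intentional; the best
        # restart is selected by reconstruction error afterwards
        warnings.simplefilter("ignore", ConvergenceWarning)
        if init == "custom":
            model.fit(X, W=W0.copy(), H=H0.copy())
        else:
            model.fit(X)
    return model


def run_nmf(
    X: FeatureMatrix | np.ndarray,
    k: int = 3,
    seed: int = 0,
    restarts: int = 10,
    max_iter: int = 5000,
    init_W: np.ndarray | None = None,
    init_H: np.ndarray | None = None,
) -> FactorizationResult:
    """Best-of-restarts nonnegative factorization X ~ W H.

    One deterministic SVD-based (nndsvda) fit plus ``restarts - 1`` seeded
    random initializations; the fit with the smallest Frobenius
    reconstruction error wins.  Deterministic for a fixed seed.  An optional
    custom (W, H) initialization joins the pool (used for warm-started k
    sweeps).
    """
    arr = X.X if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    n, m = arr.shape
    if not 1 <= k <= min(n, m):
        raise ValueError(f"k must lie in [1, {min(n, m)}], got {k}")
    fits = [_fit_once(arr, k, "nndsvda", seed, max_iter=max_iter)]
    for r in range(max(0, restarts - 1)):
        fits.append(_fit_once(arr, k, "random", seed + 1 + r, max_iter=max_iter))
    if init_W is not None and init_H is not None:
        fits.append(
            _fit_once(arr, k, "custom", seed, W0=init_W, H0=init_H, max_iter=max_iter)
        )
    best = min(fits, key=lambda m_: m_.reconstruction_err_)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        W = best.transform(arr)
    return FactorizationResult(
        W=W,
        H=best.components_,
        k=k,
        reconstruction_error=float(np.linalg.norm(arr - W @ best.components_)),
        seed=seed,
    )


def sweep_k(
    X: FeatureMatrix | np.ndarray,
    ks=range(2, 11),
    seed: int = 0,
    restarts: int = 10,
) -> pd.DataFrame:
    """Reconstruction error across component counts.

    Each k is additionally warm-started from the previous k's solution
    (padded with a tiny extra component), so the best-of-restarts error is
    non-increasing in k up to solver tolerance.
    """
    arr = X.X if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    prev: FactorizationResult | None = None
    for k in ks:
        init_W = init_H = None
        if prev is not None and k == prev.k + 1:
            eps = 1e-6
            init_W = np.hstack([prev.W, eps * rng.random((arr.shape[0], 1))])
            init_H = np.vstack([prev.H, eps * rng.random((1, arr.shape[1]))])
        res = run_nmf(arr, k=k, seed=seed, restarts=restarts, init_W=init_W, init_H=init_H)
        rows.append(dict(k=k, reconstruction_error=res.reconstruction_error))
        prev = res
    return pd.DataFrame(rows)


def mean_component_weights(result: FactorizationResult, labels: list[str]) -> pd.DataFrame:
    """Per-condition mean (and SD) of each component's weights."""
    if len(labels) != result.W.shape[0]:
        raise ValueError("one label per recording row required")
    df = pd.DataFrame(result.W, columns=[f"comp{j+1}" for j in range(result.k)])
    df["condition"] = labels
    g = df.groupby("condition", sort=False)
    out = g.mean()
    for j in range(result.k):
        out[f"comp{j+1}_sd"] = g[f"comp{j+1}"].std()
    return out


def match_components(H_est: np.ndarray, H_true: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hungarian assignment of estimated to true components by cosine similarity.

    Returns (permutation, similarities): ``H_est[permutation[i]]`` matches
    ``H_true[i]``.  NMF is identifiable only up to permutation and scale, so
    recovery is judged on matched cosine similarity.
    """

    def _unit(a):
        n = np.linalg.norm(a, axis=1, keepdims=True)
        n[n == 0] = 1.0
        return a / n

    sim = _unit(np.asarray(H_true)) @ _unit(np.asarray(H_est)).T
    rows, cols = linear_sum_assignment(-sim)
    return cols, sim[rows, cols]


def run_lda(
    X: FeatureMatrix | np.ndarray,
    labels: list[str] | None = None,
    shrinkage: str | float = "auto",
) -> LdaProjection:
    """Supervised projection maximizing between- vs within-class scatter.

    Requires at least two classes with at least two recordings each; uses
    the eigen solver with within-class covariance shrinkage because the
    concatenated histogram space is typically wider than the number of
    recordings.  Near-zero between-class scatter is flagged degenerate.
    """
    if isinstance(X, FeatureMatrix):
        arr, labels = X.X, X.conditions if labels is None else labels
    else:
        arr = np.asarray(X, dtype=float)
    if labels is None:
        raise ValueError("labels are required")
    labels = list(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for cls, cnt in zip(classes, counts):
        if cnt < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 recordings")
    lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage=shrinkage)
    coords = lda.fit_transform(arr, labels)
    coords = coords[:, : len(classes) - 1]
    lab_arr = np.asarray(labels)
    centroids = np.stack([coords[lab_arr == c].mean(axis=0) for c in classes])
    dists = [np.linalg.norm(centroids[i] - centroids[j])
             for i in range(len(classes)) for j in range(i + 1, len(classes))]
    degenerate = max(dists) < 1e-9
    if degenerate:
        log.warning("run_lda: between-class scatter is numerically zero")
    return LdaProjection(
        coordinates=coords,
        labels=labels,
        classes=list(map(str, classes)),
        centroids=centroids,
        degenerate=degenerate,
    )


def class_separation(proj: LdaProjection) -> float:
    """Minimum pairwise centroid distance in units of within-class spread.

    The within-class spread is the RMS distance of recordings to their own
    class centroid in the discriminant space.
    """
    lab = np.asarray(proj.labels)
    sq = []
    for i, c in enumerate(proj.classes):
        d = proj.coordinates[lab == c] - proj.centroids[i]
        sq.append((d**2).sum(axis=1))
    within = float(np.sqrt(np.concatenate(sq).mean()))
    k = len(proj.classes)
    dmin = min(
        np.linalg.norm(proj.centroids[i] - proj.centroids[j])
        for i in range(k)
        for j in range(i + 1, k)
    )
    if within == 0:
        return np.inf if dmin > 0 else 0.0
    return float(dmin / within)
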