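"""Comparison imputers and the permuted negative control.

Two baselines are provided:

* **KNN** — for each query sample, the target-platform profile is the
  Gaussian-kernel-weighted average of the k nearest training samples in the
  source space (k and kernel width selected by 5-fold cross-validation; the
  reference operating points are k = 15 for Olink -> SomaScan and k = 30 for
  SomaScan -> Olink).

* **WNN/sPCA** — a weighted-nearest-neighbour pipeline in the style of
  Seurat v4: (1) PCA per modality (100 components); (2) a WNN graph whose
  per-sample modality weights reflect each modality's local neighbourhood
  predictive power, built from a union of 400 candidate neighbours per
  modality refined to a core of 40 weighted neighbours per sample with a
  1e-5 regulariser; (3) PCA of the WNN-smoothed data yields a supervised-PCA
  (sPCA) basis per platform; (4) a Gaussian-kernel regressor over the 50
  nearest training samples in source sPCA space predicts target values.

The permuted control destroys cross-platform dependence by row-shuffling one
modality while exactly preserving each modality's own covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA
from sklearn.model_selection import KFold

from .io_preprocess import PairedPlatformMatrix


@dataclass
class KnnConfig:
    k: int = 15
    bandwidth: float = 1.0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")


@dataclass
class WnnConfig:
    n_pcs: int = 100
    union_neighbors: int = 400
    core_neighbors: int = 40
    regularization: float = 1e-5
    regressor_neighbors: int = 50
    weight_neighbors: int = 20  # neighbourhood size for modality-weight learning

    def __post_init__(self) -> None:
        if self.core_neighbors > self.union_neighbors:
            raise ValueError("core neighbours cannot exceed union neighbours")
        if min(self.n_pcs, self.union_neighbors, self.core_neighbors,
               self.regressor_neighbors, self.weight_neighbors) < 1:
            raise ValueError("all WNN sizes must be positive")
        if self.regularization <= 0:
            raise ValueError("regularization must be positive")


# --------------------------------------------------------------------------
# KNN
# --------------------------------------------------------------------------


def knn_impute(
    x_query: np.ndarray,
    train_source: np.ndarray,
    train_target: np.ndarray,
    config: KnnConfig,
) -> np.ndarray:
    """Gaussian-kernel weighted average of the k nearest training targets.

    w_j = exp(-d_j^2 / (2 h^2)) over the k nearest training samples in
    source space; degenerate all-zero weights fall back to a uniform
    average over the k neighbours.
    """
    x_query = np.atleast_2d(np.asarray(x_query, dtype=np.float64))
    train_source = np.asarray(train_source, dtype=np.float64)
    train_target = np.asarray(train_target, dtype=np.float64)
    n_train = train_source.shape[0]
    if config.k > n_train:
        raise ValueError(f"k={config.k} exceeds training size {n_train}")
    d = cdist(x_query, train_source)
    nn_idx = np.argpartition(d, config.k - 1, axis=1)[:, : config.k]
    nn_d = np.take_along_axis(d, nn_idx, axis=1)
    w = np.exp(-(nn_d**2) / (2.0 * config.bandwidth**2))
    sums = w.sum(axis=1, keepdims=True)
    degenerate = (sums <= 0).ravel()
    if degenerate.any():
        w[degenerate] = 1.0
        sums = w.sum(axis=1, keepdims=True)
    w /= sums
    return np.einsum("qk,qkd->qd", w, train_target[nn_idx])


def median_neighbor_distance(train_source: np.ndarray) -> float:
    """Median over samples of the distance to their nearest other sample."""
    d = cdist(train_source, train_source)
    np.fill_diagonal(d, np.inf)
    return float(np.median(d.min(axis=1)))


def knn_cv(
    train_source: np.ndarray,
    train_target: np.ndarray,
    k_grid: Sequence[int] = (5, 15, 30, 60),
    bandwidth_multipliers: Sequence[float] = (0.5, 1.0, 2.0, 4.0),
    folds: int = 5,
    seed: int = 0,
) -> KnnConfig:
    """Select (k, h) by 5-fold CV, maximising the mean across folds of the
    median feature-wise Pearson r between imputed and held-fold targets.

    Candidate bandwidths are multiples of the median nearest-neighbour
    distance in the training source space.
    """
    from .evaluation import correlation_report

    train_source = np.asarray(train_source, dtype=np.float64)
    train_target = np.asarray(train_target, dtype=np.float64)
    base_h = median_neighbor_distance(train_source)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(train_source))
    best: tuple[float, KnnConfig] = (-np.inf, KnnConfig(k=int(k_grid[0]), bandwidth=base_h))
    for k in k_grid:
        for m in bandwidth_multipliers:
            cfg = KnnConfig(k=int(k), bandwidth=m * base_h)
            scores = []
            for tr, te in splits:
                if cfg.k > tr.size:
                    scores.append(-np.inf)
                    continue
                pred = knn_impute(train_source[te], train_source[tr], train_target[tr], cfg)
                rep = correlation_report(pred, train_target[te])
                scores.append(rep.median_feature_r)
            score = float(np.mean(scores))
            if score > best[0]:
                best = (score, cfg)
    return best[1]


# --------------------------------------------------------------------------
# WNN / sPCA
# --------------------------------------------------------------------------


@dataclass
class FittedWnn:
    config: WnnConfig
    modality_weights: np.ndarray  # N x 2 (A, B), rows sum to 1
    smoothing: np.ndarray  # N x N row-stochastic operator
    spca_mean: dict[str, np.ndarray] = field(default_factory=dict)
    spca_components: dict[str, np.ndarray] = field(default_factory=dict)
    train_embedding: dict[str, np.ndarray] = field(default_factory=dict)
    train_values: dict[str, np.ndarray] = field(default_factory=dict)
    regressor_bandwidth: dict[str, float] = field(default_factory=dict)


def _knn_indices(emb: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """k nearest neighbours (excluding self) and their distances."""
    d = cdist(emb, emb)
    np.fill_diagonal(d, np.inf)
    idx = np.argpartition(d, k - 1, axis=1)[:, :k]
    dist = np.take_along_axis(d, idx, axis=1)
    order = np.argsort(dist, axis=1)
    return np.take_along_axis(idx, order, axis=1), np.take_along_axis(dist, order, axis=1)


def _modality_weights(
    emb_a: np.ndarray, emb_b: np.ndarray, k: int, reg: float
) -> np.ndarray:
    """Per-sample modality weights from cross-modality neighbourhood
    prediction: a modality scores highly when its own neighbours predict the
    sample's embedding better than the other modality's neighbours do."""
    nn_a, d_a = _knn_indices(emb_a, k)
    nn_b, d_b = _knn_indices(emb_b, k)
    sigma_a = d_a[:, -1] + 1e-12
    sigma_b = d_b[:, -1] + 1e-12
    scores = np.empty((emb_a.shape[0], 2))
    for m, (emb, sigma, nn_within, nn_cross) in enumerate(
        [(emb_a, sigma_a, nn_a, nn_b), (emb_b, sigma_b, nn_b, nn_a)]
    ):
        pred_within = emb[nn_within].mean(axis=1)
        pred_cross = emb[nn_cross].mean(axis=1)
        d_within = np.linalg.norm(emb - pred_within, axis=1)
        d_cross = np.linalg.norm(emb - pred_cross, axis=1)
        aff_within = np.exp(-((d_within / sigma) ** 2))
        aff_cross = np.exp(-((d_cross / sigma) ** 2))
        scores[:, m] = aff_within / (aff_cross + reg)
    scores = scores - scores.max(axis=1, keepdims=True)  # stable softmax
    e = np.exp(scores)
    return e / e.sum(axis=1, keepdims=True)


def wnn_fit(train_a: np.ndarray, train_b: np.ndarray, config: WnnConfig = WnnConfig()) -> FittedWnn:
    """Fit the four-step WNN/sPCA imputation pipeline on paired training data."""
    train_a = np.asarray(train_a, dtype=np.float64)
    train_b = np.asarray(train_b, dtype=np.float64)
    n = train_a.shape[0]
    if train_b.shape[0] != n:
        raise ValueError("modalities must be sample-aligned")
    n_pcs = min(config.n_pcs, n - 1, train_a.shape[1], train_b.shape[1])
    if n_pcs < config.n_pcs:
        warnings.warn(f"n_pcs lowered from {config.n_pcs} to {n_pcs} for data of this size")
    if np.any(train_a.std(axis=0) == 0) or np.any(train_b.std(axis=0) == 0):
        raise ValueError("zero-variance feature; PCA is degenerate")

    # (1) initial PCA per modality
    pca_a = PCA(n_components=n_pcs, svd_solver="full").fit(train_a)
    pca_b = PCA(n_components=n_pcs, svd_solver="full").fit(train_b)
    emb_a = pca_a.transform(train_a)
    emb_b = pca_b.transform(train_b)

    # (2) modality weights and the core WNN graph
    k_w = min(config.weight_neighbors, n - 1)
    weights = _modality_weights(emb_a, emb_b, k_w, config.regularization)
    k_union = min(config.union_neighbors, n - 1)
    k_core = min(config.core_neighbors, k_union)
    nn_a, _ = _knn_indices(emb_a, k_union)
    nn_b, _ = _knn_indices(emb_b, k_union)
    d_a = cdist(emb_a, emb_a)
    d_b = cdist(emb_b, emb_b)
    sigma_a = np.partition(d_a, k_w, axis=1)[:, k_w] + 1e-12
    sigma_b = np.partition(d_b, k_w, axis=1)[:, k_w] + 1e-12
    smoothing = np.zeros((n, n))
    for i in range(n):
        cand = np.unique(np.concatenate([nn_a[i], nn_b[i], [i]]))
        theta = weights[i, 0] * np.exp(-((d_a[i, cand] / sigma_a[i]) ** 2)) + weights[
            i, 1
        ] * np.exp(-((d_b[i, cand] / sigma_b[i]) ** 2))
        keep = cand[np.argsort(-theta)[: min(k_core, cand.size)]]
        vals = (
            weights[i, 0] * np.exp(-((d_a[i, keep] / sigma_a[i]) ** 2))
            + weights[i, 1] * np.exp(-((d_b[i, keep] / sigma_b[i]) ** 2))
            + config.regularization
        )
        smoothing[i, keep] = vals / vals.sum()

    # (3) sPCA: PCA of the WNN-smoothed data, one basis per platform
    fitted = FittedWnn(config=config, modality_weights=weights, smoothing=smoothing)
    for tag, x in (("A", train_a), ("B", train_b)):
        smoothed = smoothing @ x
        spca = PCA(n_components=n_pcs, svd_solver="full").fit(smoothed)
        fitted.spca_mean[tag] = spca.mean_
        fitted.spca_components[tag] = spca.components_
        fitted.train_embedding[tag] = (x - spca.mean_) @ spca.components_.T
        fitted.train_values[tag] = x

    # (4) Gaussian-kernel regressor bandwidth: median distance to the
    # regressor_neighbors-th nearest training sample in source sPCA space
    k_reg = min(config.regressor_neighbors, n - 1)
    for tag in ("A", "B"):
        d = cdist(fitted.train_embedding[tag], fitted.train_embedding[tag])
        np.fill_diagonal(d, np.inf)
        kth = np.partition(d, k_reg - 1, axis=1)[:, k_reg - 1]
        fitted.regressor_bandwidth[tag] = float(np.median(kth)) + 1e-12
    return fitted


def wnn_impute(fitted: FittedWnn, x_query: np.ndarray, direction: str = "A2B") -> np.ndarray:
    """Project the query into source sPCA space and regress target values
    from the nearest training samples with Gaussian kernel weights."""
    key = direction.replace("->", "2").upper()
    if key not in ("A2B", "B2A"):
        raise ValueError("direction must be 'A2B' or 'B2A'")
    src, tgt = ("A", "B") if key == "A2B" else ("B", "A")
    x_query = np.atleast_2d(np.asarray(x_query, dtype=np.float64))
    emb_q = (x_query - fitted.spca_mean[src]) @ fitted.spca_components[src].T
    emb_t = fitted.train_embedding[src]
    k = min(fitted.config.regressor_neighbors, emb_t.shape[0])
    d = cdist(emb_q, emb_t)
    idx = np.argpartition(d, k - 1, axis=1)[:, :k]
    nn_d = np.take_along_axis(d, idx, axis=1)
    h = fitted.regressor_bandwidth[src]
    w = np.exp(-(nn_d**2) / (2.0 * h**2))
    sums = w.sum(axis=1, keepdims=True)
    bad = (sums <= 0).ravel()
    if bad.any():
        w[bad] = 1.0
        sums = w.sum(axis=1, keepdims=True)
    w /= sums
    return np.einsum("qk,qkd->qd", w, fitted.train_values[tgt][idx])


# --------------------------------------------------------------------------
# negative control
# --------------------------------------------------------------------------


def permuted_control(paired: PairedPlatformMatrix, seed: int = 0) -> PairedPlatformMatrix:
    """Row-shuffle platform B with a seeded permutation.

    Each modality's own covariance is preserved exactly while the
    cross-platform sample pairing is destroyed.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(paired.n_samples)
    return PairedPlatformMatrix(
        samples=list(paired.samples),
        platform_a=paired.platform_a.copy(),
        platform_b=paired.platform_b[perm],
        probes_a=list(paired.probes_a),
        probes_b=list(paired.probes_b),
        probe_map=list(paired.probe_map) if paired.probe_map else None,
    )
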