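"""Feature-pool reduction: PCA embedding of probes + k-means representatives.

Probes (rows) are standardised across samples, embedded by PCA, and clustered
with k-means.  Each cluster contributes the probe nearest its center, giving
a pool of representative probes for the downstream greedy search.  When k is
not given it is chosen at the knee of the distortion-vs-k curve ("elbow"),
evaluated on a grid of k values.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from sklearn.cluster import KMeans, MiniBatchKMeans
from sklearn.decomposition import PCA

from .matrix import ExpressionMatrix


@dataclasses.dataclass
class ReductionConfig:
    """Parameters of the reduction stage.

    ``n_components`` is either an integer component count or a fraction in
    (0, 1) interpreted as the variance fraction to capture (default 0.90).
    ``k_grid_step`` is the spacing of the elbow grid; the coarse default of
    500 keeps the number of clusterings manageable on genome-scale pools.
    Mini-batch k-means is used above ``minibatch_threshold`` clusters.
    """

    k_grid_step: int = 500
    k_max: int | None = None
    n_components: float | int = 0.90
    random_seed: int = 0
    minibatch_threshold: int = 5000
    minibatch_batch_size: int = 4096
    minibatch_max_iter: int = 5
    kmeans_n_init: int = 3

    def __post_init__(self) -> None:
        if self.k_grid_step < 1:
            raise ValueError("k_grid_step must be >= 1")
        if self.k_max is not None and self.k_max < self.k_grid_step:
            raise ValueError("k_max must be >= k_grid_step")


@dataclasses.dataclass
class ReductionResult:
    k_chosen: int
    representatives: list[str]
    cluster_assignment: dict[str, int]
    distortion_curve: list[tuple[int, float]]
    variance_captured: float


def elbow_select_k(distortion_curve: list[tuple[int, float]]) -> int:
    """Pick k at the knee: the grid point farthest from the chord joining the
    first and last curve points, after min-max normalising both axes.

    Ties are broken toward smaller k.  A distortion curve that increases with
    k beyond numerical tolerance triggers a warning.
    """
    if len(distortion_curve) < 3:
        raise ValueError("elbow selection needs at least 3 grid points")
    ks = np.array([k for k, _ in distortion_curve], dtype=float)
    ds = np.array([d for _, d in distortion_curve], dtype=float)
    if not (np.diff(ks) > 0).all():
        raise ValueError("grid k values must be strictly increasing")
    if (np.diff(ds) > 1e-9 * max(1.0, ds.max())).any():
        warnings.warn("distortion curve is not monotone non-increasing")
    # Normalise to the unit square so k and distortion are commensurate.
    kx = (ks - ks[0]) / (ks[-1] - ks[0])
    span = ds[0] - ds[-1]
    dy = (ds - ds[-1]) / span if span != 0 else np.zeros_like(ds)
    # Perpendicular distance from (kx, dy) to the chord (0, dy0)-(1, dyN).
    x1, y1, x2, y2 = kx[0], dy[0], kx[-1], dy[-1]
    dist = np.abs((y2 - y1) * kx - (x2 - x1) * dy + x2 * y1 - y2 * x1)
    dist /= np.hypot(y2 - y1, x2 - x1)
    best = int(np.argmax(dist))  # argmax returns the first (smallest-k) maximum
    return int(ks[best])


def _standardize_rows(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (values - mu) / sd


def _embed(matrix: ExpressionMatrix, config: ReductionConfig) -> tuple[np.ndarray, float, np.ndarray]:
    """PCA-embed probes as points; returns (embedding in probe-ID-sorted
    order, variance captured, argsort order)."""
    values = _standardize_rows(matrix.data.to_numpy(dtype=float))
    # Sort rows by probe ID before fitting so the result is invariant to the
    # row order of the input matrix.
    order = np.argsort(np.asarray(matrix.probe_ids, dtype=object))
    values = values[order]
    n_comp = config.n_components
    max_comp = min(values.shape) - 1 if min(values.shape) > 1 else 1
    if isinstance(n_comp, int):
        n_comp = min(n_comp, max_comp)
        pca = PCA(n_components=n_comp, random_state=config.random_seed)
    else:
        pca = PCA(n_components=min(float(n_comp), 1.0 - 1e-12), svd_solver="full")
    embedding = pca.fit_transform(values)
    return embedding, float(pca.explained_variance_ratio_.sum()), order


def _make_clusterer(k: int, config: ReductionConfig):
    if k > config.minibatch_threshold:
        # k-means++ seeding is quadratic in k; random init from data points
        # with a few mini-batch epochs is the tractable choice at this scale.
        return MiniBatchKMeans(
            n_clusters=k,
            init="random",
            n_init=1,
            batch_size=config.minibatch_batch_size,
            max_iter=config.minibatch_max_iter,
            max_no_improvement=5,
            reassignment_ratio=0.0,
            random_state=config.random_seed,
        )
    return KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=config.kmeans_n_init,
        random_state=config.random_seed,
    )


def compute_distortion_curve(
    matrix: ExpressionMatrix, ks: list[int], config: ReductionConfig | None = None
) -> list[tuple[int, float]]:
    """Within-cluster sum of squares (k-means inertia) at each grid k."""
    cfg = config or ReductionConfig()
    embedding, _, _ = _embed(matrix, cfg)
    curve = []
    for k in ks:
        km = _make_clusterer(k, cfg).fit(embedding)
        curve.append((int(k), float(km.inertia_)))
    return curve


def reduce_features(
    matrix: ExpressionMatrix,
    config: ReductionConfig | None = None,
    k: int | None = None,
) -> ReductionResult:
    """Cluster probes in PCA space and return one representative per cluster.

    The representative of a cluster is the member probe nearest (Euclidean,
    in PCA space) to the cluster center.  Clusters left empty by the
    clusterer are re-seeded from the unused probes farthest from their
    assigned centers, so exactly ``k`` representatives are always returned.
    """
    cfg = config or ReductionConfig()
    n = matrix.n_probes
    embedding, var_captured, order = _embed(matrix, cfg)
    sorted_probes = [matrix.probe_ids[i] for i in order]

    curve: list[tuple[int, float]] = []
    if k is None:
        step = cfg.k_grid_step
        k_hi = min(cfg.k_max if cfg.k_max is not None else n - 1, n - 1)
        ks = list(range(step, k_hi + 1, step))
        if len(ks) < 3:
            raise ValueError(
                f"elbow grid over k needs >=3 points (step {step}, max {k_hi}); "
                "pass k explicitly or shrink k_grid_step"
            )
        curve = compute_distortion_curve(matrix, ks, cfg)
        k = elbow_select_k(curve)
    if k < 1 or k > n:
        raise ValueError(f"k={k} out of range for {n} probes")

    km = _make_clusterer(k, cfg).fit(embedding)
    labels = km.predict(embedding)
    centers = km.cluster_centers_
    dist = np.linalg.norm(embedding - centers[labels], axis=1)

    # Nearest member per cluster: stable lexsort so ties go to the smaller
    # probe ID (rows are already probe-ID sorted).
    rep_idx = np.full(k, -1, dtype=int)
    sort = np.lexsort((np.arange(n), dist, labels))
    seen: set[int] = set()
    for i in sort:
        lab = labels[i]
        if lab not in seen:
            seen.add(lab)
            rep_idx[lab] = i
    empty = [c for c in range(k) if rep_idx[c] < 0]
    if empty:
        used = set(rep_idx[rep_idx >= 0])
        spare = [i for i in np.argsort(-dist, kind="stable") if i not in used]
        if len(spare) < len(empty):
            raise RuntimeError("cannot fill empty clusters: not enough probes")
        for c, i in zip(empty, spare):
            rep_idx[c] = i
            labels[i] = c
    if len(set(rep_idx.tolist())) != k:
        raise RuntimeError("representative extraction failed to produce k probes")

    representatives = [sorted_probes[i] for i in rep_idx]
    assignment = {sorted_probes[i]: int(labels[i]) for i in range(n)}
    if not curve:
        curve = [(int(k), float(km.inertia_))]
    return ReductionResult(
        k_chosen=int(k),
        representatives=representatives,
        cluster_assignment=assignment,
        distortion_curve=curve,
        variance_captured=var_captured,
    )
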