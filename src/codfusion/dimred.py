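"""Dimensionality reduction and CV-guided selection of Gabor features.

The 306,916 x 35 fluorescence feature matrix is treated as 35 samples (one
per Gabor kernel) of dimension 306,916; a manifold or projection method
embeds them into 20 components, giving a 20 x 35 reduced matrix.  Methods
are scored by the mean coefficient of variation across feature vectors,

    Cv_bar = (1/n) * sum_i  sd_i / |mean_i|        (population sd, n = 35)

the larger the Cv_bar, the more the extracted vectors differ and the more
representative the reduction.  The final 5 x 128 fluorescence feature block
keeps the 32 highest-Cv kernels (20 x 32 = 640 values, reshaped
kernel-major).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA, FastICA
from sklearn.manifold import LocallyLinearEmbedding, Isomap
from sklearn.random_projection import GaussianRandomProjection, SparseRandomProjection

#: methods ranked by default; GRP is available but excluded from rankings
DEFAULT_METHODS = ("PCA", "FastICA", "Isomap", "LLE", "SRP")
ALL_METHODS = ("PCA", "FastICA", "Isomap", "LLE", "GRP", "SRP")
N_COMPONENTS = 20
N_KERNELS_KEPT = 32
# 10 neighbors on 35 kernel samples often leaves the 20-component geodesic
# kernel with a non-PSD tail (sklearn rejects it); 15 keeps the requested
# spectrum positive while staying local relative to the 35 samples
ISOMAP_N_NEIGHBORS = 15


@dataclass(frozen=True)
class ReducedFeatureMatrix:
    matrix: np.ndarray           # (n_components, n_kernels), default 20 x 35
    method: str
    seed: int | None = None


@dataclass(frozen=True)
class CvReport:
    method: str
    cv: np.ndarray               # per-feature-vector Cv
    cv_bar: float
    seconds: float               # wall time, informational
    seed: int | None = None


@dataclass(frozen=True)
class FluorescenceFeatureBlock:
    """The 5 x 128 block fed to the fusion network, with its kernel selection."""

    matrix: np.ndarray           # (5, 128)
    kept_kernels: np.ndarray     # indices of the 32 kernels kept

    def __post_init__(self) -> None:
        if self.matrix.size != 640:
            raise ValueError("feature block must hold exactly 640 elements")


def _make_estimator(method: str, n_components: int, seed: int | None):
    if method == "PCA":
        # full SVD: the 'auto' solver picks randomized SVD at these shapes,
        # which is not deterministic without a seed
        return PCA(n_components=n_components, svd_solver="full")
    if method == "FastICA":
        return FastICA(n_components=n_components, random_state=seed,
                       whiten="unit-variance", max_iter=1000)
    if method == "Isomap":
        return Isomap(n_components=n_components, n_neighbors=ISOMAP_N_NEIGHBORS)
    if method == "LLE":
        return LocallyLinearEmbedding(n_components=n_components,
                                      n_neighbors=ISOMAP_N_NEIGHBORS,
                                      random_state=seed)
    if method == "GRP":
        return GaussianRandomProjection(n_components=n_components, random_state=seed)
    if method == "SRP":
        return SparseRandomProjection(n_components=n_components, random_state=seed)
    raise ValueError(f"unknown reduction method {method!r}")


def reduce(matrix: np.ndarray, method: str = "Isomap",
           n_components: int = N_COMPONENTS, seed: int = 0) -> ReducedFeatureMatrix:
    """Embed the kernel columns of a (pixels x kernels) matrix.

    Columns are the samples; the embedding is returned transposed as
    components x kernels (default 20 x 35).  PCA/Isomap/LLE are
    deterministic given the input; FastICA/GRP/SRP are seeded.
    """
    X = np.asarray(matrix, dtype=float).T        # (n_kernels, n_pixels)
    n_samples = X.shape[0]
    if n_components >= n_samples:
        raise ValueError(
            f"n_components={n_components} must be < sample count {n_samples}")
    est = _make_estimator(method, n_components, seed)
    try:
        emb = est.fit_transform(X)               # (n_kernels, n_components)
    except Exception as exc:  # pragma: no cover - guidance path
        if method == "Isomap":
            raise RuntimeError(
                "Isomap failed (possibly disconnected neighborhood graph); "
                "try raising n_neighbors"
            ) from exc
        raise
    return ReducedFeatureMatrix(matrix=emb.T, method=method, seed=seed)


def mean_cv(reduced: ReducedFeatureMatrix | np.ndarray,
            method: str = "", seconds: float = 0.0) -> CvReport:
    """Mean coefficient of variation over the feature-vector columns.

    Per column: population standard deviation / |mean|; columns with
    |mean| < 1e-12 contribute 0.
    """
    if isinstance(reduced, ReducedFeatureMatrix):
        m, method = reduced.matrix, reduced.method
        seed = reduced.seed
    else:
        m, seed = np.asarray(reduced, dtype=float), None
    if m.size == 0:
        raise ValueError("empty matrix")
    mu = m.mean(axis=0)
    sd = m.std(axis=0)           # population form
    cv = np.where(np.abs(mu) < 1e-12, 0.0, sd / np.abs(np.where(mu == 0, 1.0, mu)))
    return CvReport(method=method, cv=cv, cv_bar=float(cv.mean()),
                    seconds=seconds, seed=seed)


def compare_methods(matrix: np.ndarray, methods=DEFAULT_METHODS,
                    n_components: int = N_COMPONENTS, seed: int = 0) -> list[CvReport]:
    """Reduce with each method, score by Cv_bar, rank descending.

    Individual method failures are recorded as reports with NaN Cv_bar
    rather than aborting the comparison.
    """
    if not methods:
        raise ValueError("need at least one method")
    reports = []
    for method in methods:
        t0 = time.perf_counter()
        try:
            red = reduce(matrix, method=method, n_components=n_components, seed=seed)
            rep = mean_cv(red, seconds=time.perf_counter() - t0)
        except Exception:
            rep = CvReport(method=method, cv=np.array([]), cv_bar=float("nan"),
                           seconds=time.perf_counter() - t0, seed=seed)
        reports.append(rep)
    return sorted(reports, key=lambda r: (-r.cv_bar if np.isfinite(r.cv_bar) else np.inf))


def select_and_reshape(reduced: ReducedFeatureMatrix) -> FluorescenceFeatureBlock:
    """Keep the 32 highest-Cv kernels of a 20 x 35 matrix; reshape to 5 x 128.

    The selected 20 x 32 submatrix is flattened kernel-major (each kernel's
    20 components contiguous) and reshaped row-wise into 5 x 128 — a
    bijection between the 640 selected entries and the block.
    """
    m = reduced.matrix
    n_comp, n_kernels = m.shape
    if n_kernels < N_KERNELS_KEPT:
        raise ValueError(f"need >= {N_KERNELS_KEPT} kernel columns, got {n_kernels}")
    if n_kernels == N_KERNELS_KEPT:
        kept = np.arange(n_kernels)
    else:
        cv = mean_cv(reduced).cv
        kept = np.sort(np.argsort(cv)[::-1][:N_KERNELS_KEPT])
    sel = m[:, kept]                              # (20, 32)
    flat = sel.T.reshape(-1)                      # kernel-major, 640 values
    return FluorescenceFeatureBlock(matrix=flat.reshape(5, 128), kept_kernels=kept)


def reduce_collection(matrices: list[np.ndarray], method: str = "Isomap",
                      n_components: int = N_COMPONENTS,
                      seed: int = 0) -> list[ReducedFeatureMatrix]:
    """Embed several EEMs' kernel columns with one shared model.

    Manifold embeddings fit per EEM have arbitrary orientation (sign,
    rotation), so independently reduced matrices are not comparable across
    EEMs.  Fitting a single estimator on the pooled kernel vectors of all
    EEMs and transforming each EEM's 35 columns through it puts every
    reduced matrix in one coordinate system — required when blocks from
    different EEMs are interpolated against each other downstream.
    """
    if not matrices:
        raise ValueError("need at least one feature matrix")
    Xs = [np.asarray(m, dtype=np.float32).T for m in matrices]  # (35, pixels) each
    pooled = np.concatenate(Xs, axis=0)
    if n_components >= pooled.shape[0]:
        raise ValueError("n_components must be < pooled sample count")
    est = _make_estimator(method, n_components, seed)
    est.fit(pooled)
    return [ReducedFeatureMatrix(matrix=est.transform(X).T, method=method, seed=seed)
            for X in Xs]


def blocks_for_collection(
    reduced: list[ReducedFeatureMatrix],
) -> list[FluorescenceFeatureBlock]:
    """5 x 128 blocks with one shared kernel selection for the whole collection.

    Kernels are ranked by their Cv averaged over the collection so every
    block keeps the same 32 kernels in the same order.
    """
    if not reduced:
        raise ValueError("empty collection")
    n_kernels = reduced[0].matrix.shape[1]
    if n_kernels == N_KERNELS_KEPT:
        kept = np.arange(n_kernels)
    else:
        cv_sum = np.zeros(n_kernels)
        for r in reduced:
            cv_sum += mean_cv(r).cv
        kept = np.sort(np.argsort(cv_sum)[::-1][:N_KERNELS_KEPT])
    out = []
    for r in reduced:
        sel = r.matrix[:, kept]
        out.append(FluorescenceFeatureBlock(matrix=sel.T.reshape(-1).reshape(5, 128),
                                            kept_kernels=kept))
    return out


def unreshape_block(block: FluorescenceFeatureBlock,
                    n_components: int = N_COMPONENTS) -> np.ndarray:
    """Invert select_and_reshape's flatten: recover the selected 20 x 32 matrix."""
    return block.matrix.reshape(-1).reshape(N_KERNELS_KEPT, n_components).T
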