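"""CAP estimation: PCA reduction, consensus clustering with PAC, k-means,
back-reconstruction and map thresholding.

Pooled high-amplitude frames are reduced by PCA to the smallest number of
components reaching a cumulative explained-variance target (default 0.90).
The number of clusters K is chosen by consensus clustering: for each candidate
K, k-means is run on many random frame subsamples and the consensus matrix
records how often each frame pair co-clusters when co-sampled.  The proportion
of ambiguously clustered pairs (PAC) is the fraction of off-diagonal consensus
entries falling strictly inside the ambiguity interval (0.1, 0.9); stability is
1 - PAC and the K maximising stability wins (ties to the smaller K).  Final
frame labels come from k-means with k-means++ initialisation, best of 20
restarts; cluster centroids are mapped back to voxel space by multiplying the
component-space centroids with the transposed eigenvectors and adding the mean.
Each CAP map is then z-scored across voxels and thresholded at |z| >= 1.04
(the 15% most positive / most negative voxels under normality) to define its
suprathreshold voxel sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from ._errors import ConfigurationError, DegenerateDataError
from .preprocess import FrameSet

#: Map display / overlap threshold: the standard-normal 85th percentile
#: rounded to two decimals (15% tails).
MAP_Z_THRESHOLD = 1.04

#: PAC ambiguity interval (open): consensus entries strictly inside count as
#: ambiguous.
PAC_BOUNDS = (0.1, 0.9)


@dataclass
class ReducedData:
    """PCA-reduced pooled frames with everything needed to go back.

    ``scores`` is frames x components, ``eigenvectors`` voxels x components
    (orthonormal columns), ``mean_map`` the per-voxel mean removed before
    projection.
    """

    scores: np.ndarray
    eigenvectors: np.ndarray
    mean_map: np.ndarray
    explained_variance_fraction: float

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass
class ConsensusResult:
    """Consensus matrices, PAC and stability per candidate K."""

    k_range: list[int]
    consensus: dict[int, np.ndarray]
    pac: dict[int, float]
    chosen_k: int

    @property
    def stability(self) -> dict[int, float]:
        return {k: 1.0 - v for k, v in self.pac.items()}


@dataclass
class CapSet:
    """K back-reconstructed, voxelwise z-scored CAP maps plus bookkeeping.

    CAPs are numbered 1..K by descending cluster size.  ``pos_voxels`` /
    ``neg_voxels`` are the suprathreshold voxel index sets at the +-1.04
    z threshold (seed voxels removed when requested); ``occupancy_pct`` is the
    percentage of assigned frames per CAP.
    """

    k: int
    maps: np.ndarray  # (K, n_voxels), z-scored across voxels
    assignments: np.ndarray  # per-pooled-frame CAP label in 1..K
    pos_voxels: list[np.ndarray]
    neg_voxels: list[np.ndarray]
    occupancy_pct: np.ndarray
    z_threshold: float = MAP_Z_THRESHOLD
    seed_voxel_ids: np.ndarray | None = None


def pool_frames(frame_sets: list[FrameSet]) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-subject FrameSets into one matrix.

    Returns ``(frames, subject_index)`` where ``subject_index[i]`` is the
    position in ``frame_sets`` contributing pooled row i.
    """
    nonempty = [(i, fs) for i, fs in enumerate(frame_sets) if fs.n_selected > 0]
    if not nonempty:
        raise DegenerateDataError("no selected frames in any subject")
    frames = np.vstack([fs.frames for _, fs in nonempty])
    subject_index = np.concatenate(
        [np.full(fs.n_selected, i) for i, fs in nonempty]
    )
    return frames, subject_index


def reduce_pca(frames: np.ndarray, variance_target: float = 0.90) -> ReducedData:
    """PCA keeping the fewest components whose cumulative EV >= target."""
    if not 0 < variance_target <= 1:
        raise ConfigurationError("variance_target must be in (0, 1]")
    frames = np.asarray(frames, dtype=float)
    if frames.shape[0] < 2 or frames.shape[1] < 2:
        raise ConfigurationError("need at least 2 frames and 2 voxels for PCA")
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(frames)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_keep = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    n_keep = min(n_keep, scores.shape[1])
    return ReducedData(
        scores=scores[:, :n_keep],
        eigenvectors=pca.components_[:n_keep].T,
        mean_map=pca.mean_,
        explained_variance_fraction=float(cum[n_keep - 1]),
    )


def pac_score(
    consensus: np.ndarray,
    bounds: tuple[float, float] = PAC_BOUNDS,
    valid: np.ndarray | None = None,
) -> float:
    """Proportion of ambiguously clustered pairs.

    The fraction of off-diagonal consensus entries strictly inside the open
    ambiguity interval.  ``valid`` marks entries whose pair was co-sampled at
    least once; never-co-sampled pairs are excluded from the denominator.
    """
    n = consensus.shape[0]
    iu = np.triu_indices(n, 1)
    c = consensus[iu]
    if valid is not None:
        ok = valid[iu]
        if not ok.any():
            raise DegenerateDataError("no co-sampled frame pairs")
        c = c[ok]
    lo, hi = bounds
    return float(np.mean((c > lo) & (c < hi)))


def consensus_cluster(
    reduced: ReducedData,
    k_range: range | list[int] = range(2, 9),
    n_iter: int = 100,
    subsample_fraction: float = 0.8,
    rng_seed: int = 0,
    bounds: tuple[float, float] = PAC_BOUNDS,
) -> ConsensusResult:
    """Choose K by subsampled k-means consensus and PAC stability.

    For each candidate K, ``n_iter`` k-means runs (single k-means++ init each,
    so genuine multi-modality of the solution shows up as ambiguity) are fit on
    random ``subsample_fraction`` frame subsets.  consensus[i, j] =
    co-cluster count / co-sample count.  chosen_k maximises 1 - PAC, ties to
    the smaller K.
    """
    k_range = sorted(k_range)
    n = reduced.scores.shape[0]
    sub_n = int(round(subsample_fraction * n))
    if sub_n < max(k_range):
        raise ConfigurationError(
            f"subsample of {sub_n} frames cannot support k={max(k_range)}"
        )
    rng = np.random.default_rng(rng_seed)
    consensus: dict[int, np.ndarray] = {}
    pac: dict[int, float] = {}
    x = reduced.scores.astype(np.float64)
    for k in k_range:
        together = np.zeros((n, n), dtype=np.float32)
        sampled = np.zeros((n, n), dtype=np.float32)
        for _ in range(n_iter):
            idx = rng.choice(n, size=sub_n, replace=False)
            km = KMeans(
                n_clusters=k,
                n_init=1,
                random_state=int(rng.integers(0, 2**31 - 1)),
            ).fit(x[idx])
            labels = km.labels_
            same = (labels[:, None] == labels[None, :]).astype(np.float32)
            ij = np.ix_(idx, idx)
            together[ij] += same
            sampled[ij] += 1.0
        valid = sampled > 0
        mat = np.zeros((n, n))
        mat[valid] = together[valid] / sampled[valid]
        np.fill_diagonal(mat, 1.0)
        mat = (mat + mat.T) / 2.0
        if not valid.all():
            n_missing = int((~valid[np.triu_indices(n, 1)]).sum())
            warnings.warn(
                f"K={k}: {n_missing} frame pair(s) never co-sampled; "
                "excluded from PAC",
                stacklevel=2,
            )
        consensus[k] = mat
        pac[k] = pac_score(mat, bounds, valid=valid)
    stability = {k: 1.0 - pac[k] for k in k_range}
    chosen_k = max(k_range, key=lambda k: (stability[k], -k))
    return ConsensusResult(list(k_range), consensus, pac, chosen_k)


def cluster_frames(
    reduced: ReducedData, k: int, rng_seed: int = 0, n_restarts: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """k-means in component space; labels 1..K by descending cluster size.

    Best of ``n_restarts`` k-means++ runs by inertia.  Returns
    ``(labels, centroids)`` with centroids ordered to match the labels.
    """
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    for attempt in range(5):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=rng_seed + attempt)
        raw = km.fit_predict(reduced.scores)
        sizes = np.bincount(raw, minlength=k)
        if (sizes > 0).all():
            break
    else:
        raise DegenerateDataError("k-means produced an empty cluster in 5 attempts")
    # stable relabel: descending size, ties by original label
    order = np.lexsort((np.arange(k), -sizes))
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = relabel[raw]
    centroids = km.cluster_centers_[order]
    return labels, centroids


def back_reconstruct(reduced: ReducedData, centroids: np.ndarray) -> np.ndarray:
    """Map component-space centroids back to voxel space.

    map_c = centroid_c @ eigenvectors.T + mean_map.
    """
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    if centroids.shape[1] != reduced.n_components:
        raise ConfigurationError(
            f"centroids have {centroids.shape[1]} components, expected "
            f"{reduced.n_components}"
        )
    return centroids @ reduced.eigenvectors.T + reduced.mean_map


def finalize_caps(
    maps: np.ndarray,
    assignments: np.ndarray,
    z_threshold: float = MAP_Z_THRESHOLD,
    seed_voxel_ids: np.ndarray | None = None,
) -> CapSet:
    """Z-score maps across voxels, threshold, and compute occupancies.

    pos_voxels = {z >= +threshold}, neg_voxels = {z <= -threshold}; seed
    voxels are removed from both sets when given.  Occupancy percentages are
    over assigned frames and sum to 100.
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    k = maps.shape[0]
    z = maps - maps.mean(axis=1, keepdims=True)
    sd = z.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    z = z / sd
    seed = (
        np.asarray(seed_voxel_ids, dtype=int)
        if seed_voxel_ids is not None
        else np.array([], dtype=int)
    )
    pos, neg = [], []
    for c in range(k):
        p = np.setdiff1d(np.flatnonzero(z[c] >= z_threshold), seed)
        m = np.setdiff1d(np.flatnonzero(z[c] <= -z_threshold), seed)
        pos.append(p)
        neg.append(m)
    assignments = np.asarray(assignments, dtype=int)
    counts = np.array([(assignments == c).sum() for c in range(1, k + 1)], dtype=float)
    total = counts.sum()
    occupancy = 100.0 * counts / total if total else counts
    return CapSet(
        k=k,
        maps=z,
        assignments=assignments,
        pos_voxels=pos,
        neg_voxels=neg,
        occupancy_pct=occupancy,
        z_threshold=z_threshold,
        seed_voxel_ids=seed if seed.size else None,
    )


@dataclass
class CapDerivation:
    """Full output of :func:`derive_caps` for one cohort."""

    cap_set: CapSet
    reduced: ReducedData
    consensus: ConsensusResult | None
    pooled_frames: np.ndarray
    subject_index: np.ndarray


def derive_caps(
    frame_sets: list[FrameSet],
    k: int | None = None,
    variance_target: float = 0.90,
    k_range: range | list[int] = range(2, 9),
    n_iter: int = 100,
    subsample_fraction: float = 0.8,
    rng_seed: int = 0,
    z_threshold: float = MAP_Z_THRESHOLD,
    seed_voxel_ids: np.ndarray | None = None,
) -> CapDerivation:
    """Pool frames, reduce, (optionally) select K by consensus, and build CAPs."""
    frames, subject_index = pool_frames(frame_sets)
    reduced = reduce_pca(frames, variance_target)
    consensus = None
    if k is None:
        consensus = consensus_cluster(
            reduced, k_range, n_iter, subsample_fraction, rng_seed
        )
        k = consensus.chosen_k
    labels, centroids = cluster_frames(reduced, k, rng_seed)
    maps = back_reconstruct(reduced, centroids)
    cap_set = finalize_caps(maps, labels, z_threshold, seed_voxel_ids)
    return CapDerivation(cap_set, reduced, consensus, frames, subject_index)
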