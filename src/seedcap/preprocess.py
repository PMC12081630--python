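"""Motion scrubbing, voxelwise z-scoring and high-amplitude seed-frame selection.

The entry point for a single subject is :func:`preprocess_subject`, which takes a
masked BOLD matrix plus its rigid-body motion trace and returns the set of
z-scored frames in which the seed region was highly active.  Those frames are
what CAP estimation clusters.

Processing order: framewise displacement (FD) is computed from the six motion
parameters; frames with FD above the scrubbing threshold (default 0.5 mm) are
censored and subjects with more than 30% censored frames are excluded; voxel
time courses are z-scored using moments from the retained frames only; the seed
score (mean z over the seed sphere, re-standardised over retained frames) gates
frame selection at z > 0.84, the 80th percentile of a standard normal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._errors import ConfigurationError, DegenerateDataError, FormatError

logger = logging.getLogger(__name__)

#: Rotation-to-arc-length radius for FD, in mm (Power-style criterion).
FD_ROTATION_RADIUS_MM = 50.0

#: Default scrubbing threshold: frames with FD strictly above this are censored.
FD_THRESHOLD_MM = 0.5

#: Subjects with more than this fraction of censored frames are excluded.
MAX_CENSORED_FRACTION = 0.30

#: Seed-score threshold for "high-amplitude" frames: the standard-normal 80th
#: percentile rounded to two decimals.
FRAME_SELECTION_Z = 0.84


@dataclass
class Bold4D:
    """Grey-matter-masked BOLD data for one subject.

    Parameters
    ----------
    data
        ``(n_voxels, n_frames)`` real matrix, one row per in-mask voxel.
    mask
        Boolean 3-D array; ``data`` rows correspond to ``np.flatnonzero(mask)``
        in C order.
    affine
        4x4 voxel-to-world (mm) affine.
    tr_seconds
        Repetition time in seconds.
    degenerate_voxels
        Indices (into the masked rows) of voxels flagged as zero-variance
        during z-scoring.  Empty before z-scoring.
    """

    data: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    tr_seconds: float
    degenerate_voxels: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise FormatError("BOLD data must be a (n_voxels, n_frames) matrix")
        if np.isnan(self.data).any():
            raise FormatError("BOLD data contain NaNs after masking")
        if int(self.mask.sum()) != self.data.shape[0]:
            raise FormatError(
                f"mask has {int(self.mask.sum())} voxels but data has "
                f"{self.data.shape[0]} rows"
            )

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    def voxel_coords_mm(self) -> np.ndarray:
        """World (mm) coordinates of in-mask voxel centres, ``(n_voxels, 3)``."""
        ijk = np.argwhere(self.mask)
        hom = np.c_[ijk, np.ones(len(ijk))]
        return (hom @ self.affine.T)[:, :3]


@dataclass
class MotionTrace:
    """Six rigid-body motion parameters per frame.

    ``params`` columns are ``trans_x, trans_y, trans_z`` in mm followed by
    ``rot_x, rot_y, rot_z`` in radians.
    """

    params: np.ndarray
    fd_threshold_mm: float = FD_THRESHOLD_MM
    exclusion_fraction: float = MAX_CENSORED_FRACTION

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise FormatError("motion parameters must have 6 columns")

    @property
    def fd(self) -> np.ndarray:
        return compute_fd(self.params)


@dataclass
class SeedDefinition:
    """A spherical seed region in world coordinates.

    The default centre is the right temporo-parietal junction (rTPJ),
    MNI [62, -34, 30]; the left homologue is [-62, -34, 30].  A pre-resolved
    ``voxel_ids`` set bypasses the sphere lookup entirely.
    """

    center_mm: tuple[float, float, float] = (62.0, -34.0, 30.0)
    radius_mm: float = 10.0
    voxel_ids: np.ndarray | None = None

    def resolve(self, bold: Bold4D) -> np.ndarray:
        """Return indices (into the masked rows) of seed voxels.

        Voxels whose centre lies within ``radius_mm`` (Euclidean, mm) of the
        sphere centre are included.
        """
        if self.voxel_ids is not None:
            ids = np.asarray(self.voxel_ids, dtype=int)
            if ids.size == 0 or ids.min() < 0 or ids.max() >= bold.n_voxels:
                raise ConfigurationError("explicit seed voxel_ids outside the mask")
            return ids
        coords = bold.voxel_coords_mm()
        d = np.linalg.norm(coords - np.asarray(self.center_mm), axis=1)
        ids = np.flatnonzero(d <= self.radius_mm)
        if ids.size == 0:
            raise ConfigurationError(
                f"seed sphere at {self.center_mm} (r={self.radius_mm} mm) contains "
                "no grey-matter voxels"
            )
        return ids


@dataclass
class FrameSet:
    """High-amplitude frames selected for one subject.

    ``frames`` holds z-scored values, one row per selected frame;
    ``frame_index`` maps rows back to original time indices.
    """

    frames: np.ndarray
    frame_index: np.ndarray
    subject_id: str
    n_frames: int
    n_censored: int

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        if self.frame_index.size and np.any(np.diff(self.frame_index) <= 0):
            raise FormatError("frame_index must be strictly increasing")
        if self.frames.shape[0] != self.frame_index.size:
            raise FormatError("frames rows and frame_index length differ")

    @property
    def n_selected(self) -> int:
        return int(self.frame_index.size)


def compute_fd(params: np.ndarray, rotation_radius_mm: float = FD_ROTATION_RADIUS_MM) -> np.ndarray:
    """Framewise displacement in mm from six rigid-body parameters.

    FD at frame t is the sum of absolute backward differences of the three
    translations (mm) plus the rotation differences (radians) converted to arc
    length on a sphere of ``rotation_radius_mm`` (default 50 mm).  The first
    frame has no predecessor; fd[0] = 0.
    """
    params = np.asarray(params, dtype=float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise FormatError("motion parameters must be (n_frames, 6)")
    if params.shape[0] < 2:
        raise FormatError("FD needs at least two frames")
    d = np.abs(np.diff(params, axis=0))
    fd = d[:, :3].sum(axis=1) + rotation_radius_mm * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def scrub_and_screen(
    fd: np.ndarray,
    threshold_mm: float = FD_THRESHOLD_MM,
    max_fraction: float = MAX_CENSORED_FRACTION,
) -> tuple[np.ndarray, bool]:
    """Censor high-motion frames and decide whether to keep the subject.

    Frames with FD strictly greater than ``threshold_mm`` are censored; the
    subject is excluded iff the censored fraction strictly exceeds
    ``max_fraction``.  Returns ``(censored_indices, keep)``.
    """
    fd = np.asarray(fd, dtype=float)
    censored = np.flatnonzero(fd > threshold_mm)
    keep = censored.size / fd.size <= max_fraction
    return censored, keep


def zscore_voxelwise(bold: Bold4D, censored: np.ndarray) -> Bold4D:
    """Temporally z-score each voxel using moments of the retained frames.

    Censored frames are excluded from the mean/SD estimates (they are still
    transformed, but never used downstream).  Zero-variance voxels are flagged
    degenerate and set to zero with a warning.
    """
    retained = np.setdiff1d(np.arange(bold.n_frames), np.asarray(censored, dtype=int))
    if retained.size < 3:
        raise DegenerateDataError("fewer than 3 retained frames; cannot z-score")
    sub = bold.data[:, retained]
    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=0, keepdims=True)
    degenerate = np.flatnonzero(sd[:, 0] == 0)
    if degenerate.size:
        warnings.warn(
            f"{degenerate.size} zero-variance voxel(s) flagged degenerate and zeroed",
            stacklevel=2,
        )
        sd[degenerate] = 1.0
    z = (bold.data - mean) / sd
    z[degenerate] = 0.0
    return Bold4D(
        data=z,
        mask=bold.mask,
        affine=bold.affine,
        tr_seconds=bold.tr_seconds,
        degenerate_voxels=degenerate,
    )


def extract_seed_signal(
    bold_z: Bold4D, seed_ids: np.ndarray, censored: np.ndarray
) -> np.ndarray:
    """Per-frame seed score: mean z over seed voxels, re-standardised.

    Re-standardisation (mean 0, SD 1) uses retained frames only, so the
    selection threshold is on the same scale regardless of sphere size.
    """
    seed_ids = np.asarray(seed_ids, dtype=int)
    if seed_ids.size == 0:
        raise ConfigurationError("empty seed after masking")
    raw = bold_z.data[seed_ids].mean(axis=0)
    retained = np.setdiff1d(np.arange(bold_z.n_frames), np.asarray(censored, dtype=int))
    mu = raw[retained].mean()
    sd = raw[retained].std(ddof=0)
    if sd == 0:
        raise DegenerateDataError("seed score has zero variance over retained frames")
    return (raw - mu) / sd


def select_active_frames(
    bold_z: Bold4D,
    seed_score: np.ndarray,
    censored: np.ndarray,
    threshold_z: float = FRAME_SELECTION_Z,
    subject_id: str = "",
    empirical_percentile: float | None = None,
) -> FrameSet:
    """Select retained frames whose seed score exceeds the threshold.

    With the default fixed threshold, frames with standardized seed score
    strictly above ``threshold_z`` (= 0.84, the standard-normal 80th
    percentile) are kept.  Passing ``empirical_percentile`` (e.g. 80) instead
    thresholds at that per-subject empirical percentile of the retained-frame
    scores.
    """
    censored = np.asarray(censored, dtype=int)
    retained_mask = np.ones(bold_z.n_frames, dtype=bool)
    retained_mask[censored] = False
    if empirical_percentile is not None:
        threshold_z = float(np.percentile(seed_score[retained_mask], empirical_percentile))
    selected = np.flatnonzero(retained_mask & (seed_score > threshold_z))
    if selected.size == 0:
        warnings.warn(
            f"subject {subject_id!r}: no frames above seed threshold; "
            "subject contributes nothing",
            stacklevel=2,
        )
    return FrameSet(
        frames=bold_z.data[:, selected].T,
        frame_index=selected,
        subject_id=subject_id,
        n_frames=bold_z.n_frames,
        n_censored=int(censored.size),
    )


@dataclass
class SubjectPreprocessResult:
    """Everything preprocessing produces for one subject."""

    frame_set: FrameSet
    censored: np.ndarray
    keep: bool
    seed_score: np.ndarray
    seed_ids: np.ndarray
    bold_z: Bold4D


def preprocess_subject(
    bold: Bold4D,
    motion: MotionTrace,
    seed: SeedDefinition,
    threshold_z: float = FRAME_SELECTION_Z,
    subject_id: str = "",
    empirical_percentile: float | None = None,
) -> SubjectPreprocessResult:
    """Run the full per-subject chain: FD -> scrub -> z-score -> seed -> select.

    Subjects failing the censored-fraction screen are still processed (so the
    caller can log them) but flagged ``keep=False`` and should be dropped.
    """
    fd = compute_fd(motion.params)
    censored, keep = scrub_and_screen(fd, motion.fd_threshold_mm, motion.exclusion_fraction)
    bold_z = zscore_voxelwise(bold, censored)
    seed_ids = seed.resolve(bold_z)
    score = extract_seed_signal(bold_z, seed_ids, censored)
    fs = select_active_frames(
        bold_z, score, censored, threshold_z, subject_id, empirical_percentile
    )
    if not keep:
        logger.warning(
            "subject %r excluded: %.1f%% of frames censored (limit %.0f%%)",
            subject_id,
            100 * censored.size / bold.n_frames,
            100 * motion.exclusion_fraction,
        )
    return SubjectPreprocessResult(fs, censored, keep, score, seed_ids, bold_z)
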