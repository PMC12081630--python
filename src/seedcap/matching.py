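"""Cross-cohort frame matching and temporal CAP metrics.

A test cohort's selected frames are assigned to the reference cohort's CAPs by
spatial (Pearson) correlation: each frame goes to its most-correlated CAP map,
provided the correlation exceeds that CAP's *gate* — the 5th percentile of the
correlations of the reference cohort's own member frames with the map.  Frames
failing every gate stay unassigned; retained frames below the seed-activity
threshold and censored frames keep their own codes.

Temporal metrics per subject and CAP: *entries* (number of maximal runs of
consecutive frames assigned to the CAP; any non-CAP code breaks a run),
*duration* (mean run length x TR, in seconds) and *occupancy* (fraction of
assigned frames).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import ConfigurationError, FormatError
from .estimation import CapSet
from .preprocess import FrameSet

#: Frame codes in assignment sequences; CAP labels are 1..K.
UNASSIGNED = 0
BELOW_SEED_THRESHOLD = -1
CENSORED = -2

#: Percentile of the reference member-correlation distribution used as gate.
GATE_PERCENTILE = 5.0


@dataclass
class MatchingReference:
    """Reference CAP maps plus per-CAP correlation gates.

    ``scope`` is the voxel index set correlations are computed over (grey
    matter minus seed voxels by default — seed voxels are near-uniformly high
    in selected frames and would inflate every correlation).
    """

    cap_maps: np.ndarray  # (K, n_voxels), z-scored
    gate_per_cap: np.ndarray  # (K,)
    scope: np.ndarray  # voxel indices

    @property
    def k(self) -> int:
        return self.cap_maps.shape[0]


def _pearson_rows(frames: np.ndarray, maps: np.ndarray) -> np.ndarray:
    """Pearson correlation of each frame (row) with each map (row)."""
    f = frames - frames.mean(axis=1, keepdims=True)
    m = maps - maps.mean(axis=1, keepdims=True)
    fn = np.linalg.norm(f, axis=1, keepdims=True)
    mn = np.linalg.norm(m, axis=1, keepdims=True)
    fn[fn == 0] = 1.0
    mn[mn == 0] = 1.0
    return (f / fn) @ (m / mn).T


def build_matching_reference(
    cap_set: CapSet,
    frames: np.ndarray,
    labels: np.ndarray,
    gate_percentile: float = GATE_PERCENTILE,
    scope: np.ndarray | None = None,
) -> MatchingReference:
    """Compute per-CAP gates from the reference cohort's own member frames.

    gate_c is the empirical ``gate_percentile``-th percentile (linear
    interpolation) of the Pearson correlations between the frames labelled c
    and map_c, over ``scope`` (defaults to all voxels minus the CapSet's seed
    voxels).
    """
    labels = np.asarray(labels, dtype=int)
    if frames.shape[0] != labels.size:
        raise FormatError("frames and labels length mismatch")
    n_vox = cap_set.maps.shape[1]
    if scope is None:
        scope = np.arange(n_vox)
        if cap_set.seed_voxel_ids is not None:
            scope = np.setdiff1d(scope, cap_set.seed_voxel_ids)
    scope = np.asarray(scope, dtype=int)
    gates = np.empty(cap_set.k)
    for c in range(1, cap_set.k + 1):
        members = frames[labels == c][:, scope]
        if members.shape[0] < 20:
            warnings.warn(
                f"CAP{c}: only {members.shape[0]} member frames; "
                "gate percentile is unstable",
                stacklevel=2,
            )
        if members.shape[0] == 0:
            raise ConfigurationError(f"CAP{c} has no member frames")
        corr = _pearson_rows(members, cap_set.maps[c - 1 : c, scope])[:, 0]
        gates[c - 1] = np.percentile(corr, gate_percentile)
    return MatchingReference(cap_maps=cap_set.maps, gate_per_cap=gates, scope=scope)


@dataclass
class AssignmentSequence:
    """Per-frame CAP labels for one subject, full scan length.

    Codes: 1..K for CAPs, 0 unassigned (failed every gate), -1 retained but
    below the seed-activity threshold, -2 censored.
    """

    labels: np.ndarray
    subject_id: str
    tr_seconds: float
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)


def match_frames(
    frame_set: FrameSet,
    ref: MatchingReference,
    tr_seconds: float,
    censored: np.ndarray | None = None,
    apply_gate: bool = True,
) -> AssignmentSequence:
    """Assign a subject's selected frames to reference CAPs.

    Each selected frame goes to argmax_c corr(frame, map_c) over the reference
    scope (exact ties break to the lower CAP index); the label sticks only if
    the correlation strictly exceeds that CAP's gate, otherwise UNASSIGNED.
    Non-selected retained frames are BELOW_SEED_THRESHOLD, censored frames
    CENSORED.
    """
    if frame_set.frames.shape[1] != ref.cap_maps.shape[1]:
        raise FormatError(
            "test frames and reference maps are on different voxel grids"
        )
    labels = np.full(frame_set.n_frames, BELOW_SEED_THRESHOLD, dtype=int)
    if censored is not None:
        labels[np.asarray(censored, dtype=int)] = CENSORED
    if frame_set.n_selected:
        corr = _pearson_rows(frame_set.frames[:, ref.scope], ref.cap_maps[:, ref.scope])
        best = np.argmax(corr, axis=1)  # argmax takes the first (lowest) index on ties
        best_corr = corr[np.arange(corr.shape[0]), best]
        assigned = best + 1
        if apply_gate:
            assigned = np.where(
                best_corr > ref.gate_per_cap[best], assigned, UNASSIGNED
            )
        labels[frame_set.frame_index] = assigned
    return AssignmentSequence(
        labels=labels,
        subject_id=frame_set.subject_id,
        tr_seconds=tr_seconds,
        k=ref.k,
    )


@dataclass
class TemporalMetrics:
    """Entries, mean-run duration (s) and occupancy per CAP for one subject."""

    entries: np.ndarray  # (K,)
    duration_s: np.ndarray  # (K,), 0 where entries == 0
    occupancy_frac: np.ndarray  # (K,)
    subject_id: str


def compute_metrics(seq: AssignmentSequence) -> TemporalMetrics:
    """Run-length metrics over one assignment sequence.

    A run is a maximal block of consecutive identical CAP labels; any non-CAP
    code (censored / unassigned / below-threshold) breaks runs.  entries_c is
    the number of runs of CAP c, duration_c the mean run length times TR,
    occupancy_c the CAP's share of assigned frames.
    """
    k = seq.k
    entries = np.zeros(k, dtype=int)
    total_len = np.zeros(k, dtype=int)
    prev = None
    for lab in seq.labels:
        lab = int(lab)
        if 1 <= lab <= k:
            if lab != prev:
                entries[lab - 1] += 1
            total_len[lab - 1] += 1
            prev = lab
        else:
            prev = None
    with np.errstate(invalid="ignore", divide="ignore"):
        duration = np.where(entries > 0, total_len / np.maximum(entries, 1), 0.0)
    duration = duration * seq.tr_seconds
    assigned = total_len.sum()
    occupancy = total_len / assigned if assigned else np.zeros(k)
    return TemporalMetrics(
        entries=entries,
        duration_s=duration,
        occupancy_frac=occupancy,
        subject_id=seq.subject_id,
    )


def metrics_table(sequences: list[AssignmentSequence]) -> pd.DataFrame:
    """Tidy per-subject x CAP metrics: subject_id, cap, entries, duration_s,
    occupancy."""
    rows = []
    for seq in sequences:
        m = compute_metrics(seq)
        for c in range(seq.k):
            rows.append(
                {
                    "subject_id": m.subject_id,
                    "cap": c + 1,
                    "entries": int(m.entries[c]),
                    "duration_s": float(m.duration_s[c]),
                    "occupancy": float(m.occupancy_frac[c]),
                }
            )
    return pd.DataFrame(rows)


def sequences_from_derivation(
    frame_sets: list[FrameSet],
    cap_set: CapSet,
    subject_index: np.ndarray,
    censored_per_subject: list[np.ndarray],
    tr_seconds: float,
) -> list[AssignmentSequence]:
    """Turn within-cohort k-means labels into full-length assignment sequences.

    Used for the reference cohort (and for within-cohort subgroup analyses,
    which skip the matching process): the pooled k-means labels are scattered
    back to each subject's timeline.
    """
    labels_per_subject: list[np.ndarray] = []
    for i, fs in enumerate(frame_sets):
        seq = np.full(fs.n_frames, BELOW_SEED_THRESHOLD, dtype=int)
        seq[np.asarray(censored_per_subject[i], dtype=int)] = CENSORED
        seq[fs.frame_index] = cap_set.assignments[subject_index == i]
        labels_per_subject.append(seq)
    return [
        AssignmentSequence(
            labels=seq,
            subject_id=fs.subject_id,
            tr_seconds=tr_seconds,
            k=cap_set.k,
        )
        for seq, fs in zip(labels_per_subject, frame_sets)
    ]
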