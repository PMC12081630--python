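"""Synthetic BOLD cohorts with planted co-activation states.

The generator emulates the data layout the CAP pipeline consumes: per subject a
grey-matter-masked voxel x time matrix (writable as NIfTI-1), a six-parameter
rigid-body motion trace (writable as TSV), and a clinical/demographic row; per
cohort an integer-label network parcellation aligned with the planted spatial
patterns, and full ground truth (latent state sequence, FD trace, censored
frames) for every subject.

The latent dynamics are a first-order Markov chain over ``n_states`` active
whole-brain patterns plus, by default, one explicit *inactive* state in which
the seed sits at baseline.  Active frames carry the state's signed spatial
pattern plus a constant ``seed_drive`` on the seed voxels, modulated by a
per-frame lognormal gain that emulates the natural variability of BOLD event
amplitudes; i.i.d. Gaussian observation noise is added everywhere.  Because the seed indicator is binary
with active fraction p, its standardized active value is sqrt((1-p)/p); the
defaults put 60% of stationary mass on the inactive state so that active
frames sit near z = +1.2, safely above the 0.84-SD selection threshold, while
inactive frames fall well below it.

Motion spikes are injected as persistent translation jumps, so the downstream
framewise-displacement computation (not the generator) decides censoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import ConfigurationError
from .preprocess import Bold4D, MotionTrace, compute_fd, FD_THRESHOLD_MM

#: Sentinel latent label for the inactive (seed-at-baseline) state.
INACTIVE = -1

#: Number of networks in the synthetic parcellation (17-network convention).
N_NETWORKS = 17


def default_transition_matrix(
    n_states: int,
    include_inactive: bool = True,
    stay: float = 0.45,
    to_inactive: float = 0.35,
    inactive_occupancy: float = 0.6,
    bias_state: int | None = None,
    bias_factor: float = 1.0,
) -> np.ndarray:
    """Row-stochastic transition matrix for the latent chain.

    With ``include_inactive`` the matrix is ``(n_states+1) x (n_states+1)`` and
    the last index is the inactive state.  The defaults give each active state
    a stay probability of 0.45, probability 0.35 of dropping to baseline and
    the remainder spread over the other active states; the inactive state's
    stay probability is set by flow balance so the stationary inactive mass is
    ``inactive_occupancy``.  Keeping that mass at 0.6 puts the standardized
    seed score of active frames near +1.2, comfortably above the 0.84
    selection threshold even under per-subject occupancy fluctuations, while
    inactive frames fall far below it.

    ``bias_state``/``bias_factor`` multiply every incoming probability to one
    active state by ``bias_factor`` (rows renormalised), the mechanism used to
    plant a group difference in entry rate.
    """
    if n_states < 1:
        raise ConfigurationError("need at least one active state")
    if include_inactive:
        if not 0 < inactive_occupancy < 1:
            raise ConfigurationError("inactive_occupancy must be in (0, 1)")
        # flow balance: q * (1 - inactive_stay) = (1 - q) * to_inactive
        q = inactive_occupancy
        inactive_stay = 1.0 - to_inactive * (1.0 - q) / q
        if inactive_stay < 0:
            raise ConfigurationError(
                "inactive_occupancy too small for the given to_inactive"
            )
        m = n_states + 1
        tm = np.zeros((m, m))
        for s in range(n_states):
            tm[s, s] = stay
            tm[s, n_states] = to_inactive
            if n_states > 1:
                rest = (1.0 - stay - to_inactive) / (n_states - 1)
                for t in range(n_states):
                    if t != s:
                        tm[s, t] = rest
            else:
                tm[s, s] += 1.0 - stay - to_inactive
        tm[n_states, n_states] = inactive_stay
        tm[n_states, :n_states] = (1.0 - inactive_stay) / n_states
    else:
        if n_states == 1:
            tm = np.array([[1.0]])
        else:
            off = (1.0 - stay) / (n_states - 1)
            tm = np.full((n_states, n_states), off)
            np.fill_diagonal(tm, stay)
    if bias_state is not None:
        if not 0 <= bias_state < n_states:
            raise ConfigurationError("bias_state must index an active state")
        tm[:, bias_state] *= bias_factor
        tm /= tm.sum(axis=1, keepdims=True)
    return tm


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic cohort generator.

    The spatial layout is a ``grid_shape`` voxel grid with cubic voxels of
    ``voxel_size_mm``, positioned so that the grid centre sits at the default
    rTPJ seed coordinate — the same seed-sphere resolution code then works on
    synthetic and real affines alike.
    """

    n_subjects_per_group: int = 10
    n_frames: int = 300
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    voxel_size_mm: float = 4.0
    n_states: int = 4
    include_inactive: bool = True
    seed_voxel_ids: np.ndarray | None = None
    seed_center_mm: tuple[float, float, float] = (62.0, -34.0, 30.0)
    seed_radius_mm: float = 10.0
    state_patterns: np.ndarray | None = None
    state_amplitude: float = 1.0
    transition_matrix: np.ndarray | None = None
    seed_drive: float = 1.0
    #: observation-noise SD relative to the unit-SD patterns; the default puts
    #: roughly half of a frame's variance in noise, so single frames correlate
    #: ~0.6-0.8 with their state map as in real CAP data (clean recovery
    #: studies may lower this explicitly).
    noise_sd: float = 1.0
    #: lognormal sigma of the per-frame gain on active frames (mean-one gain
    #: ``exp(N(-sd^2/2, sd^2))``); emulates the natural variability of BOLD
    #: event amplitudes, which is what gives the member-correlation
    #: distribution of each CAP a usable spread for the percentile gate.
    amplitude_jitter_sd: float = 0.3
    motion_spike_rate: float = 0.02
    tr_seconds: float = 2.0
    rng_seed: int = 0
    #: group-2 effect: incoming transitions to this active state are multiplied
    #: by ``bias_factor`` (rows renormalised) for test-group subjects.
    bias_state: int | None = None
    bias_factor: float = 1.0

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] *= self.voxel_size_mm
        center_vox = (np.asarray(self.grid_shape) - 1) / 2.0
        aff[:3, 3] = np.asarray(self.seed_center_mm) - center_vox * self.voxel_size_mm
        return aff

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))


@dataclass
class GroundTruth:
    """Latent truth recorded for one synthetic subject."""

    state_sequence: np.ndarray  # per-frame active-state index or INACTIVE
    fd_trace: np.ndarray
    censored_frames: np.ndarray

    def to_json(self) -> str:
        return json.dumps(
            {
                "state_sequence": self.state_sequence.tolist(),
                "fd_trace": self.fd_trace.tolist(),
                "censored_frames": self.censored_frames.tolist(),
            }
        )


@dataclass
class ResolvedDesign:
    """Deterministic cohort-level objects derived from a config."""

    seed_voxel_ids: np.ndarray
    state_patterns: np.ndarray  # (n_states, n_voxels), z-scored, 0 on seed
    transition_matrix: np.ndarray
    parcellation_labels: np.ndarray  # per-voxel network id in 1..N_NETWORKS
    mask: np.ndarray
    affine: np.ndarray


def _validate_transition_matrix(tm: np.ndarray, expected: int) -> None:
    tm = np.asarray(tm, dtype=float)
    if tm.ndim != 2 or tm.shape[0] != tm.shape[1] or tm.shape[0] != expected:
        raise ConfigurationError(
            f"transition matrix must be {expected}x{expected}, got {tm.shape}"
        )
    if (tm < 0).any():
        raise ConfigurationError("transition matrix has negative entries")
    if np.any(np.abs(tm.sum(axis=1) - 1.0) > 1e-12):
        raise ConfigurationError("transition matrix rows must sum to 1 (±1e-12)")


def resolve_design(cfg: SyntheticConfig) -> ResolvedDesign:
    """Materialise seed voxels, patterns, chain and parcellation for a config.

    Patterns are piecewise-constant over parcellation networks (plus small
    voxel-level jitter), z-scored over grey matter, zeroed on seed voxels, and
    redrawn until all pairwise spatial correlations are below 0.5 in absolute
    value so the planted states are distinguishable.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    mask = np.ones(cfg.grid_shape, dtype=bool)
    affine = cfg.affine()

    ijk = np.argwhere(mask)
    coords = (np.c_[ijk, np.ones(len(ijk))] @ affine.T)[:, :3]

    if cfg.seed_voxel_ids is not None:
        seed_ids = np.asarray(cfg.seed_voxel_ids, dtype=int)
        if seed_ids.size == 0 or seed_ids.min() < 0 or seed_ids.max() >= cfg.n_voxels:
            raise ConfigurationError("seed_voxel_ids empty or outside the grid")
    else:
        d = np.linalg.norm(coords - np.asarray(cfg.seed_center_mm), axis=1)
        seed_ids = np.flatnonzero(d <= cfg.seed_radius_mm)

    # Spatially contiguous-ish parcels: k-means on voxel coordinates.
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=N_NETWORKS, n_init=3, random_state=cfg.rng_seed)
    parcellation = km.fit_predict(coords) + 1  # labels 1..17

    if cfg.state_patterns is not None:
        patterns = np.asarray(cfg.state_patterns, dtype=float)
        if patterns.shape != (cfg.n_states, cfg.n_voxels):
            raise ConfigurationError("state_patterns must be (n_states, n_voxels)")
    else:
        for _ in range(50):
            amp = rng.normal(size=(cfg.n_states, N_NETWORKS))
            patterns = amp[:, parcellation - 1]
            patterns = patterns + 0.1 * rng.normal(size=patterns.shape)
            patterns -= patterns.mean(axis=1, keepdims=True)
            patterns /= patterns.std(axis=1, keepdims=True)
            patterns[:, seed_ids] = 0.0
            c = np.corrcoef(patterns)
            if cfg.n_states < 2 or np.abs(c[np.triu_indices(cfg.n_states, 1)]).max() < 0.5:
                break
        else:  # pragma: no cover - 50 redraws virtually never exhausted
            raise ConfigurationError("could not draw distinguishable state patterns")
        patterns = patterns * cfg.state_amplitude

    m = cfg.n_states + (1 if cfg.include_inactive else 0)
    tm = (
        np.asarray(cfg.transition_matrix, dtype=float)
        if cfg.transition_matrix is not None
        else default_transition_matrix(cfg.n_states, cfg.include_inactive)
    )
    _validate_transition_matrix(tm, m)

    return ResolvedDesign(seed_ids, patterns, tm, parcellation, mask, affine)


def _simulate_chain(tm: np.ndarray, n_frames: int, rng: np.random.Generator) -> np.ndarray:
    m = tm.shape[0]
    cum = np.cumsum(tm, axis=1)
    states = np.empty(n_frames, dtype=int)
    # start from the stationary distribution for stationarity from frame 0
    evals, evecs = np.linalg.eig(tm.T)
    pi = np.real(evecs[:, np.argmin(np.abs(evals - 1.0))])
    pi = np.abs(pi) / np.abs(pi).sum()
    states[0] = rng.choice(m, p=pi)
    u = rng.random(n_frames)
    for t in range(1, n_frames):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t], side="right")
    return states


def _simulate_motion(
    n_frames: int, spike_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Random-walk motion with persistent translation jumps as FD spikes."""
    steps = rng.normal(scale=0.02, size=(n_frames, 6))
    steps[:, 3:] *= 1e-3 / 0.02  # rotations: ~1e-3 rad steps
    steps[0] = 0.0
    spikes = rng.random(n_frames) < spike_rate
    spikes[0] = False
    # a jump of 0.8-1.5 mm on one translation axis guarantees FD > 0.5
    for t in np.flatnonzero(spikes):
        axis = rng.integers(0, 3)
        steps[t, axis] += rng.uniform(0.8, 1.5) * rng.choice([-1.0, 1.0])
    return np.cumsum(steps, axis=0)


def generate_subject(
    cfg: SyntheticConfig,
    subject_rng_seed: int,
    design: ResolvedDesign | None = None,
    transition_matrix: np.ndarray | None = None,
) -> tuple[Bold4D, MotionTrace, GroundTruth]:
    """Simulate one subject's BOLD matrix, motion trace and ground truth.

    ``subject_rng_seed`` fully determines the subject (bit-identical
    regeneration).  ``transition_matrix`` overrides the design's chain, used
    for group-specific dynamics.
    """
    if design is None:
        design = resolve_design(cfg)
    tm = design.transition_matrix if transition_matrix is None else transition_matrix
    _validate_transition_matrix(tm, design.transition_matrix.shape[0])
    rng = np.random.default_rng(subject_rng_seed)

    chain = _simulate_chain(tm, cfg.n_frames, rng)
    inactive_idx = cfg.n_states  # only meaningful when include_inactive
    state_seq = np.where(
        cfg.include_inactive & (chain == inactive_idx), INACTIVE, chain
    )

    data = np.zeros((cfg.n_voxels, cfg.n_frames))
    active = state_seq != INACTIVE
    if active.any():
        data[:, active] = design.state_patterns[state_seq[active]].T
        data[np.ix_(design.seed_voxel_ids, np.flatnonzero(active))] += cfg.seed_drive
        if cfg.amplitude_jitter_sd > 0:
            s = cfg.amplitude_jitter_sd
            gain = np.exp(rng.normal(-0.5 * s * s, s, size=int(active.sum())))
            data[:, active] *= gain
    if cfg.noise_sd > 0:
        data += rng.normal(scale=cfg.noise_sd, size=data.shape)

    params = _simulate_motion(cfg.n_frames, cfg.motion_spike_rate, rng)
    fd = compute_fd(params)
    censored = np.flatnonzero(fd > FD_THRESHOLD_MM)

    bold = Bold4D(
        data=data, mask=design.mask, affine=design.affine, tr_seconds=cfg.tr_seconds
    )
    motion = MotionTrace(params=params)
    truth = GroundTruth(state_sequence=state_seq, fd_trace=fd, censored_frames=censored)
    return bold, motion, truth


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str
    bold: Bold4D
    motion: MotionTrace
    truth: GroundTruth


@dataclass
class Cohort:
    """Two groups of synthetic subjects plus shared design and clinical table."""

    subjects: list[SyntheticSubject]
    design: ResolvedDesign
    clinical: pd.DataFrame
    config: SyntheticConfig

    def group(self, name: str) -> list[SyntheticSubject]:
        return [s for s in self.subjects if s.group == name]


def _clinical_row(
    rng: np.random.Generator, subject_id: str, group: str, subgroup: str
) -> dict:
    """Draw one clinical/demographic row.

    Distributions mirror a typical motor-FND case-control sample: patients
    score higher on depression (BDI) and state/trait anxiety (STAI), half take
    psychotropic medication, and only patients have symptom severity (S-FMDRS)
    and illness-duration entries.
    """
    patient = group == "test"
    row = {
        "subject_id": subject_id,
        "group": group,
        "subgroup": subgroup,
        "age": float(np.clip(rng.normal(35, 12), 18, 69)),
        "sex": int(rng.random() < 0.74),  # 1 = female
        "medication": int(patient and rng.random() < 0.5),
        "bdi": float(np.clip(rng.normal(14.4 if patient else 4.6, 8), 0, 60)),
        "stai_s": float(np.clip(rng.normal(37.2 if patient else 32.1, 9), 20, 80)),
        "stai_t": float(np.clip(rng.normal(45.5 if patient else 33.9, 9), 20, 80)),
        "sfmdrs": float(np.clip(rng.lognormal(1.9, 0.7), 0, 54)) if patient else np.nan,
        "illness_duration_months": float(np.clip(rng.lognormal(3.6, 1.0), 1, 400))
        if patient
        else np.nan,
    }
    return row


def generate_cohort(cfg: SyntheticConfig) -> Cohort:
    """Generate a reference group and a test group with distinct RNG streams.

    Group labels are ``"reference"`` (healthy-control analogue) and ``"test"``
    (patient analogue).  Test subjects use the bias-modified transition matrix
    when ``cfg.bias_state`` is set, and are split 50/50 into FW / no-FW
    subgroups.  Clinical covariates are drawn independently of the dynamics
    unless a bias is planted, so under the null the covariates carry no signal.
    """
    design = resolve_design(cfg)
    rng = np.random.default_rng(cfg.rng_seed)
    tm_test = design.transition_matrix
    if cfg.bias_state is not None:
        tm_test = design.transition_matrix.copy()
        tm_test[:, cfg.bias_state] *= cfg.bias_factor
        tm_test /= tm_test.sum(axis=1, keepdims=True)

    subjects: list[SyntheticSubject] = []
    rows: list[dict] = []
    child_seeds = rng.integers(0, 2**31 - 1, size=2 * cfg.n_subjects_per_group)
    i = 0
    for group, tm in (("reference", design.transition_matrix), ("test", tm_test)):
        for j in range(cfg.n_subjects_per_group):
            sid = f"{group}-{j:03d}"
            bold, motion, truth = generate_subject(
                cfg, int(child_seeds[i]), design=design, transition_matrix=tm
            )
            subjects.append(SyntheticSubject(sid, group, bold, motion, truth))
            subgroup = (
                ("FW" if j < cfg.n_subjects_per_group / 2 else "no-FW")
                if group == "test"
                else "HC"
            )
            rows.append(_clinical_row(rng, sid, group, subgroup))
            i += 1
    clinical = pd.DataFrame(rows)
    return Cohort(subjects=subjects, design=design, clinical=clinical, config=cfg)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write a cohort to disk in the pipeline's native file formats.

    Per subject: ``<id>_bold.nii.gz`` (4-D), ``<id>_motion.tsv`` and
    ``<id>_truth.json``; cohort-level: ``parcellation.nii.gz``,
    ``mask.nii.gz`` and ``clinical.csv``.
    """
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = cohort.design
    shape = design.mask.shape

    vol = np.zeros(shape, dtype=np.int16)
    vol[design.mask] = design.parcellation_labels
    nib.save(nib.Nifti1Image(vol, design.affine), out / "parcellation.nii.gz")
    nib.save(
        nib.Nifti1Image(design.mask.astype(np.uint8), design.affine),
        out / "mask.nii.gz",
    )
    cohort.clinical.to_csv(out / "clinical.csv", index=False)

    for s in cohort.subjects:
        img = np.zeros(shape + (s.bold.n_frames,), dtype=np.float32)
        img[design.mask] = s.bold.data
        ni = nib.Nifti1Image(img, design.affine)
        ni.header.set_zooms((*ni.header.get_zooms()[:3], cohort.config.tr_seconds))
        nib.save(ni, out / f"{s.subject_id}_bold.nii.gz")
        pd.DataFrame(
            s.motion.params,
            columns=["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"],
        ).to_csv(out / f"{s.subject_id}_motion.tsv", sep="\t", index=False)
        (out / f"{s.subject_id}_truth.json").write_text(s.truth.to_json())
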