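import warnings

import numpy as np
import pytest

from seedcap.preprocess import (
    compute_fd,
    extract_seed_signal,
    scrub_and_screen,
    select_active_frames,
    zscore_voxelwise,
)
from seedcap.synthetic import SyntheticConfig, generate_subject, resolve_design


def preprocess_synthetic_subject(cfg, design, subject_seed, subject_id=""):
    """Run the standard per-subject chain on one generated subject.

    Returns (frame_set, censored, truth).
    """
    bold, motion, truth = generate_subject(cfg, subject_seed, design=design)
    fd = compute_fd(motion.params)
    censored, _ = scrub_and_screen(fd)
    bold_z = zscore_voxelwise(bold, censored)
    score = extract_seed_signal(bold_z, design.seed_voxel_ids, censored)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fs = select_active_frames(bold_z, score, censored, subject_id=subject_id)
    return fs, censored, truth


@pytest.fixture(scope="session")
def small_cfg():
    """A small but realistic synthetic configuration (shared, read-only)."""
    return SyntheticConfig(
        n_subjects_per_group=4, n_frames=150, noise_sd=0.2, rng_seed=11
    )


@pytest.fixture(scope="session")
def small_design(small_cfg):
    return resolve_design(small_cfg)


@pytest.fixture(scope="session")
def small_frame_sets(small_cfg, small_design):
    """Frame sets + censoring + truth for 6 subjects of the small config."""
    rng = np.random.default_rng(123)
    out = []
    for i in range(6):
        out.append(
            preprocess_synthetic_subject(
                small_cfg, small_design, int(rng.integers(2**31)), subject_id=f"s{i}"
            )
        )
    return out
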