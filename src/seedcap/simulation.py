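"""Replicated group-difference studies on synthetic cohorts.

Utilities to measure, by Monte-Carlo replication, whether the full pipeline
(simulation -> preprocessing -> matching -> temporal metrics -> covariate
adjusted model with FDR) detects a planted difference in CAP entry rate, and
how often it rejects under the null.  One fixed reference study (reference
cohort, CAP derivation at the planted K, matching gates, CAP <-> planted-state
pairing) is shared across replicates; each replicate simulates two fresh
cohorts and fits the group model on *entries*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .estimation import derive_caps
from .matching import MatchingReference, build_matching_reference, match_frames, metrics_table
from .preprocess import SeedDefinition, preprocess_subject
from .stats import DEFAULT_COVARIATES, GroupStatsResult, fit_group_model
from .synthetic import ResolvedDesign, SyntheticConfig, generate_subject, resolve_design


@dataclass
class ReferenceStudy:
    """Frozen reference-cohort objects shared by all replicates."""

    cfg: SyntheticConfig
    design: ResolvedDesign
    matching_ref: MatchingReference
    state_to_cap: np.ndarray  # planted state s -> CAP label (1..K)


def _preprocess(cfg, design, subject_seed, subject_id):
    bold, motion, _ = generate_subject(cfg, subject_seed, design=design)
    seed = SeedDefinition(voxel_ids=design.seed_voxel_ids)
    return preprocess_subject(bold, motion, seed, subject_id=subject_id)


def build_reference_study(
    cfg: SyntheticConfig, n_reference_subjects: int = 10, rng_seed: int = 0
) -> ReferenceStudy:
    """Derive reference CAPs at the planted K and pair them with the planted
    states by map-pattern correlation."""
    design = resolve_design(cfg)
    rng = np.random.default_rng(rng_seed)
    frame_sets = [
        _preprocess(cfg, design, int(rng.integers(2**31 - 1)), f"ref-{i}").frame_set
        for i in range(n_reference_subjects)
    ]
    deriv = derive_caps(
        frame_sets,
        k=cfg.n_states,
        rng_seed=rng_seed,
        seed_voxel_ids=design.seed_voxel_ids,
    )
    matching_ref = build_matching_reference(
        deriv.cap_set, deriv.pooled_frames, deriv.cap_set.assignments
    )
    scope = matching_ref.scope
    maps = deriv.cap_set.maps[:, scope]
    pats = design.state_patterns[:, scope]
    corr = np.corrcoef(maps, pats)[: cfg.n_states, cfg.n_states :]
    cap_idx, state_idx = linear_sum_assignment(-corr)
    state_to_cap = np.empty(cfg.n_states, dtype=int)
    state_to_cap[state_idx] = cap_idx + 1
    return ReferenceStudy(cfg, design, matching_ref, state_to_cap)


def _clinical_rows(rng: np.random.Generator, subject_ids, groups) -> pd.DataFrame:
    """Covariates with no relation to the dynamics; binary columns balanced
    within group so small-sample designs stay full rank."""
    rows = []
    within = {}
    for sid, g in zip(subject_ids, groups):
        j = within.setdefault(g, 0)
        within[g] += 1
        rows.append(
            {
                "subject_id": sid,
                "group": g,
                "age": float(rng.normal(35, 12)),
                "sex": j % 2,
                "medication": (j // 2) % 2,
                "bdi": float(rng.normal(10, 6)),
                "stai_s": float(rng.normal(35, 9)),
            }
        )
    return pd.DataFrame(rows)


def run_replicate(
    study: ReferenceStudy,
    n_per_group: int,
    bias_factor: float,
    replicate_seed: int,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> GroupStatsResult:
    """Simulate two cohorts, match them to the reference CAPs and fit the
    entries model.

    ``bias_factor`` > 1 plants the effect: group-2 subjects' transition
    probabilities *into* the last active state are multiplied by it (rows
    renormalised).  ``bias_factor`` = 1 is the null.
    """
    cfg, design = study.cfg, study.design
    rng = np.random.default_rng(replicate_seed)
    tm_biased = design.transition_matrix.copy()
    bias_state = cfg.n_states - 1
    tm_biased[:, bias_state] *= bias_factor
    tm_biased /= tm_biased.sum(axis=1, keepdims=True)

    sequences, counts = [], []
    ids, groups = [], []
    for g, tm in (("reference", design.transition_matrix), ("test", tm_biased)):
        for i in range(n_per_group):
            sid = f"{g}-{i}"
            bold, motion, _ = generate_subject(
                cfg, int(rng.integers(2**31 - 1)), design=design, transition_matrix=tm
            )
            seed = SeedDefinition(voxel_ids=design.seed_voxel_ids)
            r = preprocess_subject(bold, motion, seed, subject_id=sid)
            if not r.keep:
                continue
            sequences.append(
                match_frames(
                    r.frame_set, study.matching_ref, cfg.tr_seconds, censored=r.censored
                )
            )
            counts.append(
                {"subject_id": sid, "n_censored": int(r.censored.size),
                 "n_selected": r.frame_set.n_selected}
            )
            ids.append(sid)
            groups.append(g)
    clinical = _clinical_rows(rng, ids, groups).merge(
        pd.DataFrame(counts), on="subject_id"
    )
    metrics = metrics_table(sequences)
    return fit_group_model(metrics, clinical, "entries", covariates=covariates)


def biased_cap(study: ReferenceStudy) -> int:
    """CAP label paired with the state the bias targets (the last one)."""
    return int(study.state_to_cap[study.cfg.n_states - 1])
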