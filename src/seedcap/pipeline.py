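"""End-to-end orchestration of the CAP analysis.

Two analysis modes mirror the two scientific aims:

* **match mode** (default): CAPs are derived from the *reference* cohort
  (healthy-control analogue); every test-cohort frame is then assigned to its
  most-correlated reference CAP through the 5th-percentile gate, and temporal
  metrics are compared between cohorts with covariate adjustment and FDR.
* **within mode** (``reference_only=True``): CAPs and metrics are derived from
  the test cohort alone — no matching process — and subgroups (FW vs no-FW)
  are compared within it.

Every numeric output is reproducible from the config's ``rng_seed`` and each
written file embeds the config hash.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import ConfigurationError
from .config import PipelineConfig
from .estimation import CapDerivation, derive_caps
from .matching import (
    AssignmentSequence,
    MatchingReference,
    build_matching_reference,
    match_frames,
    metrics_table,
    sequences_from_derivation,
)
from .preprocess import SeedDefinition, SubjectPreprocessResult, preprocess_subject
from .stats import (
    DEFAULT_COVARIATES,
    GroupStatsResult,
    ParcellationOverlay,
    correlate_clinical,
    fit_group_model,
    network_overlap,
)

logger = logging.getLogger(__name__)


@dataclass
class LoadedSubject:
    subject_id: str
    group: str
    bold: "object"
    motion: "object"


@dataclass
class PipelineResult:
    config: PipelineConfig
    derivation: CapDerivation
    metrics: pd.DataFrame  # tidy subject x cap metrics, all analysed subjects
    clinical: pd.DataFrame  # augmented with n_censored / n_selected
    sequences: list[AssignmentSequence]
    matching_ref: MatchingReference | None
    overlap: pd.DataFrame | None
    group_stats: dict[str, GroupStatsResult] = field(default_factory=dict)
    clinical_correlations: pd.DataFrame | None = None
    excluded_subjects: list[str] = field(default_factory=list)


def _load_cohort(config: PipelineConfig):
    """Return (subjects, parcellation, clinical, tr) from synthetic params or a
    manifest."""
    if config.synthetic is not None:
        from .synthetic import SyntheticConfig, generate_cohort

        syn = SyntheticConfig(**config.synthetic)
        cohort = generate_cohort(syn)
        parc = ParcellationOverlay(labels=cohort.design.parcellation_labels)
        subjects = [
            LoadedSubject(s.subject_id, s.group, s.bold, s.motion)
            for s in cohort.subjects
        ]
        return subjects, parc, cohort.clinical, syn.tr_seconds
    if config.manifest is None:
        raise ConfigurationError("config needs either synthetic parameters or a manifest")
    from . import io

    manifest = io.load_manifest(config.manifest)
    mask, _ = io.load_mask(manifest["mask"])
    tr = config.tr_seconds or manifest.get("tr_seconds")
    if tr is None:
        raise ConfigurationError("tr_seconds missing from both config and manifest")
    subjects = [
        LoadedSubject(
            s["subject_id"],
            s["group"],
            io.load_bold(s["bold"], mask, tr),
            io.load_motion(s["motion"]),
        )
        for s in manifest["subjects"]
    ]
    parc = (
        io.load_parcellation(manifest["parcellation"], mask)
        if manifest.get("parcellation")
        else None
    )
    clinical = (
        pd.read_csv(manifest["clinical"]) if manifest.get("clinical") else pd.DataFrame()
    )
    return subjects, parc, clinical, tr


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    reference_only: bool = False,
) -> PipelineResult:
    """Execute preprocess -> CAP derivation -> matching -> metrics -> stats."""
    subjects, parc, clinical, tr = _load_cohort(config)
    seed = SeedDefinition(center_mm=config.seed_center, radius_mm=config.seed_radius_mm)

    pre: dict[str, SubjectPreprocessResult] = {}
    excluded: list[str] = []
    rows = []
    for s in subjects:
        s.motion.fd_threshold_mm = config.fd_threshold_mm
        s.motion.exclusion_fraction = config.exclusion_fraction
        r = preprocess_subject(
            s.bold, s.motion, seed, threshold_z=config.frame_z, subject_id=s.subject_id
        )
        if not r.keep:
            excluded.append(s.subject_id)
            continue
        pre[s.subject_id] = r
        rows.append(
            {
                "subject_id": s.subject_id,
                "n_censored": int(r.censored.size),
                "n_selected": r.frame_set.n_selected,
            }
        )
    if excluded:
        logger.warning("excluded %d subject(s) by the motion screen: %s",
                       len(excluded), excluded)
    if not rows:
        raise ConfigurationError("every subject failed the motion screen")
    counts = pd.DataFrame(rows)
    if not clinical.empty:
        clinical = clinical.merge(counts, on="subject_id", how="inner")
    else:
        clinical = counts

    kept = [s for s in subjects if s.subject_id in pre]
    derive_group = "test" if reference_only else "reference"
    derive_ids = [s.subject_id for s in kept if s.group == derive_group]
    if not derive_ids:
        raise ConfigurationError(f"no subjects in group {derive_group!r} to derive CAPs")
    seed_ids = pre[derive_ids[0]].seed_ids

    frame_sets = [pre[sid].frame_set for sid in derive_ids]
    derivation = derive_caps(
        frame_sets,
        k=config.k,
        variance_target=config.variance_target,
        k_range=range(config.k_range[0], config.k_range[1] + 1),
        n_iter=config.n_iter,
        subsample_fraction=config.subsample_fraction,
        rng_seed=config.rng_seed,
        z_threshold=config.map_z,
        seed_voxel_ids=seed_ids,
    )
    cap_set = derivation.cap_set

    sequences = sequences_from_derivation(
        frame_sets,
        cap_set,
        derivation.subject_index,
        [pre[sid].censored for sid in derive_ids],
        tr,
    )

    matching_ref = None
    if not reference_only:
        matching_ref = build_matching_reference(
            cap_set,
            derivation.pooled_frames,
            cap_set.assignments,
            gate_percentile=config.gate_percentile,
        )
        for s in kept:
            if s.group == "test":
                r = pre[s.subject_id]
                sequences.append(
                    match_frames(r.frame_set, matching_ref, tr, censored=r.censored)
                )

    metrics = metrics_table(sequences)
    overlap = network_overlap(cap_set, parc) if parc is not None else None

    group_stats: dict[str, GroupStatsResult] = {}
    group_col = "subgroup" if reference_only else "group"
    if group_col in clinical.columns:
        modeled = clinical[clinical["subject_id"].isin(metrics["subject_id"])]
        if reference_only:
            modeled = modeled[modeled[group_col].isin(["FW", "no-FW"])]
        covariates = tuple(
            c for c in DEFAULT_COVARIATES if c in modeled.columns
            and modeled[c].notna().all()
        )
        if modeled[group_col].nunique() == 2:
            for metric in ("entries", "duration_s"):
                try:
                    group_stats[metric] = fit_group_model(
                        metrics, modeled, metric, group_col=group_col,
                        covariates=covariates,
                    )
                except ConfigurationError as e:
                    logger.warning("group model for %s skipped: %s", metric, e)

    correlations = None
    clin_vars = [
        v for v in ("sfmdrs", "illness_duration_months", "bdi", "stai_s", "stai_t")
        if v in clinical.columns
    ]
    if "subgroup" in clinical.columns and clin_vars:
        pats = clinical[clinical["subgroup"].isin(["FW", "no-FW"])]
        if len(pats):
            pairs = [
                (m, c, v)
                for m in ("entries", "duration_s")
                for c in range(1, cap_set.k + 1)
                for v in clin_vars
            ]
            correlations = correlate_clinical(
                metrics, pats, pairs, subgroups=["FW", "no-FW"]
            )

    result = PipelineResult(
        config=config,
        derivation=derivation,
        metrics=metrics,
        clinical=clinical,
        sequences=sequences,
        matching_ref=matching_ref,
        overlap=overlap,
        group_stats=group_stats,
        clinical_correlations=correlations,
        excluded_subjects=excluded,
    )
    if out_dir is not None:
        _write_results(result, kept, pre, Path(out_dir))
    return result


def _write_results(
    result: PipelineResult,
    kept: list[LoadedSubject],
    pre: dict[str, SubjectPreprocessResult],
    out: Path,
) -> None:
    from . import io

    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    h = cfg.config_hash()
    (out / "config.json").write_text(cfg.to_json())

    any_bold = pre[kept[0].subject_id].bold_z
    io.save_cap_maps(
        result.derivation.cap_set.maps, any_bold.mask, any_bold.affine, out, "cap", h
    )

    result.metrics.assign(config_hash=h).to_csv(out / "metrics.csv", index=False)
    result.clinical.assign(config_hash=h).to_csv(out / "clinical.csv", index=False)
    for seq in result.sequences:
        pd.DataFrame({"frame": np.arange(seq.labels.size), "code": seq.labels}).to_csv(
            out / f"assignments_{seq.subject_id}.tsv", sep="\t", index=False
        )
    if result.derivation.consensus is not None:
        cons = result.derivation.consensus
        pd.DataFrame(
            {
                "k": cons.k_range,
                "pac": [cons.pac[k] for k in cons.k_range],
                "stability": [cons.stability[k] for k in cons.k_range],
            }
        ).assign(config_hash=h).to_csv(out / "stability.csv", index=False)
    if result.overlap is not None:
        result.overlap.assign(config_hash=h).to_csv(out / "network_overlap.csv", index=False)

    report: dict = {
        "config_hash": h,
        "chosen_k": result.derivation.cap_set.k,
        "occupancy_pct": result.derivation.cap_set.occupancy_pct.tolist(),
        "excluded_subjects": result.excluded_subjects,
    }
    for metric, gs in result.group_stats.items():
        report[f"group_model_{metric}"] = {
            "omnibus": gs.omnibus.to_dict(orient="records"),
            "posthoc": gs.posthoc.to_dict(orient="records"),
            "covariates": list(gs.covariates),
            "n_obs": gs.n_obs,
        }
    if result.clinical_correlations is not None:
        report["clinical_correlations"] = result.clinical_correlations.to_dict(
            orient="records"
        )
    (out / "stats.json").write_text(json.dumps(report, indent=2))
    logger.info("pipeline outputs written to %s (config %s)", out, h)
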