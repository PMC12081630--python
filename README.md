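# seedcap

Seed-based **co-activation pattern (CAP)** analysis for resting-state fMRI,
with a focus on comparing the temporal dynamics of a seed region's network
between two cohorts (e.g. patients vs matched controls).

Static seed-based functional connectivity collapses a whole scan into one
correlation map and is blind to transient network reconfiguration. CAP
analysis instead keeps the individual volumes in which the seed is strongly
active and clusters them into a small set of recurring whole-brain
co-(de)activation states. Each subject's scan then becomes a labelled state
sequence, and simple temporal statistics — how often a subject *enters* each
state, how long they *stay* in it, what fraction of frames they *occupy* it —
become sensitive markers of altered brain dynamics. The package was built for
studies of the right temporo-parietal junction (rTPJ) network, whose dynamics
are of interest in functional neurological disorders, but seed, atlas and
thresholds are all configurable.

## What it implements

For voxel time series **X** (grey-matter masked, per subject):

1. **Scrubbing** — framewise displacement FDₜ = Σ|Δd| + 50 mm·Σ|Δθ|; frames
   with FD > 0.5 mm censored, subjects with > 30% censored excluded.
2. **Frame selection** — voxelwise temporal z-scoring; seed score = mean z
   over a 10 mm sphere; frames with seed z > 0.84 (the standard-normal 80th
   percentile) are the high-amplitude events.
3. **CAP estimation** — PCA to 90% variance; K chosen by consensus
   clustering over subsampled k-means runs, scored by the proportion of
   ambiguously clustered pairs (PAC; stability = 1 − PAC); k-means into K
   CAPs; maps back-reconstructed as centroid·Vᵀ + mean, z-scored and
   thresholded at |z| ≥ 1.04 (15% tails).
4. **Cross-cohort matching** — each test-cohort frame is assigned to its
   most-correlated reference CAP, gated by the 5th percentile of the
   reference cohort's own member-frame correlations.
5. **Temporal metrics & statistics** — Entries, Duration (mean run length ×
   TR) and Occupancy per subject × CAP; covariate-adjusted OLS
   (`metric ~ group * state + covariates`) with omnibus F tests, per-state
   post-hoc contrasts under Benjamini–Hochberg FDR; CAP composition against a
   17-network parcellation; between-cohort CAP overlap (Jaccard %); and
   exploratory clinical correlations.

A fully ground-truthed synthetic-cohort generator (`seedcap.synthetic`)
plants Markov-chain brain states, a driven seed sphere, amplitude-jittered
BOLD-like frames and motion spikes, so the entire pipeline is testable
without any data download. `seedcap.simulation` runs replicated two-cohort
studies on it to measure detection power and null behaviour of the full
pipeline. See `docs/methods.md` for models, defaults and limitations.

## Worked example

Simulate a two-cohort study in which the test group enters one planted state
twice as often (transition probabilities into state 4 doubled), then run the
complete analysis — reference-cohort CAPs, gated matching, temporal metrics
and the covariate-adjusted entries model:

```python
from seedcap import PipelineConfig, run_pipeline

config = PipelineConfig(
    synthetic=dict(n_subjects_per_group=12, n_frames=200, rng_seed=42,
                   bias_state=3, bias_factor=2.0),
    k=4, rng_seed=42)
result = run_pipeline(config)

caps = result.derivation.cap_set
print("K =", caps.k)
print("occupancy (%):", [round(float(x), 1) for x in caps.occupancy_pct])
print("matching gates:", [round(float(g), 3) for g in result.matching_ref.gate_per_cap])
posthoc = result.group_stats["entries"].posthoc
print(posthoc[["cap", "contrast", "estimate", "p_fdr", "significant"]]
      .round(4).to_string(index=False))
```

prints

```
K = 4
occupancy (%): [27.9, 25.5, 23.8, 22.9]
matching gates: [0.532, 0.539, 0.562, 0.55]
 cap         contrast  estimate  p_fdr  significant
   1 test - reference   -4.1180 0.0219         True
   2 test - reference   -2.8455 0.1098        False
   3 test - reference   -0.3079 0.8178        False
   4 test - reference    5.8086 0.0027         True
```

Reading this: the four reference CAPs split the selected frames roughly
evenly (occupancy 23–28%); each CAP accepts a test frame only if its spatial
correlation beats that CAP's gate (≈ 0.53–0.56 here). The planted effect is
recovered on CAP4 — test subjects enter it ≈ 5.8 more times per scan than
reference subjects after covariate adjustment (FDR-corrected p = 0.003) —
with a compensatory decrease spread over the other states.

The same analysis runs from the shell on cohorts stored as NIfTI + TSV via a
manifest (`seedcap run --config config.json --out out/`), and
`seedcap derive --out out/` runs the within-cohort variant (no matching)
used for subgroup comparisons. `seedcap simulate --out cohort/` writes a
synthetic cohort to disk in the pipeline's native formats.

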