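# Methods

`seedcap` implements a seed-based co-activation pattern (CAP) analysis of
resting-state fMRI: instead of summarising the connectivity of a seed region
by one static correlation map, it isolates the individual volumes in which the
seed is strongly active and clusters them into a small number of transient
whole-brain co-(de)activation states, whose spatial composition and temporal
statistics can then be compared between cohorts.

## Pipeline

**Motion scrubbing.** Framewise displacement is the Power-style scalar
FD_t = Σ|Δd| + r·Σ|Δθ| over the three translations (mm) and three rotations
(rad, converted to arc length on an r = 50 mm sphere), with FD_1 = 0. Frames
with FD strictly above 0.5 mm are censored; subjects with strictly more than
30% censored frames are excluded. Both comparisons are strict because the
criteria are phrased as exceedances.

**Normalisation and frame selection.** Each grey-matter voxel's time course is
z-scored using moments from retained frames only (zero-variance voxels are
flagged degenerate and zeroed). The seed signal is the unweighted mean of
z-scored values over a 10 mm sphere (default centre: right temporo-parietal
junction, MNI [62, −34, 30]; left homologue available as a preset),
re-standardised over retained frames. Frames with seed score z > 0.84 — the
standard-normal 80th percentile — are selected. The fixed-z rule is the
default; a per-subject empirical-percentile variant is available because the
two readings coincide only for exactly normal scores. Censoring precedes
standardisation (configurable), so high-motion frames never contaminate the
moments.

**CAP estimation.** Selected frames are pooled across the derivation cohort
and reduced by PCA to the smallest number of components reaching 90%
cumulative explained variance (configurable; 1.0 gives exact reconstruction).
K is chosen by consensus clustering: for each candidate K in 2..8, 100 k-means
runs on random 80% frame subsamples; consensus(i,j) = co-clustering frequency
among co-samplings; PAC is the fraction of off-diagonal entries strictly
inside (0.1, 0.9); stability = 1 − PAC; the most stable K wins, ties to the
smaller K. Each subsample run uses a single k-means++ initialisation so that
genuine multi-modality of the partition (e.g. an arbitrary merge at too-small
K, or an arbitrary split at too-large K) surfaces as ambiguity. Final labels
come from k-means with 20 restarts, relabelled by descending cluster size so
CAP numbering is deterministic given data and seed. CAP maps are
back-reconstructed as centroid·Vᵀ + mean, z-scored across voxels, and
thresholded at |z| ≥ 1.04 (the 15% most positive / negative voxels under
normality) to define suprathreshold sets; seed voxels are removed from those
sets.

**Cross-cohort matching.** Each selected test-cohort frame is assigned to the
reference CAP with which it is most Pearson-correlated (over grey matter
minus seed voxels; exact ties break to the lower CAP index), provided the
correlation strictly exceeds that CAP's gate: the linearly interpolated 5th
percentile of the correlations of the reference cohort's own member frames
with the map. Frames failing every gate stay unassigned; retained
below-threshold frames and censored frames carry their own codes.

**Temporal metrics.** A run is a maximal block of consecutive identical CAP
labels; any non-CAP code breaks runs, so a visit interrupted by a censored
frame counts as two entries (an optional bridging mode closes single-frame
gaps). Entries = number of runs per CAP; Duration = mean run length × TR in
seconds (run-average, following the "average number of sequential volumes"
reading); Occupancy = share of assigned frames.

**Statistics.** The group comparison is a long-format OLS per metric,
`metric ~ group * state + covariates`, with type-II F tests for the state and
group×state terms and per-state group contrasts post hoc, Benjamini–Hochberg
FDR across that per-metric family. Covariates: censored-frame count, selected
volume count, age, sex, psychotropic medication, depression (BDI) and state
anxiety (STAI-S). Rank-deficient designs raise an error naming the aliased
columns. Between-cohort CAP overlap is Jaccard (in %) of the combined
suprathreshold sets after correlation-based CAP pairing (an |A∩B|/|A|
containment variant is available, since "proportion of voxels shared" admits
both readings). Clinical correlations are exploratory Pearson r (Spearman
optional), uncorrected.

## Synthetic cohorts

The generator emulates exactly the data layout the pipeline consumes. Latent
dynamics are a first-order Markov chain over `n_states` active patterns plus
an explicit inactive state; first-order dynamics were chosen because they give
closed-form ground truth for occupancy and entry rates. Patterns are
piecewise-constant over a 17-parcel synthetic parcellation (k-means on voxel
coordinates of a 12×12×12 grid of 4 mm voxels, ~1,700 grey-matter voxels)
with voxel-level jitter, z-scored, zeroed on the seed sphere and redrawn until
pairwise |r| < 0.5. Active frames carry the pattern plus a constant seed
drive, multiplied by a mean-one lognormal per-frame gain (σ = 0.3); i.i.d.
Gaussian noise (default SD 1.0 against unit-SD patterns) is added everywhere.
Both noise knobs matter for realism. The noise floor puts single-frame
correlations with the frame's own state map around 0.6–0.8, as in real CAP
data; with much cleaner frames the within-CAP correlation distribution
collapses to a point and the 5th-percentile matching gate becomes
pathologically sharp, rejecting any cohort whose state occupancies (and hence
per-voxel z-scoring scales) differ from the reference. The gain emulates the
natural fluctuation of BOLD event amplitudes. Clean recovery studies that ask
"is the estimation machinery correct?" lower the noise explicitly (SD 0.2). Motion is a small random walk with
persistent translation jumps (0.8–1.5 mm) at a configurable spike rate, so FD
and censoring are computed downstream, never faked.

The default chain places 60% of stationary mass on the inactive state. This
is deliberate: the seed indicator is binary, so its standardized active value
is √((1−p)/p) for active fraction p, which exceeds the 0.84 threshold only
for p < 0.586; at p = 0.4 active frames sit near z ≈ +1.2 with a wide safety
margin, and the selection step has genuinely sub-threshold frames to reject.
TR defaults to 2.0 s. A group effect is planted by multiplying the transition
probabilities *into* one state by a bias factor and renormalising rows.

What the generator does **not** emulate: hemodynamic convolution and
autocorrelated noise, physiological confounds, spatially correlated noise,
realistic anatomy, and between-subject spatial variability. Passing recovery
tests therefore demonstrate the correctness of the estimation machinery under
the stated model, not robustness to real fMRI artefacts.

## Validation studies

Replicated group studies (`seedcap.simulation`) share one frozen reference
study — 10 reference subjects, CAPs derived at the planted K = 4, matching
gates, and a correlation-based pairing of CAPs to planted states — and then
simulate fresh two-cohort datasets per replicate: 14 subjects per group ×
200 frames, covariates drawn independently of the dynamics (binary columns
balanced within group to keep small designs full rank). The planted effect is
a doubling (bias factor 2.0) of the inflow to one state, a strong,
interpretable effect; 200 replicates per arm. Larger recovery runs use 20
subjects × 300 frames. These sizes are the package's validation design; the
chain and noise defaults are never changed between the null and effect arms.

## Numerical choices

* PCA uses a full SVD; component count is the smallest reaching the variance
  target (tolerance 1e−12 against the cumulative sum).
* Consensus matrices are accumulated in float32 and symmetrised; pairs never
  co-sampled are excluded from PAC (and flagged).
* Percentiles use linear interpolation throughout (gates, empirical
  selection).
* k-means empty clusters trigger a re-seeded restart, erroring after 5.
* Zero-variance voxels z-score to 0 with a warning; a zero-variance seed
  score is a hard error.
* Occupancy percentages are over assigned frames and sum to 100 exactly up to
  float rounding.

## Known limitations

* The omnibus OLS treats subject×state rows as exchangeable residuals (no
  within-subject random effects); its F statistics are exact only under that
  working model.
* Consensus clustering can prefer a coarser K when merges are unambiguous;
  the stability curve is exported so alternative K values can be inspected.
* The matching gate is sensitive to distribution shift between cohorts when
  within-CAP correlation spread is very small; this is inherent to the
  percentile construction and documented behaviour, not a defect of the
  implementation.
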