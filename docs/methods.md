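# Methods

This note documents the statistical model behind `covnet`, the choices
made where the design was genuinely open, and what the synthetic tests
do and do not establish about real data.

## Metabolic covariance networks

Regional FDG uptake is summarized per VOI as the arithmetic mean of
co-registered image voxels (SUVmean, the convention for regional FDG
quantification); non-finite voxels — typically registration margins —
are excluded from the mean with a logged count.  SUVR divides every
region by the same subject's cerebellar uptake, making values invariant
to global scaling (injected dose, body weight).  Either SUV or SUVR can
feed network construction (`use="suv"` is the default in the PET runner;
both are first-class because regional comparisons conventionally use
SUVR while inter-subject covariance is often computed on SUV — the two
give different networks, since SUVR divides out a shared subject
factor).

A group's network is the inter-subject Pearson correlation matrix over
the analysis VOIs (default 10: bilateral hippocampus, dentate gyrus,
entorhinal, cingulate and retrosplenial cortex; configurable).  The VOI
list is configuration, not hard-coded: whether an analysis uses one
10×10 network over both hemispheres or two per-hemisphere matrices is a
study-level choice the caller makes by passing region lists.
Correlation is undefined for zero-variance regions; such edges are
carried as flagged-missing (NaN) and excluded from inference rather
than imputed, because silent imputation would bias permutation nulls.

## Permutation inference

With one network per group there is no subject-level variance of an
edge, so group differences are tested by relabeling subjects into
pseudo-groups of the original sizes and rebuilding both networks per
relabeling.  Choices:

* **Two-sided p with add-one correction**, p = (1 + #{|Δr*| ≥ |Δr|}) /
  (B + 1): standard for Monte-Carlo tests, cannot return p = 0, and is
  slightly conservative.  One-sided tails are available via config.
* **Exhaustive enumeration auto-activates** when C(n_A+n_B, n_A) ≤ B:
  the test is then exact (p = hits/total with the observed labeling
  included) and free of Monte-Carlo noise; it also serves as the oracle
  for the sampled path in the test suite.
* **Sampling is uniform with replacement** over assignments; the
  identity labeling is not excluded (conservative, standard).
* **Tie tolerance 1e−12**: a relabeling that reproduces the observed
  statistic must count as a hit even when floating-point summation
  order perturbs the last bits; without it exact and sampled paths can
  disagree by a full lattice step on tied partitions.
* **FDR is Benjamini–Hochberg**, applied across the unique
  upper-triangle edges of one comparison (45 edges for K = 10), with
  significance declared at q < α (α = 0.05 default).  The step-up
  adjustment is delegated to `statsmodels.stats.multitest`; the test
  suite verifies it against an independently coded step-up oracle.

Network-metric comparisons (global efficiency by default) use the same
machinery with metric(net_A) − metric(net_B) as the statistic.

## Global efficiency

Correlation weights map to hop lengths ℓ = 1/w for w > 0; negative and
missing correlations carry no connection (the standard treatment for
covariance networks — an anticorrelation is not a communication
channel; |w| weighting is available behind a flag for sensitivity
analysis).  Shortest paths are computed with Dijkstra per source; the
suite cross-checks every tested instance against a brute-force
Floyd–Warshall oracle.

E_global is the mean of inverse shortest-path lengths over ordered node
pairs, unreachable pairs contributing 0 (the Latora–Marchiori /
Brain Connectivity Toolbox definition).  The literal
"reciprocal of the average shortest path length" (1/L̄) differs
whenever distances are unequal; it is exposed as `form="inverse_mean"`
but is not the default, because the toolbox form is the one in
established use for weighted brain networks and remains defined on
disconnected graphs.  With all weights ≤ 1 every hop length is ≥ 1, so
0 ≤ E_global ≤ 1.

No density thresholding or binarization is applied by default.

## Seed-based functional connectivity

The artifact consumes spatially preprocessed BOLD data (slice timing,
realignment, normalization and smoothing are upstream concerns; the
synthetic generator produces already-coherent clusters).  Temporal
processing is linear detrend followed by a 4th-order zero-phase
(forward–backward) Butterworth band-pass at 0.01–0.1 Hz; zero-phase
filtering avoids phase distortion of the correlation estimates.

Motion QC fails a subject if any volume exceeds 1.0 mm translation or
2.0 units of rotation on any axis.  Rotation units are taken as degrees
by convention; the thresholds are exclusive ("exceeds"), so exactly
1.0 mm passes.

The seed reference is the *mean* filtered time course over the seed
mask (not the first principal component): means are the common choice,
are linear — so the equal-halves averaging invariant holds exactly —
and are robust at the small seed sizes used here.  Group statistics run
on Fisher-z maps, the variance-stabilizing transform for correlation
inference; r is clipped to ±(1 − 1e−7) first so z stays finite at
seed-internal voxels.  Voxels whose filtered series has zero variance
get NaN (undefined correlation) and drop out of group maps.

Cluster correction follows the operational rule of voxel p < 0.005
combined with cluster extent strictly > 50 voxels under 18-neighborhood
connectivity (6 and 26 selectable).  Full Gaussian-random-field
smoothness estimation is out of scope; the two operational thresholds
are applied directly.

## Synthetic cohorts: what they emulate

`CohortSpec` draws each group's subjects from a multivariate normal
with the target correlation matrix (after eigenvalue-clipping PSD
repair, re-normalized to unit diagonal) scaled by per-region standard
deviations.  Normality makes the calibration of the downstream
Pearson machinery analytic; it does not model uptake skew, outlier
animals, or scanner batch effects.  Each group draws from an
independent RNG substream (spawned in group order), so appending a
group never perturbs earlier groups' draws.

The default study conditions (`study_cohort_spec`) are four arms of
n = 8 with 10 VOIs plus cerebellum: mean uptake ≈ 2.2 SUV-like units
(cerebellum 2.0), marginal SD 0.25, within-network coupling r = 0.75 in
sham arms, 0.15 after stroke under standard housing, 0.55 under
enrichment, and a 15% (stroke-standard) / 7% (stroke-enriched)
right-hemisphere deficit in hippocampal/parahippocampal means.  These
are plausible magnitudes chosen once to produce a detectable
network-level collapse and partial recovery at n = 8; they are a
simulation scenario, not fitted estimates.

`FmriSimSpec` builds toy 4D volumes: seed voxels share one standardized
band-limited signal s; each planted cluster voxel is r·s + √(1−r²)·e
with e independent *band-limited* standardized noise, making the
population voxel–seed correlation exactly r — and, because both terms
already live in the pass band, approximately invariant under the
pipeline's own filtering.  Background voxels are white noise.  Real
BOLD autocorrelation, physiological noise, spatial smoothness beyond
the planted clusters, and motion-correlated artifacts are not modelled,
so passing tests establish correctness of the estimators, not
robustness to those nuisances.

## Numerical and degenerate-input conventions

* Correlations are clipped to [−1, 1] after computation to absorb
  rounding.
* `repair_correlation` is idempotent on valid inputs and rejects
  non-square, non-symmetric or non-unit-diagonal matrices.
* Voxelwise ANOVA/t statistics at no-variance voxels (e.g. the clipped
  seed self-correlations, identical across subjects) are guarded to
  p = 1 rather than propagating NaN.
* Multivariate draws use the eigen-decomposition sampler, which is
  well-defined for singular (PSD) covariances.
* All generators, tests and runners are deterministic given their
  seeds; the pipeline runners derive per-stage seeds from the run seed
  via seed sequences and record the config hash and seed in a manifest.

## Problem sizes in the validation suite

The statistical guarantees are exercised at the study's own scale:
n = 8 per arm and 10 regions for calibration and power experiments
(200 null repeats at B = 1000 for type-I calibration; 25 repeats for
planted-edge recovery), C(6,3) = 20-partition enumeration for exactness
checks, n = 2000 for generator calibration, and 16×16×6×240 volumes
with 60-voxel planted clusters (25 signal, 20 null repeats) for the FC
pipeline.  B = 10,000 permutations — the scale intended for real
analyses — is used in the single-run study emulation.

## Known limitations

* No partial correlation, covariate regression, or sparse
  inverse-covariance network estimation.
* No parametric (Fisher z-difference) edge test and no network-based
  statistic (NBS) cluster correction.
* No local efficiency, clustering, modularity or hub metrics — global
  efficiency is the only topological readout.
* No nuisance regression, slice timing, realignment or spatial
  normalization in the fMRI arm; inputs must be preprocessed.
* Whether FDR should pool edges across per-hemisphere matrices is a
  study-level decision left to the caller (each
  `permutation_edge_test` call corrects within itself).
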