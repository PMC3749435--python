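# Methods

This note documents the models, numerical choices and known limitations
behind `dmnpipe`: the graded preprocessing chain, the DMN detectability
read-outs, the synthetic phantom that defines the package's study
conditions, and the statistical harness.

## Preprocessing chain

The five procedures P1–P5 are cumulative.  Stage order within a grade is
fixed: outlier rejection (when enabled) runs first, before any temporal
operation, because interpolation-based volume repair and temporal
filtering both assume smooth relationships between consecutive time
points and must not see each other's artifacts.  Ventricle estimation
runs on the unsmoothed series (the CSF/parenchyma contrast of the
temporal-mean image is sharpest there) and ventricle masking is applied
before motion regression so that ventricular voxels never enter the
parenchyma average used by GSR.  Within P2, motion regression precedes
band-pass filtering; the order is config-visible but the two stages
commute up to the filtering of the regressors themselves.

### Temporal filtering

The "band-pass" is a composition of two one-sided operations: a
least-squares polynomial detrend (default order 3) acting as the
high-pass side, and an order-1 Butterworth low-pass at f₋₃dB = 0.1 Hz
applied forward and backward.  No separate high-pass corner exists; the
polynomial defines the entire low-frequency behaviour.

Numerics: the polynomial fit uses an orthonormalized Legendre basis on
[-1, 1] (QR of the Vandermonde), which is exact for polynomial inputs
and well-conditioned at order 3 and T = 200.  The low-pass is designed by
bilinear transform with frequency pre-warping, so the realized -3 dB
point equals the nominal cutoff exactly at any sampling rate; note that
near Nyquist (0.179 Hz at TR = 2.8 s) the digital response falls off
faster than the analog prototype.  The bidirectional pass squares the
magnitude response — amplitude gain 0.5 at the cutoff — and cancels
phase.  Start-up transients are suppressed by reflect-padding of
⌈3/(f₋₃dB·TR)⌉ samples, cropped after filtering.

### Nuisance regression

MPR and GSR are ordinary least squares against `[intercept | regressors]`
per voxel, implemented as one QR-based projection over all in-mask
voxels.  The intercept is always present (raw intensity series are not
zero-mean).  Rank-deficient regressor columns are dropped with a warning;
a design with no informative regressor left is an error.  Motion
regressors are the six absolute rigid-body parameters; first temporal
derivatives are available behind a config flag but default off.  GSR is
computed on, and applied to, the series produced by the preceding stages
of the grade (the chain is cumulative, so the global signal is the
filtered, motion-cleaned parenchymal mean).  A re-run of GSR is a no-op:
a global signal with numerically zero variance is treated as "nothing to
remove" rather than a rank error.  GSR recentres the brain-wide
correlation distribution and can make genuinely uncorrelated regions
anti-correlated; this documented side effect is asserted in the tests.

### Outlier rejection

The per-volume statistic is the mean square difference (MSD) from the
temporal-mean volume over the brain mask.  Detection is two-tier:

1. candidates exceed Q3 + 1.5·IQR of the MSD trace (quartiles by linear
   interpolation of order statistics — the standard Tukey fence; the
   anchor is config-exposed);
2. a candidate is rejected only if its MSD also exceeds an absolute
   reference: 10% of the mean of the three MSDs obtained by displacing
   the reference volume one voxel along each axis (computed over in-mask
   voxel pairs whose shifted source is also in-mask).  This second tier
   prevents rejections in series whose MSD trace is merely *relatively*
   variable — e.g. through slow drift — but absolutely small.

Runs of fewer than `run_length_cut` (default 10) consecutive rejected
volumes are replaced by per-voxel linear interpolation between the
nearest preserved volumes (plain copy at the series ends); runs of 10 or
more are removed from the series and the motion table, the conservative
reading of a rule specified only for "fewer than" and "more than" 10.
The MSD-over-brain-mask choice (whole-volume is the alternative) is
config-free but documented; the brain mask restricts the statistic to
voxels whose contamination matters downstream.

### Ventricle estimation

Threshold the temporal-mean image at mean + k·SD of in-brain intensities
(k = 2 by default; CSF is bright on T2*-EPI), open with a one-voxel
6-connected structuring element to kill speckles, fill holes, and keep
6-connected components of at least 20 voxels whose centroid lies in the
central 50% bounding box of the brain — a minimal stand-in for the
anatomical prior that ventricles are central.  Defaults were calibrated
on the phantom geometry (Dice ≥ 0.9 against ground truth) and are
config-exposed, since no published values exist for this step.

## Detectability read-outs

**SBA.**  Each PCC seed's mean time course enters its own per-voxel GLM
`[intercept | seed]`; the regressor t statistic is mapped to z through
the exact t and normal distribution functions (survival functions on the
appropriate tail, so the mapping is stable to |t| ≈ 37), and the two
hemispheric maps are combined with the voxel-wise maximum.  A joint
two-seed GLM is available (`joint=True`) but is not the default: with a
genuinely bilateral network the two seed time courses are nearly
collinear, and partial t statistics then split the shared variance and
suppress both maps.  Seeds with |r| > 0.999 always collapse to a single
averaged regressor.  Under a pure-noise null each hemispheric map has
the standard-normal tail (P(z > 2) = 2.275%); the max-combined map has
1 − (1 − 0.02275)² ≈ 4.50% — calibration checks therefore target the
per-seed maps.

**Spatial ICA.**  FastICA with a fixed 20 components on the in-brain
voxels-by-time matrix (voxels as samples), whitened to the component
count.  Maps are standardized to zero mean / unit variance over the
brain and sign-aligned to positive skewness; the mixing matrix provides
the component time courses.  Determinism: all stochastic behaviour flows
from the config seed.  Non-convergence triggers seed-incremented
restarts (up to five); later restarts switch from the symmetric
(parallel) update to one-unit deflation, which converges on data where
the symmetric update orbits between near-solutions.

**Component selection.**  A component is a DMN candidate if it has
supra-threshold (z > 2) voxels in at least two of the four node ROIs;
candidates are ranked by mean z inside the node union minus mean z
outside, and the two top candidates are merged by voxel-wise maximum
when they cover disjoint node sets (hemispheric splitting).  Selection
uses the *undilated* node ROIs: on a desk-scale grid the 5-voxel
evaluation dilation covers most of the brain, making dilated-mask
coverage and ranking non-discriminative (measured: the wrong component
was selected in ~90% of runs while the true network component was
present at spatial r ≈ 0.8).  `use_dilated=True` restores dilated-mask
selection for grids where the dilation is proportionally small.
Non-detection (no candidate) is a value, not an error.

**Metrics.**  Peak z per node is read inside node masks dilated by 5
iterations of a one-voxel cubic dilation (absorbing putative
normalization error, as in atlas-based evaluation); the extra-DMN extent
is the percentage of parenchyma voxels above threshold outside the
dilated union — a specificity measure.  Nodes that do not intersect the
parenchyma (lesions) are flagged missing and later imputed to the group
median.  The detectability score sums the four node scores per grade and
normalizes by the subject's best grade.

## Synthetic phantom

The phantom emulates a 200-volume, TR = 2.8 s, 2.5 mm isotropic
acquisition on a 32 x 32 x 24 grid: an ellipsoidal brain (~9 400 voxels)
with central ellipsoidal ventricles, a static baseline combining
compartment intensity (parenchyma 1000, ventricles 1800 — CSF-bright),
a smooth ±5% bias field (coil sensitivity, σ = 6 voxels) and a ±10%
shorter-scale texture (anatomy, σ = 1.5 voxels).  The texture matters
beyond realism: the displacement reference of the outlier-rejection
stage is proportional to the image's spatial gradient energy, and an
implausibly smooth phantom would make that reference artificially small.

Dynamic components, per the signal model in `synthetic_phantom`:

* network: a unit-SD Gaussian time course band-limited to 0.01–0.08 Hz
  (FFT-domain projection), amplitude 1.5% of baseline, coupled into four
  node spheres (PCC and MPFC bilateral pairs, LP left/right) with
  node-wise coupling in [0, 1];
* drift: a seeded cubic polynomial, SD 0.5% of baseline, global over the
  brain, anchored to zero at t = 0;
* motion: six random-walk traces (translations/rotations), coupled into
  the signal through six smooth per-voxel weight fields, overall
  amplitude 0.5% (control) / 2% (patient) of baseline;
* spikes: per-spike smooth random fields with SD a configurable multiple
  of the noise SD (exactly 5 spikes at 10x for the "spikey" profile;
  Poisson(8) spikes at 6–12x for "patient");
* pulsation: a sinusoid at 0.16 Hz (aliased cardiac), 2% amplitude,
  confined to the ventricles;
* thermal noise: white Gaussian, SD 10 (temporal SNR ~100 at baseline).

Profiles: `control` (small motion, rare spikes), `patient` (large
motion, frequent spikes, 1.5x ventricles, MPFC coupling 0.2 — anterior
connectivity weakened), `clean` (no spikes or motion coupling),
`spikey`, and `noise` (static anatomy plus thermal noise only).  All
parameters are overridable per call; the defaults above are the study
conditions used by the tests and the acceptance script.

What the phantom does *not* emulate: EPI susceptibility distortion,
spin-history effects, slice-timing offsets, non-stationary or
high-rank motion artifacts, and anatomical lesions.  The motion, spike,
drift and pulsation terms are each exactly low-rank, which has a
consequence worth stating plainly: spatial ICA can isolate such
artifacts at *any* preprocessing grade, so on this phantom the ICA
read-out sits at ceiling (the network component is recovered even under
P1) and the benefit of higher grades appears as "no degradation" rather
than the marked improvement seen on real patient data, where artifacts
are high-rank and break component unmixing.  The SBA specificity
pattern, by contrast, reproduces strongly: the extra-DMN extent falls
monotonically with grade and collapses once spike volumes are rejected.
Passing tests on this phantom therefore validate the machinery and the
direction of the grade effects, not the effect sizes of any real cohort.

## Statistical harness

The Friedman test uses within-row midranks and the tie-corrected
chi-square statistic, with p from the asymptotic chi-square distribution
(grades − 1 degrees of freedom).  The Wilcoxon signed-rank test drops
zero differences, midranks |d|, and computes the exact two-sided p by
dynamic programming over the doubled (integer) rank sums for n ≤ 25,
falling back to the normal approximation with continuity and tie
correction beyond.  Holm's step-down adjustment is
`max_{j≤i} (m−j+1)·p_(j)` over the ascending sort, clipped at 1.

The grade-comparison report runs one Friedman test per metric, and
adjacent-grade Wilcoxon post-hocs only for metrics whose main effect
survives a provisional Holm pass; the final Holm adjustment is then
recomputed jointly over all Friedman and performed Wilcoxon tests (one
cohort per call).  Missing cells are imputed to the per-item group
median before testing.  The builder requires at least 6 subjects.

## Problem sizes and runtime

All simulation-based checks run on the default 32 x 32 x 24 x 200
phantom: 20 replicates each for outlier-rejection sensitivity and
specificity and for the null calibration, 20 patient-profile replicates
for the grade-pattern medians, and 100 clean replicates for coupling
recovery.  These sizes put the whole acceptance recomputation at roughly
ten minutes on a single CPU while keeping the Monte-Carlo error of the
reported medians small relative to the tolerances tested.

## Known limitations

* Inputs must already be realigned and in a common space; no affine
  resampling or normalization is performed.
* The ventricle segmenter assumes CSF-bright contrast and roughly
  central ventricles; it will miss strongly off-centre CSF spaces.
* The automated DMN selection replaces the expert-observer rating of
  component maps with a coverage + goodness-of-fit rule; on real data a
  template-matching or classifier-based selector may be preferable.
* Anti-correlations are ignored throughout (only positive z enters the
  metrics), and multi-network decompositions beyond the DMN are out of
  scope.
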