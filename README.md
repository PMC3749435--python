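# dmnpipe

Graded resting-state fMRI preprocessing and default-mode-network (DMN)
detectability evaluation.

Resting-state fMRI in poorly cooperative populations — most acutely,
patients with disorders of consciousness — is contaminated by head
movement, scanner drift and pulsatile CSF signal.  Whether a residual DMN
is "detectable" in such data depends heavily on how aggressively the
series is denoised before connectivity analysis.  `dmnpipe` implements a
family of five cumulative preprocessing procedures of increasing grade,
the connectivity read-outs used to judge DMN detectability, a fully
ground-truthed synthetic 4D phantom to exercise everything end to end,
and the nonparametric statistics for comparing grades.

## The five procedures

Each grade adds stages to the previous one (realignment, slice timing and
spatial normalization are assumed done upstream; inputs live on a common
voxel grid):

| Grade | Stages |
|-------|--------|
| P1 | isotropic Gaussian smoothing (FWHM 8 mm) |
| P2 | P1 + brain masking + motion-parameter regression (MPR) + band-pass filtering (BPF) |
| P3 | P2 + global-signal regression (GSR) |
| P4 | P3 with realignment-outlier rejection (ROR) inserted before all temporal operations |
| P5 | P4 + ventricle estimation and masking (VM) |

Key definitions:

* **BPF** — fit-and-subtract of a 3rd-order polynomial in time, then an
  order-1 Butterworth low-pass with f₋₃dB = 0.1 Hz applied twice in
  opposite directions (zero phase; amplitude gain |H(f)|²).
* **MPR / GSR** — per-voxel least-squares residual against
  `[1 | regressors]`, with the six absolute rigid-body motion parameters
  (MPR) or the mean parenchymal time course (GSR) as regressors.
* **ROR** — volumes whose residual mean-square difference (MSD) from the
  temporal-mean volume exceeds the Tukey fence Q3 + 1.5·IQR *and* an
  absolute reference (10% of the mean MSD produced by displacing the
  reference volume one voxel along each axis) are rejected; runs of fewer
  than 10 consecutive rejections are repaired by linear interpolation in
  time, longer runs are removed outright.
* **VM** — ventricles segmented from the temporal-mean image (CSF is
  bright on T2\*-EPI) by thresholding at mean + 2·SD, morphological
  opening, hole filling and central-component selection.

## Detectability read-outs

* **Seed-based analysis (SBA)** — per-voxel GLM against the left/right
  PCC seed-mean time courses; t statistics are mapped to z through the
  exact distribution functions and hemispheric maps combined with the
  voxel-wise maximum.
* **Spatial ICA** — FastICA with a fixed 20 components (voxels as
  samples); the DMN component is chosen automatically by node coverage
  and goodness-of-fit ranking, merging hemispherically split pairs by
  voxel-wise maximum.
* **Metrics** — per-node peak z inside dilated node ROIs, extra-DMN
  extent (% of parenchyma voxels with z > 2 outside the dilated ROIs),
  node-pair Pearson correlations, and a within-subject normalized
  detectability score.
* **Statistics** — related-samples Friedman test (tie-corrected),
  pairwise exact Wilcoxon signed-rank tests, Bonferroni–Holm correction
  over the whole test family, group-median imputation of missing node
  metrics.

## Worked example

Generate a contaminated "patient" phantom (large motion, spike volumes,
enlarged pulsating ventricles, weakened anterior coupling) and evaluate
DMN detectability under every grade:

```python
import dmnpipe as dp
from dmnpipe.core_io import PipelineConfig
from dmnpipe.pipeline import evaluate_dmn_by_grade

bold, motion, masks, rois, truth = dp.generate_phantom("patient", seed=7)
cfg = PipelineConfig(procedure="P1", seed=7)
res = evaluate_dmn_by_grade(bold, motion, masks, rois, cfg)
for g, r in res.items():
    print(f"{g}: ICA node peak z = {r['ica_peak_z']:.2f}   "
          f"SBA extra-DMN extent = {r['sba_extra_pct']:.1f}%   "
          f"DMN detected: {r['detected']}")
```

Output:

```
P1: ICA node peak z = 6.47   SBA extra-DMN extent = 16.4%   DMN detected: True
P2: ICA node peak z = 6.42   SBA extra-DMN extent = 18.5%   DMN detected: True
P3: ICA node peak z = 6.43   SBA extra-DMN extent = 14.7%   DMN detected: True
P4: ICA node peak z = 6.45   SBA extra-DMN extent = 0.0%   DMN detected: True
P5: ICA node peak z = 6.44   SBA extra-DMN extent = 0.0%   DMN detected: True
```

The ICA read-out holds steady across grades on this phantom, while the
SBA specificity improves sharply once outlier volumes are rejected (P4)
— the extra-DMN extent, i.e. the share of parenchyma spuriously
correlated with the seeds, collapses from ~16% to zero.

The same chains are available from a shell:

```sh
dmnpipe phantom generate --profile patient --seed 7 --out bundle/
dmnpipe preprocess run --in bundle/bold.nii.gz --motion bundle/rp.txt \
    --masks bundle/ --procedure P5 --out out/
```

which writes the processed 4D NIfTI, the outlier report (JSON + TSV QC
table), the estimated ventricle mask and a stage log.

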