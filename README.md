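# dalff

Dynamic amplitude-of-low-frequency-fluctuation (dALFF) analysis for
resting-state fMRI, built as a tested, reusable pipeline:

- **Synthetic data** (`dalff.synthetic`) — 4D BOLD-like cohorts with known
  ground truth: band-limited carriers whose slow amplitude envelope differs
  between groups in planted regions (producing windowed-ALFF-CV group
  differences), Markov-switching spatial amplitude states, AR(1) noise,
  polynomial drift and Gaussian spatial smoothness.
- **Preprocessing & I/O** (`dalff.preprocess`) — NIfTI-1 read/write, initial
  volume discard, polynomial detrending, nuisance regression, Gaussian
  smoothing, in a fixed order.
- **ALFF / dALFF** (`dalff.alff`) — static ALFF (mean one-sided amplitude
  spectrum over 0.01–0.08 Hz), sliding-window ALFF (window lengths 30/50/80
  TR, step 1 TR by default), and the dALFF variability map
  CV = sample SD / mean across windows.
- **Group inference** (`dalff.inference`) — voxelwise two-group GLM with
  age/sex covariates, residual-based smoothness estimation, Gaussian-random-
  field cluster-level correction (two-tailed, separate positive/negative
  excursions), a label-permutation correction as its distribution-free
  oracle, and cluster tables (size, peak statistic, peak world coordinates).
- **State dynamics** (`dalff.states`) — L1 (Manhattan) k-means over all
  subjects' windows (cityblock assignment, component-wise-median updates),
  elbow-based k selection, and per-subject temporal metrics: fractional
  occupancy, mean dwell time, number of transitions, transition matrix.
- **Classification** (`dalff.classify`) — mean-CV-per-cluster features,
  RBF-kernel SVM with nested powers-of-2 grid search, leave-one-out /
  stratified / resubstitution evaluation, permutation test.
- **Clinical correlation** (`dalff.correlate`) — Shapiro–Wilk-routed
  Pearson/Spearman correlation of regional dALFF with a clinical score.
- **Pipeline + CLI** (`dalff.pipeline`, `dalff.cli`) — YAML-configured,
  seed-deterministic orchestration of all stages with a JSON manifest.

## CLI

```bash
dalff simulate --out data/ --seed 1 --n-per-group 10      # synthetic cohort
dalff preprocess data/sub-001_bold.nii --out pre.nii      # discard/detrend/smooth
dalff dalff pre.nii --out cv.nii --window 30              # dALFF CV map
dalff group maps/*.nii --covariates data/covariates.csv --out stats/
dalff run-all --config config.yaml --out results/ --seed 1
```

`run-all` accepts a YAML file mirroring `dalff.pipeline.RunConfig`
(window lengths, band, thresholds, k, SVM scheme, synthetic-cohort
parameters); rerunning with the same config and seed reproduces all CSV/JSON
outputs byte-identically.

## Notes

- Window-level ALFF uses an amplitude normalization under which a pure
  sinusoid of amplitude A contributes exactly A at its frequency bin; any
  consistent normalization cancels in the CV.
- CV maps can be z-standardized within the mask before group statistics
  (`standardize_cv`); note that with very large effects this shifts
  off-effect voxels of the affected group, so effect-localization studies may
  prefer raw CV maps.
- Cluster connectivity (6/18/26), tail handling, normality threshold and all
  thresholds are configurable; defaults follow common fMRI toolbox
  conventions.
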