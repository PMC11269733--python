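# vidbold

Analysis pipeline for rapid event-related **video fMRI**: experimental-design
construction, FIR deconvolution of trial-wise responses, split-half
reliability, searchlight representational similarity analysis (RSA) with
noise ceilings, voxelwise encoding models, temporal-epoch variance
partitioning, and memorability correlates — exercised end-to-end on a
synthetic BOLD generator with known ground truth.

## Who this is for

Researchers analysing (or planning) fMRI experiments in which many short
(3 s) naturalistic videos are shown in 4 s trials with 25% interleaved null
trials: a large training set with few repetitions and a small testing set
with many repetitions, spread over sessions of mixed training/testing runs.
Every stage of the pipeline is a tested library function, so the same code
runs on simulated data (where recovery can be verified against ground
truth) and on real beta estimates.

## What it computes

- **Design** — schedules with exact presentation counts (canonical scale:
  1000 training videos × 3 repetitions + 102 testing videos × 10
  repetitions = 4020 trials per participant), no video on consecutive
  trials, no back-to-back testing runs, and exact volume arithmetic
  (testing runs 268, training runs 238 volumes at TR = 1.75 s).
- **GLM** — cubic resampling of each voxel's time series to a 1 s grid,
  then a trial-wise finite-impulse-response (FIR) model with one indicator
  per (trial, delay) at delays 1–9 s post-onset, discrete-cosine high-pass
  filtering (cutoff 1/128 Hz) and pooled AR(1) prewhitening, yielding a
  beta tensor (stimulus × repetition × delay × voxel).
- **Reliability** — split-half reliability over all 126 unordered 5/5
  partitions of the 10 testing repetitions, with the Spearman–Brown
  correction `SB = 2ρ / (1 + ρ)` and a stimulus-label permutation test
  (add-one p-values) selecting reliable voxels at p < 0.05.
- **RSA** — searchlight RDMs (1 − Pearson, radius 4 voxels = 257 lattice
  points), cosine-distance metadata RDMs from annotation embeddings (the 3
  most mutually similar of 5 annotations averaged per video), Spearman RSA
  maps, subject-to-group (upper) and leave-one-out (lower) noise ceilings,
  and per-ROI ANOVA + Tukey HSD model comparison.
- **Encoding** — train-fit standardization, 100-component PCA, per-voxel
  OLS, evaluation as the mean Pearson correlation against each of the 10
  testing repetitions, noise normalization by the pre-correction split-half
  correlation, and feature-set contrasts with Bonferroni or BH-FDR control.
- **Variance partitioning** — per-TR encoding of first- and third-second
  video features (fit jointly, applied separately), unique variance
  `uA = adjR²(y ~ A + B) − adjR²(y ~ B)` with
  `adjR² = 1 − (1 − R²)(n − 1)/(n − p − 1)`, peak-TR differences, and a
  binomial test (null p₀ = 21/81) with FDR correction.
- **Memorability** — the linear decay model `m_t = m_T + α(t − T)` with
  reference lag T = 80, and voxelwise Spearman correlation between
  memorability scores and response amplitudes with one-sided group tests.

## Worked example

Recover an injected 2 s temporal-epoch lag from simulated data:

```bash
python analysis/04_temporal_varpart.py
```

prints the subject-mean unique-variance curves (signal voxels) and the
recovered lag:

```
 tr  unique_variance_epoch1  unique_variance_epoch3
  1               -0.000002                0.000036
  2                0.000648                0.000003
  3                0.019751               -0.000018
  4                0.072524                0.000097
  5                0.094807                0.016561
  6                0.070106                0.062574
  7                0.035580                0.089203
  8                0.012705                0.072511
  9                0.002702                0.041669

Modal peak-TR difference at signal voxels: 2 (100% of 300 voxels) — the
injected 2 s epoch lag is recovered.
```

The first epoch's unique variance peaks at TR 5 (the HRF peak after the
video's first second) and the third epoch's at TR 7 (two seconds later), so
the peak-TR difference recovers the lag between the two video seconds.
The other drivers follow the same pattern — e.g.
`python analysis/02_reliability.py` reports the split-half criterion's
sensitivity (0.96) and false-positive rate (7.0%) on a simulated
participant, and `python analysis/06_memorability.py` the group-level
recovery of memorability-modulated voxels (sensitivity 1.0 at 10 subjects).

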