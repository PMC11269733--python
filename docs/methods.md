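# Methods

This note documents the models, numerical choices and design decisions
behind the package, and what the synthetic-data experiments do and do not
demonstrate.

## Experimental design model

A participant's experiment is a sequence of sessions, each holding a fixed
number of training and testing runs.  Trials are 4 s (3 s video + 1 s
inter-trial interval); 25% of each run's trials are null (fixation) trials,
inserted as exactly `round(0.25 × n_trials)` per run.  With the canonical
counts this forces testing runs of 85 stimulus + 28 null = 113 trials and
training runs of 75 + 25 = 100 trials, and the volume arithmetic
`ceil((lead_in + n_trials × 4 + lead_out) / 1.75)` gives 268 and 238
volumes exactly.  Two ordering constraints are enforced by rejection
sampling with a bound of 10,000 attempts (then an error): no video on
consecutive trials within a run, and no two testing runs adjacent within a
session.  Session assignment of each video's repetitions is balanced
greedily so that every session receives exactly its share of
presentations; with repetitions ≤ sessions no video repeats within a
session.  The 25% null proportion is enforced per run (the alternative,
per session, is not distinguishable from published totals).

## Synthetic BOLD generator

Each stimulus trial adds a hemodynamic response at the trial onset driven
by the video's *first-second* latent feature vector, plus a second response
at onset + 2 s driven by its *third-second* latents (the temporal-epoch
lag).  The response amplitude at voxel v for video i and epoch e is

    a_ev(i) = (baseline/2 + l_e(i)·w_v) × (1 + effect_v × m_i)

where `l_e(i)` are k = 10 standard-normal latents, `w_v` is the voxel's
tuning (unit-norm columns scaled by `signal_sd`, nonzero only at "reliable"
voxels — 30% of the grid by default), `m_i` is the video's memorability
score and `effect_v` the memorability gain (nonzero at 20% of voxels).
The baseline term (default 6 amplitude units against `signal_sd = 1`)
represents the mean evoked visual response; it is deliberately several
times larger than the stimulus-specific modulation, because a purely
multiplicative memorability gain on zero-mean amplitudes would change the
response variance but not produce the hypothesized positive score–response
correlation.  The impulse train is convolved with a double-gamma HRF (peak
5 s, undershoot 15 s, peak:undershoot 6:1 — conventional values; the
shape is not itself under test) on a 0.25 s grid and sampled at the
acquisition TR of 1.75 s.  Noise is stationary AR(1) per voxel
(`phi = 0.3`, marginal SD `noise_sd = 1`) plus up to three cosine drift
components confined to the GLM's own high-pass band, so filtering removes
the drift by construction.  The generator is a pure function of
(config, seed).

Defaults are desk-scale: 4 subjects, 60 training / 12 testing videos, a
16³ grid; counts scale linearly with the canonical design and the trial /
repetition / session structure is preserved.  With these defaults the
split-half reliability of reliable voxels lands at roughly 0.4–0.65, the
intended regime for a well-measured experiment.

What the generator does **not** emulate: anatomical geometry, spatially
correlated (physiological) noise, motion, susceptibility artifacts,
nonlinear HRF saturation, or inter-subject anatomical variability.
Passing recovery tests therefore shows the *estimators* are correct and
calibrated under the stated noise model, not that real acquisitions meet
that model.

Two generator levels exist.  The BOLD level feeds the full
resample → FIR → analysis chain and is used by the reliability and
memorability experiments.  The beta level (`generate_beta_dataset`) draws
per-repetition FIR-like betas directly — the epoch amplitudes traced
through the HRF at delays 1–9 plus i.i.d. estimation noise — and is used
where the question concerns group inference or regression structure over
betas rather than the deconvolution itself (the epoch-lag experiment, at
the canonical 102-video testing scale).

Multi-subject experiments redraw each subject's tuning weights `w_v`
(shared reliable and effect masks, fresh directions).  With identical
weights, chance correlations between the finite stimulus sample and any
per-video covariate replicate across subjects and the group t-test
detects them — the stimulus-as-fixed-effect artifact; subject-specific
tuning restores calibration.

## FIR GLM

The acquisition TR (1.75 s) is incommensurate with the 4 s trials, so each
voxel's series is cubically resampled to a 1 s grid aligned to run start;
onsets then fall on integer volumes.  The FIR design holds one indicator
column per (stimulus trial, delay 1..9 s); null trials are unmodeled;
columns whose timepoint falls past the run end are kept but flagged
truncated and reported as missing.  Data and design are residualized
against an orthonormal discrete-cosine set (constant + `floor(2T/128)`
components); with AR(1) enabled, a single coefficient pooled over voxels
is estimated from first-pass residuals and data and design are prewhitened
before the refit.

Because trials recur every 4 s while the FIR window spans 9 s, indicator
columns of neighboring trials can land on the same timepoint; the
trial-wise design is then rank-deficient *by construction*.  The fit uses
minimum-norm least squares, which splits a shared timepoint's value
equally among the covering (trial, delay) columns.  Downstream, z-scoring
across stimuli and averaging over repetitions treat this overlap
contamination as extra trial noise.  Two measurable consequences at desk
scale: split-half correlations are bounded by the overlap geometry as much
as by sensor noise, and the permutation test's empirical false-positive
rate runs 1–2 points above the nominal 5% (the shared noise between
temporally adjacent trials mildly violates label exchangeability; verified
to persist with white noise and no drift).  Exact-recovery tests use
designs with non-overlapping trials, where ordinary least squares is
exact to numerical precision.

Localizer runs use a conventional block GLM: per-condition boxcars
convolved with the canonical HRF, OLS t-statistics per contrast, and
Bonferroni across in-mask voxels as the family-wise error control (a
deliberate simplification of random-field FWE).

## Reliability criterion

The testing set's 10 repetitions admit C(10,5)/2 = 126 unordered
complementary 5/5 partitions; counting ordered pairs would double-count
identical correlations.  For each partition the two 5-repetition averages
are Pearson-correlated across stimuli, corrected as `SB = 2ρ/(1+ρ)`
(negative correlations pass through unclipped), and averaged over
partitions.  The permutation null redraws one stimulus permutation per
iteration and applies it to one split across all 126 partitions in that
iteration; p-values use the add-one rule, so 100 permutations give a
minimum p of 1/101.  The pre-correction mean split correlation is also
retained — it is the denominator of the encoding noise normalization.

## Searchlight RSA and noise ceilings

Searchlight RDMs use 1 − Pearson between the stimulus patterns of all
voxels within a radius-4 sphere (257 lattice offsets; spheres truncate at
volume edges; spheres containing a constant stimulus pattern yield
missing RDMs).  Metadata RDMs average, per video, the 3 most mutually
similar of its 5 annotation embeddings (exhaustive over the 10 triples,
by mean pairwise cosine similarity — the selection rule is the package's
own, as "most similar" admits several readings), with multi-vector object
annotations averaged within annotator first, then take pairwise cosine
distances.  RSA correlates lower-triangle entries with tie-aware Spearman
ranks.  The upper noise ceiling correlates each subject's RDM with the
all-subject mean (including that subject — which is why under pure noise
it sits at the analytic 1/√N rather than 0), the lower with the
leave-one-out mean; the lower bound is unbiased under independence.

## Encoding models

Features are standardized with training-set statistics and compressed to
100 principal components fit on the training set (component signs fixed by
making the largest-magnitude loading positive).  Per voxel, OLS with
intercept maps components to the repetition-averaged training response;
regularization is unnecessary at ≥10:1 observation:predictor ratios and
none is used.  Accuracy is the mean Pearson correlation between the
prediction and each of the 10 testing repetitions — which equals the
correlation against the repetition mean only in the noiseless limit; both
behaviors are tested.  Noise normalization divides by the voxel's
pre-correction split-half correlation, excluding non-positive values;
normalized values may exceed 1 and are reported unclipped.  The ratio of
single-repetition prediction correlation to 5-average split-half
correlation equals 1 only in the low-noise regime; the ceiling simulation
uses repetition-noise variance 0.2× signal variance, where the analytic
ratio is ≈0.95.

## Variance partitioning

Per TR, one linear regression is trained with *both* epochs' feature sets
entered jointly as predictors; each epoch's weight block applied to its
test features yields that epoch's synthetic test response.  Fitting the
epochs separately instead leaks each epoch's signal into the other's
weights (omitted-variable bias) and demonstrably distorts the peak
locations.  Unique variance at each (center voxel, TR) is the adjusted-R²
of the regression of the measured response on both synthetic instances
minus that of the regression on the other instance alone, computed over
the stacked (videos × in-sphere voxels) observations (the 'center' mode —
videos only — is available).  Two numerical choices matter:

* every voxel's mean across videos is removed per TR before stacking —
  the stimulus-evoked baseline varies across voxels but not videos, and a
  single pooled intercept cannot absorb it; left in place it dominates
  the denominators and biases peak TRs outward;
* the searchlight regressions are evaluated from sphere-summed
  cross-moments (a convolution over the grid), algebraically identical to
  running the nested OLS fits at every center (verified against the
  direct implementation to ~1e-15).

Peak TRs take the earliest TR on ties (conservative toward smaller
differences).  The whole-brain binomial test uses null probability
p₀ = 21/81 — the fraction of ordered peak pairs on a 9-TR grid with
difference in [1, 3] under an independent-uniform null — configurable,
since the null model is a modeling choice.

## Group statistics

BH-FDR ("assuming positive correlation" read as plain Benjamini–Hochberg,
valid under positive regression dependence), Bonferroni with explicit
comparison counts (22 ROIs, 88 = 22 × 4 block comparisons, 18 = 9 TRs × 2
epochs — always passed, never inferred), exact binomial tails, one-sample
t-tests with degenerate-input handling (zero-variance data equal to the
null give t = 0, p = 1; shifted constants give p → 0), and one-way ANOVA
with Tukey HSD pairs.

## Experiment scales

All experiment sizes are the package's own desk-scale choices: reliability
recovery uses 24 testing videos × 10 repetitions over ten 32-trial runs
(one presentation per video per run, so a video never recurs inside its
own FIR window) on an 8³ grid; the epoch-lag experiment uses 300 training
and 102 testing videos at the beta level on a 10³ grid with the radius-4
searchlight; the memorability experiment runs the full BOLD pipeline for
10 subjects on an 8³ grid with 60 + 12 videos; noise-ceiling ordering and
FDR calibration use 200 Monte-Carlo replicates each.

## Known limitations

Trial-wise FIR betas on a 4 s ISI are identified only up to the
minimum-norm convention; analyses relying on absolute (rather than
z-scored, repetition-averaged) single-trial amplitudes should not use this
estimator.  The permutation reliability criterion inherits a small
(≤ 2-point) anticonservative bias from overlap noise sharing.  The
generator's noise model is temporally AR(1) and spatially independent, so
spatial statistics (searchlight smoothness, cluster extent) are not
realistic.  ROI definition assumes the anatomical masks are supplied; no
atlas is bundled.
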