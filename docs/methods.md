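# Methods

## Behavioral generative model

Each subject's go finish times are truncated-normal (mean `go_mu`, SD
`go_sigma`, resampled below 100 ms; an ex-Gaussian alternative can be wired
through `RaceModelParams` if heavier tails are wanted). On a stop trial the
stop process finishes `SSD + SSRT + ε`, `ε ~ N(0, ssrt_sigma²)` floored so
the stop latency never drops below 50 ms; the response escapes iff the go
finish precedes the stop finish, or the stop process fails to trigger
(Bernoulli `trigger_failure_rate`, default 0). Go omissions are Bernoulli
per go trial (default 6%, echoing ~94% go accuracy in child cohorts) and
are labeled GoError — a separate GLM condition. An omission on a stop trial
counts as a successful inhibition, as it would behaviorally.

The staircase starts at the design's initial SSD, moves up one step after a
successful stop and down one step after a failed stop, floored at 0 ms with
no ceiling; updates apply only to stop trials and the state carries across
runs within a subject (a continuing session, not a restart). Stop trials are
placed by a seeded shuffle of a fixed per-run count (`round(trials ×
fraction)`: 32 of 96 at 33%). The fixed-SSD adult design draws delays
cyclically from an explicit user-supplied list; the published description of
that design (eight delays derived from a practice session) is ambiguous, so
no default list pretends otherwise.

Population defaults mirror the child cohort's published behavioral summary:
go RT 504 ± 78 ms between/within, SSRT 299 ± 53 ms, 6% omissions. The
trial-to-trial stop-latency SD (30 ms) is not published anywhere we know of;
it was set to a plausible fraction of the between-subject SD.

**SSRT estimators.** Default is the integration method — the p-th
linearly-interpolated quantile of correct-go RTs minus mean SSD, p the
observed respond-given-stop probability — because the published cohort means
(go RT 504, SSD 187, SSRT 299) are inconsistent with the mean method
(504 − 187 = 317), so the mean method cannot be what produced them. Both are
implemented. On staircase data the integration estimator carries a small
negative bias (≈ −7 ms at these parameters, stable across stop-latency
variability settings); tests bound it below 10 ms rather than pretending
it away.

## Latent brain-behavior structure

One standard-normal factor `u` per child sets
`maturity = 0.55 + 0.15u` (clipped to [0.05, 0.95]),
`stn_amp = 1 + 0.25u + noise`, `ppi_gain = 0.8 + 0.3u + noise`, and
`true_ssrt = 299 + 53(−0.8u + √(1−0.64) ε)`. The −0.8 loading fixes the
population correlation between the latent factor and SSRT; imaging noise
attenuates recovered correlations toward ≈ −0.7 at the default noise level.
Adults sit at the mature end: maturity 1, unit STN amplitude, baseline
coupling gain.

## BOLD forward model

Voxel signal = Σ over conditions of amplitude-map × HRF-convolved event
indicator + a stop-specific coupling term confined to the rSTN + linear
drift + Gaussian AR(1) noise (ρ = 0.3, innovation SD 1.0 in the same
arbitrary units as the unit-scale template amplitudes — CNR of order 1, a
realistic event-related regime). Child amplitude maps are
`maturity × adult template + (1 − maturity) × idiosyncratic smooth field`
(idiosyncratic scale matched to the template's SD); the STN stop response is
then overwritten with `stn_amp ×` the unit STN profile so that latent is
exact by construction. The adult template itself — cortical bumps strongest
at rAI, a default-mode-like midline deactivation, a smooth random field for
voxel-level richness, sensorimotor activation for Go — is built from a fixed
seed: it is a property of the study design, not of the cohort draw.

The coupling term is `ppi_gain × s × centered(convolved SuccStop
regressor)` at rSTN voxels, where `s` is the seed's task signal
residualized against that run's motion and intercept and centered — the
same cleaning the analysis applies when extracting a seed series, which is
what makes the gain the exact regression coefficient of the reconstructed
interaction on noiseless data.

Motion parameters are smoothed random walks scaled to a target maximum
framewise displacement drawn from 0.1–0.8 mm; they enter the GLM as
covariates but do not corrupt the signal (no realignment artifacts are
modeled).

What the generator does **not** emulate: anatomy, smoothing/registration
artifacts, physiological noise, slice timing, multiband details,
susceptibility dropout around the STN. Passing tests therefore demonstrate
statistical correctness of the estimators under the assumed model, not
robustness to real-scanner nuisance structure.

## GLM

The canonical HRF is a double-gamma difference parameterized by its modes
(response peak exactly 6 s, undershoot 16 s, peak:undershoot 6:1, unit
peak), with no derivative terms. Events are delta onsets; the same closed
form drives synthesis and analysis, so noiseless beta recovery is exact.
Runs are concatenated with per-run intercepts and per-run motion columns;
no prewhitening or high-pass filtering is applied (AR noise inflates t
slightly — a documented limitation relative to SPM-style prewhitened fits;
optional filtering was left out rather than half-implemented). Contrast t
uses OLS per voxel, `t = c'β̂ / √(σ̂² c'(X'X)⁻¹c)`; group maps are one-sample
t-tests with zero-variance voxels flagged by signed-infinity sentinels; FDR
is Benjamini–Hochberg over the gray mask on two-sided p.

## Similarity, NMI, ROI, MVPA, gPPI choices

- Similarity shuffles the **adult** map only (child fixed), one-sided
  (positive) alternative, add-one p: minimum attainable p with 100 shuffles
  is 1/101 ≈ 0.0099. A p below 0.001 cannot arise from 100 shuffles; the
  permutation count is therefore configurable and results report the
  attainable bound.
- The similarity mask is gray matter minus sensorimotor cortex, since
  sensorimotor responses are stimulus/effector-specific; the network
  profile likewise drops sensorimotor-network ROIs before any statistic.
- NMI correlates the child t-map with the reference **t-values** (not a
  binarized mask) inside the FDR mask; r is clipped to 1 − 1e-12 before
  atanh so the index stays finite, and records note when clipping fired.
  The 3-SD outlier screen is single-pass (no iterative re-screening). Note
  a single extreme value cannot exceed 3 SD in samples smaller than ~11 —
  the screen only bites at realistic cohort sizes.
- ROI spheres use Euclidean distance from affine-mapped voxel centers; the
  packaged ROI set places the cortical (6 mm-equivalent) and STN (4
  mm-equivalent) spheres on the synthetic grid, and a CSV loader accepts
  real MNI tables. STN stop activation averages SuccStop and UnsuccStop
  betas, since neither condition preferentially drives the STN.
- MVPA uses one pattern per condition per subject (per-run exemplars are a
  flag away), linear SVM C = 1, leave-one-subject-out folds,
  standardization fit on training folds only, constant features dropped
  within folds, and a within-subject label-permutation null (add-one p).
- gPPI builds interactions in convolved (BOLD) space — seed series ×
  mean-centered convolved condition regressor, one interaction per
  condition — without hemodynamic deconvolution, which is deterministic and
  well-posed at this scale; a deconvolution variant is an extension point.
  On noiseless data the seed series is an exact linear combination of task
  regressors, so the augmented design is legitimately rank-deficient in the
  seed main effect; the fit checks identifiability of the interaction
  columns specifically and uses the minimum-norm solution, under which the
  interaction betas are unique.
- Cohen's d from r uses `d = 2r/√(1−r²)`. Applied to 2-decimal published
  correlations it reproduces six of the seven published (r, d) pairs
  exactly; the seventh (0.32 → 0.67) is the image of an unrounded r ≈ 0.3177
  and differs by one final-digit unit when recomputed from the printed r.
- Framewise displacement: Power-style, Σ|Δtranslation| + 50 mm ×
  Σ|Δrotation|, maximum over volumes.
- Confound regression: OLS of SSRT on measure + age + gender (0/1) +
  max FD, unstandardized, two-sided p per predictor.

## Problem sizes and determinism

Default study scale is 20 children + 12 adults on a 10×12×10 grid of 4 mm
voxels with full-length child runs (2 × 96 trials, 150 scans at TR 2 s) — a
scale chosen so a complete study simulates and analyses in seconds while
every estimator still has working power; the full 38-child behavioral
cohort is the behavioral default. Multi-cohort validation uses 20 seeded
replicates. All randomness in a study descends from one seed
(`numpy.random.default_rng`); pipeline stages derive their own seeds from
the run seed by fixed offsets, so stages are individually reproducible and
identical seeds give byte-identical reports.

## Known limitations

- No prewhitening: t-statistics are mildly optimistic under AR(1) noise;
  inference-sensitive conclusions in the pipeline rest on permutation nulls
  or on recovery against ground truth, not on parametric p alone.
- The integration SSRT estimator's small negative bias on staircase data is
  inherent to the estimator, not a simulator artifact.
- The synthetic grid's "MNI-like" coordinates are internally consistent but
  not anatomically meaningful; real ROI tables only make sense with real
  data on a real grid.
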