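# Methods

`dyadscope` analyses nonverbal communication between the two members of a
patient–clinician dyad recorded simultaneously: framewise facial action-unit
(AU) activations for both members (20 channels at 20 frames/s), block/trial
annotations of a cuff-pressure pain and pain/treatment paradigm, and
trial-wise parcel-level brain responses. This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Data model

An `AURecording` holds exactly 20 AU channels in a cohort-wide label order
(FACS-style codes where they exist, e.g. `AU28_lip_suck`, `AU43_eye_closure`);
a fixed channel manifest keeps causality matrices comparable across dyads.
AU values are accepted on any finite scale because every estimator z-scores
its inputs. Event windows are half-open `[onset, onset + duration)` in
seconds and map to frames as `[round(onset*rate), round(onset*rate) +
round(duration*rate))`, so a block of duration `d` always contains exactly
`round(d*rate)` frames and boundary frames are never double counted. The
patient and clinician streams are assumed pre-synchronized on a shared
clock; no resampling or lag alignment is performed.

## Pain-state classification

Frames from moderate-pain and innocuous-pressure blocks (rest, rating, and
anticipation frames excluded) are classified with a gradient-boosted tree
ensemble (XGBoost; shallow trees of depth 3, 200 rounds, learning rate 0.1
by default — all exposed). The unit of classification is the individual
frame, which matches state discrimination and maximizes sample size;
block-level aggregation can be built on the same frame table. Validation is
grouped k-fold (k = 5) with subjects as groups, so no subject contributes to
both sides of a fold; AUC is pooled over all held-out predictions and
precision/recall are evaluated at a 0.5 posterior threshold (configurable).
Feature importance is the mean absolute SHAP value per AU over all frames,
computed with XGBoost's exact TreeSHAP; ties are broken by AU label so the
ranking is deterministic.

## Echo-state Granger causality (ESGC)

For a source series *x* and target series *y*, Granger causality asks
whether the past of *x* improves prediction of *y* beyond *y*'s own past.
Both prediction models are echo-state networks: a fixed random recurrent
matrix `W` (rescaled to spectral radius 0.9 < 1, which guarantees the
echo-state/fading-memory property), random input weights, a leaky-tanh state
update

    s_t = (1 − a) s_{t−1} + a · tanh(W s_{t−1} + W_in u_t),   a = 0.3,

and a ridge-regressed linear readout (λ = 1e−2), so the only trained
parameters are the readout weights. The restricted model is driven by the
target alone (`u_t = y_t`), the full model by target and source jointly
(`u_t = (y_t, x_t)`); both predict `y_{t+1}`. The statistic is

    F_{x→y} = ln( MSE_restricted / MSE_full ),

with both MSEs pooled over held-out blocks under leave-one-block-out
cross-validation. Out-of-sample evaluation is essential here: a nonlinear
readout fits in-sample noise, and the held-out ratio is what keeps the
estimator near zero for independent series. Estimates are deliberately not
clipped at zero so the pseudo-dyad null distribution stays unbiased for
rank-based inference.

Numerical and design choices:

* **Defaults**: 100 reservoir units, 5 reservoir realizations averaged (log
  MSE ratios averaged; reported MSEs are geometric means so the log-ratio
  identity holds exactly), washout of 10 frames per block excluded from
  fitting and scoring. Recurrent weights are shared between the restricted
  and full model of a realization (variance reduction); input weights are
  drawn independently because the input dimensionality differs.
* **State reset**: the reservoir state is reset to zero at every block start,
  so no information leaks across non-contiguous blocks; permuting block
  order leaves the estimate unchanged because leave-one-block-out folds are
  a set, not a sequence.
* **z-scoring**: source and target are z-scored per fold with training-block
  statistics, which makes the estimate exactly invariant to positive
  rescaling of either series.
* **Conditioning**: causality is bivariate (pairwise), producing a
  nonsymmetric 20 × 20 (source AU, target AU) matrix per direction
  (patient→clinician and clinician→patient) — 400 estimates per direction
  per dyad — rather than conditioning on the other 18 channels.
* **Degenerate inputs**: a channel with zero variance across training blocks
  yields a flagged-missing (NaN) cell rather than an error; missing cells
  are excluded from the inference family with the family size recorded.

A classical linear Granger-causality reference (`linear_gc_reference`, the
log ratio of AR(p) OLS residual variances) serves as an independent oracle:
for `y_t = 0.8·x_{t−1} + ε` with unit variances its population value is
ln(1.64) ≈ 0.495. On such data the ESGC estimate lands in the same range
(typically 0.4–0.5 on 12 × 200-frame blocks) with the reverse direction near
zero, and on a purely nonlinear coupling with zero linear cross-correlation
(target driven by an even function of the lagged source) ESGC detects the
dependence that the linear reference misses.

## Pseudo-dyad inference

Group-level significance of each directed AU→AU cell is assessed against an
empirical null of pseudo-dyads: all ordered (patient_i, clinician_j)
pairings with i ≠ j that never actually interacted, optionally capped by a
seeded uniform subsample. Pseudo-dyad members keep their own block timings
(blocks paired by index and truncated to the shorter member), so
protocol-driven "pseudo-concordance" is present in the null and cancels.
Each cell gets a one-sided Mann-Whitney U test (real > null; exact
enumeration when min(n, m) ≤ 8 without ties, midrank normal approximation
with tie correction otherwise), and the p-grid is Benjamini-Hochberg
corrected across all cells of the direction's matrix (α = 0.05), 400 cells
per direction at the default grid. The per-dyad facial-coupling score used
downstream is the mean of the patient's AU28 (lip suck) row of the
patient→clinician matrix, i.e. the overall causal strength of the patient's
lip-suck dynamics on all clinician AUs.

## Brain-to-brain concordance

A first-level GLM per subject estimates one anticipation-phase beta per
trial and parcel (boxcar regressors convolved with a double-gamma HRF, SPM
constants: response peak 6 s, undershoot 16 s, ratio 1/6; pain and rating
periods as nuisance regressors; OLS). The 12 trial betas per parcel form
the beta series. The partner's seed-ROI trial vector (per-trial mean over
ROI parcels, z-scored across trials) is regressed on each of the subject's
parcels; with both sides z-scored the standardized slope equals the Pearson
correlation across trials. Parcel-level group inference — OLS of the
concordance coefficients on the z-scored AU28 facial score with two-sided
t-tests and BH-FDR across parcels — replaces voxelwise mixed-effects maps
with cluster correction; it plays the same inferential role at desk scale.
Dyad-level ROI-pair concordance (clinician anterior insula × patient
mid/posterior insula by default) is correlated (Pearson, two-sided p) with
the dyad-mean CARE score (mean of patient- and clinician-rated totals) and
with the patient's Berkeley negative-expressivity subscale.

## Synthetic-data generator

The generator is the package's test bed; its defaults define the study
conditions every downstream claim is tested under.

* **Dyadic AU streams**: each channel is AR(1) (coefficient 0.8, unit
  Gaussian innovations) and coupled target channels additionally receive
  `gain · tanh(source lagged by lag_frames)` — a minimal model carrying
  exactly the lagged directed dependence the ESGC stage must detect, not a
  facial-biomechanics model. Coupling is active only inside anticipation
  blocks by default (where causality is estimated); a flag extends it to
  pain blocks. The default session has 12 anticipation blocks of 6–12 s
  (uniform), split over two runs, with rest/stimulus/rating periods between.
  The cohort default plants patient→clinician edges from AU28 (to AU43 and
  AU7) and AU4→AU43, with per-dyad gains jittered by a uniform factor so
  the facial-coupling score varies across dyads.
* **Pain sessions**: two runs of 3 moderate-pain + 3 innocuous trials in
  pseudorandom order; during painful blocks the pain-expression set is
  shifted upward (AU28 +2.5, AU43 +2.0, AU7 +1.6, AU4 +1.2, with a
  per-trial offset of SD 0.3). The ordered shifts were chosen once so the
  frame-level Bayes-optimal AUC is ≈ 0.9 and the SHAP ranking has a unique
  correct order; the AU autocorrelation and noise levels are chosen for
  testability, as no empirical values are available.
* **Dyadic brains and behavior**: the trial-wise correlation between the
  clinician's anterior-insula betas and the patient's coupled-ROI betas is
  `tanh(concordance_gain × facial_score)` (gain 0.8 by default; tanh keeps
  the correlation inside (−1, 1)); other parcels are independent noise.
  CARE totals and Berkeley negative expressivity are linear in the true
  coupling plus Gaussian noise, clamped to instrument ranges (CARE 9–45,
  Berkeley subscales 6–42). Raw parcel BOLD consistent with the betas can
  optionally be emitted (TR 1.25 s) to exercise the first-level GLM end to
  end; by default betas are emitted directly to keep runs fast.

What the generator does **not** emulate: video, faces, or AU extraction;
fMRI noise beyond white parcel noise (no motion or physiological confounds);
clock drift or missing frames; non-stationary coupling. Passing tests
therefore demonstrate that the estimators recover the planted dependence
structure under idealized dynamics, not that they would do so on real video
or fMRI data.

## Problem sizes used in the test and acceptance runs

Simulation-heavy checks run at desk-scale versions of the study layout,
chosen as the package's own defaults for its verification suite:

* GC oracle: 12 blocks × 200 frames per series, 20 seeds, default reservoir
  (100 units, 5 realizations).
* Null calibration: 50 cohorts of 10 uncoupled dyads; causality estimated
  on the 4-channel pain-expression sub-grid with a 20-unit, 2-realization
  reservoir, 6 blocks of 2.5–3.5 s, pseudo-dyads capped at 20 per cohort.
* Leader-follower recovery: 20 cohorts of 6 dyads with two planted
  patient→clinician edges (gain 3.0, lag 3), 8 blocks of 3–4.5 s, 25-unit
  single-realization reservoir, pseudo-dyad cap 12.
* Classifier recovery: 8 subjects × 12 labelled blocks (19,200 frames).
* Concordance recovery: 10 cohorts of 40 dyads, 50 parcels, 12 trials.

The channel sub-grid keeps the 20-channel recording invariant intact while
letting repeated-cohort experiments run in minutes; the full 20 × 20 grid is
exercised directly in the structural checks and the pipeline.

## Known limitations

* Pairwise GC does not distinguish direct from relayed influence among AUs.
* The ESGC magnitude depends on reservoir capacity and block length; only
  its rank order across dyads (what the inference consumes) is calibrated.
* Mann-Whitney cells treat pseudo-dyads as independent samples although
  pseudo-dyads share members; the calibration experiment bounds the
  practical effect at the cohort sizes used.
* The parcel-level group model assumes homoscedastic dyads (OLS), not
  mixed effects.
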