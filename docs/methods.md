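# Methods

`neurofuse` implements a multi-feature, multimodal machine-learning pipeline
for separating dementia subtypes (behavioral-variant frontotemporal
dementia, Alzheimer's disease) from healthy controls using data pooled
across heterogeneous acquisition sites. This note documents the models,
the numerical choices, and what the synthetic validation does and does not
establish.

## Feature extraction

**EEG connectivity.** Recordings (channels × samples, assumed
artifact-cleaned upstream) are band-filtered with a zero-phase 4th-order
Butterworth filter applied forward–backward on the continuous signal, then
cut into non-overlapping 1000 ms segments (trailing partial segment
discarded). Filtering precedes epoching so segment edges carry no filter
transients. Two connectivity metrics are computed per channel pair and
averaged across segments:

- *Phase-locking value (PLV)*: |⟨exp(i(φᵢ−φⱼ))⟩ₜ| with instantaneous phases
  from the analytic (Hilbert) signal. PLV ∈ [0, 1]; 1 for a constant lag.
  Band set: delta 0.5–4, theta 4–8, alpha 8–13, beta 13–30, gamma 30–45 Hz —
  the conventional clinical bands clipped to the 0.5–45 Hz offline filter
  range; configurable.
- *Weighted symbolic mutual information (wSMI)*: each channel is mapped to
  ordinal patterns of k = 3 samples spaced τ apart (τ grid {8, 16, 32, 64} ms,
  converted to samples by floor with a minimum of 1); the pattern-sequence
  mutual information is computed with natural logs, normalized by log k!,
  with weight 0 on identical and sign-opposite pattern pairs so common
  sources and volume conduction do not contribute. Ordinal ties are broken
  by temporal order (earlier sample ranks lower), deterministically.
  Pattern probabilities are pooled within each segment, the metric is
  evaluated per segment and averaged across segments; pooling across the
  whole recording is available behind a flag.

Channel matrices are reduced to 16 regions of interest (8 channels each in
the 128-channel layout): one within-ROI feature (mean over the intra-ROI
channel pairs, diagonal excluded) and one feature per ROI pair (mean over
all cross pairs), 136 features per metric — 680 PLV + 544 wSMI features at
the default 5 bands × 4 τ values.

**fMRI connectivity.** ROI × volume series with a ROI → network map over the
five canonical resting-state networks (default-mode, salience, executive,
visual, motor). *SFC* is the within-network mean of pairwise Pearson
correlations over the full series, averaged in Fisher-z and reported
back-transformed. *DCFA* (dynamic connectivity fluctuation) is the standard
sliding-window construction: windows of 20 volumes advanced by 2, per-window
mean Fisher-z within-network correlation, feature = SD of that windowed
series (z-units). This is a reconstruction of the dynamic-fluctuation
statistic from its standard definition, not a port of any specific toolbox.
Windows containing a zero-variance ROI are dropped with a warning rather
than poisoning the SD. *Framewise displacement* is the per-volume sum of
absolute backward differences of the six realignment parameters, rotations
converted to mm on a 50 mm sphere; FD of the first volume is 0.

**Morphometry.** FreeSurfer-style plain-text stats tables are parsed
(comment lines, `Measure EstimatedTotalIntraCranialVol` header, whitespace
rows); regional volumes are reported as percentages of eTIV so head size
does not masquerade as atrophy; thickness and area pass through
unnormalized. Region names are canonicalized to lowercase with `lh_`/`rh_`
prefixes.

## Harmonization, imputation, validation plan

Subjects are split 80/20 stratified by (group × site); the 80% carries a
k = 10 inner fold assignment. All fitting operations (harmonization,
imputation, selection, tuning) see training rows only; the fit functions
raise if offered a held-out row, and the deletion-mutation check verifies
that removing any test subject changes no fitted artifact.

Site harmonization is control-referenced z-scoring: per (site, feature),
the mean and sample SD (ddof = 1) of the *training healthy controls* of that
site; every row — control or patient — is transformed with its own site's
statistics. Features with zero control variance are excluded with a log
entry rather than failing the run. No empirical-Bayes batch correction is
applied; the harmonization model is deliberately this simple.

Missing data are handled block-wise: a feature with at most 30% missing
values among training rows is filled with its single training-row mean;
features beyond the threshold are dropped (the conservative reading of an
"impute up to 30%" rule). Imputation means are training-scoped for
consistency with the harmonization leakage rule. Harmonization runs
*before* imputation (control statistics are NaN-aware): filling raw,
site-shifted values with a site-agnostic global mean and z-scoring
afterwards would mix the two scales and re-introduce a decodable site
signature — measurably so in the site audit — whereas means of harmonized
values are site-neutral by construction.

A caveat worth knowing: z-scoring against small per-site control samples
injects a site-constant noise shift of order 1/√n_HC per feature into
patient rows. With many features and few controls per site this residual is
itself decodable by a site classifier. The audit experiments therefore use
control counts comparable to a realistic multi-site cohort (dozens per
site), where the residual is far below decodability.

## Feature stabilization and site audit

Features are ranked by random-forest Gini importance (mean decrease in
impurity, 100 trees, seeded, ties broken alphabetically). Backward
elimination removes the lowest-ranked features — one at a time below 100
features, 10% blocks above (a geometric ×0.75 schedule is available for
large tables) — recording the stratified 10-fold CV accuracy (mean ± SD) of
the forest at each retained count. The ranking is recomputed after each
elimination step by default (importance drifts as features leave); a flag
freezes the initial ranking for speed. The retained set is the top-N prefix
where N is the smallest count whose accuracy is strictly inside one
standard error (SD/√k, configurable tolerance) of the curve maximum — i.e.
adding features beyond N no longer improves the classifier. Accuracy exactly
at the band edge does not qualify; a count attaining the maximum always
does.

The site audit trains a default random forest to predict acquisition site
from the selected features under stratified CV; significance is a site-label
permutation test, p = (1 + #{permuted accuracy ≥ observed})/(1 + n_perm)
with the same CV procedure per permutation (mean of fold accuracies as the
statistic). The permutation p is exact by construction at any forest size,
so scaled-down audits (smaller forests, fewer folds/permutations) remain
valid tests, just with coarser p resolution (minimum p = 1/(n_perm+1)).

## Classification

The classifier is XGBoost (regularized gradient-boosted trees,
single-thread exact tree construction for determinism). Hyper-parameters —
learning rate (log 10⁻³–0.3), minimum split loss γ (0–5), max depth (2–10),
max leaves (2–256, log), L1/L2 regularization (log 10⁻³–10), boosting
rounds (50–500) — are tuned by Bayesian optimization: a Gaussian-process
surrogate (Matérn ν = 2.5, fixed length scale 0.3 on the unit cube, no
marginal-likelihood refitting, for determinism and speed) with
expected-improvement acquisition maximized over 1000 seeded random
candidates per iteration. The stock XGBoost configuration is always the
first evaluation, then 10 random points, then GP-guided points to the
budget (default 50), so the tuned score can never fall below the default
configuration's CV AUC.

Evaluation on the held-out 20%: ROC/AUC; 95% percentile bootstrap CI over
5000 resamples of test subjects (single-class resamples are redrawn so
exactly n_boot valid resamples enter the percentile); sensitivity and
specificity at an operating threshold chosen by Youden's J on inner-CV
predictions of the training split (the threshold never sees test labels);
confusion matrix at that threshold; gain-based feature importances
normalized to shares. Patient groups are the positive class against
controls; bvFTD is positive against AD. Two models are compared by a
nonparametric permutation test that swaps their per-subject scores with
probability ½ (two-sided p on ΔAUC). BCa corrections are not applied — the
percentile interval is the documented convention here.

## Synthetic cohort generator

The generator emulates a 3-site, 3-group cohort and is the ground-truth
source for every validation experiment. All randomness derives from one
seed through counter-based substreams (`numpy` SeedSequence spawning), so
identical configurations reproduce cohorts bit for bit and any subject's
payload can be regenerated in isolation.

- *Demographics*: age ~ N(72, 8²) yr, education ~ N(14, 4²) yr,
  sex ~ Bernoulli(0.5); configurable. Groups are matched by construction,
  so demographic features carry no class signal in synthetic runs.
- *EEG*: phase-coupled oscillators. A designated ROI pair shares a common
  phase process; each channel adds an independent random-walk phase
  perturbation scaled by (1 − κ), plus optional 1/f amplitude noise. κ = 1
  with zero noise gives PLV = 1 exactly; κ = 0 gives independent phases
  (PLV at the √π/(2√M) null level per M-sample segment). The phase-walk
  step SD (default 1.0 rad/sample) is chosen so independent channels
  decorrelate within a segment. This controls phase-locking analytically;
  it makes no claim to biophysical realism (no dipole geometry, no
  volume-conduction structure beyond what the sign-flip weighting of wSMI
  is designed to reject).
- *fMRI*: blockwise multivariate normal with within-network equicorrelation
  r, resampled every 20 volumes with a configurable switch probability to an
  alternative level (−r for 2-ROI networks). switch_prob = 0 is stationary
  (DCFA ≈ 0); switching directly inflates DCFA while leaving SFC near the
  average level — the SFC/DCFA dissociation the features are meant to
  capture.
- *Morphometry*: 12 bilateral regions with typical adult volumes and 8%
  between-subject SD; dementia-sensitive regions (insula, temporal pole,
  anterior cingulate for bvFTD; hippocampus, entorhinal, amygdala for AD)
  are reduced by d·σ in patients. eTIV ~ N(1.5·10⁶, 1.2·10⁵) mm³. Written
  and re-read through the same stats-table dialect as real input.
- *Cognition*: screening and executive totals (0–30, clipped) shifted down
  by d·σ in patients, with subscores at half the effect.
- *Site effects*: per-site additive shift (z-units) and multiplicative
  scale applied after group effects. The magnitudes of real between-scanner
  effects are not identifiable from the emulated study, so defaults are 0/1
  and every experiment states its planted values explicitly.
- *Missingness*: missing-completely-at-random at the assessment-block level
  (a subject drawn missing for EEG loses all EEG features), with per-group
  block rates defaulting to the observed pattern of the emulated cohort
  (cognitive blocks 22–27%, imaging 27–28%, EEG 26–29%).
- A feature-level fast path (`simulate_feature_table`) plants group and
  site effects directly in an assembled table (unit-normal noise features;
  informative features shifted by d·σ, the second patient group with an
  alternating sign pattern so patient–patient pairs stay separable). The
  machine-learning-stage experiments use this path: at hundreds of subjects
  the raw-signal path adds hours of feature extraction without changing
  what those experiments measure.

What passing synthetic tests does **not** show: performance on real
clinical data (effects there are correlated across features and modalities,
missingness is not MCAR, site effects are not purely location/scale), nor
the validity of the upstream preprocessing (artifact rejection, FreeSurfer
reconstruction, fMRI nuisance regression) that this package deliberately
treats as done.

## Validation experiments and problem sizes

The standard self-checks (in `neurofuse.experiments`, exercised by the test
suite and `scripts/acceptance.py`) use these sizes, chosen to finish in
minutes on one CPU:

- harmonization residual: 3 × 3 × 20 cohort; the per-site training-control
  mean after z-scoring is 0 to float precision by construction.
- site-audit flip: 3 sites × (34 controls + 34 patients), 10 noise
  features, ±2 SD planted offsets; audit with 10 trees, 3 folds, 49
  permutations (minimum p = 0.02), 20 seeds. Expected: significant before
  harmonization, non-significant after, in ≥ 18/20 seeds.
- recovery: 3 sites × 60 per group per site, 5 informative features at
  d = 1.5 among 200 noise features; elimination on the geometric schedule
  with 50-tree forests and 5-fold CV; default-configuration boosting on the
  selected set; 10 seeds. Expected: ≥ 80% of planted features recovered
  (median), held-out AUC ≥ 0.9 (median).
- null calibration: same geometry with d = 0, default boosting on all
  features, 1000 bootstrap resamples; 20 seeds. Expected: the 95% CI covers
  0.5 in ≥ 90% of runs.
- dominance: effects in every modality block (d = 1.5 cognitive, 1.2
  atrophy, 0.75 connectivity); full table vs each modality subset on
  identical splits, 10 seeds. Expected: full-table AUC ≥ every subset's
  (median margin ≥ 0).
- leakage mutation: delete held-out subjects one at a time and refit;
  expected zero changed artifacts.

## Known limitations

- The DCFA statistic is a standard sliding-window reconstruction; window
  and step were not externally fixed, so absolute DCFA values are only
  comparable within a fixed parameterization.
- The wSMI τ grid and band edges are package defaults, configurable but not
  canonical.
- The elimination curve recomputes CV accuracy per retained count; at
  thousands of features the default schedule is expensive, and the
  geometric schedule or frozen ranking trades path resolution for speed.
- Bayesian tuning uses a fixed-kernel GP; it is deterministic and cheap but
  will not adapt its length scale to unusual objective landscapes.
- The bootstrap CI is percentile, not BCa; with very small test sets the
  interval endpoints sit on the discrete atoms of the resampled AUC
  distribution.
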