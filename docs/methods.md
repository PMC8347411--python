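# Methods

This note documents the models, conventions and numerical choices
behind `rpmgait`, and what the synthetic generator does and does not
emulate.

## Data model and units

A session is one sensor's recording: six uniform-rate channels —
tri-axial acceleration in g and angular velocity in deg/s — at a
nominal 1149 Hz, tagged with patient, schedule week (pre-op, Weeks 2–6,
Week 12), limb (operative / non-operative) and location (ankle /
thigh). Time is seconds from session start. On CSV import the rate is
inferred from the median time step, tolerating 1% jitter before
warning, because real loggers drift; a metadata sidecar can pin the
exact rate, making the CSV round trip lossless to double precision.

Windows are *backward*: the window ending at time t covers the
half-open interval (t − w, t]. The half-open convention means a target
time belongs to exactly one stride window and consecutive windows
partition the series without duplicated samples.

## Step detection

Foot strikes are short transients riding on the 1 g gravity baseline.
The detector:

1. high-pass filters the resultant acceleration `√(ax²+ay²+az²)` with a
   4th-order zero-phase Butterworth at 10 Hz (removes gravity and
   orientation drift without lagging the peak);
2. takes local maxima of the filtered trace above a threshold,
   separated by a refractory interval;
3. reads each event's peak off the *unfiltered* resultant at the
   detected sample, so peaks are absolute g.

Defaults: cutoff 10 Hz, threshold 0.2 g, refractory 0.25 s. The
threshold is set from the filter physics: a 50 ms half-sine transient
retains ≈ 0.41 of its raw amplitude after this filter, so 0.2 g
corresponds to a raw transient of ≈ 0.5 g above baseline — roughly ten
standard deviations above high-passed sensor noise at the 0.02 g noise
level typical of this sensor class, while still far below the smallest
simulated impact. The refractory of 0.25 s caps detection at
4 steps/s/limb, beyond any plausible walking cadence, and suppresses
filter ringing.

## Impact levels and load metrics

Peaks are binned at integer levels x = 1…200 g with
`level = floor(peak)` clamped at 200, so level x reads "at least x g".
Peaks below 1 g fall outside the level range; they are excluded from
the histogram but tallied separately. Then

* impact load `IL = Σₓ x·n_x` (g-weighted steps);
* Bone Stimulus `S = (Σⱼ nⱼ σⱼᵐ)^(1/2m)` per recording session, with
  σⱼ either the integer level (histogram mode, ≤ 200 terms, the
  default) or the exact event peak (raw mode). The exponent m defaults
  to 4 — the classic daily-stress weighting under which halving cycles
  costs far less stimulus than halving magnitude — and the root 1/(2m)
  makes S scale as √c when all peaks scale by c. Both m and the root
  convention (1/(2m) vs 1/m) are configurable because vendor
  implementations differ and neither is standardised.
* asymmetry `= (ĪL_op − ĪL_nonop)/(ĪL_op + ĪL_nonop) × 100` on mean
  load per step; it is antisymmetric under limb swap, bounded in
  [−100, 100], zero iff the means agree, and deliberately *undefined*
  (an error, not 0) when a limb has no steps — zero would misread as
  perfect symmetry. The recording session is treated as the day's full
  load exposure (patients wear the device all waking hours).

Weekly summaries report mean ± sample SD (n − 1); a single-patient
week reports SD 0 with a warning rather than NaN.

## Flexion surrogate

The estimator maps 1-s backward windows of the 24 channels from four
sensors (thigh + ankle, both legs) to the knee flexion angle at the
window's end time, trained on a paired angle trace (100 Hz in the
synthetic data; motion-capture-derived in a clinical setting). The
IMU signal is never resampled; windows are anchored at target
timestamps.

* **Feature bank**: 26 deterministic features per channel (moments,
  range/RMS, quantiles, lag-1/10/100 autocorrelation, dominant
  frequency, three fixed band energies, linear trend, endpoint values,
  absolute energy and a threshold-crossing peak count). The bank is a
  compact, config-extensible stand-in for large automated extractors;
  its size changes the feature count, not the pipeline's structure.
* **Significance filter**: per-feature Spearman rank test against the
  target with Benjamini–Yekutieli FDR control at α = 0.05 — valid under
  the arbitrary dependence that windowed features exhibit. Constant
  features are never selected. On pure-noise targets the selection rate
  stays below α by construction (BY is conservative).
* **Regressor**: random forest, 200 bootstrap trees, unlimited depth,
  √p feature subsampling, fixed seed. Features are ranked by model
  importance, the top 200 kept (or all significant ones if fewer), and
  the forest refit. Predictions are leaf averages of training targets,
  so estimated angles never leave the training target range.
* **Evaluation**: a contiguous last-25% block hold-out avoids temporal
  leakage between overlapping windows. Prediction over a session uses
  a 0.1 s default hop. Both the continuous angle trace and the
  per-activity maximum are exposed, since either may be the clinical
  quantity of interest; activity segments (walk, sit-to-stand) are
  supplied as labels, not inferred.

## PROMs scoring and reporting

OKS: 12 items scored 0–4 (4 best), summed to 0–48; item reversal is an
ingestion concern, not a scoring one. EQ-5D-3L: the additive UK
time-trade-off tariff ships as a plain-text TSV (constant 0.081,
per-dimension level decrements, any-level-3 term 0.269), anchored at
1.0 for state 11111 with floor −0.594 at 33333; other additive tariffs
load from the same format. The index is monotone non-increasing in
every dimension — verified exhaustively over all 243 states in the
tests.

Cohort reports reference PROMs to the pre-operative week and IMU
metrics to Week 2 (the first post-operative recording). Both the
difference convention ((v − b)/b·100) and the ratio convention
(v/b·100) are emitted, labeled, because published recovery figures mix
them; display columns round percents to integers. Report generation is
pure — identical inputs give byte-identical CSV/JSON.

The package ships the published weekly means of a 14-patient pilot
cohort as a reference input table. The report arithmetic applied to
those means reproduces the cohort's headline figures (+52% Bone
Stimulus and a 371% impact-load ratio over Weeks 2→6; +32%/+37% EQ-5D
and +52% OKS against the pre-operative baseline; absolute gains of
10.86 OKS points and 0.20 index points at Week 6). Patient-level
endpoint values (asymmetry −17.55 → −10.62; 6MWT 372.14 → 417 m; max
flexion 91.45° → 99.25°) appear only as formatting fixtures: the raw
recordings behind them are not public, so they cannot be recomputed.

## Synthetic generator

The generator produces the statistical structure the analysis assumes,
with exact ground truth:

* **Gait**: steps evenly spaced at the configured per-limb cadence
  (default 55 steps/min) with ±10 ms jitter, limbs half a stride apart;
  each step is a 50 ms half-sine on the axial accelerometer channel
  atop the 1 g baseline, so the resultant peak equals the drawn
  per-step peak exactly. Peaks are log-normal (μ = ln 3 g, σ = 0.4) —
  heavy-tailed like real tibial impact distributions — truncated below
  at 2.5 g: soft sub-threshold contacts are not modeled, and every
  simulated impact is unambiguous at histogram level ≥ 1 g. Sensor
  noise is white, 0.02 g on accelerometer channels (50× in deg/s on
  gyros). Asymmetry multiplies the operative limb's peaks; both limbs
  share base draws, so the mean-peak ratio equals the factor exactly at
  zero noise.
* **Recovery cohorts**: one bilateral session per patient-week, with a
  per-week overall peak scale (default 1.0 → 1.8 across Weeks 2–6) and
  per-week asymmetry factors 0.70 → 0.81, the range that corresponds to
  asymmetry indices of roughly −17.6% → −10.5% — the magnitude of
  early post-arthroplasty asymmetry. Per-patient-week seeds spawn
  deterministically from the cohort seed.
* **Flexion data**: the knee angle is `offset + amplitude·sin(2πft)`
  (defaults 30° ± 30° at 0.8 Hz); thigh and shank segment angles take
  fixed shares of it (0.4/−0.6, difference = knee angle), sagittal
  gyros carry the segment angular velocities and accelerometers the
  unit-gravity projection of the segment tilt. The mapping is smooth
  and invertible, so surrogate-recovery tests are meaningful.
* **PROMs**: OKS items Binomial(4, mean/4), EQ-5D levels categorical
  per dimension, EQ-VAS clipped normal — expected weekly scores follow
  the configured trajectory, degenerate at the anchors (all-4 items
  score exactly 48; all-ones states index exactly 1.0).

What this does **not** emulate: realistic signal morphology between
foot strikes (swing-phase dynamics, soft-tissue artifact), correlated
or non-stationary sensor noise, activity mixtures (stairs, cycling),
irregular cadence, or any musculoskeletal realism in the flexion
channels. Passing tests therefore demonstrate that the *pipeline*
recovers known structure under its stated assumptions — not that the
detector or surrogate would achieve the same fidelity on clinical
recordings.

## Problem sizes and determinism

Default test and acceptance runs use 60 s sessions (≈ 55–100
steps/limb), five-patient cohorts, 60-s flexion recordings windowed at
0.25 s hop (≈ 236 windows × 624 features), and 20 replicate seeds for
the false-selection simulation — sizes chosen so the full pipeline
exercises every code path in minutes on one core while keeping ≥ 100
steps/limb where asymmetry recovery is asserted. Every stochastic step
draws from an explicit `numpy.random.Generator`; cohort generation
spawns per-patient-week seeds via `SeedSequence`. Identical parameters
and seed give bit-identical sessions, selections, models and reports.

## Known limitations

* The vendor's proprietary step definition and its exact Bone-Stimulus
  constants (m, root) are not public; results are comparable within
  this implementation, not against the vendor dashboard.
* Integer-g binning biases mean load per step downward by up to 1 g,
  which shifts the asymmetry index by ~2 points at typical magnitudes;
  raw-event mode avoids the bias where exactness matters.
* The flexion surrogate is patient-specific and interpolative: it
  cannot predict angles outside its training range, and transfer across
  patients is out of scope.
* Inferential statistics (paired tests, ANOVA) are deliberately not
  reimplemented; the report tables are tidy inputs for any standard
  stats environment.
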