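# Methods

This note documents the models, estimators, parameter choices and numerical
conventions behind `gaitdecode`, and what the synthetic-data generator does
and does not emulate.

## Kinematics: speed and the freezing index

Instantaneous speed is the Euclidean 3-D displacement between adjacent
samples of the waist markers times the sampling rate (mm → m/s), averaged
over left/right waist when both are present; the trial's average speed is
the arithmetic mean of the instantaneous values. No smoothing is applied by
default (`speed_lowpass` in the config enables an optional low-pass); with
the generator's small vertical waist bob the inflation of speed from
vertical motion is below 1%.

The freezing index is computed per channel on the **vertical (z)**
component of the eight foot/shank/thigh/waist markers (two sides), because
trembling during freezing is most visible vertically. Each 6 s window
(0.1 s step) is linearly detrended, Hann-tapered and Fourier transformed;
iFOG = power in 3–8 Hz / power in 0–3 Hz (DC excluded; detrending removes
it anyway). Per-channel indices are **averaged** into one series; `max`
aggregation is available via `channel_agg`. The index is a power ratio and
therefore invariant to amplitude scaling of the trace.

Segmentation: maximal runs with iFOG > 3 become freezes after merging runs
separated by gaps ≤ 0.2 s and discarding runs shorter than 0.5 s. These two
values are this package's own anti-chatter choices — a 0.1 s-step sliding
estimate produces single-window blips that no clinician would call an
episode. The 1.5 s flanks become `f_pre`/`f_post`, truncated at trial
boundaries, with the freeze label taking precedence on overlap; remaining
time is walking or dual-task walking per trial metadata (a dual-task trial's
non-freeze time stays `dual_task`). Segment intervals are half-open
[start, end) and the output tiles the trial span exactly.

A centered 6 s window smears episode boundaries: detection crosses the
threshold when roughly one third to one half of the window lies inside the
episode, so the attainable interval overlap (IoU) with ground truth is
bounded below 1. With the generator's tremble-to-step power ratio (~4) the
crossing sits close to the true boundary and mean IoU is ≈ 0.9 for 4–5 s
episodes.

## Preprocessing

Filters are zero-phase (forward–backward `sosfiltfilt`) 4th-order
Butterworth: a 2–200 Hz band-pass and 4 Hz-wide band-stops at 50/100/150 Hz
(the line harmonics inside the band). Zero-phase filtering preserves event
timing (cross-correlation lag 0).

The bipolar montage differences adjacent contacts within each physical
electrode (n contacts → n−1 channels), removing any component common to the
contacts (including the common-average reference) exactly. A bipolar
channel keeps its region tag only when both contacts share a region;
mixed-region pairs are tagged `boundary` and excluded from features.
S1 channels are carried through but excluded from the 4-region feature set;
left/right STN channels are pooled into one STN feature region.

Epochs are non-overlapping 2 s windows aligned to segment onsets; partial
windows are discarded and `f_pre`/`f_post` segments contribute no epochs.
Non-overlap is a deliberate leakage/imbalance precaution.

Artifact screening is an automated surrogate for manual inspection: a trial
is rejected when its peak amplitude exceeds the session median + 8×MAD
(MAD floored so identical trials are never rejected) or its 0–1 Hz drift
power exceeds 10× the session median. Both multipliers are configurable.

## Spectral parameterization

Welch PSDs use a Hann taper with per-segment mean detrend (n_fft = 2000,
n_overlap = 1000; 1 Hz resolution at 2000 Hz). The model fit works in
log₁₀-power coordinates over 2–200 Hz, excluding bins within ±3 Hz of
50/100/150 Hz:

1. robust aperiodic fit — least squares of log₁₀P on log₁₀f, then refit on
   the points at or below the median residual so oscillatory peaks cannot
   bias the power law;
2. iterative peak extraction from the flattened spectrum — largest residual
   first, half-height width guess, stop below 0.1 log₁₀-units or at 6
   peaks; then a joint bounded Gaussian refit (width σ limited to 1–12 Hz)
   with an analytic Jacobian;
3. aperiodic refit on the peak-removed spectrum.

On noiseless power laws this recovers offset and exponent to ~3 decimals;
on realized 60 s 1/f signals the exponent is recovered within ±0.1.

Because the recordings are band-pass filtered before spectra are taken, the
known power response of the zero-phase filter cascade (|H(f)|⁴) is divided
out of the PSD before fitting (`filter_power_response`). Without this the
roll-off skirt below the 200 Hz edge bends the log-spectrum and manifests
as spurious high-frequency "peaks".

Band power is the sum of the fitted Gaussians evaluated on a 1 Hz grid over
the half-open band [low, high), so adjacent bands never double-count a grid
point and disjoint bands are exactly additive (low_beta + high_beta =
all_beta). Peaks centred inside a line-noise exclusion zone are excluded
from band power with a warning. Scale equivariance holds: multiplying the
PSD by 10 shifts the offset by 1 and leaves exponent and peaks unchanged.

The gait-artifact rule interprets "1/f power" as the integral of the fitted
aperiodic model in **linear** power units over the fit range (notch zones
omitted); a walking trial is discarded when this exceeds the session's
resting (sitting + standing average) value by more than 50%. Alternatives
(offset-only or broadband raw power) would react differently to exponent
changes; the integral responds to both offset and exponent, which matches
the broadband character of movement artifacts. The rule is applied per
trial on channel-averaged trial spectra.

## Decoding

Features: 4 regions × 8 bands = 32 periodic band powers per 2 s epoch; a
region's value is the mean across its bipolar channels; regions without
coverage yield missing values. Nested stratified 5-fold CV, per outer fold:
random undersampling of the training portion to the minority class, then
mean imputation with training-fold means (applied to both portions), then a
25-round random hyperparameter search (trees 50–500, depth 2–10, learning
rate log-uniform 0.01–0.3, subsample and column subsample 0.5–1.0, minimum
child weight 1–10) scored by inner stratified 5-fold accuracy. Undersample-
then-impute keeps the imputation means computed on exactly the rows the
model trains on. Outer folds stratify on class only; epochs of one subject
may appear on both sides of a split (pooled-epoch design) — decoding
accuracy is therefore a within-cohort, not cross-subject, estimate. If the
undersampled training fold has fewer rows per class than inner folds, the
search is skipped and documented defaults are used (a warning is emitted).

Multiclass AUC is the macro average of one-vs-rest AUCs on the pooled
out-of-fold probabilities. Feature importance is XGBoost total gain per
feature, averaged over outer folds and normalized to sum to 1. All
randomness (fold shuffling, undersampling, search sampling, tree fitting)
derives from the single `seed` argument; identical inputs and seed give
identical results.

## Statistics

* Wilcoxon signed-rank: zero differences discarded (classic convention; at
  least 5 nonzero pairs required); exact enumerated null for n ≤ 25, normal
  approximation above. Bonferroni with family size 8 (the bands within a
  region).
* Friedman omnibus on within-subject ranks; Conover all-pairs post hoc with
  the Friedman-adjusted variance, t distribution on (n−1)(k−1) degrees of
  freedom. Both are rank-based and invariant under monotone transforms of
  all cells. Note the Conover variance shrinks with the omnibus statistic,
  so under a strong omnibus effect even modest pairwise rank differences
  reach significance — a property of the test, not a bug.
* Spearman: Pearson correlation of average ranks; exact permutation
  two-sided p for n ≤ 9 (all n! orderings, vectorized), t-approximation
  above.
* Mixed model: speed = β₀ + β₁·betapower + β₂·medication + u_subject + ε,
  REML via statsmodels MixedLM; the medication term is dropped when only
  one state is present. A boundary fit (optimizer boundary report, or
  between-subject variance below 1% of residual variance) is returned with
  a `singular` flag and a warning rather than raising. Speed–beta analyses
  pair per-trial average speed with per-trial mean periodic band power.

Calibration (checked by simulation in the test suite): Friedman and LMM
type-I error within 5% ± 2% under the null; the 95% CI of β₁ covers the
true value in ≥ 90% of replicates at 12 subjects × 20 observations.

## Synthetic data

The generator realizes the statistical structure the analysis assumes:

* **Aperiodic background** — frequency-domain shaping of white noise with
  amplitude ∝ f^(−χ/2) gives an exact expected power law (defaults: cortex
  offset 1.0, STN 0.7, exponent 1.5 — typical intracranial values).
* **Oscillations** — narrowband noise with a Gaussian spectral profile
  (σ_f = band width/6) added per status segment, scaled so the *fitted*
  log₁₀ peak height equals the profile's amplitude:
  P_osc(f_c) = P_ap(f_c)·(10^h − 1). Each contact carries an independent
  realization so the bipolar montage does not cancel oscillatory power.
* **Effect profiles** — the default set encodes the effect *directions* the
  analysis is designed to detect, with parietal beta as the dominant status
  contrast (heights 0.55/0.60/0.10/0.32/0.20 for sitting/standing/walking/
  dual-task/freeze), a weaker M1-beta gradient partially restored by
  medication (+0.10), premotor alpha raised under dual-task load, STN
  low-frequency power raised during freezing, and a parietal low-gamma
  increase with gait. No published effect magnitudes exist for these
  contrasts, so the heights are free parameters of the generator, chosen
  once as plausible log₁₀-unit values.
* **Kinematics** — forward progress at the commanded speed plus a
  sinusoidal step oscillation (cadence 1.8 Hz) on the vertical component;
  freezes stall forward progress and replace the step with a 5 Hz tremble
  at ~2× amplitude; sitting/standing sway is low-amplitude 0.2–0.5 Hz
  noise. Left/right markers step in antiphase.
* **Speed–beta coupling** — per gait trial a latent parietal-beta deviation
  d ~ N(0, 0.15²) (clipped so heights stay ≥ 0) shifts the SPL beta height,
  and trial speed = subject base (N(0.9, 0.08²) m/s) + medication effect
  (+0.2 m/s in Mon) + γ·d + N(0, 0.05²), with γ = −0.3 m/s per log₁₀-unit.
  Parameterizing the coupling in the speed-on-power direction makes γ
  exactly the mixed model's target coefficient.
* **Determinism** — one master seed spawns per-subject `SeedSequence`
  children, each trial drawing from a further spawn in a fixed order;
  identical (config, seed) reproduce bit-identical samples.

Not emulated: biomechanical gait structure (heel strikes, turns), volume
conduction and electrode geometry, stimulation artifacts, non-stationary
medication kinetics, and any elevation of the freezing index during
dual-task walking without actual freezes. Passing tests therefore
demonstrate that the estimators recover what the generative model puts in —
they do not validate the clinical effect sizes themselves.

## Problem sizes

The test suite and acceptance script run scaled-down studies chosen as the
smallest sizes at which the checked properties are stable: cohorts of 2–3
subjects with 20–30 s trials (a few hundred 2 s epochs), 5–10 Monte-Carlo
seeds for recovery checks, 500–1000 replicates for error-calibration
checks, and reduced hyperparameter searches (1–10 rounds) where search
depth is not the property under test.

## Known limitations

* Pooled-epoch cross-validation overstates accuracy relative to a
  cross-subject split; the latter is out of scope here.
* The spectral model fits only a single power-law regime (no knee); very
  long recordings with a low-frequency knee would bias the exponent.
* Conover post-hoc p-values are computed unadjusted; apply `bonferroni`
  when testing many pairs.
* The EDF writer is not implemented (recordings round-trip through
  CSV + JSON sidecars); EDF files can be read when `mne` is installed.
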