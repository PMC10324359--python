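# gaitdecode

Decoding motor status in Parkinson's disease from cortico-subthalamic
recordings and gait kinematics.

Patients with Parkinson's disease move between motor statuses — sitting,
standing, walking, dual-task walking and freezing of gait — and each status
leaves a signature in the oscillatory activity of the motor network
(premotor cortex PMC, primary motor cortex M1, superior parietal lobule SPL,
subthalamic nucleus STN). `gaitdecode` implements, as a tested and reusable
pipeline, the full analysis chain that turns multichannel intracranial
recordings (ECoG strips + STN depth leads, 2000 Hz) and motion-capture
kinematics (100/200 Hz) into a motor-status decoder and the statistics
around it. Because no patient recordings are distributable, the package
ships a synthetic-data generator that emulates the statistical structure
of such a study — with full ground truth — so every stage is testable.

## The methods at its core

**Freezing index (iFOG).** Freezing-of-gait episodes are trembling-in-place:
marker power shifts from the 0–3 Hz locomotion band into the 3–8 Hz freeze
band. In a 6 s sliding window (0.1 s step), per leg-marker channel,

&nbsp;&nbsp;&nbsp;&nbsp;iFOG(t) = P(3–8 Hz) / P(0–3 Hz),

averaged across the eight foot/shank/thigh/waist channels. iFOG > 3 marks a
freeze; the 1.5 s flanks become `f_pre`/`f_post` and the rest of the trial
is walking (or dual-task walking).

**Periodic band power after 1/f removal.** Each 2 s epoch's Welch PSD
(n_fft = 2000, n_overlap = 1000) is parameterized as

&nbsp;&nbsp;&nbsp;&nbsp;log₁₀ P(f) = b − χ·log₁₀ f + Σₖ hₖ·exp(−(f−cₖ)²/2wₖ²),

an aperiodic power law (offset b, exponent χ) plus Gaussian peaks. Band
power is the area under the *periodic* component only, in eight canonical
bands (LFO 2–8, alpha 8–13, low/high/all beta 13–20/20–35/13–35, low/high/
all gamma 60–90/90–200/60–200 Hz). A walking trial whose integrated
aperiodic power exceeds the session's resting (sitting + standing)
reference by more than 50% is discarded as movement-contaminated.

**Decoding.** The 4 regions × 8 bands = 32 periodic band powers per epoch
feed a gradient-boosted tree classifier (XGBoost) under nested stratified
5-fold cross-validation: per outer fold the training portion is randomly
undersampled to class balance and mean-imputed, 25 rounds of random
hyperparameter search are scored by inner 5-fold accuracy, and the best
model is evaluated on the untouched outer fold. Reported: fold accuracies,
macro one-vs-rest AUC, pooled confusion matrix, gain-based feature
importances.

**Statistics.** Wilcoxon signed-rank contrasts (exact null for small n)
with Bonferroni correction over the 8 bands; Friedman + Conover post-hoc
comparisons of iFOG and speed across gait conditions; Spearman
correlations; and a linear mixed-effects model speed ~ beta power +
medication + (1 | subject), REML.

## Worked example

```python
from gaitdecode import CohortConfig, PipelineConfig, simulate_cohort
from gaitdecode.pipeline import run_pipeline
from gaitdecode.decode import feature_importance

cfg = CohortConfig(n_subjects=3, med_states=("Moff",),
                   trials_per_status={"walking": 2, "dual_task": 2,
                                      "freezing": 2},
                   sit_duration=30, stand_duration=30, gait_duration=20,
                   freeze_trial_duration=26,
                   freeze_intervals=((8.0, 13.0), (18.0, 22.5)))
study = simulate_cohort(cfg, seed=2)
results = run_pipeline(study, PipelineConfig(n_search=6), seed=2)

clf = results["classification"]["Moff"]
print(f"accuracy {clf.mean_accuracy:.1f}% +- {clf.sd_accuracy:.1f}, "
      f"AUC {clf.auc_macro:.2f}")
for name, share in feature_importance(clf)[:3]:
    print(f"{name:16s} {share:.3f}")
```

prints (exact numbers vary with the seed):

```
accuracy 48.3% +- 7.8, AUC 0.79
SPL_all_beta     0.065
SPL_high_beta    0.061
SPL_low_gamma    0.054
```

Five motor statuses are decoded well above the 20% chance level from a
deliberately small, noisy three-subject cohort, and the parietal (SPL) beta
features — the ones the generator makes most status-dependent — dominate
the gain importance ranking, mirroring the scientific claim the pipeline is
built to test. `results` also carries the per-trial speed/iFOG table, the
Friedman/Conover comparisons and the speed–beta mixed-model fit (a negative
beta-power coefficient, since parietal beta is suppressed at faster
walking).

The same stages are scriptable from a shell:

```bash
gaitdecode simulate --out study/ --subjects 2 --moff-only --seed 1
gaitdecode run --manifest study/manifest.tsv --out results/ --seed 1
```

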