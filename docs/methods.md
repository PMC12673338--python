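# Methods

`fnirs_decnef` implements a closed-loop decoded-neurofeedback (DecNef)
pipeline for continuous-wave functional near-infrared spectroscopy
(fNIRS): a synthetic data generator that stands in for human
recordings, the standard preprocessing chain from raw light intensity
to hemoglobin concentration changes, construction of individualized
time-resolved conflict decoders by multivariate pattern analysis
(MVPA), simulation of the real-time feedback-score loop, and the
offline behavioral/hemodynamic statistics of a blocked color-word
Stroop (CWST) neurofeedback experiment.

## The experimental model

The emulated experiment is a blocked CWST session: 60 blocks (30
congruent, 30 incongruent, pseudo-randomized), each block four
consecutive trials (0.4 s fixation + 1.1 s color-word, 1.5 s per
trial) followed by 19 s of rest, so blocks repeat every 25 s. Signals
are recorded by a 35-channel prefrontal montage at three wavelengths
(780/805/830 nm), 3.0 cm source–detector separation, 25.6 Hz sampling.

Neurofeedback blocks have a different structure: a 15 s relaxation
baseline followed by 25 s of regulation during which the participant
tries to maximize an on-screen disk whose size reflects the decoder's
incongruent-class probability, updated at 10 Hz. A training session is
30 such blocks with a rest after every fifth block.

## Synthetic generator

The generator's defaults *are* the study conditions above; everything
the source experiment leaves unstated is a modeling choice documented
here and fixed once.

**Hemodynamics.** Each block's evoked HbO response is a trial-onset
impulse train (one impulse per color-word trial) convolved with the
canonical double-gamma HRF (SPM-convention gamma shapes 6 and 16, unit
scale, undershoot ratio 1/6; the positive lobe peaks near 5 s). With
the 4-trial block this compound response peaks ~7.8 s after block
onset, inside the physiological 4–8 s range; a 6 s boxcar drive was
rejected because its convolution peaks after 8 s. Responses are
normalized so the configured amplitude is the peak concentration
change in μM. HbR is modeled as −1/3 × HbO with a 1 s lag, the typical
empirical ratio; both are configurable.

**Effect map.** The default "conflict" configuration gives 10 of the
35 channels amplitudes of 0.20 μM (congruent) vs 0.35 μM
(incongruent), and 0.15 μM condition-independent responses elsewhere.
The 0.15 μM gap was calibrated once so that full-sample decoding
accuracy in the 10–17 s window lands near 0.70 and the reduced-sample
(sham) decoder near 0.60 — the moderately-above-chance regime the
method operates in — rather than saturating at 1.0, where comparisons
between decoders would degenerate into ties. The null configuration
zeroes all amplitudes.

**Noise.** Additive per-channel noise: white sensor noise (0.05 μM SD
per sample), 1/f drift (0.03 μM), and three physiological bands —
cardiac (~1.2 Hz, 0.03 μM), respiratory (~0.27 Hz, 0.05 μM), Mayer
waves (~0.10 Hz, 0.08 μM). The oscillations are *narrowband stochastic
processes* (bandpassed white noise with bandwidths of 0.15/0.06/0.04
Hz), not fixed-phase sinusoids: real physiological rhythms are
phase-coherent over a few cycles, not over a 25-minute session.
This matters statistically: session-long phase-locked sinusoids induce
long-range across-block correlations that bias leave-one-out accuracy
below chance on null data (a finite-population artifact of the
bin-partition step), which no generic fNIRS dataset exhibits at that
magnitude. HbR receives the same physiological noise scaled by −1/3.

**Optical forward model.** Concentrations map to raw intensities via
the modified Beer–Lambert law: ΔOD(λ) = (ε_HbO(λ)·ΔHbO +
ε_HbR(λ)·ΔHbR)·d·DPF(λ), I = I₀·exp(−ΔOD), with hemoglobin molar
extinction coefficients at 760–850 nm compiled from the standard
Prahl/Gratzer tabulation (values in cm⁻¹/M at 780/805/830 nm: HbO
710.0/840.0/974.0, HbR 1075.4/753.4/693.0; linear interpolation in
between). The baseline intensity defaults to 1.0 arbitrary units —
optical density is relative, so the choice is immaterial, which a test
asserts.

**Behavior.** Reaction times are lognormal (σ_log = 0.25 around a
600 ms congruent mean — right-skewed, as RT distributions are), with
the incongruent mean shifted by the configured Stroop effect per
(group, stage). Default effects mirror the emulated study's group
means (Sham ≈ 95/97/104 ms across pre/post/follow-up; DecNef ≈
93/67/83 ms). Between-subject dispersion is a random intercept with
70 ms SD — consistent with the study's printed group dispersions — and
a 10 ms stage-to-stage jitter, a typical Stroop test–retest
variability that yields group×time interaction power ≈ 0.7 at the
study's group sizes (25 + 20). Accuracy is Bernoulli(0.97) with no
congruency effect.

**Virtual participant.** A closed-loop test harness: during
regulation it adds, on top of the physiological noise, a channel-space
pattern aligned with the decoder's incongruent class, ramping over 5 s
to an amplitude of `gain` μM. The direction is built from the
calibration-signed decoder weights on HbO/HbR features averaged over
post-onset bins; weights on derivative features are ignored because a
static pattern cannot sustain a nonzero derivative — this only lowers
the attainable score and cannot break monotonicity in the gain.

## Preprocessing

The offline chain runs in a fixed order (a configuration hash records
order and parameters): (1) intensity → optical density, ΔOD =
−ln(I/Ī) against the channel temporal mean (Homer convention — so
recovered concentrations are defined up to a per-channel constant, and
round-trip checks compare mean-centered series); (2) 0.01–1 Hz
bandpass; (3) motion detection; (4) cubic-spline correction; (5)
0.01–0.2 Hz bandpass; (6) MBLL inversion by per-sample least squares
over the three wavelengths with DPF = [6, 6, 6] and d = 3.0 cm,
output in μM; (7) for task data, segmentation into [−5, 25] s block
windows and averaging into per-condition HRFs with SEM traces.

Numerical choices:

* Filters are 3rd-order Butterworth applied forward–backward
  (zero-phase); the passband is amplitude-preserving within 5% and a
  1.2 Hz cardiac probe is attenuated below 10% through the 0.01–0.2 Hz
  band.
* Motion detection flags any sample whose 3 s window excursion
  (max − min) exceeds 60 × the channel's difference SD or an absolute
  OD amplitude criterion (default 6); flags dilate to the full window
  and a channel's wavelengths share one mask. The difference SD is a
  robust estimate (1.4826 × MAD) because the plain SD is inflated by
  the very artifacts being detected. Both thresholds, and whether the
  SD criterion applies to first differences (default) or raw OD, are
  exposed in the configuration.
* Spline correction fits a cubic smoothing spline (p = 0.99, the
  Homer default, mapped to scipy's λ = (1−p)/p convention) inside each
  flagged interval, subtracts it, and rigidly re-joins segment means to
  their neighbors; clean samples keep their shape.
* HRF averaging subtracts the pre-stimulus ([−5, 0) s) mean per
  segment by default (difference-wave analyses presuppose
  baseline-referenced traces); the toggle is exposed.
* Block time-zero is the onset of the block's first fixation.

## Time-resolved MVPA

For each 1-s bin in [−5, 25] s (31 bins; bin *t* covers [t, t+1) s)
each block contributes a 140-feature pattern: HbO, HbR and their first
temporal derivatives (central differences at 25.6 Hz) per channel,
averaged within the bin. Accuracy at a bin is estimated by the
shuffle–bin–average procedure: per condition, blocks are randomly
permuted and partitioned into 4 near-equal bins (sizes differ by at
most one: 30 → {8,8,7,7}, 14 → {4,4,3,3}) and bin-averaged, giving 8
averaged patterns; leave-one-pair-out cross-validation with a linear
SVM (C = 1) scores 8 test classifications; the shuffle repeats 100
times and accuracies are averaged. A master seed spawns one
independent stream per (bin, shuffle).

Feature screening ranks each of the 140 candidates by its
single-feature accuracy averaged over the 10–17 s post-stimulus window
(20 shuffles — screening is rank-based, so reduced Monte-Carlo
precision is acceptable) and keeps the top 35, ties broken toward the
lower feature index. Individual ranking is used rather than greedy
subset selection.

The final decoder is one probability-emitting linear model per 1-s
bin sharing the single screened feature space. Per bin, a linear SVM
is trained on all blocks' z-scored features — each block standardized
by its own pre-stimulus baseline mean/SD at the native sampling rate,
mirroring the online z-scoring so training and inference see the same
input distribution — followed by Platt scaling implemented as a
logistic fit on 3-fold cross-validated SVM margins. Decoders are
trained on raw block patterns (not bin-averaged ones): more training
data per model. The bundle persists as a single JSON file (weights,
biases, calibration parameters, feature list, metadata).

The sham decoder runs the identical pipeline — screening included —
restricted to the first 14 blocks of each condition (28 total). The
reduced sample degrades accuracy toward chance while leaving the
feedback procedure unchanged; this degradation, not a different
procedure, is the sham-control mechanism.

Known feature of blocked designs reproduced by the generator: with
25 s between onsets the [−5, 0) s baseline and late bins contain the
previous block's response tail, and in any single pseudo-random
sequence the preceding-condition composition differs slightly between
classes, so pre-stimulus bins can decode above (or below) chance
within one session. The effect averages out across sessions and
vanishes in the null configuration.

## Feedback loop

Per block: baseline statistics (mean, SD per selected feature at the
native rate) are recomputed from the 15 s relaxation window — never
carried across blocks. During regulation, every 0.1 s the trailing
1 s window is sub-sampled at 10 Hz (slot midpoints, all strictly
before the update time: the loop is causal, and replaying a recorded
stream reproduces the online scores exactly), averaged per feature,
z-scored against the baseline, and scored by the model at bin
⌊elapsed⌋ (elapsed times beyond the trained bins clamp to the nearest
model with a warning). Scores are calibrated probabilities, bounded in
(0, 1) for any input. The block score is 100 × the mean of the 250
instantaneous scores — bounded, and on the scale of reported session
scores; sum and leaky-integrator accumulators are provided as
alternatives since the original disk formula is unspecified. The sham
group's scores use the sham decoder's probabilities directly.

A property worth knowing: on task-free input (a resting participant),
calibrated probabilities sit somewhat *below* 0.5 — a resting pattern
lies on the weaker-response (congruent) side of every per-second
hyperplane — and decoders trained on fewer blocks have shallower
calibration slopes, so their out-of-distribution probabilities sit a
few points closer to 0.5. The full-vs-sham score comparison in the
test suite therefore uses an equivalence (TOST) formulation with a
±10-point margin on the 0–100 scale, an order of magnitude below the
session-score dispersion the paradigm produces across engaged
participants: deterministic virtual participants would otherwise let
arbitrarily small calibration offsets reach point-null significance.

## Offline statistics

* **Stroop effect**: incongruent − congruent mean RT over correct
  trials only (error-trial RTs confound failure modes; the filter is
  configurable), and the proportion-correct difference over all trials,
  per subject × stage.
* **Mixed ANOVA** (between = group, within = stage) via pingouin, with
  F, degrees of freedom, p, and partial η² = SS_eff/(SS_eff+SS_err);
  the test suite verifies every statistic against hand-computed sums of
  squares to 1e-10.
* **Point-by-point paired t-tests** on a common time grid, reporting
  maximal contiguous runs of p < α as second intervals; uncorrected by
  default (matching how such HRF contrasts are usually reported), with
  an optional Benjamini–Hochberg mode.
* **Accuracy–behavior correlation**: Pearson r between per-subject
  window-mean (10–17 s) accuracy and the post − pre change in the RT
  Stroop effect (the raw post-test effect is available via flag).
* **Chromophore comparison**: window-mean accuracy restricted to each
  35-feature kind (HbO, HbR, HbO′, HbR′), one-way repeated-measures
  ANOVA across kinds and all 6 pairwise paired t-tests.
* **Power analysis**: the within–between interaction of a k-group,
  m-measurement repeated-measures design, noncentral-F formulation
  with λ = f²·N·m·ε/(1−ρ), df₁ = (k−1)(m−1)ε, df₂ = (N−k)(m−1)ε
  (G*Power 3.1 convention; ρ defaults to 0.5, ε to 1). The default
  configuration (f = 0.25, α = 0.05, power = 0.80, k = m = 2) returns
  a minimum balanced N of 34. For the 2×2 case the test suite verifies
  the power value against an independent Monte-Carlo simulation using
  the textbook equivalence between the interaction F and the squared
  two-sample t on change scores. Between-group contrasts use
  independent-samples t-tests (group sizes differ).

## Problem sizes and reproducibility

Every stochastic component is driven by `numpy` seed sequences;
identical seeds reproduce synthetic sessions bit-for-bit. The heavier
test-suite checks use the full 35-channel, 60-block study conditions
with 20 seeded sessions (chance-level calibration, sham mechanism) and
3 gain levels × 20 seeds for the closed loop; structural and oracle
checks run on reduced montages. `scripts/acceptance.py` re-runs the
power analysis, the structural counts, and the 20-session null
calibration (100 shuffles per bin) from scratch with all seeds derived
from its `--seed` argument.

## What passing tests do and do not show

The generator emulates the *structure* of a blocked Stroop fNIRS
experiment — condition-dependent double-gamma responses, realistic
noise spectra, motion artifacts, lognormal RTs — but not scalp/skull
optics, photon transport, superficial-layer physiology, eye/EMG
artifacts, or real inter-subject variability in channel sensitivity.
Chance-level calibration, the sham degradation, detector sensitivity
and closed-loop monotonicity on this generator validate the pipeline's
statistical machinery; they are not evidence about any particular
human dataset. Short-channel regression is deliberately absent from
the preprocessing chain (the emulated setup has no short channels), so
systemic physiology is only attenuated by the 0.01–0.2 Hz bandpass,
not regressed out.
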