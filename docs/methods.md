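# Methods

## Scope and design

`heplpp` implements a between-group ERP analysis of interoception–emotion
coupling: heartbeat-evoked potentials (HEP) computed from heartbeats in the
pre-stimulus anticipation window, late positive potentials (LPP) evoked by
emotional faces, sensor-level cluster-based permutation statistics for group
differences, and partial-correlation / stepwise-regression linkage between
the two ERP indices. Because raw clinical recordings for this design are
not publicly distributable, the package pairs the analysis chain with a
synthetic cohort generator whose ground truth is known exactly; every
pipeline stage is validated by parameter recovery against that truth.

## Data model and conventions

All signals are microvolts in a `channels × samples` float array with one
uniform sampling rate; exactly one channel has the `ecg` role. Event onsets
are seconds from recording start; the sample of an onset is
`round(onset_s * fs)` and every window is the half-open sample interval
`[start, end)` — one fixed convention in place of the usual off-by-one
ambiguity. Recordings interchange as EDF (16-bit, 1-second records,
written by a built-in minimal writer and read through MNE; amplitudes are
quantized to the 16-bit range of each channel, and signals are zero-padded
to whole seconds). Events are BIDS-style TSV; montages are plain
`label x y z` text with standard 10-10 positions available from MNE.

## Synthetic cohort generator

The generator's defaults are the study conditions:

| parameter | default | note |
|---|---|---|
| group sizes | 27 + 27 | MDD-like / HC-like |
| trials | 300 (100 per emotion) | 20 % capture trials, spread evenly |
| timing | cue U(1.5, 2.5) s → face 2.5 s → ITI U(2.5, 3.5) s | |
| sampling | 1000 Hz, 47 scalp channels + ECG | 10-10 cap minus peri-orbital rows |
| heart rate | 70.4 ± 8.8 (MDD), 69.9 ± 7.6 (HC) bpm | truncated at the 86 bpm cap; 40 ms beat-to-beat jitter |
| background | pink (1/f-power) noise, 12 µV SD; 50 Hz line, 2 µV | |
| CFA | per-channel gain ~N(0.02, 0.01) on the ECG waveform | instantaneous linear mixing |
| HEP | 2.0 µV (HC) vs 0.8 µV (MDD), subject SD 0.6 | on F2/F4/F6/FC2/FC4/FC6, 455–595 ms post-R |
| LPP centroparietal | HC 6/5/4, MDD 4/3/2 µV (sad/happy/neutral) | C4/CP4/CP6, 300–1000 ms |
| LPP frontocentral | HC 1/1/1, MDD 3/1/2.5 µV | F5/F3/FC5/FC3/FC1 |
| artifacts | 10 % of trials get a ±500 µV, ~25 ms transient | matches ≈90 % trial retention |
| HCT accuracy | 0.3 ± 0.2 (MDD), 0.5 ± 0.2 (HC), truncated [0, 1] | |
| questionnaires | group means/SDs of the published summary table | truncated at instrument bounds |

The ECG is a sum-of-Gaussians PQRST template (P −180 ms, Q −25 ms, R 0,
S +25 ms, T +220 ms relative to R). The template is numerically negligible
beyond ~450 ms after R, so the 455–595 ms HEP index window is free of
cardiac field artifact *by construction*; what leaks into that window in
practice is only the zero-phase high-pass response to the large QRS
deflection, which is shared by both groups and is exactly what the
ECG-amplitude confound check measures.

Evoked components are raised-cosine bumps spanning their analysis windows,
scaled so the **mean over the window equals the configured amplitude** —
the pipeline's mean-amplitude index therefore estimates the injected
amplitude directly. Bumps are band-limited well inside 0.3–30 Hz.

Subject-level coupling: within the MDD-like group only, a subject's sad
frontocentral LPP amplitude is the group mean plus
`slope × (subject HEP − group HEP mean)` plus a small residual. The
residual SD (0.05 µV) and slope (1.0) make within-patient coupling nearly
deterministic: the generated condition is that the linkage is reliably
detectable in the patient group, so recovery experiments probe *group
specificity* (patient group flagged, control group not) rather than
statistical power. `simulate_measured_effects` additionally provides the
subject-level table the EEG pipeline would produce, adding 0.2 µV
measurement noise per cluster mean — the residual of averaging ~10 µV
single-epoch noise over the study's hundreds of epochs and several
channels — plus two uncoupled decoy HEP clusters for model-selection tests.

Determinism: every output is a pure function of `(config, seed)`; cohorts
derive per-subject seeds from one `SeedSequence`, and the behavioral and
signal simulators draw subject-level traits in a single fixed order so the
two stay consistent for the same subject seed.

### What the generator does *not* emulate

Ocular/EMG artifact morphology (transients are generic high-amplitude
spikes), head-model-based forward projection (components are injected on
named channels; the cardiac field is instantaneous mixing), heart-rate
dynamics beyond IBI jitter, and habituation or sequence effects. Passing
recovery tests therefore demonstrates that the *analysis chain* is correct
and calibrated, not that it is robust to every pathology of real
recordings; in particular ICA-based artifact separation is intentionally
out of scope, with threshold-based trial rejection in its place.

## Preprocessing

Zero-phase (forward–backward) 4th-order Butterworth band-pass, 0.3–30 Hz
on scalp channels; the ECG channel gets its own 0.5–40 Hz band so the QRS
survives for detection. Zero-phase filtering preserves component latencies;
band edges outside Nyquist are rejected. Common average reference subtracts
the instantaneous scalp mean (ECG untouched; idempotent). Note two
inherent, documented consequences: (i) an AC-coupled chain cannot keep the
DC level of a repeated bump train, so measured component amplitudes are
scaled down by roughly the component's duty cycle (~16 % for the HEP at
70 bpm) — group *contrasts* are preserved, and unbiasedness tests run on
unfiltered data; (ii) the average reference redistributes any signal shared
by k of n channels, subtracting k/n of it everywhere, so small
opposite-sign effects appear off-cluster.

## Cardiac chain

R-peak detection follows Pan–Tompkins: 5–18 Hz band-pass, derivative,
squaring, 150 ms moving-window integration, adaptive threshold (25 % of the
99th percentile of the integrated trace) with a 250 ms refractory period,
then re-alignment to the raw R maximum within ±50 ms after an automatic
polarity check. Flat input returns an empty series with a warning. The
heartbeat-counting score inserts the absolute value into
(1/5)·Σ(1 − |recorded − counted| / recorded) so over-counting cannot score
above a perfect 1.0; the score is otherwise not clamped. Heart-rate
exclusion drops subjects strictly above 86 bpm (exactly 86 keeps), with the
threshold configurable.

## Epoching

LPP epochs: −200…1000 ms around each non-capture face onset, baseline
−200…0 ms, index window 300–1000 ms. HEP epochs: −100…600 ms around R
peaks whose full epoch lies inside a cue period *and* starts at least 1 s
after the most recent face onset (suppressing visual-evoked overlap); no
baseline by default, because the pre-R interval belongs to the previous
cardiac cycle and the group contrast is taken at matched latencies. Each
HEP epoch carries the upcoming face's condition label, but the primary HEP
average pools all cue-period beats; the HEP index window default is
455–595 ms with 455–550 ms available as a configuration choice (both
windows appear in the source literature for this design). Epochs that
would leave the recording are dropped with a logged reason. Rejection
marks any trial whose any scalp channel exceeds 100 µV peak-to-peak
(order-independent, combines with existing masks); subjects with any
condition under the 70-trial floor are excluded with that rule recorded.

## Cluster statistics

Electrode adjacency defaults to Delaunay triangulation of the montage's
azimuthal-equidistant 2-D projection, with a distance-quantile graph as
fallback for degenerate geometry. The cluster statistic is the sum of
member t values (two-sided via max |mass|), forming threshold from the t
distribution at α = 0.05 two-sided; permutation relabels *subjects*, never
trials. When the number of distinct relabelings is at most `n_perm`, the
null is enumerated exactly and p is the exact proportion; otherwise
Monte-Carlo with the add-one rule, so p ∈ [1/(n_perm+1), 1]. Group sums
are computed per group (not as total-minus-group) so the complementary
relabeling is exactly antisymmetric in floating point — this is what makes
exact-enumeration p values reproducible against an independent oracle tie
for tie.

## Association statistics

Student's pooled-variance t is the default (Welch optional) and is
computable identically from raw values or printed (mean, SD, n) summaries;
with the patient group passed first, it reproduces the published
state-anxiety t of −10.161 to three decimals, as does the Pearson χ²
(0.076, no continuity correction) on the published sex table. Partial
correlation residualizes both variables on the controls plus intercept;
p uses df = n − k − 2; a variable fully explained by the controls gets
r = 0 by convention; rank-deficient controls are an error naming the
collinear columns. Stepwise regression is classical forward selection with
backward checks (entry p ≤ 0.05, removal p ≥ 0.10, ties broken by column
order, iterated to a fixed point), reporting B, SE, p, standardized β, R²,
adjusted R², F and the model p. Gender is coded F = 0 / M = 1; continuous
candidates are z-scored (SD with denominator n − 1). The linkage analysis
computes the full HEP × LPP partial-correlation grid per group (constant
covariates within a group — e.g. illness duration in controls — are
dropped) and fits the patient-group stepwise models: sad frontocentral LPP
from HEP clusters + gender, and sad centroparietal LPP from HEP clusters +
gender + the BDI cognitive factor. No multiple-testing correction is
applied across the correlation grid by default, matching the source
procedure; raw p values are reported.

## Pipeline

`run_all` chains simulate (or load) → filter → re-reference → R-peak
detection → heart-rate / capture-response exclusions → LPP and HEP epoching
and rejection → per-electrode mean-amplitude matrices → cluster permutation
tests (HEP pooled; LPP per condition) → ECG confound t test → linkage on
cluster means (significant clusters where found, the configured channel
sets as fallback). The report embeds the resolved configuration and every
exclusion with its rule, and is deterministic given the seeds. The covariate
list is truncated to fit the analyzed group size (full set at n = 27).

## Problem sizes and numerical choices

Tests and the acceptance script run the full-EEG paths at reduced problem
sizes chosen once — channel subsets (9–18 channels covering all injected
cluster sites) with 12–45 trials for unit and recovery tests, and a
10 + 10-subject, 80-trial, full-montage cohort for the end-to-end
demonstration — while
behavioral and statistics-level paths (heartbeat counting, measured-effects
recovery, calibration experiments) run at the study scale of 27 + 27.
A full 300-trial single-subject session is simulated for trial accounting.
Condition parameters (rates, amplitudes, noise, timing) are never altered
for testing; only problem sizes are.

Known numerical choices: EDF round trips are exact only to 16-bit
quantization of each channel's range; epoch windows are resolved to whole
samples by rounding; the permutation p under exact enumeration includes the
identity relabeling; the cluster-forming threshold uses the pooled-t df of
the observed group sizes; `zscore` refuses constant input.

## Limitations

Single-electrode-domain clustering only (no electrode × time clustering,
no TFCE, no source localization); no ICA; the generator's cardiac field is
a single spatial pattern per subject rather than a dipolar field; the
heartbeat-counting task's known biases (belief-based counting) are not
modeled — the generator writes the accuracy distribution directly. The
"control group non-significant at α = 0.05" criterion used in recovery
experiments has an irreducible ~5 % per-seed failure rate; across 20-seed
experiments the expected group-specificity rate is therefore ≈ 0.95, not 1.
At the demonstration scale (10 subjects per group), the between-subject
amplitude SD alone makes cohort-level cluster p values volatile — a cohort
can draw a true group difference half the population value — so the
end-to-end run reports the recovered amplitude difference alongside the
cluster p rather than treating the p value as a stable summary.
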