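# Methods

This note documents the models behind `impedcyto`, the parameter defaults
and why they were chosen, and what the synthetic-data generators can and
cannot show about real measurements.

## Signal model

A cell transiting the Coulter aperture displaces electrolyte in proportion
to its volume, so the noiseless pulse peak is `gain × d³` with `d` the cell
diameter in µm. The default gain, 1.6 × 10⁻³ V/µm³, places the lymphocyte
amplitude mode near 1 V and the granulocyte+monocyte mode near 3.5 V, with
the 0.5 V detection threshold sitting well below the smallest lymphocyte
pulses — the regime in which a counter is actually operated. Pulses are
Gaussian bumps (σ = width/4) rather than rectangles: a cell has a finite
rise time through a 30 µm × 15 µm aperture, and the Gaussian keeps the peak
amplitude exact while giving the filters something realistic to act on.
Pulse width is the transit time, inversely proportional to total stream
flow; at the default 10 µl/min total flow it is 100 µs (25 samples at
250 kHz).

Disturbances are additive: a sub-20 Hz baseline-drift sinusoid, power-line
tones at 60 and 120 Hz, optional residual carrier, and white Gaussian noise
(default SD 0.05 V, i.e. SNR ≥ 20 for every pulse class).

### Filter chain

Each stage is a Butterworth design applied forward-backward
(`sosfiltfilt`), so the chain is zero-phase: peak times and amplitudes used
downstream are not skewed. Defaults: 4th-order 20 Hz high-pass; band-stops
at (58, 62) and (118, 122) Hz realized at half the nominal order so every
stage has the same overall order; low-pass at the configured cutoff. A
low-pass cutoff at or above 0.45 × the sampling rate is unrealizable as a
digital filter (the reference configuration's 303 kHz cutoff exceeds the
125 kHz Nyquist frequency of 250 kHz sampling); that stage degrades to an
identity and logs a warning instead of failing the chain.

Measured on pure tones, the chain attenuates 60 and 120 Hz by > 20 dB,
suppresses a 0.5 V, 2 Hz drift to a residual mean below 0.01 V, and changes
a reference pulse's peak by < 1%.

### Detection and baseline noise

A pulse is a maximal run of samples above threshold; runs separated by
fewer than 20 samples are merged, because noise can dip a true pulse below
threshold within one transit. Width is run length × sampling interval; area
integrates the run above zero (whether the reference analysis integrated
above zero or above a local baseline is not documented; above-zero is the
implemented convention). The baseline SD is estimated in two passes: a
rough exclusion at 5 × a MAD-based global SD with ±1 ms guard bands, then a
plain SD on the remaining pulse-free samples. The default threshold policy
couples the two definitions used in practice — max(0.5 V, 10 × baseline
SD).

### Gating

The amplitude histogram uses Freedman–Diaconis bin widths capped at
range/40 (floor 0.02 V); the cap matters because on a bimodal sample the
broad granulocyte+monocyte mode inflates the IQR and uncapped FD bins
cannot resolve the valley. Counts are smoothed with a 5-bin moving average,
the two largest modes located, and the threshold placed at the deepest
local minimum strictly between them (ties broken toward the mode
midpoint). Amplitudes below the threshold are lymphocytes; at or above,
granulocytes+monocytes (the boundary value goes to g+m). A unimodal
histogram raises an error rather than guessing. Area histograms are
computed but never used for gating — at realistic noise the lymphocyte
area population merges with the noise floor.

Concentration = count / (blood flow × duration); only the blood pump rate
enters, because buffer flows dilute the stream without adding cells. The
dilution factor (total/blood flow ≈ 19.3 at default pump rates) is
reported for reference.

## Capture model and calibration

Granulocytes+monocytes are captured in the antibody chamber with
probability `P = 1 − exp(−κE)` for per-cell CD64 expression `E`. The
supplementary theory of antibody capture only guarantees monotonicity in
antigen density; this saturating one-parameter form is chosen because it is
identifiable from a single dose–response and is linear in the small-κE
regime, matching the observed linear percent-capture vs nCD64 relation.
The default κ = ln 2 / 2.43 ≈ 0.285 puts a sample at nCD64 = 2.43 at 50%
capture — the documented operating point of the reference chamber.
Per-cell expression is log-normal with median equal to the sample's nCD64
(MFI histograms are right-skewed; σ = 0.35). Lymphocytes are essentially
CD64-negative and are not specifically captured; instead the exit
lymphocyte count is multiplied by 1.27 by default, emulating the observed
127% lymphocyte recovery downstream of the chamber (configurable to 1.0).

The count-level calibration cohort draws true nCD64 log-normally with
median 2.0 and log-SD 0.472 — a 50% cohort CV, between the observed group
CVs of 46.07% (septic) and 56.60% (non-septic). Entrance g+m counts are
Poisson (mean 1,700 ≈ 20 s of counting at a typical differential), and
both counts receive 1% multiplicative measurement noise: entrance and exit
pass through the same gating, so systematic counting bias largely cancels
in the differential and only a small independent error remains.

Calibration is ordinary least squares under repeated k-fold
cross-validation (default 3 folds × 1,000 random re-partitions). Each
sample's reported prediction is the **mean of its held-out predictions**
across rounds (not a final refit), and the model's slope/intercept are
means over all training fits. Negative percent-capture values (noisy
counts can put exit above entrance) are retained for fitting, not
truncated. Predictions are clipped at 0 from below, since nCD64 is
non-negative. Under these defaults the held-out R² against true nCD64 is
≈ 0.9; the residual comes mostly from the saturating tail of the capture
law, not from counting noise.

Bin-agreement accuracy uses bins anchored at 0 (so bins are comparable
across cohorts): two values agree at bin size `s` when
`floor(pred/s) == floor(control/s)`. Accuracy is guaranteed non-decreasing
only along nested coarsenings (s, 2s, 4s, …), which is how it should be
read.

## Clinical statistics

- **Bland–Altman**: differences are device − reference, so the sign of the
  bias is meaningful; limits of agreement are bias ± 1.96 × sample SD.
- **ROC/AUC**: trapezoid rule over all thresholds with simultaneous steps
  at ties, which makes the AUC equal the Wilcoxon–Mann–Whitney concordance
  probability (ties counted half) — asserted against a brute-force
  pairwise oracle in the tests.
- **Correlation power analysis**: Fisher-z,
  `N = ((Zα + Zβ)/arctanh ρ)² + 3`, rounded to the nearest integer as in
  the standard power tables: (ρ=0.5, α=0.05, power 0.8) → 29 and
  (ρ=0.9, α=0.01, power 0.9) → 10. Published worked examples of this
  design sometimes quote N = 13 for the latter configuration from a
  formula that was not reproducible here; this implementation reports the
  standard result and documents the discrepancy rather than
  reverse-engineering it.
- **Quartiles** for the 1.5×IQR outlier rule use linear interpolation (no
  convention was documented; this is numpy's default).
- **Leukocytosis/neutrophilia** default thresholds, 11,000 and 7,700
  cells/µl, are the standard clinical definitions; the call is strictly
  greater-than, so a concentration exactly at threshold is negative. Both
  are configurable.
- **Flow-cytometry indices**: populations are gated rectangularly in
  scatter space; nCD64 = MFI(neutrophil)/MFI(bead) and mCD64 =
  MFI(monocyte)/MFI(bead) on the CD64 channel, with MFI the arithmetic
  mean of the gated events.

## Stratification models

The sepsis classifier is a linear-kernel maximum-margin model — linear
because the weight-vector coefficients are then directly interpretable as
feature importances, which is how features are ranked (mean |weight| over
all fold fits). Features are z-scored with training-fold statistics only.
Partitions are stratified (the synthetic cohort mirrors a 76 vs 368 class
imbalance; no reweighting is applied). Two feature sets are compared on
identical per-iteration partitions with a one-sided paired Wilcoxon
signed-rank test on per-iteration AUCs.

The prognosis network has 10 logistic hidden units and a single
probabilistic output trained on cross-entropy. A softmax over a single
output unit is constant, so the single-sigmoid output is the functional
reading of that architecture. Data split 50/25/25 into train/validation/
test: the optimizer (adam, learning rate 0.02) sees the first 75% and
holds out one third of it for early stopping when validation loss stops
improving for 50 iterations; the untouched last 25% yields the reported
ROC. The reference implementation used scaled conjugate gradient; any
deterministic seeded gradient method with the same architecture and
stopping rule satisfies the contract, and adam's library defaults (learning
rate 10⁻³, patience 20) stall at initialization on cohort-sized data, which
is why they are raised here.

## Synthetic cohorts: what they emulate and what they do not

Cohorts carry one row per patient per time window TW1–TW6 with nCD64, WBC
and the two-part differential, the four Quick-SIRS vitals, lactic acid,
the sepsis label and the outcome. WBC is log-normal per group with CVs
62.88% (septic) and 68.81% (non-septic), clipped to the device's dynamic
range 530–38,570 cells/µl. Septic effect sizes are configuration, not
inferred fact — no per-vital effect sizes were documented — and the
defaults are calibrated so the stratification regime is realistic: Quick
SIRS alone reaches a mean 10-fold-CV AUC ≈ 0.72 and adding the biochip
panel raises it significantly (the clinically reported regime is
0.70 → 0.77). Recovered patients' nCD64 rises then falls across TW1–TW6;
non-survivors run at a persistently elevated level (×2.2 by default) and
rise again from TW5 to TW6 — both shapes follow the documented recovery
trajectories, and the persistent elevation is required for any
single-window prognosis signal to exist at early windows.

What passing tests on these cohorts **do not** show: real EMR feature
encodings, missingness, within-patient correlation of vitals over time,
co-morbidity structure, or the actual effect sizes of a hospital
population. The printed clinical AUCs and R² values are properties of
undeposited patient data; the synthetic cohorts mirror their direction and
rough magnitude, nothing more. Likewise the trace generator omits fluid
dynamics, cell deformability and electronics beyond additive noise; its
role is to give every stage a ground truth, not to replace device
characterization.

## Numerical choices and problem sizes

All generators take explicit seeds and are bit-reproducible; the pipeline
expands one root seed into independent per-stage seeds. Acceptance-style
computations use: 1,000 injected pulses for detection metrics, 60 s of
trace at 5,000 cells/µl for count recovery, 100-sample cohorts × 1,000 CV
rounds for calibration, 444-patient cohorts × 100 iterations for the
feature-set comparison, and 160-patient single-class cohorts for the
prognosis network — sizes at which every stochastic check has comfortable
margin while a full run stays in the tens of seconds.

Known limitations: coincident transits (two cells within one transit time)
merge into one pulse and are not deconvolved — at 5,000 cells/µl and
0.518 µl/min this loses well under 1% of counts but grows with
concentration; the valley gate requires a resolvable bimodal histogram and
deliberately errors on unimodal input; the capture calibration is linear
by design and under-reads nCD64 in the saturating tail of the capture law.
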