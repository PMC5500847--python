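# impedcyto

Signal processing, gating, calibration and clinical statistics for a
point-of-care impedance cytometer that counts leukocytes and quantifies the
neutrophil CD64 (nCD64) sepsis biomarker from ~10 µl of whole blood.

## The problem

Sepsis diagnosis at the point of care needs two numbers fast: the total
leukocyte count with a lymphocyte vs granulocyte+monocyte differential, and
the CD64 expression level on neutrophils, which rises with inflammatory
stimulus. A microfluidic biochip measures both electrically: erythrocytes are
lysed on-chip, the remaining leukocytes pass through a Coulter aperture where
each cell produces a voltage pulse proportional to its volume
(V ∝ d³), and an anti-CD64 antibody chamber between an *entrance* and an
*exit* counter captures granulocytes+monocytes in proportion to their CD64
expression. The package implements the full computational stack behind such a
device, exercised end to end on seeded synthetic data with known ground
truth:

- **signal processing** — zero-phase Butterworth chain (20 Hz high-pass for
  baseline drift, band-stops at (58, 62) and (118, 122) Hz for power-line
  interference, low-pass stage), baseline-noise estimation, and
  threshold-run pulse detection (default max(0.5 V, 10 × baseline SD)) with
  amplitude, width and area extraction;
- **gating** — bimodal amplitude-histogram valley thresholding of
  lymphocytes (6–10 µm) vs granulocytes+monocytes (11–15 µm) and conversion
  of counts to cells/µl of whole blood via the blood pump rate;
- **capture quantification** — the differential-capture statistics
  `percent capture = 100·(entrance_gm − exit_gm)/entrance_gm` and
  `(A − B)/B`, a repeated three-fold cross-validated (×1,000) linear
  calibration of percent capture to nCD64, binned analysis and
  bin-agreement accuracy curves;
- **clinical statistics** — OLS regression, Bland–Altman limits of
  agreement (bias ± 1.96·SD), ROC/AUC, Fisher-z correlation power analysis,
  CV%, the 1.5×IQR outlier rule, bead-normalized flow-cytometry MFI indices
  and threshold diagnosis of leukocytosis/neutrophilia;
- **stratification models** — repeated stratified 10-fold linear SVM for
  the sepsis label with weight-vector feature ranking and a paired Wilcoxon
  comparison of feature sets, plus a 10-hidden-unit feed-forward network
  for per-time-window recovery prognosis (50/25/25 split, early stopping);
- **synthetic data** — seeded generators for cell ensembles, the
  expression-dependent capture process P(capture) = 1 − exp(−κ·E), raw
  noisy traces, flow-cytometry control event tables with beads, and patient
  cohorts with TW1–TW6 nCD64 trajectories.

## Worked example

```bash
python examples/count_leukocytes.py
```

```
ground truth: 427 lymphocytes, 869 g+m
detected pulses: 1286 (threshold 0.51 V)
gate threshold: 1.96 V
gated counts: 417 lymphocytes, 869 g+m
total concentration: 4965 cells/ul (true 5000)
dilution factor: 19.3
```

A 30-second, 5,000 cells/µl sample is synthesized at 250 kHz, filtered,
thresholded and gated: the valley between the ~1 V lymphocyte mode and the
~3.5 V granulocyte+monocyte mode lands at 1.96 V, the per-class counts come
back within ~2% of ground truth, and the concentration within ~1%. The
dilution factor 19.3 is the total stream flow (blood + lysing + quenching
buffers at 0.518, 6.218 and 3.264 µl/min) over the blood flow.

The other examples cover CD64 quantification (`quantify_cd64.py`),
method-agreement statistics (`method_agreement_stats.py`) and patient
stratification (`stratify_patients.py`). A thin CLI mirrors the library:
`impedcyto simulate|process|gate|calibrate|stats|classify|run --help`.

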