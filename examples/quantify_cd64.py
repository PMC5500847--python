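"""Quantify neutrophil CD64 from differential immunocapture.

Generates a 100-sample cohort under the exponential capture law
P = 1 − exp(−κE), calibrates percent g+m capture against the true nCD64
with repeated three-fold cross-validation (1,000 rounds), and reports how
well held-out predictions recover the truth.
"""

from impedcyto import bin_accuracy_curve, binned_analysis, fit_capture_calibration
from impedcyto.pipeline import simulate_capture_cohort

pairs = simulate_capture_cohort(n_samples=100, seed=7)
model = fit_capture_calibration(
    pairs["percent_capture"], pairs["true_ncd64"], folds=3, trials=1000, seed=7
)

binned = binned_analysis(pairs["percent_capture"], pairs["true_ncd64"], bin_size=0.25)
accuracy = bin_accuracy_curve(
    model.held_out_predictions, pairs["true_ncd64"], [0.25, 0.6, 1.0]
)

print(f"calibration: nCD64 = {model.slope:.4f} x capture% + {model.intercept:.3f}")
print(f"held-out R^2 vs true nCD64: {model.r_squared:.3f}")
print(f"binned (0.25-wide nCD64 bins) capture-vs-nCD64 R^2: {binned['r_squared']:.3f}")
for ba in accuracy:
    print(
        f"bin size {ba.bin_size}: {100 * ba.accuracy:.0f}% of samples in the "
        f"same bin as truth ({ba.n_bins} bins)"
    )
# The slope says how many percent of g+m capture one nCD64 unit buys; R^2
# near 0.9 means the one-parameter capture law plus counting noise leaves
# ~10% of nCD64 variance unexplained by a linear readout.
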