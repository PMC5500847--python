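"""Differential-capture statistics and the percent-capture → nCD64 calibration.

The CD64 assay is a difference measurement: the same sample is counted at
the entrance and exit of an anti-CD64 antibody chamber, and the fraction of
granulocytes+monocytes retained in the chamber —

    percent capture = 100 · (entrance_gm − exit_gm) / entrance_gm

— rises linearly with the neutrophil CD64 index over the clinical range.
A second, flow-referenced form normalizes an antibody-chamber count A to a
blocked-chamber count B as (A − B)/B.

Calibration maps percent capture to nCD64 with an ordinary-least-squares
line fitted under repeated k-fold cross-validation (default three folds,
1,000 random re-partitions): each sample's reported prediction is the mean
of its held-out predictions over all rounds, and the model's slope and
intercept are the means over all training fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as scs

from .core import ConfigurationError
from .gating import GateResult

__all__ = [
    "DifferentialCounts",
    "CaptureRatio",
    "CalibrationModel",
    "BinAccuracy",
    "percent_capture",
    "capture_ratio_flow",
    "fit_capture_calibration",
    "predict_ncd64",
    "binned_analysis",
    "bin_accuracy_curve",
]


@dataclass(frozen=True)
class DifferentialCounts:
    """Entrance/exit gate results and the derived capture statistics."""

    entrance: GateResult
    exit: GateResult
    percent_capture_gm: float
    lymphocyte_recovery_percent: float


@dataclass(frozen=True)
class CaptureRatio:
    """Blocked-chamber-referenced capture: (A − B)/B."""

    a: float
    b: float
    ratio: float


@dataclass
class CalibrationModel:
    """Repeated-CV linear map from percent capture (%) to nCD64."""

    slope: float
    intercept: float
    held_out_predictions: np.ndarray  # mean held-out prediction per sample
    r_squared: float
    folds: int
    trials: int
    seed: int
    fitted: bool = True

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "folds": self.folds,
            "trials": self.trials,
            "seed": self.seed,
            "held_out_predictions": self.held_out_predictions.tolist(),
        }


@dataclass(frozen=True)
class BinAccuracy:
    """Agreement between predicted and control nCD64 at one bin size."""

    bin_size: float
    n_bins: int
    accuracy: float


def percent_capture(entrance: GateResult, exit: GateResult) -> DifferentialCounts:
    """Capture fraction of granulocytes+monocytes across the chamber.

    Lymphocyte recovery (exit/entrance, %) may exceed 100: the chamber can
    release weakly bound lymphocytes downstream, so the statistic is
    reported, not clipped.
    """
    if entrance.gm_count <= 0:
        raise ConfigurationError("entrance granulocyte+monocyte count must be > 0")
    pct = 100.0 * (entrance.gm_count - exit.gm_count) / entrance.gm_count
    recovery = (
        100.0 * exit.lymphocyte_count / entrance.lymphocyte_count
        if entrance.lymphocyte_count > 0
        else np.nan
    )
    return DifferentialCounts(
        entrance=entrance,
        exit=exit,
        percent_capture_gm=pct,
        lymphocyte_recovery_percent=recovery,
    )


def capture_ratio_flow(a: float, b: float) -> CaptureRatio:
    """(A − B)/B, the capture normalized to the blocked chamber."""
    if b <= 0:
        raise ConfigurationError("blocked-chamber count B must be > 0")
    return CaptureRatio(a=float(a), b=float(b), ratio=(a - b) / b)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def fit_capture_calibration(
    capture_percent,
    control_ncd64,
    folds: int = 3,
    trials: int = 1000,
    seed: int = 0,
) -> CalibrationModel:
    """Repeated k-fold OLS calibration of percent capture against control nCD64.

    Per trial the samples are randomly partitioned into ``folds`` nearly
    equal subsets; the line is fitted on ``folds − 1`` subsets and the
    held-out subset is predicted.  Negative capture values (noisy counts
    can make the exit count exceed the entrance) are retained.
    """
    x = np.asarray(capture_percent, dtype=float)
    y = np.asarray(control_ncd64, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigurationError("capture and control vectors must match 1-D shapes")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ConfigurationError("calibration inputs must be finite")
    if folds < 2 or trials < 1:
        raise ConfigurationError("need folds >= 2 and trials >= 1")
    n = x.size
    if n < 2 * folds:
        raise ConfigurationError(f"need at least {2 * folds} pairs for {folds} folds")
    if np.var(x) == 0:
        raise ConfigurationError("degenerate capture values: zero variance")

    rng = np.random.default_rng(seed)
    pred_sum = np.zeros(n)
    pred_count = np.zeros(n)
    slopes = []
    intercepts = []

    for _ in range(trials):
        order = rng.permutation(n)
        fold_ids = np.empty(n, dtype=int)
        fold_ids[order] = np.arange(n) % folds
        for k in range(folds):
            test = fold_ids == k
            slope, intercept = _ols(x[~test], y[~test])
            slopes.append(slope)
            intercepts.append(intercept)
            pred_sum[test] += slope * x[test] + intercept
            pred_count[test] += 1

    predictions = pred_sum / pred_count
    ss_res = float(np.sum((y - predictions) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan

    return CalibrationModel(
        slope=float(np.mean(slopes)),
        intercept=float(np.mean(intercepts)),
        held_out_predictions=predictions,
        r_squared=r_squared,
        folds=folds,
        trials=trials,
        seed=seed,
    )


def predict_ncd64(model: CalibrationModel, capture_percent) -> np.ndarray:
    """Apply the calibration line; predictions are clipped at 0 from below."""
    if not getattr(model, "fitted", False):
        raise ConfigurationError("calibration model is not fitted")
    capture = np.asarray(capture_percent, dtype=float)
    return np.clip(model.slope * capture + model.intercept, 0.0, None)


def binned_analysis(
    capture_percent, control_ncd64, bin_size: float = 0.25
) -> dict:
    """Average percent capture within fixed-width nCD64 bins anchored at 0.

    Returns bin centers, per-bin mean capture, per-bin sample counts, and
    the OLS R² of mean capture against bin center over occupied bins.
    """
    if bin_size <= 0:
        raise ConfigurationError("bin_size must be > 0")
    x = np.asarray(capture_percent, dtype=float)
    y = np.asarray(control_ncd64, dtype=float)
    if x.size == 0:
        raise ConfigurationError("binned analysis needs at least one pair")

    idx = np.floor(y / bin_size).astype(int)
    n_bins = int(idx.max()) + 1
    centers = (np.arange(n_bins) + 0.5) * bin_size
    means = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        mask = idx == b
        counts[b] = mask.sum()
        if counts[b]:
            means[b] = x[mask].mean()

    occupied = counts > 0
    if occupied.sum() < 2:
        raise ConfigurationError(
            "all samples fall in a single nCD64 bin: the binned fit is undefined"
        )
    fit = scs.linregress(centers[occupied], means[occupied])
    return {
        "bin_size": bin_size,
        "bin_centers": centers,
        "mean_capture": means,
        "bin_counts": counts,
        "r_squared": float(fit.rvalue**2),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
    }


def bin_accuracy_curve(predicted, control, bin_sizes) -> list[BinAccuracy]:
    """Fraction of samples whose predicted and control nCD64 share a bin.

    Bins tile [0, ∞) with width ``bin_size``; a sample agrees when
    ``floor(pred/size) == floor(control/size)``.  The number of bins is
    reported over the observed control range.
    """
    pred = np.asarray(predicted, dtype=float)
    ctrl = np.asarray(control, dtype=float)
    if pred.shape != ctrl.shape:
        raise ConfigurationError("prediction and control vectors must match")
    results = []
    value_range = float(ctrl.max() - ctrl.min()) if ctrl.size else 0.0
    for size in np.atleast_1d(bin_sizes):
        if size <= 0:
            raise ConfigurationError("bin sizes must be > 0")
        agree = np.floor(pred / size) == np.floor(ctrl / size)
        results.append(
            BinAccuracy(
                bin_size=float(size),
                n_bins=max(int(np.ceil(value_range / size)), 1),
                accuracy=float(agree.mean()),
            )
        )
    return results
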