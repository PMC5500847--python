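"""Method-comparison and cohort statistics.

The toolkit behind the clinical validation of the counting/CD64 assay:
ordinary least-squares regression with a slope t-test, Bland–Altman
agreement analysis, ROC curves with trapezoidal AUC, the Fisher-z power
analysis for a target correlation, coefficient of variation, the 1.5×IQR
box-plot outlier rule, bead-normalized flow-cytometry CD64 indices, and
threshold diagnosis of leukocytosis/neutrophilia.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as scs
from sklearn import metrics as skm

from .core import ConfigurationError

__all__ = [
    "RegressionResult",
    "BlandAltmanResult",
    "ROCResult",
    "PowerSpec",
    "FlowEventSummary",
    "linear_regression",
    "bland_altman",
    "roc_curve",
    "sample_size_correlation",
    "coefficient_of_variation",
    "boxplot_outliers",
    "flow_summary",
    "diagnose_threshold",
    "LEUKOCYTOSIS_THRESHOLD_PER_UL",
    "NEUTROPHILIA_THRESHOLD_PER_UL",
]

#: Conventional clinical cutoffs (cells/µl) for elevated total leukocytes
#: and granulocytes; both are configurable at call sites.
LEUKOCYTOSIS_THRESHOLD_PER_UL = 11_000.0
NEUTROPHILIA_THRESHOLD_PER_UL = 7_700.0


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float  # two-tailed, t-test on the slope


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and 1.96·SD limits of agreement; differences are method1 − method2."""

    bias: float
    loa_low: float
    loa_high: float
    differences: np.ndarray
    means: np.ndarray


@dataclass(frozen=True)
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


@dataclass(frozen=True)
class PowerSpec:
    """Sample size for detecting a correlation ρ at given α and power."""

    rho: float
    alpha: float
    power: float
    z_alpha: float
    z_beta: float
    n_required: int


@dataclass(frozen=True)
class FlowEventSummary:
    """Bead-normalized CD64 indices from a gated flow-cytometry event table."""

    population_mfi: dict
    bead_mfi: float
    ncd64: float
    mcd64: float
    mcd64_over_ncd64: float


def linear_regression(x, y) -> RegressionResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ConfigurationError("regression needs matched vectors with n >= 3")
    if np.var(x) == 0:
        raise ConfigurationError("degenerate x: zero variance")
    fit = scs.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
    )


def bland_altman(method1, method2) -> BlandAltmanResult:
    """Agreement between two measurements of the same quantity.

    Convention: differences are method1 − method2, with the device under
    test as method1 and the reference as method2, so a negative bias means
    the device reads low.
    """
    m1 = np.asarray(method1, dtype=float)
    m2 = np.asarray(method2, dtype=float)
    if m1.shape != m2.shape:
        raise ConfigurationError("method vectors must have matching lengths")
    if m1.size < 2:
        raise ConfigurationError("Bland-Altman needs n >= 2")
    diff = m1 - m2
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        differences=diff,
        means=(m1 + m2) / 2.0,
    )


def roc_curve(scores, labels) -> ROCResult:
    """ROC over all score thresholds, AUC by the trapezoid rule.

    Tied scores step diagonally (handled by the underlying curve
    construction), making the AUC equal to the Wilcoxon–Mann–Whitney
    concordance probability with ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size != 2:
        raise ConfigurationError("ROC requires both classes present")
    fpr, tpr, thresholds = skm.roc_curve(labels, scores)
    return ROCResult(
        fpr=fpr, tpr=tpr, thresholds=thresholds, auc=float(skm.auc(fpr, tpr))
    )


def sample_size_correlation(rho: float, alpha: float, power: float) -> PowerSpec:
    """Fisher-z sample size: N = ((Zα + Zβ) / arctanh ρ)² + 3, rounded.

    ``alpha`` is two-tailed.  The +3 correction and nearest-integer rounding
    follow the standard correlation-power tables; ρ=0.5, α=0.05, power 0.8
    gives N = 29, and ρ=0.9, α=0.01, power 0.9 gives N = 10.
    """
    if not 0.0 < rho < 1.0:
        raise ConfigurationError("rho must be in (0, 1)")
    if not 0.0 < alpha < 1.0 or not 0.0 < power < 1.0:
        raise ConfigurationError("alpha and power must be in (0, 1)")
    z_alpha = float(scs.norm.ppf(1.0 - alpha / 2.0))
    z_beta = float(scs.norm.ppf(power))
    c = np.arctanh(rho)
    n = int(np.floor(((z_alpha + z_beta) / c) ** 2 + 3.0 + 0.5))
    return PowerSpec(
        rho=rho, alpha=alpha, power=power,
        z_alpha=z_alpha, z_beta=z_beta, n_required=max(n, 4),
    )


def coefficient_of_variation(values) -> float:
    """100 × sample SD / mean, in percent."""
    x = np.asarray(values, dtype=float)
    mean = x.mean()
    if mean == 0:
        raise ConfigurationError("CV undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / mean)


def boxplot_outliers(values) -> np.ndarray:
    """Values outside [q1 − 1.5·IQR, q3 + 1.5·IQR]; quartiles by linear interpolation."""
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ConfigurationError("outlier rule needs n >= 4")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return x[(x > q3 + 1.5 * iqr) | (x < q1 - 1.5 * iqr)]


def _apply_gate(events: pd.DataFrame, gate: dict) -> pd.DataFrame:
    mask = np.ones(len(events), dtype=bool)
    for channel, (lo, hi) in gate.items():
        mask &= (events[channel] >= lo) & (events[channel] <= hi)
    return events.loc[mask]


def flow_summary(
    events: pd.DataFrame,
    gates: dict[str, dict],
    cd64_channel: str = "cd64_fitc",
) -> FlowEventSummary:
    """Per-population MFI on the CD64 channel and bead-normalized indices.

    ``gates`` maps population names (must include ``bead``, ``neutrophil``
    and ``monocyte``) to per-channel (low, high) rectangular gates.
    """
    mfi = {}
    for name, gate in gates.items():
        gated = _apply_gate(events, gate)
        if len(gated) == 0:
            raise ConfigurationError(f"gate {name!r} selected no events")
        mfi[name] = float(gated[cd64_channel].mean())
    if "bead" not in mfi or mfi["bead"] <= 0:
        raise ConfigurationError("bead gate is required for MFI normalization")

    ncd64 = mfi.get("neutrophil", np.nan) / mfi["bead"]
    mcd64 = mfi.get("monocyte", np.nan) / mfi["bead"]
    return FlowEventSummary(
        population_mfi=mfi,
        bead_mfi=mfi["bead"],
        ncd64=float(ncd64),
        mcd64=float(mcd64),
        mcd64_over_ncd64=float(mcd64 / ncd64),
    )


def diagnose_threshold(
    concentrations, labels=None, threshold: float = LEUKOCYTOSIS_THRESHOLD_PER_UL
) -> dict:
    """Binary call: concentration strictly above threshold is positive.

    With labels, also reports sensitivity/specificity at the threshold and
    the ROC over a full threshold sweep.
    """
    if threshold <= 0:
        raise ConfigurationError("diagnosis threshold must be > 0")
    conc = np.atleast_1d(np.asarray(concentrations, dtype=float))
    calls = conc > threshold
    out: dict = {"calls": calls, "threshold": float(threshold)}
    if labels is not None:
        y = np.asarray(labels).astype(int)
        if np.unique(y).size != 2:
            raise ConfigurationError("labels must contain both classes")
        tp = int((calls & (y == 1)).sum())
        fn = int((~calls & (y == 1)).sum())
        tn = int((~calls & (y == 0)).sum())
        fp = int((calls & (y == 0)).sum())
        out["sensitivity"] = tp / (tp + fn)
        out["specificity"] = tn / (tn + fp)
        out["roc"] = roc_curve(conc, y)
    return out
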