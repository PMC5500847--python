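"""Patient stratification: repeated-CV SVM diagnosis and ANN prognosis.

Two models operate on the cohort table.  For sepsis *diagnosis*, a
linear-kernel maximum-margin classifier is trained under repeated
stratified 10-fold cross-validation (default 1,000 random re-partitions)
on z-scored features; the linear kernel is what makes the weight-vector
coefficients directly interpretable as feature importances.  Two feature
sets are compared: Quick SIRS (temperature, pulse, respirations, systolic
blood pressure) versus Quick SIRS plus the biochip panel (lactic acid,
nCD64, total leukocytes, granulocytes+monocytes, lymphocytes), with a
one-sided paired Wilcoxon signed-rank test on the per-iteration AUC pairs.

For recovery *prognosis* within one time window, a small feed-forward
network (10 sigmoid hidden units, single probabilistic output trained on
cross-entropy) maps (nCD64, WBC) to the recovery outcome, with a
50%/25%/25% train/validation/test split and early stopping when the
validation loss stops improving; the ROC is computed on the untouched test
split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as scs
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC

from .core import ConfigurationError
from .clinstats import roc_curve

__all__ = [
    "QUICK_SIRS_FEATURES",
    "BIOCHIP_FEATURES",
    "FeatureSetSpec",
    "CVModelResult",
    "svm_sepsis",
    "compare_feature_sets",
    "ann_prognosis",
]

QUICK_SIRS_FEATURES = ("temp_c", "pulse_bpm", "resp_rpm", "sbp_mmhg")
BIOCHIP_FEATURES = (
    "lactic_acid",
    "ncd64",
    "wbc_per_ul",
    "gm_per_ul",
    "lymph_per_ul",
)


@dataclass(frozen=True)
class FeatureSetSpec:
    """A named feature list; the biochip-augmented set strictly contains Quick SIRS."""

    name: str
    features: tuple[str, ...]

    @classmethod
    def quick_sirs(cls) -> "FeatureSetSpec":
        return cls("quick_sirs", QUICK_SIRS_FEATURES)

    @classmethod
    def quick_sirs_plus_biochip(cls) -> "FeatureSetSpec":
        return cls(
            "quick_sirs_plus_biochip", QUICK_SIRS_FEATURES + BIOCHIP_FEATURES
        )


@dataclass
class CVModelResult:
    """Per-iteration held-out AUCs, pooled scores and feature importances."""

    feature_set: FeatureSetSpec
    iteration_aucs: np.ndarray
    mean_auc: float
    feature_importance: dict  # feature -> mean |weight|, ranked in insertion order
    folds: int
    iterations: int
    seed: int


def _zscore_train_apply(train: np.ndarray, test: np.ndarray):
    """Standardize with training-fold statistics only (no leakage)."""
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mean) / sd, (test - mean) / sd


def svm_sepsis(
    cohort: pd.DataFrame,
    spec: FeatureSetSpec | None = None,
    folds: int = 10,
    iterations: int = 1000,
    seed: int = 0,
    c: float = 1.0,
) -> CVModelResult:
    """Repeated stratified k-fold linear SVM for the sepsis label.

    Each iteration draws a fresh stratified partition; held-out decision
    scores are pooled into one ROC per iteration.  Feature importance is
    the mean absolute weight-vector coefficient across all fold fits.
    """
    spec = spec or FeatureSetSpec.quick_sirs_plus_biochip()
    y = cohort["septic"].to_numpy().astype(int)
    if np.unique(y).size != 2:
        raise ConfigurationError("cohort must contain both septic and non-septic")
    x = cohort.loc[:, list(spec.features)].to_numpy(dtype=float)

    rng = np.random.default_rng(seed)
    aucs = np.empty(iterations)
    weight_sum = np.zeros(x.shape[1])
    n_fits = 0

    for it in range(iterations):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True,
            random_state=int(rng.integers(2**31)),
        )
        scores = np.empty(len(y))
        for train_idx, test_idx in skf.split(x, y):
            xtr, xte = _zscore_train_apply(x[train_idx], x[test_idx])
            clf = LinearSVC(C=c, dual=True, max_iter=5000, random_state=0)
            clf.fit(xtr, y[train_idx])
            scores[test_idx] = clf.decision_function(xte)
            weight_sum += np.abs(clf.coef_.ravel())
            n_fits += 1
        aucs[it] = roc_curve(scores, y).auc

    importance = weight_sum / n_fits
    order = np.argsort(importance)[::-1]
    ranked = {spec.features[i]: float(importance[i]) for i in order}

    return CVModelResult(
        feature_set=spec,
        iteration_aucs=aucs,
        mean_auc=float(aucs.mean()),
        feature_importance=ranked,
        folds=folds,
        iterations=iterations,
        seed=seed,
    )


def compare_feature_sets(
    cohort: pd.DataFrame,
    set_a: FeatureSetSpec,
    set_b: FeatureSetSpec,
    folds: int = 10,
    iterations: int = 100,
    seed: int = 0,
) -> dict:
    """Paired comparison of two feature sets on identical CV partitions.

    Runs both models with the same seed so iteration partitions match, then
    applies a one-sided paired Wilcoxon signed-rank test of
    H1: AUC(set_b) > AUC(set_a) on the per-iteration AUC pairs.
    """
    if iterations < 2:
        raise ConfigurationError("paired comparison needs >= 2 iterations")
    result_a = svm_sepsis(cohort, set_a, folds=folds, iterations=iterations, seed=seed)
    result_b = svm_sepsis(cohort, set_b, folds=folds, iterations=iterations, seed=seed)
    delta = result_b.iteration_aucs - result_a.iteration_aucs
    if np.all(delta == 0):
        p_value = 1.0
    else:
        p_value = float(
            scs.wilcoxon(
                result_b.iteration_aucs,
                result_a.iteration_aucs,
                alternative="greater",
            ).pvalue
        )
    return {
        "result_a": result_a,
        "result_b": result_b,
        "median_auc_difference": float(np.median(delta)),
        "p_value": p_value,
    }


@dataclass(frozen=True)
class PrognosisModelSpec:
    """Architecture and split for the per-time-window recovery network."""

    hidden_units: int = 10
    split_fractions: tuple[float, float, float] = (0.5, 0.25, 0.25)
    features: tuple[str, ...] = ("ncd64", "wbc_per_ul")
    learning_rate: float = 0.02
    patience: int = 50
    max_iter: int = 3000

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ConfigurationError("hidden_units must be >= 1")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ConfigurationError("split fractions must sum to 1")


def ann_prognosis(
    cohort: pd.DataFrame,
    time_window: str,
    spec: PrognosisModelSpec | None = None,
    seed: int = 0,
) -> dict:
    """Train the prognosis network on one time window; ROC on the test split.

    The train+validation portion (75%) feeds the optimizer, which holds out
    one third of it (25% of the data) for early stopping on validation
    loss; the remaining 25% is an untouched test split.
    """
    spec = spec or PrognosisModelSpec()
    window = cohort.loc[cohort["time_window"] == time_window]
    y = (window["outcome"] == "recovered").to_numpy().astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < 8:
        raise ConfigurationError(
            f"need >= 8 patients per outcome class in {time_window}; "
            f"got {counts.tolist()} — enlarge the cohort or pool windows"
        )
    x = window.loc[:, list(spec.features)].to_numpy(dtype=float)

    train_frac = spec.split_fractions[0] + spec.split_fractions[1]
    x_trval, x_test, y_trval, y_test = train_test_split(
        x, y, test_size=spec.split_fractions[2], random_state=seed, stratify=y
    )
    if np.unique(y_test).size < 2 or np.unique(y_trval).size < 2:
        raise ConfigurationError(
            "an outcome class is missing from a split; re-split with a "
            "different seed or a larger cohort"
        )

    x_trval_z, x_test_z = _zscore_train_apply(x_trval, x_test)
    net = MLPClassifier(
        hidden_layer_sizes=(spec.hidden_units,),
        activation="logistic",
        solver="adam",
        learning_rate_init=spec.learning_rate,
        early_stopping=True,
        validation_fraction=spec.split_fractions[1] / train_frac,
        n_iter_no_change=spec.patience,
        max_iter=spec.max_iter,
        random_state=seed,
    )
    net.fit(x_trval_z, y_trval)

    test_scores = net.predict_proba(x_test_z)[:, 1]
    roc = roc_curve(test_scores, y_test)
    return {
        "roc": roc,
        "auc": roc.auc,
        "n_train_val": int(len(y_trval)),
        "n_test": int(len(y_test)),
        "loss_curve": list(net.loss_curve_),
        "time_window": time_window,
        "spec": spec,
        "seed": seed,
    }
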