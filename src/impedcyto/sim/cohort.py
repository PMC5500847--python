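"""Synthetic patient cohorts for the clinical-stratification stages.

Each patient contributes one row per time window TW1–TW6 (ordered sampling
epochs across the hospital stay) with the features the stratification
models consume: nCD64, total leukocytes and the two-part differential,
the four Quick-SIRS vitals (temperature, pulse, respirations, systolic
blood pressure), lactic acid, the sepsis label and the recovery outcome.

Structure emulated:

* total leukocyte counts are log-normal per group, clipped to the device's
  dynamic range (530–38,570 cells/µl), with group coefficients of variation
  defaulting to the observed 62.88% (septic) and 68.81% (non-septic);
* septic patients carry configurable mean shifts on nCD64, WBC, vitals and
  lactic acid — all shifts live in the config, none are hard-coded facts;
* nCD64 trajectories: recovered patients rise then fall across TW1–TW6;
  non-recovered patients show a late rise from TW5 to TW6.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ..core import ConfigurationError

__all__ = ["CohortConfig", "simulate_cohort", "TIME_WINDOWS"]

TIME_WINDOWS = ["TW1", "TW2", "TW3", "TW4", "TW5", "TW6"]

#: Per-window nCD64 multipliers: rise-then-fall for recovered patients,
#: late rise (TW5 -> TW6) for patients who did not recover.
RECOVERED_TRAJECTORY = (1.0, 1.7, 1.9, 1.5, 1.15, 0.9)
DECEASED_TRAJECTORY = (1.0, 1.25, 1.15, 1.1, 1.3, 2.0)

# Non-septic baseline vitals: (mean, sd)
_VITALS_BASE = {
    "temp_c": (36.9, 0.5),
    "pulse_bpm": (80.0, 12.0),
    "resp_rpm": (16.0, 3.0),
    "sbp_mmhg": (122.0, 14.0),
    "lactic_acid": (1.3, 0.5),
}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort size, class balance, effect sizes and dispersion.

    ``vitals_shift_septic`` maps each vital to the additive mean shift in
    the septic group; positive pulse/respiration/temperature/lactic-acid
    shifts and a negative systolic-pressure shift give the septic class its
    SIRS-like signature.
    """

    n_patients: int = 200
    septic_fraction: float = 76.0 / 444.0
    deceased_fraction_septic: float = 0.08
    wbc_mean_nonseptic: float = 9_000.0
    wbc_shift_septic: float = 2_500.0
    wbc_cv_septic: float = 62.88
    wbc_cv_nonseptic: float = 68.81
    ncd64_mean_nonseptic: float = 1.2
    ncd64_shift_septic: float = 0.8
    ncd64_deceased_multiplier: float = 2.2
    ncd64_cv_septic: float = 46.07
    ncd64_cv_nonseptic: float = 56.60
    gm_fraction_mean: float = 0.65
    gm_fraction_shift_septic: float = 0.04
    vitals_shift_septic: dict = field(
        default_factory=lambda: {
            "temp_c": 0.27,
            "pulse_bpm": 6.5,
            "resp_rpm": 1.6,
            "sbp_mmhg": -7.5,
            "lactic_acid": 0.25,
        }
    )
    leukocyte_range: tuple[float, float] = (530.0, 38_570.0)
    trajectory_recovered: tuple = RECOVERED_TRAJECTORY
    trajectory_deceased: tuple = DECEASED_TRAJECTORY
    within_patient_jitter_sd: float = 0.10

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ConfigurationError("n_patients must be >= 2")
        if not 0.0 <= self.septic_fraction <= 1.0:
            raise ConfigurationError("septic_fraction must be in [0, 1]")
        lo, hi = self.leukocyte_range
        if not 0 < lo < hi:
            raise ConfigurationError("leukocyte_range must satisfy 0 < low < high")

    def null(self) -> "CohortConfig":
        """A copy with every septic/non-septic and outcome effect removed."""
        return replace(
            self,
            wbc_shift_septic=0.0,
            ncd64_shift_septic=0.0,
            ncd64_deceased_multiplier=1.0,
            gm_fraction_shift_septic=0.0,
            wbc_cv_septic=self.wbc_cv_nonseptic,
            ncd64_cv_septic=self.ncd64_cv_nonseptic,
            vitals_shift_septic={k: 0.0 for k in self.vitals_shift_septic},
            trajectory_deceased=self.trajectory_recovered,
        )


def _lognormal(rng, mean: float, cv_percent: float, n: int) -> np.ndarray:
    """Log-normal draws with the given arithmetic mean and CV (%)."""
    cv = cv_percent / 100.0
    sigma = np.sqrt(np.log1p(cv**2))
    mu = np.log(mean) - 0.5 * sigma**2
    return np.exp(rng.normal(mu, sigma, size=n))


def simulate_cohort(
    config: CohortConfig, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Draw a cohort table, one row per patient per time window."""
    rng = np.random.default_rng(seed)
    n = config.n_patients

    septic = (rng.uniform(size=n) < config.septic_fraction).astype(int)
    if 0.0 < config.septic_fraction < 1.0:
        # guarantee both classes so downstream classifiers are defined
        if septic.sum() == 0:
            septic[rng.integers(n)] = 1
        elif septic.sum() == n:
            septic[rng.integers(n)] = 0

    deceased = np.where(
        septic == 1, rng.uniform(size=n) < config.deceased_fraction_septic, False
    )

    # Non-survivors run at a persistently elevated nCD64 level on top of
    # their late-rise trajectory: their inflammation never resolves.
    ncd64_base = np.where(
        septic == 1,
        _lognormal(
            rng,
            config.ncd64_mean_nonseptic + config.ncd64_shift_septic,
            config.ncd64_cv_septic,
            n,
        ),
        _lognormal(rng, config.ncd64_mean_nonseptic, config.ncd64_cv_nonseptic, n),
    )
    ncd64_base = np.where(
        deceased, config.ncd64_deceased_multiplier * ncd64_base, ncd64_base
    )

    wbc_mean = config.wbc_mean_nonseptic + config.wbc_shift_septic * septic
    gm_frac_mean = np.clip(
        config.gm_fraction_mean + config.gm_fraction_shift_septic * septic, 0.05, 0.95
    )

    rows = []
    lo, hi = config.leukocyte_range
    for i in range(n):
        traj = (
            config.trajectory_deceased if deceased[i] else config.trajectory_recovered
        )
        for w, window in enumerate(TIME_WINDOWS):
            wbc = float(
                np.clip(
                    _lognormal(
                        rng,
                        wbc_mean[i],
                        config.wbc_cv_septic if septic[i] else config.wbc_cv_nonseptic,
                        1,
                    )[0],
                    lo,
                    hi,
                )
            )
            gm_frac = float(np.clip(rng.normal(gm_frac_mean[i], 0.05), 0.05, 0.95))
            ncd64 = float(
                ncd64_base[i]
                * traj[w]
                * np.exp(config.within_patient_jitter_sd * rng.standard_normal())
            )
            row = {
                "patient_id": f"P{i:04d}",
                "time_window": window,
                "ncd64": ncd64,
                "wbc_per_ul": wbc,
                "gm_per_ul": wbc * gm_frac,
                "lymph_per_ul": wbc * (1.0 - gm_frac),
                "septic": int(septic[i]),
                "outcome": "deceased" if deceased[i] else "recovered",
            }
            for vital, (base_mean, base_sd) in _VITALS_BASE.items():
                shift = config.vitals_shift_septic.get(vital, 0.0) * septic[i]
                row[vital] = float(rng.normal(base_mean + shift, base_sd))
            row["lactic_acid"] = max(row["lactic_acid"], 0.1)
            rows.append(row)

    columns = [
        "patient_id", "time_window", "ncd64", "wbc_per_ul", "gm_per_ul",
        "lymph_per_ul", "temp_c", "pulse_bpm", "resp_rpm", "sbp_mmhg",
        "lactic_acid", "septic", "outcome",
    ]
    return pd.DataFrame(rows)[columns]
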