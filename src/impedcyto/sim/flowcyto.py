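"""Synthetic flow-cytometry event tables with internal control beads.

The control-side measurement of CD64 expression gates leukocyte
subpopulations on forward/side scatter and normalizes each population's
CD64-channel mean fluorescence intensity (MFI) by the MFI of co-acquired
calibration beads: nCD64 = MFI(neutrophil)/MFI(bead), mCD64 =
MFI(monocyte)/MFI(bead).  The generator draws per-event intensities
log-normally with the configured population *arithmetic mean*, so the
normalized indices recovered downstream match the configured values up to
sampling error.  The true population label is retained as hidden ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..core import ConfigurationError

__all__ = ["FlowConfig", "simulate_flow_events", "default_flow_gates"]

# Scatter-space layout (arbitrary units): population -> (fsc mean, ssc mean)
_SCATTER_MEANS = {
    "debris": (20.0, 20.0),
    "lymphocyte": (60.0, 30.0),
    "monocyte": (90.0, 55.0),
    "neutrophil": (85.0, 90.0),
    "bead": (40.0, 130.0),
}
_SCATTER_SD = 5.0


@dataclass(frozen=True)
class FlowConfig:
    """Mixture of leukocytes, beads and debris on the control cytometer.

    ``ncd64`` / ``mcd64`` set the neutrophil and monocyte CD64 means as
    multiples of the bead mean; lymphocytes are nearly CD64-negative.
    """

    n_events: int = 10_000
    fractions: dict = field(
        default_factory=lambda: {
            "neutrophil": 0.45,
            "lymphocyte": 0.25,
            "monocyte": 0.08,
            "bead": 0.12,
            "debris": 0.10,
        }
    )
    bead_mfi: float = 100.0
    ncd64: float = 2.0
    mcd64: float = 5.0
    lymph_cd64: float = 0.05
    log_sd: float = 0.4

    def __post_init__(self) -> None:
        if self.n_events <= 0:
            raise ConfigurationError("n_events must be > 0")
        if abs(sum(self.fractions.values()) - 1.0) > 1e-9:
            raise ConfigurationError("population fractions must sum to 1")
        if self.fractions.get("bead", 0.0) * self.n_events < 1:
            raise ConfigurationError(
                "at least one bead event is required: downstream MFI "
                "normalization is impossible without beads"
            )
        if self.bead_mfi <= 0:
            raise ConfigurationError("bead_mfi must be > 0")


def _lognormal_with_mean(
    rng: np.random.Generator, mean: float, log_sd: float, n: int
) -> np.ndarray:
    """Log-normal draws whose arithmetic mean equals ``mean``."""
    mu = np.log(mean) - 0.5 * log_sd**2
    return np.exp(rng.normal(mu, log_sd, size=n))


def simulate_flow_events(
    config: FlowConfig, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Generate an event table: fsc, ssc, cd64_fitc, population (ground truth)."""
    rng = np.random.default_rng(seed)

    names = list(config.fractions)
    counts = rng.multinomial(config.n_events, [config.fractions[k] for k in names])
    cd64_means = {
        "neutrophil": config.ncd64 * config.bead_mfi,
        "monocyte": config.mcd64 * config.bead_mfi,
        "lymphocyte": config.lymph_cd64 * config.bead_mfi,
        "bead": config.bead_mfi,
        "debris": 0.01 * config.bead_mfi,
    }

    frames = []
    for name, n in zip(names, counts):
        if n == 0:
            continue
        fsc_mean, ssc_mean = _SCATTER_MEANS[name]
        frames.append(
            pd.DataFrame(
                {
                    "fsc": rng.normal(fsc_mean, _SCATTER_SD, size=n),
                    "ssc": rng.normal(ssc_mean, _SCATTER_SD, size=n),
                    "cd64_fitc": _lognormal_with_mean(
                        rng, cd64_means[name], config.log_sd, n
                    ),
                    "population": name,
                }
            )
        )
    events = pd.concat(frames, ignore_index=True)
    return events.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(
        drop=True
    )


def default_flow_gates() -> dict[str, dict[str, tuple[float, float]]]:
    """Rectangular scatter gates matched to the generator's layout (±3 SD)."""
    gates = {}
    for name, (fsc, ssc) in _SCATTER_MEANS.items():
        if name == "debris":
            continue
        gates[name] = {
            "fsc": (fsc - 3 * _SCATTER_SD, fsc + 3 * _SCATTER_SD),
            "ssc": (ssc - 3 * _SCATTER_SD, ssc + 3 * _SCATTER_SD),
        }
    return gates
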