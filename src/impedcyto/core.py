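"""Shared data containers and configuration errors for the impedance pipeline.

The central object is :class:`RawTrace`, a uniformly sampled voltage time
series from one of the two Coulter counters (entrance or exit of the
immunocapture chamber).  Acquisition geometry — sampling rate and the three
pump rates that set the dilution between whole blood and the counted
stream — lives in :class:`AcquisitionConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "ConfigurationError",
    "AcquisitionConfig",
    "RawTrace",
    "DEFAULT_BLOOD_FLOW_UL_MIN",
    "DEFAULT_LYSING_FLOW_UL_MIN",
    "DEFAULT_QUENCHING_FLOW_UL_MIN",
]

#: Default pump rates (µl/min) for blood, erythrocyte-lysing buffer and
#: quenching buffer.  Their sum sets the total stream flow; the ratios set
#: the on-chip dilution of whole blood.
DEFAULT_BLOOD_FLOW_UL_MIN = 0.518
DEFAULT_LYSING_FLOW_UL_MIN = 6.218
DEFAULT_QUENCHING_FLOW_UL_MIN = 3.264


class ConfigurationError(ValueError):
    """A configuration value violates a module precondition."""


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition geometry for one counting run.

    Parameters
    ----------
    sampling_rate_hz:
        Digitizer sampling rate, Hz.  The reference system samples the
        demodulated impedance signal at 250 kHz.
    blood_flow_ul_min, lysing_flow_ul_min, quenching_flow_ul_min:
        Pump rates in µl/min.  Cell concentrations are referenced to the
        blood flow; the buffer flows only dilute the stream.
    duration_s:
        Acquisition duration in seconds.
    blood_volume_ul:
        Metered whole-blood input volume (µl).
    """

    sampling_rate_hz: float = 250_000.0
    blood_flow_ul_min: float = DEFAULT_BLOOD_FLOW_UL_MIN
    lysing_flow_ul_min: float = DEFAULT_LYSING_FLOW_UL_MIN
    quenching_flow_ul_min: float = DEFAULT_QUENCHING_FLOW_UL_MIN
    duration_s: float = 60.0
    blood_volume_ul: float = 10.0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ConfigurationError("sampling_rate_hz must be > 0")
        if self.blood_flow_ul_min <= 0:
            raise ConfigurationError("blood_flow_ul_min must be > 0")
        if self.lysing_flow_ul_min < 0 or self.quenching_flow_ul_min < 0:
            raise ConfigurationError("buffer flow rates must be >= 0")
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be > 0")

    @property
    def total_flow_ul_min(self) -> float:
        return (
            self.blood_flow_ul_min
            + self.lysing_flow_ul_min
            + self.quenching_flow_ul_min
        )

    @property
    def dilution_factor(self) -> float:
        """Total stream flow over blood flow (≈ 19.3 at the default rates)."""
        return self.total_flow_ul_min / self.blood_flow_ul_min


@dataclass
class RawTrace:
    """A uniformly sampled voltage trace from one counter.

    Invariants: ``sampling_rate_hz > 0``, all samples finite, length ≥ 2.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    counter_role: Literal["entrance", "exit"] = "entrance"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate_hz <= 0:
            raise ConfigurationError("sampling_rate_hz must be > 0")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ConfigurationError("trace must be a 1-D array of length >= 2")
        if not np.all(np.isfinite(self.samples)):
            raise ConfigurationError("trace contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz

    def with_samples(self, samples: np.ndarray) -> "RawTrace":
        return replace(self, samples=np.asarray(samples, dtype=float))
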