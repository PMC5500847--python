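"""Raw-trace synthesis: Coulter pulses plus instrument noise.

A cell transiting the sensing aperture displaces conducting fluid in
proportion to its volume, so the noiseless peak amplitude follows the
Coulter volume law ``gain × diameter³``.  Each cell contributes a Gaussian
bump (σ = width/4) centred at its arrival time — a finite-rise-time
approximation of the transit through a 30 µm × 15 µm aperture that keeps
the peak amplitude exact.  Pulse width scales inversely with the total
stream flow rate: faster flow, shorter transit.

On top of the pulse train the generator adds the disturbances the digital
filter chain is designed to remove: a slow baseline-drift sinusoid
(< 20 Hz), power-line interference at 60 and 120 Hz, an optional residual
carrier tone, and white Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import AcquisitionConfig, ConfigurationError, RawTrace
from .cells import CellEnsemble

__all__ = ["NoiseConfig", "synthesize_trace", "DEFAULT_GAIN_V_PER_UM3"]

#: Volts per µm³ of cell volume-equivalent; places the lymphocyte amplitude
#: mode near 1 V and the granulocyte+monocyte mode near 3.5 V.
DEFAULT_GAIN_V_PER_UM3 = 1.6e-3

#: Pulse full width (s) at a 10 µl/min total stream flow — 25 samples at
#: 250 kHz, matching the reference transit time.
WIDTH_AT_10_UL_MIN_S = 100e-6


@dataclass(frozen=True)
class NoiseConfig:
    """Additive disturbance amplitudes, all in volts.

    ``drift_frequency_hz`` must stay below 20 Hz so the specified high-pass
    stage can remove the drift.
    """

    white_noise_sd: float = 0.05
    drift_amplitude: float = 0.5
    drift_frequency_hz: float = 2.0
    powerline_60hz_amplitude: float = 0.1
    powerline_120hz_amplitude: float = 0.05
    carrier_residual_amplitude: float = 0.0
    carrier_frequency_hz: float = 50_000.0

    def __post_init__(self) -> None:
        for name in (
            "white_noise_sd",
            "drift_amplitude",
            "powerline_60hz_amplitude",
            "powerline_120hz_amplitude",
            "carrier_residual_amplitude",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0 < self.drift_frequency_hz < 20.0:
            raise ConfigurationError(
                "drift_frequency_hz must lie in (0, 20) Hz so the 20 Hz "
                "high-pass stage can remove it"
            )

    @classmethod
    def off(cls) -> "NoiseConfig":
        """All disturbance amplitudes zero (noiseless pulse train)."""
        return cls(
            white_noise_sd=0.0,
            drift_amplitude=0.0,
            powerline_60hz_amplitude=0.0,
            powerline_120hz_amplitude=0.0,
            carrier_residual_amplitude=0.0,
        )


def pulse_width_s(acquisition: AcquisitionConfig) -> float:
    """Transit-time pulse width for the configured total flow."""
    return WIDTH_AT_10_UL_MIN_S * 10.0 / acquisition.total_flow_ul_min


def synthesize_trace(
    ensemble: CellEnsemble,
    noise: NoiseConfig | None = None,
    acquisition: AcquisitionConfig | None = None,
    seed: int | np.random.Generator = 0,
    gain_v_per_um3: float = DEFAULT_GAIN_V_PER_UM3,
    counter_role: str = "entrance",
) -> RawTrace:
    """Render an ensemble into a noisy voltage trace.

    Raises
    ------
    ConfigurationError
        If any arrival time falls beyond the acquisition duration; the
        message lists the offending cell indices.
    """
    noise = noise or NoiseConfig()
    acquisition = acquisition or AcquisitionConfig()
    rng = np.random.default_rng(seed)

    n_samples = int(round(acquisition.duration_s * acquisition.sampling_rate_hz))
    if n_samples < 2:
        raise ConfigurationError("duration too short for the sampling rate")

    arrivals = ensemble.cells["arrival_time_s"].to_numpy()
    late = np.flatnonzero(arrivals > acquisition.duration_s)
    if late.size:
        raise ConfigurationError(
            f"arrival times beyond trace duration for cells {late.tolist()}"
        )

    fs = acquisition.sampling_rate_hz
    signal = np.zeros(n_samples)

    width = pulse_width_s(acquisition)
    sigma = width / 4.0
    half_span = int(np.ceil(4.0 * sigma * fs))  # ±4σ support per pulse
    offsets = np.arange(-half_span, half_span + 1)

    amplitudes = gain_v_per_um3 * ensemble.cells["diameter_um"].to_numpy() ** 3
    centers = arrivals * fs
    for amp, c in zip(amplitudes, centers):
        idx = int(round(c)) + offsets
        valid = (idx >= 0) & (idx < n_samples)
        t = idx[valid] - c
        np.add.at(signal, idx[valid], amp * np.exp(-0.5 * (t / (sigma * fs)) ** 2))

    t = np.arange(n_samples) / fs
    disturbance = np.zeros(n_samples)
    if noise.drift_amplitude:
        disturbance += noise.drift_amplitude * np.sin(
            2 * np.pi * noise.drift_frequency_hz * t
        )
    if noise.powerline_60hz_amplitude:
        disturbance += noise.powerline_60hz_amplitude * np.sin(2 * np.pi * 60.0 * t)
    if noise.powerline_120hz_amplitude:
        disturbance += noise.powerline_120hz_amplitude * np.sin(2 * np.pi * 120.0 * t)
    if noise.carrier_residual_amplitude:
        disturbance += noise.carrier_residual_amplitude * np.sin(
            2 * np.pi * noise.carrier_frequency_hz * t
        )
    if noise.white_noise_sd:
        disturbance += noise.white_noise_sd * rng.standard_normal(n_samples)

    return RawTrace(
        samples=signal + disturbance,
        sampling_rate_hz=fs,
        counter_role=counter_role,
        metadata={
            "gain_v_per_um3": gain_v_per_um3,
            "pulse_width_s": width,
            "n_cells": len(ensemble),
            "ground_truth": dict(ensemble.ground_truth),
        },
    )
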