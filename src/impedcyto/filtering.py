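"""Zero-phase digital filter chain for Coulter-counter traces.

The chain mirrors the reference acquisition software: a 20 Hz high-pass
stage removes baseline drift, two band-stop stages at (58, 62) Hz and
(118, 122) Hz remove power-line interference and its first harmonic, and a
low-pass stage removes residual carrier noise.  Each stage is a Butterworth
design applied forward-backward (``sosfiltfilt``) so pulse peak times and
amplitudes — the quantities gating depends on — are not shifted or skewed
by filter phase.

A configured low-pass cutoff at or above ~0.45× the sampling rate (for the
reference 303 kHz cutoff at 250 kHz sampling, i.e. above Nyquist) cannot be
realized as a digital filter; that stage degrades to an identity with a
logged warning rather than failing the whole chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy import signal as sps

from .core import ConfigurationError, RawTrace

__all__ = ["FilterConfig", "apply_filter_chain"]

logger = logging.getLogger(__name__)

#: Fraction of the sampling rate above which a low-pass cutoff is treated
#: as unrealizable and the stage becomes an identity.
LP_REALIZABLE_FRACTION = 0.45


@dataclass(frozen=True)
class FilterConfig:
    """Cutoffs (Hz) and per-stage order of the filter chain."""

    hp_cutoff_hz: float = 20.0
    bandstops_hz: tuple[tuple[float, float], ...] = ((58.0, 62.0), (118.0, 122.0))
    lp_cutoff_hz: float = 303_000.0
    order: int = 4

    def __post_init__(self) -> None:
        if self.hp_cutoff_hz <= 0:
            raise ConfigurationError("hp_cutoff_hz must be > 0")
        if self.order < 1:
            raise ConfigurationError("filter order must be >= 1")
        prev_high = self.hp_cutoff_hz
        for low, high in self.bandstops_hz:
            if not prev_high < low < high:
                raise ConfigurationError(
                    "band-stop intervals must be ordered, non-overlapping and "
                    "above the high-pass cutoff"
                )
            prev_high = high

    def validate_against(self, sampling_rate_hz: float) -> None:
        nyquist = sampling_rate_hz / 2.0
        if self.hp_cutoff_hz >= nyquist:
            raise ConfigurationError(
                f"hp_cutoff_hz={self.hp_cutoff_hz} is at or above the Nyquist "
                f"frequency {nyquist}"
            )
        for low, high in self.bandstops_hz:
            if high >= nyquist:
                raise ConfigurationError(
                    f"band-stop ({low}, {high}) Hz exceeds Nyquist {nyquist}"
                )


def _sos_stages(config: FilterConfig, fs: float) -> list:
    """Build the second-order-section cascade for one sampling rate."""
    # Butterworth order is halved for band-stop designs so every stage has
    # the same overall order.
    stages = [
        sps.butter(config.order, config.hp_cutoff_hz, "highpass", fs=fs, output="sos")
    ]
    for low, high in config.bandstops_hz:
        stages.append(
            sps.butter(
                max(config.order // 2, 1), [low, high], "bandstop", fs=fs, output="sos"
            )
        )
    if config.lp_cutoff_hz < LP_REALIZABLE_FRACTION * fs:
        stages.append(
            sps.butter(config.order, config.lp_cutoff_hz, "lowpass", fs=fs, output="sos")
        )
    else:
        logger.warning(
            "low-pass cutoff %.0f Hz is unrealizable at %.0f Hz sampling "
            "(needs < %.2f x fs); stage degraded to identity",
            config.lp_cutoff_hz, fs, LP_REALIZABLE_FRACTION,
        )
    return stages


def apply_filter_chain(trace: RawTrace, config: FilterConfig | None = None) -> RawTrace:
    """Apply the high-pass / band-stop / low-pass cascade, zero phase."""
    config = config or FilterConfig()
    config.validate_against(trace.sampling_rate_hz)

    samples = trace.samples
    for sos in _sos_stages(config, trace.sampling_rate_hz):
        samples = sps.sosfiltfilt(sos, samples)

    out = trace.with_samples(samples)
    out.metadata = {**trace.metadata, "filtered": True}
    return out
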