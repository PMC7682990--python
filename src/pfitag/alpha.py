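"""Event-locked alpha-band amplitude.

The alpha (8-12 Hz) envelope is extracted per electrode by a Gaussian
bandpass (center 10 Hz, FWHM 2 Hz on the amplitude spectrum) followed by
the analytic-signal magnitude, then normalized by each participant's mean
envelope over a pre-event baseline window (-2.5 to -1.5 s before button
press), so a value of 1 is baseline level and event-related suppression
shows as values below 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .ress import gaussian_narrowband_filter

__all__ = ["AlphaParams", "alpha_envelope", "baseline_normalize", "suppression_depth"]


@dataclass(frozen=True)
class AlphaParams:
    band: tuple[float, float] = (8.0, 12.0)
    center: float = 10.0
    fwhm: float = 2.0
    baseline_window: tuple[float, float] = (-2.5, -1.5)
    epoch_window: tuple[float, float] = (-2.5, 2.5)
    #: outer margin (s) excluded from statistics against analytic-signal
    #: edge effects
    edge_exclude: float = 0.25

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        b0, b1 = self.baseline_window
        e0, e1 = self.epoch_window
        if not (e0 <= b0 < b1 <= e1):
            raise ValueError("baseline window must lie inside the epoch window")


def alpha_envelope(
    epoch: np.ndarray,
    sample_rate: float,
    params: AlphaParams = AlphaParams(),
) -> np.ndarray:
    """Alpha-band amplitude envelope along the last axis.

    Gaussian bandpass at ``params.center`` then the magnitude of the
    analytic (Hilbert-transformed) signal, on the same sampling grid.
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.shape[-1] / sample_rate < 1.0:
        raise ValueError("epoch shorter than 1 s; need several alpha cycles")
    filtered = gaussian_narrowband_filter(
        epoch, sample_rate, params.center, params.fwhm
    )
    return np.abs(hilbert(filtered, axis=-1))


def baseline_normalize(
    envelopes: np.ndarray,
    times: np.ndarray,
    params: AlphaParams = AlphaParams(),
) -> np.ndarray:
    """Divide envelopes by the participant-level mean baseline amplitude.

    ``envelopes`` is (n_epochs, ..., n_samples) for one participant;
    ``times`` are the shared relative times.  One baseline value is computed
    per electrode by pooling all of the participant's epochs over the
    baseline window, then every time point is divided by it, following the
    within-participant convention.
    """
    envelopes = np.asarray(envelopes, dtype=float)
    times = np.asarray(times)
    b0, b1 = params.baseline_window
    mask = (times >= b0) & (times <= b1)
    if not mask.any():
        raise ValueError("baseline window not present in the epoch")
    baseline = envelopes[..., mask].mean(axis=(0, -1), keepdims=True)
    if np.any(baseline == 0):
        raise FloatingPointError("zero baseline mean; cannot normalize")
    return envelopes / baseline


def suppression_depth(
    normalized: np.ndarray,
    times: np.ndarray,
    window: tuple[float, float] = (0.0, 1.0),
) -> float:
    """Fractional suppression (1 - mean normalized amplitude) over a
    post-event window, averaged across epochs."""
    times = np.asarray(times)
    mask = (times >= window[0]) & (times <= window[1])
    return float(1.0 - np.asarray(normalized)[..., mask].mean())
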