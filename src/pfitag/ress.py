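"""Rhythmic entrainment source separation (RESS).

A RESS filter is a channel-weight vector maximizing the variance of
narrowband activity at one tag frequency relative to broadband reference
activity, obtained from the generalized eigendecomposition of the
(narrowband signal covariance, broadband reference covariance) pair.
Applying the weights collapses the multichannel recording to a single
component time series per frequency, on which log-SNR is then computed,
avoiding any post-hoc channel selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = ["gaussian_narrowband_filter", "RESS", "RESSFilter", "fit_ress", "apply_ress"]


def gaussian_narrowband_filter(
    signal: np.ndarray,
    sample_rate: float,
    center: float,
    fwhm: float,
) -> np.ndarray:
    """Frequency-domain Gaussian bandpass along the last axis.

    The amplitude gain is 1 at ``center`` and 0.5 at ``center +- fwhm / 2``
    (FWHM defined on the amplitude spectrum); negative frequencies receive
    the mirrored gain implicitly through the real FFT.  Output is real and
    has the input's length.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    if center >= sample_rate / 2:
        raise ValueError("center frequency must be below Nyquist")
    x = np.asarray(signal, dtype=float)
    n = x.shape[-1]
    freqs = np.fft.rfftfreq(n, 1.0 / sample_rate)
    gain = np.exp(np.log(0.5) * ((freqs - center) / (fwhm / 2.0)) ** 2)
    return np.fft.irfft(np.fft.rfft(x, axis=-1) * gain, n=n, axis=-1)


@dataclass
class RESSFilter:
    """Fitted spatial filter: one gain per channel, with the generalized
    eigenvalue lambda (narrowband-to-broadband variance ratio)."""

    weights: np.ndarray
    frequency: float
    eigenvalue: float
    fwhm: float = 0.5


class RESS:
    """Spatial filter maximizing narrowband vs broadband variance.

    Parameters
    ----------
    frequency : float
        Tag frequency (Hz) the filter is tuned to.
    fwhm : float
        Full-width at half-maximum (Hz) of the Gaussian narrowband filter
        used to build the signal covariance (amplitude-gain convention).
    shrinkage : float
        Fraction by which the broadband reference covariance is shrunk
        toward its scaled identity (1% by default) to guard against
        ill-conditioning from short filtered epochs.

    Attributes (after :meth:`fit`)
    ------------------------------
    weights_ : ndarray, (n_channels,)
        Unit-norm spatial filter; sign fixed so the channel with the
        largest absolute weight is positive.
    eigenvalue_ : float
        Largest generalized eigenvalue.
    eigenvalues_ : ndarray
        Full spectrum, descending.
    signal_cov_, reference_cov_ : ndarray
        The covariance pair actually decomposed (reference after
        shrinkage).
    """

    def __init__(self, frequency: float, fwhm: float = 0.5, shrinkage: float = 0.01):
        self.frequency = frequency
        self.fwhm = fwhm
        self.shrinkage = shrinkage

    # -- sklearn-style plumbing -------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "frequency": self.frequency,
            "fwhm": self.fwhm,
            "shrinkage": self.shrinkage,
        }

    def set_params(self, **params) -> "RESS":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # ----------------------------------------------------------------------
    def fit(self, epochs, sample_rate: float) -> "RESS":
        """Fit from channels x time epochs (list or 3-D array).

        Epochs are demeaned per channel; the signal covariance comes from
        their narrowband-filtered versions, the reference covariance from
        the unfiltered (broadband) versions, averaged across epochs.
        """
        if isinstance(epochs, np.ndarray) and epochs.ndim == 2:
            epochs = [epochs]
        epochs = [np.asarray(e, dtype=float) for e in epochs]
        if not epochs:
            raise ValueError("need at least one epoch")
        n_channels = epochs[0].shape[0]
        if n_channels < 2:
            raise ValueError("need at least two channels")

        S = np.zeros((n_channels, n_channels))
        R = np.zeros((n_channels, n_channels))
        for ep in epochs:
            ep = ep - ep.mean(axis=1, keepdims=True)
            nb = gaussian_narrowband_filter(ep, sample_rate, self.frequency, self.fwhm)
            nb = nb - nb.mean(axis=1, keepdims=True)
            S += nb @ nb.T / nb.shape[1]
            R += ep @ ep.T / ep.shape[1]
        S /= len(epochs)
        R /= len(epochs)

        # shrink reference toward its scaled identity (mean eigenvalue)
        gamma = self.shrinkage
        R_reg = (1.0 - gamma) * R + gamma * (np.trace(R) / n_channels) * np.eye(
            n_channels
        )

        try:
            evals, evecs = linalg.eigh(S, R_reg)
        except linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "generalized eigendecomposition failed; the reference "
                "covariance is singular even after shrinkage - raise the "
                "shrinkage parameter"
            ) from exc
        order = np.argsort(evals)[::-1]
        evals = evals[order]
        evecs = evecs[:, order]

        w = evecs[:, 0]
        w = w / np.linalg.norm(w)
        peak = int(np.argmax(np.abs(w)))
        if w[peak] < 0:
            w = -w

        self.weights_ = w
        self.eigenvalue_ = float(evals[0])
        self.eigenvalues_ = evals
        self.signal_cov_ = S
        self.reference_cov_ = R_reg
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project channels x time data (any leading shape) onto the filter."""
        if not hasattr(self, "weights_"):
            raise RuntimeError("RESS filter is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[-2] != self.weights_.size:
            raise ValueError(
                f"channel mismatch: data has {X.shape[-2]}, filter has "
                f"{self.weights_.size}"
            )
        return np.einsum("c,...ct->...t", self.weights_, X)

    def fit_transform(self, epochs, sample_rate: float) -> np.ndarray:
        self.fit(epochs, sample_rate)
        return np.stack([self.transform(np.asarray(e, dtype=float)) for e in epochs])

    @property
    def filter_(self) -> RESSFilter:
        return RESSFilter(
            weights=self.weights_,
            frequency=self.frequency,
            eigenvalue=self.eigenvalue_,
            fwhm=self.fwhm,
        )


def fit_ress(
    epochs,
    sample_rate: float,
    frequency: float,
    fwhm: float = 0.5,
    shrinkage: float = 0.01,
) -> RESSFilter:
    """Functional wrapper over :class:`RESS`; returns the fitted filter."""
    return RESS(frequency, fwhm=fwhm, shrinkage=shrinkage).fit(
        epochs, sample_rate
    ).filter_


def apply_ress(filt: RESSFilter, data: np.ndarray) -> np.ndarray:
    """Weighted channel sum: collapse channels x time data to one component."""
    data = np.asarray(data, dtype=float)
    if data.shape[-2] != filt.weights.size:
        raise ValueError("channel count does not match the filter")
    return np.einsum("c,...ct->...t", filt.weights, data)
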