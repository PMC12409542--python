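"""Time-series diagnostics of scalar trajectory observables.

Autocorrelation reveals persistence and periodicity in an RMSD (or any
per-frame scalar) signal; the Welch periodogram-averaging method gives a
variance-reduced power spectral density. The PSD is delegated to
``scipy.signal.welch``; the autocorrelation uses the biased
(divide-by-N) estimator, which guarantees ``|rho| <= 1`` and stable plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .errors import ConfigurationError, DegenerateSignalError

__all__ = [
    "AutocorrelationFunction",
    "PowerSpectrum",
    "autocorrelation",
    "welch_psd",
    "spectral_centroid",
]


@dataclass(frozen=True)
class AutocorrelationFunction:
    """Normalized autocorrelation rho(k) for lags 0..max_lag."""

    lags: np.ndarray
    rho: np.ndarray


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided Welch PSD.

    ``freqs`` is in cycles/frame (0..0.5); ``freqs_per_ns`` converts via
    the frame spacing when one was given. The PSD is normalized so that
    its integral over frequency approximates the series variance.
    """

    freqs: np.ndarray
    psd: np.ndarray
    freqs_per_ns: np.ndarray | None = None


def autocorrelation(series: np.ndarray, max_lag: int) -> AutocorrelationFunction:
    """Biased-estimator autocorrelation of a per-frame scalar series.

    ``rho(k) = sum_t (x_t - xbar)(x_{t+k} - xbar) / sum_t (x_t - xbar)^2``
    with the full-length denominator, so ``rho(0) = 1`` and ``|rho| <= 1``.

    Raises
    ------
    ConfigurationError
        If ``max_lag`` is not in ``[1, len(series))``.
    DegenerateSignalError
        For a zero-variance series.
    """
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    if not (1 <= max_lag < n):
        raise ConfigurationError(f"need 1 <= max_lag < {n}, got {max_lag}")
    x = x - x.mean()
    denom = float(x @ x)
    if denom <= 0.0 or not np.isfinite(denom):
        raise DegenerateSignalError("series has zero variance; autocorrelation undefined")
    # FFT-based full autocovariance, biased normalization; dividing by the
    # FFT's own zero-lag value keeps rho(0) = 1 exactly under round-off
    nfft = 1 << int(np.ceil(np.log2(2 * n - 1)))
    fx = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(fx * np.conj(fx), nfft)[: max_lag + 1]
    rho = acov / acov[0]
    return AutocorrelationFunction(lags=np.arange(max_lag + 1), rho=rho)


def welch_psd(
    series: np.ndarray,
    segment_length: int | None = None,
    overlap_fraction: float = 0.5,
    window: str = "hann",
    detrend: str | bool = "linear",
    dt: float | None = None,
) -> PowerSpectrum:
    """One-sided Welch power spectral density of a per-frame series.

    Defaults follow the method's canonical usage: Hann window, segment
    length N/8 rounded down to a power of two, 50% overlap, and linear
    detrending per segment. The frequency axis is cycles/frame; pass the
    frame spacing ``dt`` (ns) to also get cycles/ns.
    """
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    if n < 8:
        raise ConfigurationError(f"series too short for spectral estimation (n={n})")
    if segment_length is None:
        segment_length = 1 << max(3, int(np.floor(np.log2(max(n // 8, 8)))))
    if segment_length > n:
        raise ConfigurationError(
            f"segment_length {segment_length} exceeds series length {n}"
        )
    if not (0.0 <= overlap_fraction < 1.0):
        raise ConfigurationError(f"overlap_fraction must be in [0, 1), got {overlap_fraction}")
    noverlap = int(segment_length * overlap_fraction)
    freqs, psd = sp_signal.welch(
        x,
        fs=1.0,
        window=window,
        nperseg=segment_length,
        noverlap=noverlap,
        detrend=detrend,
        return_onesided=True,
        scaling="density",
    )
    freqs_per_ns = freqs / dt if dt else None
    return PowerSpectrum(freqs=freqs, psd=psd, freqs_per_ns=freqs_per_ns)


def spectral_centroid(spectrum: PowerSpectrum) -> float:
    """Power-weighted mean frequency (cycles/frame) of a spectrum.

    Slower processes concentrate power at low frequency, so a smaller
    centroid indicates slower dynamics.
    """
    total = float(spectrum.psd.sum())
    if total <= 0:
        raise DegenerateSignalError("spectrum has no power")
    return float((spectrum.freqs * spectrum.psd).sum() / total)
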