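"""Welch spectra, individual alpha-peak selection and Hilbert envelopes.

The analysis band is individualized: the alpha peak is located in the Welch
power spectrum (a clear spectral peak above the 1/f background being a
prerequisite for studying the oscillation at all), and signals are then
band-pass filtered to peak +/- 1 Hz before the analytic amplitude envelope
is taken via the Hilbert transform.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recording import Recording

logger = logging.getLogger(__name__)

#: Half-width of the individualized analysis band around the alpha peak (Hz).
BAND_HALF_WIDTH_HZ = 1.0


@dataclass
class PowerSpectrum:
    freqs: np.ndarray          # (n_freqs,), Hz, strictly increasing
    power: np.ndarray          # (n_channels, n_freqs), µV²/Hz
    window_s: float
    overlap: float
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")


@dataclass
class AlphaBand:
    f_peak: float | None
    band: tuple[float, float] | None   # (f_peak - 1, f_peak + 1) when found
    peak_found: bool
    prominence_db: float = 0.0         # dB above the fitted 1/f background


def welch_psd(rec: Recording, window_s: float = 2.0, overlap: float = 0.5) -> PowerSpectrum:
    """Average of modified periodograms (Hamming taper) per channel."""
    nperseg = int(round(window_s * rec.fs))
    if nperseg < 2:
        raise ValueError("window too short: window_s * fs must be >= 2")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    if rec.n_samples < nperseg:
        raise ValueError("record shorter than one Welch window")
    freqs, power = signal.welch(
        rec.data,
        fs=rec.fs,
        window=signal.get_window("hamming", nperseg),
        nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)),
        detrend="constant",
        axis=-1,
    )
    # drop the DC bin so log-log background fits are well defined
    return PowerSpectrum(freqs[1:], power[..., 1:], window_s, overlap, list(rec.labels))


def _background_db(freqs: np.ndarray, power_db: np.ndarray,
                   fit_range: tuple[float, float],
                   exclude: tuple[float, float]) -> np.ndarray:
    """Log-log linear 1/f fit, excluding the peak search band."""
    m = (freqs >= fit_range[0]) & (freqs <= fit_range[1])
    m &= ~((freqs >= exclude[0]) & (freqs <= exclude[1]))
    if m.sum() < 4:
        raise ValueError("not enough spectrum outside the search band for a 1/f fit")
    coef = np.polyfit(np.log10(freqs[m]), power_db[m], 1)
    return np.polyval(coef, np.log10(freqs))


def find_alpha_peak(
    psd: PowerSpectrum,
    search_band: tuple[float, float] = (7.0, 13.0),
    min_prominence_db: float = 3.0,
    fit_range: tuple[float, float] = (2.0, 30.0),
    channels: np.ndarray | None = None,
) -> AlphaBand:
    """Locate the individual alpha peak above the 1/f background.

    The channel-averaged spectrum (or the subset in ``channels``) is
    expressed in dB, a log-log linear background is fitted outside the
    search band, and the most prominent local maximum of the residual
    within the band is taken. If no local maximum exceeds
    ``min_prominence_db`` above the background the spectrum is declared
    peakless (``peak_found=False``) — the oscillation is then not
    demonstrable and downstream correlation analysis must be skipped.
    """
    lo, hi = search_band
    if hi <= lo:
        raise ValueError("empty search band")
    power = psd.power if channels is None else psd.power[channels]
    spec = power.mean(axis=0)
    floor = max(spec[spec > 0].min() * 1e-6, 1e-300) if np.any(spec > 0) else 1e-300
    power_db = 10 * np.log10(np.maximum(spec, floor))
    fit_lo = max(fit_range[0], psd.freqs[0])
    fit_hi = min(fit_range[1], psd.freqs[-1])
    bg_db = _background_db(psd.freqs, power_db, (fit_lo, fit_hi), search_band)
    resid = power_db - bg_db

    in_band = (psd.freqs >= lo) & (psd.freqs <= hi)
    if not np.any(in_band):
        raise ValueError("search band outside the frequency grid")
    peaks, _ = signal.find_peaks(resid)
    peaks = peaks[in_band[peaks]]
    peaks = peaks[resid[peaks] >= min_prominence_db]
    if peaks.size == 0:
        return AlphaBand(None, None, False, 0.0)
    best = peaks[np.argmax(resid[peaks])]
    f_peak = float(psd.freqs[best])
    return AlphaBand(
        f_peak,
        (f_peak - BAND_HALF_WIDTH_HZ, f_peak + BAND_HALF_WIDTH_HZ),
        True,
        float(resid[best]),
    )


def _band_tuple(band: AlphaBand | tuple[float, float]) -> tuple[float, float]:
    if isinstance(band, AlphaBand):
        if not band.peak_found or band.band is None:
            raise ValueError("no alpha peak found; cannot band-pass filter")
        return band.band
    return (float(band[0]), float(band[1]))


def bandpass(rec: Recording, band: AlphaBand | tuple[float, float], order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass to the individualized alpha band.

    Forward-backward filtering doubles the effective order, giving a flat
    (<1 dB ripple) passband and >40 dB attenuation one octave outside the
    band for the default order.
    """
    lo, hi = _band_tuple(band)
    nyq = rec.fs / 2
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band ({lo}, {hi}) Hz must lie strictly inside (0, {nyq})")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=-1)
    return rec.copy_with(data=data, band=(lo, hi))


def edge_duration_s(band: tuple[float, float]) -> float:
    """Filter + Hilbert edge-transient duration to flag: 2 / bandwidth."""
    return 2.0 / (band[1] - band[0])


def analytic_envelope(rec: Recording) -> np.ndarray:
    """Instantaneous amplitude: magnitude of the Hilbert analytic signal.

    Returns a (n_channels, n_samples) nonnegative array. Inputs should be
    narrow-band; a non-filtered input triggers a provenance warning (not
    fatal). The first and last ``edge_duration_s`` seconds are unreliable
    and should be excluded from correlation statistics.
    """
    if rec.band is None:
        warnings.warn(
            "analytic_envelope on a record without a recorded passband; "
            "the envelope of broadband data is not interpretable",
            stacklevel=2,
        )
    return np.abs(signal.hilbert(rec.data, axis=-1))


def analytic_signal(rec: Recording) -> np.ndarray:
    """Complex analytic signal per channel (Hilbert transform)."""
    if rec.band is None:
        warnings.warn("analytic_signal on a record without a recorded passband",
                      stacklevel=2)
    return signal.hilbert(rec.data, axis=-1)
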