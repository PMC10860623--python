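"""Spectral parameterization: Welch PSD, vector-sum combination of planar
gradiometer pairs, aperiodic (1/f) fitting and the periodic beta profile.

The aperiodic model is ``log10 P(f) = offset - chi * log10 f`` (fixed mode,
no knee), fitted robustly so that narrow oscillatory peaks do not drag the
slope: an initial least-squares fit is refit after excluding bins whose
positive residual exceeds 2.5 residual standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "PowerSpectrum",
    "AperiodicFit",
    "PeriodicProfile",
    "ChannelSelection",
    "welch_psd",
    "vector_sum_psd",
    "fit_aperiodic",
    "periodic_component",
    "select_peak_channel",
    "bandpass_fir",
]

BETA_BAND = (14.0, 30.0)


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided power spectral density on an ascending frequency grid."""

    freqs: np.ndarray
    power: np.ndarray
    n_segments: int = 1

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        power = np.asarray(self.power, dtype=float)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "power", power)
        if freqs.shape != power.shape:
            raise ValueError("freqs and power must have the same length")
        if freqs.size > 1 and not np.all(np.diff(freqs) > 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(power < 0):
            raise ValueError("power must be nonnegative")

    def band(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask for lo <= f <= hi."""
        return (self.freqs >= lo) & (self.freqs <= hi)


@dataclass(frozen=True)
class AperiodicFit:
    """Power-law background: offset (log10 power at 1 Hz) and exponent chi."""

    offset: float
    exponent: float
    fit_range: tuple[float, float]
    fit_error: float  # RMSE in log10 space over the (unmasked) fit range

    def evaluate(self, freqs: np.ndarray) -> np.ndarray:
        """Model PSD in linear units at the given frequencies (inf at DC
        for a decaying power law)."""
        freqs = np.asarray(freqs, dtype=float)
        with np.errstate(divide="ignore"):
            return 10.0 ** self.offset * freqs ** (-self.exponent)


@dataclass(frozen=True)
class PeriodicProfile:
    """Aperiodic-subtracted residual spectrum and its beta-band summary.

    ``beta_peak_freq``/``beta_peak_power`` are None when no positive
    residual exists in the beta band. ``total_beta_power`` is the
    trapezoidal area of the residual over 14-30 Hz with negative residuals
    clipped to zero (power is nonnegative by definition); peak finding uses
    the unclipped residual.
    """

    freqs: np.ndarray
    residual: np.ndarray
    beta_peak_freq: float | None
    beta_peak_power: float | None
    total_beta_power: float


@dataclass(frozen=True)
class ChannelSelection:
    selected_pair_index: int
    peak_beta_frequency: float
    selection_mode: str


def welch_psd(signal: np.ndarray, sampling_rate: float, nfft: int = 1024) -> PowerSpectrum:
    """Welch PSD: mean of Hamming-windowed periodograms over non-overlapping
    ``nfft``-sample segments (density scaling, trailing partial segment dropped).
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if signal.size < nfft:
        raise ValueError(f"signal has {signal.size} samples, needs >= nfft={nfft}")
    freqs, power = sps.welch(
        signal, fs=sampling_rate, window="hamming", nperseg=nfft,
        noverlap=0, nfft=nfft, detrend=False, scaling="density",
    )
    return PowerSpectrum(freqs=freqs, power=power, n_segments=signal.size // nfft)


def vector_sum_psd(psd_a: PowerSpectrum, psd_b: PowerSpectrum) -> PowerSpectrum:
    """Combine the two orthogonal gradiometers of a sensor site:
    ``sqrt(PSD_ch1^2 + PSD_ch2^2)`` per frequency bin."""
    if psd_a.freqs.shape != psd_b.freqs.shape or not np.allclose(psd_a.freqs, psd_b.freqs):
        raise ValueError("frequency grids differ between channels")
    return PowerSpectrum(
        freqs=psd_a.freqs,
        power=np.hypot(psd_a.power, psd_b.power),
        n_segments=min(psd_a.n_segments, psd_b.n_segments),
    )


def _loglog_lsq(logf: np.ndarray, logp: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(logf, logp, 1)
    return float(intercept), float(-slope)


def fit_aperiodic(psd: PowerSpectrum,
                  fit_range: tuple[float, float] = (2.0, 48.0)) -> AperiodicFit:
    """Robust log-log power-law fit of the aperiodic background.

    Initial least squares on log10 power vs log10 frequency, then a single
    refit excluding bins whose positive residual exceeds 2.5x the residual
    SD — oscillatory peaks sit above the background and are suppressed,
    while the noiseless power-law case is recovered exactly.
    """
    lo, hi = fit_range
    mask = psd.band(lo, hi) & (psd.freqs > 0)
    if mask.sum() < 10:
        raise ValueError(f"need >= 10 bins in fit range {fit_range}, got {mask.sum()}")
    power = psd.power[mask]
    if np.any(power <= 0):
        raise ValueError("nonpositive power inside the fit range")
    logf = np.log10(psd.freqs[mask])
    logp = np.log10(power)

    offset, exponent = _loglog_lsq(logf, logp)
    resid = logp - (offset - exponent * logf)
    sd = resid.std()
    if sd > 0:
        keep = resid <= 2.5 * sd
        if keep.sum() >= 10 and keep.sum() < keep.size:
            offset, exponent = _loglog_lsq(logf[keep], logp[keep])
            resid = logp - (offset - exponent * logf)
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    return AperiodicFit(offset=offset, exponent=exponent,
                        fit_range=(lo, hi), fit_error=rmse)


def periodic_component(psd: PowerSpectrum, fit: AperiodicFit,
                       band: tuple[float, float] = BETA_BAND) -> PeriodicProfile:
    """Subtract the fitted aperiodic background and summarize the beta band.

    The residual is in linear power units. The beta peak is the argmax of
    the (signed) residual within the band; the band AUC integrates the
    residual clipped at zero.
    """
    residual = psd.power - fit.evaluate(psd.freqs)
    mask = psd.band(*band)
    peak_freq: float | None = None
    peak_power: float | None = None
    if mask.any():
        band_res = residual[mask]
        i = int(np.argmax(band_res))
        if band_res[i] > 0:
            peak_freq = float(psd.freqs[mask][i])
            peak_power = float(band_res[i])
        auc = float(np.trapezoid(np.clip(band_res, 0.0, None), psd.freqs[mask]))
    else:
        auc = 0.0
    return PeriodicProfile(freqs=psd.freqs, residual=residual,
                           beta_peak_freq=peak_freq, beta_peak_power=peak_power,
                           total_beta_power=auc)


def select_peak_channel(
    roi_profiles: Sequence[PeriodicProfile],
    mode: str = "rest-peak",
    mot_profiles: Sequence[PeriodicProfile] | None = None,
    band: tuple[float, float] = BETA_BAND,
) -> ChannelSelection:
    """Pick the peak channel pair of a sensorimotor ROI.

    ``rest-peak``: the pair with the largest periodic beta peak at rest.
    ``modulation``: the pair whose beta-band residual drops most from rest
    to the motor condition (automated counterpart of selecting the movement-
    modulated frequency by eye). Ties break to the lowest pair index.
    """
    if len(roi_profiles) == 0:
        raise ValueError("empty ROI profile list")
    if mode == "rest-peak":
        best_idx, best_val, best_freq = None, -np.inf, None
        for i, prof in enumerate(roi_profiles):
            if prof.beta_peak_power is None:
                continue
            if prof.beta_peak_power > best_val:
                best_idx, best_val, best_freq = i, prof.beta_peak_power, prof.beta_peak_freq
        if best_idx is None:
            raise ValueError("no positive periodic beta peak in any ROI pair")
        return ChannelSelection(best_idx, float(best_freq), mode)
    if mode == "modulation":
        if mot_profiles is None or len(mot_profiles) != len(roi_profiles):
            raise ValueError("modulation mode needs matching motor-condition profiles")
        best_idx, best_val, best_freq = None, -np.inf, None
        for i, (rest, mot) in enumerate(zip(roi_profiles, mot_profiles)):
            mask = (rest.freqs >= band[0]) & (rest.freqs <= band[1])
            diff = rest.residual[mask] - mot.residual[mask]
            j = int(np.argmax(diff))
            if diff[j] > best_val:
                best_idx, best_val = i, float(diff[j])
                best_freq = float(rest.freqs[mask][j])
        if best_idx is None or best_val <= 0:
            raise ValueError("no movement-modulated beta residual in any ROI pair")
        return ChannelSelection(best_idx, best_freq, mode)
    raise ValueError(f"unknown selection mode {mode!r}")


def bandpass_fir(signal: np.ndarray, sampling_rate: float,
                 lo: float = 2.0, hi: float = 48.0,
                 transition: float = 2.0) -> np.ndarray:
    """Zero-phase Hamming-window FIR bandpass (optional preprocessing step;
    the synthetic generator is already band-limited so the pipeline leaves
    this off by default)."""
    numtaps = int(6.6 * sampling_rate / transition)
    numtaps += 1 - numtaps % 2  # odd length for a type-I filter
    taps = sps.firwin(numtaps, [lo, hi], pass_zero=False,
                      window="hamming", fs=sampling_rate)
    return sps.filtfilt(taps, [1.0], signal)
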