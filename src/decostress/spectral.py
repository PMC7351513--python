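"""Frequency-domain HRV: per-window power spectral density and band powers.

Each 256-beat window is mean-removed and transformed with the FFT. The beat
series is treated as uniformly sampled at the mean heart period, so DFT bin k
maps to frequency ``k / (W * mean_rr_seconds)``. The one-sided bin powers are
normalized so that their sum equals the window's population variance
(Parseval's identity), i.e. total spectral power tracks SDNN².

Band definitions (half-open, lower edge inclusive; the 0.4 Hz upper edge of
HF is inclusive):

* VLF: 0.01–0.04 Hz (short recordings resolve this band poorly),
* LF:  0.04–0.15 Hz,
* HF:  0.15–0.4 Hz.

Normalized units express a band as a percentage of VLF+LF+HF; band fractions
divide by SDNN², the total-power proxy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .rr_processing import RRWindow

logger = logging.getLogger("decostress")

VLF_BAND = (0.01, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided PSD of a window: DC excluded, power in ms² per bin."""

    frequencies: np.ndarray  # Hz, ascending
    power: np.ndarray  # ms² per bin, sums to the window's population variance
    total_power: float  # ms²
    #: bins below 1/(W·mean_rr) cannot complete one cycle in the window
    min_resolvable_hz: float = 0.0


@dataclass(frozen=True)
class BandPowers:
    """Band-integrated spectral summary of one window."""

    vlf: float  # ms²
    lf: float  # ms²
    hf: float  # ms²
    total_low: float  # vlf + lf, ms²
    lf_hf_ratio: float  # nan when hf == 0
    lf_nu: float  # % of VLF+LF+HF
    hf_nu: float  # % of VLF+LF+HF
    vlf_nu: float  # % of VLF+LF+HF
    lf_frac: float  # lf / sdnn²
    hf_frac: float  # hf / sdnn²
    sdnn_sq: float  # ms², total-power proxy


def compute_psd(window: RRWindow, resample_hz: float | None = None) -> PowerSpectrum:
    """One-sided power spectrum of a mean-removed R-R window.

    Parameters
    ----------
    window
        R-R window; length must be a power of two unless resampling.
    resample_hz
        If given, the tachogram is cubic-spline interpolated onto a uniform
        grid at this rate (e.g. 4 Hz) spanning the window's cumulative time
        before the transform. Default is no resampling: beat-indexed FFT with
        the mean-R-R frequency mapping.

    The bin powers are scaled so their sum equals the (population) variance of
    the analyzed signal; a zero-variance window yields an all-zero spectrum.
    """
    x = np.asarray(window.intervals, dtype=float)
    mean_rr_s = float(np.mean(x)) / 1000.0

    if resample_hz is not None:
        # beat i occurs at the cumulative time of the preceding intervals
        t_beats = np.cumsum(x) / 1000.0
        t_beats -= t_beats[0]
        grid = np.arange(0.0, t_beats[-1], 1.0 / resample_hz)
        x = CubicSpline(t_beats, x)(grid)
        dt = 1.0 / resample_hz
        w = x.size
    else:
        if (len(window) & (len(window) - 1)) != 0:
            raise ValueError("window length must be a power of two for the FFT")
        dt = mean_rr_s
        w = len(window)

    centered = x - np.mean(x)
    variance = float(np.mean(centered**2))  # population variance
    spectrum = np.fft.rfft(centered)
    # one-sided power; double interior bins, never DC (k=0) nor Nyquist
    power = np.abs(spectrum) ** 2 / w**2
    power[1:] *= 2.0
    if w % 2 == 0:
        power[-1] /= 2.0
    power = power[1:]  # drop DC (zero after mean removal)
    freqs = np.arange(1, power.size + 1) / (w * dt)
    return PowerSpectrum(
        frequencies=freqs,
        power=power,
        total_power=variance,
        min_resolvable_hz=1.0 / (w * dt),
    )


def band_power(spectrum: PowerSpectrum, lo: float, hi: float, *, inclusive_hi: bool = False) -> float:
    """Integrate bin powers over [lo, hi) — or [lo, hi] when inclusive_hi."""
    f = spectrum.frequencies
    mask = (f >= lo) & ((f <= hi) if inclusive_hi else (f < hi))
    return float(np.sum(spectrum.power[mask]))


def band_powers(spectrum: PowerSpectrum, sdnn: float) -> BandPowers:
    """The standard HRV band summaries of one window's spectrum.

    ``sdnn`` (ms) supplies the total-power proxy SDNN² used for the band
    fractions. When HF power is zero the LF/HF ratio is reported as NaN.
    """
    if sdnn < 0:
        raise ValueError("sdnn must be >= 0")
    vlf = band_power(spectrum, *VLF_BAND)
    lf = band_power(spectrum, *LF_BAND)
    hf = band_power(spectrum, *HF_BAND, inclusive_hi=True)
    if spectrum.min_resolvable_hz > VLF_BAND[0]:
        logger.debug(
            "VLF lower edge %g Hz below the window's resolution %g Hz",
            VLF_BAND[0], spectrum.min_resolvable_hz,
        )
    total_nu = vlf + lf + hf
    if total_nu > 0:
        lf_nu = 100.0 * lf / total_nu
        hf_nu = 100.0 * hf / total_nu
        vlf_nu = 100.0 * vlf / total_nu
    else:
        lf_nu = hf_nu = vlf_nu = math.nan
    sdnn_sq = sdnn**2
    return BandPowers(
        vlf=vlf,
        lf=lf,
        hf=hf,
        total_low=vlf + lf,
        lf_hf_ratio=(lf / hf) if hf > 0 else math.nan,
        lf_nu=lf_nu,
        hf_nu=hf_nu,
        vlf_nu=vlf_nu,
        lf_frac=(lf / sdnn_sq) if sdnn_sq > 0 else math.nan,
        hf_frac=(hf / sdnn_sq) if sdnn_sq > 0 else math.nan,
        sdnn_sq=sdnn_sq,
    )
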