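"""Welch spectra and aperiodic/periodic spectral parameterization.

The power spectrum is decomposed into an aperiodic component — a straight
line in log10-power vs log10-frequency space, parameterized by its offset
(log power at 1 Hz) and exponent (the x in 1/f^x; positive = descending) —
plus Gaussian periodic peaks.  The fitting procedure follows the fixed-mode
(no knee) spectral parameterization algorithm: a robust initial line fit
that ignores points lying far above the line, iterative extraction of
Gaussian peaks from the flattened spectrum until no candidate exceeds the
peak threshold, and a final aperiodic refit on the peak-subtracted spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.optimize import curve_fit

from .montage import Montage

__all__ = [
    "Spectrum",
    "AperiodicFit",
    "SpecparamSettings",
    "welch",
    "smooth_spectrum",
    "fit_specparam",
    "band_measures",
    "average_channels",
]

_FWHM_TO_SD = 2 * np.sqrt(2 * np.log(2))


@dataclass
class Spectrum:
    """One-sided PSD, per channel, in µV²/Hz."""

    frequencies: np.ndarray  # Hz, strictly increasing
    power: np.ndarray  # (n_channels, n_freqs)
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if self.power.shape[1] != self.frequencies.size:
            raise ValueError("power and frequency grids disagree")

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


@dataclass
class AperiodicFit:
    offset: float  # log10 power at 1 Hz
    exponent: float  # x in 1/f^x
    peaks: list[tuple[float, float, float]] = field(default_factory=list)
    # (center Hz, height in log10 units, sd in Hz)
    mae: float = 0.0  # log10 units, full model vs data
    r_squared: float = 1.0
    fit_range: tuple[float, float] = (2.0, 35.0)

    def aperiodic_model(self, freqs: np.ndarray) -> np.ndarray:
        """log10 aperiodic power on the given frequency grid."""
        return self.offset - self.exponent * np.log10(freqs)

    def full_model(self, freqs: np.ndarray) -> np.ndarray:
        model = self.aperiodic_model(freqs)
        for c, h, sd in self.peaks:
            model = model + h * np.exp(-((freqs - c) ** 2) / (2 * sd**2))
        return model


@dataclass(frozen=True)
class SpecparamSettings:
    """Fit settings: peak FWHM limits 0.5–12 Hz, unlimited peaks in
    principle (guarded by an iteration cap), minimum height 0, peak
    threshold 2 SD of the flattened spectrum, fixed aperiodic mode."""

    peak_width_limits: tuple[float, float] = (0.5, 12.0)
    max_peaks: int = 12  # practical cap; unreachable on realistic spectra
    min_peak_height: float = 0.0
    peak_threshold: float = 2.0
    robust_percentile: float = 2.5  # top % of positive residuals discarded


def welch(x: np.ndarray, fs: float, window_s: float = 4.0) -> Spectrum:
    """Welch PSD with 4-s Hanning windows and 50% overlap (0.25 Hz grid)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    nper = int(round(window_s * fs))
    if x.shape[1] < nper:
        raise ValueError(f"need at least {window_s} s of signal")
    freqs, power = sps.welch(
        x, fs=fs, window="hann", nperseg=nper, noverlap=nper // 2, axis=1
    )
    return Spectrum(frequencies=freqs, power=power)


def smooth_spectrum(spectrum: Spectrum, span_hz: float = 2.0) -> Spectrum:
    """Locally weighted moving average over a fixed frequency span.

    Each output point is a tricube-weighted mean of the bins within
    ±span_hz/2, so a flat spectrum passes through unchanged.
    """
    if span_hz < spectrum.df:
        raise ValueError("smoothing span below the frequency grid step")
    half = span_hz / 2.0
    f = spectrum.frequencies
    nbins = int(np.floor(half / spectrum.df))
    offsets = np.arange(-nbins, nbins + 1)
    w = (1 - (np.abs(offsets) * spectrum.df / half) ** 3) ** 3
    w = np.clip(w, 0, None)
    out = np.empty_like(spectrum.power)
    p = spectrum.power
    n = f.size
    # edge windows shrink; weights renormalized per position
    csum = np.zeros(n)
    acc = np.zeros_like(p)
    for off, wt in zip(offsets, w):
        lo = max(0, -off)
        hi = min(n, n - off)
        acc[:, lo:hi] += wt * p[:, lo + off : hi + off]
        csum[lo:hi] += wt
    out = acc / csum
    return Spectrum(frequencies=f, power=out, smoothed=True)


def _gauss_sum(freqs: np.ndarray, *params: float) -> np.ndarray:
    out = np.zeros_like(freqs)
    for i in range(0, len(params), 3):
        c, h, sd = params[i : i + 3]
        out += h * np.exp(-((freqs - c) ** 2) / (2 * sd**2))
    return out


def _robust_line(
    log_f: np.ndarray, log_p: np.ndarray, robust_percentile: float
) -> tuple[float, float]:
    """Line fit that ignores points far above it (oscillation peaks)."""
    slope, intercept = np.polyfit(log_f, log_p, 1)
    resid = log_p - (intercept + slope * log_f)
    pos = resid[resid > 0]
    if pos.size:
        cut = np.percentile(pos, 100 - robust_percentile)
        keep = resid <= cut
        if keep.sum() >= 3:
            slope, intercept = np.polyfit(log_f[keep], log_p[keep], 1)
    return slope, intercept


def _extract_peaks(
    freqs: np.ndarray,
    flat: np.ndarray,
    settings: "SpecparamSettings",
    sd_lim: tuple[float, float],
    df: float,
) -> list[tuple[float, float, float]]:
    """Sequential Gaussian extraction until no candidate exceeds the
    threshold (in SD of the current residual)."""
    peaks: list[tuple[float, float, float]] = []
    work = flat.copy()
    for _ in range(settings.max_peaks):
        i_max = int(np.argmax(work))
        height = work[i_max]
        if height <= max(
            settings.peak_threshold * np.std(work), settings.min_peak_height
        ):
            break
        center = freqs[i_max]
        half = height / 2  # half-height crossings give the width guess
        i_lo = i_max
        while i_lo > 0 and work[i_lo] > half:
            i_lo -= 1
        i_hi = i_max
        while i_hi < work.size - 1 and work[i_hi] > half:
            i_hi += 1
        fwhm = max(freqs[i_hi] - freqs[i_lo], 2 * df)
        sd = float(np.clip(fwhm / _FWHM_TO_SD, *sd_lim))
        work = work - height * np.exp(-((freqs - center) ** 2) / (2 * sd**2))
        peaks.append((float(center), float(height), sd))
    return peaks


def _refine_peaks(
    freqs: np.ndarray,
    flat: np.ndarray,
    peaks: list[tuple[float, float, float]],
    sd_lim: tuple[float, float],
) -> list[tuple[float, float, float]]:
    """Joint least-squares fit of all Gaussians on the flattened spectrum."""
    if not peaks:
        return peaks
    p0 = np.ravel(peaks)
    lb, ub = [], []
    for _ in peaks:
        lb += [freqs[0], 0.0, sd_lim[0]]
        ub += [freqs[-1], np.inf, sd_lim[1]]
    try:
        popt, _ = curve_fit(
            _gauss_sum, freqs, flat, p0=p0, bounds=(lb, ub), maxfev=5000
        )
    except RuntimeError:
        return peaks
    return [
        (float(popt[i]), float(popt[i + 1]), float(popt[i + 2]))
        for i in range(0, popt.size, 3)
    ]


def _joint_polish(
    log_f: np.ndarray,
    log_p: np.ndarray,
    freqs: np.ndarray,
    slope: float,
    intercept: float,
    peaks: list[tuple[float, float, float]],
    sd_lim: tuple[float, float],
):
    def model(x, *params):
        b0, b1 = params[0], params[1]
        return b0 + b1 * np.log10(x) + _gauss_sum(x, *params[2:])

    p0 = [intercept, slope] + list(np.ravel(peaks))
    lb = [-np.inf, -np.inf]
    ub = [np.inf, np.inf]
    for _ in peaks:
        lb += [freqs[0], 0.0, sd_lim[0]]
        ub += [freqs[-1], np.inf, sd_lim[1]]
    try:
        popt, _ = curve_fit(
            model, freqs, log_p, p0=p0, bounds=(lb, ub), maxfev=8000
        )
    except RuntimeError:
        return slope, intercept, peaks
    new_peaks = [
        (float(popt[i]), float(popt[i + 1]), float(popt[i + 2]))
        for i in range(2, popt.size, 3)
    ]
    return float(popt[1]), float(popt[0]), new_peaks


def fit_specparam(
    spectrum: Spectrum,
    fit_range: tuple[float, float] = (2.0, 35.0),
    settings: SpecparamSettings | None = None,
    channel: int = 0,
) -> AperiodicFit:
    """Decompose one channel's spectrum into aperiodic + periodic parts."""
    settings = settings or SpecparamSettings()
    f = spectrum.frequencies
    if f[0] > fit_range[0] + spectrum.df or f[-1] < fit_range[1] - spectrum.df:
        raise ValueError("spectrum does not cover the fit range")
    sel = (f >= fit_range[0]) & (f <= fit_range[1])
    if sel.sum() < 4:
        raise ValueError("spectrum does not cover the fit range")
    freqs = f[sel]
    power = spectrum.power[channel, sel]
    if np.any(power < 0):
        raise ValueError("power must be non-negative")
    power = np.maximum(power, np.finfo(float).tiny)
    log_f = np.log10(freqs)
    log_p = np.log10(power)

    slope, intercept = _robust_line(log_f, log_p, settings.robust_percentile)
    initial_mae = float(np.mean(np.abs(log_p - (intercept + slope * log_f))))

    sd_lim = (
        settings.peak_width_limits[0] / _FWHM_TO_SD,
        settings.peak_width_limits[1] / _FWHM_TO_SD,
    )
    # alternate peak extraction and aperiodic refit: the first line sits
    # above the true aperiodic wherever peaks exist, so peak heights are
    # underestimated until the aperiodic is re-estimated on the
    # peak-subtracted spectrum
    peaks: list[tuple[float, float, float]] = []
    for _ in range(4):
        flat = log_p - (intercept + slope * log_f)
        peaks = _extract_peaks(freqs, flat, settings, sd_lim, spectrum.df)
        peaks = _refine_peaks(freqs, flat, peaks, sd_lim)
        peak_model = _gauss_sum(freqs, *np.ravel(peaks)) if peaks else 0.0
        new_slope, new_intercept = np.polyfit(log_f, log_p - peak_model, 1)
        if abs(new_slope - slope) < 1e-4 and abs(new_intercept - intercept) < 1e-4:
            slope, intercept = new_slope, new_intercept
            break
        slope, intercept = new_slope, new_intercept

    # final polish: refit line and Gaussians simultaneously; the staged
    # estimates are the starting point, so this only tightens the solution.
    # If clear structure remains in the residual (overlapping peaks split
    # badly), seed extra Gaussians from it and re-polish.
    for _ in range(3):
        if not peaks:
            break
        slope, intercept, peaks = _joint_polish(
            log_f, log_p, freqs, slope, intercept, peaks, sd_lim
        )
        resid = (
            log_p
            - (intercept + slope * log_f)
            - _gauss_sum(freqs, *np.ravel(peaks))
        )
        extra = _extract_peaks(freqs, resid, settings, sd_lim, spectrum.df)
        if not extra or len(peaks) + len(extra) > settings.max_peaks:
            break
        peaks = peaks + extra

    peak_model = _gauss_sum(freqs, *np.ravel(peaks)) if peaks else 0.0

    model = intercept + slope * log_f + peak_model
    resid = log_p - model
    mae = float(np.mean(np.abs(resid)))
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((log_p - log_p.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    fit = AperiodicFit(
        offset=float(intercept),
        exponent=float(-slope),
        peaks=peaks,
        mae=mae,
        r_squared=r2,
        fit_range=fit_range,
    )
    # the full model can never fit worse than the initial bare line
    if mae > initial_mae:
        fit.peaks = []
        slope, intercept = np.polyfit(log_f, log_p, 1)
        fit.offset, fit.exponent = float(intercept), float(-slope)
        resid = log_p - (intercept + slope * log_f)
        fit.mae = float(np.mean(np.abs(resid)))
        fit.r_squared = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot else 1.0
    return fit


def band_measures(
    spectrum: Spectrum,
    fit: AperiodicFit,
    band: tuple[float, float] = (4.0, 16.0),
    channel: int = 0,
) -> tuple[float, float]:
    """(power, periodic power): mean log10 power in the band, and the mean
    log10 power above the fitted aperiodic component."""
    lo, hi = band
    if lo < fit.fit_range[0] or hi > fit.fit_range[1]:
        raise ValueError("band outside the aperiodic fit range")
    sel = (spectrum.frequencies >= lo) & (spectrum.frequencies <= hi)
    freqs = spectrum.frequencies[sel]
    log_p = np.log10(np.maximum(spectrum.power[channel, sel], np.finfo(float).tiny))
    power = float(np.mean(log_p))
    periodic = float(np.mean(log_p - fit.aperiodic_model(freqs)))
    return power, periodic


def average_channels(values: np.ndarray, montage: Montage) -> float:
    """Mean over non-edge analysis channels (98 on the full montage)."""
    if not montage.edge:
        raise ValueError("montage does not flag edge channels")
    keep = [
        i
        for i, l in enumerate(montage.labels)
        if l not in montage.edge and l not in montage.excluded
    ]
    values = np.asarray(values, dtype=float)
    if values.shape[0] != montage.n_channels:
        raise ValueError("one value per montage channel required")
    return float(np.mean(values[keep]))
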