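"""Respiratory and cardiac spectral modulation of the flow-rate signal.

This is the analytical core of the package.  A 60 s flow-rate recording shows
two dominant oscillations: a high-frequency (HF) peak at the breathing rate,
around 0.2 Hz, and a very-high-frequency (VHF) peak at the heart rate, around
1.2 Hz (with harmonics above 2 Hz).  The procedure:

1. remove slow drift with a 4th-order polynomial detrend (kills the
   zero-frequency pile-up);
2. estimate the one-sided power spectral density, normalized so that its
   trapezoidal integral over [0, fs/2] equals the variance of the detrended
   signal (Parseval convention — band powers become variance fractions);
3. locate the HF and VHF peaks, optionally guided by the measured breathing
   and heart rates;
4. integrate the respiratory band (default fixed [0.15, 0.35] Hz) and cardiac
   band (0.5 Hz wide, centered at the VHF peak);
5. form the indices: AUC(R), AUC(C), their variance-normalized counterparts
   NAUC(R), NAUC(C) in [0, 1], and the respiratory-to-cardiac power ratio.

A ratio above 1 means breathing modulates the flow more than the heartbeat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import FlowSignal

__all__ = [
    "Spectrum",
    "BandDefinition",
    "SpectralSummary",
    "BandError",
    "bandpass_visual",
    "detrend_poly",
    "compute_psd",
    "find_spectral_peaks",
    "band_limits",
    "band_auc",
    "modulation_indices",
    "spectral_summary",
]

RESP_BAND_FIXED = (0.15, 0.35)  # Hz, matches the band-pass used for display
CARD_BAND_WIDTH = 0.5  # Hz, centered at the VHF peak
RESP_SEARCH_WINDOW = (0.10, 0.50)  # Hz
CARD_SEARCH_WINDOW = (0.60, 3.0)  # Hz
RESP_GUIDE_HALFWIDTH = 0.15  # Hz around the measured breathing rate
CARD_GUIDE_HALFWIDTH = 0.30  # Hz around the measured heart rate


class BandError(ValueError):
    pass


@dataclass
class Spectrum:
    """One-sided PSD with its Parseval normalization anchor.

    freqs : Hz, uniform from 0 to fs/2
    psd : (mL/s)^2 / Hz; trapezoidal integral over [0, fs/2] equals `variance`
    variance : variance of the detrended signal, (mL/s)^2
    """

    freqs: np.ndarray
    psd: np.ndarray
    fs: float
    variance: float

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    @property
    def nyquist(self) -> float:
        return self.fs / 2.0


@dataclass(frozen=True)
class BandDefinition:
    resp_lo: float
    resp_hi: float
    card_lo: float
    card_hi: float
    hf_peak: float
    vhf_peak: float

    def __post_init__(self):
        if not (self.resp_lo < self.resp_hi and self.card_lo < self.card_hi):
            raise BandError("band limits must be increasing")


@dataclass
class SpectralSummary:
    """Scalar indices of one acquisition's flow-rate spectrum."""

    auc_resp: float
    auc_card: float
    nauc_resp: float
    nauc_card: float
    ratio_resp_card: float  # NaN when the cardiac AUC is zero
    hf_peak: float
    vhf_peak: float
    mean_flow: float
    variance: float
    area_mean: float = math.nan


def bandpass_visual(
    flow: FlowSignal, lo: float = RESP_BAND_FIXED[0], hi: float = RESP_BAND_FIXED[1]
) -> np.ndarray:
    """Zero-phase band-pass of the flow signal for overlay display.

    4th-order Butterworth applied forward-backward (zero phase shift); unity
    gain at band centre to within 1%.
    """
    fs = flow.fs
    if not 0 < lo < hi < fs / 2:
        raise BandError(f"band ({lo}, {hi}) outside (0, {fs / 2:g}) Hz")
    n_min = 6 * (1.0 / lo) * fs  # ~six periods of the slow edge
    if flow.values.size < n_min:
        raise ValueError("signal too short for the requested band")
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, flow.values)


def detrend_poly(flow, order: int = 4, times=None):
    """Least-squares polynomial detrend.

    Returns ``(residual, coefficients)`` where the coefficients are in the
    unscaled-domain power basis (constant term first).  The residual is
    orthogonal to all monomials up to ``order``.
    """
    if isinstance(flow, FlowSignal):
        y = flow.values
        t = flow.times if times is None else np.asarray(times, dtype=float)
    else:
        y = np.asarray(flow, dtype=float)
        t = np.arange(y.size, dtype=float) if times is None else np.asarray(times, dtype=float)
    if y.size <= order + 1:
        raise ValueError(f"need more than {order + 1} samples for order {order}")
    poly = np.polynomial.Polynomial.fit(t, y, deg=order)
    trend = poly(t)
    return y - trend, poly.convert().coef


def _resample_uniform(values: np.ndarray, times: np.ndarray, dt: float):
    grid = np.arange(times[0], times[-1] + dt / 2, dt)
    return np.interp(grid, times, values)


def compute_psd(values, fs: float, window: str = "hann", times=None) -> Spectrum:
    """One-sided periodogram, renormalized so band powers are variance shares.

    A single-taper (Hann) periodogram keeps the full 1/duration frequency
    resolution a 60 s record needs to separate the breathing and cardiac
    peaks.  The raw density is rescaled so its trapezoidal integral over
    [0, fs/2] equals the sample variance, absorbing the window's power loss.
    Irregular ``times`` are first linearly resampled to the uniform grid.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 64:
        raise ValueError("need at least 64 samples")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite input")
    if times is not None:
        times = np.asarray(times, dtype=float)
        dt = 1.0 / fs
        if not np.allclose(np.diff(times), dt, rtol=1e-6, atol=dt * 1e-6):
            values = _resample_uniform(values, times, dt)
    variance = float(np.var(values))
    freqs, psd = sps.periodogram(values, fs=fs, window=window, detrend=False)
    total = float(np.trapezoid(psd, freqs))
    if total > 0 and variance > 0:
        psd = psd * (variance / total)
    return Spectrum(freqs=freqs, psd=psd, fs=fs, variance=variance)


def _window_argmax(spec: Spectrum, lo: float, hi: float) -> float:
    sel = (spec.freqs >= lo) & (spec.freqs <= hi)
    if not sel.any():
        raise BandError(f"empty search window [{lo:g}, {hi:g}] Hz")
    idx = np.nonzero(sel)[0]
    # np.argmax keeps the first (lowest-frequency) maximum on ties
    return float(spec.freqs[idx[np.argmax(spec.psd[idx])]])


def find_spectral_peaks(
    spec: Spectrum,
    resp_window=RESP_SEARCH_WINDOW,
    card_window=CARD_SEARCH_WINDOW,
    resp_rate: float | None = None,
    card_rate: float | None = None,
) -> tuple[float, float]:
    """Locate the HF (breathing) and VHF (cardiac) spectral peaks.

    Each peak is the frequency of maximum PSD within its search window.  When
    measured physiological rates are supplied, the windows shrink to
    rate +- 0.15 Hz (breathing) and rate +- 0.3 Hz (cardiac), which keeps a
    taller cardiac harmonic from stealing the VHF peak.
    """
    eps = spec.df / 2
    if resp_rate is not None:
        resp_window = (resp_rate - RESP_GUIDE_HALFWIDTH, resp_rate + RESP_GUIDE_HALFWIDTH)
    if card_rate is not None:
        card_window = (card_rate - CARD_GUIDE_HALFWIDTH, card_rate + CARD_GUIDE_HALFWIDTH)
    windows = []
    for lo, hi in (resp_window, card_window):
        lo, hi = max(lo, eps), min(hi, spec.nyquist)
        if lo >= hi:
            raise BandError("search window empty after clipping to (0, fs/2)")
        windows.append((lo, hi))
    hf = _window_argmax(spec, *windows[0])
    vhf = _window_argmax(spec, *windows[1])
    return hf, vhf


def band_limits(
    hf_peak: float,
    vhf_peak: float,
    mode: str = "fixed",
    nyquist: float | None = None,
) -> BandDefinition:
    """Derive the respiratory and cardiac integration bands from the peaks.

    mode "fixed": respiratory band [0.15, 0.35] Hz, consistent with the
    display band-pass; mode "peak-relative": [hf - 0.15, hf + 0.35] Hz.  The
    cardiac band is 0.5 Hz wide, centered at the VHF peak.  Bands are clipped
    to (0, nyquist); an overlap after clipping flags implausible peaks and
    raises ``BandError``.
    """
    if not (hf_peak > 0 and vhf_peak > 0):
        raise BandError("peaks must be positive frequencies")
    if mode == "fixed":
        resp_lo, resp_hi = RESP_BAND_FIXED
    elif mode == "peak-relative":
        resp_lo, resp_hi = hf_peak - 0.15, hf_peak + 0.35
    else:
        raise BandError(f"unknown band mode {mode!r}")
    half = CARD_BAND_WIDTH / 2.0
    card_lo, card_hi = vhf_peak - half, vhf_peak + half
    resp_lo = max(resp_lo, 1e-9)
    if nyquist is not None:
        card_hi = min(card_hi, nyquist)
        resp_hi = min(resp_hi, nyquist)
    if card_lo < resp_hi:
        raise BandError(
            f"cardiac band [{card_lo:g}, {card_hi:g}] overlaps respiratory band "
            f"[{resp_lo:g}, {resp_hi:g}]: implausible peak locations"
        )
    return BandDefinition(
        resp_lo=resp_lo,
        resp_hi=resp_hi,
        card_lo=card_lo,
        card_hi=card_hi,
        hf_peak=hf_peak,
        vhf_peak=vhf_peak,
    )


def band_auc(spec: Spectrum, lo: float, hi: float) -> float:
    """Trapezoidal area under the PSD between ``lo`` and ``hi`` Hz.

    Band edges falling between grid points contribute via linear
    interpolation, so adjacent bands tile the support exactly.
    """
    if not lo < hi:
        raise BandError("inverted band limits")
    if lo < spec.freqs[0] - 1e-12 or hi > spec.freqs[-1] + 1e-12:
        raise BandError("band outside spectrum support")
    inside = (spec.freqs > lo) & (spec.freqs < hi)
    f = np.concatenate(([lo], spec.freqs[inside], [hi]))
    p = np.concatenate(
        ([np.interp(lo, spec.freqs, spec.psd)], spec.psd[inside], [np.interp(hi, spec.freqs, spec.psd)])
    )
    return float(np.trapezoid(p, f))


def modulation_indices(
    spec: Spectrum,
    bands: BandDefinition,
    mean_flow: float = math.nan,
    area_mean: float = math.nan,
) -> SpectralSummary:
    """Band powers, variance-normalized powers and the respiratory/cardiac ratio.

    nauc_* = band AUC / variance of the detrended signal (dimensionless,
    in [0, 1] up to spectral leakage); ratio = AUC(R) / AUC(C), reported as
    NaN when the cardiac band power is zero.
    """
    if not spec.variance > 0:
        raise ValueError("zero-variance spectrum has no modulation indices")
    auc_r = band_auc(spec, bands.resp_lo, bands.resp_hi)
    auc_c = band_auc(spec, bands.card_lo, bands.card_hi)
    ratio = auc_r / auc_c if auc_c > 0 else math.nan
    return SpectralSummary(
        auc_resp=auc_r,
        auc_card=auc_c,
        nauc_resp=auc_r / spec.variance,
        nauc_card=auc_c / spec.variance,
        ratio_resp_card=ratio,
        hf_peak=bands.hf_peak,
        vhf_peak=bands.vhf_peak,
        mean_flow=mean_flow,
        variance=spec.variance,
        area_mean=area_mean,
    )


def spectral_summary(
    flow: FlowSignal,
    resp_rate: float | None = None,
    card_rate: float | None = None,
    detrend_order: int = 4,
    band_mode: str = "fixed",
    area_mean: float = math.nan,
) -> SpectralSummary:
    """Full spectral chain: detrend -> PSD -> peaks -> bands -> indices."""
    detrended, _ = detrend_poly(flow, order=detrend_order)
    spec = compute_psd(detrended, fs=flow.fs)
    hf, vhf = find_spectral_peaks(spec, resp_rate=resp_rate, card_rate=card_rate)
    bands = band_limits(hf, vhf, mode=band_mode, nyquist=spec.nyquist)
    return modulation_indices(
        spec, bands, mean_flow=float(np.mean(flow.values)), area_mean=area_mean
    )
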