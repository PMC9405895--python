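"""Physiological-signal alignment and average breathing / heart rates.

The belt and oximeter traces carry their own start time; they are trimmed to
the image acquisition window and the average rates come from peak counting
with physiologically bounded minimum peak separations (breathing <= 40/min,
heart <= 180/min).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .io import PCSeries, PhysioRecord

__all__ = ["RateEstimate", "AlignmentError", "align_physio", "mean_rate"]

#: minimum peak-to-peak separation in seconds per signal kind
MIN_SEPARATION = {"resp": 1.5, "pulse": 0.33}


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class RateEstimate:
    rate: float  # Hz
    n_events: int
    method: str = "peak-interval"

    def __post_init__(self):
        if not self.rate > 0:
            raise ValueError("rate must be > 0")
        if self.n_events < 2:
            raise ValueError("need at least 2 events")

    @property
    def per_minute(self) -> float:
        return self.rate * 60.0


def align_physio(physio: PhysioRecord, series: PCSeries) -> PhysioRecord:
    """Trim the physio record to the image acquisition window.

    Keeps samples with timestamps within [first frame time, last frame time].
    Raises ``AlignmentError`` when the windows do not overlap.
    """
    t = physio.times
    t0, t1 = series.frame_times[0], series.frame_times[-1]
    keep = (t >= t0) & (t <= t1)
    if not keep.any():
        raise AlignmentError(
            f"no overlap: physio [{t[0]:.3f}, {t[-1]:.3f}] s vs "
            f"acquisition [{t0:.3f}, {t1:.3f}] s"
        )
    first = int(np.argmax(keep))
    return PhysioRecord(
        resp=physio.resp[keep],
        pulse=physio.pulse[keep],
        fs=physio.fs,
        start_time=float(t[first]),
    )


def mean_rate(
    signal: np.ndarray,
    fs: float,
    kind: str,
    prominence_frac: float = 0.5,
    smooth_s: float = 0.05,
) -> RateEstimate:
    """Average event rate from peak intervals.

    The signal is first smoothed with a short moving average (``smooth_s``
    seconds, suppressing sample-level noise without moving breath- or
    beat-scale peaks), then peaks are detected with a kind-specific minimum
    separation (resp: 1.5 s, pulse: 0.33 s) and a prominence of
    ``prominence_frac`` times the smoothed signal's interquartile range —
    making the estimate invariant to amplitude scaling and DC offset.
    rate = (n_peaks - 1) / elapsed time between the first and last peak.
    """
    if kind not in MIN_SEPARATION:
        raise ValueError(f"kind must be one of {sorted(MIN_SEPARATION)}")
    signal = np.asarray(signal, dtype=float)
    if signal.size < 10 * fs:
        raise ValueError("need at least 10 s of signal")
    signal = signal - np.median(signal)  # DC removal keeps edge padding neutral
    w = max(1, int(round(smooth_s * fs)))
    if w > 1:
        signal = np.convolve(signal, np.ones(w) / w, mode="same")
    iqr = float(np.subtract(*np.percentile(signal, [75, 25])))
    distance = max(1, int(round(MIN_SEPARATION[kind] * fs)))
    peaks, _ = find_peaks(signal, distance=distance, prominence=prominence_frac * iqr)
    if len(peaks) < 2:
        raise ValueError(f"found {len(peaks)} peaks; need at least 2")
    elapsed = (peaks[-1] - peaks[0]) / fs
    return RateEstimate(rate=(len(peaks) - 1) / elapsed, n_events=len(peaks))
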