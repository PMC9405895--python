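"""Phase to velocity to flow rate.

Background phase is estimated per frame as the mean phase over the no-flow
area and subtracted inside the vessel ROI; phase maps linearly to velocity
(v = VENC * phi / pi); aliased pixels are unwrapped by one +-2*VENC step
toward the ROI median; flow rate is mean ROI velocity times cross-sectional
area, with the venous sign convention (upward-positive velocities multiplied
by -1 so venous flow reads positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import FlowSignal, PCSeries
from .segmentation import VesselROI, mask_area

__all__ = [
    "VelocityField",
    "background_offset",
    "correct_background",
    "phase_to_velocity",
    "correct_aliasing",
    "flow_rate_series",
]


@dataclass
class VelocityField:
    """Velocity maps in cm/s, positive = upward (head-ward)."""

    values: np.ndarray  # (frames, rows, cols)
    venc: float


def background_offset(phase_series: np.ndarray, nfa_mask: np.ndarray) -> np.ndarray:
    """Per-frame background phase offset: spatial mean over the NFA, radians."""
    nfa_mask = np.asarray(nfa_mask, dtype=bool)
    if not nfa_mask.any():
        raise ValueError("NFA mask is empty")
    phase_series = np.asarray(phase_series, dtype=float)
    return phase_series[:, nfa_mask].mean(axis=1)


def correct_background(
    phase_series: np.ndarray, roi: VesselROI, time_average: bool = False
) -> np.ndarray:
    """Subtract the NFA phase offset inside each frame's vessel mask.

    Pixels outside the ROI are untouched.  ``time_average`` replaces the
    per-frame offsets by their temporal mean (cancels less drift but matches a
    single static offset model).
    """
    offsets = background_offset(phase_series, roi.nfa)
    if time_average:
        offsets = np.full_like(offsets, offsets.mean())
    corrected = np.array(phase_series, dtype=float, copy=True)
    for t in range(corrected.shape[0]):
        m = roi.masks[t]
        corrected[t][m] = corrected[t][m] - offsets[t]
    return corrected


def phase_to_velocity(phase, venc: float):
    """Linear phase-to-velocity map: v [cm/s] = venc * phase / pi."""
    if not venc > 0:
        raise ValueError("venc must be > 0")
    return venc * np.asarray(phase, dtype=float) / np.pi


def correct_aliasing(
    velocity_frame: np.ndarray, vessel_mask: np.ndarray, venc: float
) -> tuple[np.ndarray, int]:
    """Unwrap velocity-aliased pixels within the vessel mask.

    A pixel deviating from the in-mask median by more than VENC receives a
    single +-2*VENC correction, with the sign that brings it closest to the
    median.  The pass is repeated with a freshly computed median until no
    further pixel qualifies (each pixel is corrected at most once): as the
    worst-wrapped pixels — which alias back closest to zero — are restored,
    the median moves toward the true bulk velocity and exposes the rest.
    Returns the corrected frame and the number of corrected pixels.
    """
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if not vessel_mask.any():
        raise ValueError("vessel mask is empty")
    v = np.array(velocity_frame, dtype=float, copy=True)
    corrected = np.zeros_like(vessel_mask)
    while True:
        med = float(np.median(v[vessel_mask]))
        wrapped = (np.abs(v - med) > venc) & vessel_mask & ~corrected
        if not wrapped.any():
            break
        sign = np.where(v[wrapped] < med, 1.0, -1.0)
        v[wrapped] = v[wrapped] + sign * 2.0 * venc
        corrected |= wrapped
    return v, int(corrected.sum())


def flow_rate_series(
    series: PCSeries,
    roi: VesselROI,
    venous_sign: bool = True,
    unwrap: bool = True,
    time_average_offset: bool = False,
) -> FlowSignal:
    """Flow rate in mL/s per frame from a phase series and its ROI.

    Runs background correction, phase-to-velocity conversion and (optionally)
    aliasing unwrap, then Q_t = s * mean(v over mask_t) [cm/s] * area_t [mm^2]
    / 100, with s = -1 under the venous sign convention.
    """
    meta = series.meta
    phase = correct_background(series.phase, roi, time_average=time_average_offset)
    velocity = phase_to_velocity(phase, meta.venc)
    q = np.empty(series.n_frames, dtype=float)
    for t in range(series.n_frames):
        mask = roi.masks[t]
        if not mask.any():
            raise ValueError(f"empty vessel mask at frame {t}")
        vt = velocity[t]
        if unwrap:
            vt, _ = correct_aliasing(vt, mask, meta.venc)
        area = mask_area(mask, meta.pixel_spacing)
        q[t] = vt[mask].mean() * area / 100.0
    if venous_sign:
        q = -q
    return FlowSignal(
        values=q,
        frame_interval=meta.frame_interval,
        vessel_label=meta.vessel_label,
        breathing_mode=meta.breathing_mode,
    )
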