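"""Semi-automated vessel ROI and no-flow-area definition.

The vessel is segmented on a magnitude frame by seeded region growing: the
threshold is half the mean of the 25 brightest pixels inside a user box
(a full-width-half-maximum style criterion), and the mask is the 4-connected
component of supra-threshold pixels containing the seed, confined to the box.
Static-tissue no-flow areas (NFA), used for background phase correction, are
automated as a dilation ring around the vessel that excludes supra-threshold
pixels.

Coordinates are 0-based, row-major; boxes are half-open (row0, col0, row1, col1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import PCSeries

__all__ = [
    "SeedBox",
    "VesselROI",
    "SegmentationError",
    "select_reference_frame",
    "box_threshold",
    "segment_vessel",
    "segment_nfa",
    "propagate_masks",
    "mask_area",
]

log = logging.getLogger(__name__)

# 4-connectivity: conservative against diagonal leakage between vessels
_STRUCT4 = ndimage.generate_binary_structure(2, 1)


class SegmentationError(ValueError):
    pass


@dataclass(frozen=True)
class SeedBox:
    """A rectangular search box with a seed pixel near the vessel centre."""

    box: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    seed: tuple[int, int]

    def __post_init__(self):
        r0, c0, r1, c1 = self.box
        if (r1 - r0) * (c1 - c0) < 25:
            raise SegmentationError("box must contain at least 25 pixels")
        sr, sc = self.seed
        if not (r0 <= sr < r1 and c0 <= sc < c1):
            raise SegmentationError("seed must lie inside the box")

    @property
    def slices(self) -> tuple[slice, slice]:
        r0, c0, r1, c1 = self.box
        return slice(r0, r1), slice(c0, c1)


@dataclass
class VesselROI:
    """Per-frame vessel masks plus one static no-flow-area mask.

    masks : (frames, rows, cols) boolean
    nfa : (rows, cols) boolean, disjoint from every vessel mask
    """

    masks: np.ndarray
    nfa: np.ndarray
    reference_frame: int = 0

    def __post_init__(self):
        self.masks = np.asarray(self.masks, dtype=bool)
        self.nfa = np.asarray(self.nfa, dtype=bool)
        if self.masks.ndim != 3:
            raise SegmentationError("masks must be (frames, rows, cols)")
        if not self.masks.any(axis=(1, 2)).all():
            raise SegmentationError("every frame needs a non-empty vessel mask")
        if (self.nfa & self.masks.any(axis=0)).any():
            raise SegmentationError("NFA must be disjoint from all vessel masks")


def select_reference_frame(series: PCSeries, box: SeedBox) -> int:
    """Index of the frame with the highest flow, proxied by mean |phase| in the box.

    Ties resolve to the first (lowest-index) maximum.
    """
    if series.n_frames < 1:
        raise SegmentationError("empty series")
    rs, cs = box.slices
    score = np.abs(series.phase[:, rs, cs]).mean(axis=(1, 2))
    return int(np.argmax(score))


def box_threshold(magnitude_frame: np.ndarray, box: SeedBox) -> float:
    """Half the mean of the 25 brightest pixels inside the box."""
    rs, cs = box.slices
    vals = np.sort(np.asarray(magnitude_frame, dtype=float)[rs, cs], axis=None)
    return 0.5 * float(np.mean(vals[-25:]))


def segment_vessel(magnitude_frame: np.ndarray, box_seed: SeedBox) -> np.ndarray:
    """Region-grow the vessel from the seed inside the box.

    Returns a full-frame boolean mask: the 4-connected component, within the
    box, of pixels whose intensity is strictly above the threshold, containing
    the seed.  Raises ``SegmentationError`` if the seed pixel itself does not
    pass the threshold.
    """
    magnitude_frame = np.asarray(magnitude_frame, dtype=float)
    tau = box_threshold(magnitude_frame, box_seed)
    rs, cs = box_seed.slices
    above = np.zeros(magnitude_frame.shape, dtype=bool)
    above[rs, cs] = magnitude_frame[rs, cs] > tau
    sr, sc = box_seed.seed
    if not above[sr, sc]:
        raise SegmentationError(
            f"seed outside vessel: intensity {magnitude_frame[sr, sc]:g} <= threshold {tau:g}"
        )
    labels, _ = ndimage.label(above, structure=_STRUCT4)
    return labels == labels[sr, sc]


def segment_nfa(
    magnitude_frame: np.ndarray,
    vessel_mask: np.ndarray,
    box: SeedBox,
    inner: int = 2,
    outer: int = 5,
) -> np.ndarray:
    """Static-tissue ring close to the vessel.

    The ring is the band between ``inner`` and ``outer`` 4-connected dilations
    of the vessel mask, minus any pixel brighter than the vessel threshold
    (which would belong to this or another vessel).
    """
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if not vessel_mask.any():
        raise SegmentationError("vessel mask is empty")
    if not 0 <= inner < outer:
        raise SegmentationError("need 0 <= inner < outer ring distances")
    tau = box_threshold(magnitude_frame, box)
    grow_out = ndimage.binary_dilation(vessel_mask, _STRUCT4, iterations=outer)
    grow_in = ndimage.binary_dilation(vessel_mask, _STRUCT4, iterations=inner)
    ring = grow_out & ~grow_in & (np.asarray(magnitude_frame, dtype=float) <= tau)
    if not ring.any():
        raise SegmentationError("empty NFA ring: vessel fills the neighbourhood")
    return ring


def _centroid(mask: np.ndarray) -> tuple[int, int]:
    r, c = np.nonzero(mask)
    return int(round(r.mean())), int(round(c.mean()))


def propagate_masks(
    series: PCSeries,
    ref_mask: np.ndarray,
    ref_frame: int,
    mode: str = "copy",
    box: SeedBox | None = None,
    nfa: np.ndarray | None = None,
) -> VesselROI:
    """Carry the reference-frame vessel mask over all time frames.

    mode "copy": the reference mask is used verbatim on every frame.
    mode "reseed": ``segment_vessel`` is re-run on each frame, seeded at the
    previous processed frame's mask centroid (walking outward from the
    reference frame); a frame where re-segmentation fails falls back to the
    previous mask, with a log record.

    ``nfa`` (if given) is stored after removing any overlap with the
    propagated vessel masks.
    """
    ref_mask = np.asarray(ref_mask, dtype=bool)
    n = series.n_frames
    masks = np.repeat(ref_mask[None], n, axis=0)
    if mode == "reseed":
        if box is None:
            raise SegmentationError("reseed mode needs the seed box")
        r0, c0, r1, c1 = box.box
        order = list(range(ref_frame + 1, n)) + list(range(ref_frame - 1, -1, -1))
        for t in order:
            prev = masks[t + 1] if t < ref_frame else masks[t - 1]
            seed = _centroid(prev)
            try:
                sb = SeedBox(box=box.box, seed=seed)
                masks[t] = segment_vessel(series.magnitude[t], sb)
            except SegmentationError as exc:
                log.info("frame %d: reseed failed (%s); copying previous mask", t, exc)
                masks[t] = prev
    elif mode != "copy":
        raise SegmentationError(f"unknown propagation mode {mode!r}")
    if nfa is None:
        nfa = np.zeros(ref_mask.shape, dtype=bool)
    else:
        nfa = np.asarray(nfa, dtype=bool) & ~masks.any(axis=0)
    return VesselROI(masks=masks, nfa=nfa, reference_frame=ref_frame)


def mask_area(mask: np.ndarray, pixel_spacing) -> float:
    """Cross-sectional area in mm^2: pixel count times pixel area."""
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise SegmentationError("empty mask has no area")
    dr, dc = pixel_spacing
    return n * float(dr) * float(dc)
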