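"""Region-growing segmentation against hand calculations and a brute-force oracle."""

from collections import deque

import numpy as np
import pytest

from rtpcflow.io import PCSeries
from rtpcflow.segmentation import (
    SeedBox,
    SegmentationError,
    box_threshold,
    mask_area,
    propagate_masks,
    segment_nfa,
    segment_vessel,
    select_reference_frame,
)
from rtpcflow.simulate import FlowSimParams, PhantomParams, gen_pc_phantom, rasterize_disk


def brute_force_segment(frame, box, seed):
    """Independent reference: explicit sort for the threshold + BFS flood fill."""
    r0, c0, r1, c1 = box
    vals = sorted(frame[r0:r1, c0:c1].ravel(), reverse=True)
    tau = 0.5 * (sum(vals[:25]) / 25.0)
    mask = np.zeros(frame.shape, dtype=bool)
    if not frame[seed] > tau:
        return None
    queue = deque([seed])
    mask[seed] = True
    while queue:
        r, c = queue.popleft()
        for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if r0 <= nr < r1 and c0 <= nc < c1 and not mask[nr, nc] and frame[nr, nc] > tau:
                mask[nr, nc] = True
                queue.append((nr, nc))
    return mask


class TestSegmentVessel:
    def test_hand_worked_threshold_and_mask(self):
        # 6x6 box: nine 100s + sixteen 10s among the 25 brightest
        # -> mean 42.4, threshold 21.2, mask = the 3x3 block
        frame = np.full((10, 10), 10.0)
        frame[3:6, 3:6] = 100.0
        sb = SeedBox(box=(2, 2, 8, 8), seed=(4, 4))
        assert box_threshold(frame, sb) == pytest.approx(21.2)
        mask = segment_vessel(frame, sb)
        expected = np.zeros_like(frame, dtype=bool)
        expected[3:6, 3:6] = True
        assert np.array_equal(mask, expected)

    def test_uniform_box_fills_entirely(self):
        frame = np.full((8, 8), 50.0)
        sb = SeedBox(box=(1, 1, 7, 7), seed=(4, 4))
        mask = segment_vessel(frame, sb)
        assert mask[1:7, 1:7].all() and mask.sum() == 36

    def test_seed_on_background_rejected(self):
        frame = np.full((10, 10), 10.0)
        frame[3:6, 3:6] = 100.0
        sb = SeedBox(box=(2, 2, 8, 8), seed=(7, 7))
        with pytest.raises(SegmentationError, match="seed outside vessel"):
            segment_vessel(frame, sb)

    def test_box_smaller_than_25_rejected(self):
        with pytest.raises(SegmentationError, match="25"):
            SeedBox(box=(0, 0, 4, 4), seed=(1, 1))

    def test_oracle_equivalence_on_random_phantoms(self):
        """Exact match with the sort+flood-fill reference on random cases."""
        rng = np.random.default_rng(42)
        n_checked = 0
        while n_checked < 50:
            frame = rng.uniform(0, 30, (24, 24))
            r, c = rng.integers(8, 16, 2)
            rad = rng.uniform(2.0, 5.0)
            disk = rasterize_disk((24, 24), (r, c), rad, (1.0, 1.0))
            frame[disk] += rng.uniform(40, 120)
            sb = SeedBox(box=(2, 2, 22, 22), seed=(int(r), int(c)))
            ref = brute_force_segment(frame, sb.box, sb.seed)
            if ref is None:
                continue
            assert np.array_equal(segment_vessel(frame, sb), ref)
            n_checked += 1

    def test_mask_invariant_to_intensity_scaling(self):
        rng = np.random.default_rng(3)
        frame = rng.uniform(5, 10, (20, 20))
        frame[8:13, 8:13] = rng.uniform(60, 80, (5, 5))
        sb = SeedBox(box=(4, 4, 17, 17), seed=(10, 10))
        base = segment_vessel(frame, sb)
        for factor in (0.5, 3.0, 17.0):
            assert np.array_equal(segment_vessel(frame * factor, sb), base)

    def test_recovers_rasterized_disk_within_boundary_band(self, quiet_phantom, center_box):
        _, series, truth = quiet_phantom
        mask = segment_vessel(series.magnitude[0], center_box)
        true_mask = truth.vessel_masks[0]
        # no disagreement beyond a 1-pixel boundary band
        from scipy import ndimage

        grown = ndimage.binary_dilation(true_mask, iterations=1)
        shrunk = ndimage.binary_erosion(true_mask, iterations=1)
        assert not (mask & ~grown).any()
        assert not (~mask & shrunk).any()


class TestReferenceFrame:
    def test_finds_systolic_peak_frame(self, small_series, default_meta):
        sb = SeedBox(box=(2, 2, 10, 10), seed=(5, 5))
        assert select_reference_frame(small_series, sb) == 1

    def test_constant_flow_returns_first_frame(self, default_meta):
        mag = np.full((4, 8, 8), 50.0)
        phase = np.full((4, 8, 8), -0.4)
        series = PCSeries(mag, phase, default_meta)
        sb = SeedBox(box=(1, 1, 7, 7), seed=(4, 4))
        assert select_reference_frame(series, sb) == 0

    def test_single_frame(self, default_meta):
        series = PCSeries(np.ones((1, 8, 8)), np.zeros((1, 8, 8)), default_meta)
        sb = SeedBox(box=(1, 1, 7, 7), seed=(4, 4))
        assert select_reference_frame(series, sb) == 0


class TestNFA:
    def test_ring_disjoint_and_nonempty(self, quiet_phantom, center_box):
        _, series, _ = quiet_phantom
        vessel = segment_vessel(series.magnitude[0], center_box)
        nfa = segment_nfa(series.magnitude[0], vessel, center_box)
        assert nfa.sum() > 0
        assert not (nfa & vessel).any()

    def test_vessel_filling_frame_rejected(self):
        frame = np.full((10, 10), 90.0)
        vessel = np.ones((10, 10), dtype=bool)
        sb = SeedBox(box=(0, 0, 10, 10), seed=(5, 5))
        with pytest.raises(SegmentationError, match="empty NFA"):
            segment_nfa(frame, vessel, sb)

    def test_second_bright_vessel_excluded_from_ring(self):
        frame = np.full((30, 30), 10.0)
        disk1 = rasterize_disk((30, 30), (15, 10), 4.0, (1.0, 1.0))
        disk2 = rasterize_disk((30, 30), (15, 18), 3.0, (1.0, 1.0))
        frame[disk1] = 100.0
        frame[disk2] = 95.0
        sb = SeedBox(box=(8, 3, 23, 18), seed=(15, 10))
        vessel = segment_vessel(frame, sb)
        nfa = segment_nfa(frame, vessel, sb)
        assert not (nfa & disk2).any()
        assert not (nfa & disk1).any()
        assert nfa.sum() > 0


class TestPropagation:
    def test_static_phantom_copy_equals_reseed(self, quiet_phantom, center_box):
        _, series, _ = quiet_phantom
        short = PCSeries(
            series.magnitude[:20], series.phase[:20], series.meta
        )
        ref = select_reference_frame(short, center_box)
        mask = segment_vessel(short.magnitude[ref], center_box)
        roi_copy = propagate_masks(short, mask, ref, mode="copy")
        roi_reseed = propagate_masks(short, mask, ref, mode="reseed", box=center_box)
        assert np.array_equal(roi_copy.masks, roi_reseed.masks)

    def test_reseed_tracks_drifting_vessel(self):
        p = PhantomParams(
            drift_px_per_min=1.0,
            flow=FlowSimParams(noise_sd=0.0, seed=5, duration=30.0),
        )
        series, truth = gen_pc_phantom(p)
        sb = SeedBox(box=(38, 54, 58, 74), seed=(48, 64))
        ref = 0
        mask0 = segment_vessel(series.magnitude[0], sb)
        roi = propagate_masks(series, mask0, ref, mode="reseed", box=sb)
        for t in (len(series.frame_times) - 1, len(series.frame_times) // 2):
            got_r, got_c = np.argwhere(roi.masks[t]).mean(axis=0)
            true_r, true_c = np.argwhere(truth.vessel_masks[t]).mean(axis=0)
            assert abs(got_r - true_r) <= 1.0 and abs(got_c - true_c) <= 1.0

    def test_reseed_falls_back_to_copy_on_corrupt_frame(self, default_meta):
        mag = np.full((3, 16, 16), 10.0)
        mag[:, 6:10, 6:10] = 100.0
        # frame 1: signal jumps away so the carried-over seed lands on
        # background (below threshold) and re-segmentation errors out
        mag[1] = 10.0
        mag[1, 3:5, 3:8] = 100.0
        phase = np.zeros_like(mag)
        series = PCSeries(mag, phase, default_meta)
        sb = SeedBox(box=(3, 3, 13, 13), seed=(8, 8))
        mask0 = segment_vessel(series.magnitude[0], sb)
        roi = propagate_masks(series, mask0, 0, mode="reseed", box=sb)
        assert np.array_equal(roi.masks[1], roi.masks[0])


class TestMaskArea:
    @pytest.mark.parametrize("n_pixels, expected", [(100, 49.0), (1, 0.49)])
    def test_pixel_count_times_pixel_area(self, n_pixels, expected):
        mask = np.zeros(400, dtype=bool)
        mask[:n_pixels] = True
        assert mask_area(mask.reshape(20, 20), (0.7, 0.7)) == pytest.approx(expected)

    def test_digitized_disk_close_to_analytic(self):
        disk = rasterize_disk((40, 40), (20, 20), 3.5, (0.7, 0.7))
        area = mask_area(disk, (0.7, 0.7))
        assert area == pytest.approx(np.pi * 3.5**2, rel=0.10)

    def test_empty_mask_rejected(self):
        with pytest.raises(SegmentationError):
            mask_area(np.zeros((5, 5), dtype=bool), (0.7, 0.7))
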