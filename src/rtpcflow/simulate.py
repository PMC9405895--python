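"""Synthetic venous-flow waveforms, physiological traces and image phantoms.

Every pipeline stage is exercised against generated data with analytically
known structure.  The flow waveform combines a mean level, slow polynomial
drift, a cardiac oscillation (fundamental around 1.2 Hz plus two harmonics,
optionally amplitude-modulated at the breathing rate), an additive
respiratory oscillation around 0.2-0.25 Hz, and white noise:

    Q(t) = q0 + drift(t)
         + (1 + m sin(2 pi f_r t)) * sum_h a_h cos(2 pi h f_c t + phi_h)
         + b sin(2 pi f_r t + psi) + eps_t

The image phantom paints a circular vessel with a pulsatile parabolic
velocity profile into a phase/magnitude frame stack at the real-time
acquisition geometry (96 x 128 matrix, 0.7 x 0.7 mm pixels, 58.5 ms frames,
60 s), with background phase offset, optional aliasing and slow in-plane
drift.  All generators are bit-reproducible given (params, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io import AcquisitionMeta, FlowSignal, PCSeries, PhysioRecord, wrap_phase
from .spectral import CARD_BAND_WIDTH, RESP_BAND_FIXED

__all__ = [
    "FlowSimParams",
    "PhantomParams",
    "GroundTruth",
    "GroupBundle",
    "gen_flow_waveform",
    "theoretical_indices",
    "gen_physio",
    "gen_pc_phantom",
    "gen_group_dataset",
    "DEFAULT_MODE_EFFECTS",
]

FRAME_INTERVAL_S = 0.0585  # real-time frame time
DURATION_S = 60.0
PHYSIO_FS = 400.0


@dataclass(frozen=True)
class FlowSimParams:
    """Parameters of the synthetic flow-rate waveform.

    q0 : mean flow, mL/s
    f_c, a : cardiac fundamental (Hz) and harmonic amplitudes (mL/s)
    f_r, b : respiratory frequency (Hz) and additive amplitude (mL/s)
    m : cardiac amplitude-modulation depth in [0, 1)
    drift : polynomial coefficients (constant first, up to order 4), mL/s
            over normalized time t/duration
    noise_sd : white-noise SD, mL/s
    """

    q0: float = 5.0
    f_c: float = 1.2
    a: tuple[float, float, float] = (1.0, 0.3, 0.1)
    f_r: float = 0.25
    b: float = 0.6
    m: float = 0.0
    drift: tuple[float, ...] = (0.0,)
    noise_sd: float = 0.3
    fs: float = 1.0 / FRAME_INTERVAL_S
    duration: float = DURATION_S
    seed: int = 0

    def __post_init__(self):
        if not 0.1 < self.f_r < 0.4:
            raise ValueError("f_r must lie in (0.1, 0.4) Hz")
        if not 0.7 < self.f_c < 2.0:
            raise ValueError("f_c must lie in (0.7, 2.0) Hz")
        if not self.f_c - CARD_BAND_WIDTH / 2 > RESP_BAND_FIXED[1]:
            raise ValueError("cardiac band would touch the respiratory band")
        if any(x < 0 for x in self.a) or self.b < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes must be non-negative")
        if not 0 <= self.m < 1:
            raise ValueError("m must lie in [0, 1)")


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and contrast of the circular-vessel image phantom."""

    grid: tuple[int, int] = (96, 128)
    pixel_spacing: tuple[float, float] = (0.7, 0.7)  # mm
    vessel_center: tuple[float, float] = (48.0, 64.0)  # pixels (row, col)
    vessel_radius: float = 3.5  # mm
    venc: float = 70.0  # cm/s
    background_phase_offset: float = 0.0  # radians
    magnitude_contrast: tuple[float, float] = (100.0, 20.0)  # vessel, background
    noise_sd_phase: float = 0.0  # radians
    noise_sd_magnitude: float = 0.0
    drift_px_per_min: float = 0.0  # slow in-plane drift along columns
    slice_thickness: float = 8.6  # mm
    vessel_label: str = "IJV"
    breathing_mode: str = "F"
    flow: FlowSimParams = field(default_factory=FlowSimParams)

    def __post_init__(self):
        if self.vessel_radius / max(self.pixel_spacing) < 2:
            raise ValueError("vessel radius must cover at least 2 pixels")
        r, c = self.vessel_center
        rad_px = self.vessel_radius / min(self.pixel_spacing)
        if not (rad_px <= r <= self.grid[0] - rad_px and rad_px <= c <= self.grid[1] - rad_px):
            raise ValueError("vessel must lie inside the grid")


@dataclass
class GroundTruth:
    """What the generator knows: per-frame truth for pipeline validation."""

    flow_series: np.ndarray  # mL/s per frame, noiseless convention noted by caller
    vessel_masks: np.ndarray | None = None  # (frames, rows, cols) bool
    area: float = math.nan  # rasterized cross-section, mm^2
    nauc_resp: float = math.nan
    nauc_card: float = math.nan
    ratio: float = math.nan


def _waveform(p: FlowSimParams, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    phis = rng.uniform(0, 2 * np.pi, size=len(p.a))
    psi = rng.uniform(0, 2 * np.pi)
    cardiac = sum(
        a_h * np.cos(2 * np.pi * (h + 1) * p.f_c * t + phi)
        for h, (a_h, phi) in enumerate(zip(p.a, phis))
    )
    am = 1.0 + p.m * np.sin(2 * np.pi * p.f_r * t)
    resp = p.b * np.sin(2 * np.pi * p.f_r * t + psi)
    drift = np.polynomial.polynomial.polyval(t / p.duration, p.drift)
    noise = rng.normal(0.0, p.noise_sd, size=t.size) if p.noise_sd > 0 else 0.0
    return p.q0 + drift + am * cardiac + resp + noise


def gen_flow_waveform(p: FlowSimParams) -> tuple[FlowSignal, GroundTruth]:
    """Simulate one flow-rate recording; deterministic given ``p.seed``."""
    rng = np.random.default_rng(p.seed)
    n = int(round(p.duration * p.fs))
    t = np.arange(n) / p.fs
    q = _waveform(p, t, rng)
    flow = FlowSignal(values=q, frame_interval=1.0 / p.fs)
    truth = GroundTruth(flow_series=q.copy())
    truth.nauc_resp, truth.nauc_card, truth.ratio = _maybe_theoretical(p)
    return flow, truth


def _maybe_theoretical(p: FlowSimParams) -> tuple[float, float, float]:
    """Closed-form indices where defined, NaNs otherwise (m != 0, zero variance)."""
    try:
        return theoretical_indices(p)
    except ValueError:
        return math.nan, math.nan, math.nan


def theoretical_indices(p: FlowSimParams) -> tuple[float, float, float]:
    """Closed-form NAUC(R), NAUC(C) and ratio for the m = 0 waveform.

    Total variance V = sum_h a_h^2/2 + b^2/2 + noise_sd^2.  Each band
    captures its sinusoid's full power plus the white-noise share
    proportional to its width: nauc_resp = (b^2/2 + noise^2 w_r) / V,
    nauc_card = (a1^2/2 + noise^2 w_c) / V, with w = band width / (fs/2).
    Harmonics above the fundamental fall outside the 0.5 Hz cardiac band.
    """
    if p.m != 0:
        raise ValueError("closed-form indices require m = 0")
    nyq = p.fs / 2.0
    w_r = (RESP_BAND_FIXED[1] - RESP_BAND_FIXED[0]) / nyq
    w_c = CARD_BAND_WIDTH / nyq
    v_card = sum(a_h**2 / 2.0 for a_h in p.a)
    v = v_card + p.b**2 / 2.0 + p.noise_sd**2
    if v == 0:
        raise ValueError("zero-variance waveform")
    nauc_r = (p.b**2 / 2.0 + p.noise_sd**2 * w_r) / v
    nauc_c = (p.a[0] ** 2 / 2.0 + p.noise_sd**2 * w_c) / v
    ratio = nauc_r / nauc_c if nauc_c > 0 else math.nan
    return nauc_r, nauc_c, ratio


def gen_physio(
    p: FlowSimParams,
    fs_physio: float = PHYSIO_FS,
    start_time: float = 0.0,
    noise_sd: float = 0.02,
) -> PhysioRecord:
    """Matched belt and pulse-oximeter traces.

    The belt is a sinusoid at the breathing rate; the oximeter trace is a
    train of narrow asymmetric pulses at the cardiac rate (an exponentiated
    sinusoid), which gives one well-defined peak per beat.
    """
    rng = np.random.default_rng(np.random.SeedSequence([p.seed, 977]))
    n = int(round(p.duration * fs_physio))
    t = np.arange(n) / fs_physio
    resp = np.sin(2 * np.pi * p.f_r * t)
    pulse = np.exp(4.0 * (np.sin(2 * np.pi * p.f_c * t) - 1.0))
    if noise_sd > 0:
        resp = resp + rng.normal(0, noise_sd, n)
        pulse = pulse + rng.normal(0, noise_sd, n)
    return PhysioRecord(resp=resp, pulse=pulse, fs=fs_physio, start_time=start_time)


def rasterize_disk(grid, center, radius_mm, pixel_spacing) -> np.ndarray:
    """Pixels whose centres lie within the disk (row/col in pixel units)."""
    rows, cols = np.mgrid[0 : grid[0], 0 : grid[1]]
    dr = (rows - center[0]) * pixel_spacing[0]
    dc = (cols - center[1]) * pixel_spacing[1]
    return dr**2 + dc**2 <= radius_mm**2


def gen_pc_phantom(
    p: PhantomParams, start_time: float = 0.0
) -> tuple[PCSeries, GroundTruth]:
    """Full phase/magnitude frame stack of a pulsatile circular vessel.

    Per frame the mean vessel velocity is v_bar(t) = 100 Q(t) / area [cm/s]
    (area from the rasterized disk) and the profile is parabolic,
    v(rho) = 2 v_bar (1 - (rho/R)^2), painted head-ward-negative so the
    venous sign convention recovers positive flow.  Phase is
    pi v / VENC + offset, wrapped into [-pi, pi) — aliasing arises naturally
    when |v| exceeds VENC.
    """
    fp = p.flow
    rng = np.random.default_rng(np.random.SeedSequence([fp.seed, 1331]))
    n = int(round(fp.duration * fp.fs))
    t = np.arange(n) / fp.fs
    q = _waveform(fp, t, np.random.default_rng(fp.seed))

    rows, cols = p.grid
    mag = np.full((n, rows, cols), p.magnitude_contrast[1], dtype=float)
    phs = np.full((n, rows, cols), p.background_phase_offset, dtype=float)
    masks = np.zeros((n, rows, cols), dtype=bool)

    rr, cc = np.mgrid[0:rows, 0:cols]
    drift_px_per_s = p.drift_px_per_min / 60.0
    px_area = p.pixel_spacing[0] * p.pixel_spacing[1]

    def frame_geometry(center):
        dr = (rr - center[0]) * p.pixel_spacing[0]
        dc = (cc - center[1]) * p.pixel_spacing[1]
        rho2 = dr**2 + dc**2
        disk = rho2 <= p.vessel_radius**2
        return disk, 1.0 - rho2[disk] / p.vessel_radius**2

    if drift_px_per_s == 0.0:
        # stationary vessel: one geometry for all frames
        disk, unit_profile = frame_geometry(p.vessel_center)
        masks[:] = disk
        v_bar = 100.0 * q / (disk.sum() * px_area)  # cm/s per frame
        # venous flow is downward: head-ward-positive convention stores -v
        phs[:, disk] = (
            -np.pi * 2.0 * np.outer(v_bar, unit_profile) / p.venc
            + p.background_phase_offset
        )
        mag[:, disk] = p.magnitude_contrast[0]
    else:
        # drift shifts the centre along columns frame by frame
        for k in range(n):
            center = (p.vessel_center[0], p.vessel_center[1] + drift_px_per_s * t[k])
            disk, unit_profile = frame_geometry(center)
            masks[k] = disk
            v_bar = 100.0 * q[k] / (disk.sum() * px_area)
            phs[k][disk] = (
                -np.pi * 2.0 * v_bar * unit_profile / p.venc + p.background_phase_offset
            )
            mag[k][disk] = p.magnitude_contrast[0]

    if p.noise_sd_phase > 0:
        phs = phs + rng.normal(0, p.noise_sd_phase, phs.shape)
    if p.noise_sd_magnitude > 0:
        mag = np.clip(mag + rng.normal(0, p.noise_sd_magnitude, mag.shape), 0, None)

    meta = AcquisitionMeta(
        venc=p.venc,
        pixel_spacing=p.pixel_spacing,
        slice_thickness=p.slice_thickness,
        frame_interval=1.0 / fp.fs,
        start_time=start_time,
        vessel_label=p.vessel_label,
        breathing_mode=p.breathing_mode,
    )
    series = PCSeries(magnitude=mag, phase=wrap_phase(phs), meta=meta)
    area0 = float(masks[0].sum() * p.pixel_spacing[0] * p.pixel_spacing[1])
    truth = GroundTruth(flow_series=q, vessel_masks=masks, area=area0)
    truth.nauc_resp, truth.nauc_card, truth.ratio = _maybe_theoretical(fp)
    return series, truth


# ---------------------------------------------------------------------------
# Group-level simulation: 16 subjects x 3 breathing modes

#: multiplicative parameter effects per breathing mode, relative to free
#: breathing.  Paced-deep breathing doubles the respiratory drive (the
#: thoracic pump), lowers the mean flow and slows the breathing rate a
#: little, mirroring the qualitative group-level picture.
DEFAULT_MODE_EFFECTS = {
    "F": {},
    "PN": {"b": 1.3},
    "PD": {"b": 2.0, "q0": 0.7, "f_r": 0.9},
}

#: subject-level lognormal coefficients of variation on waveform parameters
SUBJECT_CV = {"q0": 0.25, "b": 0.3, "a1": 0.3}


@dataclass
class GroupBundle:
    """GroupTables of every scalar index for one simulated cohort."""

    tables: dict  # index name -> GroupTable
    mode_labels: tuple[str, ...]
    rows: list  # raw per-acquisition result rows


def _jitter(rng: np.random.Generator, value: float, cv: float) -> float:
    sigma = math.sqrt(math.log(1 + cv**2))
    return value * rng.lognormal(-sigma**2 / 2.0, sigma)


def gen_group_dataset(
    n_subjects: int = 16,
    mode_effects: dict | None = None,
    base: FlowSimParams | None = None,
    seed: int = 0,
    vessel: str = "IJV",
) -> GroupBundle:
    """Simulate a cohort and push every waveform through the spectral chain.

    Each subject draws random effects (lognormal, CVs of 25-30%) on mean
    flow, respiratory amplitude and cardiac amplitude, plus a personal
    breathing and heart rate; each breathing mode then applies its
    multiplicative effects.  The returned bundle holds GroupTables of
    nauc_resp, nauc_card, ratio, mean_flow, variance, hf_peak and vhf_peak,
    ready for the Friedman machinery.  Deterministic given ``seed``.
    """
    from .spectral import spectral_summary  # local import avoids cycles
    from .stats import GroupTable

    if mode_effects is None:
        mode_effects = DEFAULT_MODE_EFFECTS
    modes = tuple(mode_effects)
    base = base or FlowSimParams()
    ss = np.random.SeedSequence(seed)
    indices = ["nauc_resp", "nauc_card", "ratio", "mean_flow", "variance", "hf_peak", "vhf_peak"]
    data = {name: np.empty((n_subjects, len(modes))) for name in indices}
    rows = []
    for s, child in enumerate(ss.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        q0_s = _jitter(rng, base.q0, SUBJECT_CV["q0"])
        b_s = _jitter(rng, base.b, SUBJECT_CV["b"])
        a1_s = _jitter(rng, base.a[0], SUBJECT_CV["a1"])
        f_r_s = rng.uniform(0.2, 0.3)
        f_c_s = rng.uniform(1.0, 1.4)
        for j, mode in enumerate(modes):
            eff = mode_effects[mode]
            p = replace(
                base,
                q0=q0_s * eff.get("q0", 1.0),
                b=b_s * eff.get("b", 1.0),
                a=(a1_s * eff.get("a1", 1.0), base.a[1], base.a[2]),
                f_r=float(np.clip(f_r_s * eff.get("f_r", 1.0), 0.12, 0.38)),
                f_c=f_c_s,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            flow, _ = gen_flow_waveform(p)
            summ = spectral_summary(flow, resp_rate=p.f_r, card_rate=p.f_c)
            row = {
                "subject": f"S{s + 1:02d}",
                "vessel": vessel,
                "mode": mode,
                "nauc_resp": summ.nauc_resp,
                "nauc_card": summ.nauc_card,
                "ratio": summ.ratio_resp_card,
                "mean_flow": summ.mean_flow,
                "variance": summ.variance,
                "hf_peak": summ.hf_peak,
                "vhf_peak": summ.vhf_peak,
                "br_hz": p.f_r,
                "hr_hz": p.f_c,
            }
            rows.append(row)
            for name in indices:
                data[name][s, j] = row[name]
    tables = {
        name: GroupTable(values=data[name], condition_labels=modes) for name in indices
    }
    return GroupBundle(tables=tables, mode_labels=modes, rows=rows)
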