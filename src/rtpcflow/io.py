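"""Shared data types and on-disk round trips.

Image stacks live in NIfTI pairs (magnitude, phase) with a JSON metadata
sidecar; physiological recordings are two-column CSV files with a JSON header
line; per-acquisition results go to a flat CSV.  Phase is stored in radians in
[-pi, pi) everywhere inside the package — scanners exporting scaled integers
must be converted at ingest.

Arrays are kept in (frame, row, col) order, 0-based, row-major.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionMeta",
    "PCSeries",
    "PhysioRecord",
    "FlowSignal",
    "IngestError",
    "wrap_phase",
    "read_pc_series",
    "write_pc_series",
    "read_physio",
    "write_physio",
    "write_results_table",
    "read_flow_signal",
    "write_flow_signal",
]

VESSEL_LABELS = ("IJV", "SSS")
BREATHING_MODES = ("F", "PN", "PD")


class IngestError(ValueError):
    """Raised when an on-disk record violates the reader contract."""


def wrap_phase(phase):
    """Wrap phase values into [-pi, pi).  Idempotent.

    Values already in range are passed through untouched (bit-exactly), so
    in the common unaliased case this is a cheap copy.
    """
    phase = np.asarray(phase, dtype=float)
    out = phase.copy()
    bad = (out < -np.pi) | (out >= np.pi)
    if bad.any():
        out[bad] = np.mod(out[bad] + np.pi, 2.0 * np.pi) - np.pi
    return out


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition metadata for one real-time phase-contrast series.

    venc : velocity-encoding limit, cm/s (velocities beyond +-venc alias)
    pixel_spacing : (row, col) in mm
    slice_thickness : mm
    frame_interval : seconds between frames
    start_time : seconds since epoch of the first frame
    vessel_label : "IJV" or "SSS"
    breathing_mode : "F", "PN" or "PD"
    """

    venc: float
    pixel_spacing: tuple[float, float]
    slice_thickness: float
    frame_interval: float
    start_time: float
    vessel_label: str = "IJV"
    breathing_mode: str = "F"

    def __post_init__(self):
        if not self.venc > 0:
            raise ValueError("venc must be > 0")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")
        if not all(s > 0 for s in self.pixel_spacing):
            raise ValueError("pixel_spacing components must be > 0")
        if self.vessel_label not in VESSEL_LABELS:
            raise ValueError(f"vessel_label must be one of {VESSEL_LABELS}")
        if self.breathing_mode not in BREATHING_MODES:
            raise ValueError(f"breathing_mode must be one of {BREATHING_MODES}")


@dataclass
class PCSeries:
    """A time-resolved 2-D phase-contrast acquisition.

    magnitude, phase : (frames, rows, cols); phase in radians within [-pi, pi).
    frame_times : absolute per-frame timestamps, s.
    """

    magnitude: np.ndarray
    phase: np.ndarray
    meta: AcquisitionMeta
    frame_times: np.ndarray = field(default=None)

    def __post_init__(self):
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.magnitude.shape != self.phase.shape:
            raise IngestError(
                f"magnitude shape {self.magnitude.shape} != phase shape {self.phase.shape}"
            )
        if self.magnitude.ndim != 3:
            raise IngestError("expected (frames, rows, cols) arrays")
        if self.frame_times is None:
            k = np.arange(self.n_frames)
            self.frame_times = self.meta.start_time + k * self.meta.frame_interval
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if len(self.frame_times) != self.n_frames:
            raise IngestError("frame_times length mismatch")
        if self.n_frames > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise IngestError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.magnitude.shape[0]

    @property
    def shape(self):
        return self.magnitude.shape


@dataclass
class PhysioRecord:
    """Respiratory-belt and pulse-oximeter traces at a common sampling rate."""

    resp: np.ndarray
    pulse: np.ndarray
    fs: float
    start_time: float

    def __post_init__(self):
        self.resp = np.asarray(self.resp, dtype=float)
        self.pulse = np.asarray(self.pulse, dtype=float)
        if not self.fs > 0:
            raise IngestError("fs must be > 0")
        if self.resp.shape != self.pulse.shape or self.resp.ndim != 1:
            raise IngestError("resp and pulse must be 1-D and equally long")

    @property
    def n_samples(self) -> int:
        return len(self.resp)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.fs


@dataclass
class FlowSignal:
    """Flow rate versus time in mL/s, one sample per image frame."""

    values: np.ndarray
    frame_interval: float
    vessel_label: str = "IJV"
    breathing_mode: str = "F"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 2:
            raise ValueError("FlowSignal needs at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FlowSignal values must be finite")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def fs(self) -> float:
        return 1.0 / self.frame_interval

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.frame_interval


# ---------------------------------------------------------------------------
# NIfTI + JSON sidecar


_SIDECAR_KEYS = {
    "venc_cm_s",
    "pixel_spacing_mm",
    "slice_thickness_mm",
    "frame_interval_ms",
    "start_time_s",
    "vessel",
    "mode",
}


def _meta_to_sidecar(meta: AcquisitionMeta) -> dict:
    return {
        "venc_cm_s": meta.venc,
        "pixel_spacing_mm": list(meta.pixel_spacing),
        "slice_thickness_mm": meta.slice_thickness,
        "frame_interval_ms": meta.frame_interval * 1000.0,
        "start_time_s": meta.start_time,
        "vessel": meta.vessel_label,
        "mode": meta.breathing_mode,
    }


def _meta_from_sidecar(d: dict) -> AcquisitionMeta:
    missing = _SIDECAR_KEYS - set(d)
    if missing:
        raise IngestError(f"metadata sidecar missing keys: {sorted(missing)}")
    return AcquisitionMeta(
        venc=float(d["venc_cm_s"]),
        pixel_spacing=tuple(float(s) for s in d["pixel_spacing_mm"]),
        slice_thickness=float(d["slice_thickness_mm"]),
        frame_interval=float(d["frame_interval_ms"]) / 1000.0,
        start_time=float(d["start_time_s"]),
        vessel_label=str(d["vessel"]),
        breathing_mode=str(d["mode"]),
    )


def write_pc_series(series: PCSeries, path_magnitude, path_phase, path_meta) -> None:
    """Persist a series as two float64 NIfTI volumes plus a JSON sidecar."""
    affine = np.eye(4)
    for arr, path in ((series.magnitude, path_magnitude), (series.phase, path_phase)):
        img = nib.Nifti1Image(np.asarray(arr, dtype=np.float64), affine)
        nib.save(img, str(path))
    Path(path_meta).write_text(json.dumps(_meta_to_sidecar(series.meta), indent=1))


def read_pc_series(path_magnitude, path_phase, path_meta) -> PCSeries:
    """Read a magnitude/phase NIfTI pair with its JSON metadata sidecar.

    Phase values are wrapped into [-pi, pi); frame times are synthesized from
    ``start_time + k * frame_interval``.  Non-finite voxels and shape
    mismatches are rejected.
    """
    mag = np.asarray(nib.load(str(path_magnitude)).get_fdata(), dtype=float)
    phs = np.asarray(nib.load(str(path_phase)).get_fdata(), dtype=float)
    if mag.shape != phs.shape:
        raise IngestError(f"shape mismatch: magnitude {mag.shape} vs phase {phs.shape}")
    if not (np.all(np.isfinite(mag)) and np.all(np.isfinite(phs))):
        raise IngestError("non-finite voxels in image data")
    meta = _meta_from_sidecar(json.loads(Path(path_meta).read_text()))
    return PCSeries(magnitude=mag, phase=wrap_phase(phs), meta=meta)


# ---------------------------------------------------------------------------
# Physio CSV (two columns + JSON header line)


def write_physio(rec: PhysioRecord, path) -> None:
    header = json.dumps({"fs_hz": rec.fs, "start_time_s": rec.start_time})
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        fh.write("resp,pulse\n")
        for r, p in zip(rec.resp, rec.pulse):
            fh.write(f"{float(r)!r},{float(p)!r}\n")


def read_physio(path) -> PhysioRecord:
    """Read a two-channel physio CSV with its JSON header line."""
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise IngestError("physio file missing JSON header line")
        try:
            hdr = json.loads(first.lstrip("#").strip())
        except json.JSONDecodeError as exc:
            raise IngestError(f"bad physio header: {exc}") from exc
        if "fs_hz" not in hdr or "start_time_s" not in hdr:
            raise IngestError("physio header must provide fs_hz and start_time_s")
        df = pd.read_csv(fh, float_precision="round_trip")
    if list(df.columns) != ["resp", "pulse"]:
        raise IngestError("physio CSV must have columns resp,pulse")
    if float(hdr["fs_hz"]) <= 0:
        raise IngestError("fs must be > 0")
    return PhysioRecord(
        resp=df["resp"].to_numpy(),
        pulse=df["pulse"].to_numpy(),
        fs=float(hdr["fs_hz"]),
        start_time=float(hdr["start_time_s"]),
    )


# ---------------------------------------------------------------------------
# Flow-signal CSV + sidecar


def write_flow_signal(flow: FlowSignal, path, sidecar_path=None, extra=None) -> None:
    df = pd.DataFrame({"time_s": flow.times, "flow_ml_s": flow.values})
    df.to_csv(path, index=False)
    if sidecar_path is not None:
        payload = {
            "vessel": flow.vessel_label,
            "mode": flow.breathing_mode,
            "frame_interval_ms": flow.frame_interval * 1000.0,
        }
        if extra:
            payload.update(extra)
        Path(sidecar_path).write_text(json.dumps(payload, indent=1))


def read_flow_signal(path, sidecar_path=None) -> FlowSignal:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    kwargs = {}
    if sidecar_path is not None:
        d = json.loads(Path(sidecar_path).read_text())
        kwargs = {"vessel_label": d["vessel"], "breathing_mode": d["mode"]}
        dt = float(d["frame_interval_ms"]) / 1000.0
    else:
        dt = float(np.median(np.diff(t)))
    return FlowSignal(values=df["flow_ml_s"].to_numpy(), frame_interval=dt, **kwargs)


# ---------------------------------------------------------------------------
# Results table

_KEY_COLS = ["subject", "vessel", "mode"]


def write_results_table(rows, path) -> pd.DataFrame:
    """Write one CSV row per (subject, vessel, mode) with stable column order.

    ``rows`` is an iterable of mappings; every row must carry the three key
    fields.  Duplicate keys are rejected.  Returns the DataFrame written.
    """
    rows = list(rows)
    if rows:
        for row in rows:
            missing = [k for k in _KEY_COLS if k not in row]
            if missing:
                raise ValueError(f"result row missing key fields {missing}")
        df = pd.DataFrame(rows)
        dupes = df.duplicated(subset=_KEY_COLS)
        if dupes.any():
            bad = df.loc[dupes, _KEY_COLS].to_records(index=False).tolist()
            raise ValueError(f"duplicate (subject, vessel, mode) keys: {bad}")
        value_cols = [c for c in df.columns if c not in _KEY_COLS]
        df = df[_KEY_COLS + sorted(value_cols)]
    else:
        df = pd.DataFrame(columns=_KEY_COLS)
    df.to_csv(path, index=False)
    return df
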