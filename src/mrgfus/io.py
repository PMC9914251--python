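"""Interchange formats: complex gradient-echo series, probe logs, manifests.

Complex image data travel as paired magnitude/phase NIfTI volumes plus a JSON
sidecar carrying the acquisition metadata, which keeps the volumes openable in
any standard viewer.  In memory the array index order is fixed as
``[time, slice, row, col]`` with row as the phase-encode axis; pixel centers
sit at ``index * spacing`` (0-based).  All angles are radians internally;
degrees appear only at I/O boundaries.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionMeta",
    "ComplexImageSeries",
    "ProbeLog",
    "Roi",
    "read_complex_series",
    "write_complex_series",
    "read_fiber_log",
    "write_manifest",
]

#: Proton gyromagnetic ratio over 2*pi, MHz/T.
GAMMA_BAR_MHZ_PER_T = 42.577478518


@dataclass
class Roi:
    """Rectangular region of interest in pixel coordinates (half-open stops)."""

    slice_index: int
    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def __post_init__(self) -> None:
        if self.row_stop <= self.row_start or self.col_stop <= self.col_start:
            raise ValueError("ROI must have positive extent")

    def extract(self, volume: np.ndarray) -> np.ndarray:
        """Pull the ROI out of a [slice, row, col] volume."""
        if volume.ndim != 3:
            raise ValueError("expected a [slice, row, col] volume")
        ns, nr, nc = volume.shape
        if not (0 <= self.slice_index < ns
                and 0 <= self.row_start < self.row_stop <= nr
                and 0 <= self.col_start < self.col_stop <= nc):
            raise ValueError(f"ROI {self} outside volume bounds {volume.shape}")
        return volume[self.slice_index,
                      self.row_start:self.row_stop,
                      self.col_start:self.col_stop]

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.slice_index,
          self.row_start:self.row_stop,
          self.col_start:self.col_stop] = True
        return m

    def overlaps(self, other: "Roi") -> bool:
        if self.slice_index != other.slice_index:
            return False
        return (self.row_start < other.row_stop and other.row_start < self.row_stop
                and self.col_start < other.col_stop and other.col_start < self.col_stop)

    def contains_col(self, col: int) -> bool:
        return self.col_start <= col < self.col_stop


@dataclass
class AcquisitionMeta:
    """Gradient-echo acquisition parameters.

    Parameters
    ----------
    TE_ms, TR_ms : float
        Echo and repetition time in milliseconds; ``TR_ms > TE_ms > 0``.
    FA_deg : float
        Flip angle in degrees, in ``(0, 90]``.
    B0_T : float
        Static field strength (tesla).
    f0_MHz : float
        Larmor frequency; must agree with ``B0_T * 42.577 MHz/T`` within 1%.
    FOV_mm : tuple of float
        Field of view per in-plane axis (row, col), mm.
    matrix : tuple of int
        Image matrix (rows, cols); each dimension at least 8.
    timestamp_s : tuple of float
        Acquisition start time of each frame, seconds.
    """

    TE_ms: float
    TR_ms: float
    FA_deg: float
    B0_T: float
    f0_MHz: float
    FOV_mm: tuple[float, float]
    matrix: tuple[int, int]
    slice_thickness_mm: float = 2.0
    inter_slice_gap_mm: float = 0.5
    n_slices: int = 1
    timestamp_s: tuple[float, ...] = field(default_factory=lambda: (0.0,))

    def __post_init__(self) -> None:
        if self.TE_ms <= 0:
            raise ValueError(f"TE_ms must be positive, got {self.TE_ms}")
        if self.TR_ms <= self.TE_ms:
            raise ValueError("TR_ms must exceed TE_ms")
        if not 0 < self.FA_deg <= 90:
            raise ValueError(f"flip angle out of (0, 90]: {self.FA_deg}")
        expected_f0 = GAMMA_BAR_MHZ_PER_T * self.B0_T
        if abs(self.f0_MHz - expected_f0) > 0.01 * expected_f0:
            raise ValueError(
                f"f0={self.f0_MHz} MHz inconsistent with B0={self.B0_T} T "
                f"(expected ~{expected_f0:.1f} MHz)")
        if min(self.matrix) < 8:
            raise ValueError("matrix dimensions must be >= 8")
        self.FOV_mm = tuple(float(v) for v in self.FOV_mm)
        self.matrix = tuple(int(v) for v in self.matrix)
        self.timestamp_s = tuple(float(t) for t in self.timestamp_s)

    @property
    def pixel_spacing_mm(self) -> tuple[float, float]:
        return (self.FOV_mm[0] / self.matrix[0], self.FOV_mm[1] / self.matrix[1])

    @property
    def slice_spacing_mm(self) -> float:
        return self.slice_thickness_mm + self.inter_slice_gap_mm

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AcquisitionMeta":
        d = json.loads(Path(path).read_text())
        return cls(**d)


@dataclass
class ComplexImageSeries:
    """Complex image samples indexed ``[time, slice, row, col]``."""

    data: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D [time, slice, row, col]")
        if not np.iscomplexobj(self.data):
            raise ValueError("data must be complex-valued")
        if len(self.meta.timestamp_s) != self.data.shape[0]:
            raise ValueError("one timestamp per frame required")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.data)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.data)

    def frame(self, t: int) -> np.ndarray:
        return self.data[t]


def _nifti_affine(meta: AcquisitionMeta) -> np.ndarray:
    dr, dc = meta.pixel_spacing_mm
    aff = np.diag([dc, dr, meta.slice_spacing_mm, 1.0])
    return aff


def write_complex_series(series: ComplexImageSeries,
                         path_magnitude: str | Path,
                         path_phase: str | Path,
                         path_meta: str | Path) -> None:
    """Write magnitude/phase NIfTI volumes plus the JSON metadata sidecar.

    Volumes are stored in scanner-friendly axis order (col, row, slice, time)
    as float64 with identity scaling, so a read-back is bitwise lossless.
    """
    aff = _nifti_affine(series.meta)
    mag = series.magnitude.transpose(3, 2, 1, 0)
    pha = series.phase.transpose(3, 2, 1, 0)
    for arr, path in ((mag, path_magnitude), (pha, path_phase)):
        img = nib.Nifti1Image(np.asarray(arr, dtype=np.float64), aff)
        img.header.set_data_dtype(np.float64)
        nib.save(img, str(path))
    series.meta.to_json(path_meta)


def read_complex_series(path_magnitude: str | Path,
                        path_phase: str | Path,
                        path_meta: str | Path) -> ComplexImageSeries:
    """Reassemble a complex series from magnitude/phase volumes and sidecar.

    The phase volume must be in radians within ``[-pi, pi]`` after any NIfTI
    scale/slope is applied (nibabel applies it transparently).
    """
    meta = AcquisitionMeta.from_json(path_meta)
    mag = np.asanyarray(nib.load(str(path_magnitude)).dataobj, dtype=np.float64)
    pha = np.asanyarray(nib.load(str(path_phase)).dataobj, dtype=np.float64)
    if mag.shape != pha.shape:
        raise ValueError(f"magnitude {mag.shape} and phase {pha.shape} shapes differ")
    if pha.size and (pha.min() < -np.pi - 1e-6 or pha.max() > np.pi + 1e-6):
        raise ValueError("phase volume not in radians within [-pi, pi]")
    if mag.ndim == 3:  # single frame stored spatially
        mag = mag[..., None]
        pha = pha[..., None]
    mag = mag.transpose(3, 2, 1, 0)
    pha = pha.transpose(3, 2, 1, 0)
    return ComplexImageSeries(data=mag * np.exp(1j * pha), meta=meta)


@dataclass
class ProbeLog:
    """Fiber-optic probe temperature log."""

    time_s: np.ndarray
    temp_C: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.temp_C = np.asarray(self.temp_C, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.shape != self.temp_C.shape:
            raise ValueError("time_s and temp_C must be matching 1-D arrays")
        if len(self.time_s) == 0:
            raise ValueError("empty probe log")
        if np.any(np.diff(self.time_s) == 0):
            raise ValueError("duplicate timestamps in probe log")
        if np.any(np.diff(self.time_s) < 0):
            raise ValueError("probe log must be time-sorted")

    def __len__(self) -> int:
        return len(self.time_s)

    def interp(self, times_s: np.ndarray) -> np.ndarray:
        """Linear interpolation of temperature at the requested times."""
        t = np.asarray(times_s, dtype=float)
        if t.size and (t.min() < self.time_s[0] - 1e-9 or t.max() > self.time_s[-1] + 1e-9):
            raise ValueError("requested times outside probe log coverage")
        return np.interp(t, self.time_s, self.temp_C)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.time_s, "temp_C": self.temp_C}).to_csv(
            path, index=False)


def read_fiber_log(path: str | Path) -> ProbeLog:
    """Read a fiber-optic probe CSV with columns ``time_s, temp_C``."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"empty probe log: {path}")
    missing = {"time_s", "temp_C"} - set(df.columns)
    if missing:
        raise ValueError(f"probe log missing columns: {sorted(missing)}")
    for col in ("time_s", "temp_C"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.loc[vals.isna()].index.tolist()
            raise ValueError(f"non-numeric values in '{col}' at rows {bad}")
        df[col] = vals
    if not df["time_s"].is_monotonic_increasing:
        warnings.warn("probe log timestamps unsorted; sorting", stacklevel=2)
        df = df.sort_values("time_s", kind="stable")
    return ProbeLog(df["time_s"].to_numpy(), df["temp_C"].to_numpy())


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path,
                   config: dict,
                   seed: int | None,
                   inputs: dict[str, str | Path] | None = None,
                   outputs: dict[str, str | Path] | None = None) -> dict:
    """Write a reproducibility manifest: config hash, seed, input digests.

    Deterministic stages rerun with the same manifest reproduce their outputs
    bit-identically.
    """
    cfg_json = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": seed,
        "inputs": {k: _sha256(v) for k, v in (inputs or {}).items()},
        "outputs": {k: str(v) for k, v in (outputs or {}).items()},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
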