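"""Proton-resonance-frequency (PRF) shift MR thermometry.

Heating lowers the water proton resonance by alpha ~= -0.01 ppm/°C, so the
phase accrued over the echo time changes with temperature.  Referencing each
frame to a pre-heating baseline through the complex-conjugate product,

    dphi = angle(conj(baseline) * frame)
    dT   = dphi / (2*pi * alpha * f0 * TE)

with dphi in radians, f0 in Hz, TE in seconds (equivalently alpha [ppm/°C]
times f0 [MHz] gives the PRF sensitivity in Hz/°C directly).  Because alpha
is negative, a phase decrease at the later frame maps to positive heating.

Frames are treated as gated snapshots acquired between sonications (imaging
during sonication is too noisy), so the series cadence is the sonicate-then-
image loop, not continuous acquisition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import ComplexImageSeries, ProbeLog, Roi

__all__ = [
    "ThermometryConfig",
    "TemperatureSeries",
    "delta_T_map",
    "drift_correct",
    "temporal_unwrap",
    "reconstruct_series",
    "hotspot_trace",
    "compare_to_probe",
]


@dataclass
class ThermometryConfig:
    """PRF reconstruction parameters.

    ``alpha_ppm_per_C`` is the PRF temperature coefficient (negative; values
    outside [-0.012, -0.008] trigger a warning — the accepted literature range
    around -0.0103).  ``drift_roi`` is an unheated region whose apparent
    temperature change is subtracted per frame; ``unwrap_mode`` is one of
    ``none`` or ``temporal``.  ``flip_sign`` accommodates sequences with the
    reversed phase convention.
    """

    f0_MHz: float
    TE_ms: float
    alpha_ppm_per_C: float = -0.01
    baseline_index: int = 0
    baseline_average: int = 1
    drift_roi: Roi | None = None
    unwrap_mode: str = "temporal"
    flip_sign: bool = False
    T_ref_C: float | None = None

    def __post_init__(self) -> None:
        if self.alpha_ppm_per_C >= 0:
            raise ValueError("alpha must be negative (heating lowers the PRF)")
        if not -0.012 <= self.alpha_ppm_per_C <= -0.008:
            warnings.warn(
                f"alpha={self.alpha_ppm_per_C} ppm/°C outside the accepted "
                "[-0.012, -0.008] range", stacklevel=2)
        if self.unwrap_mode not in ("none", "temporal"):
            raise ValueError(f"unknown unwrap_mode {self.unwrap_mode!r}")
        if self.TE_ms <= 0:
            raise ValueError("TE must be positive")

    @property
    def rad_per_C(self) -> float:
        """Phase change per °C: 2*pi * alpha*f0 [Hz/°C] * TE [s]."""
        sign = -1.0 if self.flip_sign else 1.0
        return sign * (2.0 * np.pi * self.alpha_ppm_per_C * self.f0_MHz
                       * self.TE_ms * 1e-3)


@dataclass
class TemperatureSeries:
    """Reconstructed temperature maps plus metadata.

    ``dT_C`` is [time, slice, row, col] relative to the baseline frame (which
    is identically zero); ``valid`` flags voxels with nonzero magnitude.
    Absolute temperature is ``T_ref_C + dT_C``.
    """

    times_s: np.ndarray
    dT_C: np.ndarray
    valid: np.ndarray
    T_ref_C: float = 37.0
    baseline_index: int = 0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("frames must be time-ordered")
        if np.any(self.dT_C[self.baseline_index][self.valid[self.baseline_index]] != 0):
            raise ValueError("baseline frame dT must be identically zero")

    @property
    def absolute_C(self) -> np.ndarray:
        return self.T_ref_C + self.dT_C


def _wrap_to_pi(phi: np.ndarray) -> np.ndarray:
    return np.mod(phi + np.pi, 2.0 * np.pi) - np.pi


def delta_T_map(frame: np.ndarray, baseline: np.ndarray,
                cfg: ThermometryConfig) -> np.ndarray:
    """Single-frame temperature-change map (no unwrapping, no drift term).

    Zero-magnitude voxels come back as NaN (flagged, not propagated into
    neighbors).
    """
    if frame.shape != baseline.shape:
        raise ValueError("frame and baseline geometry differ")
    dphi = _wrap_to_pi(np.angle(np.conj(baseline) * frame))
    ok = (np.abs(frame) > 0) & (np.abs(baseline) > 0)
    dT = dphi / cfg.rad_per_C
    return np.where(ok, dT, np.nan)


def drift_correct(dT_map: np.ndarray, drift_roi: Roi,
                  focus_roi: Roi | None = None) -> np.ndarray:
    """Subtract the mean apparent dT in an unheated reference ROI.

    Scanner frequency drift adds a spatially global pseudo-temperature; the
    reference ROI must not overlap the heated focus.
    """
    if focus_roi is not None and drift_roi.overlaps(focus_roi):
        raise ValueError("drift ROI overlaps the heating focus")
    ref = drift_roi.extract(dT_map)
    offset = float(np.nanmean(ref))
    return dT_map - offset


def temporal_unwrap(dphi_trace: np.ndarray, axis: int = 0,
                    warn_aliasing: bool = True) -> np.ndarray:
    """Cumulative frame-to-frame phase unwrapping along the time axis.

    Valid when the inter-frame phase step stays below pi (guaranteed by the
    acquisition cadence for physiological heating rates); steps at/near pi are
    unrecoverable aliasing and are flagged with a warning.  The check is only
    meaningful at voxels carrying signal — volume-level callers that include
    noise-only background disable it.
    """
    dphi_trace = np.asarray(dphi_trace, dtype=float)
    if warn_aliasing:
        steps = _wrap_to_pi(np.diff(dphi_trace, axis=axis))
        if np.any(np.abs(steps) >= np.pi * 0.999):
            warnings.warn("inter-frame phase step at/near pi: aliasing is "
                          "unrecoverable by temporal unwrapping", stacklevel=2)
    return np.unwrap(dphi_trace, axis=axis)


def reconstruct_series(series: ComplexImageSeries,
                       cfg: ThermometryConfig) -> TemperatureSeries:
    """Full PRF pipeline: baseline reference, unwrap, scale, drift-correct.

    The baseline is a single pre-heating frame by default; setting
    ``baseline_average > 1`` averages that many complex frames starting at
    ``baseline_index`` before referencing.
    """
    data = series.data
    b0 = cfg.baseline_index
    b1 = b0 + cfg.baseline_average
    if b1 > series.n_frames:
        raise ValueError("baseline frames exceed series length")
    baseline = data[b0] if cfg.baseline_average == 1 else data[b0:b1].mean(axis=0)

    dphi = _wrap_to_pi(np.angle(np.conj(baseline)[None] * data))
    if cfg.unwrap_mode == "temporal":
        dphi = temporal_unwrap(dphi, axis=0, warn_aliasing=False)
        # re-anchor so the baseline frame is exactly zero phase
        dphi = dphi - dphi[b0][None]
    valid = (np.abs(data) > 0) & (np.abs(baseline) > 0)[None]
    dT = dphi / cfg.rad_per_C
    if cfg.drift_roi is not None:
        dT = np.stack([drift_correct(dT[t], cfg.drift_roi)
                       for t in range(dT.shape[0])])
    dT[~valid] = np.nan
    dT[b0] = np.where(valid[b0], 0.0, np.nan)
    t_ref = cfg.T_ref_C if cfg.T_ref_C is not None else 37.0
    return TemperatureSeries(times_s=np.asarray(series.meta.timestamp_s),
                             dT_C=dT, valid=valid, T_ref_C=t_ref,
                             baseline_index=b0)


def hotspot_trace(temps: TemperatureSeries,
                  voxel: tuple[int, int, int] | None = None,
                  roi: Roi | None = None,
                  absolute: bool = True) -> ProbeLog:
    """Per-frame temperature at a voxel (or ROI mean), as a probe-like log."""
    if (voxel is None) == (roi is None):
        raise ValueError("give exactly one of voxel or roi")
    if voxel is not None:
        s, r, c = voxel
        if not temps.valid[:, s, r, c].all():
            raise ValueError("hot-spot voxel is masked out in some frame")
        vals = temps.dT_C[:, s, r, c]
    else:
        vals = np.array([np.nanmean(roi.extract(temps.dT_C[t]))
                         for t in range(temps.dT_C.shape[0])])
        if np.isnan(vals).any():
            raise ValueError("hot-spot ROI empty or fully masked")
    if absolute:
        vals = temps.T_ref_C + vals
    return ProbeLog(time_s=temps.times_s.copy(), temp_C=np.asarray(vals, float))


def compare_to_probe(trace: ProbeLog, probe: ProbeLog) -> dict:
    """PRF-vs-fiber-optic comparison at the imaging frame times.

    The probe log is linearly interpolated to the frame times; returns the
    maximum absolute discrepancy (°C), the residual series (PRF minus probe),
    and the frame time where the worst disagreement occurs.
    """
    lo = max(trace.time_s[0], probe.time_s[0])
    hi = min(trace.time_s[-1], probe.time_s[-1])
    if hi < lo:
        raise ValueError("probe log and trace do not overlap in time")
    sel = (trace.time_s >= lo - 1e-9) & (trace.time_s <= hi + 1e-9)
    t = trace.time_s[sel]
    resid = trace.temp_C[sel] - probe.interp(t)
    i = int(np.argmax(np.abs(resid)))
    return {
        "max_abs_discrepancy_C": float(np.abs(resid[i])),
        "at_time_s": float(t[i]),
        "residuals_C": resid,
        "frame_times_s": t,
    }
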