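"""Matrix-array focused ultrasound field model and focal-spot metrics.

Models the 11 x 11 element, 909 um pitch piston array (aperture ~10 x 10 mm,
center frequency 960 kHz) as a Rayleigh-Sommerfeld sum over sub-sources: each
square element face is tiled with point sources at <= lambda/4 spacing, kerf
non-radiating, and the complex pressure at an observation point r is

    p(r) = sum_s exp(i * (k*d_s + omega*tau_s)) / d_s

where d_s is the sub-source-to-point distance and tau_s the geometric
focusing delay of the parent element.  This is a continuous-wave single-
frequency model — the relevant focal metrics (peak position, -6 dB widths)
are CW-type beam metrics — with a water-path (no attenuation) assumption and
uncalibrated absolute pressure: all outputs are normalized, and intensities
are relative unless a source pressure scale is supplied.

Lengths at this module's interfaces are millimeters; delays are seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ArrayGeometry",
    "DelaySet",
    "PulseTiming",
    "focusing_delays",
    "pressure_field",
    "fwhm_minus6db",
    "characterize_focus",
    "intensity_metrics",
]


@dataclass
class ArrayGeometry:
    """Planar matrix array in the z=0 plane, beam axis along +z.

    Element centers form an ``n_x`` x ``n_y`` grid at ``pitch_mm`` spacing
    centered on the origin; the radiating face of each element is a square of
    side ``pitch_mm - kerf_mm``.
    """

    n_x: int = 11
    n_y: int = 11
    pitch_mm: float = 0.909
    kerf_mm: float = 0.100
    frequency_hz: float = 960e3
    sound_speed_m_s: float = 1540.0

    def __post_init__(self) -> None:
        if self.kerf_mm >= self.pitch_mm:
            raise ValueError("element size (pitch - kerf) must be positive")
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError("element counts must be positive")
        if self.frequency_hz <= 0 or self.sound_speed_m_s <= 0:
            raise ValueError("frequency and sound speed must be positive")

    @property
    def aperture_mm(self) -> tuple[float, float]:
        """Overall aperture extent (n * pitch per axis); ~10 x 10 mm default."""
        return (self.n_x * self.pitch_mm, self.n_y * self.pitch_mm)

    @property
    def element_size_mm(self) -> float:
        return self.pitch_mm - self.kerf_mm

    @property
    def wavelength_mm(self) -> float:
        return self.sound_speed_m_s / self.frequency_hz * 1e3

    @property
    def wavenumber_per_mm(self) -> float:
        return 2.0 * np.pi / self.wavelength_mm

    def element_centers_mm(self) -> np.ndarray:
        """(n_x*n_y, 3) element centers, z = 0."""
        x = (np.arange(self.n_x) - (self.n_x - 1) / 2) * self.pitch_mm
        y = (np.arange(self.n_y) - (self.n_y - 1) / 2) * self.pitch_mm
        gx, gy = np.meshgrid(x, y, indexing="ij")
        n = self.n_x * self.n_y
        return np.column_stack([gx.ravel(), gy.ravel(), np.zeros(n)])

    def subsources_mm(self, max_spacing_mm: float | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
        """Sub-source positions and their parent-element indices.

        Each element face is tiled with an ``m x m`` grid, ``m`` chosen so the
        sub-source spacing is at most ``max_spacing_mm`` (default lambda/4).
        Returns ``(points (N,3), parent (N,))``.
        """
        if max_spacing_mm is None:
            max_spacing_mm = self.wavelength_mm / 4.0
        m = max(1, int(np.ceil(self.element_size_mm / max_spacing_mm)))
        off = (np.arange(m) - (m - 1) / 2) * (self.element_size_mm / m)
        ox, oy = np.meshgrid(off, off, indexing="ij")
        centers = self.element_centers_mm()
        pts = (centers[:, None, :]
               + np.column_stack([ox.ravel(), oy.ravel(),
                                  np.zeros(m * m)])[None, :, :])
        parent = np.repeat(np.arange(len(centers)), m * m)
        return pts.reshape(-1, 3), parent


@dataclass
class DelaySet:
    """Per-element transmit delays realizing a geometric focus."""

    delays_s: np.ndarray
    focus_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.delays_s = np.asarray(self.delays_s, dtype=float)
        if np.any(self.delays_s < 0):
            raise ValueError("delays must be non-negative")
        if abs(self.delays_s.min()) > 1e-15:
            raise ValueError("minimum delay must be zero")


def focusing_delays(geom: ArrayGeometry,
                    focus_mm: tuple[float, float, float]) -> DelaySet:
    """Geometric delay law: tau_n = (max_m d_m - d_n) / c.

    Elements farther from the focus fire first so all wavefronts arrive in
    phase; the farthest element gets zero delay.
    """
    focus = np.asarray(focus_mm, dtype=float)
    if focus[2] <= 0:
        raise ValueError("focus must lie in front of the array (z > 0)")
    centers = geom.element_centers_mm()
    d_mm = np.linalg.norm(centers - focus, axis=1)
    if np.any(d_mm < 1e-9):
        raise ValueError("focus coincides with an element center")
    tau = (d_mm.max() - d_mm) * 1e-3 / geom.sound_speed_m_s
    return DelaySet(delays_s=tau, focus_mm=tuple(focus))


def pressure_field(geom: ArrayGeometry,
                   delays: DelaySet,
                   grid_mm: np.ndarray,
                   subsource_spacing_mm: float | None = None,
                   normalize: bool = True,
                   chunk: int = 4096) -> np.ndarray:
    """Complex pressure at the given observation points (N, 3), normalized.

    Rayleigh-Sommerfeld summation over the element sub-sources with the
    parent element's focusing delay applied as a phase advance
    ``exp(i*omega*tau)``.
    """
    pts = np.asarray(grid_mm, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("grid must be (N, 3) points in mm")
    src, parent = geom.subsources_mm(subsource_spacing_mm)
    k = geom.wavenumber_per_mm
    omega = 2.0 * np.pi * geom.frequency_hz
    phase_delay = omega * delays.delays_s[parent]
    out = np.empty(len(pts), dtype=np.complex128)
    for i in range(0, len(pts), chunk):
        d = np.linalg.norm(pts[i:i + chunk, None, :] - src[None, :, :], axis=2)
        if np.any(d < 1e-12):
            raise ValueError("observation point coincides with a source point")
        out[i:i + chunk] = np.sum(np.exp(1j * (k * d + phase_delay[None, :])) / d,
                                  axis=1)
    if normalize:
        out = out / np.abs(out).max()
    return out


def fwhm_minus6db(axis_mm: np.ndarray, profile: np.ndarray) -> float:
    """-6 dB (half-amplitude) full width of a beam profile, mm.

    Linear interpolation between the half-amplitude crossings bracketing the
    unique global maximum.  Raises if either crossing lies outside the grid
    (the caller should extend the profile).
    """
    x = np.asarray(axis_mm, dtype=float)
    p = np.abs(np.asarray(profile, dtype=float))
    if len(x) != len(p) or len(x) < 3:
        raise ValueError("need matching axis/profile with >= 3 samples")
    p = p / p.max()
    i = int(np.argmax(p))
    half = 0.5
    left = np.nonzero(p[:i] < half)[0]
    right = np.nonzero(p[i:] < half)[0]
    if len(left) == 0 or len(right) == 0:
        raise ValueError("-6 dB crossings outside grid; enlarge the profile")
    il = left[-1]
    ir = i + right[0]
    xl = x[il] + (half - p[il]) / (p[il + 1] - p[il]) * (x[il + 1] - x[il])
    xr = x[ir - 1] + (half - p[ir - 1]) / (p[ir] - p[ir - 1]) * (x[ir] - x[ir - 1])
    return float(xr - xl)


def characterize_focus(geom: ArrayGeometry,
                       focus_mm: tuple[float, float, float] = (0.0, 0.0, 5.0),
                       axial_span_mm: tuple[float, float] = (0.5, 20.0),
                       lateral_halfspan_mm: float = 3.0,
                       step_mm: float = 0.005,
                       subsource_spacing_mm: float | None = None) -> dict:
    """Simulate the focused field and measure the focal-spot metrics.

    Finds the on-axis pressure peak, then measures the -6 dB full widths of
    the lateral line through the peak and of the on-axis (axial) profile.
    Returns the peak depth and both widths, plus the raw profiles.
    """
    delays = focusing_delays(geom, focus_mm)
    fx, fy, _ = focus_mm
    z = np.arange(axial_span_mm[0], axial_span_mm[1] + step_mm / 2, step_mm)
    axial_pts = np.column_stack([np.full_like(z, fx), np.full_like(z, fy), z])
    p_ax = np.abs(pressure_field(geom, delays, axial_pts,
                                 subsource_spacing_mm, normalize=False))
    z_peak = float(z[np.argmax(p_ax)])
    xs = np.arange(-lateral_halfspan_mm, lateral_halfspan_mm + step_mm / 2, step_mm)
    lat_pts = np.column_stack([fx + xs, np.full_like(xs, fy),
                               np.full_like(xs, z_peak)])
    p_lat = np.abs(pressure_field(geom, delays, lat_pts,
                                  subsource_spacing_mm, normalize=False))
    return {
        "focus_mm": tuple(focus_mm),
        "z_peak_mm": z_peak,
        "lateral_fwhm_mm": fwhm_minus6db(xs, p_lat),
        "axial_fwhm_mm": fwhm_minus6db(z, p_ax),
        "axial_axis_mm": z,
        "axial_profile": p_ax,
        "lateral_axis_mm": xs + fx,
        "lateral_profile": p_lat,
    }


@dataclass
class PulseTiming:
    """Burst timing; duty cycle = burst length x pulse repetition frequency.

    System limits: bursts up to 50 us at up to 1 kHz PRF, i.e. a duty cycle
    of at most 5%.
    """

    burst_us: float = 50.0
    prf_hz: float = 1000.0

    def __post_init__(self) -> None:
        if not 0 <= self.burst_us <= 50.0:
            raise ValueError("burst length limited to 50 us")
        if not 0 <= self.prf_hz <= 1000.0:
            raise ValueError("pulse repetition frequency limited to 1 kHz")

    @property
    def duty_cycle(self) -> float:
        return self.burst_us * 1e-6 * self.prf_hz


def intensity_metrics(field: np.ndarray,
                      timing: PulseTiming,
                      rho_c_rayl: float | None = None,
                      source_pressure_pa: float = 1.0) -> dict:
    """Relative time-averaged intensity of a normalized field.

    ``I = |p|^2 / (2 * rho*c) * duty_cycle``; with the default unit source
    pressure the map is relative (the absolute ISPTA calibration requires a
    measured source-pressure scale).  ``rho_c_rayl`` is the characteristic
    acoustic impedance (kg m^-2 s^-1) and must be given.
    """
    if rho_c_rayl is None:
        raise ValueError("characteristic impedance rho*c is required")
    p = np.abs(np.asarray(field)) * source_pressure_pa
    ispta = p ** 2 / (2.0 * rho_c_rayl) * timing.duty_cycle
    return {
        "ispta_map_w_m2": ispta,
        "ispta_peak_w_m2": float(ispta.max()),
        "duty_cycle": timing.duty_cycle,
    }
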