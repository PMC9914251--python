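"""Synthetic gradient-echo test bed with known temperature and field truth.

Generates complex FLASH-like image series of a phantom or mouse-like object in
which every downstream quantity — temperature change, static-field offset,
temporal drift, noise level — is known exactly.  The forward model:

* magnitude from the spoiled gradient-echo signal equation per tissue label;
* voxel phase ``phi0 + 2*pi*(B0_offset + drift + alpha*f0*dT)*TE`` — the
  proton-resonance-frequency mechanism, temperature acting on phase only;
* independent zero-mean Gaussian noise of SD ``sigma`` added to the real and
  imaginary channels (magnitude noise therefore Rician, with background SD
  0.655 * sigma);
* instrument artifacts applied last: a bright "zipper" stripe along the
  phase-encode direction through image center, and a signal-void mask at the
  transducer site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .control import ProtocolState
from .io import AcquisitionMeta, ComplexImageSeries

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "NoiseSpec",
    "ernst_angle",
    "spoiled_gre_signal",
    "synthesize_series",
    "heating_truth_from_bioheat",
    "rician_background_ratio",
    "default_phantom",
    "condition_ladder",
    "RICIAN_SD_FACTOR",
]

#: Exact SD of the magnitude of unit-SD complex Gaussian noise,
#: sqrt(2 - pi/2) = 0.6551... — the "0.655" Rician correction factor.
RICIAN_SD_FACTOR = math.sqrt(2.0 - math.pi / 2.0)


def ernst_angle(TR_ms: float, T1_ms: float) -> float:
    """Ernst angle arccos(exp(-TR/T1)) in degrees.

    The flip angle maximizing spoiled gradient-echo signal; for the agar
    phantom (T1 = 283 ms) at short TR it lands in the 12-14 degree range used
    for the thermometry scans.
    """
    if TR_ms <= 0 or T1_ms <= 0:
        raise ValueError("TR and T1 must be positive")
    return math.degrees(math.acos(math.exp(-TR_ms / T1_ms)))


def spoiled_gre_signal(PD: float, T1_ms: float, T2star_ms: float,
                       meta: AcquisitionMeta) -> float:
    """Steady-state spoiled gradient-echo (FLASH) magnitude.

    ``PD * sin(FA) * (1 - E1) / (1 - cos(FA) * E1) * exp(-TE/T2*)`` with
    ``E1 = exp(-TR/T1)``.
    """
    if T2star_ms <= 0:
        raise ValueError("T2* must be positive")
    if T1_ms <= 0:
        raise ValueError("T1 must be positive")
    e1 = math.exp(-meta.TR_ms / T1_ms)
    theta = math.radians(meta.FA_deg)
    return (PD * math.sin(theta) * (1.0 - e1)
            / (1.0 - math.cos(theta) * e1)
            * math.exp(-meta.TE_ms / T2star_ms))


@dataclass
class PhantomSpec:
    """Labeled object: tissue properties per label on a [slice, row, col] grid.

    ``properties`` maps label -> (PD, T1_ms, T2star_ms).  Every label present
    in ``label_map`` must have properties; label 0 is background (PD 0).
    """

    label_map: np.ndarray
    properties: dict[int, tuple[float, float, float]]
    voxel_spacing_mm: tuple[float, float, float] = (1.5, 0.3125, 0.3125)

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map)
        if self.label_map.ndim != 3:
            raise ValueError("label_map must be [slice, row, col]")
        present = set(np.unique(self.label_map).tolist())
        missing = present - set(self.properties)
        if missing:
            raise ValueError(f"labels without properties: {sorted(missing)}")
        for lbl, (pd_, t1, t2s) in self.properties.items():
            if pd_ > 0 and (t1 <= 0 or t2s <= 0):
                raise ValueError(f"label {lbl}: T1 and T2* must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.label_map.shape

    def magnitude(self, meta: AcquisitionMeta) -> np.ndarray:
        """Noiseless magnitude volume from the signal equation per label."""
        out = np.zeros(self.shape, dtype=float)
        for lbl, (pd_, t1, t2s) in self.properties.items():
            if pd_ <= 0:
                continue
            out[self.label_map == lbl] = spoiled_gre_signal(pd_, t1, t2s, meta)
        return out


# Phantom relaxation times as measured by relaxometry: T1 = 283 ms, T2 = 75 ms.
# T2* is set slightly below T2 to represent static dephasing.
PHANTOM_T1_MS = 283.0
PHANTOM_T2_MS = 75.0
PHANTOM_T2STAR_MS = 60.0


def default_phantom(shape: tuple[int, int, int] = (1, 64, 64),
                    voxel_spacing_mm: tuple[float, float, float] = (2.5, 0.625, 0.625),
                    radius_frac: float = 0.38) -> PhantomSpec:
    """Cylindrical agar phantom (label 1) in air background (label 0)."""
    ns, nr, nc = shape
    rr, cc = np.mgrid[:nr, :nc]
    r0, c0 = (nr - 1) / 2, (nc - 1) / 2
    disk = (rr - r0) ** 2 + (cc - c0) ** 2 <= (radius_frac * min(nr, nc)) ** 2
    labels = np.broadcast_to(disk.astype(np.int16), shape).copy()
    return PhantomSpec(
        label_map=labels,
        properties={0: (0.0, 1.0, 1.0),
                    1: (1.0, PHANTOM_T1_MS, PHANTOM_T2STAR_MS)},
        voxel_spacing_mm=voxel_spacing_mm,
    )


@dataclass
class GroundTruth:
    """Known-answer fields behind a synthetic series.

    ``dT_C`` is the temperature change per frame (°C, zero at baseline);
    ``b0_offset_hz`` the static off-resonance map; ``drift_hz`` the global
    frequency drift per frame (zero at the first frame); ``phi0`` the initial
    phase map (rad).  The temperature-induced local shielding change is
    ``sigma_T = alpha * dT`` (dimensionless, ppm scale), on top of the static
    ``sigma_0`` that the B0 offset map represents.
    """

    dT_C: np.ndarray                       # [time, slice, row, col]
    b0_offset_hz: np.ndarray               # [slice, row, col]
    drift_hz: np.ndarray                   # [time]
    phi0: np.ndarray                       # [slice, row, col]
    baseline_index: int = 0

    def __post_init__(self) -> None:
        self.dT_C = np.asarray(self.dT_C, dtype=float)
        self.b0_offset_hz = np.asarray(self.b0_offset_hz, dtype=float)
        self.drift_hz = np.asarray(self.drift_hz, dtype=float)
        self.phi0 = np.asarray(self.phi0, dtype=float)
        if self.dT_C.ndim != 4:
            raise ValueError("dT_C must be [time, slice, row, col]")
        if np.any(self.dT_C[self.baseline_index] != 0):
            raise ValueError("dT must be zero everywhere at the baseline frame")
        if self.drift_hz[0] != 0:
            raise ValueError("drift must be zero at the first frame")

    @classmethod
    def zeros(cls, n_frames: int, shape: tuple[int, int, int]) -> "GroundTruth":
        return cls(dT_C=np.zeros((n_frames, *shape)),
                   b0_offset_hz=np.zeros(shape),
                   drift_hz=np.zeros(n_frames),
                   phi0=np.zeros(shape))

    def sigma_T(self, alpha_ppm_per_C: float) -> np.ndarray:
        return alpha_ppm_per_C * 1e-6 * self.dT_C

    def hotspot_trace(self) -> np.ndarray:
        """Per-frame maximum of |dT| (the focal trace for localized heating)."""
        return self.dT_C.reshape(self.dT_C.shape[0], -1).max(axis=1)


@dataclass
class NoiseSpec:
    """Channel noise and instrument artifacts.

    ``sigma`` is the Gaussian SD per real/imaginary channel in signal units.
    The zipper stripe is additive high intensity along the phase-encode (row)
    axis at a given column, default width 0.8 mm; the transducer signal void
    zeroes a masked region.
    """

    sigma: float = 0.0
    zipper: bool = False
    zipper_col: int | None = None          # default: image center
    zipper_width_mm: float = 0.8
    zipper_amplitude: float = 5.0
    void_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def zipper_cols(self, n_cols: int, col_spacing_mm: float) -> slice:
        center = self.zipper_col if self.zipper_col is not None else n_cols // 2
        width = max(1, round(self.zipper_width_mm / col_spacing_mm))
        start = center - (width - 1) // 2
        return slice(max(0, start), min(n_cols, start + width))


def synthesize_series(phantom: PhantomSpec,
                      truth: GroundTruth,
                      noise: NoiseSpec,
                      meta: AcquisitionMeta,
                      alpha_ppm_per_C: float = -0.01,
                      rng: np.random.Generator | int | None = None) -> ComplexImageSeries:
    """Forward-model a complex FLASH series from phantom + truth + noise.

    Voxel phase at frame t is ``phi0 + 2*pi*(B0 + drift_t + alpha*f0*dT_t)*TE``
    with ``alpha*f0`` in Hz/°C (ppm/°C times MHz), so heating (dT > 0 with
    alpha < 0) lowers the accrued phase.  Noise is added to the real and
    imaginary channels independently — never sampled from a Rician directly —
    so phase noise stays physically coupled to magnitude.  Artifacts are
    applied last.  Seeded generation is bitwise reproducible.
    """
    n_frames = truth.dT_C.shape[0]
    shape = phantom.shape
    if truth.dT_C.shape[1:] != shape or truth.b0_offset_hz.shape != shape:
        raise ValueError("phantom and truth shapes disagree")
    if len(truth.drift_hz) != n_frames:
        raise ValueError("drift must have one value per frame")
    if len(meta.timestamp_s) != n_frames:
        raise ValueError("meta.timestamp_s must have one entry per frame")
    rng = np.random.default_rng(rng)

    mag = phantom.magnitude(meta)
    te_s = meta.TE_ms * 1e-3
    alpha_hz_per_C = alpha_ppm_per_C * meta.f0_MHz  # ppm/°C * MHz = Hz/°C

    data = np.empty((n_frames, *shape), dtype=np.complex128)
    for t in range(n_frames):
        freq_hz = (truth.b0_offset_hz + truth.drift_hz[t]
                   + alpha_hz_per_C * truth.dT_C[t])
        phase = truth.phi0 + 2.0 * np.pi * freq_hz * te_s
        data[t] = mag * np.exp(1j * phase)

    if noise.sigma > 0:
        data += (rng.normal(0.0, noise.sigma, data.shape)
                 + 1j * rng.normal(0.0, noise.sigma, data.shape))

    if noise.zipper:
        cols = noise.zipper_cols(shape[2], phantom.voxel_spacing_mm[2])
        stripe = data[:, :, :, cols]
        m = np.abs(stripe)
        # boost magnitude, preserve phase; zero-magnitude pixels get phase 0
        boosted = np.where(m > 0,
                           stripe * (m + noise.zipper_amplitude) / np.where(m > 0, m, 1.0),
                           noise.zipper_amplitude + 0.0j)
        data[:, :, :, cols] = boosted
    if noise.void_mask is not None:
        vm = np.asarray(noise.void_mask, dtype=bool)
        if vm.shape != shape:
            raise ValueError("void mask shape mismatch")
        data[:, vm] = 0.0

    return ComplexImageSeries(data=data, meta=meta)


def heating_truth_from_bioheat(state: ProtocolState,
                               phantom: PhantomSpec,
                               meta: AcquisitionMeta,
                               focus_voxel: tuple[int, int, int],
                               lateral_fwhm_mm: float = 1.5,
                               axial_fwhm_mm: float = 7.3,
                               b0_offset_hz: np.ndarray | None = None,
                               drift_hz: np.ndarray | None = None,
                               phi0: np.ndarray | None = None) -> GroundTruth:
    """Turn a protocol temperature trace into a spatial heating truth.

    The focal heating pattern is a separable Gaussian whose full widths at
    half maximum equal the -6 dB focal widths (lateral in-plane, axial across
    slices), unit peak at the focus voxel, times the protocol's temperature
    rise interpolated at the frame times.  The spatial profile is a modeling
    stand-in (the in-tissue profile is not specified by the beam metrics
    alone).
    """
    shape = phantom.shape
    fs, fr, fc = focus_voxel
    if not (0 <= fs < shape[0] and 0 <= fr < shape[1] and 0 <= fc < shape[2]):
        raise ValueError(f"focus {focus_voxel} outside grid {shape}")
    frame_times = np.asarray(meta.timestamp_s)
    if frame_times.min() < state.time_s.min() - 1e-9 or \
       frame_times.max() > state.time_s.max() + 1e-9:
        raise ValueError("protocol trace does not cover the frame times")

    rise = np.interp(frame_times, state.time_s,
                     state.temp_C - state.temp_C[0])
    ds, dr, dc = phantom.voxel_spacing_mm
    s = (np.arange(shape[0]) - fs) * ds
    r = (np.arange(shape[1]) - fr) * dr
    c = (np.arange(shape[2]) - fc) * dc
    ln2_4 = 4.0 * np.log(2.0)
    kernel = np.exp(-ln2_4 * ((s[:, None, None] / axial_fwhm_mm) ** 2
                              + (r[None, :, None] / lateral_fwhm_mm) ** 2
                              + (c[None, None, :] / lateral_fwhm_mm) ** 2))
    dT = rise[:, None, None, None] * kernel[None]
    n = len(frame_times)
    return GroundTruth(
        dT_C=dT,
        b0_offset_hz=np.zeros(shape) if b0_offset_hz is None else b0_offset_hz,
        drift_hz=np.zeros(n) if drift_hz is None else drift_hz,
        phi0=np.zeros(shape) if phi0 is None else phi0,
    )


def rician_background_ratio(n: int = 100_000,
                            sigma: float = 1.0,
                            rng: np.random.Generator | int | None = None) -> float:
    """Monte-Carlo SD of background magnitude noise over the channel SD.

    Draws ``n`` complex samples with independent N(0, sigma) real and
    imaginary parts and returns ``SD(|z|) / sigma``; converges to
    sqrt(2 - pi/2) = 0.655, the Rician SNR correction factor.
    """
    if n < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(rng)
    z = rng.normal(0, sigma, n) + 1j * rng.normal(0, sigma, n)
    return float(np.std(np.abs(z), ddof=1) / sigma)


def condition_ladder(phantom: PhantomSpec,
                     base_sigma: float = 0.004) -> dict[str, NoiseSpec]:
    """Noise/artifact presets for the four hardware conditions.

    (a) phantom only; (b) transducer installed (signal void, more noise
    pickup); (c) driving electronics powered (void + zipper, much more
    noise); (d) transducer sonicating (worst).  Channel noise rises along the
    ladder so image SNR decreases a > b > c > d — the ordering observed on
    hardware; absolute SNR values are scanner-specific and not emulated.
    """
    ns, nr, nc = phantom.shape
    void = np.zeros(phantom.shape, dtype=bool)
    void[:, nr - max(2, nr // 8):, :] = True  # transducer side of the image
    return {
        "a_phantom_only": NoiseSpec(sigma=base_sigma),
        "b_transducer_installed": NoiseSpec(sigma=base_sigma * 2.4,
                                            void_mask=void),
        "c_electronics_on": NoiseSpec(sigma=base_sigma * 10.6, zipper=True,
                                      void_mask=void),
        "d_sonicating": NoiseSpec(sigma=base_sigma * 14.7, zipper=True,
                                  void_mask=void),
    }
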