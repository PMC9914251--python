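"""B0 off-resonance mapping from dual-echo complex gradient-echo images.

The phase of a gradient echo at echo time TE is ``phi = phi0 + omega*TE``;
two echoes at TE1 < TE2 therefore give the off-resonance directly:

    omega/2pi [Hz] = angle(conj(m1) * m2) / (2*pi * (TE2 - TE1))

The complex-conjugate product cancels the (unknown) initial phase phi0.  With
this ordering a positive off-resonance yields a positive map.  The unambiguous
range is +/- 1/(2*dTE); larger offsets alias unless unwrapping is enabled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FieldMap", "phase_difference", "b0_map", "field_drift_summary"]


def _wrap_to_pi(phi: np.ndarray) -> np.ndarray:
    """Principal value in [-pi, pi)."""
    return np.mod(phi + np.pi, 2.0 * np.pi) - np.pi


def phase_difference(m1: np.ndarray, m2: np.ndarray) -> np.ndarray:
    """Principal-value phase of ``conj(m1) * m2`` in [-pi, pi).

    Equals ``angle(m2) - angle(m1)`` wrapped, but computed through the complex
    product so it is robust at the wrap boundary.
    """
    m1 = np.asarray(m1)
    m2 = np.asarray(m2)
    if m1.shape != m2.shape:
        raise ValueError(f"shape mismatch: {m1.shape} vs {m2.shape}")
    return _wrap_to_pi(np.angle(np.conj(m1) * m2))


@dataclass
class FieldMap:
    """Per-pixel off-resonance with validity mask.

    ``hz`` and ``ppm`` carry NaN outside the validity mask so masked-out
    pixels carry no value.  Without unwrapping, |hz| <= 1/(2*dTE).
    """

    hz: np.ndarray
    ppm: np.ndarray
    valid: np.ndarray
    dte_ms: float
    f0_MHz: float

    def __post_init__(self) -> None:
        if not (self.hz.shape == self.ppm.shape == self.valid.shape):
            raise ValueError("field map components must share shape")

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.dte_ms * 1e-3)


def b0_map(m1: np.ndarray,
           m2: np.ndarray,
           te1_ms: float,
           te2_ms: float,
           f0_MHz: float,
           mask: np.ndarray | None = None,
           noise_roi=None,
           snr_crop_k: float = 5.0,
           unwrap: bool = False) -> FieldMap:
    """Dual-echo B0 field map in Hz and ppm.

    Parameters
    ----------
    m1, m2 : complex arrays
        Echo volumes at ``te1_ms`` and ``te2_ms`` (TE2 > TE1), any matching
        shape (a single [slice, row, col] volume in the usual workflow).
    mask : bool array, optional
        Pixels to evaluate; defaults to all.
    noise_roi : Roi, optional
        Background region used to crop low-SNR pixels: the magnitude
        threshold is ``snr_crop_k`` times the background Rayleigh mean (3-D
        input only).  Regions outside the object are otherwise kept.
    unwrap : bool
        Apply quality-guided spatial unwrapping to the echo phase difference
        before scaling (off by default; phantom offsets are sub-wrap).

    Zero-magnitude pixels inside the mask are flagged invalid rather than
    propagating NaNs.
    """
    if te2_ms <= te1_ms:
        raise ValueError("TE2 must exceed TE1")
    m1 = np.asarray(m1)
    m2 = np.asarray(m2)
    dte_s = (te2_ms - te1_ms) * 1e-3
    dphi = phase_difference(m1, m2)
    valid = np.ones(m1.shape, dtype=bool) if mask is None else np.asarray(mask, bool).copy()
    valid &= (np.abs(m1) > 0) & (np.abs(m2) > 0)
    if noise_roi is not None:
        if m1.ndim != 3:
            raise ValueError("noise-ROI cropping expects a [slice, row, col] volume")
        bg_mean = float(np.mean(noise_roi.extract(np.abs(m1))))
        thresh = snr_crop_k * bg_mean
        valid &= (np.abs(m1) >= thresh) & (np.abs(m2) >= thresh)
    if unwrap:
        from skimage.restoration import unwrap_phase
        dphi = np.asarray(unwrap_phase(np.ma.masked_array(dphi, ~valid)))
    hz = np.where(valid, dphi / (2.0 * np.pi * dte_s), np.nan)
    ppm = hz / f0_MHz
    return FieldMap(hz=hz, ppm=ppm, valid=valid,
                    dte_ms=te2_ms - te1_ms, f0_MHz=f0_MHz)


#: Display window for field maps, Hz (roughly +/- 1 ppm at 7 T).
DISPLAY_RANGE_HZ = (-300.0, 300.0)


def field_drift_summary(map_a: FieldMap, map_b: FieldMap,
                        mode: str = "ppm") -> dict:
    """Field change between two hardware conditions, in every candidate unit.

    Returns mean |dHz|, mean |dppm|, and the percentage under each candidate
    normalization: relative to the Larmor frequency (ppm * 1e-4) and relative
    to the +/-300 Hz display window span.  All modes are always included
    (a bare printed "drift percentage" does not pin down its normalization);
    ``mode`` in {ppm, hz, percent_of_f0, percent_of_display_range} selects
    which one is surfaced as ``value``.
    """
    both = map_a.valid & map_b.valid
    if not both.any():
        raise ValueError("field maps share no valid pixels")
    dhz = np.abs(map_a.hz[both] - map_b.hz[both])
    mean_dhz = float(np.mean(dhz))
    mean_dppm = mean_dhz / map_a.f0_MHz
    span = DISPLAY_RANGE_HZ[1] - DISPLAY_RANGE_HZ[0]
    out = {
        "mean_abs_dhz": mean_dhz,
        "mean_abs_dppm": mean_dppm,
        "percent_of_f0": mean_dppm * 1e-4,        # ppm -> percent
        "percent_of_display_range": 100.0 * mean_dhz / span,
        "n_pixels": int(both.sum()),
    }
    key = {"ppm": "mean_abs_dppm", "hz": "mean_abs_dhz",
           "percent_of_f0": "percent_of_f0",
           "percent_of_display_range": "percent_of_display_range"}
    if mode not in key:
        raise ValueError(f"unknown mode {mode!r}; choose from {sorted(key)}")
    out["mode"] = mode
    out["value"] = out[key[mode]]
    return out
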