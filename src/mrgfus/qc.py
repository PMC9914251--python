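"""MRI-compatibility quality metrics: Rician-corrected SNR and homogeneity.

On magnitude images the background noise is Rician (Rayleigh where there is
no signal), so its SD underestimates the per-channel Gaussian SD by the
factor sqrt(2 - pi/2) = 0.655.  The standard correction folds that factor
into the ratio:

    SNR = 0.655 * mean(signal ROI) / SD(background ROI)

Homogeneity is the normalized max/min contrast of an ROI,
``(1 - (Smax - Smin)/(Smax + Smin)) * 100%``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Roi
__all__ = ["QCResult", "snr", "homogeneity", "slice_profiles"]

#: Printed precision of the Rician correction factor, used for reporting.
RICIAN_FACTOR = 0.655


def snr(image: np.ndarray, signal_roi: Roi, noise_roi: Roi,
        zipper_col: int | None = None) -> float:
    """Rician-corrected SNR of a magnitude volume.

    ``signal_roi`` and ``noise_roi`` are disjoint rectangles; the noise ROI
    must avoid phase-encode artifacts — if the zipper column is known it is
    checked here, otherwise placement is the caller's responsibility.  The SD
    uses the n-1 denominator.  A zero noise SD (degenerate noiseless input)
    raises rather than returning infinity.
    """
    if signal_roi.overlaps(noise_roi):
        raise ValueError("signal and noise ROIs overlap")
    if zipper_col is not None and noise_roi.contains_col(zipper_col):
        raise ValueError(f"noise ROI crosses the zipper column {zipper_col}")
    sig = signal_roi.extract(image)
    noi = noise_roi.extract(image)
    sd = float(np.std(noi, ddof=1))
    if sd == 0:
        raise ValueError("noise ROI has zero SD; SNR undefined")
    return RICIAN_FACTOR * float(np.mean(sig)) / sd


def homogeneity(image: np.ndarray, roi: Roi) -> float:
    """ROI homogeneity in percent: (1 - (Smax-Smin)/(Smax+Smin)) * 100."""
    vals = roi.extract(image)
    smax = float(vals.max())
    smin = float(vals.min())
    if smax + smin <= 0:
        raise ValueError("ROI signal is all zero; homogeneity undefined")
    return float(np.clip((1.0 - (smax - smin) / (smax + smin)) * 100.0, 0.0, 100.0))


@dataclass
class QCResult:
    """Quality metrics for one volume under one hardware condition."""

    condition: str
    snr: float
    homogeneity: float
    S_mean: float
    sigma: float
    S_max: float
    S_min: float

    @classmethod
    def measure(cls, image: np.ndarray, signal_roi: Roi, noise_roi: Roi,
                condition: str = "", zipper_col: int | None = None) -> "QCResult":
        sig = signal_roi.extract(image)
        noi = noise_roi.extract(image)
        return cls(condition=condition,
                   snr=snr(image, signal_roi, noise_roi, zipper_col),
                   homogeneity=homogeneity(image, signal_roi),
                   S_mean=float(np.mean(sig)),
                   sigma=float(np.std(noi, ddof=1)),
                   S_max=float(sig.max()),
                   S_min=float(sig.min()))


def slice_profiles(repeats: list[np.ndarray],
                   signal_roi: Roi,
                   noise_roi: Roi,
                   zipper_col: int | None = None) -> pd.DataFrame:
    """Per-slice SNR and homogeneity, mean +/- SD over repeated acquisitions.

    ``repeats`` is a list of [slice, row, col] magnitude volumes (>= 2 for an
    SD); the same in-plane ROI rectangles are applied to every slice.  Returns
    a DataFrame with columns ``slice, snr_mean, snr_sd, hom_mean, hom_sd``.
    """
    if len(repeats) < 2:
        raise ValueError("need at least 2 repeats for an SD")
    shapes = {r.shape for r in repeats}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent volume shapes across repeats: {shapes}")
    n_slices = repeats[0].shape[0]
    rows = []
    for s in range(n_slices):
        sroi = Roi(s, signal_roi.row_start, signal_roi.row_stop,
                   signal_roi.col_start, signal_roi.col_stop)
        nroi = Roi(s, noise_roi.row_start, noise_roi.row_stop,
                   noise_roi.col_start, noise_roi.col_stop)
        snrs = [snr(r, sroi, nroi, zipper_col) for r in repeats]
        homs = [homogeneity(r, sroi) for r in repeats]
        rows.append({"slice": s,
                     "snr_mean": float(np.mean(snrs)),
                     "snr_sd": float(np.std(snrs, ddof=1)),
                     "hom_mean": float(np.mean(homs)),
                     "hom_sd": float(np.std(homs, ddof=1))})
    return pd.DataFrame(rows)
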