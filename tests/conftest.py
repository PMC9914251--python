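import numpy as np
import pytest

import mrgfus as m


@pytest.fixture
def meta_300():
    """Thermometry-style acquisition at f0 = 300 MHz, TE = 10 ms, 1 frame."""
    return m.AcquisitionMeta(TE_ms=10.0, TR_ms=400.0, FA_deg=13.0, B0_T=7.046,
                             f0_MHz=300.0, FOV_mm=(32.0, 32.0), matrix=(32, 32),
                             n_slices=1, timestamp_s=(0.0,))


def make_meta(n_frames=2, shape=(1, 32, 32), te_ms=10.0, cadence_s=55.0,
              fov_mm=32.0):
    return m.AcquisitionMeta(
        TE_ms=te_ms, TR_ms=400.0, FA_deg=13.0, B0_T=7.046, f0_MHz=300.0,
        FOV_mm=(fov_mm, fov_mm), matrix=shape[1:], n_slices=shape[0],
        timestamp_s=tuple(np.arange(n_frames) * cadence_s))


@pytest.fixture
def small_phantom():
    """32x32 single-slice agar disk, 1 mm in-plane spacing."""
    return m.default_phantom((1, 32, 32), voxel_spacing_mm=(2.5, 1.0, 1.0))


@pytest.fixture
def ramp_hold_setup(small_phantom):
    """Bioheat-driven focal heating truth on the small phantom, 35 frames."""
    n = 35
    meta = make_meta(n_frames=n)
    params = m.calibrate()
    state = m.run_protocol(params, hold_s=1800.0, rng=0)
    truth = m.heating_truth_from_bioheat(state, small_phantom, meta,
                                         focus_voxel=(0, 16, 16),
                                         lateral_fwhm_mm=1.5,
                                         axial_fwhm_mm=7.3)
    return small_phantom, truth, meta, state
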