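"""PRF thermometry on a synthetic heated phantom, compared to a probe.

Builds a bioheat-driven hyperthermia series (8 °C ramp-hold at the focus),
adds channel noise at the with-transducer image SNR (~66), reconstructs the
temperature maps, and compares the hot-spot trace against a noiseless probe
reading of the true temperature.
"""

import numpy as np

import mrgfus as m

phantom = m.default_phantom((1, 32, 32), voxel_spacing_mm=(2.5, 1.0, 1.0))
meta = m.AcquisitionMeta(TE_ms=10.0, TR_ms=400.0, FA_deg=13.0, B0_T=7.046,
                         f0_MHz=300.0, FOV_mm=(32.0, 32.0), matrix=(32, 32),
                         n_slices=1, timestamp_s=tuple(np.arange(35) * 55.0))

state = m.run_protocol(m.calibrate(), hold_s=1800.0, feedback_noise_sd_C=0.2,
                       rng=0)
truth = m.heating_truth_from_bioheat(state, phantom, meta,
                                     focus_voxel=(0, 16, 16))

signal = m.spoiled_gre_signal(1.0, 283.0, 60.0, meta)
series = m.synthesize_series(phantom, truth,
                             m.NoiseSpec(sigma=signal / 66.0), meta, rng=1)

cfg = m.ThermometryConfig(f0_MHz=300.0, TE_ms=10.0,
                          drift_roi=m.Roi(0, 6, 9, 14, 18))
temps = m.reconstruct_series(series, cfg)
trace = m.hotspot_trace(temps, voxel=(0, 16, 16))        # absolute, T_ref=37

probe = m.ProbeLog(state.time_s, state.temp_C)
comp = m.compare_to_probe(trace, probe)

inside = phantom.label_map == 1
print(f"peak reconstructed dT:      {np.nanmax(temps.dT_C[:, inside]):.2f} °C")
print(f"hot-spot at end of hold:    {trace.temp_C[-1]:.2f} °C")
print(f"max PRF-vs-probe mismatch:  {comp['max_abs_discrepancy_C']:.2f} °C "
      f"(at t = {comp['at_time_s']:.0f} s)")
# The mismatch is the thermometric error at realistic noise: it should stay
# well below the 1 °C precision target of the method.
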