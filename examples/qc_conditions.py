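"""Image-quality ladder across the four hardware conditions.

Reproduces the qualitative MRI-compatibility finding: installing and driving
the ultrasound hardware degrades image SNR monotonically (the absolute SNRs
are scanner-specific; the ordering is the reproducible content).
"""

import mrgfus as m

phantom = m.default_phantom((1, 64, 64))
meta = m.AcquisitionMeta(TE_ms=10.0, TR_ms=400.0, FA_deg=13.0, B0_T=7.046,
                         f0_MHz=300.0, FOV_mm=(40.0, 40.0), matrix=(64, 64),
                         n_slices=1, timestamp_s=(0.0,))
truth = m.GroundTruth.zeros(1, phantom.shape)

signal_roi = m.Roi(0, 24, 40, 24, 40)
noise_roi = m.Roi(0, 0, 10, 0, 10)

print(f"{'condition':<26} {'SNR':>8} {'homogeneity %':>14}")
for name, spec in m.condition_ladder(phantom).items():
    series = m.synthesize_series(phantom, truth, spec, meta, rng=0)
    img = series.magnitude[0]
    print(f"{name:<26} {m.snr(img, signal_roi, noise_roi):8.1f} "
          f"{m.homogeneity(img, signal_roi):14.1f}")
# SNR falls from condition (a) to (d) as the hardware adds noise pickup and
# artifacts; homogeneity stays high because the ROI avoids the artifacts.
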