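"""Focal-spot characterization of the 11x11 matrix array at (0,0,5) mm.

Computes geometric focusing delays, evaluates the Rayleigh-Sommerfeld field
on axial and lateral lines, and reports the -6 dB focal widths plus the duty
cycle of the maximal burst timing.
"""

import mrgfus as m

geom = m.ArrayGeometry()  # 11x11, 909 um pitch, 960 kHz, 1540 m/s
print(f"aperture: {geom.aperture_mm[0]:.2f} x {geom.aperture_mm[1]:.2f} mm, "
      f"wavelength {geom.wavelength_mm:.3f} mm")

metrics = m.characterize_focus(geom, (0.0, 0.0, 5.0), step_mm=0.01)
print(f"on-axis pressure peak at z = {metrics['z_peak_mm']:.2f} mm "
      "(proximal of the 5 mm geometric focus, as expected for a")
print("  strongly focused aperture with spherical spreading)")
print(f"lateral -6 dB width: {metrics['lateral_fwhm_mm']:.2f} mm")
print(f"axial   -6 dB width: {metrics['axial_fwhm_mm']:.2f} mm")

timing = m.PulseTiming(burst_us=50.0, prf_hz=1000.0)
print(f"duty cycle at maximal timing: {timing.duty_cycle:.3f}")
# The lateral width lands close to the device's 1.5 mm figure; the axial
# width of this free-field model comes out shorter than the printed 7.3 mm.
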